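"""Synthetic endonucleolytic-cleavage experiment generator.

Emulates the data-generating process behind a multi-condition, multi-
replicate ribosome-profiling + RNA-seq experiment in which a treatment
activates an endonuclease:

* motif-specific cleavage — per transcript copy, each candidate motif site
  is cut independently with a fixed probability (memoryless Bernoulli
  model; presets for a UU/UA-specific nuclease and a generic
  pyrimidine-specific nuclease);
* global mRNA loss with transcriptional compensation — treated copy
  numbers are scaled down by a loss fraction while an induced gene subset
  is multiplied up, so induced genes rise *relatively* even when their
  absolute abundance falls;
* translation on intact mRNAs — main-ORF loading proportional to
  abundance x TE, with a configurable initiation peak at the first codon,
  3-nt periodicity, and probabilistic uORF initiation for uORF-bearing
  genes (the knob an ISR-like condition turns down);
* re-initiation on 3' cleavage fragments — scanning ribosomes pick the
  first available ORF on a fragment, a fraction of fragment-borne
  footprints stalls at the last complete codon before the fragment 3' end;
* sequencing — footprint 5' ends are P-site minus a fixed offset (12 nt),
  read lengths 26-32 nt; RNA-seq counts are multinomial over CDS-overlap
  mass of intact copies and surviving fragments.

The generator returns (and optionally writes) the complete input bundle
plus a ground-truth record sufficient for parameter-recovery tests.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field, asdict
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .annotation import (
    DEFAULT_START_CODONS,
    STOP_CODONS,
    TranscriptModel,
    TranscriptomeSet,
    UORFAnnotation,
    as_rna,
    first_orf_on_fragment,
    write_transcript_table,
)
from .psites import ALIGNMENT_COLUMNS, DEFAULT_PSITE_OFFSET

RNA_BASES = np.array(list("ACGU"))


# ---------------------------------------------------------------------------
# Cleavage model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CleavageModel:
    """Motif-weighted endonucleolytic cleavage propensities.

    ``motif_weights`` maps k-mers (k <= 2) to relative cleavage propensity;
    a candidate site immediately 3' of a matched motif is cut with
    probability ``per_site_probability * weight / max(weights)``.
    """

    motif_weights: Mapping[str, float]
    per_site_probability: float
    name: str = "custom"

    def __post_init__(self) -> None:
        if not self.motif_weights:
            raise ValueError("motif_weights must be non-empty")
        weights = {as_rna(m): float(w) for m, w in self.motif_weights.items()}
        for m, w in weights.items():
            if not 1 <= len(m) <= 2:
                raise ValueError(f"motif {m!r}: only k<=2 motifs supported")
            if w < 0:
                raise ValueError(f"motif {m!r}: negative weight")
        if max(weights.values()) <= 0:
            raise ValueError("at least one motif weight must be positive")
        if not 0 <= self.per_site_probability <= 1:
            raise ValueError("per_site_probability must lie in [0, 1]")
        object.__setattr__(self, "motif_weights", weights)

    @classmethod
    def rnasel_like(cls, per_site_probability: float = 0.02) -> "CleavageModel":
        """UU/UA dinucleotide specificity (2-5A-activated endonuclease)."""
        return cls({"UU": 1.0, "UA": 1.0}, per_site_probability, "rnasel_like")

    @classmethod
    def rnasea_like(cls, per_site_probability: float = 0.02) -> "CleavageModel":
        """Pyrimidine (U/C) mononucleotide specificity (generic RNase)."""
        return cls({"U": 1.0, "C": 1.0}, per_site_probability, "rnasea_like")

    def to_dict(self) -> dict:
        return {
            "motif_weights": dict(self.motif_weights),
            "per_site_probability": self.per_site_probability,
            "name": self.name,
        }


def find_cleavage_sites(
    sequence: str, model: CleavageModel
) -> Tuple[np.ndarray, np.ndarray]:
    """Candidate cut positions and their per-site cut probabilities.

    A motif match at positions ``[i, i+k)`` yields a cut point ``i + k``
    (immediately 3' of the motif; a cut at position c severs the backbone
    between c-1 and c).  Overlapping matches each contribute a candidate.
    Deterministic given sequence and model.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    seq = as_rna(sequence)
    wmax = max(model.motif_weights.values())
    positions: List[int] = []
    probs: List[float] = []
    for i in range(len(seq)):
        for motif, w in model.motif_weights.items():
            if w > 0 and seq.startswith(motif, i):
                positions.append(i + len(motif))
                probs.append(model.per_site_probability * w / wmax)
    order = np.argsort(positions, kind="stable")
    return np.asarray(positions, dtype=np.int64)[order], np.asarray(probs)[order]


# ---------------------------------------------------------------------------
# Fragmentation
# ---------------------------------------------------------------------------


@dataclass
class FragmentPool:
    """Per-transcript intact copy numbers and cleavage fragments.

    ``fragments[tid]`` lists ``(start, end, copies)`` in transcript
    coordinates (surviving decay, when applied).
    """

    intact: Dict[str, int] = field(default_factory=dict)
    fragments: Dict[str, List[Tuple[int, int, int]]] = field(default_factory=dict)

    def nucleotide_mass(self, transcriptome: TranscriptomeSet) -> float:
        total = 0.0
        for tid, n in self.intact.items():
            total += n * transcriptome[tid].length
        for tid, frags in self.fragments.items():
            total += sum((e - s) * c for s, e, c in frags)
        return total


def simulate_fragmentation(
    transcriptome: TranscriptomeSet,
    abundances: Mapping[str, int],
    model: CleavageModel,
    rng: np.random.Generator,
    decay_fraction: float = 0.0,
    resistant: Iterable[str] = (),
) -> FragmentPool:
    """Cut each transcript copy independently at each candidate site.

    Every copy of a transcript is cut at each candidate site with that
    site's probability; the resulting fragments inherit transcript
    coordinates.  Before decay, nucleotide mass is conserved exactly.
    ``decay_fraction`` then removes each fragment copy independently
    (intact copies are not decayed here; net loss of intact mRNA is the
    caller's abundance scaling).  Transcripts in ``resistant`` are never
    cut, emulating motif-poor cleavage-resistant mRNAs.
    """
    if not 0 <= decay_fraction < 1:
        raise ValueError("decay_fraction must lie in [0, 1)")
    resistant = set(resistant)
    pool = FragmentPool()
    for tid, n in abundances.items():
        n = int(n)
        if n < 0:
            raise ValueError(f"{tid}: negative abundance")
        if n == 0:
            pool.intact[tid] = 0
            continue
        tx = transcriptome[tid]
        if tid in resistant or model.per_site_probability == 0:
            pool.intact[tid] = n
            continue
        seq = transcriptome.sequence(tid)
        sites, probs = find_cleavage_sites(seq, model)
        keep = sites < tx.length  # a cut 3' of the last base severs nothing
        sites, probs = sites[keep], probs[keep]
        if sites.size == 0:
            pool.intact[tid] = n
            continue
        hits = rng.random((n, sites.size)) < probs
        ncuts = hits.sum(axis=1)
        pool.intact[tid] = int((ncuts == 0).sum())
        if (ncuts > 0).any():
            counter: Dict[Tuple[int, int], int] = {}
            for row in np.flatnonzero(ncuts):
                cuts = sites[hits[row]]
                bounds = np.concatenate(([0], cuts, [tx.length]))
                for a, b in zip(bounds[:-1], bounds[1:]):
                    if b > a:
                        counter[(int(a), int(b))] = counter.get((int(a), int(b)), 0) + 1
            frags = []
            for (a, b), c in sorted(counter.items()):
                if decay_fraction > 0:
                    c = int(rng.binomial(c, 1.0 - decay_fraction))
                if c > 0:
                    frags.append((a, b, c))
            if frags:
                pool.fragments[tid] = frags
    return pool


# ---------------------------------------------------------------------------
# Configuration and truth
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic cleavage experiment.

    Defaults describe the reference design: 2,000 genes, three control and
    three treated replicates, UU/UA-specific cleavage at per-site
    probability 0.02, 90% global mRNA loss with 20x transcriptional
    induction of 5% of genes, fragment re-initiation probability 0.3, and
    two million footprints and RNA-seq fragments per sample.
    """

    n_genes: int = 2000
    replicates_per_condition: int = 3
    conditions: Tuple[str, ...] = ("control", "treated")
    treated_conditions: Tuple[str, ...] = ("treated",)

    # transcript geometry (nt / codons, uniform ranges, stop codon included)
    utr5_length_range: Tuple[int, int] = (60, 200)
    cds_codons_range: Tuple[int, int] = (120, 400)
    utr3_length_range: Tuple[int, int] = (60, 250)

    # abundance: log-normal copy numbers with the given mean
    abundance_mean: float = 150.0
    abundance_sigma: float = 1.0

    global_loss_fraction: float = 0.9
    induced_gene_fraction: float = 0.05
    induction_factor: float = 20.0
    induced_genes: Optional[Tuple[str, ...]] = None  # explicit override

    te_sigma: float = 0.35
    te_shift_genes: Mapping[str, float] = field(default_factory=dict)

    uorf_gene_fraction: float = 0.2
    uorf_genes: Optional[Tuple[str, ...]] = None
    uorf_codons_range: Tuple[int, int] = (4, 9)
    p_uorf_initiation: Union[float, Mapping[str, float]] = 0.8

    cleavage: CleavageModel = field(default_factory=CleavageModel.rnasel_like)
    fragment_decay_fraction: float = 0.5
    resistant_genes: Tuple[str, ...] = ()
    p_fragment_reinitiation: float = 0.3
    reinit_te: float = 1.0
    stall_fraction_at_fragment_end: float = 0.2

    background_occupancy: float = 0.01  # uniform noise density rel. to CDS=1
    start_codon_boost: float = 5.0  # initiation-peak weight of an ORF's first codon
    frame_weights: Tuple[float, float, float] = (0.70, 0.15, 0.15)
    read_lengths: Tuple[int, ...] = (26, 27, 28, 29, 30, 31, 32)
    read_length_weights: Tuple[float, ...] = (0.05, 0.10, 0.15, 0.30, 0.20, 0.12, 0.08)
    psite_offset: int = DEFAULT_PSITE_OFFSET

    footprint_depth: int = 2_000_000
    rnaseq_depth: int = 2_000_000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 10:
            raise ValueError("n_genes must be >= 10")
        if self.footprint_depth <= 0 or self.rnaseq_depth <= 0:
            raise ValueError("sequencing depths must be positive")
        for name in (
            "global_loss_fraction",
            "induced_gene_fraction",
            "uorf_gene_fraction",
            "p_fragment_reinitiation",
            "stall_fraction_at_fragment_end",
            "fragment_decay_fraction",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.global_loss_fraction >= 1:
            raise ValueError("global_loss_fraction must be < 1")
        for c, p in self._p_uorf_map().items():
            if not 0 <= p <= 1:
                raise ValueError(f"p_uorf_initiation[{c}]={p} outside [0, 1]")
        if abs(sum(self.frame_weights) - 1) > 1e-9:
            raise ValueError("frame_weights must sum to 1")
        if len(self.read_lengths) != len(self.read_length_weights):
            raise ValueError("read_lengths and read_length_weights length mismatch")

    def _p_uorf_map(self) -> Dict[str, float]:
        if isinstance(self.p_uorf_initiation, Mapping):
            return {c: float(self.p_uorf_initiation.get(c, 0.8)) for c in self.conditions}
        return {c: float(self.p_uorf_initiation) for c in self.conditions}

    def p_uorf(self, condition: str) -> float:
        return self._p_uorf_map()[condition]

    def is_treated(self, condition: str) -> bool:
        return condition in self.treated_conditions

    @property
    def sample_ids(self) -> List[str]:
        return [
            f"{c}_rep{r + 1}"
            for c in self.conditions
            for r in range(self.replicates_per_condition)
        ]

    def sample_condition(self, sample_id: str) -> str:
        return sample_id.rsplit("_rep", 1)[0]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cleavage"] = self.cleavage.to_dict()
        d["te_shift_genes"] = dict(self.te_shift_genes)
        if isinstance(self.p_uorf_initiation, Mapping):
            d["p_uorf_initiation"] = dict(self.p_uorf_initiation)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "cleavage" in d and isinstance(d["cleavage"], Mapping):
            d["cleavage"] = CleavageModel(**d["cleavage"])
        for key in (
            "conditions", "treated_conditions", "utr5_length_range",
            "cds_codons_range", "utr3_length_range", "uorf_codons_range",
            "frame_weights", "read_lengths", "read_length_weights",
            "resistant_genes",
        ):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        for key in ("induced_genes", "uorf_genes"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SimulationTruth:
    """Ground truth of one generated experiment (JSON-serializable)."""

    config: dict
    gene_ids: List[str]
    transcript_ids: List[str]
    abundance: Dict[str, float]  # baseline expected copies per gene
    condition_abundance: Dict[str, Dict[str, float]]  # condition -> gene -> copies
    te: Dict[str, Dict[str, float]]  # condition -> gene -> TE
    te_shift_log2: Dict[str, float]
    induced: List[str]
    uorf_genes: List[str]
    per_sample: Dict[str, dict]  # realized intact/fragment tallies

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str) -> "SimulationTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# Footprint and RNA-seq sampling
# ---------------------------------------------------------------------------

_KIND_ORF, _KIND_NOISE, _KIND_FRAG = 0, 1, 2


def simulate_footprints(
    pool: FragmentPool,
    transcriptome: TranscriptomeSet,
    config: SimulationConfig,
    condition: str,
    rng: np.random.Generator,
    gene_te: Optional[Mapping[str, float]] = None,
    depth: Optional[int] = None,
) -> pd.DataFrame:
    """Sample footprint alignment records from a fragment pool.

    Intact copies load the main ORF (and, for uORF-bearing genes, the uORF
    with the condition's initiation probability) with expected footprint
    counts proportional to copies x TE x ORF length; within an ORF, P-sites
    sit at codon positions with a ``start_codon_boost``-weighted initiation
    peak at the first codon and 3-nt periodicity across frame offsets.
    3' fragments containing CDS or 3'UTR sequence contribute their first
    available ORF with probability ``p_fragment_reinitiation`` (folded into
    the expected weight); ``stall_fraction_at_fragment_end`` of those
    footprints sit at the last complete codon before the fragment 3' end.
    A uniform background of ``background_occupancy`` (relative to CDS
    density 1) covers each expressed transcript.  Records report the read
    5' end = P-site - offset, clipped at 0.
    """
    if condition not in config.conditions:
        raise ValueError(f"unknown condition {condition!r}")
    depth = int(depth if depth is not None else config.footprint_depth)
    p_u = config.p_uorf(condition)
    p_frag = config.p_fragment_reinitiation
    treated = config.is_treated(condition)

    def te_of(tid: str) -> float:
        if gene_te is not None:
            return float(gene_te.get(tid, 1.0))
        shift = config.te_shift_genes.get(transcriptome.gene_of(tid), 0.0)
        return float(2.0 ** shift) if treated else 1.0

    tids: List[str] = []
    kinds: List[int] = []
    weights: List[float] = []
    ostarts: List[int] = []
    ncods: List[int] = []  # transcript length for noise units
    stallpos: List[int] = []

    def add_unit(tid, kind, w, ostart, ncod, stall=-1):
        if w <= 0 or ncod < 1:
            return
        tids.append(tid)
        kinds.append(kind)
        weights.append(w)
        ostarts.append(ostart)
        ncods.append(ncod)
        stallpos.append(stall)

    for tid in transcriptome.models:
        model = transcriptome[tid]
        n_i = pool.intact.get(tid, 0)
        te = te_of(tid)
        if n_i > 0 and te > 0:
            cds_len = model.cds_end - model.cds_start
            main_share = (1.0 - p_u) if model.uorfs else 1.0
            add_unit(tid, _KIND_ORF, n_i * te * main_share * cds_len,
                     model.cds_start, cds_len // 3)
            for u in model.uorfs:
                ulen = u.end - u.start
                add_unit(tid, _KIND_ORF,
                         n_i * te * (p_u / len(model.uorfs)) * ulen,
                         u.start, ulen // 3)
            add_unit(tid, _KIND_NOISE,
                     n_i * te * config.background_occupancy * model.length,
                     0, model.length)
        for (s, e, c) in pool.fragments.get(tid, []):
            if s == 0:
                continue  # 5' fragment retains the cap; no re-initiation modeled
            if e <= model.cds_start:
                continue  # contains neither CDS nor 3'UTR sequence
            orf = first_orf_on_fragment(transcriptome.sequence(tid)[s:e])
            if orf is None:
                continue
            olen = orf.end - orf.start
            if olen < 3:
                continue
            ostart_t = s + orf.start
            n_cod = olen // 3
            last_codon = ostart_t + 3 * max((e - ostart_t) // 3 - 1, 0)
            add_unit(tid, _KIND_FRAG,
                     c * p_frag * config.reinit_te * olen,
                     ostart_t, n_cod, last_codon)

    w = np.asarray(weights, dtype=float)
    if w.size == 0 or w.sum() <= 0:
        raise ValueError("empty library: no translatable material in pool")
    counts = rng.multinomial(depth, w / w.sum())
    reps = np.repeat(np.arange(w.size), counts)
    kind_arr = np.asarray(kinds, dtype=np.int8)[reps]
    ostart_arr = np.asarray(ostarts, dtype=np.int64)
    ncod_arr = np.asarray(ncods, dtype=np.int64)
    stall_arr = np.asarray(stallpos, dtype=np.int64)

    n = reps.size
    psite = np.empty(n, dtype=np.int64)

    orf_mask = kind_arr != _KIND_NOISE
    if orf_mask.any():
        units = reps[orf_mask]
        nc = ncod_arr[units]
        boost = float(config.start_codon_boost)
        u = rng.random(units.size)
        p0 = boost / (boost + nc - 1)
        at_start = u < p0
        rest = np.floor((u - p0) / np.maximum(1.0 - p0, 1e-300) * (nc - 1)).astype(np.int64)
        codon = np.where(at_start, 0, np.clip(1 + rest, 1, np.maximum(nc - 1, 1)))
        frame = rng.choice(3, size=units.size, p=config.frame_weights)
        psite[orf_mask] = ostart_arr[units] + 3 * codon + frame

    noise_mask = ~orf_mask
    if noise_mask.any():
        units = reps[noise_mask]
        psite[noise_mask] = np.floor(
            rng.random(units.size) * ncod_arr[units]
        ).astype(np.int64)

    frag_idx = np.flatnonzero(kind_arr == _KIND_FRAG)
    if frag_idx.size:
        stall = rng.random(frag_idx.size) < config.stall_fraction_at_fragment_end
        sel = frag_idx[stall]
        psite[sel] = stall_arr[reps[sel]]

    five_prime = np.maximum(psite - config.psite_offset, 0)
    read_length = rng.choice(
        np.asarray(config.read_lengths), size=n, p=np.asarray(config.read_length_weights)
    )
    tid_categories = list(dict.fromkeys(tids)) or list(transcriptome.models)
    tid_code_of = {t: i for i, t in enumerate(tid_categories)}
    unit_codes = np.asarray([tid_code_of[t] for t in tids], dtype=np.int64)
    transcript = pd.Categorical.from_codes(unit_codes[reps], categories=tid_categories)
    return pd.DataFrame(
        {
            "transcript_id": transcript,
            "five_prime": five_prime,
            "read_length": read_length,
            "weight": 1.0,
        }
    )


def simulate_rnaseq(
    pool: FragmentPool,
    transcriptome: TranscriptomeSet,
    depth: int,
    rng: np.random.Generator,
) -> pd.Series:
    """Multinomial CDS-assigned RNA-seq counts per gene.

    Gene weights are the summed CDS-overlap length of intact copies and
    surviving fragments, emulating CDS fragment counting of a paired-end
    library.  Column sum equals ``depth``.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    genes: List[str] = []
    weights: List[float] = []
    for tid in transcriptome.models:
        model = transcriptome[tid]
        w = pool.intact.get(tid, 0) * (model.cds_end - model.cds_start)
        for (s, e, c) in pool.fragments.get(tid, []):
            ov = min(e, model.cds_end) - max(s, model.cds_start)
            if ov > 0:
                w += c * ov
        genes.append(model.gene_id)
        weights.append(float(w))
    w = np.asarray(weights)
    if w.sum() <= 0:
        raise ValueError("empty library: no CDS-overlapping material")
    counts = rng.multinomial(int(depth), w / w.sum())
    return pd.Series(counts, index=pd.Index(genes, name="gene_id"))


# ---------------------------------------------------------------------------
# Whole-experiment generation
# ---------------------------------------------------------------------------


@dataclass
class SimulationResult:
    """In-memory bundle of one generated experiment."""

    transcriptome: TranscriptomeSet
    truth: SimulationTruth
    footprints: Dict[str, pd.DataFrame]  # sample -> alignment frame
    rnaseq: pd.DataFrame  # genes x samples
    conditions: Dict[str, str]  # sample -> condition


def _random_transcriptome(config: SimulationConfig, rng: np.random.Generator):
    """Random transcript models and sequences with implanted main ORFs and
    (for a gene subset) uORFs using AUG or near-cognate starts."""
    n = config.n_genes
    gene_ids = [f"g{i:04d}" for i in range(n)]
    tx_ids = [f"tx{i:04d}" for i in range(n)]
    if config.uorf_genes is not None:
        uorf_set = set(config.uorf_genes)
    else:
        k = int(round(config.uorf_gene_fraction * n))
        uorf_set = set(rng.choice(gene_ids, size=k, replace=False)) if k else set()
    start_choices = sorted(DEFAULT_START_CODONS)
    models, sequences = [], {}
    for gid, tid in zip(gene_ids, tx_ids):
        u5 = int(rng.integers(*config.utr5_length_range))
        ncod = int(rng.integers(*config.cds_codons_range))
        u3 = int(rng.integers(*config.utr3_length_range))
        cds_start, cds_end = u5, u5 + 3 * ncod
        length = cds_end + u3
        seq = rng.choice(RNA_BASES, size=length)
        seq[cds_start : cds_start + 3] = list("AUG")
        seq[cds_end - 3 : cds_end] = list("UAA")
        uorfs = []
        if gid in uorf_set:
            ucod = int(rng.integers(*config.uorf_codons_range))
            lo = config.psite_offset + 3
            hi = cds_start - 3 * ucod - 3
            if hi > lo:
                ustart = int(rng.integers(lo, hi))
                uend = ustart + 3 * ucod
                codon = start_choices[int(rng.integers(len(start_choices)))]
                seq[ustart : ustart + 3] = list(codon)
                seq[uend - 3 : uend] = list("UAA")
                # scrub accidental in-frame stops so the scanned ORF matches
                for p in range(ustart + 3, uend - 3, 3):
                    if "".join(seq[p : p + 3]) in STOP_CODONS:
                        seq[p + 2] = "C"
                uorfs.append(UORFAnnotation(ustart, uend, codon))
        models.append(
            TranscriptModel(tid, gid, length, cds_start, cds_end, uorfs=uorfs)
        )
        sequences[tid] = "".join(seq)
    transcriptome = TranscriptomeSet(models, sequences)
    return transcriptome, gene_ids, tx_ids, sorted(uorf_set)


def generate_experiment(
    config: SimulationConfig,
    out_dir: Optional[str] = None,
) -> SimulationResult:
    """Generate a complete synthetic experiment, optionally writing files.

    The bundle comprises a transcriptome (FASTA + transcript table),
    per-sample footprint alignments (BED6 in transcript space), an RNA-seq
    count table, and the ground truth (JSON) plus the configuration (YAML).
    Identical seeds give byte-identical outputs.
    """
    root = np.random.SeedSequence(config.rng_seed)
    seq_ss, abund_ss, sample_ss = root.spawn(3)
    rng = np.random.default_rng(seq_ss)

    transcriptome, gene_ids, tx_ids, uorf_genes = _random_transcriptome(config, rng)
    tx_of = dict(zip(gene_ids, tx_ids))

    rng_a = np.random.default_rng(abund_ss)
    mu = np.log(config.abundance_mean) - config.abundance_sigma**2 / 2
    abundance = rng_a.lognormal(mu, config.abundance_sigma, size=config.n_genes)

    if config.induced_genes is not None:
        induced = list(config.induced_genes)
    else:
        k = int(round(config.induced_gene_fraction * config.n_genes))
        induced = sorted(rng_a.choice(gene_ids, size=k, replace=False)) if k else []
    induced_set = set(induced)

    te_base = rng_a.lognormal(0.0, config.te_sigma, size=config.n_genes)
    shift = {g: float(config.te_shift_genes.get(g, 0.0)) for g in gene_ids}

    condition_abundance: Dict[str, Dict[str, float]] = {}
    te_truth: Dict[str, Dict[str, float]] = {}
    for cond in config.conditions:
        treated = config.is_treated(cond)
        ca, tt = {}, {}
        for g, a, t in zip(gene_ids, abundance, te_base):
            fac = 1.0
            if treated:
                fac *= 1.0 - config.global_loss_fraction
                if g in induced_set:
                    fac *= config.induction_factor
            ca[g] = float(a * fac)
            tt[g] = float(t * 2.0 ** shift[g]) if treated else float(t)
        condition_abundance[cond] = ca
        te_truth[cond] = tt

    sample_children = sample_ss.spawn(len(config.sample_ids))
    footprints: Dict[str, pd.DataFrame] = {}
    rnaseq_cols: Dict[str, pd.Series] = {}
    per_sample: Dict[str, dict] = {}
    conditions_map: Dict[str, str] = {}
    for sid, child in zip(config.sample_ids, sample_children):
        cond = config.sample_condition(sid)
        conditions_map[sid] = cond
        srng = np.random.default_rng(child)
        copies = {
            tx_of[g]: int(srng.poisson(condition_abundance[cond][g]))
            for g in gene_ids
        }
        if config.is_treated(cond) and config.cleavage.per_site_probability > 0:
            pool = simulate_fragmentation(
                transcriptome,
                copies,
                config.cleavage,
                srng,
                decay_fraction=config.fragment_decay_fraction,
                resistant={tx_of[g] for g in config.resistant_genes},
            )
        else:
            pool = FragmentPool(intact=dict(copies))
        gene_te = {tx_of[g]: te_truth[cond][g] for g in gene_ids}
        footprints[sid] = simulate_footprints(
            pool, transcriptome, config, cond, srng, gene_te=gene_te
        )
        rnaseq_cols[sid] = simulate_rnaseq(
            pool, transcriptome, config.rnaseq_depth, srng
        )
        per_sample[sid] = {
            "condition": cond,
            "intact_copies": {t: int(c) for t, c in pool.intact.items()},
            "fragment_copies": {
                t: int(sum(c for _, _, c in frags))
                for t, frags in pool.fragments.items()
            },
            "total_intact_mass": float(
                sum(pool.intact.get(t, 0) * transcriptome[t].length for t in tx_ids)
            ),
        }

    rnaseq = pd.DataFrame(rnaseq_cols)
    truth = SimulationTruth(
        config=config.to_dict(),
        gene_ids=gene_ids,
        transcript_ids=tx_ids,
        abundance={g: float(a) for g, a in zip(gene_ids, abundance)},
        condition_abundance=condition_abundance,
        te=te_truth,
        te_shift_log2=shift,
        induced=sorted(induced_set),
        uorf_genes=uorf_genes,
        per_sample=per_sample,
    )
    result = SimulationResult(transcriptome, truth, footprints, rnaseq, conditions_map)
    if out_dir is not None:
        write_experiment(result, out_dir)
    return result


def write_experiment(result: SimulationResult, out_dir: str) -> None:
    """Write the experiment bundle: FASTA, transcript table, per-sample
    footprint BED6 files, RNA-seq counts TSV, truth JSON, config YAML."""
    import yaml

    os.makedirs(out_dir, exist_ok=True)
    fp_dir = os.path.join(out_dir, "footprints")
    os.makedirs(fp_dir, exist_ok=True)

    with open(os.path.join(out_dir, "transcripts.fa"), "w") as fh:
        for tid in result.transcriptome.models:
            seq = result.transcriptome.sequence(tid)
            fh.write(f">{tid}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")

    write_transcript_table(
        result.transcriptome, os.path.join(out_dir, "transcript_table.tsv")
    )

    for sid, df in result.footprints.items():
        length_of = {t: result.transcriptome[t].length
                     for t in result.transcriptome.models}
        lengths = df["transcript_id"].astype(str).map(length_of).to_numpy(dtype=np.int64)
        bed = pd.DataFrame(
            {
                "transcript_id": df["transcript_id"].astype(str),
                "start": df["five_prime"],
                "end": np.minimum(
                    df["five_prime"].to_numpy() + df["read_length"].to_numpy(), lengths
                ),
                "read_id": [f"r{i}" for i in range(len(df))],
                "score": df["weight"],
                "strand": "+",
            }
        )
        bed.to_csv(os.path.join(fp_dir, f"{sid}.bed"), sep="\t", index=False, header=False)

    result.rnaseq.rename_axis("gene_id").to_csv(
        os.path.join(out_dir, "rnaseq_counts.tsv"), sep="\t"
    )
    result.truth.to_json(os.path.join(out_dir, "truth.json"))
    with open(os.path.join(out_dir, "config.yaml"), "w") as fh:
        yaml.safe_dump(result.truth.config, fh, sort_keys=True)
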