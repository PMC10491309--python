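"""Transcript models, region partitioning, and ORF scanning.

All coordinates are 0-based, half-open, and live in transcript space
(position 0 is the transcript 5' end).  The CDS interval includes the stop
codon, so the 3'UTR begins immediately after the stop and the three regions
``[0, cds_start)``, ``[cds_start, cds_end)``, ``[cds_end, length)`` tile the
transcript exactly.  ``T`` and ``U`` are treated as equivalent on input so
that DNA and RNA FASTA files are interchangeable.
"""

from __future__ import annotations

import os
from collections import namedtuple
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import pandas as pd

STOP_CODONS = frozenset({"UAA", "UAG", "UGA"})
#: Default start-codon set for uORF scanning: AUG plus the near-cognate
#: codons CUG and GUG, which initiate uORFs on interferon-induced mRNAs.
DEFAULT_START_CODONS = frozenset({"AUG", "CUG", "GUG"})

_VALID_BASES = set("ACGU")


def as_rna(sequence: str) -> str:
    """Uppercase a nucleotide string and convert T to U."""
    return sequence.upper().replace("T", "U")


OrfHit = namedtuple("OrfHit", ["start", "end", "start_codon", "open_ended"])


@dataclass(frozen=True)
class UORFAnnotation:
    """An upstream ORF in transcript coordinates (end exclusive).

    The uORF must begin in the 5'UTR of its owning transcript; it may end
    inside the CDS (the ATF4-style overlapping configuration).
    """

    start: int
    end: int
    start_codon: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"uORF start {self.start} must precede end {self.end}")
        if (self.end - self.start) % 3 != 0:
            raise ValueError(
                f"uORF [{self.start},{self.end}) length is not a multiple of 3"
            )
        codon = as_rna(self.start_codon)
        if len(codon) != 3 or not set(codon) <= _VALID_BASES:
            raise ValueError(f"invalid uORF start codon {self.start_codon!r}")
        object.__setattr__(self, "start_codon", codon)


@dataclass
class TranscriptModel:
    """Region structure of one transcript: 5'UTR, CDS (incl. stop), 3'UTR."""

    transcript_id: str
    gene_id: str
    length: int
    cds_start: int
    cds_end: int
    uorfs: List[UORFAnnotation] = field(default_factory=list)
    complete_cds: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.cds_start < self.cds_end <= self.length):
            raise ValueError(
                f"{self.transcript_id}: CDS [{self.cds_start},{self.cds_end}) "
                f"does not fit in transcript of length {self.length}"
            )
        if self.complete_cds and (self.cds_end - self.cds_start) % 3 != 0:
            raise ValueError(
                f"{self.transcript_id}: complete CDS length "
                f"{self.cds_end - self.cds_start} is not a multiple of 3"
            )
        for u in self.uorfs:
            if u.start >= self.cds_start:
                raise ValueError(
                    f"{self.transcript_id}: uORF at {u.start} does not begin "
                    f"in the 5'UTR (cds_start={self.cds_start})"
                )
            if u.end > self.length:
                raise ValueError(
                    f"{self.transcript_id}: uORF end {u.end} exceeds length"
                )

    @property
    def utr5(self) -> Tuple[int, int]:
        return (0, self.cds_start)

    @property
    def cds(self) -> Tuple[int, int]:
        return (self.cds_start, self.cds_end)

    @property
    def utr3(self) -> Tuple[int, int]:
        return (self.cds_end, self.length)


def partition_regions(
    model: TranscriptModel,
) -> Tuple[Tuple[int, int], Tuple[int, int], Tuple[int, int]]:
    """Return the (utr5, cds, utr3) intervals of a transcript.

    Empty intervals are permitted (cds_start == 0 or cds_end == length).
    The three intervals tile ``[0, length)`` without overlap.
    """
    return model.utr5, model.cds, model.utr3


class TranscriptomeSet:
    """A keyed collection of transcript models with optional sequences.

    When ``single_isoform`` is set, at most one model per gene is allowed,
    mirroring a reduced single-isoform transcriptome (RefSeq Select/MANE
    style) used for region-level footprint analysis.
    """

    def __init__(
        self,
        models: Iterable[TranscriptModel],
        sequences: Optional[Dict[str, str]] = None,
        single_isoform: bool = True,
    ) -> None:
        self.models: Dict[str, TranscriptModel] = {}
        for m in models:
            if m.transcript_id in self.models:
                raise ValueError(f"duplicate transcript_id {m.transcript_id!r}")
            self.models[m.transcript_id] = m
        if single_isoform:
            seen: Dict[str, str] = {}
            for m in self.models.values():
                if m.gene_id in seen:
                    raise ValueError(
                        f"gene {m.gene_id!r} has multiple isoforms "
                        f"({seen[m.gene_id]}, {m.transcript_id}) in a "
                        "single-isoform set"
                    )
                seen[m.gene_id] = m.transcript_id
        self.single_isoform = single_isoform
        self.sequences: Optional[Dict[str, str]] = None
        if sequences is not None:
            self.sequences = {k: as_rna(v) for k, v in sequences.items()}
            for tid, model in self.models.items():
                seq = self.sequences.get(tid)
                if seq is not None and len(seq) != model.length:
                    raise ValueError(
                        f"{tid}: sequence length {len(seq)} != annotated "
                        f"length {model.length}"
                    )

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self.models.values())

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.models

    def __getitem__(self, transcript_id: str) -> TranscriptModel:
        return self.models[transcript_id]

    def sequence(self, transcript_id: str) -> str:
        if self.sequences is None or transcript_id not in self.sequences:
            raise KeyError(f"no sequence available for {transcript_id!r}")
        return self.sequences[transcript_id]

    def gene_of(self, transcript_id: str) -> str:
        return self.models[transcript_id].gene_id


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

TABLE_COLUMNS = ["transcript_id", "gene_id", "length", "cds_start", "cds_end"]


def _parse_uorf_fields(row: pd.Series) -> List[UORFAnnotation]:
    starts = row.get("uorf_starts")
    if starts is None or (isinstance(starts, float) and pd.isna(starts)) or starts == "":
        return []
    ends = row["uorf_ends"]
    codons = row["uorf_codons"]
    # mixed empty/filled columns parse as float; accept "80" and "80.0"
    s_list = [int(float(x)) for x in str(starts).split(",")]
    e_list = [int(float(x)) for x in str(ends).split(",")]
    c_list = [str(x) for x in str(codons).split(",")]
    if not (len(s_list) == len(e_list) == len(c_list)):
        raise ValueError(
            f"{row['transcript_id']}: uORF columns have mismatched lengths"
        )
    return [
        UORFAnnotation(s, e, c) for s, e, c in zip(s_list, e_list, c_list)
    ]


def _load_transcript_table(path: str, single_isoform: bool) -> TranscriptomeSet:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str, "gene_id": str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"cannot parse transcript table {path}: {exc}") from exc
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"transcript table {path} lacks columns {missing}")
    models = []
    for i, row in df.iterrows():
        try:
            models.append(
                TranscriptModel(
                    transcript_id=row["transcript_id"],
                    gene_id=row["gene_id"],
                    length=int(row["length"]),
                    cds_start=int(row["cds_start"]),
                    cds_end=int(row["cds_end"]),
                    uorfs=_parse_uorf_fields(row),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path} line {i + 2}: {exc}") from exc
    return TranscriptomeSet(models, single_isoform=single_isoform)


def _project_gtf_transcript(exons, cds_parts, strand: str):
    """Project genomic CDS coordinates onto exon-concatenated transcript
    coordinates.  Input intervals are 1-based inclusive (GTF); output is
    0-based half-open in transcript space."""
    exons = sorted(exons)  # genomic order
    length = sum(e - s + 1 for s, e in exons)

    def to_tx(gpos: int) -> int:
        offset = 0
        for s, e in exons:
            if s <= gpos <= e:
                plus = offset + (gpos - s)
                return plus if strand == "+" else length - 1 - plus
            offset += e - s + 1
        raise ValueError(f"genomic position {gpos} outside exons")

    g_lo = min(s for s, _ in cds_parts)
    g_hi = max(e for _, e in cds_parts)
    if strand == "+":
        cds_start, cds_last = to_tx(g_lo), to_tx(g_hi)
    else:
        cds_start, cds_last = to_tx(g_hi), to_tx(g_lo)
    return length, cds_start, cds_last + 1


def _load_gtf(path: str, single_isoform: bool) -> TranscriptomeSet:
    import gffutils

    try:
        db = gffutils.create_db(
            path,
            ":memory:",
            force=True,
            keep_order=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:
        raise ValueError(f"cannot parse GTF {path}: {exc}") from exc

    per_tx: Dict[str, dict] = {}
    for ftype in ("exon", "CDS", "stop_codon"):
        for feat in db.features_of_type(ftype):
            tid = feat.attributes.get("transcript_id", [None])[0]
            if tid is None:
                raise ValueError(f"GTF {path}: {ftype} feature lacks transcript_id")
            rec = per_tx.setdefault(
                tid,
                {"gene": None, "strand": feat.strand, "exons": [], "cds": [],
                 "tags": set()},
            )
            rec["gene"] = feat.attributes.get("gene_id", [tid])[0]
            rec["tags"].update(feat.attributes.get("tag", []))
            if ftype == "exon":
                rec["exons"].append((feat.start, feat.end))
            else:  # CDS or stop_codon both count toward the stop-inclusive CDS
                rec["cds"].append((feat.start, feat.end))

    models = []
    for tid, rec in per_tx.items():
        if not rec["exons"]:
            raise ValueError(f"GTF {path}: transcript {tid} has no exon features")
        if not rec["cds"]:
            continue  # non-coding transcript: no region structure to analyze
        length, cds_start, cds_end = _project_gtf_transcript(
            rec["exons"], rec["cds"], rec["strand"]
        )
        cds_len = cds_end - cds_start
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=rec["gene"],
                length=length,
                cds_start=cds_start,
                cds_end=cds_end,
                complete_cds=(cds_len % 3 == 0),
            )
        )
        models[-1]._tags = rec["tags"]  # kept for isoform selection below

    if single_isoform:
        by_gene: Dict[str, TranscriptModel] = {}
        for m in models:
            prev = by_gene.get(m.gene_id)
            if prev is None:
                by_gene[m.gene_id] = m
                continue
            # prefer the RefSeq Select / MANE tagged isoform, else longest CDS
            def rank(x: TranscriptModel) -> tuple:
                tags = " ".join(getattr(x, "_tags", ())).lower()
                preferred = ("mane" in tags) or ("refseq select" in tags)
                return (preferred, x.cds_end - x.cds_start)

            if rank(m) > rank(prev):
                by_gene[m.gene_id] = m
        models = list(by_gene.values())

    return TranscriptomeSet(models, single_isoform=single_isoform)


def load_annotation(
    path: str,
    format: Optional[str] = None,
    single_isoform: bool = True,
) -> TranscriptomeSet:
    """Load a transcript annotation from a GTF or transcript-table TSV.

    ``format`` is one of ``"gtf"`` or ``"transcript_table"``; when omitted it
    is inferred from the file extension.  GTF genomic coordinates (1-based
    inclusive, Ensembl dialect) are projected to 0-based half-open transcript
    coordinates by exon concatenation, strand-resolved; ``stop_codon``
    features, when present, are folded into the stop-inclusive CDS interval.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format is None:
        format = "gtf" if path.endswith((".gtf", ".gff")) else "transcript_table"
    if format == "gtf":
        return _load_gtf(path, single_isoform)
    if format == "transcript_table":
        return _load_transcript_table(path, single_isoform)
    raise ValueError(f"unknown annotation format {format!r}")


def write_transcript_table(transcriptome: TranscriptomeSet, path: str) -> None:
    """Write a TranscriptomeSet as a transcript-table TSV (round-trippable)."""
    rows = []
    for m in transcriptome:
        rows.append(
            {
                "transcript_id": m.transcript_id,
                "gene_id": m.gene_id,
                "length": m.length,
                "cds_start": m.cds_start,
                "cds_end": m.cds_end,
                "uorf_starts": ",".join(str(u.start) for u in m.uorfs),
                "uorf_ends": ",".join(str(u.end) for u in m.uorfs),
                "uorf_codons": ",".join(u.start_codon for u in m.uorfs),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ORF scanning
# ---------------------------------------------------------------------------


def scan_orfs(
    sequence: str,
    start_codons: Iterable[str] = DEFAULT_START_CODONS,
    min_codons: int = 2,
) -> List[OrfHit]:
    """Find all ORFs beginning at any of ``start_codons``.

    Each ORF runs from its start codon to the first in-frame stop codon
    (UAA/UAG/UGA, stop included in the interval).  If no in-frame stop occurs
    before the sequence end the ORF is reported as open-ended, truncated at
    the last complete codon.  Overlapping ORFs are all reported, sorted by
    start position.  ``min_codons`` counts codons including the start codon
    (and the stop, when present); the default of 2 discards bare,
    stop-less single start codons.
    """
    starts = {as_rna(c) for c in start_codons}
    if not starts:
        raise ValueError("start_codons must be non-empty")
    if min_codons < 1:
        raise ValueError("min_codons must be >= 1")
    seq = as_rna(sequence)
    hits: List[OrfHit] = []
    n = len(seq)
    for i in range(n - 2):
        codon = seq[i : i + 3]
        if codon not in starts:
            continue
        j = i
        end = None
        while j + 3 <= n:
            if seq[j : j + 3] in STOP_CODONS and j > i:
                end = j + 3
                break
            j += 3
        if end is None:
            end = i + 3 * ((n - i) // 3)
            open_ended = True
        else:
            open_ended = False
        if (end - i) // 3 >= min_codons:
            hits.append(OrfHit(i, end, codon, open_ended))
    hits.sort(key=lambda h: (h.start, h.end))
    return hits


def first_orf_on_fragment(
    sequence: str,
    start_codons: Iterable[str] = DEFAULT_START_CODONS,
) -> Optional[OrfHit]:
    """Return the first (5'-most) ORF on a cleavage-fragment sequence.

    Models a scanning ribosome that re-initiates at the first available
    start codon on a capped-or-not 3' fragment; returns None if the fragment
    contains no start codon.  A start codon with no downstream in-frame stop
    yields an open-ended ORF running to the fragment end.
    """
    hits = scan_orfs(sequence, start_codons, min_codons=1)
    return hits[0] if hits else None
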