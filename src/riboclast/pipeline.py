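"""End-to-end orchestration: simulate/load -> P-sites -> regions -> stats.

One :class:`RunConfig` (YAML-serializable) drives every stage with a single
root seed; re-running with the same config and seed reproduces the summary
JSON byte for byte.  Each stage's tabular output is written under the run's
output directory, and a machine-readable ``summary.json`` collects the
headline statistics (aggregate UTR:ORF ratios, DE counts, TE categories,
uORF shift, discard tallies).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import metrics, psites, stats, te as te_mod, uorf as uorf_mod
from .annotation import TranscriptomeSet, load_annotation
from .simulate import SimulationConfig, SimulationResult, generate_experiment

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name in its message."""


@dataclass
class RunConfig:
    """Everything one pipeline run needs: inputs (or a simulation block),
    contrast, thresholds, output directory, and the root seed."""

    output_dir: str
    seed: int = 0
    log_level: str = "INFO"
    simulate: Optional[SimulationConfig] = None
    inputs: Optional[dict] = None  # annotation/fasta/footprints/rnaseq_counts/conditions
    contrast: Tuple[str, str] = ("control", "treated")

    psite_offset: int = psites.DEFAULT_PSITE_OFFSET
    calibrate_offset: bool = False
    uorf_overlap_policy: str = "overlap_to_utr"
    min_cds_rpm: float = 1.0
    metagene_window: Tuple[int, int] = (60, 90)
    metagene_min_cds_density: float = 0.5

    alpha: float = stats.DEFAULT_ALPHA
    lfc_threshold: float = stats.DEFAULT_LFC_THRESHOLD
    te_lfc_gate: float = te_mod.DEFAULT_LFC_GATE
    te_padj_gate: float = te_mod.DEFAULT_PADJ_GATE
    te_basemean_gate: float = te_mod.DEFAULT_BASEMEAN_GATE
    te_fold_gate: float = te_mod.DEFAULT_TE_FOLD_GATE
    uorf_score_threshold: float = 5.0
    uorf_min_reads: float = 10.0

    def __post_init__(self) -> None:
        if self.simulate is None and self.inputs is None:
            raise ValueError(
                "config must provide either real-input paths or a simulation block"
            )
        if self.simulate is not None and self.inputs is not None:
            raise ValueError("provide input paths or a simulation block, not both")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "simulate" in raw and raw["simulate"] is not None:
            raw["simulate"] = SimulationConfig.from_dict(raw["simulate"])
        if "contrast" in raw and isinstance(raw["contrast"], list):
            raw["contrast"] = tuple(raw["contrast"])
        for key in ("metagene_window",):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r}: {exc}") from exc

        return wrapper

    return deco


@_stage("inputs")
def _acquire_inputs(config: RunConfig) -> SimulationResult:
    if config.simulate is not None:
        sim = dataclasses.replace(config.simulate, rng_seed=config.seed)
        logger.info("simulating experiment (seed=%d)", config.seed)
        return generate_experiment(sim)
    paths = config.inputs
    transcriptome = load_annotation(paths["annotation"])
    if "fasta" in paths and paths["fasta"]:
        from pyfaidx import Fasta

        fa = Fasta(paths["fasta"])
        transcriptome = TranscriptomeSet(
            list(transcriptome),
            sequences={k: str(fa[k][:]) for k in fa.keys()},
            single_isoform=transcriptome.single_isoform,
        )
    footprints = {
        sid: psites.load_footprints(p) for sid, p in paths["footprints"].items()
    }
    rnaseq = pd.read_csv(paths["rnaseq_counts"], sep="\t", index_col="gene_id")
    conditions = dict(paths["conditions"])
    from .simulate import SimulationTruth

    truth = SimulationTruth(
        config={}, gene_ids=list(rnaseq.index), transcript_ids=[],
        abundance={}, condition_abundance={}, te={}, te_shift_log2={},
        induced=[], uorf_genes=[], per_sample={},
    )
    return SimulationResult(transcriptome, truth, footprints, rnaseq, conditions)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in dependency order; return the summary dict.

    Writes per-stage TSVs, ``summary.json``, and a run log under
    ``config.output_dir``.
    """
    os.makedirs(config.output_dir, exist_ok=True)
    log_path = os.path.join(config.output_dir, "run.log")
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root_logger = logging.getLogger("riboclast")
    root_logger.addHandler(handler)
    root_logger.setLevel(config.log_level)
    summary: dict = {"seed": config.seed, "thresholds": {
        "psite_offset": config.psite_offset,
        "alpha": config.alpha,
        "lfc_threshold": config.lfc_threshold,
        "te_gates": [config.te_lfc_gate, config.te_padj_gate,
                     config.te_basemean_gate, config.te_fold_gate],
    }}
    try:
        bundle = _acquire_inputs(config)
        tx = bundle.transcriptome
        samples = list(bundle.footprints)
        conditions = bundle.conditions
        control_label, treated_label = config.contrast

        tracksets = _stage("psites")(
            lambda: [
                psites.assign_psites(bundle.footprints[s], tx,
                                     offset=config.psite_offset, sample_id=s)
                for s in samples
            ]
        )()
        summary["discarded_psites"] = {t.sample_id: t.discarded for t in tracksets}
        if config.calibrate_offset:
            cal = _stage("psites")(
                lambda: psites.calibrate_psite_offset(
                    pd.concat([bundle.footprints[s] for s in samples]), tx
                )
            )()
            summary["calibrated_offset"] = cal.offset

        region_counts = _stage("regions")(
            lambda: psites.count_regions(tracksets, tx, config.uorf_overlap_policy)
        )()
        rpm = psites.to_rpm(region_counts)
        region_counts.write_tsv(os.path.join(config.output_dir, "region_counts.tsv"))

        ratio_frames = []
        for which in ("utr3", "utr5"):
            ratio_frames.append(
                metrics.utr_orf_ratio(rpm, which=which, scope="aggregate",
                                      min_cds_rpm=config.min_cds_rpm)
            )
        ratios = pd.concat(ratio_frames, ignore_index=True)
        ratios.to_csv(os.path.join(config.output_dir, "utr_orf_ratios.tsv"),
                      sep="\t", index=False)
        summary["aggregate_ratios"] = {
            which: {
                row["sample_id"]: row["ratio"]
                for _, row in ratios[ratios["which"] == which].iterrows()
            }
            for which in ("utr3", "utr5")
        }

        meta_rows = []
        for anchor in ("start_codon", "stop_codon"):
            for ts in tracksets:
                try:
                    prof = metrics.metagene(
                        ts, tx, anchor=anchor, window=config.metagene_window,
                        min_cds_density=config.metagene_min_cds_density,
                    )
                except ValueError:
                    continue
                f = prof.to_frame()
                f["anchor"] = anchor
                f["sample_id"] = ts.sample_id
                meta_rows.append(f)
        if meta_rows:
            pd.concat(meta_rows, ignore_index=True).to_csv(
                os.path.join(config.output_dir, "metagene.tsv"), sep="\t", index=False
            )

        de_rna = _stage("de")(
            lambda: stats.differential_expression(
                bundle.rnaseq, conditions, control_label, treated_label,
                alpha=config.alpha, lfc_threshold=config.lfc_threshold,
            )
        )()
        ribo_cds = region_counts["cds"]
        de_ribo = _stage("de")(
            lambda: stats.differential_expression(
                ribo_cds, conditions, control_label, treated_label,
                alpha=config.alpha, lfc_threshold=config.lfc_threshold,
            )
        )()
        de_rna.to_csv(os.path.join(config.output_dir, "de_rnaseq.tsv"), sep="\t")
        de_ribo.to_csv(os.path.join(config.output_dir, "de_ribo_cds.tsv"), sep="\t")
        summary["de_counts"] = {
            "rna_flag_de": int(de_rna["flag_de"].sum()),
            "rna_up": int(((de_rna["padj"] < config.alpha)
                           & (de_rna["log2fc"] > config.lfc_threshold)).sum()),
            "ribo_flag_de": int(de_ribo["flag_de"].sum()),
        }

        te_stage = _stage("te")
        rna_rpm = bundle.rnaseq * 1e6 / bundle.rnaseq.sum(axis=0)
        ribo_rpm_cds = rpm["cds"]
        te_table = te_stage(lambda: te_mod.compute_te(ribo_rpm_cds, rna_rpm))()
        te_table.rename_axis("gene_id").to_csv(
            os.path.join(config.output_dir, "te_per_sample.tsv"), sep="\t"
        )
        te_class = te_stage(
            lambda: te_mod.classify_te_changes(
                de_ribo, de_rna,
                lfc_gate=config.te_lfc_gate, padj_gate=config.te_padj_gate,
                basemean_gate=config.te_basemean_gate,
                te_fold_gate=config.te_fold_gate,
            )
        )()
        te_class.to_csv(os.path.join(config.output_dir, "te_classification.tsv"), sep="\t")
        cat_counts = te_class["category"].value_counts()
        summary["te_categories"] = {
            c: int(cat_counts.get(c, 0)) for c in te_mod.CATEGORIES
        }

        ctrl_samples = [s for s in samples if conditions[s] == control_label]
        trt_samples = [s for s in samples if conditions[s] == treated_label]
        uorf_stage = _stage("uorf")
        uorf_genes = [
            tx.gene_of(tid) for tid in tx.models if tx[tid].uorfs
        ]
        shift_results = uorf_stage(
            lambda: [
                uorf_mod.utr5_main_shift(rpm, g, ctrl_samples, trt_samples)
                for g in uorf_genes
            ]
        )()
        shifts = uorf_mod.shift_results_frame(shift_results)
        if len(shifts):
            shifts.to_csv(os.path.join(config.output_dir, "uorf_shift.tsv"),
                          sep="\t", index=False)
            finite = shifts["log2_shift"].replace([np.inf, -np.inf], np.nan).dropna()
            summary["uorf_shift"] = {
                "n_genes": int(len(shifts)),
                "mean_log2_shift": float(finite.mean()) if len(finite) else None,
            }
        if tx.sequences is not None and trt_samples:
            pooled = {}
            for ts in tracksets:
                if ts.sample_id not in trt_samples:
                    continue
                for tid, track in ts.tracks.items():
                    pooled[tid] = pooled.get(tid, 0) + track
            signals = []
            for tid in tx.models:
                if tid not in pooled or not tx[tid].uorfs:
                    continue
                signals.extend(
                    uorf_mod.detect_uorf_peaks(
                        pooled[tid], tx[tid], tx.sequence(tid),
                        score_threshold=config.uorf_score_threshold,
                        min_reads=config.uorf_min_reads,
                    )
                )
            sig_frame = uorf_mod.uorf_signals_frame(signals)
            if len(sig_frame):
                sig_frame.to_csv(
                    os.path.join(config.output_dir, "uorf_signals.tsv"),
                    sep="\t", index=False,
                )
                summary["uorf_peaks_called"] = int(sig_frame["called"].sum())

        with open(os.path.join(config.output_dir, "summary.json"), "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
        logger.info("pipeline complete: %s", config.output_dir)
        return summary
    finally:
        root_logger.removeHandler(handler)
        handler.close()
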