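"""P-site assignment, offset calibration, and region counting."""

import numpy as np
import pandas as pd
import pytest

from riboclast.annotation import TranscriptModel, TranscriptomeSet, UORFAnnotation
from riboclast.psites import (
    FootprintAlignment,
    assign_psites,
    calibrate_psite_offset,
    count_regions,
    read_bed,
    to_rpm,
)

from conftest import make_transcriptome


def frame(rows):
    return pd.DataFrame(rows, columns=["transcript_id", "five_prime", "read_length", "weight"])


# ---------------------------------------------------------------------------
# assign_psites
# ---------------------------------------------------------------------------


def test_psite_shift_places_count_at_offset(tiny_transcriptome):
    ts = assign_psites(frame([("tx1", 100, 29, 1.0)]), tiny_transcriptome, offset=12)
    assert ts["tx1"][112] == 1.0
    assert ts["tx1"].sum() == 1.0


def test_zero_offset_reproduces_five_prime_coverage(tiny_transcriptome, rng):
    rows = [("tx1", int(rng.integers(0, 300)), 29, 1.0) for _ in range(50)]
    ts = assign_psites(frame(rows), tiny_transcriptome, offset=0)
    expected = np.zeros(300)
    for _, fp, _, w in rows:
        expected[fp] += w
    assert np.array_equal(ts["tx1"], expected)


def test_offpiste_psites_are_discarded_not_clamped(tiny_transcriptome):
    ts = assign_psites(frame([("tx1", 295, 29, 1.0), ("tx1", 10, 29, 2.0)]),
                       tiny_transcriptome, offset=12)
    assert ts.discarded == 1.0
    assert ts["tx1"].sum() == 2.0


def test_negative_offset_rejected(tiny_transcriptome):
    with pytest.raises(ValueError):
        assign_psites(frame([("tx1", 0, 29, 1.0)]), tiny_transcriptome, offset=-1)


def test_unannotated_transcript_rejected(tiny_transcriptome):
    with pytest.raises(ValueError, match="unannotated"):
        assign_psites(frame([("txX", 0, 29, 1.0)]), tiny_transcriptome)


def test_assign_psites_linear_in_weights(tiny_transcriptome, rng):
    rows = [("tx1", int(rng.integers(0, 280)), 29, float(rng.integers(1, 4)))
            for _ in range(30)]
    single = assign_psites(frame(rows), tiny_transcriptome)
    doubled_rows = [(t, fp, rl, 2 * w) for t, fp, rl, w in rows]
    doubled = assign_psites(frame(doubled_rows), tiny_transcriptome)
    assert np.allclose(doubled["tx1"], 2 * single["tx1"])


def test_alignment_validation():
    with pytest.raises(ValueError):
        FootprintAlignment("tx1", -1, 29)
    with pytest.raises(ValueError):
        FootprintAlignment("tx1", 0, 0)
    with pytest.raises(ValueError):
        FootprintAlignment("tx1", 0, 29, weight=0.0)


def test_read_bed_round_trip(tmp_path, tiny_transcriptome):
    path = tmp_path / "fp.bed"
    path.write_text("tx1\t100\t129\tr0\t1.0\t+\ntx1\t50\t78\tr1\t0.5\t+\n")
    df = read_bed(str(path))
    assert list(df["five_prime"]) == [100, 50]
    assert list(df["read_length"]) == [29, 28]
    assert list(df["weight"]) == [1.0, 0.5]
    ts = assign_psites(df, tiny_transcriptome)
    assert ts["tx1"][112] == 1.0 and ts["tx1"][62] == 0.5


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("true_offset", [10, 11, 12, 13, 14])
def test_calibration_recovers_generating_offset(tiny_transcriptome, true_offset):
    # initiation peak: many reads whose 5' end sits offset nt before the start
    rows = [("tx1", 100 - true_offset, 29, 1.0)] * 150
    rows += [("tx1", 150, 29, 1.0)] * 20  # unrelated internal reads
    cal = calibrate_psite_offset(frame(rows), tiny_transcriptome)
    assert cal.offset == true_offset
    assert not cal.low_confidence


def test_calibration_flat_profile_ties_to_12(tiny_transcriptome):
    # uniform 5' ends across the start window: all candidates tie
    rows = [("tx1", fp, 29, 1.0) for fp in range(70, 110) for _ in range(5)]
    cal = calibrate_psite_offset(frame(rows), tiny_transcriptome)
    assert cal.offset == 12
    assert cal.low_confidence


def test_calibration_requires_reads(tiny_transcriptome):
    with pytest.raises(ValueError, match="cannot calibrate"):
        calibrate_psite_offset(frame([("tx1", 88, 29, 1.0)] * 5), tiny_transcriptome)


# ---------------------------------------------------------------------------
# region counting
# ---------------------------------------------------------------------------


def tracks_from(psite_rows, transcriptome, sample_id="s1"):
    """Place unit counts directly at P-sites via a zero offset."""
    rows = [(tid, pos, 29, w) for tid, pos, w in psite_rows]
    return assign_psites(frame(rows), transcriptome, offset=0, sample_id=sample_id)


def test_counts_land_in_utr3(tiny_transcriptome):
    ts = tracks_from([("tx1", p, 1.0) for p in range(250, 300, 5)], tiny_transcriptome)
    mat = count_regions(ts, tiny_transcriptome)
    assert mat["utr3"].loc["g1", "s1"] == 10
    assert mat["cds"].loc["g1", "s1"] == 0
    assert mat["utr5"].loc["g1", "s1"] == 0


def test_uorf_overlap_policy_assigns_overlap(tiny_transcriptome):
    # tx2 has uORF [80,131) overlapping CDS start 100; 6 counts at 100-105
    rows = [("tx2", p, 1.0) for p in range(100, 106)]
    ts = tracks_from(rows, tiny_transcriptome)
    to_utr = count_regions(ts, tiny_transcriptome, "overlap_to_utr")
    assert to_utr["utr5"].loc["g2", "s1"] == 6
    assert to_utr["cds"].loc["g2", "s1"] == 0
    assert to_utr["uorf"].loc["g2", "s1"] == 6
    to_cds = count_regions(ts, tiny_transcriptome, "overlap_to_cds")
    assert to_cds["cds"].loc["g2", "s1"] == 6
    assert to_cds["utr5"].loc["g2", "s1"] == 0
    assert to_cds["uorf"].loc["g2", "s1"] == 6


def test_region_counts_match_per_position_oracle(rng):
    """count_regions equals a naive per-position loop on a random instance."""
    models, psite_rows = [], []
    for i in range(12):
        length = int(rng.integers(60, 240))
        cds_start = int(rng.integers(0, length // 2))
        ncod = int(rng.integers(2, (length - cds_start) // 3 + 1))
        cds_end = cds_start + 3 * ncod
        uorfs = []
        if cds_start >= 12 and rng.random() < 0.5:
            u_start = int(rng.integers(0, cds_start - 6))
            max_codons = (length - u_start) // 3
            u_codons = int(rng.integers(2, max_codons + 1))
            uorfs = [UORFAnnotation(u_start, u_start + 3 * u_codons, "AUG")]
        models.append(TranscriptModel(f"t{i}", f"g{i}", length, cds_start,
                                      cds_end, uorfs=uorfs))
        for _ in range(30):
            psite_rows.append((f"t{i}", int(rng.integers(0, length)), 1.0))
    tset = make_transcriptome(models)
    ts = tracks_from(psite_rows, tset)
    mat = count_regions(ts, tset, "overlap_to_utr")

    # oracle: loop over every transcript position
    expect = {r: {m.gene_id: 0.0 for m in models} for r in ("utr5", "cds", "utr3", "uorf")}
    track = {m.transcript_id: np.zeros(m.length) for m in models}
    for tid, pos, w in psite_rows:
        track[tid][pos] += w
    for m in models:
        for pos in range(m.length):
            w = track[m.transcript_id][pos]
            in_uorf = any(u.start <= pos < u.end for u in m.uorfs)
            if in_uorf:
                expect["uorf"][m.gene_id] += w
            if pos < m.cds_start or (in_uorf and pos < m.cds_end):
                expect["utr5"][m.gene_id] += w
            elif pos < m.cds_end:
                expect["cds"][m.gene_id] += w
            else:
                expect["utr3"][m.gene_id] += w
    for region in ("utr5", "cds", "utr3", "uorf"):
        for m in models:
            assert mat[region].loc[m.gene_id, "s1"] == expect[region][m.gene_id]


def test_region_tiling_conserves_track_totals(tiny_transcriptome, rng):
    rows = [("tx1", int(rng.integers(0, 300)), 1.0) for _ in range(100)]
    rows += [("tx2", int(rng.integers(0, 300)), 1.0) for _ in range(100)]
    ts = tracks_from(rows, tiny_transcriptome)
    mat = count_regions(ts, tiny_transcriptome)
    tiling = mat["utr5"] + mat["cds"] + mat["utr3"]
    assert tiling["s1"].sum() == pytest.approx(ts.total)
    assert mat.library_sizes["s1"] == pytest.approx(ts.total)


# ---------------------------------------------------------------------------
# rpm
# ---------------------------------------------------------------------------


def test_rpm_definition_and_scale_invariance(tiny_transcriptome, rng):
    rows = [("tx1", int(rng.integers(0, 300)), 1.0) for _ in range(200)]
    ts = tracks_from(rows, tiny_transcriptome)
    mat = count_regions(ts, tiny_transcriptome)
    rpm = to_rpm(mat)
    lib = mat.library_sizes["s1"]
    assert rpm["cds"].loc["g1", "s1"] == pytest.approx(
        mat["cds"].loc["g1", "s1"] * 1e6 / lib
    )
    # scaling every weight by c leaves rpm unchanged
    ts3 = tracks_from([(t, p, 3.0) for t, p, _ in rows], tiny_transcriptome)
    rpm3 = to_rpm(count_regions(ts3, tiny_transcriptome))
    for region in ("utr5", "cds", "utr3"):
        assert np.allclose(rpm3[region], rpm[region])


def test_rpm_rejects_zero_library(tiny_transcriptome):
    ts = tracks_from([], tiny_transcriptome)
    # empty alignments: library size 0 for every annotated transcript
    mat = count_regions(ts, tiny_transcriptome)
    if len(mat.samples):
        with pytest.raises(ValueError, match="library"):
            to_rpm(mat)
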