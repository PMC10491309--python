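"""Cleavage simulation: sites, fragmentation, footprints, counts, bundles."""

import hashlib
import os

import numpy as np
import pytest

from riboclast.annotation import TranscriptModel, TranscriptomeSet
from riboclast.simulate import (
    CleavageModel,
    FragmentPool,
    SimulationConfig,
    generate_experiment,
    find_cleavage_sites,
    simulate_footprints,
    simulate_fragmentation,
    simulate_rnaseq,
)

from conftest import make_transcriptome, random_sequence

RNASEL = CleavageModel.rnasel_like(0.5)


# ---------------------------------------------------------------------------
# cleavage sites
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "seq,model,expected",
    [
        ("UAUU", CleavageModel.rnasel_like(0.1), [2, 4]),
        ("ACAU", CleavageModel.rnasea_like(0.1), [2, 4]),
        ("AAAA", CleavageModel.rnasea_like(0.1), []),
        ("AAAA", CleavageModel.rnasel_like(0.1), []),
        ("UUU", CleavageModel.rnasel_like(0.1), [2, 3]),  # overlapping UU
    ],
)
def test_candidate_cut_sites(seq, model, expected):
    pos, probs = find_cleavage_sites(seq, model)
    assert list(pos) == expected
    assert np.allclose(probs, model.per_site_probability)


def test_cleavage_model_validation():
    with pytest.raises(ValueError):
        CleavageModel({}, 0.1)
    with pytest.raises(ValueError):
        CleavageModel({"UUU": 1.0}, 0.1)  # k > 2
    with pytest.raises(ValueError):
        CleavageModel({"UU": -1.0}, 0.1)
    with pytest.raises(ValueError):
        CleavageModel({"UU": 0.0}, 0.1)  # no positive weight
    with pytest.raises(ValueError):
        CleavageModel({"UU": 1.0}, 1.5)


def test_motif_weights_are_normalized_to_max():
    model = CleavageModel({"UU": 2.0, "UA": 1.0}, 0.4)
    _, probs = find_cleavage_sites("UUAA", model)
    # UU at 0 -> cut 2 with p 0.4; UA at 1 -> cut 3 with p 0.2
    assert np.allclose(sorted(probs, reverse=True), [0.4, 0.2])


# ---------------------------------------------------------------------------
# fragmentation
# ---------------------------------------------------------------------------


def one_transcript(seq, cds=(0, None)):
    length = len(seq)
    cds_start, cds_end = cds[0], cds[1] or length - length % 3
    m = TranscriptModel("tx", "g", length, cds_start, cds_end)
    return make_transcriptome([m], sequences={"tx": seq})


def test_no_cleavage_leaves_all_copies_intact(rng):
    tset = one_transcript(random_sequence(rng, 120))
    pool = simulate_fragmentation(tset, {"tx": 25}, CleavageModel.rnasel_like(0.0), rng)
    assert pool.intact["tx"] == 25
    assert pool.fragments == {}


def test_certain_cut_at_single_site_is_forced(rng):
    # exactly one UU site and no UA anywhere (UU followed by G)
    seq = "ACG" * 10 + "UU" + "GCG" * 10
    tset = one_transcript(seq)
    pool = simulate_fragmentation(tset, {"tx": 10}, CleavageModel.rnasel_like(1.0), rng)
    assert pool.intact["tx"] == 0
    assert pool.fragments["tx"] == [(0, 32, 10), (32, len(seq), 10)]


def test_resistant_transcripts_are_never_cut(rng):
    seq = "UU" * 50
    tset = one_transcript(seq)
    pool = simulate_fragmentation(tset, {"tx": 10}, CleavageModel.rnasel_like(1.0),
                                  rng, resistant={"tx"})
    assert pool.intact["tx"] == 10 and not pool.fragments


def test_nucleotide_mass_conserved_before_decay(rng):
    seq = random_sequence(rng, 400)
    tset = one_transcript(seq)
    n = 200
    pool = simulate_fragmentation(tset, {"tx": n}, RNASEL, rng, decay_fraction=0.0)
    assert pool.nucleotide_mass(tset) == n * len(seq)


def test_intact_fraction_matches_binomial_closed_form(rng):
    seq = random_sequence(rng, 150)
    tset = one_transcript(seq)
    model = CleavageModel.rnasel_like(0.05)
    sites, probs = find_cleavage_sites(seq, model)
    k = int((sites < len(seq)).sum())
    n = 20_000
    pool = simulate_fragmentation(tset, {"tx": n}, model, rng)
    expected = (1 - 0.05) ** k
    se = np.sqrt(expected * (1 - expected) / n)
    assert abs(pool.intact["tx"] / n - expected) < 3 * se


def test_decay_removes_fragments_not_intact(rng):
    seq = random_sequence(rng, 300)
    tset = one_transcript(seq)
    full = simulate_fragmentation(tset, {"tx": 500}, RNASEL,
                                  np.random.default_rng(0), decay_fraction=0.0)
    decayed = simulate_fragmentation(tset, {"tx": 500}, RNASEL,
                                     np.random.default_rng(0), decay_fraction=0.9)
    assert decayed.intact["tx"] == full.intact["tx"]
    n_full = sum(c for _, _, c in full.fragments.get("tx", []))
    n_dec = sum(c for _, _, c in decayed.fragments.get("tx", []))
    assert n_dec < 0.3 * n_full


# ---------------------------------------------------------------------------
# footprints
# ---------------------------------------------------------------------------


def small_config(**kw):
    defaults = dict(
        n_genes=30, replicates_per_condition=2, footprint_depth=30_000,
        rnaseq_depth=30_000, abundance_mean=50.0,
        cleavage=CleavageModel.rnasel_like(0.02),
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


def psites_of(df, offset=12):
    return df["five_prime"].to_numpy() + offset


def test_without_fragments_footprints_stay_in_annotated_orfs(rng):
    cfg = small_config(background_occupancy=0.0,
                       cleavage=CleavageModel.rnasel_like(0.0))
    res = generate_experiment(cfg)
    tx = res.transcriptome
    for sid, df in res.footprints.items():
        for tid, sub in df.groupby("transcript_id", observed=True):
            m = tx[tid]
            ps = psites_of(sub)
            in_cds = (ps >= m.cds_start) & (ps < m.cds_end)
            in_uorf = np.zeros(len(sub), dtype=bool)
            for u in m.uorfs:
                in_uorf |= (ps >= u.start) & (ps < u.end)
            assert (in_cds | in_uorf).all()


def test_utr3_fragment_reinitiation_lands_downstream_of_stop(rng):
    # hand-built pool: one 3' fragment spanning only the 3'UTR
    seq = random_sequence(rng, 150) + "AUG" + random_sequence(rng, 147)
    m = TranscriptModel("tx", "g", 300, 30, 240)
    tset = make_transcriptome([m], sequences={"tx": seq})
    frag = (250, 300, 40)
    pool = FragmentPool(intact={"tx": 0}, fragments={"tx": [frag]})
    cfg = small_config(p_fragment_reinitiation=1.0, background_occupancy=0.0)
    df = simulate_footprints(pool, tset, cfg, "treated", rng, depth=500)
    assert (psites_of(df) >= m.cds_end).all()


def test_five_prime_end_is_psite_minus_12():
    # intact-only pool on one transcript: P-sites all in the CDS, and
    # five_prime + 12 reproduces them
    rng = np.random.default_rng(5)
    seq = random_sequence(rng, 300)
    m = TranscriptModel("tx", "g", 300, 90, 240)
    tset = make_transcriptome([m], sequences={"tx": seq})
    pool = FragmentPool(intact={"tx": 50})
    cfg = small_config(background_occupancy=0.0)
    df = simulate_footprints(pool, tset, cfg, "control", rng, depth=2_000)
    ps = psites_of(df, cfg.psite_offset)
    assert (ps >= m.cds_start).all() and (ps < m.cds_end).all()
    assert (df["five_prime"] == ps - 12).all()


def test_unknown_condition_rejected(rng):
    tset = one_transcript(random_sequence(rng, 120))
    pool = FragmentPool(intact={"tx": 10})
    with pytest.raises(ValueError, match="condition"):
        simulate_footprints(pool, tset, small_config(), "mystery", rng)


def test_empty_pool_is_an_error(rng):
    tset = one_transcript(random_sequence(rng, 120))
    with pytest.raises(ValueError, match="empty library"):
        simulate_footprints(FragmentPool(intact={"tx": 0}), tset,
                            small_config(), "control", rng)


# ---------------------------------------------------------------------------
# RNA-seq
# ---------------------------------------------------------------------------


def test_rnaseq_expectation_follows_cds_mass(rng):
    seqs = {f"t{i}": random_sequence(rng, 300) for i in range(2)}
    models = [TranscriptModel(f"t{i}", f"g{i}", 300, 0, 300) for i in range(2)]
    tset = make_transcriptome(models, sequences=seqs)
    pool = FragmentPool(intact={"t0": 30, "t1": 10})  # 3:1 CDS mass
    counts = simulate_rnaseq(pool, tset, 40_000, rng)
    assert counts.sum() == 40_000
    assert counts["g0"] == pytest.approx(30_000, abs=4 * np.sqrt(40_000 * 0.75 * 0.25))


def test_rnaseq_zero_for_fully_decayed_gene(rng):
    seqs = {f"t{i}": random_sequence(rng, 300) for i in range(2)}
    models = [TranscriptModel(f"t{i}", f"g{i}", 300, 0, 300) for i in range(2)]
    tset = make_transcriptome(models, sequences=seqs)
    pool = FragmentPool(intact={"t0": 30, "t1": 0})
    counts = simulate_rnaseq(pool, tset, 1_000, rng)
    assert counts["g1"] == 0


def test_rnaseq_requires_material(rng):
    tset = one_transcript(random_sequence(rng, 120))
    with pytest.raises(ValueError, match="empty library"):
        simulate_rnaseq(FragmentPool(intact={"tx": 0}), tset, 100, rng)


# ---------------------------------------------------------------------------
# whole-experiment bundle
# ---------------------------------------------------------------------------


def bundle_digest(path):
    h = hashlib.sha256()
    for root, _, files in sorted(os.walk(path)):
        for f in sorted(files):
            h.update(f.encode())
            with open(os.path.join(root, f), "rb") as fh:
                h.update(fh.read())
    return h.hexdigest()


def test_identical_seed_gives_byte_identical_bundle(tmp_path):
    cfg = small_config(rng_seed=7)
    generate_experiment(cfg, out_dir=str(tmp_path / "a"))
    generate_experiment(cfg, out_dir=str(tmp_path / "b"))
    assert bundle_digest(tmp_path / "a") == bundle_digest(tmp_path / "b")


def test_different_seed_changes_bundle(tmp_path):
    generate_experiment(small_config(rng_seed=7), out_dir=str(tmp_path / "a"))
    generate_experiment(small_config(rng_seed=8), out_dir=str(tmp_path / "b"))
    assert bundle_digest(tmp_path / "a") != bundle_digest(tmp_path / "b")


def test_global_loss_reflected_in_truth_mass():
    cfg = small_config(n_genes=100, global_loss_fraction=0.9,
                       induced_gene_fraction=0.0,
                       cleavage=CleavageModel.rnasel_like(0.0), rng_seed=3)
    res = generate_experiment(cfg)
    ctrl = np.mean([res.truth.per_sample[s]["total_intact_mass"]
                    for s in res.truth.per_sample if s.startswith("control")])
    trt = np.mean([res.truth.per_sample[s]["total_intact_mass"]
                   for s in res.truth.per_sample if s.startswith("treated")])
    assert trt / ctrl == pytest.approx(0.1, rel=0.05)


def test_induced_genes_gain_relative_share_in_treated_counts():
    cfg = small_config(
        n_genes=100, global_loss_fraction=0.9, induction_factor=20.0,
        induced_gene_fraction=0.05, cleavage=CleavageModel.rnasel_like(0.0),
        rnaseq_depth=200_000, rng_seed=11,
    )
    res = generate_experiment(cfg)
    counts = res.rnaseq
    share = counts.div(counts.sum(axis=0), axis=1)
    induced = res.truth.induced
    rest = [g for g in res.truth.gene_ids if g not in induced]
    ctrl_cols = [s for s in counts if s.startswith("control")]
    trt_cols = [s for s in counts if s.startswith("treated")]
    gain_induced = (share.loc[induced, trt_cols].mean().mean()
                    / share.loc[induced, ctrl_cols].mean().mean())
    gain_rest = (share.loc[rest, trt_cols].mean().mean()
                 / share.loc[rest, ctrl_cols].mean().mean())
    assert gain_induced > 5 * gain_rest


def test_exchangeable_null_has_no_structure():
    """With no cleavage, loss, induction or TE shifts, treated and control
    samples are exchangeable: DE finds only nominal false positives."""
    from riboclast.stats import differential_expression

    cfg = small_config(
        n_genes=400, global_loss_fraction=0.0, induced_gene_fraction=0.0,
        uorf_gene_fraction=0.0, cleavage=CleavageModel.rnasel_like(0.0),
        replicates_per_condition=3, rnaseq_depth=400_000, rng_seed=19,
    )
    res = generate_experiment(cfg)
    de = differential_expression(res.rnaseq, res.conditions, "control", "treated")
    assert (de["pvalue"] < 0.05).mean() < 0.1
    assert int(de["flag_de"].sum()) <= 3
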