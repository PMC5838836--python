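"""Gapped k-mer features, training, deltaSVM, and significance calls."""

import math

import numpy as np
import pytest

from crossreg.gkm import (
    GkmFeatureSpace,
    TrainingSet,
    delta_svm,
    extract_gkm_features,
    load_model,
    make_training_set,
    reverse_complement,
    save_model,
    score_percentile,
    train_model,
)
from crossreg.regions import NamedRegion
from crossreg.simulate import planted_motif_training_set

COMP = dict(zip("ACGT", "TGCA"))


def test_sequence_shorter_than_l_has_no_features():
    assert extract_gkm_features("ACGTACGTA", l=10, k=6) == {}


def test_single_window_feature_count():
    feats = extract_gkm_features("ACGT", l=4, k=2, rc_collapse=False)
    assert sum(feats.values()) == math.comb(4, 2)
    assert len(feats) == math.comb(4, 2)


def test_total_feature_mass_closed_form(rng):
    l, k = 6, 3
    for _ in range(5):
        L = int(rng.integers(l, 60))
        seq = "".join("ACGT"[int(rng.integers(4))] for _ in range(L))
        feats = extract_gkm_features(seq, l=l, k=k, rc_collapse=False)
        assert sum(feats.values()) == (L - l + 1) * math.comb(l, k)
        # RC collapsing scans both strands: exactly twice the mass
        both = extract_gkm_features(seq, l=l, k=k, rc_collapse=True)
        assert sum(both.values()) == 2 * (L - l + 1) * math.comb(l, k)


def test_rc_collapsed_features_strand_invariant(rng):
    seq = "".join("ACGT"[int(rng.integers(4))] for _ in range(40))
    fwd = extract_gkm_features(seq, l=8, k=4, rc_collapse=True)
    rc = extract_gkm_features(reverse_complement(seq), l=8, k=4, rc_collapse=True)
    assert fwd == rc


def test_windows_containing_n_are_skipped():
    seq = "ACGTACGTAC" + "N" + "GTACGTACGT"
    feats = extract_gkm_features(seq, l=10, k=6, rc_collapse=False)
    # only the two N-free windows at each end contribute
    assert sum(feats.values()) == 2 * math.comb(10, 6)


def test_l_less_than_k_rejected():
    with pytest.raises(ValueError):
        extract_gkm_features("ACGTACGT", l=3, k=5)


def _toy_genome(rng, size=20_000):
    return {"chr1": "".join("ACGT"[int(rng.integers(4))] for _ in range(size))}


def test_training_set_lengths_and_determinism():
    rng = np.random.default_rng(2)
    genome = _toy_genome(rng)
    positives = [NamedRegion("chr1", 100 * i, 100 * i + 50 + i, f"p{i}")
                 for i in range(1, 11)]
    ts1 = make_training_set(positives, genome, seed=5)
    ts2 = make_training_set(positives, genome, seed=5)
    ts3 = make_training_set(positives, genome, seed=6)
    assert sorted(map(len, ts1.negatives)) == sorted(map(len, ts1.positives))
    assert ts1.negatives == ts2.negatives
    assert ts1.negatives != ts3.negatives
    # negatives avoid the positive regions
    for neg in ts1.negatives:
        assert neg in genome["chr1"]


def test_training_set_gc_matches_uniform_background():
    """On a uniform-random genome, negative GC tracks the genome background."""
    from scipy.stats import kstest

    rng = np.random.default_rng(3)
    genome = _toy_genome(rng, size=300_000)
    positives = [NamedRegion("chr1", 500 * i, 500 * i + 200, f"p{i}")
                 for i in range(500)]
    ts = make_training_set(positives, genome, seed=3)
    gc = np.array([(s.count("G") + s.count("C")) / len(s) for s in ts.negatives])
    # binomial(200, 0.5) / 200 under the uniform background
    stat = kstest(gc, "norm", args=(0.5, math.sqrt(0.25 / 200)))
    assert stat.pvalue > 0.01


def test_training_set_impossible_placement_errors():
    genome = {"chr1": "ACGT" * 10}
    positives = [NamedRegion("chr1", 0, 30, "p")]
    with pytest.raises(ValueError):
        make_training_set(positives, genome, seed=0)


def test_mismatched_length_distribution_rejected():
    with pytest.raises(ValueError, match="length distribution"):
        TrainingSet(["ACGT"], ["ACGTA"], seed=0)


@pytest.fixture(scope="module")
def planted_model():
    ts = planted_motif_training_set(seed=11)
    return ts, train_model(ts, l=10, k=6, seed=11)


def test_planted_motif_model_separates_classes(planted_model):
    _, model = planted_model
    assert model.trainer_meta["cv_auc"] >= 0.95


def test_shuffled_labels_give_chance_auc(planted_model):
    ts, _ = planted_model
    rng = np.random.default_rng(11)
    pool = list(ts.positives) + list(ts.negatives)
    perm = rng.permutation(len(pool))
    shuffled = TrainingSet([pool[i] for i in perm[:200]],
                           [pool[i] for i in perm[200:]], seed=11)
    model = train_model(shuffled, l=10, k=6, seed=11)
    assert 0.4 <= model.trainer_meta["cv_auc"] <= 0.6


def test_planted_motif_lmers_rank_top_percent(planted_model, rng):
    """l-mers embedding the planted motif sit in the top 1% by weight."""
    _, model = planted_model
    motif = "TGACGTCA"
    embed = motif + "AG"
    w = model.weight(embed)
    sample = np.array([
        model.weight("".join("ACGT"[int(rng.integers(4))] for _ in range(10)))
        for _ in range(3000)
    ])
    assert (sample >= w).mean() < 0.01


def test_training_is_deterministic(planted_model):
    ts, model = planted_model
    model2 = train_model(ts, l=10, k=6, seed=11)
    np.testing.assert_array_equal(model.coef, model2.coef)
    assert model.intercept == model2.intercept


def test_degenerate_inputs_rejected():
    with pytest.raises(ValueError, match="at least 20"):
        train_model(TrainingSet(["ACGT" * 5] * 5, ["ACGT" * 5] * 5, 0))


def test_delta_identity_and_antisymmetry(planted_model, rng):
    _, model = planted_model
    for _ in range(10):
        ctx = "".join("ACGT"[int(rng.integers(4))] for _ in range(19))
        ref = ctx[9]
        alt = COMP[ref]
        assert delta_svm(ctx, ref, ref, model) == 0.0
        fwd = delta_svm(ctx, ref, alt, model)
        back_ctx = ctx[:9] + alt + ctx[10:]
        assert delta_svm(back_ctx, alt, ref, model) == pytest.approx(-fwd)


def test_delta_rc_invariance(planted_model, rng):
    _, model = planted_model
    ctx = "".join("ACGT"[int(rng.integers(4))] for _ in range(19))
    ref, alt = ctx[9], COMP[ctx[9]]
    fwd = delta_svm(ctx, ref, alt, model)
    rc = delta_svm(reverse_complement(ctx), COMP[ref], COMP[alt], model)
    assert rc == pytest.approx(fwd)


def test_delta_signs_for_motif_disruption(planted_model, rng):
    _, model = planted_model
    motif = "TGACGTCA"
    flank = lambda n: "".join("ACGT"[int(rng.integers(4))] for _ in range(n))
    seq = flank(20) + motif + flank(20)
    i = 23  # a consensus position inside the motif
    ctx = seq[i - 9:i + 10]
    ref = seq[i]
    alt = COMP[ref]
    destroy = delta_svm(ctx, ref, alt, model)
    assert destroy < 0
    restored_ctx = ctx[:9] + alt + ctx[10:]
    assert delta_svm(restored_ctx, alt, ref, model) > 0


def test_delta_indel_windows(planted_model):
    _, model = planted_model
    ctx = "ACGTACGTACGTACGTACG"
    # deletion of the center base: still scores finitely and antisymmetrically
    d = delta_svm(ctx, ctx[9], "", model)
    assert np.isfinite(d)
    with pytest.raises(ValueError, match="reference allele"):
        delta_svm(ctx, "T" if ctx[9] != "T" else "A", "G", model)


def test_score_percentile_median_and_extremes():
    dist = np.arange(1000, dtype=float)
    pct, sig = score_percentile(500.0, dist)
    assert not sig and 45 < pct < 55
    pct_low, sig_low = score_percentile(-10.0, dist)
    assert sig_low and pct_low == 0.0
    with pytest.raises(ValueError):
        score_percentile(0.0, [])


def test_score_percentile_normal_rate():
    """Two-sided 95% exclusion flags ~5% of standard-normal scores."""
    gen = np.random.default_rng(5)
    dist = gen.standard_normal(100_000)
    _, flags = score_percentile(dist, dist)
    assert abs(flags.mean() - 0.05) < 0.003
    # the empirical cutoffs sit near the +-1.96 closed form
    _, sig_hi = score_percentile(1.97, dist)
    _, sig_lo = score_percentile(-1.97, dist)
    assert sig_hi and sig_lo


def test_model_save_load_round_trip(tmp_path, planted_model):
    _, model = planted_model
    path = tmp_path / "model.tsv"
    save_model(model, path)
    back = load_model(path)
    np.testing.assert_array_equal(back.coef, model.coef)
    assert back.intercept == model.intercept
    assert (back.l, back.k, back.rc_collapse) == (model.l, model.k, model.rc_collapse)
    assert back.trainer_meta["cv_auc"] == pytest.approx(model.trainer_meta["cv_auc"])
    assert back.weight("TGACGTCAAG") == pytest.approx(model.weight("TGACGTCAAG"))


def test_weight_table_enumerates_small_space():
    ts = planted_motif_training_set(n_pos=30, n_neg=30, seq_len=30,
                                    motif="ACGT", seed=2)
    model = train_model(ts, l=4, k=2, seed=2)
    table = dict(model.weight_table())
    assert len(table) == 4 ** 4
    assert table["ACGT"] == pytest.approx(model.weight("ACGT"))
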