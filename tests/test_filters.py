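"""Filter cascade predicates, union semantics, and enrichment arithmetic."""

import numpy as np
import pandas as pd
import pytest

from crossreg.features import ThresholdSpec
from crossreg.filters import (
    FilterSpec,
    apply_filters,
    enrichment_ratio,
    fold_enrichment,
    optimize_filter_params,
    resolve_filters,
)
from crossreg.regions import NamedRegion


def _features(**cols):
    n = max(len(v) for v in cols.values())
    base = {
        "chrom": ["chr1"] * n, "start": range(n), "end": range(1, n + 1),
        "length": [1000] * n, "cage_count": [0] * n, "rnaseq_signal": [0.0] * n,
        "h3k27ac_signal": [0.0] * n, "svm_score": [0.0] * n,
        "annotation_count": [1] * n, "phastcons": [0.0] * n, "tfbs_count": [0] * n,
    }
    base.update(cols)
    return pd.DataFrame(base, index=[f"r{i}" for i in range(n)])


REF = pd.DataFrame({
    "cage_count": [1, 2, 3, 4],
    "rnaseq_signal": [10.0, 20.0, 30.0, 40.0],
    "h3k27ac_signal": [3.0, 7.0, 15.0, 31.0],
    "svm_score": [0.0, 1.0, 2.0, 3.0],
    "annotation_count": [1, 2, 3, 4],
    "phastcons": [0.2, 0.4, 0.6, 0.8],
    "tfbs_count": [0, 2, 4, 6],
})


def test_cage_predicate_with_rnaseq_backup():
    specs = resolve_filters(REF, enabled=("CAGE",))
    feats = _features(cage_count=[2, 1, 1, 0],
                      rnaseq_signal=[0.0, 30.0, 10.0, 100.0])
    retained, _ = apply_filters(feats, specs)
    # mean reference rnaseq = 25: cage>=2 passes; cage==1 needs rnaseq > 25
    assert list(retained.index) == ["r0", "r1"]


def test_svm_length_boundary_is_strict():
    specs = resolve_filters(REF, enabled=("SVM",))
    feats = _features(length=[2999, 3000, 3001], svm_score=[99.0, 99.0, 99.0])
    retained, _ = apply_filters(feats, specs)
    assert list(retained.index) == ["r0"]


def test_region_passing_no_filter_dropped_and_union_lists_passes():
    specs = resolve_filters(REF)
    feats = _features(cage_count=[2, 0], h3k27ac_signal=[0.0, 0.0])
    retained, _ = apply_filters(feats, specs)
    assert list(retained.index) == ["r0"]
    assert "CAGE" in retained.loc["r0", "passing_filters"]


def test_union_equals_set_union_of_independent_retentions():
    rng = np.random.default_rng(3)
    n = 300
    feats = _features(
        cage_count=rng.integers(0, 4, n),
        rnaseq_signal=rng.uniform(0, 60, n),
        h3k27ac_signal=rng.uniform(0, 40, n),
        svm_score=rng.uniform(-2, 4, n),
        annotation_count=rng.integers(1, 6, n),
        phastcons=rng.uniform(0, 1, n),
        tfbs_count=rng.integers(0, 8, n),
        length=rng.integers(500, 5000, n),
    )
    specs = resolve_filters(REF)
    retained, report = apply_filters(feats, specs)
    union = set()
    for spec in specs:
        only, _ = apply_filters(feats, [spec])
        union |= set(only.index)
    assert set(retained.index) == union
    # per-filter report rows agree with independent runs
    for spec in specs:
        only, _ = apply_filters(feats, [spec])
        row = report.loc[report["filter"] == spec.name].iloc[0]
        assert row["n_retained"] == len(only)


def test_disabled_filters_retain_nothing():
    specs = resolve_filters(REF)
    for s in specs:
        s.enabled = False
    feats = _features(cage_count=[5, 5])
    retained, report = apply_filters(feats, specs)
    assert len(retained) == 0 and len(report) == 0


def test_intersection_mode_is_subset_of_union():
    rng = np.random.default_rng(4)
    n = 100
    feats = _features(
        cage_count=rng.integers(0, 5, n),
        rnaseq_signal=rng.uniform(0, 60, n),
        h3k27ac_signal=rng.uniform(0, 60, n),
        svm_score=rng.uniform(0, 4, n),
        annotation_count=rng.integers(1, 6, n),
        phastcons=rng.uniform(0, 1, n),
        tfbs_count=rng.integers(0, 8, n),
    )
    specs = resolve_filters(REF)
    union, _ = apply_filters(feats, specs, "union")
    inter, _ = apply_filters(feats, specs, "intersection")
    assert set(inter.index) <= set(union.index)


def test_missing_feature_column_names_filter():
    specs = resolve_filters(REF, enabled=("PhastCons",))
    feats = _features(cage_count=[1]).drop(columns=["phastcons"])
    with pytest.raises(ValueError, match="PhastCons"):
        apply_filters(feats, specs)


def test_enrichment_ratio_from_printed_counts():
    """Density of reference enhancers per Mb from summary counts."""
    rep = enrichment_ratio([], [], [], genome_size_mb=2670.4,
                           n_enh=31_971, n_prom=13_796, total_length_mb=937.4)
    assert round(rep.ratio_e, 1) == 34.1
    rep_genome = enrichment_ratio([], [], [], genome_size_mb=2670.4,
                                  n_enh=31_971, n_prom=13_796,
                                  total_length_mb=2670.4)
    assert round(rep_genome.ratio_e, 1) == 12.0


def test_enrichment_ratio_self_reference():
    ref = [NamedRegion("chr1", i * 2000, i * 2000 + 1000, f"e{i}") for i in range(50)]
    rep = enrichment_ratio(ref, ref, [], genome_size_mb=10.0)
    total_mb = 50 * 1000 / 1e6
    assert rep.ratio_e == pytest.approx(50 / total_mb)
    assert rep.n_overlapping_ref_enh == 50
    with pytest.raises(ValueError, match="zero total length"):
        enrichment_ratio([], [], [], 10.0, n_enh=1, n_prom=1, total_length_mb=0.0)


@pytest.mark.parametrize("pct_ref,pct_genome,expected", [
    (84.1, 0.138, 609),
    (51.0, 0.138, 370),
    (81.2, 0.129, 629),
    (91.9, 5.08, 18),
    (100.0, 100.0, 1),
])
def test_fold_enrichment_reproduces_printed_cells(pct_ref, pct_genome, expected):
    assert fold_enrichment(pct_ref, pct_genome) == expected


def test_fold_enrichment_zero_denominator():
    with pytest.raises(ValueError):
        fold_enrichment(50.0, 0.0)


def _grid_setup(rng, n=400):
    starts = np.arange(n) * 2000
    regions = {f"r{i}": NamedRegion("chr1", int(s), int(s) + 1000, f"r{i}")
               for i, s in enumerate(starts)}
    active = rng.random(n) < 0.3
    h3k = np.where(active, rng.uniform(20, 40, n), rng.uniform(0, 6, n))
    feats = _features(h3k27ac_signal=h3k, length=[1000] * n)
    feats.index = list(regions)
    ref_enh = [regions[f"r{i}"] for i in np.flatnonzero(active)]
    ref_feats = pd.DataFrame({"h3k27ac_signal": h3k[active]})
    return feats, regions, ref_enh, ref_feats


def test_optimize_single_spec_matches_apply_filters(rng):
    feats, regions, ref_enh, ref_feats = _grid_setup(rng)
    spec = {"h3k27ac_signal": ThresholdSpec("median", "log2p1")}
    table = optimize_filter_params(
        feats, ref_feats, regions, ref_enh, [], genome_size_mb=1.0,
        grid={"H3K27Ac": [spec]},
    )
    fspecs = resolve_filters(ref_feats, {"H3K27Ac": spec}, enabled=("H3K27Ac",))
    retained, report = apply_filters(feats, fspecs)
    assert table.iloc[0]["retained_Mb"] == pytest.approx(report.iloc[0]["retained_Mb"])


def test_optimize_stricter_thresholds_retain_less(rng):
    feats, regions, ref_enh, ref_feats = _grid_setup(rng)
    grid = {"H3K27Ac": [
        {"h3k27ac_signal": ThresholdSpec(stat, "log2p1")}
        for stat in ("median", "q3", "p95")
    ]}
    table = optimize_filter_params(
        feats, ref_feats, regions, ref_enh, [], genome_size_mb=1.0, grid=grid,
    ).set_index("parameters")
    mb = [table.loc[f"h3k27ac_signal:{s}:log2p1", "retained_Mb"]
          for s in ("median", "q3", "p95")]
    assert mb[0] >= mb[1] >= mb[2]
    with pytest.raises(ValueError, match="empty"):
        optimize_filter_params(feats, ref_feats, regions, ref_enh, [], 1.0, {})


def test_planted_signal_filter_increases_ratio_e(rng):
    """Signal-thresholded retention enriches reference-enhancer density."""
    feats, regions, ref_enh, ref_feats = _grid_setup(rng)
    specs = resolve_filters(ref_feats, {"H3K27Ac": {
        "h3k27ac_signal": ThresholdSpec("median", "log2p1")}},
        enabled=("H3K27Ac",))
    retained, _ = apply_filters(feats, specs)
    universe = list(regions.values())
    kept = [regions[name] for name in retained.index]
    before = enrichment_ratio(universe, ref_enh, [], 1.0).ratio_e
    after = enrichment_ratio(kept, ref_enh, [], 1.0).ratio_e
    assert after > before


def test_yaml_filter_config(tmp_path):
    from crossreg.filters import load_filter_config

    cfg = tmp_path / "filters.yaml"
    cfg.write_text(
        "combine: intersection\n"
        "filters:\n"
        "  H3K27Ac: {statistic: mean, transform: log2p1}\n"
        "  SVM: {enabled: false}\n"
        "  PhastCons: {statistic: median}\n"
    )
    specs, enabled, combine = load_filter_config(cfg)
    assert combine == "intersection"
    assert "SVM" not in enabled and "CAGE" in enabled
    assert specs["H3K27Ac"]["h3k27ac_signal"].statistic == "mean"
    assert specs["PhastCons"]["phastcons"].statistic == "median"
    resolved = resolve_filters(REF, specs, enabled)
    assert {s.name for s in resolved} == set(enabled)
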