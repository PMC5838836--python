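"""Projection, reciprocal validation, and the two-stage mapping."""

import numpy as np
import pytest

from crossreg.chain import invert_chains
from crossreg.project import (
    ProjectionParams,
    hprs_map,
    project_interval,
    project_pairs,
    reciprocal_check,
)
from crossreg.regions import GenomicInterval, NamedRegion

from conftest import (
    identity_chainset,
    make_chain,
    make_chainset,
    oracle_project,
    random_chain,
)


def test_interval_inside_single_block_maps_exactly():
    cs = identity_chainset(size=1000)
    res = project_interval(GenomicInterval("chr1", 100, 200), cs, 0.2)
    assert len(res) == 1 and res[0].status == "mapped"
    assert res[0].coverage == 1.0
    assert (res[0].target.start, res[0].target.end) == (100, 200)
    assert len(res[0].target) == 200 - 100


def test_partial_coverage_thresholds():
    """100-bp interval with 25 bp aligned: passes 0.2, fails 0.55."""
    # block of 25 at source 100..125, then a 75-bp source gap
    chain = make_chain(1, "chr1", 1000, 100, [(25, 75, 0), (300, 0, 0)],
                       "chrB", 1000, 0)
    cs = make_chainset([chain])
    iv = GenomicInterval("chr1", 100, 200)
    res = project_interval(iv, cs, 0.2)[0]
    assert res.status == "mapped" and res.coverage == pytest.approx(0.25)
    res55 = project_interval(iv, cs, 0.55)[0]
    assert res55.status == "unmapped"


def test_two_passing_chains_single_map_is_ambiguous():
    c1 = make_chain(1, "chr1", 1000, 0, [(500, 0, 0)], "chrB", 2000, 0)
    c2 = make_chain(2, "chr1", 1000, 0, [(500, 0, 0)], "chrB", 2000, 1000)
    cs = make_chainset([c1, c2])
    iv = GenomicInterval("chr1", 100, 200)
    res = project_interval(iv, cs, 0.2, allow_multiple=False)
    assert len(res) == 1 and res[0].status == "ambiguous"
    multi = project_interval(iv, cs, 0.2, allow_multiple=True)
    assert [r.status for r in multi] == ["mapped", "mapped"]
    # deterministic ordering: equal coverage and score, higher chain id first
    assert [r.chain_id for r in multi] == [2, 1]


def test_unknown_chromosome_and_zero_length_errors():
    cs = identity_chainset()
    with pytest.raises(ValueError, match="chromosome"):
        project_interval(GenomicInterval("chrZ", 0, 10), cs, 0.2)
    with pytest.raises(ValueError):
        GenomicInterval("chr1", 5, 5)


def test_projection_matches_per_base_oracle(rng):
    """Coverage and target span equal exhaustive per-base mapping (<=10 kb)."""
    for _ in range(40):
        strand = "-" if rng.random() < 0.5 else "+"
        chain = random_chain(rng, t_strand=strand)
        cs = make_chainset([chain])
        lo = max(0, chain.s_start - 50)
        hi = min(chain.s_size, chain.s_end + 50)
        start = int(rng.integers(lo, hi - 1))
        end = int(rng.integers(start + 1, hi))
        iv = GenomicInterval("chrA", start, end)
        cov, span = oracle_project(iv, chain)
        res = project_interval(iv, cs, min_match=1e-9)[0]
        if span is None:
            assert res.status == "unmapped"
        else:
            assert res.coverage == pytest.approx(cov)
            assert (res.target.chrom, res.target.start, res.target.end,
                    res.strand) == span


def test_min_match_monotonicity(fx):
    """Mapped set shrinks monotonically across the threshold sweep."""
    thresholds = [0.1, 0.2, 0.3, 0.4, 0.5, 0.55, 0.65, 0.75, 0.8, 0.9, 0.95]
    mapped_sets = []
    for t in thresholds:
        mapped = set()
        for region in fx.regions:
            res = project_interval(region.interval, fx.fwd_chains, t,
                                   allow_multiple=True)
            if any(r.status == "mapped" for r in res):
                mapped.add(region.name)
        mapped_sets.append(mapped)
    for smaller_t, larger_t in zip(mapped_sets, mapped_sets[1:]):
        assert larger_t <= smaller_t


def test_reciprocal_identity_accepts_with_zero_deltas():
    cs = identity_chainset(size=1000)
    iv = GenomicInterval("chr1", 100, 300)
    proj = project_interval(iv, cs, 0.2)[0]
    ok, reason = reciprocal_check(iv, proj, invert_chains(cs), ProjectionParams())
    assert ok and reason == "reciprocal_ok"


def test_reciprocal_boundary_tolerance():
    """A 30-bp shift planted in the reverse chain violates the 25-bp window."""
    size = 10_000
    fwd = identity_chainset(size=size)
    shift = 30
    rev_chain = make_chain(1, "chr1", size, 0, [(size - shift, 0, 0)],
                           "chr1", size, shift)
    rev = make_chainset([rev_chain])
    iv = GenomicInterval("chr1", 1000, 1200)
    proj = project_interval(iv, fwd, 0.2)[0]
    ok, reason = reciprocal_check(iv, proj, rev, ProjectionParams())
    assert not ok and reason == "boundary_tolerance"
    # a 20-bp shift is within tolerance
    rev20 = make_chainset([make_chain(1, "chr1", size, 0, [(size - 20, 0, 0)],
                                      "chr1", size, 20)])
    ok20, _ = reciprocal_check(iv, proj, rev20, ProjectionParams())
    assert ok20


def test_reciprocal_ambiguous_back_projection_rejected():
    size = 2000
    fwd = identity_chainset(size=size)
    # two reverse chains both cover the target: back-projection not unique
    r1 = make_chain(1, "chr1", size, 0, [(size, 0, 0)], "chr1", size, 0)
    r2 = make_chain(2, "chr1", size, 0, [(1000, 0, 0)], "chr1", size, 1000)
    rev = make_chainset([r1, r2])
    iv = GenomicInterval("chr1", 100, 400)
    proj = project_interval(iv, fwd, 0.2)[0]
    ok, reason = reciprocal_check(iv, proj, rev, ProjectionParams())
    assert not ok and reason == "not_unique"


def test_hprs_map_identity_all_primary():
    cs = identity_chainset(size=5000)
    rev = invert_chains(cs)
    dataset = [NamedRegion("chr1", i * 500, i * 500 + 200, f"r{i}") for i in range(8)]
    result = hprs_map(dataset, cs, rev)
    assert result.counts["primary_mapped"] == 8
    assert result.recovered_rate(8) == 1.0
    assert all(r.stage == "primary" for r in result.accepted)


def test_hprs_map_fixture_ground_truth(fx):
    result = hprs_map(fx.regions, fx.fwd_chains, fx.rev_chains)
    manifest = fx.manifest.set_index("name")
    accepted = {}
    for r in result.accepted:
        accepted.setdefault(r.name, []).append(r)
    for name, row in manifest.iterrows():
        if row["expected_status"] == "unmapped":
            assert name not in accepted
            continue
        hits = accepted[name]
        assert len(hits) == row["n_expected_targets"]
        assert {h.stage for h in hits} == {row["expected_stage"]}
        expected = set()
        for item in row["expected_targets"].split("|"):
            chrom, span, strand = item.split(":")
            s, e = span.split("-")
            expected.add((chrom, int(s), int(e), strand))
        got = {(h.target.chrom, h.target.start, h.target.end, h.strand) for h in hits}
        assert got == expected


def test_rescue_hits_meet_stringent_threshold(fx):
    result = hprs_map(fx.regions, fx.fwd_chains, fx.rev_chains)
    primary = {r.name for r in result.accepted if r.stage == "primary"}
    rescue = [r for r in result.accepted if r.stage == "rescue"]
    assert rescue, "fixture must exercise the rescue stage"
    assert primary.isdisjoint({r.name for r in rescue})
    assert all(r.coverage >= 0.8 for r in rescue)


def test_round_trip_projection_recovers_interval(fx):
    """fwd then rev projection returns intervals inside one block exactly."""
    manifest = fx.manifest
    primaries = manifest[manifest["expected_stage"] == "primary"].head(20)
    rev = fx.rev_chains
    for _, row in primaries.iterrows():
        iv = GenomicInterval(row["chrom"], row["start"], row["end"])
        proj = project_interval(iv, fx.fwd_chains, 0.2)[0]
        assert proj.status == "mapped" and proj.coverage == 1.0
        back = project_interval(proj.target, rev, 0.2)[0]
        assert (back.target.chrom, back.target.start, back.target.end) == (
            iv.chrom, iv.start, iv.end
        )


def test_assembly_mismatch_rejected(fx):
    with pytest.raises(ValueError, match="assemblies"):
        hprs_map(fx.regions, fx.fwd_chains, fx.fwd_chains)


def test_project_pairs_keeps_and_drops(fx):
    manifest = fx.manifest.set_index("name")
    primary = manifest[manifest["expected_stage"] == "primary"]
    deleted = manifest[manifest["expected_status"] == "unmapped"]
    a = primary.iloc[0]
    b = primary.iloc[1]
    d = deleted.iloc[0]
    mk = lambda row, name: NamedRegion(row["chrom"], row["start"], row["end"], name)
    pairs = [
        (mk(a, "a"), mk(b, "b")),
        (mk(a, "a2"), mk(d, "dead")),
    ]
    kept, dropped = project_pairs(pairs, fx.fwd_chains, fx.rev_chains)
    assert len(kept) == 1 and len(dropped) == 1
    assert dropped[0] == (1, "B")


def test_pair_spanning_inversion_has_discordant_strands(fx):
    manifest = fx.manifest
    inverted = manifest[manifest["expected_targets"].str.contains(":-", regex=False)
                        & (manifest["expected_stage"] == "primary")]
    upright = manifest[manifest["expected_targets"].str.endswith(":+")
                       & (manifest["expected_stage"] == "primary")]
    assert len(inverted) and len(upright)
    a, b = upright.iloc[0], inverted.iloc[0]
    mk = lambda row: NamedRegion(row["chrom"], row["start"], row["end"], row["name"])
    kept, _ = project_pairs([(mk(a), mk(b))], fx.fwd_chains, fx.rev_chains)
    assert len(kept) == 1
    pa, pb = kept[0]
    assert pa.strand == "+" and pb.strand == "-"


def test_params_validation():
    with pytest.raises(ValueError):
        ProjectionParams(min_match_main=0.9, min_match_multi=0.5)
    with pytest.raises(ValueError):
        ProjectionParams(recip_tolerance_bp=-1)
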