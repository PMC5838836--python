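"""Interval projection between assemblies with reciprocal validation.

The mapping procedure has two stages.  Stage 1 projects each region with a
permissive alignment-coverage threshold (minMatch, default 0.2), requires a
unique passing chain, and validates the hit by projecting it back through
the reverse chains: both borders of the back-projection must return within
25 bp of the original region.  Stage 2 takes everything stage 1 could not
place — unmapped, ambiguous, or reciprocally failed regions — and re-projects
them allowing multiple targets under a stringent threshold (minMatchMulti,
default 0.8), which rescues regions duplicated in the target genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from crossreg.chain import Chain, ChainSet
from crossreg.regions import GenomicInterval, NamedRegion

__all__ = [
    "ProjectionParams",
    "ProjectedRegion",
    "MappedDataset",
    "project_interval",
    "reciprocal_check",
    "hprs_map",
    "project_pairs",
]

STATUS_MAPPED = "mapped"
STATUS_UNMAPPED = "unmapped"
STATUS_AMBIGUOUS = "ambiguous"
STATUS_RECIPROCAL_FAIL = "reciprocal_fail"


@dataclass(frozen=True)
class ProjectionParams:
    """Mapping thresholds.

    min_match_main: fraction of region bases that must sit in aligned blocks
        for the strict single-target stage (default 0.2).
    min_match_multi: stricter fraction for the multi-target rescue stage
        (default 0.8).
    recip_tolerance_bp: maximum border drift allowed on reciprocal mapping
        (default 25 bp).
    """

    min_match_main: float = 0.2
    min_match_multi: float = 0.8
    recip_tolerance_bp: int = 25
    allow_multiple: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.min_match_main <= self.min_match_multi <= 1):
            raise ValueError(
                "require 0 < min_match_main <= min_match_multi <= 1, got "
                f"{self.min_match_main}, {self.min_match_multi}"
            )
        if self.recip_tolerance_bp < 0:
            raise ValueError("recip_tolerance_bp must be >= 0")


@dataclass(frozen=True)
class ProjectedRegion:
    """Outcome of projecting one source interval through one chain."""

    source: GenomicInterval
    target: GenomicInterval | None
    strand: str | None
    coverage: float
    chain_id: int | None
    stage: str  # 'primary' or 'rescue'
    status: str
    name: str = ""
    reason: str = ""


@dataclass
class MappedDataset:
    """Full mapping result: accepted regions plus per-status bookkeeping."""

    regions: list[ProjectedRegion] = field(default_factory=list)
    counts: dict = field(default_factory=dict)

    @property
    def accepted(self) -> list[ProjectedRegion]:
        return [r for r in self.regions if r.status == STATUS_MAPPED]

    def to_named_regions(self) -> list[NamedRegion]:
        return [
            NamedRegion(r.target.chrom, r.target.start, r.target.end, r.name, r.strand)
            for r in self.accepted
        ]

    def recovered_rate(self, n_source: int) -> float:
        recovered = {r.name for r in self.accepted}
        return len(recovered) / n_source if n_source else 0.0


def _project_through(iv: GenomicInterval, chain: Chain):
    """Coverage and forward-coordinate target span of iv through one chain.

    Coverage counts iv bases inside aligned blocks; the target span runs
    from the projection of the first to the last aligned base of iv.
    Returns (coverage, target_interval|None).
    """
    covered = 0
    first_t = last_t = None
    for s0, s1, t0, _ in chain.aligned_segments():
        lo, hi = max(iv.start, s0), min(iv.end, s1)
        if lo < hi:
            covered += hi - lo
            t_lo = t0 + (lo - s0)
            t_hi = t0 + (hi - s0) - 1  # last aligned base, stored coords
            if first_t is None:
                first_t = t_lo
            last_t = t_hi
    coverage = covered / len(iv)
    if covered == 0:
        return 0.0, None
    start, end = chain.target_forward(first_t, last_t + 1)
    target = GenomicInterval(chain.t_chrom, start, end, chain.t_strand)
    return coverage, target


def project_interval(
    iv: GenomicInterval,
    chains: ChainSet,
    min_match: float,
    allow_multiple: bool = False,
    stage: str = "primary",
    name: str = "",
) -> list[ProjectedRegion]:
    """Project one interval through every overlapping chain.

    A chain passes when the fraction of iv's bases inside its aligned blocks
    reaches ``min_match``.  Single-target mode returns one mapped result for
    exactly one passing chain, an ``ambiguous`` result for several, and
    ``unmapped`` for none.  Multi-target mode returns one result per passing
    chain, ordered by coverage, then chain score, then chain id, descending.
    """
    if iv.chrom not in chains.assembly_from.chrom_sizes:
        raise ValueError(f"chromosome {iv.chrom!r} not in assembly {chains.assembly_from.name!r}")
    if len(iv) < 1:
        raise ValueError("zero-length interval")

    passing = []
    for chain in chains.overlapping(iv.chrom, iv.start, iv.end):
        coverage, target = _project_through(iv, chain)
        if target is not None and coverage >= min_match:
            passing.append((coverage, chain, target))

    def unplaced(status: str, reason: str = "") -> ProjectedRegion:
        return ProjectedRegion(iv, None, None, 0.0, None, stage, status, name, reason)

    if not passing:
        return [unplaced(STATUS_UNMAPPED, "no_passing_chain")]
    if not allow_multiple:
        if len(passing) > 1:
            return [unplaced(STATUS_AMBIGUOUS, "multiple_passing_chains")]
        coverage, chain, target = passing[0]
        return [
            ProjectedRegion(iv, target, chain.t_strand, coverage, chain.chain_id,
                            stage, STATUS_MAPPED, name)
        ]
    passing.sort(key=lambda t: (t[0], t[1].score, t[1].chain_id), reverse=True)
    return [
        ProjectedRegion(iv, target, chain.t_strand, coverage, chain.chain_id,
                        stage, STATUS_MAPPED, name)
        for coverage, chain, target in passing
    ]


def reciprocal_check(
    orig: GenomicInterval,
    proj: ProjectedRegion,
    reverse_chains: ChainSet,
    params: ProjectionParams,
) -> tuple[bool, str]:
    """Project a hit back and require it to return within tolerance.

    Accepted iff the back-projection maps uniquely, lands on the original
    chromosome, and both borders are within ``recip_tolerance_bp`` of the
    original region.  Returns (accepted, reason).
    """
    if proj.status != STATUS_MAPPED or proj.target is None:
        raise ValueError("reciprocal_check requires a mapped projection")
    back = project_interval(
        proj.target, reverse_chains, params.min_match_main, allow_multiple=False
    )[0]
    if back.status == STATUS_AMBIGUOUS:
        return False, "not_unique"
    if back.status != STATUS_MAPPED:
        return False, "not_mapped_back"
    if back.target.chrom != orig.chrom:
        return False, "wrong_chromosome"
    tol = params.recip_tolerance_bp
    if abs(back.target.start - orig.start) > tol or abs(back.target.end - orig.end) > tol:
        return False, "boundary_tolerance"
    return True, "reciprocal_ok"


def _check_assemblies(fwd: ChainSet, rev: ChainSet) -> None:
    if (fwd.assembly_from.chrom_sizes != rev.assembly_to.chrom_sizes
            or fwd.assembly_to.chrom_sizes != rev.assembly_from.chrom_sizes):
        raise ValueError("forward and reverse chain sets do not connect the same assemblies")


def hprs_map(
    dataset: list[NamedRegion],
    fwd: ChainSet,
    rev: ChainSet,
    params: ProjectionParams = ProjectionParams(),
) -> MappedDataset:
    """Two-stage mapping of a region dataset.

    Stage 1 (primary): strict single-target projection at ``min_match_main``
    followed by the reciprocal border check.  Stage 2 (rescue): regions that
    stage 1 left unmapped, ambiguous, or reciprocally failed are re-projected
    allowing multiple targets at ``min_match_multi``; every passing target is
    kept.  Source names are preserved on all outputs.
    """
    _check_assemblies(fwd, rev)
    out = MappedDataset()
    counts = {
        "n_input": len(dataset),
        "primary_mapped": 0,
        "rescue_regions": 0,
        "rescue_hits": 0,
        STATUS_UNMAPPED: 0,
        STATUS_AMBIGUOUS: 0,
        STATUS_RECIPROCAL_FAIL: 0,
    }
    deferred: list[tuple[NamedRegion, str]] = []
    for region in dataset:
        iv = region.interval
        proj = project_interval(iv, fwd, params.min_match_main,
                                allow_multiple=False, name=region.name)[0]
        if proj.status == STATUS_MAPPED:
            ok, reason = reciprocal_check(iv, proj, rev, params)
            if ok:
                counts["primary_mapped"] += 1
                out.regions.append(proj)
                continue
            deferred.append((region, f"{STATUS_RECIPROCAL_FAIL}:{reason}"))
        else:
            deferred.append((region, proj.status))

    for region, why in deferred:
        counts["rescue_regions"] += 1
        hits = project_interval(region.interval, fwd, params.min_match_multi,
                                allow_multiple=True, stage="rescue", name=region.name)
        mapped = [h for h in hits if h.status == STATUS_MAPPED]
        if mapped:
            counts["rescue_hits"] += len(mapped)
            out.regions.extend(mapped)
        else:
            status = why.split(":")[0]
            counts[status] += 1
            out.regions.append(
                ProjectedRegion(region.interval, None, None, 0.0, None,
                                "rescue", status, region.name, why)
            )
    out.counts = counts
    return out


def project_pairs(
    pairs,
    fwd: ChainSet,
    rev: ChainSet,
    params: ProjectionParams = ProjectionParams(),
):
    """Map interacting anchor pairs (e.g. Hi-C anchors) independently.

    Each anchor goes through the full two-stage mapping; a pair is reported
    only when both anchors map (first accepted hit each), with orientation
    preserved.  Returns (kept_pairs, dropped) where dropped carries the
    failing pair index and side.
    """
    kept, dropped = [], []
    for idx, (a, b) in enumerate(pairs):
        mapped = {}
        for side, anchor in (("A", a), ("B", b)):
            res = hprs_map([anchor], fwd, rev, params)
            if res.accepted:
                mapped[side] = res.accepted[0]
        if len(mapped) == 2:
            kept.append((mapped["A"], mapped["B"]))
        else:
            missing = "A" if "A" not in mapped else "B"
            dropped.append((idx, missing))
    return kept, dropped
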