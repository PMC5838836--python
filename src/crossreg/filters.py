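"""Species-specific filtering of the universal dataset.

Seven evidence filters, each thresholded against the same feature computed
on a species-specific reference enhancer set, reduce the universal dataset
to a filtered dataset.  A region is retained when it passes at least one
enabled filter (union semantics; sequential/intersection mode available for
sensitivity analysis).  Filter quality is judged by the density of
reference enhancers (Ratio_E) and promoters (Ratio_P) per Mb of retained
regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from crossreg.features import ThresholdSpec, reference_thresholds

__all__ = [
    "FilterSpec",
    "EnrichmentReport",
    "DEFAULT_FILTERS",
    "resolve_filters",
    "apply_filters",
    "enrichment_ratio",
    "fold_enrichment",
    "optimize_filter_params",
]

FILTER_NAMES = (
    "CAGE", "H3K27Ac", "RNAseq", "SVM", "AnnCount", "PhastCons", "TFBScount",
)

# Default statistic per filter: first-listed parameterization of each
# filter's row, except TFBScount where the median variant degenerates
# (retains almost nothing) and mean is the sensible default.
DEFAULT_SPECS: dict[str, dict[str, ThresholdSpec]] = {
    "CAGE": {"rnaseq_signal": ThresholdSpec("mean")},
    "H3K27Ac": {"h3k27ac_signal": ThresholdSpec("median", "log2p1")},
    "RNAseq": {"rnaseq_signal": ThresholdSpec("q3", "log2p1")},
    "SVM": {"svm_score": ThresholdSpec("median")},
    "AnnCount": {"annotation_count": ThresholdSpec("q3")},
    "PhastCons": {"phastcons": ThresholdSpec("p95")},
    "TFBScount": {"tfbs_count": ThresholdSpec("mean")},
}

_FILTER_FEATURES = {
    "CAGE": ["cage_count", "rnaseq_signal"],
    "H3K27Ac": ["h3k27ac_signal"],
    "RNAseq": ["rnaseq_signal"],
    "SVM": ["svm_score", "length"],
    "AnnCount": ["annotation_count"],
    "PhastCons": ["phastcons"],
    "TFBScount": ["tfbs_count"],
}

SVM_MAX_LENGTH = 3000  # regions this long or longer are outside the model's scale


@dataclass
class FilterSpec:
    """One filter with its resolved threshold(s)."""

    name: str
    thresholds: dict[str, float] = field(default_factory=dict)
    specs: dict[str, ThresholdSpec] = field(default_factory=dict)
    enabled: bool = True
    max_length: int = SVM_MAX_LENGTH  # SVM filter only

    def __post_init__(self) -> None:
        if self.name not in FILTER_NAMES:
            raise ValueError(f"unknown filter {self.name!r}")

    def resolved(self) -> bool:
        return all(k in self.thresholds for k in self.specs) or bool(self.thresholds)


def resolve_filters(
    reference_features: pd.DataFrame,
    specs: dict[str, dict[str, ThresholdSpec]] | None = None,
    enabled: tuple[str, ...] = FILTER_NAMES,
) -> list[FilterSpec]:
    """Resolve thresholds for each filter against the reference feature table."""
    specs = specs or DEFAULT_SPECS
    out = []
    for name in enabled:
        fspecs = specs.get(name, DEFAULT_SPECS[name])
        thresholds = reference_thresholds(reference_features, fspecs)
        out.append(FilterSpec(name, thresholds=thresholds, specs=fspecs))
    return out


def _log2p1(x):
    return np.log2(np.asarray(x, dtype=float) + 1.0)


def _predicate(spec: FilterSpec, feats: pd.DataFrame) -> np.ndarray:
    """Boolean pass mask of one filter over the feature table."""
    missing = [c for c in _FILTER_FEATURES[spec.name] if c not in feats.columns]
    if missing:
        raise ValueError(f"filter {spec.name}: missing feature column(s) {missing}")
    name = spec.name
    if name == "CAGE":
        thr = spec.thresholds["rnaseq_signal"]  # mean reference RNA-seq, raw scale
        cage = feats["cage_count"].to_numpy()
        return (cage >= 2) | ((cage == 1) & (feats["rnaseq_signal"].to_numpy() > thr))
    if name == "H3K27Ac":
        thr = spec.thresholds["h3k27ac_signal"]
        spec_t = spec.specs.get("h3k27ac_signal", ThresholdSpec("median", "log2p1"))
        vals = feats["h3k27ac_signal"].to_numpy(float)
        vals = _log2p1(vals) if spec_t.transform == "log2p1" else vals
        return vals >= thr
    if name == "RNAseq":
        thr = spec.thresholds["rnaseq_signal"]
        spec_t = spec.specs.get("rnaseq_signal", ThresholdSpec("q3", "log2p1"))
        vals = feats["rnaseq_signal"].to_numpy(float)
        vals = _log2p1(vals) if spec_t.transform == "log2p1" else vals
        return vals >= thr
    if name == "SVM":
        thr = spec.thresholds["svm_score"]
        return (feats["length"].to_numpy() < spec.max_length) & (
            feats["svm_score"].to_numpy(float) >= thr
        )
    if name == "AnnCount":
        return feats["annotation_count"].to_numpy(float) >= spec.thresholds["annotation_count"]
    if name == "PhastCons":
        return feats["phastcons"].to_numpy(float) >= spec.thresholds["phastcons"]
    if name == "TFBScount":
        return feats["tfbs_count"].to_numpy(float) >= spec.thresholds["tfbs_count"]
    raise AssertionError(name)


def apply_filters(
    features: pd.DataFrame,
    specs: list[FilterSpec],
    combine: str = "union",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the filter cascade to the universal dataset's feature table.

    union (default): a region is retained iff it passes >= 1 enabled filter.
    intersection: it must pass every enabled filter.  Returns
    (retained feature table with a ``passing_filters`` column, per-filter
    independent retention report).
    """
    if combine not in ("union", "intersection"):
        raise ValueError(f"unknown combine mode {combine!r}")
    enabled = [s for s in specs if s.enabled]
    masks = {s.name: _predicate(s, features) for s in enabled}
    n = len(features)
    if enabled:
        stack = np.vstack([masks[s.name] for s in enabled])
        keep = stack.any(axis=0) if combine == "union" else stack.all(axis=0)
    else:
        keep = np.zeros(n, dtype=bool)

    passing = [
        ";".join(s.name for s in enabled if masks[s.name][i]) for i in range(n)
    ]
    retained = features.loc[keep].copy()
    retained["passing_filters"] = [p for p, k in zip(passing, keep) if k]

    report_rows = []
    for s in enabled:
        m = masks[s.name]
        report_rows.append({
            "filter": s.name,
            "n_retained": int(m.sum()),
            "retained_Mb": round(float(features["length"].to_numpy()[m].sum()) / 1e6, 6),
        })
    report = pd.DataFrame(report_rows)
    return retained, report


@dataclass(frozen=True)
class EnrichmentReport:
    """Reference-region density of a predicted dataset.

    ratio_E / ratio_P: reference enhancers / promoters overlapped per Mb of
    the dataset; fold_vs_genome compares that density to spreading the same
    reference set over the whole genome.
    """

    n_regions: int
    total_length_mb: float
    n_overlapping_ref_enh: int
    n_overlapping_ref_prom: int
    ratio_e: float
    ratio_p: float
    fold_vs_genome_e: float
    fold_vs_genome_p: float

    def rounded(self) -> dict:
        return {
            "n_regions": self.n_regions,
            "total_length_Mb": round(self.total_length_mb, 1),
            "ratio_E": round(self.ratio_e, 1),
            "ratio_P": round(self.ratio_p, 1),
            "fold_vs_genome_E": round(self.fold_vs_genome_e, 1),
            "fold_vs_genome_P": round(self.fold_vs_genome_p, 1),
        }


def _count_overlapping(reference, dataset) -> int:
    from crossreg.regions import overlap_stats

    if not reference:
        return 0
    return overlap_stats(dataset, reference)["n_ref_covered"]


def enrichment_ratio(
    dataset,
    ref_enh,
    ref_prom,
    genome_size_mb: float,
    n_enh: int | None = None,
    n_prom: int | None = None,
    total_length_mb: float | None = None,
) -> EnrichmentReport:
    """Reference enhancer/promoter density of a dataset.

    ``dataset`` is a region list; alternatively pass precomputed counts
    (``n_enh``/``n_prom``) and ``total_length_mb`` for worked-example
    arithmetic from printed summary numbers.
    """
    if total_length_mb is None:
        total_length_mb = sum(len(r) for r in dataset) / 1e6
    if total_length_mb <= 0:
        raise ValueError("dataset has zero total length")
    if n_enh is None:
        n_enh = _count_overlapping(ref_enh, dataset)
    if n_prom is None:
        n_prom = _count_overlapping(ref_prom, dataset)
    ratio_e = n_enh / total_length_mb
    ratio_p = n_prom / total_length_mb
    n_ref_enh_total = len(ref_enh) if ref_enh else n_enh
    n_ref_prom_total = len(ref_prom) if ref_prom else n_prom
    fold_e = ratio_e / (n_ref_enh_total / genome_size_mb) if n_ref_enh_total else 0.0
    fold_p = ratio_p / (n_ref_prom_total / genome_size_mb) if n_ref_prom_total else 0.0
    return EnrichmentReport(
        n_regions=len(dataset) if dataset else 0,
        total_length_mb=total_length_mb,
        n_overlapping_ref_enh=n_enh,
        n_overlapping_ref_prom=n_prom,
        ratio_e=ratio_e,
        ratio_p=ratio_p,
        fold_vs_genome_e=fold_e,
        fold_vs_genome_p=fold_p,
    )


def fold_enrichment(pct_ref_covered: float, pct_genome_covered: float) -> int:
    """Fold enrichment of reference coverage over genome coverage.

    Defined as pct_ref_covered / pct_genome_covered, reported rounded to the
    nearest integer.
    """
    if pct_genome_covered <= 0:
        raise ValueError("pct_genome_covered must be positive")
    return int(round(pct_ref_covered / pct_genome_covered))


def optimize_filter_params(
    features: pd.DataFrame,
    reference_features: pd.DataFrame,
    regions_by_name: dict,
    ref_enh,
    ref_prom,
    genome_size_mb: float,
    grid: dict[str, list[dict[str, ThresholdSpec]]],
) -> pd.DataFrame:
    """Evaluate each filter independently over a grid of threshold specs.

    Every candidate parameterization is applied alone to the universal
    dataset; the retained regions are scored by Ratio_E / Ratio_P.  Rows are
    sorted by filter name then Ratio_E descending, mirroring the per-filter
    comparison protocol used to pick production thresholds.
    """
    if not grid:
        raise ValueError("empty parameter grid")
    rows = []
    for fname, candidates in grid.items():
        for fspecs in candidates:
            thresholds = reference_thresholds(reference_features, fspecs)
            spec = FilterSpec(fname, thresholds=thresholds, specs=fspecs)
            mask = _predicate(spec, features)
            retained = [regions_by_name[name] for name in features.index[mask]]
            length_mb = sum(len(r) for r in retained) / 1e6
            if length_mb > 0:
                rep = enrichment_ratio(retained, ref_enh, ref_prom, genome_size_mb)
                ratio_e, ratio_p = rep.ratio_e, rep.ratio_p
            else:
                ratio_e = ratio_p = 0.0
            rows.append({
                "filter": fname,
                "parameters": ";".join(
                    f"{feat}:{sp.statistic}:{sp.transform}" for feat, sp in fspecs.items()
                ),
                "retained_Mb": length_mb,
                "ratio_E": ratio_e,
                "ratio_P": ratio_p,
            })
    df = pd.DataFrame(rows)
    return df.sort_values(["filter", "ratio_E"], ascending=[True, False]).reset_index(drop=True)


DEFAULT_FILTERS = DEFAULT_SPECS

# feature thresholded by each filter's configurable statistic
_PRIMARY_FEATURE = {
    "CAGE": "rnaseq_signal",
    "H3K27Ac": "h3k27ac_signal",
    "RNAseq": "rnaseq_signal",
    "SVM": "svm_score",
    "AnnCount": "annotation_count",
    "PhastCons": "phastcons",
    "TFBScount": "tfbs_count",
}


def load_filter_config(path) -> tuple[dict, tuple, str]:
    """Read a YAML filter configuration.

    Layout::

        combine: union
        filters:
          H3K27Ac: {statistic: median, transform: log2p1}
          PhastCons: {statistic: p95}
          SVM: {enabled: false}

    Unlisted filters keep their defaults; returns (specs, enabled, combine)
    suitable for :func:`resolve_filters` / :func:`apply_filters`.
    """
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    combine = cfg.get("combine", "union")
    specs = {name: dict(d) for name, d in DEFAULT_SPECS.items()}
    enabled = []
    for name in FILTER_NAMES:
        entry = (cfg.get("filters") or {}).get(name, {})
        if not entry.get("enabled", True):
            continue
        enabled.append(name)
        if "statistic" in entry:
            feature = _PRIMARY_FEATURE[name]
            default = DEFAULT_SPECS[name][feature]
            specs[name] = {feature: ThresholdSpec(
                entry["statistic"], entry.get("transform", default.transform)
            )}
    return specs, tuple(enabled), combine
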