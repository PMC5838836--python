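"""Per-region evidence features consumed by the filter cascade.

Each candidate region is summarized as a feature vector: number of CAGE
peaks it contains, aggregated RNA-seq and H3K27Ac signal, a sequence-model
score, the number of contributing annotations, mean per-base conservation,
and the number of motif (PWM) hits.  Filter thresholds are taken from the
same features computed over a species-specific reference region set.
"""

from __future__ import annotations

from bisect import bisect_left
from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs

__all__ = [
    "ThresholdSpec",
    "count_overlaps",
    "aggregate_signal",
    "mean_conservation",
    "read_pwms",
    "scan_tfbs",
    "reference_thresholds",
    "featurize",
    "FEATURE_COLUMNS",
]

FEATURE_COLUMNS = [
    "cage_count", "rnaseq_signal", "h3k27ac_signal", "svm_score",
    "annotation_count", "phastcons", "tfbs_count",
]

_STATISTICS = ("median", "mean", "q3", "p95")
_TRANSFORMS = ("identity", "log2p1")


@dataclass(frozen=True)
class ThresholdSpec:
    """How to turn reference feature values into a filter threshold."""

    statistic: str
    transform: str = "identity"

    def __post_init__(self) -> None:
        if self.statistic not in _STATISTICS:
            raise ValueError(f"unknown statistic {self.statistic!r}")
        if self.transform not in _TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}")


def _sorted_by_chrom(items, key):
    table = defaultdict(list)
    for it in items:
        chrom, start, end, payload = key(it)
        table[chrom].append((start, end, payload))
    for chrom in table:
        table[chrom].sort(key=lambda t: (t[0], t[1]))
    return table


def count_overlaps(regions, peaks) -> np.ndarray:
    """Number of peak intervals sharing >= 1 base with each region.

    A peak touching two regions counts in both.
    """
    table = _sorted_by_chrom(peaks, lambda p: (p.chrom, p.start, p.end, None))
    counts = np.zeros(len(regions), dtype=int)
    for i, r in enumerate(regions):
        counts[i] = sum(
            1 for s, e, _ in table.get(r.chrom, ()) if s < r.end and e > r.start
        )
    return counts


def _check_disjoint(track) -> dict:
    table = _sorted_by_chrom(track, lambda t: (t[0], t[1], t[2], t[3]))
    for chrom, rows in table.items():
        for (s0, e0, _), (s1, _, _) in zip(rows, rows[1:]):
            if s1 < e0:
                raise ValueError(f"overlapping track intervals on {chrom} at {s1} < {e0}")
    return table


def _overlap_scan(table_entry, start: int, end: int):
    """Yield (overlap_len, value) of sorted disjoint rows against [start, end)."""
    rows, starts = table_entry
    i = bisect_left(starts, start)
    if i > 0 and rows[i - 1][1] > start:
        i -= 1
    while i < len(rows):
        s, e, v = rows[i]
        if s >= end:
            break
        ov = min(end, e) - max(start, s)
        if ov > 0:
            yield ov, v
        i += 1


def _indexed(table) -> dict:
    return {chrom: (rows, [s for s, _, _ in rows]) for chrom, rows in table.items()}


def aggregate_signal(regions, track, mode: str = "sum") -> np.ndarray:
    """Aggregate a bedGraph track over regions.

    sum mode: sum of (overlap length x value); mean mode divides by the
    region length.  Bases absent from the track contribute 0.  The track
    intervals must be non-overlapping.
    """
    if mode not in ("sum", "mean"):
        raise ValueError(f"unknown mode {mode!r}")
    table = _indexed(_check_disjoint(track))
    out = np.zeros(len(regions))
    for i, r in enumerate(regions):
        acc = 0.0
        for ov, v in _overlap_scan(table.get(r.chrom, ([], [])), r.start, r.end):
            acc += ov * v
        out[i] = acc / len(r) if mode == "mean" else acc
    return out


def mean_conservation(regions, track) -> tuple[np.ndarray, np.ndarray]:
    """Mean per-base conservation over *scored* bases only.

    Scores must lie in [0, 1].  Returns (means, has_score flag); regions
    with no scored base get 0 and a False flag.
    """
    for _, _, _, v in track:
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"conservation score {v} outside [0, 1]")
    table = _indexed(_check_disjoint(track))
    means = np.zeros(len(regions))
    scored = np.zeros(len(regions), dtype=bool)
    for i, r in enumerate(regions):
        acc = 0.0
        nbases = 0
        for ov, v in _overlap_scan(table.get(r.chrom, ([], [])), r.start, r.end):
            acc += ov * v
            nbases += ov
        if nbases:
            means[i] = acc / nbases
            scored[i] = True
    return means, scored


# ---------------------------------------------------------------------------
# PWM scanning

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def read_pwms(path) -> list:
    """Read JASPAR-style PFM text via Bio.motifs."""
    with open(path) as fh:
        return list(motifs.parse(fh, "jaspar"))


def _log_odds_matrix(motif, background, eps: float = 1e-4) -> np.ndarray:
    """Per-position log2 odds with pseudo-frequency eps on both sides."""
    counts = np.array([motif.counts[b] for b in "ACGT"], dtype=float)
    freqs = counts / counts.sum(axis=0)
    bg = np.array([background[b] for b in "ACGT"], dtype=float)[:, None]
    return np.log2((freqs + eps) / (bg + eps))


def _scan_one(seq: str, lom: np.ndarray, threshold: float) -> list[tuple[int, float]]:
    """Best-per-run hits of one PWM on one strand of one sequence."""
    w = lom.shape[1]
    if len(seq) < w:
        return []
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, -1, dtype=np.int64)
    for base, idx in _BASE_INDEX.items():
        codes[arr == ord(base)] = idx
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)
    valid = (windows >= 0).all(axis=1)
    scores = lom[np.clip(windows, 0, 3), np.arange(w)].sum(axis=1)
    hits = [
        (int(pos), float(scores[pos]))
        for pos in np.flatnonzero(valid & (scores >= threshold))
    ]
    # collapse overlapping hits to the best-scoring window
    collapsed = []
    for pos, score in hits:
        if collapsed and pos < collapsed[-1][0] + w:
            if score > collapsed[-1][1]:
                collapsed[-1] = (pos, score)
        else:
            collapsed.append((pos, score))
    return collapsed


def scan_tfbs(
    regions,
    genome: dict,
    pwms,
    rel_threshold: float = 0.8,
    background: dict | None = None,
) -> np.ndarray:
    """Count PWM hits in each region's sequence, both strands.

    A hit is a window whose log-odds score reaches ``rel_threshold`` times
    the PWM's maximum achievable score; overlapping hits of one PWM on one
    strand collapse to the best window.  The count is summed over all PWMs
    and both strands (so the count is invariant to reverse-complementing
    the sequence).
    """
    if background is None:
        background = {b: 0.25 for b in "ACGT"}
    mats = [_log_odds_matrix(m, background) for m in pwms]
    thresholds = [rel_threshold * float(np.max(lom, axis=0).sum()) for lom in mats]
    counts = np.zeros(len(regions), dtype=int)
    for i, r in enumerate(regions):
        chrom_seq = genome.get(r.chrom)
        if chrom_seq is None or r.end > len(chrom_seq):
            raise ValueError(f"region {r.chrom}:{r.start}-{r.end} outside genome bounds")
        seq = str(chrom_seq[r.start:r.end]).upper()
        rc = seq.translate(_COMPLEMENT)[::-1]
        n = 0
        for lom, thr in zip(mats, thresholds):
            n += len(_scan_one(seq, lom, thr)) + len(_scan_one(rc, lom, thr))
        counts[i] = n
    return counts


def load_genome(path) -> dict[str, str]:
    """Read a FASTA genome into a chrom -> sequence dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# Reference thresholds

def _apply_transform(values: np.ndarray, transform: str) -> np.ndarray:
    if transform == "log2p1":
        return np.log2(values + 1.0)
    return values


def reference_thresholds(reference_features: pd.DataFrame, specs: dict) -> dict:
    """Resolve per-feature thresholds from a reference feature table.

    ``specs`` maps feature name -> ThresholdSpec.  Quantiles use linear
    interpolation between order statistics (numpy default); the log2p1
    transform applies log2(x + 1) before the statistic.
    """
    if reference_features.empty:
        raise ValueError("reference feature set is empty")
    out = {}
    for feature, spec in specs.items():
        if feature not in reference_features.columns:
            raise ValueError(f"feature {feature!r} missing from reference table")
        values = _apply_transform(
            reference_features[feature].to_numpy(float), spec.transform
        )
        if spec.statistic == "median":
            out[feature] = float(np.quantile(values, 0.5))
        elif spec.statistic == "mean":
            out[feature] = float(np.mean(values))
        elif spec.statistic == "q3":
            out[feature] = float(np.quantile(values, 0.75))
        elif spec.statistic == "p95":
            out[feature] = float(np.quantile(values, 0.95))
    return out


def featurize(
    regions,
    cage_peaks=None,
    h3k27ac_track=None,
    rnaseq_track=None,
    conservation_track=None,
    genome=None,
    pwms=None,
    svm_scores=None,
    annotation_counts=None,
    rel_threshold: float = 0.8,
    signal_mode: str = "sum",
) -> pd.DataFrame:
    """Build the full feature table for a region list.

    Missing evidence defaults to zeros so partial pipelines remain usable.
    The result is indexed by region name with a length column plus one
    column per feature.
    """
    n = len(regions)
    df = pd.DataFrame(index=[r.name for r in regions])
    df["chrom"] = [r.chrom for r in regions]
    df["start"] = [r.start for r in regions]
    df["end"] = [r.end for r in regions]
    df["length"] = [len(r) for r in regions]
    df["cage_count"] = count_overlaps(regions, cage_peaks) if cage_peaks is not None else 0
    df["h3k27ac_signal"] = (
        aggregate_signal(regions, h3k27ac_track, signal_mode)
        if h3k27ac_track is not None else 0.0
    )
    df["rnaseq_signal"] = (
        aggregate_signal(regions, rnaseq_track, signal_mode)
        if rnaseq_track is not None else 0.0
    )
    if conservation_track is not None:
        means, _ = mean_conservation(regions, conservation_track)
        df["phastcons"] = means
    else:
        df["phastcons"] = 0.0
    df["tfbs_count"] = (
        scan_tfbs(regions, genome, pwms, rel_threshold)
        if genome is not None and pwms is not None else 0
    )
    if svm_scores is not None:
        df["svm_score"] = np.asarray(svm_scores, dtype=float)
    else:
        df["svm_score"] = 0.0
    if annotation_counts is not None:
        df["annotation_count"] = np.asarray(annotation_counts, dtype=int)
    else:
        df["annotation_count"] = [
            getattr(r, "annotation_count", max(1, len(r.name.split(","))))
            for r in regions
        ]
    return df
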