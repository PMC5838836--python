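"""Gapped k-mer sequence model and deltaSVM variant scoring.

A sequence is represented by counts of gapped k-mers: every length-``l``
window contributes one word per choice of ``k`` informative positions
(C(l, k) position subsets), the remaining positions being wildcards.  A
regularized linear classifier trained on positive (reference enhancer) and
length-matched background sequences yields a weight for every possible
l-mer — the score of that l-mer's own feature vector.  The deltaSVM score
of a variant is the summed weight of all l-mers overlapping the variant in
the alternate sequence minus the same sum in the reference sequence.

Feature ids are canonicalized under reverse complement by default, so a
sequence and its reverse complement produce identical feature vectors
(regulatory activity is strand-symmetric).
"""

from __future__ import annotations

import ast
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import sparse
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

__all__ = [
    "GkmFeatureSpace",
    "TrainingSet",
    "GappedKmerModel",
    "extract_gkm_features",
    "make_training_set",
    "train_model",
    "delta_svm",
    "score_percentile",
    "save_model",
    "load_model",
]

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT_CODE = np.array([3, 2, 1, 0], dtype=np.int64)
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    """Sequence to base codes; anything outside ACGT becomes -1."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int64)
    for base, code in _CODE.items():
        out[arr == ord(base)] = code
    return out


class GkmFeatureSpace:
    """The gapped k-mer feature map for fixed (l, k, rc_collapse).

    Feature id = pattern_index * 4**k + word_id, canonicalized under
    reverse complement when rc_collapse is set.  Instances are cached per
    parameter triple because the canonical map is moderately expensive.
    """

    _cache: dict = {}

    def __new__(cls, l: int, k: int, rc_collapse: bool = True):
        key = (l, k, rc_collapse)
        if key not in cls._cache:
            inst = super().__new__(cls)
            inst._init(l, k, rc_collapse)
            cls._cache[key] = inst
        return cls._cache[key]

    def _init(self, l: int, k: int, rc_collapse: bool) -> None:
        if k > l or k < 1:
            raise ValueError(f"require 1 <= k <= l, got l={l} k={k}")
        self.l, self.k, self.rc_collapse = l, k, rc_collapse
        self.patterns = list(combinations(range(l), k))
        self.n_patterns = len(self.patterns)
        self.n_words = 4 ** k
        self.n_features = self.n_patterns * self.n_words
        self._pow4 = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)

        pattern_index = {p: i for i, p in enumerate(self.patterns)}
        # Word digits for every word id, used to build the RC word map.
        words = np.arange(self.n_words, dtype=np.int64)
        digits = (words[:, None] // self._pow4[None, :]) % 4  # (n_words, k)
        rc_digits = _COMPLEMENT_CODE[digits[:, ::-1]]
        rc_word = rc_digits @ self._pow4

        if rc_collapse:
            canon = np.empty((self.n_patterns, self.n_words), dtype=np.int64)
            for pi, pattern in enumerate(self.patterns):
                rc_pattern = tuple(sorted(l - 1 - p for p in pattern))
                rc_pi = pattern_index[rc_pattern]
                fwd_ids = pi * self.n_words + words
                rc_ids = rc_pi * self.n_words + rc_word
                canon[pi] = np.minimum(fwd_ids, rc_ids)
            self._canonical = canon
        else:
            self._canonical = None

    def window_feature_ids(self, window_codes: np.ndarray) -> np.ndarray:
        """Canonical feature ids of the C(l, k) gapped words of one window."""
        ids = np.empty(self.n_patterns, dtype=np.int64)
        for pi, pattern in enumerate(self.patterns):
            word = int(window_codes[list(pattern)] @ self._pow4)
            ids[pi] = (
                self._canonical[pi, word] if self._canonical is not None
                else pi * self.n_words + word
            )
        return ids

    def feature_counts(self, seq: str) -> np.ndarray:
        """Dense count vector over the full feature space for one sequence.

        Windows containing non-ACGT characters are skipped.  With RC
        collapsing, both strands are scanned; since a window and its
        reverse complement share canonical features, this doubles every
        count relative to a single-strand scan.
        """
        counts = np.zeros(self.n_features, dtype=np.float64)
        ids, n = np.unique(self.feature_ids(seq), return_counts=True)
        counts[ids] = n
        if self.rc_collapse:
            counts *= 2.0  # both strands: RC windows share canonical ids
        return counts

    def feature_ids(self, seq: str) -> np.ndarray:
        """Canonical feature ids of every (window, pattern) pair of one strand."""
        codes = _encode(seq)
        if codes.size < self.l:
            return np.empty(0, dtype=np.int64)
        windows = np.lib.stride_tricks.sliding_window_view(codes, self.l)
        windows = windows[(windows >= 0).all(axis=1)]
        if windows.shape[0] == 0:
            return np.empty(0, dtype=np.int64)
        parts = []
        for pi, pattern in enumerate(self.patterns):
            words = windows[:, list(pattern)] @ self._pow4
            parts.append(
                self._canonical[pi, words] if self._canonical is not None
                else pi * self.n_words + words
            )
        return np.concatenate(parts)

    def feature_matrix(self, seqs) -> sparse.csr_matrix:
        """Sparse count matrix (one row per sequence) over the feature space."""
        indptr = [0]
        indices: list[np.ndarray] = []
        data: list[np.ndarray] = []
        scale = 2.0 if self.rc_collapse else 1.0
        for seq in seqs:
            ids, counts = np.unique(self.feature_ids(seq), return_counts=True)
            indices.append(ids)
            data.append(counts.astype(np.float64) * scale)
            indptr.append(indptr[-1] + ids.size)
        return sparse.csr_matrix(
            (np.concatenate(data) if data else np.empty(0),
             np.concatenate(indices) if indices else np.empty(0, dtype=np.int64),
             np.array(indptr)),
            shape=(len(seqs), self.n_features),
        )


def extract_gkm_features(seq: str, l: int = 10, k: int = 6, rc_collapse: bool = True):
    """Sparse gapped k-mer counts of one sequence.

    Returns a dict mapping feature id -> count; feature ids are
    ``pattern_index * 4**k + word_id`` canonicalized under reverse
    complement when ``rc_collapse`` is set.
    """
    if l < k:
        raise ValueError(f"require l >= k, got l={l} k={k}")
    counts = GkmFeatureSpace(l, k, rc_collapse).feature_counts(seq)
    nz = np.flatnonzero(counts)
    return {int(i): float(counts[i]) for i in nz}


# ---------------------------------------------------------------------------
# Training data

@dataclass
class TrainingSet:
    """Positive and length-matched negative training sequences."""

    positives: list[str]
    negatives: list[str]
    seed: int
    provenance: str = ""

    def __post_init__(self) -> None:
        if sorted(len(s) for s in self.positives) != sorted(len(s) for s in self.negatives):
            raise ValueError("negative length distribution must match positives")


def make_training_set(
    positives,
    genome: dict,
    n_neg_per_pos: int = 1,
    seed: int = 0,
    exclusions=None,
) -> TrainingSet:
    """Sample length-matched background sequences from the genome.

    For each positive region, ``n_neg_per_pos`` same-length intervals are
    drawn uniformly over all valid placements in the genome, rejected when
    they overlap any positive or exclusion region or contain non-ACGT
    bases (at most 100 tries per negative).
    """
    rng = np.random.default_rng(seed)
    forbidden: dict[str, list[tuple[int, int]]] = {}
    for r in list(positives) + (list(exclusions) if exclusions else []):
        forbidden.setdefault(r.chrom, []).append((r.start, r.end))
    for chrom in forbidden:
        forbidden[chrom].sort()

    chroms = sorted(genome)
    pos_seqs = [genome[r.chrom][r.start:r.end].upper() for r in positives]

    neg_seqs = []
    for r in positives:
        length = r.end - r.start
        placements = np.array(
            [max(0, len(genome[c]) - length + 1) for c in chroms], dtype=np.int64
        )
        total = int(placements.sum())
        if total == 0:
            raise ValueError(f"genome too small to place a {length}-bp negative")
        cum = np.cumsum(placements)
        for _ in range(n_neg_per_pos):
            for _attempt in range(100):
                flat = int(rng.integers(total))
                ci = int(np.searchsorted(cum, flat, side="right"))
                start = flat - (cum[ci - 1] if ci else 0)
                chrom = chroms[ci]
                end = start + length
                if any(s < end and e > start for s, e in forbidden.get(chrom, ())):
                    continue
                seq = genome[chrom][start:end].upper()
                if any(b not in _BASES for b in seq):
                    continue
                neg_seqs.append(seq)
                break
            else:
                raise ValueError("failed to place a negative after 100 tries")

    pos_all = pos_seqs if n_neg_per_pos == 1 else [
        s for s in pos_seqs for _ in range(n_neg_per_pos)
    ]
    return TrainingSet(pos_all, neg_seqs, seed, provenance="length-matched genomic background")


# ---------------------------------------------------------------------------
# Model

@dataclass
class GappedKmerModel:
    """A trained linear model over gapped k-mer counts.

    The l-mer weight table is derived lazily: weight(w) is the linear score
    (sans intercept) of w's own feature vector, computed deterministically
    from the coefficients; derived weights are cached.
    """

    l: int
    k: int
    rc_collapse: bool
    coef: np.ndarray
    intercept: float
    trainer_meta: dict = field(default_factory=dict)
    _weight_cache: dict = field(default_factory=dict, repr=False)

    @property
    def space(self) -> GkmFeatureSpace:
        return GkmFeatureSpace(self.l, self.k, self.rc_collapse)

    def score_sequence(self, seq: str) -> float:
        """Linear decision value of a whole sequence."""
        ids = self.space.feature_ids(seq)
        scale = 2.0 if self.rc_collapse else 1.0
        return float(scale * self.coef[ids].sum() + self.intercept)

    def weight(self, lmer: str) -> float:
        """Derived weight of one l-mer (its single window's linear score)."""
        if len(lmer) != self.l:
            raise ValueError(f"need an {self.l}-mer, got length {len(lmer)}")
        lmer = lmer.upper()
        cached = self._weight_cache.get(lmer)
        if cached is not None:
            return cached
        codes = _encode(lmer)
        if (codes < 0).any():
            w = 0.0  # l-mers with ambiguous bases carry no weight
        else:
            ids = self.space.window_feature_ids(codes)
            scale = 2.0 if self.rc_collapse else 1.0
            w = float(scale * self.coef[ids].sum())
        self._weight_cache[lmer] = w
        return w

    def weight_table(self):
        """Iterate (l-mer, weight) over all 4**l l-mers (small l only)."""
        for idx in range(4 ** self.l):
            digits = []
            v = idx
            for _ in range(self.l):
                digits.append(_BASES[v % 4])
                v //= 4
            lmer = "".join(reversed(digits))
            yield lmer, self.weight(lmer)


def train_model(
    ts: TrainingSet,
    l: int = 10,
    k: int = 6,
    regularization: float = 1.0,
    seed: int = 0,
    rc_collapse: bool = True,
    cv_folds: int = 5,
) -> GappedKmerModel:
    """Fit the gapped k-mer linear classifier.

    Requires >= 20 sequences per class.  Reports stratified ``cv_folds``-fold
    cross-validated AUC in ``trainer_meta['cv_auc']``, then refits on the
    full training set.  Training is deterministic given the training set
    and seed.
    """
    if len(ts.positives) < 20 or len(ts.negatives) < 20:
        raise ValueError("need at least 20 positives and 20 negatives")
    space = GkmFeatureSpace(l, k, rc_collapse)
    X = space.feature_matrix(list(ts.positives) + list(ts.negatives))
    y = np.array([1] * len(ts.positives) + [0] * len(ts.negatives))
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate single-class training input")

    def new_clf():
        # dual solver: n_samples << n_features; seeded, hence deterministic
        return LinearSVC(C=regularization, dual=True, max_iter=10000, tol=1e-6,
                         random_state=seed)

    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    scores = np.zeros(len(y))
    for train_idx, test_idx in skf.split(X, y):
        clf = new_clf()
        clf.fit(X[train_idx], y[train_idx])
        scores[test_idx] = clf.decision_function(X[test_idx])
    cv_auc = float(roc_auc_score(y, scores))

    final = new_clf()
    final.fit(X, y)
    return GappedKmerModel(
        l=l, k=k, rc_collapse=rc_collapse,
        coef=final.coef_.ravel().astype(np.float64),
        intercept=float(final.intercept_[0]),
        trainer_meta={
            "regularization": regularization,
            "seed": seed,
            "n_pos": len(ts.positives),
            "n_neg": len(ts.negatives),
            "cv_auc": cv_auc,
        },
    )


# ---------------------------------------------------------------------------
# deltaSVM

def _window_weight_sum(seq: str, span_start: int, span_end: int, model: GappedKmerModel) -> float:
    """Sum of weights of all l-mers of ``seq`` intersecting [span_start, span_end)."""
    l = model.l
    first = max(0, span_start - l + 1)
    last = min(len(seq) - l, span_end - 1)
    total = 0.0
    for pos in range(first, last + 1):
        total += model.weight(seq[pos:pos + l])
    return total


def delta_svm(context: str, ref_allele: str, alt_allele: str, model: GappedKmerModel) -> float:
    """deltaSVM score of a variant inside its reference sequence context.

    ``context`` is the reference sequence around the variant (length
    2l - 1 for a SNV, centered on it); the reference allele must occupy the
    center.  The score is the summed weight of every l-mer overlapping the
    edited span in the alternate sequence minus the same sum in the
    reference sequence.  Indels follow the same rule with the overlapping
    window set taken over the edited span in each sequence.
    """
    context = context.upper()
    ref_allele = ref_allele.upper()
    alt_allele = alt_allele.upper()
    start = (len(context) - len(ref_allele)) // 2
    if context[start:start + len(ref_allele)] != ref_allele:
        raise ValueError(
            f"context does not carry the reference allele at its center: "
            f"{context[start:start + len(ref_allele)]!r} != {ref_allele!r}"
        )
    alt_seq = context[:start] + alt_allele + context[start + len(ref_allele):]
    ref_sum = _window_weight_sum(context, start, start + max(1, len(ref_allele)), model)
    alt_sum = _window_weight_sum(alt_seq, start, start + max(1, len(alt_allele)), model)
    return alt_sum - ref_sum


def _empirical_percentile(sorted_dist: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Mean-rank percentile of scores within a sorted sample."""
    left = np.searchsorted(sorted_dist, scores, side="left")
    right = np.searchsorted(sorted_dist, scores, side="right")
    return 50.0 * (left + right) / sorted_dist.size


def score_percentile(
    score,
    score_distribution,
    mode: str = "two_sided",
    central_range: float = 95.0,
):
    """Percentile of a score in an empirical distribution plus a flag.

    two_sided (default): significant when the score falls outside the
    central ``central_range`` % of the distribution (<= 2.5th or >= 97.5th
    percentile for the default range).  one_sided: significant when
    |score| reaches the ``central_range``-th percentile of |distribution|.
    Accepts a scalar or an array of scores.
    """
    dist = np.sort(np.asarray(score_distribution, dtype=float))
    if dist.size == 0:
        raise ValueError("empty score distribution")
    scores = np.asarray(score, dtype=float)
    scalar = scores.ndim == 0
    if mode == "two_sided":
        pct = _empirical_percentile(dist, scores)
        tail = (100.0 - central_range) / 2.0
        sig = (pct <= tail) | (pct >= 100.0 - tail)
    elif mode == "one_sided":
        pct = _empirical_percentile(np.sort(np.abs(dist)), np.abs(scores))
        sig = pct >= central_range
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if scalar:
        return float(pct), bool(sig)
    return pct, sig


# ---------------------------------------------------------------------------
# Serialization: versioned flat table of the sparse model coefficients.

_FORMAT_VERSION = 1


def save_model(model: GappedKmerModel, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#crossreg-gkm\tv{_FORMAT_VERSION}\n")
        fh.write(
            f"#l={model.l}\tk={model.k}\trc={int(model.rc_collapse)}\t"
            f"intercept={model.intercept!r}\n"
        )
        meta = model.trainer_meta
        fh.write("#meta\t" + "\t".join(f"{k}={meta[k]!r}" for k in sorted(meta)) + "\n")
        fh.write("feature_id\tcoef\n")
        for idx in np.flatnonzero(model.coef):
            fh.write(f"{int(idx)}\t{float(model.coef[idx])!r}\n")


def load_model(path) -> GappedKmerModel:
    with open(path) as fh:
        magic = fh.readline().strip().split("\t")
        if magic[0] != "#crossreg-gkm" or magic[1] != f"v{_FORMAT_VERSION}":
            raise ValueError(f"not a crossreg gkm model file: {magic}")
        params = dict(item.split("=", 1) for item in fh.readline().strip().lstrip("#").split("\t"))
        meta = {}
        for item in fh.readline().strip().split("\t")[1:]:
            key, val = item.split("=", 1)
            try:
                meta[key] = ast.literal_eval(val)
            except (ValueError, SyntaxError):
                meta[key] = val
        header = fh.readline()
        if not header.startswith("feature_id"):
            raise ValueError("malformed model file header")
        l, k = int(params["l"]), int(params["k"])
        rc = bool(int(params["rc"]))
        coef = np.zeros(GkmFeatureSpace(l, k, rc).n_features)
        for line in fh:
            idx, val = line.split("\t")
            coef[int(idx)] = float(val)
    return GappedKmerModel(
        l=l, k=k, rc_collapse=rc, coef=coef,
        intercept=float(params["intercept"]), trainer_meta=meta,
    )
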