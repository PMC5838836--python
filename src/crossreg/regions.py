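"""Genomic intervals, BED I/O, dataset merging, and overlap statistics.

All coordinates are 0-based half-open.  SNP tables are 1-based on disk
(chip/VCF convention) and converted at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import defaultdict

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "NamedRegion",
    "MergedRegion",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "merge_datasets",
    "merge_regions",
    "overlap_stats",
    "read_snp_table",
    "snp_set_enrichment",
    "BedParseError",
]


class BedParseError(ValueError):
    pass


@dataclass(frozen=True, order=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"bad interval {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True, order=True)
class NamedRegion:
    chrom: str
    start: int
    end: int
    name: str = ""
    strand: str | None = None
    source_dataset: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"bad region {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)


@dataclass(frozen=True)
class MergedRegion:
    """A non-overlapping union interval with the provenance of every input."""

    chrom: str
    start: int
    end: int
    names: tuple[str, ...]

    @property
    def name(self) -> str:
        return ",".join(self.names)

    @property
    def annotation_count(self) -> int:
        return len(self.names)

    def __len__(self) -> int:
        return self.end - self.start


def read_bed(path) -> list[NamedRegion]:
    """Read BED3–BED6; missing names are auto-generated as ``chrom:start-end``."""
    regions: list[NamedRegion] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise BedParseError(f"line {lineno}: fewer than 3 BED fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise BedParseError(f"line {lineno}: non-integer coordinates") from None
            if start >= end:
                raise BedParseError(f"line {lineno}: start >= end ({start} >= {end})")
            name = fields[3] if len(fields) > 3 and fields[3] not in ("", ".") else f"{chrom}:{start}-{end}"
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else None
            regions.append(NamedRegion(chrom, start, end, name, strand))
    return regions


def write_bed(regions, path, score=None) -> None:
    """Write regions as BED6, sorted by (chrom, start, end).

    ``score`` may be a callable mapping a region to the BED score column
    (the projector stores coverage x 1000 there); default 0.
    """
    ordered = sorted(regions, key=lambda r: (r.chrom, r.start, r.end))
    with open(path, "w") as fh:
        for r in ordered:
            sc = score(r) if score is not None else 0
            strand = getattr(r, "strand", None) or "."
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{sc}\t{strand}\n")


def read_bedgraph(path) -> list[tuple[str, int, int, float]]:
    """Read a 4-column bedGraph into (chrom, start, end, value) tuples."""
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise BedParseError(f"line {lineno}: fewer than 4 bedGraph fields")
            try:
                rows.append((fields[0], int(fields[1]), int(fields[2]), float(fields[3])))
            except ValueError:
                raise BedParseError(f"line {lineno}: malformed bedGraph row") from None
    return rows


def merge_regions(intervals, merge_distance: int = 0):
    """Union of intervals given as (chrom, start, end, payload) tuples.

    Intervals closer than or equal to ``merge_distance`` (default 0:
    book-ended intervals merge) are unioned.  Yields
    (chrom, start, end, [payloads in sorted genomic order]).
    """
    by_chrom: dict[str, list] = defaultdict(list)
    for chrom, start, end, payload in intervals:
        by_chrom[chrom].append((start, end, payload))
    for chrom in sorted(by_chrom):
        items = sorted(by_chrom[chrom], key=lambda t: (t[0], t[1]))
        cur_start, cur_end, payloads = items[0][0], items[0][1], [items[0][2]]
        for start, end, payload in items[1:]:
            if start <= cur_end + merge_distance:
                cur_end = max(cur_end, end)
                payloads.append(payload)
            else:
                yield chrom, cur_start, cur_end, payloads
                cur_start, cur_end, payloads = start, end, [payload]
        yield chrom, cur_start, cur_end, payloads


def merge_datasets(datasets, merge_distance: int = 0) -> list[MergedRegion]:
    """Merge several (label, regions) datasets into non-overlapping regions.

    Overlapping or book-ended intervals are unioned; contributing names are
    kept comma-joinable, prefixed by their dataset label, and their count is
    the region's annotation count.  Idempotent and independent of dataset
    order.
    """
    tagged = []
    for label, regs in datasets:
        for r in regs:
            name = r.name if getattr(r, "name", "") else f"{r.chrom}:{r.start}-{r.end}"
            tag = f"{label}:{name}" if label else name
            tagged.append((r.chrom, r.start, r.end, (r.start, r.end, tag)))
    merged = []
    for chrom, start, end, payloads in merge_regions(tagged, merge_distance):
        names = tuple(tag for _, _, tag in sorted(payloads))
        merged.append(MergedRegion(chrom, start, end, names))
    return merged


def _base_overlap(query, reference) -> int:
    """Total number of bases shared between two region sets."""
    total = 0
    ref_by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for r in reference:
        ref_by_chrom[r.chrom].append((r.start, r.end))
    for chrom in ref_by_chrom:
        ref_by_chrom[chrom].sort()
    for q in query:
        for start, end in ref_by_chrom.get(q.chrom, ()):
            if start >= q.end:
                break
            lo, hi = max(q.start, start), min(q.end, end)
            if lo < hi:
                total += hi - lo
    return total


def overlap_stats(query, reference, genome_size: int | None = None) -> dict:
    """Coverage statistics of a reference region set by a query set.

    Overlap means >= 1 shared base.  Percentages are rounded to 1 decimal.
    Returns n_query_hitting_ref, n_ref_covered, pct_ref_covered,
    query_total_Mb and, when ``genome_size`` is given, pct_genome.
    """
    reference = list(reference)
    query = list(query)
    if not reference:
        raise ValueError("reference region set is empty")
    q_by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for q in query:
        q_by_chrom[q.chrom].append((q.start, q.end))
    for chrom in q_by_chrom:
        q_by_chrom[chrom].sort()

    def hits(region, table) -> bool:
        for start, end in table.get(region.chrom, ()):
            if start >= region.end:
                return False
            if end > region.start:
                return True
        return False

    r_by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for r in reference:
        r_by_chrom[r.chrom].append((r.start, r.end))
    for chrom in r_by_chrom:
        r_by_chrom[chrom].sort()

    n_ref_covered = sum(1 for r in reference if hits(r, q_by_chrom))
    n_query_hitting = sum(1 for q in query if hits(q, r_by_chrom))
    total_len = sum(len(q) for q in query)
    out = {
        "n_query_hitting_ref": n_query_hitting,
        "n_ref_covered": n_ref_covered,
        "pct_ref_covered": round(100.0 * n_ref_covered / len(reference), 1),
        "query_total_Mb": round(total_len / 1e6, 6),
    }
    if genome_size is not None:
        out["pct_genome"] = round(100.0 * total_len / genome_size, 1)
    return out


def read_snp_table(path) -> pd.DataFrame:
    """Read a tab-separated SNP table (chrom, pos_1based, id, ref, alt[, p]).

    Positions are converted to 0-based ``pos0`` internally.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = {c.lower(): c for c in df.columns}
    required = ["chrom", "pos", "id", "ref", "alt"]
    missing = [c for c in required if c not in cols]
    if missing:
        raise ValueError(f"SNP table missing columns: {missing}")
    df = df.rename(columns={v: k for k, v in cols.items()})
    df["pos0"] = df["pos"].astype(int) - 1
    return df


def snp_set_enrichment(
    snps: pd.DataFrame,
    categories: dict,
    n_sample: int,
    seed: int,
    bins=tuple(range(1, 21)),
) -> pd.DataFrame:
    """Count significant SNPs per category at -log10(p) thresholds.

    Each category is either a region set (SNPs falling inside are taken) or
    an explicit boolean mask / index over ``snps``.  From each category,
    ``n_sample`` SNPs are sampled without replacement (seeded).  Categories
    smaller than ``n_sample`` are counted in full and the counts scaled by
    ``n_sample / size``.  Returns a DataFrame indexed by category with one
    column per -log10(p) bin.
    """
    if "p" not in snps.columns:
        raise ValueError("SNP table has no p-value column")
    p = snps["p"].to_numpy(float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    neglogp = -np.log10(p)
    rng = np.random.default_rng(seed)
    rows = {}
    for label in sorted(categories):
        spec = categories[label]
        if isinstance(spec, (list, tuple)) and spec and hasattr(spec[0], "chrom"):
            by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
            for r in spec:
                by_chrom[r.chrom].append((r.start, r.end))
            for chrom in by_chrom:
                by_chrom[chrom].sort()
            mask = np.array([
                any(s <= pos < e for s, e in by_chrom.get(chrom, ()))
                for chrom, pos in zip(snps["chrom"], snps["pos0"])
            ])
            idx = np.flatnonzero(mask)
        else:
            idx = np.asarray(spec)
            if idx.dtype == bool:
                idx = np.flatnonzero(idx)
        if idx.size == 0:
            raise ValueError(f"category {label!r} is empty")
        if idx.size >= n_sample:
            chosen = rng.choice(idx, size=n_sample, replace=False)
            scale = 1.0
        else:
            chosen = idx
            scale = n_sample / idx.size
        vals = neglogp[chosen]
        rows[label] = [scale * float(np.sum(vals >= b)) for b in bins]
    return pd.DataFrame(rows, index=[f"neglogp>={b}" for b in bins]).T
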