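"""UCSC chain files: parsing, validation, indexing, and inversion.

A chain describes a pairwise alignment between a *source* assembly (the
``t`` side of the UCSC header, the genome regions are projected **from**)
and a *target* assembly (the ``q`` side, projected **to**).  The body is a
list of gapless aligned blocks; ``dt`` / ``dq`` are the unaligned gaps that
follow each block on the source / target respectively.

Coordinate conventions (relied on by every other module):

* all intervals are 0-based half-open;
* the source strand is always ``+``;
* when the target strand is ``-`` the stored target coordinates live on the
  *reversed* target sequence, and the forward-strand interval is
  ``(target_size - end, target_size - start)``.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from typing import Iterator

from intervaltree import IntervalTree

__all__ = [
    "AssemblyInfo",
    "AlignmentBlock",
    "Chain",
    "ChainSet",
    "ChainParseError",
    "parse_chain_file",
    "write_chain_file",
    "invert_chains",
]


class ChainParseError(ValueError):
    """Malformed chain file; message carries the offending line number."""


@dataclass(frozen=True)
class AssemblyInfo:
    """A named assembly with its chromosome lengths."""

    name: str
    chrom_sizes: dict[str, int]

    def __post_init__(self) -> None:
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length {size}")


@dataclass(frozen=True)
class AlignmentBlock:
    """One gapless block: ``size`` aligned bases, then ``dt``/``dq`` gap bases."""

    size: int
    dt: int = 0
    dq: int = 0

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError(f"block size must be positive, got {self.size}")
        if self.dt < 0 or self.dq < 0:
            raise ValueError(f"block gaps must be non-negative, got dt={self.dt} dq={self.dq}")


@dataclass(frozen=True)
class Chain:
    """One alignment chain between a source and a target assembly."""

    chain_id: int
    score: float
    s_chrom: str
    s_size: int
    s_start: int
    s_end: int
    t_chrom: str
    t_size: int
    t_strand: str
    t_start: int
    t_end: int
    blocks: tuple[AlignmentBlock, ...]

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("chain must contain at least one block")
        if self.s_start >= self.s_end or self.t_start >= self.t_end:
            raise ValueError(f"chain {self.chain_id}: empty span")
        if self.t_strand not in "+-":
            raise ValueError(f"chain {self.chain_id}: bad target strand {self.t_strand!r}")
        last = self.blocks[-1]
        if last.dt != 0 or last.dq != 0:
            raise ValueError(f"chain {self.chain_id}: final block must have zero gaps")
        s_span = sum(b.size + b.dt for b in self.blocks)
        t_span = sum(b.size + b.dq for b in self.blocks)
        if s_span != self.s_end - self.s_start:
            raise ValueError(
                f"chain {self.chain_id}: block-sum mismatch on source "
                f"({s_span} != {self.s_end - self.s_start})"
            )
        if t_span != self.t_end - self.t_start:
            raise ValueError(
                f"chain {self.chain_id}: block-sum mismatch on target "
                f"({t_span} != {self.t_end - self.t_start})"
            )

    # -- coordinate helpers -------------------------------------------------

    def aligned_segments(self) -> Iterator[tuple[int, int, int, int]]:
        """Yield ``(s_start, s_end, t_start, t_end)`` per block, stored coords."""
        s, t = self.s_start, self.t_start
        for b in self.blocks:
            yield s, s + b.size, t, t + b.size
            s += b.size + b.dt
            t += b.size + b.dq

    def map_base(self, s_pos: int) -> int | None:
        """Stored-coordinate target position of an aligned source base, else None."""
        for s0, s1, t0, _ in self.aligned_segments():
            if s0 <= s_pos < s1:
                return t0 + (s_pos - s0)
        return None

    def target_forward(self, start: int, end: int) -> tuple[int, int]:
        """Convert a stored target interval to forward-strand coordinates."""
        if self.t_strand == "+":
            return start, end
        return self.t_size - end, self.t_size - start

    @property
    def aligned_bases(self) -> int:
        return sum(b.size for b in self.blocks)


@dataclass
class ChainSet:
    """Chains between one ordered pair of assemblies, indexed by source span.

    The index returns *all* chains overlapping a query span; overlapping
    source spans across chains are legal (duplications map one source
    region to several targets).
    """

    assembly_from: AssemblyInfo
    assembly_to: AssemblyInfo
    chains: list[Chain] = field(default_factory=list)
    _index: dict[str, IntervalTree] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for chain in self.chains:
            self._check(chain)
        self._reindex()

    def _check(self, chain: Chain) -> None:
        sizes = self.assembly_from.chrom_sizes
        if chain.s_chrom not in sizes:
            raise ValueError(f"chain {chain.chain_id}: source chromosome {chain.s_chrom!r} "
                             f"not in assembly {self.assembly_from.name!r}")
        if sizes[chain.s_chrom] != chain.s_size:
            raise ValueError(f"chain {chain.chain_id}: source size {chain.s_size} disagrees "
                             f"with assembly ({sizes[chain.s_chrom]})")

    def _reindex(self) -> None:
        self._index = {}
        for chain in self.chains:
            tree = self._index.setdefault(chain.s_chrom, IntervalTree())
            tree.addi(chain.s_start, chain.s_end, chain)

    def overlapping(self, chrom: str, start: int, end: int) -> list[Chain]:
        """All chains whose source span overlaps [start, end) on chrom."""
        tree = self._index.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(start, end)]
        return sorted(hits, key=lambda c: c.chain_id)

    def __len__(self) -> int:
        return len(self.chains)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ChainSet):
            return NotImplemented
        return (
            self.assembly_from == other.assembly_from
            and self.assembly_to == other.assembly_to
            and sorted(self.chains, key=lambda c: c.chain_id)
            == sorted(other.chains, key=lambda c: c.chain_id)
        )


def _open_text(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def parse_chain_file(path) -> ChainSet:
    """Parse a UCSC chain file (gzip-transparent) into a validated ChainSet.

    Header layout: ``chain score tName tSize tStrand tStart tEnd qName qSize
    qStrand qStart qEnd id`` where the ``t`` side is the projection source.
    Raises :class:`ChainParseError` with a line number on malformed input.
    """
    chains: list[Chain] = []
    from_sizes: dict[str, int] = {}
    to_sizes: dict[str, int] = {}
    seen_ids: set[int] = set()

    with _open_text(path) as fh:
        lines = fh.read().splitlines()

    i = 0
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        if not line or line.startswith("#"):
            i += 1
            continue
        fields = line.split()
        if fields[0] != "chain":
            raise ChainParseError(f"line {i + 1}: expected chain header, got {line!r}")
        if len(fields) != 13:
            raise ChainParseError(f"line {i + 1}: malformed header ({len(fields)} fields, need 13)")
        try:
            score = float(fields[1])
            s_chrom, s_size = fields[2], int(fields[3])
            s_strand = fields[4]
            s_start, s_end = int(fields[5]), int(fields[6])
            t_chrom, t_size = fields[7], int(fields[8])
            t_strand = fields[9]
            t_start, t_end = int(fields[10]), int(fields[11])
            chain_id = int(fields[12])
        except ValueError as exc:
            raise ChainParseError(f"line {i + 1}: malformed header field ({exc})") from None
        if s_strand != "+":
            raise ChainParseError(f"line {i + 1}: source strand must be '+', got {s_strand!r}")
        if chain_id in seen_ids:
            raise ChainParseError(f"line {i + 1}: duplicate chain id {chain_id}")
        seen_ids.add(chain_id)

        header_line = i + 1
        i += 1
        blocks: list[AlignmentBlock] = []
        while i < n:
            body = lines[i].strip()
            if not body:
                break
            parts = body.split()
            try:
                if len(parts) == 3:
                    blocks.append(AlignmentBlock(int(parts[0]), int(parts[1]), int(parts[2])))
                elif len(parts) == 1:
                    blocks.append(AlignmentBlock(int(parts[0])))
                    i += 1
                    break
                else:
                    raise ValueError(f"{len(parts)} fields")
            except ValueError as exc:
                raise ChainParseError(f"line {i + 1}: malformed block line ({exc})") from None
            i += 1
        if not blocks or blocks[-1].dt != 0 or blocks[-1].dq != 0:
            raise ChainParseError(f"line {header_line}: chain {chain_id} missing terminal block")
        try:
            chain = Chain(
                chain_id=chain_id, score=score,
                s_chrom=s_chrom, s_size=s_size, s_start=s_start, s_end=s_end,
                t_chrom=t_chrom, t_size=t_size, t_strand=t_strand,
                t_start=t_start, t_end=t_end, blocks=tuple(blocks),
            )
        except ValueError as exc:
            raise ChainParseError(f"line {header_line}: {exc}") from None
        for sizes, chrom, size in ((from_sizes, s_chrom, s_size), (to_sizes, t_chrom, t_size)):
            if sizes.setdefault(chrom, size) != size:
                raise ChainParseError(
                    f"line {header_line}: inconsistent size for chromosome {chrom!r}"
                )
        chains.append(chain)

    return ChainSet(
        assembly_from=AssemblyInfo("from", from_sizes),
        assembly_to=AssemblyInfo("to", to_sizes),
        chains=chains,
    )


def write_chain_file(chains: ChainSet, path) -> None:
    """Write a ChainSet in UCSC chain format; round-trips through the parser."""
    with _open_text(path, "wt") as fh:
        for c in chains.chains:
            score = int(c.score) if float(c.score).is_integer() else c.score
            fh.write(
                f"chain {score} {c.s_chrom} {c.s_size} + {c.s_start} {c.s_end} "
                f"{c.t_chrom} {c.t_size} {c.t_strand} {c.t_start} {c.t_end} {c.chain_id}\n"
            )
            for b in c.blocks[:-1]:
                fh.write(f"{b.size} {b.dt} {b.dq}\n")
            fh.write(f"{c.blocks[-1].size}\n\n")


def _invert_chain(c: Chain) -> Chain:
    """Swap source and target, keeping the per-base correspondence identical."""
    segs = list(c.aligned_segments())
    if c.t_strand == "+":
        # Roles swap directly; both sides stay increasing.
        pairs = [(t0, s0, s1 - s0) for s0, s1, t0, _ in segs]
        new_t_strand = "+"
        new_s_chrom, new_s_size = c.t_chrom, c.t_size
        new_t_chrom, new_t_size = c.s_chrom, c.s_size
    else:
        # Old target stored on the reversed sequence: express the new source
        # forward, which reverses block order and pushes the old source side
        # onto its reversed sequence (new target strand '-').
        pairs = [
            (c.t_size - (t0 + (s1 - s0)), c.s_size - s1, s1 - s0)
            for s0, s1, t0, _ in segs
        ]
        pairs.reverse()
        new_t_strand = "-"
        new_s_chrom, new_s_size = c.t_chrom, c.t_size
        new_t_chrom, new_t_size = c.s_chrom, c.s_size

    blocks: list[AlignmentBlock] = []
    for idx, (s0, t0, size) in enumerate(pairs):
        if idx + 1 < len(pairs):
            ns, nt, _ = pairs[idx + 1]
            dt = ns - (s0 + size)
            dq = nt - (t0 + size)
        else:
            dt = dq = 0
        blocks.append(AlignmentBlock(size, dt, dq))

    return Chain(
        chain_id=c.chain_id, score=c.score,
        s_chrom=new_s_chrom, s_size=new_s_size,
        s_start=pairs[0][0], s_end=pairs[-1][0] + pairs[-1][2],
        t_chrom=new_t_chrom, t_size=new_t_size, t_strand=new_t_strand,
        t_start=pairs[0][1], t_end=pairs[-1][1] + pairs[-1][2],
        blocks=tuple(blocks),
    )


def invert_chains(chains: ChainSet) -> ChainSet:
    """Reverse the mapping direction of every chain.

    The inverted set projects target coordinates back to the source; for
    every aligned base pair (s, t) of the input, the output aligns (t, s).
    Negative-strand chains are renormalized so the new source strand is '+'.
    """
    return ChainSet(
        assembly_from=replace(chains.assembly_to, name=chains.assembly_to.name),
        assembly_to=replace(chains.assembly_from, name=chains.assembly_from.name),
        chains=[_invert_chain(c) for c in chains.chains],
    )
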