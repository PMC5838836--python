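"""Shared fixtures and brute-force oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from crossreg.chain import AlignmentBlock, AssemblyInfo, Chain, ChainSet
from crossreg.pipeline import run_fixture_pipeline
from crossreg.simulate import FixtureConfig, generate_fixture


# ---------------------------------------------------------------------------
# chain construction helpers

def make_chain(chain_id, s_chrom, s_size, s_start, blocks,
               t_chrom, t_size, t_start, t_strand="+", score=None):
    """Build a Chain from (size, dt, dq) block tuples."""
    blk = tuple(AlignmentBlock(*b) for b in blocks)
    s_end = s_start + sum(b.size + b.dt for b in blk)
    t_end = t_start + sum(b.size + b.dq for b in blk)
    return Chain(
        chain_id=chain_id, score=score if score is not None else sum(b.size for b in blk),
        s_chrom=s_chrom, s_size=s_size, s_start=s_start, s_end=s_end,
        t_chrom=t_chrom, t_size=t_size, t_strand=t_strand,
        t_start=t_start, t_end=t_end, blocks=blk,
    )


def make_chainset(chains, from_name="src", to_name="tgt"):
    from_sizes, to_sizes = {}, {}
    for c in chains:
        from_sizes[c.s_chrom] = c.s_size
        to_sizes[c.t_chrom] = c.t_size
    return ChainSet(AssemblyInfo(from_name, from_sizes),
                    AssemblyInfo(to_name, to_sizes), list(chains))


def identity_chainset(chrom="chr1", size=1000):
    """A single chain aligning a chromosome to itself base for base."""
    c = make_chain(1, chrom, size, 0, [(size, 0, 0)], chrom, size, 0)
    return make_chainset([c])


def per_base_map(chain):
    """Exhaustive source -> (stored target pos) map of one chain."""
    mapping = {}
    for s0, s1, t0, _ in chain.aligned_segments():
        for off in range(s1 - s0):
            mapping[s0 + off] = t0 + off
    return mapping


def oracle_project(iv, chain):
    """Brute-force coverage and forward-coordinate target span through a chain."""
    mapping = per_base_map(chain)
    hits = [mapping[p] for p in range(iv.start, iv.end) if p in mapping]
    coverage = len(hits) / (iv.end - iv.start)
    if not hits:
        return coverage, None
    lo, hi = min(hits), max(hits) + 1
    start, end = chain.target_forward(lo, hi)
    return coverage, (chain.t_chrom, start, end, chain.t_strand)


def random_chain(rng, chain_id=1, s_chrom="chrA", t_chrom="chrB",
                 max_blocks=6, t_strand="+"):
    """A random small chain (<= ~10 kb span) with valid block sums."""
    n_blocks = int(rng.integers(1, max_blocks + 1))
    blocks = []
    for i in range(n_blocks):
        size = int(rng.integers(1, 400))
        if i == n_blocks - 1:
            blocks.append((size, 0, 0))
        else:
            blocks.append((size, int(rng.integers(0, 200)), int(rng.integers(0, 200))))
    s_span = sum(s + dt for s, dt, _ in blocks)
    t_span = sum(s + dq for s, _, dq in blocks)
    s_start = int(rng.integers(0, 500))
    t_start = int(rng.integers(0, 500))
    s_size = s_start + s_span + int(rng.integers(0, 500))
    t_size = t_start + t_span + int(rng.integers(0, 500))
    return make_chain(chain_id, s_chrom, s_size, s_start, blocks,
                      t_chrom, t_size, t_start, t_strand=t_strand)


# ---------------------------------------------------------------------------
# session-scoped fixture genome and pipeline run

@pytest.fixture(scope="session")
def fx():
    """The default synthetic source/target fixture (seed 42)."""
    return generate_fixture(FixtureConfig(seed=42))


@pytest.fixture(scope="session")
def pipeline_out(fx):
    """Full pipeline run over the default fixture."""
    return run_fixture_pipeline(fx, seed=0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
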