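"""Seeded synthetic genome-pair fixtures with exact ground truth.

The generator fabricates a small source genome, derives a target genome
from it by an explicit rearrangement plan (inversions, deletions,
insertions, tandem duplications, translocations), and emits the alignment
chains *directly from the rearrangement map* — never by re-alignment — so
the per-base source/target correspondence is exact by construction.  On
top of the genome pair it plants regulatory regions (promoter-like,
enhancer-like, TFBS-like), motif instances, CAGE peaks, signal and
conservation tracks enriched over "active" regions, reference
enhancer/promoter sets, and SNPs that destroy planted motifs, together
with a manifest of the expected mapping/filtering/scoring outcome of every
planted object.

The genome background is i.i.d. uniform over ACGT: the simplest background
with fully controllable signal.  Defaults are chosen to exercise every
pipeline stage (primary mapping, reciprocal failure, duplication rescue,
deletion loss, strand flips) within a 2 Mb genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from crossreg.chain import AlignmentBlock, AssemblyInfo, Chain, ChainSet, invert_chains, write_chain_file
from crossreg.regions import NamedRegion, write_bed

__all__ = [
    "FixtureConfig",
    "Fixture",
    "generate_fixture",
    "planted_motif_training_set",
    "DEFAULT_EVENTS",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# Default rearrangement plan for a 2 x 1 Mb source genome.  Events must not
# overlap each other on the source.
DEFAULT_EVENTS = (
    {"kind": "inversion", "chrom": "chrS1", "start": 300_000, "end": 320_000},
    {"kind": "deletion", "chrom": "chrS1", "start": 500_000, "end": 505_000},
    {"kind": "insertion", "chrom": "chrS1", "pos": 650_000, "size": 4_000},
    {"kind": "tandem_duplication", "chrom": "chrS1", "start": 700_000, "end": 703_000},
    {"kind": "translocation", "chrom": "chrS2", "start": 100_000, "end": 110_000,
     "dest_chrom": "chrS1"},
    {"kind": "inversion", "chrom": "chrS2", "start": 400_000, "end": 410_000},
)

# Planted motif consensus sequences (CREB- and E-box-like).
DEFAULT_MOTIFS = ("TGACGTCA", "GCCACGTGAC")


@dataclass
class FixtureConfig:
    seed: int = 42
    chrom_sizes: dict = field(
        default_factory=lambda: {"chrS1": 1_000_000, "chrS2": 1_000_000}
    )
    events: tuple = DEFAULT_EVENTS
    n_promoters: int = 30
    n_enhancers: int = 40
    n_tfbs: int = 30
    n_dup_enhancers: int = 2      # planted inside the tandem duplication
    n_deleted_regions: int = 2    # planted inside the deletion
    motifs: tuple = DEFAULT_MOTIFS
    motif_copies: int = 2         # consensus copies per active enhancer
    active_fraction: float = 0.5
    signal_enrichment: float = 8.0
    n_neutral_snps: int = 60
    n_disrupting_snps: int = 20
    promoter_length: tuple = (300, 600)
    enhancer_length: tuple = (400, 900)
    tfbs_length: tuple = (120, 250)

    def validate(self) -> None:
        spans: dict[str, list[tuple[int, int]]] = {}
        for ev in self.events:
            chrom = ev["chrom"]
            if chrom not in self.chrom_sizes:
                raise ValueError(f"event on unknown chromosome {chrom!r}")
            if ev["kind"] == "insertion":
                start, end = ev["pos"], ev["pos"]
            else:
                start, end = ev["start"], ev["end"]
            if end > self.chrom_sizes[chrom]:
                raise ValueError(f"event {ev} exceeds chromosome bounds")
            for s, e in spans.setdefault(chrom, []):
                if start < e and s < end:
                    raise ValueError(f"overlapping events on {chrom}")
            spans[chrom].append((start, end))


@dataclass
class _Segment:
    """One piece of a target chromosome."""

    src_chrom: str | None  # None for novel insertions
    s_start: int
    s_end: int
    strand: str = "+"
    novel_seq: str = ""

    def __len__(self) -> int:
        return len(self.novel_seq) if self.src_chrom is None else self.s_end - self.s_start


@dataclass
class Fixture:
    """All fixture artifacts in memory, plus ground truth."""

    config: FixtureConfig
    source_genome: dict
    target_genome: dict
    fwd_chains: ChainSet
    rev_chains: ChainSet
    regions: list              # planted source NamedRegions (all classes)
    support_regions: list      # jittered companion annotations of active regions
    manifest: pd.DataFrame     # ground truth per planted region
    cage_peaks: list           # target-coordinate NamedRegions
    h3k27ac_track: list        # (chrom, start, end, value)
    rnaseq_track: list
    conservation_track: list
    ref_enhancers: list        # target-coordinate NamedRegions
    ref_promoters: list
    pwm_text: str
    snps: pd.DataFrame         # target-coordinate SNP table with ground truth


def _random_genome(rng, chrom_sizes) -> dict:
    return {
        chrom: _BASES[rng.integers(0, 4, size=size)].tobytes().decode("ascii")
        for chrom, size in sorted(chrom_sizes.items())
    }


def _target_name(src_chrom: str) -> str:
    return src_chrom.replace("chrS", "chrT")


def _build_segments(cfg: FixtureConfig, rng) -> dict[str, list[_Segment]]:
    """Apply the event plan left-to-right, producing target segment lists."""
    events_by_chrom: dict[str, list[dict]] = {c: [] for c in cfg.chrom_sizes}
    translocated: dict[str, list[_Segment]] = {c: [] for c in cfg.chrom_sizes}
    for ev in cfg.events:
        events_by_chrom[ev["chrom"]].append(ev)
    for chrom in events_by_chrom:
        events_by_chrom[chrom].sort(
            key=lambda e: e.get("start", e.get("pos", 0))
        )

    segments: dict[str, list[_Segment]] = {}
    for chrom in sorted(cfg.chrom_sizes):
        size = cfg.chrom_sizes[chrom]
        segs: list[_Segment] = []
        cursor = 0
        for ev in events_by_chrom[chrom]:
            kind = ev["kind"]
            if kind == "insertion":
                pos = ev["pos"]
                if pos > cursor:
                    segs.append(_Segment(chrom, cursor, pos))
                novel = _BASES[rng.integers(0, 4, size=ev["size"])].tobytes().decode("ascii")
                segs.append(_Segment(None, 0, 0, novel_seq=novel))
                cursor = pos
                continue
            start, end = ev["start"], ev["end"]
            if start > cursor:
                segs.append(_Segment(chrom, cursor, start))
            if kind == "deletion":
                pass
            elif kind == "inversion":
                segs.append(_Segment(chrom, start, end, strand="-"))
            elif kind == "tandem_duplication":
                segs.append(_Segment(chrom, start, end))
                segs.append(_Segment(chrom, start, end))
            elif kind == "translocation":
                translocated[ev["dest_chrom"]].append(_Segment(chrom, start, end))
            else:
                raise ValueError(f"unknown event kind {kind!r}")
            cursor = end
        if cursor < size:
            segs.append(_Segment(chrom, cursor, size))
        segments[_target_name(chrom)] = segs
    for dest, segs in translocated.items():
        segments[_target_name(dest)].extend(segs)
    return segments


def _target_sequences(segments, source_genome) -> dict:
    from crossreg.gkm import reverse_complement

    out = {}
    for tchrom, segs in segments.items():
        parts = []
        for seg in segs:
            if seg.src_chrom is None:
                parts.append(seg.novel_seq)
            else:
                piece = source_genome[seg.src_chrom][seg.s_start:seg.s_end]
                parts.append(reverse_complement(piece) if seg.strand == "-" else piece)
        out[tchrom] = "".join(parts)
    return out


def _build_chains(cfg: FixtureConfig, segments, target_sizes) -> ChainSet:
    """Emit chains straight from the segment map (never re-aligned)."""
    chains: list[Chain] = []
    next_id = 1

    for tchrom in sorted(segments):
        t_size = target_sizes[tchrom]
        t_off = 0
        pending: dict | None = None

        def flush():
            nonlocal pending, next_id
            if pending is None:
                return
            blocks = []
            segs = pending["blocks"]  # list of (s_start, s_end, t_start)
            for i, (s0, s1, t0) in enumerate(segs):
                if i + 1 < len(segs):
                    ns0, _, nt0 = segs[i + 1]
                    blocks.append(AlignmentBlock(s1 - s0, ns0 - s1, nt0 - (t0 + (s1 - s0))))
                else:
                    blocks.append(AlignmentBlock(s1 - s0))
            s_start, s_end = segs[0][0], segs[-1][1]
            t_start = segs[0][2]
            t_end = segs[-1][2] + (segs[-1][1] - segs[-1][0])
            chains.append(Chain(
                chain_id=next_id, score=sum(b.size for b in blocks),
                s_chrom=pending["src_chrom"], s_size=cfg.chrom_sizes[pending["src_chrom"]],
                s_start=s_start, s_end=s_end,
                t_chrom=tchrom, t_size=t_size, t_strand="+",
                t_start=t_start, t_end=t_end, blocks=tuple(blocks),
            ))
            next_id += 1
            pending = None

        for seg in segments[tchrom]:
            if seg.src_chrom is None:
                t_off += len(seg)  # novel bases widen the pending dq gap
                continue
            if seg.strand == "-":
                flush()
                # single-block chain; stored target coords on the reversed sequence
                chains.append(Chain(
                    chain_id=next_id, score=len(seg),
                    s_chrom=seg.src_chrom, s_size=cfg.chrom_sizes[seg.src_chrom],
                    s_start=seg.s_start, s_end=seg.s_end,
                    t_chrom=tchrom, t_size=t_size, t_strand="-",
                    t_start=t_size - (t_off + len(seg)), t_end=t_size - t_off,
                    blocks=(AlignmentBlock(len(seg)),),
                ))
                next_id += 1
            else:
                colinear = (
                    pending is not None
                    and pending["src_chrom"] == seg.src_chrom
                    and seg.s_start >= pending["blocks"][-1][1]
                )
                if not colinear:
                    flush()
                    pending = {"src_chrom": seg.src_chrom, "blocks": []}
                pending["blocks"].append((seg.s_start, seg.s_end, t_off))
            t_off += len(seg)
        flush()

    src_assembly = AssemblyInfo("source", dict(sorted(cfg.chrom_sizes.items())))
    tgt_assembly = AssemblyInfo("target", dict(sorted(target_sizes.items())))
    return ChainSet(assembly_from=src_assembly, assembly_to=tgt_assembly, chains=chains)


def _expected_targets(region: NamedRegion, segments) -> list[tuple[str, int, int, str]]:
    """All target placements of a source region fully inside one segment."""
    hits = []
    for tchrom in sorted(segments):
        t_off = 0
        for seg in segments[tchrom]:
            if (seg.src_chrom == region.chrom
                    and seg.s_start <= region.start and region.end <= seg.s_end):
                if seg.strand == "+":
                    start = t_off + (region.start - seg.s_start)
                else:
                    start = t_off + (seg.s_end - region.end)
                hits.append((tchrom, start, start + len(region), seg.strand))
            t_off += len(seg)
    return hits


def _place_regions(cfg: FixtureConfig, rng) -> list[dict]:
    """Plant non-overlapping source regions clear of event boundaries."""
    margin = 60
    forbidden: dict[str, list[tuple[int, int]]] = {c: [] for c in cfg.chrom_sizes}
    special: list[tuple[str, int, int, str]] = []  # chrom,start,end,tag
    for ev in cfg.events:
        chrom = ev["chrom"]
        if ev["kind"] == "insertion":
            forbidden[chrom].append((ev["pos"] - margin, ev["pos"] + margin))
        else:
            # boundaries are off-limits; interiors are allowed (deliberately used)
            forbidden[chrom].append((ev["start"] - margin, ev["start"] + margin))
            forbidden[chrom].append((ev["end"] - margin, ev["end"] + margin))
            if ev["kind"] == "deletion":
                special.append((chrom, ev["start"], ev["end"], "deleted"))
            elif ev["kind"] == "tandem_duplication":
                special.append((chrom, ev["start"], ev["end"], "duplicated"))

    taken: dict[str, list[tuple[int, int]]] = {c: list(forbidden[c]) for c in forbidden}

    def conflicts(chrom, start, end) -> bool:
        return any(s < end and e > start for s, e in taken[chrom])

    placements: list[dict] = []
    chroms = sorted(cfg.chrom_sizes)

    def sample_region(length_range, cls, where=None) -> dict:
        lo, hi = length_range
        for _ in range(1000):
            length = int(rng.integers(lo, hi + 1))
            if where is None:
                chrom = chroms[int(rng.integers(len(chroms)))]
                limit = cfg.chrom_sizes[chrom] - length
                start = int(rng.integers(margin, limit - margin))
            else:
                chrom, wstart, wend = where
                if wend - wstart - 2 * margin <= length:
                    continue
                start = int(rng.integers(wstart + margin, wend - margin - length))
            end = start + length
            if conflicts(chrom, start, end):
                continue
            taken[chrom].append((start, end))
            return {"chrom": chrom, "start": start, "end": end, "class": cls}
        raise ValueError("could not place a region; plan too dense for the genome")

    # special regions first: inside the duplication / deletion spans
    dup = next(((c, s, e) for c, s, e, tag in special if tag == "duplicated"), None)
    dele = next(((c, s, e) for c, s, e, tag in special if tag == "deleted"), None)
    for i in range(cfg.n_dup_enhancers if dup else 0):
        r = sample_region((300, 500), "enhancer", where=dup)
        r["fate"] = "duplicated"
        placements.append(r)
    for i in range(cfg.n_deleted_regions if dele else 0):
        r = sample_region((300, 500), "enhancer", where=dele)
        r["fate"] = "deleted"
        placements.append(r)

    for cls, count, lrange in (
        ("promoter", cfg.n_promoters, cfg.promoter_length),
        ("enhancer", cfg.n_enhancers, cfg.enhancer_length),
        ("tfbs", cfg.n_tfbs, cfg.tfbs_length),
    ):
        for _ in range(count):
            r = sample_region(lrange, cls)
            r["fate"] = "normal"
            placements.append(r)
    return placements


def _plant_motifs(source_genome: dict, placements, cfg: FixtureConfig, rng) -> tuple[dict, list[dict]]:
    """Overwrite active-enhancer sequence with motif consensus copies."""
    genomes = {c: bytearray(s, "ascii") for c, s in source_genome.items()}
    planted_sites = []
    for r in placements:
        if not r.get("active") or r["class"] != "enhancer" or r["fate"] == "deleted":
            continue
        length = r["end"] - r["start"]
        for copy in range(cfg.motif_copies):
            motif = cfg.motifs[int(rng.integers(len(cfg.motifs)))]
            # motifs sit in the central third (the enhancer "core")
            lo, hi = length // 3, 2 * length // 3 - len(motif)
            offset = int(rng.integers(lo, max(lo + 1, hi)))
            start = r["start"] + offset
            genomes[r["chrom"]][start:start + len(motif)] = motif.encode("ascii")
            planted_sites.append({
                "chrom": r["chrom"], "start": start, "end": start + len(motif),
                "motif": motif, "region": r["name"],
            })
    return {c: bytes(b).decode("ascii") for c, b in genomes.items()}, planted_sites


def _jaspar_text(motifs_consensus, pseudo: int = 2, strong: int = 94) -> str:
    """JASPAR-format PFMs whose consensus is the planted motif."""
    lines = []
    for i, consensus in enumerate(motifs_consensus, 1):
        lines.append(f">PL{i:04d}.1\tplanted_{i}")
        for base in "ACGT":
            counts = [strong if c == base else pseudo for c in consensus]
            lines.append(f"{base}  [ " + " ".join(f"{v:3d}" for v in counts) + " ]")
    return "\n".join(lines) + "\n"


def _tile_track(chrom_sizes, highlights, rng, base_range, high_value, tile=5000):
    """Non-overlapping piecewise-constant track with elevated highlight spans."""
    track = []
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        spans = sorted((s, e) for c, s, e in highlights if c == chrom)
        cursor = 0
        for s, e in spans:
            s = max(s, cursor)  # clip in case highlight spans touch
            if s >= e:
                continue
            while cursor < s:
                end = min(cursor + tile, s)
                track.append((chrom, cursor, end,
                              round(float(rng.uniform(*base_range)), 4)))
                cursor = end
            track.append((chrom, s, e, high_value))
            cursor = e
        while cursor < size:
            end = min(cursor + tile, size)
            track.append((chrom, cursor, end,
                          round(float(rng.uniform(*base_range)), 4)))
            cursor = end
    return track


def generate_fixture(cfg: FixtureConfig = FixtureConfig(), outdir=None) -> Fixture:
    """Build the full fixture; optionally write every artifact under outdir.

    Deterministic: the same config (including seed) regenerates byte-identical
    outputs.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    source = _random_genome(rng, cfg.chrom_sizes)
    segments = _build_segments(cfg, rng)

    placements = _place_regions(cfg, rng)
    for i, r in enumerate(placements):
        r["name"] = f"{r['class']}_{i:04d}"
    # active regions get planted motifs and enriched signal
    for r in placements:
        r["active"] = (
            r["fate"] != "deleted"
            and bool(rng.random() < cfg.active_fraction or r["fate"] == "duplicated")
        )
    source, planted_sites = _plant_motifs(source, placements, cfg, rng)

    target = _target_sequences(segments, source)
    target_sizes = {c: len(s) for c, s in target.items()}
    fwd = _build_chains(cfg, segments, target_sizes)
    rev = invert_chains(fwd)

    # ground truth per region
    rows = []
    regions = []
    for r in placements:
        named = NamedRegion(r["chrom"], r["start"], r["end"], r["name"])
        regions.append(named)
        targets = _expected_targets(named, segments)
        if not targets:
            status, stage = "unmapped", ""
        elif len(targets) == 1:
            status, stage = "mapped", "primary"
        else:
            status, stage = "mapped", "rescue"
        rows.append({
            "name": r["name"], "class": r["class"],
            "chrom": r["chrom"], "start": r["start"], "end": r["end"],
            "active": r["active"], "fate": r["fate"],
            "expected_status": status, "expected_stage": stage,
            "expected_filter": (
                "retain" if r["active"] and status == "mapped"
                else ("drop" if status == "mapped" else "")
            ),
            "n_expected_targets": len(targets),
            "expected_targets": "|".join(
                f"{c}:{s}-{e}:{st}" for c, s, e, st in targets
            ),
        })
    manifest = pd.DataFrame(rows)

    # companion annotations: active regions are independently supported by a
    # second (jittered) dataset, so merged annotation counts separate active
    # from inactive regions the way multi-dataset support does in real data
    support = []
    for r in placements:
        if r["active"] and r["fate"] != "deleted":
            jitter = int(rng.integers(-30, 31))
            start = max(0, r["start"] + jitter)
            support.append(NamedRegion(
                r["chrom"], start, start + (r["end"] - r["start"]),
                f"support_{r['name']}"
            ))

    # target-coordinate artifacts -----------------------------------------
    def first_target(name):
        row = manifest.loc[manifest["name"] == name].iloc[0]
        if not row["expected_targets"]:
            return None
        c, span, st = row["expected_targets"].split("|")[0].split(":")
        s, e = span.split("-")
        return c, int(s), int(e), st

    active_enh, active_prom = [], []
    for r in placements:
        if not r["active"]:
            continue
        t = first_target(r["name"])
        if t is None:
            continue
        c, s, e, st = t
        named_t = NamedRegion(c, s, e, r["name"], st if st == "-" else None)
        if r["class"] == "enhancer":
            active_enh.append(named_t)
        elif r["class"] == "promoter":
            active_prom.append(named_t)

    cage = []
    for i, p in enumerate(active_prom):
        mid = (p.start + p.end) // 2
        cage.append(NamedRegion(p.chrom, max(0, mid - 25), mid + 25, f"cage_{i:04d}a"))
        cage.append(NamedRegion(p.chrom, min(p.end - 10, mid + 60),
                                min(p.end + 50, mid + 110), f"cage_{i:04d}b"))
    # background CAGE noise
    tchroms = sorted(target_sizes)
    for i in range(15):
        chrom = tchroms[int(rng.integers(len(tchroms)))]
        start = int(rng.integers(0, target_sizes[chrom] - 60))
        cage.append(NamedRegion(chrom, start, start + 50, f"cage_bg_{i:04d}"))

    enh_spans = [(r.chrom, r.start, r.end) for r in active_enh]
    prom_spans = [(r.chrom, r.start, r.end) for r in active_prom]
    all_active = enh_spans + prom_spans
    h3k27ac = _tile_track(target_sizes, enh_spans, rng, (0.2, 1.0),
                          cfg.signal_enrichment)
    rnaseq = _tile_track(target_sizes, all_active, rng, (0.2, 1.0),
                         cfg.signal_enrichment)
    conservation = _tile_track(target_sizes, all_active, rng, (0.05, 0.3), 0.95)

    # SNPs (target coordinates, 1-based in the table) ----------------------
    snp_rows = []
    region_spans = {}
    for c, s, e in all_active:
        region_spans.setdefault(c, []).append((s, e))

    def in_active(chrom, pos0):
        return any(s <= pos0 < e for s, e in region_spans.get(chrom, ()))

    bases = "ACGT"
    planted_in_target = []
    for site in planted_sites:
        src_region = NamedRegion(site["chrom"], site["start"], site["end"], "m")
        t_hits = _expected_targets(src_region, segments)
        for c, s, e, st in t_hits:
            planted_in_target.append((c, s, e, st, site["motif"]))

    n_disrupt = 0
    for c, s, e, st, motif in planted_in_target:
        if n_disrupt >= cfg.n_disrupting_snps:
            break
        # hit the middle of the motif instance on the target genome
        pos0 = (s + e) // 2
        ref = target[c][pos0]
        alt = bases[(bases.index(ref) + 2) % 4]
        snp_rows.append({
            "chrom": c, "pos": pos0 + 1, "id": f"snp_mot_{n_disrupt:04d}",
            "ref": ref, "alt": alt,
            "p": float(10 ** -rng.uniform(4, 9)),
            "expected_sign": "negative", "category": "motif_disrupting",
        })
        n_disrupt += 1

    for i in range(cfg.n_neutral_snps):
        for _ in range(200):
            chrom = tchroms[int(rng.integers(len(tchroms)))]
            pos0 = int(rng.integers(50, target_sizes[chrom] - 50))
            if not in_active(chrom, pos0):
                break
        ref = target[chrom][pos0]
        alt = bases[(bases.index(ref) + 1) % 4]
        snp_rows.append({
            "chrom": chrom, "pos": pos0 + 1, "id": f"snp_neu_{i:04d}",
            "ref": ref, "alt": alt,
            "p": float(rng.uniform(1e-3, 1.0)),
            "expected_sign": "none", "category": "neutral",
        })
    snps = pd.DataFrame(snp_rows)

    fixture = Fixture(
        config=cfg,
        source_genome=source,
        target_genome=target,
        fwd_chains=fwd,
        rev_chains=rev,
        regions=regions,
        support_regions=support,
        manifest=manifest,
        cage_peaks=cage,
        h3k27ac_track=h3k27ac,
        rnaseq_track=rnaseq,
        conservation_track=conservation,
        ref_enhancers=active_enh,
        ref_promoters=active_prom,
        pwm_text=_jaspar_text(cfg.motifs),
        snps=snps,
    )

    if outdir is not None:
        _write_fixture(fixture, Path(outdir))
    return fixture


def planted_motif_training_set(
    n_pos: int = 200,
    n_neg: int = 200,
    seq_len: int = 100,
    motif: str = "TGACGTCA",
    seed: int = 11,
):
    """Sequence classification problem with a single planted motif.

    Every positive carries one copy of ``motif`` at a random offset; every
    negative is uniform random sequence guaranteed (by resampling) not to
    contain the motif on either strand.  Returns a
    :class:`crossreg.gkm.TrainingSet`.
    """
    from crossreg.gkm import TrainingSet, reverse_complement

    rng = np.random.default_rng(seed)
    rc = reverse_complement(motif)

    def rand_seq(n):
        return _BASES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")

    positives = []
    for _ in range(n_pos):
        s = rand_seq(seq_len)
        off = int(rng.integers(0, seq_len - len(motif) + 1))
        positives.append(s[:off] + motif + s[off + len(motif):])
    negatives = []
    while len(negatives) < n_neg:
        s = rand_seq(seq_len)
        if motif in s or rc in s:
            continue
        negatives.append(s)
    return TrainingSet(positives, negatives, seed, provenance="planted-motif simulation")


def _write_fasta(genome: dict, path: Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def _write_track(track, path: Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in track:
            fh.write(f"{chrom}\t{start}\t{end}\t{value}\n")


def _write_fixture(fx: Fixture, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    _write_fasta(fx.source_genome, outdir / "source.fa")
    _write_fasta(fx.target_genome, outdir / "target.fa")
    write_chain_file(fx.fwd_chains, outdir / "fwd.chain")
    write_chain_file(fx.rev_chains, outdir / "rev.chain")
    for cls in ("promoter", "enhancer", "tfbs"):
        subset = [r for r in fx.regions if r.name.startswith(cls)]
        write_bed(subset, outdir / f"regions_{cls}.bed")
    write_bed(fx.support_regions, outdir / "regions_support.bed")
    write_bed(fx.cage_peaks, outdir / "cage_peaks.bed")
    _write_track(fx.h3k27ac_track, outdir / "h3k27ac.bedGraph")
    _write_track(fx.rnaseq_track, outdir / "rnaseq.bedGraph")
    _write_track(fx.conservation_track, outdir / "conservation.bedGraph")
    write_bed(fx.ref_enhancers, outdir / "ref_enhancers.bed")
    write_bed(fx.ref_promoters, outdir / "ref_promoters.bed")
    (outdir / "pwms.jaspar").write_text(fx.pwm_text)
    fx.snps.to_csv(outdir / "snps.tsv", sep="\t", index=False)
    fx.manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
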