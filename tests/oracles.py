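"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive (per-base accumulation, exhaustive
scans, membership tables) and shares no code with the library paths it
checks.
"""

from __future__ import annotations

import math

from epibridge.genomic_io import GeneModel, HotspotTrack, StateElement
from epibridge.tss_profiling import ProfileParams


def window_signal_per_base(
    track: HotspotTrack, gene: GeneModel, center: int, params: ProfileParams
) -> float:
    """Score added to every covered base, then summed over window bases."""
    half_lo = params.window // 2
    half_hi = params.window - half_lo
    total = 0.0
    for iv in track:
        if iv.chrom != gene.chrom:
            continue
        for base in range(iv.start, iv.end):
            if base < 0:
                continue
            if gene.strand == "+" or not params.strand_aware:
                offset = base - gene.tss
            else:
                offset = gene.tss - base
            if center - half_lo <= offset < center + half_hi:
                total += iv.score
    return total


def nearest_midpoint_exhaustive(
    gene: GeneModel, track: HotspotTrack, flank: int
) -> int | None:
    """Scan every interval; signed strand-aware offset of the nearest
    midpoint within [TSS - flank, TSS + flank), upstream on ties."""
    best: int | None = None
    for iv in track:
        if iv.chrom != gene.chrom:
            continue
        mid = (iv.start + iv.end) // 2
        if not (gene.tss - flank <= mid < gene.tss + flank):
            continue
        offset = mid - gene.tss if gene.strand == "+" else gene.tss - mid
        if best is None or abs(offset) < abs(best) or (
            abs(offset) == abs(best) and offset < best
        ):
            best = offset
    return best


def nearest_state_exhaustive(
    gene: GeneModel, segmentation: list[StateElement], state_class: int
) -> int | None:
    best: int | None = None
    for e in segmentation:
        if e.chrom != gene.chrom or e.state_class != state_class:
            continue
        mid = (e.start + e.end) // 2
        offset = mid - gene.tss if gene.strand == "+" else gene.tss - mid
        if best is None or abs(offset) < abs(best) or (
            abs(offset) == abs(best) and offset < best
        ):
            best = offset
    return best


def venn_regions_membership_table(sets_by_name: dict[str, set[str]]) -> dict[tuple[str, ...], int]:
    """Tally genes by exact membership pattern across named sets."""
    names = sorted(sets_by_name)
    counts: dict[tuple[str, ...], int] = {}
    union = set().union(*sets_by_name.values())
    for gene in union:
        region = tuple(n for n in names if gene in sets_by_name[n])
        counts[region] = counts.get(region, 0) + 1
    return counts


def pearson_direct(xs: list[float], ys: list[float]) -> float:
    """Covariance-formula Pearson r, written out longhand."""
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    cov = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    vx = sum((x - mx) ** 2 for x in xs)
    vy = sum((y - my) ** 2 for y in ys)
    return cov / math.sqrt(vx * vy)
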