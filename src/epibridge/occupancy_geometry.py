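"""Promoter-region co-occupancy, nearest-signal geometry and feature
enrichment.

The analyses here support the "distal mark, proximal binding" question:
given an effector track (e.g. an engineered activator) and a repressive
mark track (e.g. H3K27me3),

* classify each gene's TSS region (+/- flank bp, default 5 kb) as marked
  by one, both, or neither track (>= 1 bp overlap, half-open arithmetic);
* locate the nearest mark signal (hotspot midpoint) to each TSS,
  strand-aware signed so negative is upstream in gene orientation;
* summarise nearest-signal distances per fold-change response group as
  box statistics;
* find the nearest chromatin-state element of each class (15-state HMM
  style; class 3 "poised promoter", class 12 "repressed") to each TSS and
  report medians per state x response group;
* measure signal enrichment over genomic background per feature class
  (promoter / genic / intergenic).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genomic_io import GeneModel, HotspotTrack, StateElement

__all__ = [
    "TssRegion",
    "OccupancyCall",
    "BoxStats",
    "STATE_LABELS",
    "tss_region",
    "overlaps_min1bp",
    "cooccupancy",
    "nearest_signal_distance",
    "fold_change_group",
    "FOLD_CHANGE_GROUPS",
    "distance_stats_by_group",
    "nearest_state_element",
    "state_proximity_report",
    "feature_class_enrichment",
]

logger = logging.getLogger(__name__)

#: Named labels for the two chromatin-state classes the analysis singles out.
STATE_LABELS = {3: "poised_promoter", 12: "repressed_region"}

#: Default fold-change groups (label, condition on log2 FC); the eightfold
#: boundary goes to the upper group.
FOLD_CHANGE_GROUPS = (
    ("up_8x_plus", lambda x: x >= 3.0),
    ("up_2x_8x", lambda x: 1.0 <= x < 3.0),
    ("no_change", lambda x: -1.0 < x < 1.0),
    ("down_2x_plus", lambda x: x <= -1.0),
)


@dataclass(frozen=True)
class TssRegion:
    gene_id: str
    chrom: str
    start: int
    end: int
    flank: int


@dataclass(frozen=True)
class OccupancyCall:
    gene_id: str
    mark_a_present: bool
    mark_b_present: bool

    @property
    def occupancy_class(self) -> str:
        if self.mark_a_present and self.mark_b_present:
            return "both"
        if self.mark_a_present:
            return "a_only"
        if self.mark_b_present:
            return "b_only"
        return "neither"


@dataclass(frozen=True)
class BoxStats:
    """Five-number summary plus count, as drawn in a box-and-whisker plot."""

    n: int
    median: float
    q25: float
    q75: float
    min: float
    max: float

    @classmethod
    def from_values(cls, values: Sequence[float]) -> "BoxStats":
        arr = np.asarray(values, dtype=float)
        if arr.size == 0:
            raise ValueError("cannot summarise an empty group")
        return cls(
            n=int(arr.size),
            median=float(np.median(arr)),
            q25=float(np.percentile(arr, 25)),
            q75=float(np.percentile(arr, 75)),
            min=float(arr.min()),
            max=float(arr.max()),
        )


def tss_region(gene: GeneModel, flank: int = 5000) -> TssRegion:
    """Genomic interval [TSS - flank, TSS + flank), clipped at 0."""
    if flank <= 0:
        raise ValueError(f"flank must be > 0, got {flank}")
    return TssRegion(
        gene_id=gene.gene_id,
        chrom=gene.chrom,
        start=max(gene.tss - flank, 0),
        end=gene.tss + flank,
        flank=flank,
    )


def overlaps_min1bp(region: TssRegion, track: HotspotTrack) -> bool:
    """True iff any track interval intersects the region by >= 1 bp
    (half-open: [a,b) and [c,d) overlap iff a < d and c < b)."""
    return bool(track.overlapping(region.chrom, region.start, region.end))


def cooccupancy(
    genes: Sequence[GeneModel],
    track_a: HotspotTrack,
    track_b: HotspotTrack,
    flank: int = 5000,
) -> tuple[list[OccupancyCall], dict[str, int]]:
    """Per-gene occupancy calls and region counts.

    Counts: a_only, b_only, both, neither, marked_total (= a_only +
    b_only + both).
    """
    calls = []
    for g in genes:
        region = tss_region(g, flank)
        calls.append(
            OccupancyCall(
                gene_id=g.gene_id,
                mark_a_present=overlaps_min1bp(region, track_a),
                mark_b_present=overlaps_min1bp(region, track_b),
            )
        )
    counts = {"a_only": 0, "b_only": 0, "both": 0, "neither": 0}
    for c in calls:
        counts[c.occupancy_class] += 1
    counts["marked_total"] = counts["a_only"] + counts["b_only"] + counts["both"]
    logger.info(
        "cooccupancy: %d genes in -> %d marked (%d both)",
        len(calls), counts["marked_total"], counts["both"],
    )
    return calls, counts


def nearest_signal_distance(
    gene: GeneModel, track: HotspotTrack, flank: int = 5000
) -> int | None:
    """Signed strand-aware offset of the nearest hotspot midpoint.

    Only midpoints within [TSS - flank, TSS + flank) qualify; returns
    None when none do.  The nearest is the minimum absolute offset; exact
    up/downstream ties resolve upstream (negative).
    """
    mids = track.midpoints(gene.chrom)
    if mids.size == 0:
        return None
    lo, hi = gene.tss - flank, gene.tss + flank
    i0, i1 = np.searchsorted(mids, [lo, hi])
    window = mids[i0:i1]
    if window.size == 0:
        return None
    if gene.strand == "+":
        offsets = window - gene.tss
    else:
        offsets = gene.tss - window
    # argmin of |offset|, upstream (negative) wins ties
    order = np.lexsort((offsets, np.abs(offsets)))
    return int(offsets[order[0]])


def fold_change_group(log2_fc: float) -> str | None:
    """Default response-group label for a log2 fold change (None for NaN)."""
    if log2_fc is None or (isinstance(log2_fc, float) and math.isnan(log2_fc)):
        return None
    for label, cond in FOLD_CHANGE_GROUPS:
        if cond(log2_fc):
            return label
    return None


def distance_stats_by_group(
    records: pd.DataFrame,
    gene_length_min: int = 2000,
    require_cooccupied: bool = True,
) -> dict[str, BoxStats | None]:
    """Box statistics of nearest-signal distances per response group.

    ``records`` needs columns gene_id, signed_distance, gene_length,
    response_group and (when ``require_cooccupied``) cooccupied.  Genes
    shorter than ``gene_length_min`` bp, genes with no qualifying signal
    (NaN distance) and — when required — genes whose TSS region is not
    co-occupied by both marks are dropped.  Groups with no surviving
    genes map to None.
    """
    df = records
    n_in = len(df)
    df = df[df["gene_length"] >= gene_length_min]
    n_len = len(df)
    if require_cooccupied:
        df = df[df["cooccupied"].astype(bool)]
    n_cooc = len(df)
    df = df[df["signed_distance"].notna()]
    logger.info(
        "distance_stats: %d genes in -> %d after length >= %d -> %d after "
        "co-occupancy filter -> %d with signal",
        n_in, n_len, gene_length_min, n_cooc, len(df),
    )
    groups = [label for label, _ in FOLD_CHANGE_GROUPS]
    seen = set(df["response_group"].dropna())
    out: dict[str, BoxStats | None] = {}
    for label in list(groups) + sorted(seen - set(groups)):
        vals = df.loc[df["response_group"] == label, "signed_distance"].to_numpy(float)
        out[label] = BoxStats.from_values(vals) if vals.size else None
    return out


class _StateIndex:
    """Per-(chrom, state) sorted midpoint arrays for nearest queries."""

    def __init__(self, segmentation: Iterable[StateElement]) -> None:
        acc: dict[tuple[str, int], list[int]] = {}
        for e in segmentation:
            acc.setdefault((e.chrom, e.state_class), []).append(e.midpoint)
        self._mids = {k: np.array(sorted(v), dtype=np.int64) for k, v in acc.items()}

    def midpoints(self, chrom: str, state_class: int) -> np.ndarray:
        return self._mids.get((chrom, state_class), np.empty(0, dtype=np.int64))


def nearest_state_element(
    gene: GeneModel,
    segmentation: Iterable[StateElement] | _StateIndex,
    state_class: int,
    strand_aware: bool = True,
) -> int | None:
    """Signed distance (element midpoint to TSS) of the nearest element of
    one chromatin-state class; search is genome-wide per chromosome.

    None when the class is absent from the gene's chromosome.  Ties
    resolve upstream.
    """
    index = segmentation if isinstance(segmentation, _StateIndex) else _StateIndex(segmentation)
    mids = index.midpoints(gene.chrom, state_class)
    if mids.size == 0:
        return None
    if strand_aware and gene.strand == "-":
        offsets = gene.tss - mids
    else:
        offsets = mids - gene.tss
    order = np.lexsort((offsets, np.abs(offsets)))
    return int(offsets[order[0]])


def state_proximity_report(
    genes: Sequence[GeneModel],
    segmentation: Iterable[StateElement],
    expression: pd.DataFrame,
    state_classes: Sequence[int] = tuple(range(1, 16)),
    signed: bool = True,
    strand_aware: bool = True,
) -> pd.DataFrame:
    """Median nearest-element distance per (state class x response group).

    ``expression`` is a classified table (gene_id, log2_fc,
    response_class); genes excluded for zero FPKM in both conditions are
    dropped.  Returns one row per cell with columns state_class,
    state_label, response_group, n, median_distance (NaN when n = 0).
    Distances are signed by default; ``signed=False`` reports absolute
    distances.
    """
    expr = expression.set_index("gene_id")
    index = _StateIndex(segmentation)
    kept = []
    for g in genes:
        if g.gene_id not in expr.index:
            continue
        row = expr.loc[g.gene_id]
        if row["response_class"] == "excluded":
            continue
        group = fold_change_group(float(row["log2_fc"]))
        if group is None:
            continue
        kept.append((g, group))
    logger.info(
        "state_proximity: %d genes in -> %d after exclusion/join", len(genes), len(kept)
    )
    group_order = [label for label, _ in FOLD_CHANGE_GROUPS]
    rows = []
    for sc in state_classes:
        dists: dict[str, list[float]] = {gl: [] for gl in group_order}
        for g, group in kept:
            d = nearest_state_element(g, index, sc, strand_aware=strand_aware)
            if d is not None:
                dists[group].append(abs(d) if not signed else d)
        for gl in group_order:
            vals = dists[gl]
            rows.append(
                (
                    sc,
                    STATE_LABELS.get(sc, f"state_{sc}"),
                    gl,
                    len(vals),
                    float(np.median(vals)) if vals else math.nan,
                )
            )
    return pd.DataFrame(
        rows,
        columns=["state_class", "state_label", "response_group", "n", "median_distance"],
    )


# ---------------------------------------------------------------------------
# feature-class enrichment


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals.sort()
    out = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def _subtract(base: list[tuple[int, int]], cut: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Set difference of merged, sorted interval lists."""
    out = []
    for s, e in base:
        cur = s
        for cs, ce in cut:
            if ce <= cur or cs >= e:
                continue
            if cs > cur:
                out.append((cur, cs))
            cur = max(cur, ce)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return out


def _overlap_bp(intervals: list[tuple[int, int]], s: int, e: int) -> int:
    return sum(max(0, min(ie, e) - max(is_, s)) for is_, ie in intervals)


def feature_class_enrichment(
    track: HotspotTrack,
    genes: Sequence[GeneModel],
    chrom_lengths: Mapping[str, int],
    promoter_def: tuple[int, int] = (2000, 500),
) -> pd.DataFrame:
    """Signal enrichment over genomic background per feature class.

    The genome is partitioned into promoter (strand-aware
    [TSS - upstream, TSS + downstream), taking precedence), genic (merged
    gene bodies minus promoters) and intergenic (the rest).  For each
    class, enrichment = (fraction of total track signal, score x bp, in
    the class) / (fraction of genome bp in the class).  Ratios are NaN
    when the class has zero bp or the track carries zero signal
    (flagged by the zero_signal column).
    """
    up, down = promoter_def
    promoters: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_lengths}
    bodies: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_lengths}
    for g in genes:
        if g.chrom not in chrom_lengths:
            raise ValueError(f"gene {g.gene_id}: no chromosome length for {g.chrom}")
        L = chrom_lengths[g.chrom]
        if g.strand == "+":
            p = (g.tss - up, g.tss + down)
        else:
            p = (g.tss - down + 1, g.tss + up + 1)
        promoters[g.chrom].append((max(p[0], 0), min(p[1], L)))
        bodies[g.chrom].append((max(g.start, 0), min(g.end, L)))
    classes = ("promoter", "genic", "intergenic")
    partition: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for chrom, L in chrom_lengths.items():
        prom = _merge(promoters[chrom])
        genic = _subtract(_merge(bodies[chrom]), prom)
        inter = _subtract([(0, L)], _merge(prom + genic))
        partition[chrom] = {"promoter": prom, "genic": genic, "intergenic": inter}
    genome_bp = sum(chrom_lengths.values())
    class_bp = {
        cl: sum(sum(e - s for s, e in partition[c][cl]) for c in chrom_lengths)
        for cl in classes
    }
    signal = {cl: 0.0 for cl in classes}
    total_signal = 0.0
    for iv in track:
        if iv.chrom not in chrom_lengths:
            raise ValueError(f"track interval on {iv.chrom}: no chromosome length")
        total_signal += iv.score * (iv.end - iv.start)
        for cl in classes:
            bp = _overlap_bp(partition[iv.chrom][cl], iv.start, iv.end)
            signal[cl] += iv.score * bp
    rows = []
    for cl in classes:
        if total_signal == 0 or class_bp[cl] == 0:
            ratio = math.nan
        else:
            ratio = (signal[cl] / total_signal) / (class_bp[cl] / genome_bp)
        rows.append((cl, class_bp[cl], signal[cl], ratio, total_signal == 0))
    return pd.DataFrame(
        rows, columns=["feature_class", "class_bp", "signal", "enrichment", "zero_signal"]
    )
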