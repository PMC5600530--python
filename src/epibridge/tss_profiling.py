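"""TSS-centered sliding-window metaprofiles of hotspot signal.

A profile evaluates, at each window center c in {-flank, -flank+step,
..., +flank}, the total hotspot signal inside a window of fixed width
centered at TSS + c, summed over genes.  Offsets are strand-aware:
negative means upstream of the TSS in the gene's own orientation, so
profiles aggregate in gene orientation (a genome-oriented mode is
available via ``strand_aware=False``).

"Signal inside a window" is score-weighted overlap: each hotspot
contributes score x (bp of overlap with the window).  This reduces to the
hotspot's full score x length when fully contained and degrades
gracefully for partial overlap.  A cruder any-overlap mode (sum of scores
of every hotspot touching the window, regardless of overlap length) is
available via ``mode="any_overlap"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .genomic_io import GeneModel, HotspotTrack

__all__ = [
    "ProfileParams",
    "TssProfile",
    "signed_offset",
    "window_span",
    "window_signal",
    "tss_profile",
    "stratified_profiles",
]


@dataclass(frozen=True)
class ProfileParams:
    """Sliding-window geometry: +/-flank around the TSS, window width and step
    (defaults 5000 / 200 / 50 bp)."""

    flank: int = 5000
    window: int = 200
    step: int = 50
    strand_aware: bool = True
    mode: str = "weighted"  # or "any_overlap"

    def __post_init__(self) -> None:
        if self.window <= 0 or self.step <= 0:
            raise ValueError("window and step must be > 0")
        if self.step > self.window:
            raise ValueError(f"step ({self.step}) must be <= window ({self.window})")
        if self.flank < self.window // 2:
            raise ValueError("flank must be >= window/2")
        if self.mode not in ("weighted", "any_overlap"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.flank, self.flank + 1, self.step, dtype=np.int64)


@dataclass
class TssProfile:
    """Aggregated windowed signal as a function of signed offset from the TSS."""

    offsets: np.ndarray
    signal: np.ndarray
    n_genes: int
    category: str = "all"

    def __post_init__(self) -> None:
        if len(self.offsets) != len(self.signal):
            raise ValueError("offsets and signal must have equal length")

    def argmax_offset(self) -> int:
        """Offset of the profile maximum (first on ties)."""
        return int(self.offsets[int(np.argmax(self.signal))])

    def argmin_offset(self) -> int:
        return int(self.offsets[int(np.argmin(self.signal))])


def signed_offset(position: int, gene: GeneModel, chrom: str | None = None) -> int:
    """Strand-aware offset of a genomic position from the gene's TSS.

    Negative means upstream of the TSS in gene orientation.  If ``chrom``
    is given it must match the gene's chromosome.
    """
    if chrom is not None and chrom != gene.chrom:
        raise ValueError(
            f"chromosome mismatch: position on {chrom}, gene {gene.gene_id} on {gene.chrom}"
        )
    if gene.strand == "+":
        return position - gene.tss
    return gene.tss - position


def window_span(
    gene: GeneModel, center_offset: int, window: int, strand_aware: bool = True
) -> tuple[int, int]:
    """Genomic half-open span of the window centered at TSS + center_offset.

    In strand space the window at offset c covers offsets
    [c - window//2, c + window - window//2); the genomic span is its
    strand-aware image (per-base exact, which introduces a one-bp shift on
    the minus strand).
    """
    half_lo = window // 2
    half_hi = window - half_lo
    strand = gene.strand if strand_aware else "+"
    if strand == "+":
        return gene.tss + center_offset - half_lo, gene.tss + center_offset + half_hi
    # minus strand: offsets o in [c-half_lo, c+half_hi) map to bases tss - o
    return (
        gene.tss - center_offset - half_hi + 1,
        gene.tss - center_offset + half_lo + 1,
    )


def window_signal(
    track: HotspotTrack,
    gene: GeneModel,
    center_offset: int,
    params: ProfileParams = ProfileParams(),
) -> float:
    """Total hotspot signal in one window (see module docstring for modes)."""
    lo, hi = window_span(gene, center_offset, params.window, params.strand_aware)
    lo = max(lo, 0)
    if hi <= lo:
        return 0.0
    total = 0.0
    for iv in track.overlapping(gene.chrom, lo, hi):
        if params.mode == "weighted":
            total += iv.score * (min(iv.end, hi) - max(iv.start, lo))
        else:
            total += iv.score
    return total


def _gene_profile(
    track: HotspotTrack, gene: GeneModel, params: ProfileParams
) -> np.ndarray:
    """Vectorised per-gene profile over all window centers."""
    offsets = params.offsets
    first = window_span(gene, int(offsets[0]), params.window, params.strand_aware)
    last = window_span(gene, int(offsets[-1]), params.window, params.strand_aware)
    span_lo = min(*first, *last)  # minus strand reverses genomic order
    span_hi = max(*first, *last)
    hits = track.overlapping(gene.chrom, max(span_lo, 0), span_hi)
    out = np.zeros(len(offsets), dtype=float)
    if not hits:
        return out
    los = np.empty(len(offsets), dtype=np.int64)
    his = np.empty(len(offsets), dtype=np.int64)
    for i, c in enumerate(offsets):
        lo, hi = window_span(gene, int(c), params.window, params.strand_aware)
        los[i], his[i] = max(lo, 0), hi
    starts = np.array([iv.start for iv in hits], dtype=np.int64)
    ends = np.array([iv.end for iv in hits], dtype=np.int64)
    scores = np.array([iv.score for iv in hits], dtype=float)
    if params.mode == "weighted":
        overlap = np.clip(
            np.minimum(ends[None, :], his[:, None]) - np.maximum(starts[None, :], los[:, None]),
            0,
            None,
        )
        out = (overlap * scores[None, :]).sum(axis=1)
    else:
        touches = (starts[None, :] < his[:, None]) & (ends[None, :] > los[:, None])
        out = (touches * scores[None, :]).sum(axis=1)
    return out


def tss_profile(
    track: HotspotTrack,
    genes: Iterable[GeneModel],
    params: ProfileParams = ProfileParams(),
    category: str = "all",
) -> TssProfile:
    """Sum of per-gene window signals at every offset; genes on chromosomes
    absent from the track contribute zero."""
    offsets = params.offsets
    signal = np.zeros(len(offsets), dtype=float)
    n = 0
    for gene in genes:
        signal += _gene_profile(track, gene, params)
        n += 1
    return TssProfile(offsets=offsets, signal=signal, n_genes=n, category=category)


def stratified_profiles(
    track: HotspotTrack,
    genes: Sequence[GeneModel],
    category_of: Callable[[GeneModel], str] | Mapping[str, str],
    params: ProfileParams = ProfileParams(),
) -> dict[str, TssProfile]:
    """Per-category profiles normalised by category gene count (mean signal
    per gene per window).  Empty categories are omitted."""
    if not callable(category_of):
        mapping = dict(category_of)
        lookup = lambda g: mapping[g.gene_id]  # noqa: E731
    else:
        lookup = category_of
    groups: dict[str, list[GeneModel]] = {}
    for g in genes:
        groups.setdefault(lookup(g), []).append(g)
    out: dict[str, TssProfile] = {}
    for label in sorted(groups):
        members = groups[label]
        prof = tss_profile(track, members, params, category=label)
        prof.signal = prof.signal / len(members)
        out[label] = prof
    return out
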