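"""Transcriptional response classification and cross-sample set algebra.

Genes are classified from control/treated FPKM as up (fold change at or
above the threshold, default twofold — boundary inclusive), down (at
least the same factor decreased), no_change, or excluded (FPKM zero in
both conditions, for which no fold change is defined).

A pseudocount (default 0.01 FPKM) is added to both numerator and
denominator only when exactly one of the two values is zero, so that
finite fold changes exist for on/off switches without perturbing the
bulk of the distribution.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ResponseSummary",
    "BasalStratum",
    "VennResult",
    "classify_response",
    "classify_table",
    "response_summary",
    "common_sets",
    "default_strata",
    "assign_basal_stratum",
    "upregulation_frequency_by_stratum",
]

CLASSES = ("up", "down", "no_change", "excluded")


@dataclass(frozen=True)
class ResponseSummary:
    n_total: int
    counts: Mapping[str, int]
    fraction_up: float  # percent of non-excluded genes
    fraction_down: float


@dataclass(frozen=True)
class BasalStratum:
    """Half-open log10(control FPKM) bin; ``zero=True`` marks the dedicated
    FPKM == 0 stratum (bounds ignored)."""

    label: str
    log10_lower: float
    log10_upper: float
    zero: bool = False

    def contains(self, fpkm: float) -> bool:
        if self.zero:
            return fpkm == 0
        if fpkm <= 0:
            return False
        return self.log10_lower <= math.log10(fpkm) < self.log10_upper


@dataclass(frozen=True)
class VennResult:
    """Exact region counts for k named sets.

    ``region_counts`` is keyed by the sorted tuple of set names a gene
    belongs to (every non-empty subset of names); ``common`` is the sorted
    intersection of all sets.
    """

    names: tuple[str, ...]
    region_counts: Mapping[tuple[str, ...], int]
    common: tuple[str, ...]


def classify_response(
    fpkm_control: float,
    fpkm_treated: float,
    pseudocount: float = 0.01,
    fc_threshold: float = 2.0,
) -> tuple[float, str]:
    """Classify one gene; returns (log2_fc, class).

    log2_fc is NaN for the excluded (both-zero) class.  The up boundary is
    inclusive: an exact ``fc_threshold``-fold increase is classified up,
    and symmetrically for down.
    """
    if fpkm_control < 0 or fpkm_treated < 0:
        raise ValueError(
            f"FPKM values must be >= 0, got ({fpkm_control}, {fpkm_treated})"
        )
    if fc_threshold <= 1:
        raise ValueError(f"fc_threshold must be > 1, got {fc_threshold}")
    if fpkm_control == 0 and fpkm_treated == 0:
        return math.nan, "excluded"
    c, t = fpkm_control, fpkm_treated
    if c == 0 or t == 0:
        c += pseudocount
        t += pseudocount
    # difference of logs: robust for subnormal FPKM where t/c underflows
    log2_fc = math.log2(t) - math.log2(c)
    cut = math.log2(fc_threshold)
    if log2_fc >= cut:
        return log2_fc, "up"
    if log2_fc <= -cut:
        return log2_fc, "down"
    return log2_fc, "no_change"


def classify_table(
    table: pd.DataFrame, pseudocount: float = 0.01, fc_threshold: float = 2.0
) -> pd.DataFrame:
    """Vectorised :func:`classify_response` over an expression table.

    Input needs columns gene_id, fpkm_control, fpkm_treated; returns a
    copy with log2_fc and response_class added.
    """
    c = table["fpkm_control"].to_numpy(dtype=float)
    t = table["fpkm_treated"].to_numpy(dtype=float)
    if (c < 0).any() or (t < 0).any():
        raise ValueError("FPKM values must be >= 0")
    both_zero = (c == 0) & (t == 0)
    one_zero = ((c == 0) | (t == 0)) & ~both_zero
    cc = np.where(one_zero, c + pseudocount, c)
    tt = np.where(one_zero, t + pseudocount, t)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2_fc = np.log2(tt) - np.log2(cc)
    log2_fc[both_zero] = np.nan
    cut = math.log2(fc_threshold)
    cls = np.where(log2_fc >= cut, "up", np.where(log2_fc <= -cut, "down", "no_change"))
    cls = np.where(both_zero, "excluded", cls)
    out = table.copy()
    out["log2_fc"] = log2_fc
    out["response_class"] = cls
    return out


def response_summary(table: pd.DataFrame) -> ResponseSummary:
    """Class counts and up/down percentages over non-excluded genes."""
    if len(table) == 0:
        raise ValueError("empty expression table")
    counts = {c: int((table["response_class"] == c).sum()) for c in CLASSES}
    n_eval = len(table) - counts["excluded"]
    if n_eval == 0:
        raise ValueError("all genes excluded (FPKM zero in both conditions)")
    return ResponseSummary(
        n_total=len(table),
        counts=counts,
        fraction_up=100.0 * counts["up"] / n_eval,
        fraction_down=100.0 * counts["down"] / n_eval,
    )


def common_sets(
    tables_by_sample: Mapping[str, pd.DataFrame] | Mapping[str, Iterable[str]],
    response_class: str = "up",
) -> VennResult:
    """Exact Venn region counts of class-member gene sets across samples.

    Accepts classified tables (gene_id + response_class columns) or raw
    gene-id collections.  When gene universes differ, a warning reports
    the symmetric-difference size and counts are computed over the
    intersection universe.
    """
    if len(tables_by_sample) < 2:
        raise ValueError("need at least 2 samples")
    names = tuple(sorted(tables_by_sample))
    sets: dict[str, set[str]] = {}
    universes: dict[str, set[str]] = {}
    for name in names:
        obj = tables_by_sample[name]
        if isinstance(obj, pd.DataFrame):
            universes[name] = set(obj["gene_id"])
            sets[name] = set(obj.loc[obj["response_class"] == response_class, "gene_id"])
        else:
            # raw gene-id collection: member set only, universe unknown
            sets[name] = set(obj)
    if len(universes) == len(names):  # universe check needs full tables
        shared = set.intersection(*universes.values())
        union_univ = set.union(*universes.values())
        if shared != union_univ:
            warnings.warn(
                f"gene universes differ across samples "
                f"(symmetric difference: {len(union_univ - shared)} genes); "
                f"counting over the {len(shared)}-gene intersection universe",
                stacklevel=2,
            )
            sets = {k: v & shared for k, v in sets.items()}
    region_counts: dict[tuple[str, ...], int] = {}
    for gene in set.union(*sets.values()):
        region = tuple(n for n in names if gene in sets[n])
        region_counts[region] = region_counts.get(region, 0) + 1
    # emit every non-empty subset, zero-filled
    from itertools import combinations

    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            region_counts.setdefault(combo, 0)
    common = tuple(sorted(set.intersection(*sets.values())))
    return VennResult(names=names, region_counts=region_counts, common=common)


def default_strata() -> list[BasalStratum]:
    """Zero stratum plus half-open log10 FPKM bins [-4,-2), [-2,0), [0,2), [2,inf)."""
    return [
        BasalStratum("zero", math.nan, math.nan, zero=True),
        BasalStratum("fpkm_1e-4_1e-2", -4.0, -2.0),
        BasalStratum("fpkm_1e-2_1", -2.0, 0.0),
        BasalStratum("fpkm_1_100", 0.0, 2.0),
        BasalStratum("fpkm_ge_100", 2.0, math.inf),
    ]


def assign_basal_stratum(fpkm_control: float, strata: Sequence[BasalStratum]) -> str:
    """Label of the stratum containing the control FPKM value.

    Nonzero values below every finite lower bound are assigned to the
    lowest nonzero stratum (practically, FPKM below 1e-4 is
    indistinguishable from silenced).
    """
    for s in strata:
        if s.contains(fpkm_control):
            return s.label
    nonzero = [s for s in strata if not s.zero]
    if fpkm_control > 0 and nonzero:
        lowest = min(nonzero, key=lambda s: s.log10_lower)
        if math.log10(fpkm_control) < lowest.log10_lower:
            return lowest.label
    raise ValueError(f"no stratum contains FPKM value {fpkm_control}")


def upregulation_frequency_by_stratum(
    table: pd.DataFrame,
    strata: Sequence[BasalStratum] | None = None,
    silenced_range: tuple[float, float] = (1e-4, 1.0),
) -> pd.DataFrame:
    """Fraction of genes up-regulated, per basal-expression stratum.

    Returns one row per stratum (n genes, n up, fraction up in percent;
    NaN fraction for empty strata) plus two rows for the silenced/active
    two-bin split on control FPKM (silenced: ``silenced_range`` half-open;
    active: at or above its upper bound).  Excluded genes are dropped
    first.
    """
    if strata is None:
        strata = default_strata()
    df = table[table["response_class"] != "excluded"]
    labels = df["fpkm_control"].map(lambda v: assign_basal_stratum(v, strata))
    rows = []
    for s in strata:
        sub = df[labels == s.label]
        n, n_up = len(sub), int((sub["response_class"] == "up").sum())
        rows.append((s.label, n, n_up, 100.0 * n_up / n if n else math.nan))
    lo, hi = silenced_range
    silenced = df[(df["fpkm_control"] >= lo) & (df["fpkm_control"] < hi)]
    active = df[df["fpkm_control"] >= hi]
    for label, sub in (("silenced", silenced), ("active", active)):
        n, n_up = len(sub), int((sub["response_class"] == "up").sum())
        rows.append((label, n, n_up, 100.0 * n_up / n if n else math.nan))
    return pd.DataFrame(rows, columns=["stratum", "n", "n_up", "percent_up"])
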