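"""qRT-PCR and ChIP-qPCR arithmetic.

Crossing-point (Cp) values are qPCR cycle numbers; one cycle corresponds
to one template doubling, so all quantities here are powers of two in Cp
differences:

* expression level relative to a reference gene: ``2**(Cp_ref - Cp_gene)``
* fold change (log2) of treated vs mock expression levels
* percent input recovered by immunoprecipitation:
  ``100 * 2**(Cp_input_adjusted - Cp_ip)``, where the input Cp is first
  adjusted for the fraction of the chromatin prep that was sampled
  (default factor 20, i.e. subtract log2(20))
* mock-IP (IgG) percentage subtracted from %IP to give enrichment.

Plasmid-expression scaling quotients rescale per-timepoint fold changes by
the effector transcript's own fold change relative to a reference
timepoint, compensating for transient-transfection decay.  The quotient is
applied multiplicatively to log2 fold changes, exactly as the source
protocol prescribes; the sampling factor and quotients are all exposed as
parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genomic_io import CpRecord

__all__ = [
    "ScalingQuotient",
    "IpEnrichment",
    "expression_level",
    "fold_change_log2",
    "plasmid_scaling_quotients",
    "apply_scaling",
    "adjusted_input_cp",
    "percent_ip",
    "ip_enrichment",
    "dose_response_correlation",
    "expression_report",
    "fold_change_report",
    "percent_ip_report",
]


@dataclass(frozen=True)
class ScalingQuotient:
    timepoint: str
    quotient: float


@dataclass(frozen=True)
class IpEnrichment:
    percent_ip: float
    percent_mock: float

    @property
    def enrichment(self) -> float:
        return self.percent_ip - self.percent_mock


def _require_finite(name: str, *values: float) -> None:
    for v in values:
        if not math.isfinite(v):
            raise ValueError(f"{name}: non-finite value {v!r}")


def expression_level(cp_reference: float, cp_gene: float) -> float:
    """Expression relative to the reference gene: ``2**(cp_reference - cp_gene)``."""
    _require_finite("expression_level", cp_reference, cp_gene)
    return 2.0 ** (cp_reference - cp_gene)


def fold_change_log2(level_treated: float, level_mock: float) -> float:
    """log2 ratio of treated over mock expression levels."""
    _require_finite("fold_change_log2", level_treated, level_mock)
    if level_mock <= 0:
        raise ValueError(f"fold_change_log2: mock level must be > 0, got {level_mock}")
    if level_treated <= 0:
        raise ValueError(f"fold_change_log2: treated level must be > 0, got {level_treated}")
    return math.log2(level_treated / level_mock)


def plasmid_scaling_quotients(
    effector_log2_fc_by_timepoint: Mapping[str, float], reference_timepoint: str
) -> list[ScalingQuotient]:
    """Per-timepoint quotients: effector log2 FC divided by its value at the
    reference timepoint.  The reference quotient is exactly 1."""
    if reference_timepoint not in effector_log2_fc_by_timepoint:
        raise ValueError(f"reference timepoint {reference_timepoint!r} not present")
    ref = effector_log2_fc_by_timepoint[reference_timepoint]
    if ref == 0:
        raise ValueError("reference timepoint effector fold change is 0; quotients undefined")
    out = []
    for tp, value in effector_log2_fc_by_timepoint.items():
        q = 1.0 if tp == reference_timepoint else value / ref
        out.append(ScalingQuotient(tp, q))
    return out


def apply_scaling(gene_log2_fc: float, quotient: ScalingQuotient | float) -> float:
    """Multiply a gene's log2 fold change by its timepoint's quotient."""
    q = quotient.quotient if isinstance(quotient, ScalingQuotient) else quotient
    _require_finite("apply_scaling", gene_log2_fc, q)
    return gene_log2_fc * q


def adjusted_input_cp(cp_input: float, input_fraction_factor: float = 20.0) -> float:
    """Correct an input Cp for sampling 1/factor of the chromatin prep.

    The default factor 20 (20% input sampled) subtracts log2(20) cycles.
    """
    _require_finite("adjusted_input_cp", cp_input)
    if input_fraction_factor <= 0:
        raise ValueError(
            f"input_fraction_factor must be > 0, got {input_fraction_factor}"
        )
    return cp_input - math.log2(input_fraction_factor)


def percent_ip(cp_input_adjusted: float, cp_ip: float) -> float:
    """IP DNA as percent of adjusted input: ``100 * 2**(cp_input_adjusted - cp_ip)``.

    Not clamped: values above 100% (over-recovery) are reported as-is.
    """
    _require_finite("percent_ip", cp_input_adjusted, cp_ip)
    return 100.0 * 2.0 ** (cp_input_adjusted - cp_ip)


def ip_enrichment(pct_ip: float, pct_mock: float) -> IpEnrichment:
    """Mock-subtracted enrichment; negative values are preserved."""
    _require_finite("ip_enrichment", pct_ip, pct_mock)
    return IpEnrichment(pct_ip, pct_mock)


def dose_response_correlation(
    gene_log2_fc_by_dose: Sequence[float], effector_log2_fc_by_dose: Sequence[float]
) -> tuple[float, float]:
    """Pearson product-moment correlation (r, r^2) of gene vs effector
    fold change across doses."""
    x = np.asarray(gene_log2_fc_by_dose, dtype=float)
    y = np.asarray(effector_log2_fc_by_dose, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("dose vectors must be 1-D and of equal length")
    if x.size < 3:
        raise ValueError(f"need >= 3 doses, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in a dose vector: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    return r, r * r


# ---------------------------------------------------------------------------
# record-level reports (CLI backbone)


def _mean_cp(records: Iterable[CpRecord]) -> dict[tuple[str, str, str, str], float]:
    """Average Cp over replicates, keyed by (sample, target, role, timepoint)."""
    acc: dict[tuple[str, str, str, str], list[float]] = {}
    for r in records:
        acc.setdefault((r.sample_id, r.target_id, r.role, r.timepoint), []).append(r.cp)
    return {k: float(np.mean(v)) for k, v in acc.items()}


def expression_report(
    records: Iterable[CpRecord], reference_target: str = "GAPDH"
) -> pd.DataFrame:
    """Per (sample, target, timepoint) expression level relative to the
    reference target, from role 'gene' and 'reference' Cp records."""
    cp = _mean_cp(records)
    refs = {
        (s, tp): v for (s, t, role, tp), v in cp.items()
        if role == "reference" and t == reference_target
    }
    rows = []
    for (s, t, role, tp), v in sorted(cp.items()):
        if role != "gene":
            continue
        if (s, tp) not in refs:
            raise ValueError(
                f"no reference Cp for sample {s!r} timepoint {tp!r} "
                f"(reference target {reference_target!r})"
            )
        rows.append((s, t, tp, expression_level(refs[(s, tp)], v)))
    return pd.DataFrame(rows, columns=["sample_id", "target_id", "timepoint", "level"])


def fold_change_report(
    records: Iterable[CpRecord],
    mock_sample: str,
    reference_target: str = "GAPDH",
) -> pd.DataFrame:
    """log2 fold change of every non-mock sample vs the mock sample, per
    (target, timepoint)."""
    levels = expression_report(records, reference_target)
    mock = levels[levels["sample_id"] == mock_sample].set_index(["target_id", "timepoint"])
    rows = []
    for _, row in levels[levels["sample_id"] != mock_sample].iterrows():
        key = (row["target_id"], row["timepoint"])
        if key not in mock.index:
            raise ValueError(f"no mock level for target/timepoint {key}")
        lfc = fold_change_log2(row["level"], float(mock.loc[key, "level"]))
        rows.append((row["sample_id"], row["target_id"], row["timepoint"], lfc))
    return pd.DataFrame(rows, columns=["sample_id", "target_id", "timepoint", "log2_fc"])


def percent_ip_report(
    records: Iterable[CpRecord], input_fraction_factor: float = 20.0
) -> pd.DataFrame:
    """%IP, %mock-IP and enrichment per (sample, target, timepoint).

    Requires roles ip and input; mock is optional (enrichment equals %IP
    when absent).
    """
    cp = _mean_cp(records)
    by_role: dict[str, dict[tuple[str, str, str], float]] = {}
    for (s, t, role, tp), v in cp.items():
        by_role.setdefault(role, {})[(s, t, tp)] = v
    rows = []
    for key, cp_ip in sorted(by_role.get("ip", {}).items()):
        if key not in by_role.get("input", {}):
            raise ValueError(f"no input Cp for {key}")
        adj = adjusted_input_cp(by_role["input"][key], input_fraction_factor)
        pct = percent_ip(adj, cp_ip)
        mock_cp = by_role.get("mock", {}).get(key)
        pct_mock = percent_ip(adj, mock_cp) if mock_cp is not None else 0.0
        enr = ip_enrichment(pct, pct_mock)
        rows.append((*key, pct, pct_mock, enr.enrichment))
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id", "target_id", "timepoint",
            "percent_ip", "percent_mock", "enrichment",
        ],
    )
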