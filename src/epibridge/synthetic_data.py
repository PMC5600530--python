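"""Synthetic epigenome generator with planted ground truth.

Emulates the statistical structure the downstream analyses assume, so
every stage is testable without sequencing data:

* genes laid out on one or more chromosomes with wide spacing (TSS-to-TSS
  >= 20 kb by default) so that +/-5 kb TSS windows never collide;
* a response class per gene (up_strong / up_moderate / no_change / down)
  with class-conditional log2 fold changes and basal FPKM ranges;
* one repressive-mark (H3K27me3-style) hotspot per marked gene, its
  midpoint placed at a signed, strand-aware offset from the TSS drawn
  from a class-conditional normal — distal upstream for up-regulated
  classes (defaults -2500 and -1300 bp, matching the geometry the
  analysis is designed to detect), TSS-proximal for non-responsive and
  down-regulated genes (-500 bp);
* a TSS depletion zone: mark midpoints are re-drawn until they fall at
  least ``tss_depletion_halfwidth`` bp from the TSS, reproducing the
  nucleosome-free-region valley at offset zero in aggregate profiles;
* effector hotspots spanning the TSS with class-conditional probability;
* a 15-state chromatin segmentation tiling each chromosome, with class-3
  (poised promoter) and class-12 (repressed) elements planted nearer to
  responsive genes' TSSs than to non-responsive ones;
* qPCR crossing-point tables with known true expression ratios or IP
  fractions.

All outputs are deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .genomic_io import (
    CpRecord,
    GeneModel,
    HotspotInterval,
    HotspotTrack,
    StateElement,
)

__all__ = [
    "ConfigurationError",
    "SimConfig",
    "SimulatedEpigenome",
    "simulate_epigenome",
    "simulate_cp_table",
    "simulate_chip_cp_table",
    "RESPONSE_CLASSES",
]

RESPONSE_CLASSES = ("up_strong", "up_moderate", "no_change", "down")

#: Background segmentation states (planted classes 3 and 12 are reserved).
_BACKGROUND_STATES = tuple(s for s in range(1, 16) if s not in (3, 12))


class ConfigurationError(ValueError):
    """The simulation configuration is internally infeasible."""


def _per_class(value, default: Mapping[str, float]) -> dict[str, float]:
    if value is None:
        return dict(default)
    out = dict(default)
    out.update(value)
    return out


@dataclass
class SimConfig:
    """Study conditions for one synthetic epigenome.

    Class-conditional dict fields accept partial overrides; unspecified
    classes keep their defaults.
    """

    n_genes: int = 400
    n_chroms: int = 2
    chrom_length: int = 5_000_000
    seed: int = 0

    response_class_probs: dict[str, float] = field(
        default_factory=lambda: {
            "up_strong": 0.05, "up_moderate": 0.10, "no_change": 0.75, "down": 0.10,
        }
    )
    #: signed strand-aware mark-midpoint offset from the TSS, per class (bp)
    k27_offset_mean: dict[str, float] = field(
        default_factory=lambda: {
            "up_strong": -1300.0, "up_moderate": -2500.0,
            "no_change": -500.0, "down": -500.0,
        }
    )
    k27_offset_sd: dict[str, float] = field(
        default_factory=lambda: {
            "up_strong": 300.0, "up_moderate": 300.0, "no_change": 200.0, "down": 200.0,
        }
    )
    #: probability that a gene of each class carries a mark hotspot at all
    k27_present_prob: dict[str, float] = field(
        default_factory=lambda: {
            "up_strong": 1.0, "up_moderate": 1.0, "no_change": 0.7, "down": 0.9,
        }
    )
    effector_at_tss_prob: dict[str, float] = field(
        default_factory=lambda: {
            "up_strong": 0.9, "up_moderate": 0.9, "no_change": 0.1, "down": 0.2,
        }
    )
    #: no mark midpoint closer than this to any TSS (bp); with the default
    #: 400 bp hotspots and 200 bp windows, 300 bp keeps the window at
    #: offset zero mark-free, producing the aggregate-profile valley
    tss_depletion_halfwidth: int = 300
    hotspot_width: int = 400
    score_lognormal_mu: float = 1.0
    score_lognormal_sigma: float = 0.5

    fold_change_log2_mean: dict[str, float] = field(
        default_factory=lambda: {
            "up_strong": 3.5, "up_moderate": 2.0, "no_change": 0.0, "down": -2.0,
        }
    )
    fold_change_log2_sd: float = 0.3
    #: basal (control) FPKM drawn log-uniform from these log10 ranges
    fpkm_log10_range: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "up_strong": (-4.0, 0.0), "up_moderate": (-4.0, 0.0),
            "no_change": (-2.0, 2.0), "down": (-2.0, 2.0),
        }
    )

    gene_length_range: tuple[int, int] = (1000, 10_000)
    gene_spacing: int = 20_000

    seg_tile_length: int = 2000
    #: planted class-3/class-12 element offsets from the TSS (bp)
    seg_offset_mean: dict[str, float] = field(
        default_factory=lambda: {"responsive": -1500.0, "non_responsive": -8000.0}
    )
    seg_offset_sd: dict[str, float] = field(
        default_factory=lambda: {"responsive": 400.0, "non_responsive": 2000.0}
    )

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        total = sum(self.response_class_probs.get(c, 0.0) for c in RESPONSE_CLASSES)
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ConfigurationError(
                f"response_class_probs must sum to 1, got {total}"
            )
        for c in RESPONSE_CLASSES:
            if self.k27_offset_sd.get(c, 0.0) < 0:
                raise ConfigurationError(f"k27_offset_sd[{c}] must be >= 0")
        if self.fold_change_log2_sd < 0:
            raise ConfigurationError("fold_change_log2_sd must be >= 0")
        if self.hotspot_width <= 0:
            raise ConfigurationError("hotspot_width must be > 0")
        if self.gene_spacing < self.gene_length_range[1]:
            raise ConfigurationError(
                "gene_spacing must be at least the maximum gene length "
                "(gene bodies must not overlap)"
            )


@dataclass
class SimulatedEpigenome:
    """One simulated study: inputs for every downstream stage plus the
    planted ground truth (gene_id, response_class, true_log2_fc,
    fpkm_control, planted_k27_offset (NaN = no mark), effector_present)."""

    genes: list[GeneModel]
    k27_track: HotspotTrack
    effector_track: HotspotTrack
    expression: pd.DataFrame
    segmentation: list[StateElement]
    truth: pd.DataFrame


def _hotspot_at(chrom: str, midpoint: int, width: int, score: float) -> HotspotInterval:
    half = width // 2
    return HotspotInterval(chrom, max(midpoint - half, 0), midpoint + (width - half), score)


def _strand_midpoint(tss: int, strand: str, offset: int) -> int:
    return tss + offset if strand == "+" else tss - offset


def simulate_epigenome(config: SimConfig) -> SimulatedEpigenome:
    """Generate one synthetic epigenome (see module docstring).

    Raises :class:`ConfigurationError` when the requested gene count and
    spacing cannot fit on the configured chromosomes.
    """
    rng = np.random.default_rng(config.seed)
    margin = 10_000
    per_chrom = -(-config.n_genes // config.n_chroms)  # ceil
    needed = margin + (per_chrom - 1) * config.gene_spacing \
        + config.gene_length_range[1] + margin
    if needed > config.chrom_length:
        raise ConfigurationError(
            f"cannot place {per_chrom} genes with spacing {config.gene_spacing} bp on a "
            f"{config.chrom_length} bp chromosome (need >= {needed} bp); "
            "increase chrom_length or n_chroms, or reduce n_genes/gene_spacing"
        )

    classes = rng.choice(
        RESPONSE_CLASSES,
        size=config.n_genes,
        p=[config.response_class_probs.get(c, 0.0) for c in RESPONSE_CLASSES],
    )
    strands = rng.choice(["+", "-"], size=config.n_genes)
    lengths = rng.integers(
        config.gene_length_range[0], config.gene_length_range[1] + 1, size=config.n_genes
    )

    genes: list[GeneModel] = []
    k27: list[HotspotInterval] = []
    effector: list[HotspotInterval] = []
    truth_rows = []
    expr_rows = []
    hw = config.tss_depletion_halfwidth

    for i in range(config.n_genes):
        chrom = f"chr{i % config.n_chroms + 1}"
        slot = i // config.n_chroms
        tss = margin + slot * config.gene_spacing
        strand = str(strands[i])
        length = int(lengths[i])
        if strand == "+":
            start, end = tss, tss + length
        else:
            start, end = tss - length + 1, tss + 1
        gene_id = f"gene{i:05d}"
        genes.append(GeneModel(gene_id, chrom, start, end, strand))
        cls = str(classes[i])

        # repressive mark: one hotspot at a class-conditional signed offset,
        # re-drawn until outside the TSS depletion zone
        planted_offset = math.nan
        if rng.random() < config.k27_present_prob[cls]:
            mean = config.k27_offset_mean[cls]
            sd = config.k27_offset_sd[cls]
            offset = int(round(rng.normal(mean, sd)))
            for _ in range(1000):
                if abs(offset) > hw:  # boundary-inclusive exclusion zone
                    break
                offset = int(round(rng.normal(mean, sd)))
            else:  # pathological config (|mean| << hw, tiny sd): push out
                offset = hw if mean >= 0 else -hw
            planted_offset = float(offset)
            mid = _strand_midpoint(tss, strand, offset)
            score = float(rng.lognormal(config.score_lognormal_mu, config.score_lognormal_sigma))
            k27.append(_hotspot_at(chrom, mid, config.hotspot_width, score))

        effector_present = bool(rng.random() < config.effector_at_tss_prob[cls])
        if effector_present:
            score = float(rng.lognormal(config.score_lognormal_mu, config.score_lognormal_sigma))
            effector.append(_hotspot_at(chrom, tss, config.hotspot_width, score))

        lo10, hi10 = config.fpkm_log10_range[cls]
        fpkm_control = float(10.0 ** rng.uniform(lo10, hi10))
        true_lfc = float(rng.normal(config.fold_change_log2_mean[cls], config.fold_change_log2_sd))
        fpkm_treated = fpkm_control * 2.0 ** true_lfc
        expr_rows.append((gene_id, fpkm_control, fpkm_treated))
        truth_rows.append(
            (gene_id, cls, true_lfc, fpkm_control, planted_offset, effector_present)
        )

    segmentation = _simulate_segmentation(config, rng, genes, classes)

    return SimulatedEpigenome(
        genes=genes,
        k27_track=HotspotTrack(k27),
        effector_track=HotspotTrack(effector),
        expression=pd.DataFrame(
            expr_rows, columns=["gene_id", "fpkm_control", "fpkm_treated"]
        ),
        segmentation=segmentation,
        truth=pd.DataFrame(
            truth_rows,
            columns=[
                "gene_id", "response_class", "true_log2_fc",
                "fpkm_control", "planted_k27_offset", "effector_present",
            ],
        ),
    )


def _simulate_segmentation(
    config: SimConfig, rng: np.random.Generator, genes: list[GeneModel], classes
) -> list[StateElement]:
    """Tile chromosomes with background states; plant class 3 and 12 near
    each gene's TSS, nearer for responsive (non-no_change) genes."""
    elements: list[StateElement] = []
    tile = config.seg_tile_length
    for c in range(1, config.n_chroms + 1):
        chrom = f"chr{c}"
        n_tiles = config.chrom_length // tile
        states = rng.choice(_BACKGROUND_STATES, size=n_tiles)
        elements.extend(
            StateElement(chrom, t * tile, (t + 1) * tile, int(states[t]))
            for t in range(n_tiles)
        )
    for gene, cls in zip(genes, classes):
        group = "non_responsive" if cls == "no_change" else "responsive"
        for state_class in (3, 12):
            offset = int(round(rng.normal(
                config.seg_offset_mean[group], config.seg_offset_sd[group]
            )))
            mid = _strand_midpoint(gene.tss, gene.strand, offset)
            start = max(mid - tile // 2, 0)
            elements.append(StateElement(gene.chrom, start, start + tile, state_class))
    elements.sort(key=lambda e: (e.chrom, e.start, e.end, e.state_class))
    return elements


# ---------------------------------------------------------------------------
# qPCR simulation


def simulate_cp_table(
    true_ratios: Mapping[str, float],
    reference_gene: str = "GAPDH",
    cp_reference: float = 20.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    mock_sample: str = "mock",
    treated_sample: str = "treated",
    timepoint: str = "24h",
) -> list[CpRecord]:
    """Cp records for a mock and a treated sample with known expression
    ratios.

    Every gene's expression level in the mock sample is 1 (relative to the
    reference); in the treated sample it is the given ratio.  Cp values
    follow ``Cp_gene = Cp_ref - log2(level) + N(0, noise_sd)``; at
    ``noise_sd=0`` the downstream fold-change arithmetic recovers the
    ratios exactly.
    """
    rng = np.random.default_rng(seed)
    records: list[CpRecord] = []
    for sample, level_of in (
        (mock_sample, lambda r: 1.0),
        (treated_sample, lambda r: r),
    ):
        records.append(
            CpRecord(sample, reference_gene, "reference", timepoint,
                     cp_reference + float(rng.normal(0, noise_sd)) if noise_sd else cp_reference)
        )
        for gene in true_ratios:
            ratio = true_ratios[gene]
            if not (ratio > 0):
                raise ValueError(f"gene {gene}: expression ratio must be > 0, got {ratio}")
            level = level_of(ratio)
            cp = cp_reference - math.log2(level)
            if noise_sd:
                cp += float(rng.normal(0, noise_sd))
            records.append(CpRecord(sample, gene, "gene", timepoint, cp))
    return records


def simulate_chip_cp_table(
    true_ip_fractions: Mapping[str, float],
    cp_input: float = 30.0,
    input_fraction_factor: float = 20.0,
    mock_fraction: float = 0.001,
    noise_sd: float = 0.0,
    seed: int = 0,
    sample_id: str = "chip",
    timepoint: str = "0h",
) -> list[CpRecord]:
    """ChIP-qPCR Cp records with known IP-recovery fractions (0 < f <= ~1).

    The emitted input Cp is the raw (unadjusted) value for sampling
    ``1/input_fraction_factor`` of the prep; IP and mock Cp values satisfy
    ``Cp = adjusted_input - log2(fraction)`` plus optional noise, so the
    downstream percent-input arithmetic recovers ``100 * fraction``.
    """
    rng = np.random.default_rng(seed)
    adjusted = cp_input - math.log2(input_fraction_factor)
    records: list[CpRecord] = []
    for target, frac in true_ip_fractions.items():
        if not (frac > 0):
            raise ValueError(f"target {target}: IP fraction must be > 0, got {frac}")
        records.append(CpRecord(sample_id, target, "input", timepoint, cp_input))
        cp_ip = adjusted - math.log2(frac)
        cp_mock = adjusted - math.log2(mock_fraction)
        if noise_sd:
            cp_ip += float(rng.normal(0, noise_sd))
            cp_mock += float(rng.normal(0, noise_sd))
        records.append(CpRecord(sample_id, target, "ip", timepoint, cp_ip))
        records.append(CpRecord(sample_id, target, "mock", timepoint, cp_mock))
    return records
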