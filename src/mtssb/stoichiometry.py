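"""Quantitative-immunoblot and copy-number arithmetic for mtSSB stoichiometry.

Reproduces the cellular bookkeeping behind the claim that mtSSB is
abundant enough to coat the displaced parental H-strand: band intensities
are interpolated on a recombinant-protein calibration curve, converted to
molecules per cell via Avogadro's number and the 16 kDa monomer mass,
divided by the qPCR-derived mtDNA copy number (with first-order error
propagation), and expressed as tetramers and coatable nucleotides.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import floor, sqrt
from typing import NamedTuple

import numpy as np
from scipy import stats

from .strandseq import fit_log_quantity_curve

__all__ = [
    "MeanSd",
    "StandardCurve",
    "fit_standard_curve",
    "molecules_per_cell",
    "ssb_per_mtdna",
    "tetramer_summary",
    "mtdna_copy_number",
    "StoichiometryResult",
    "AVOGADRO",
    "MTSSB_MONOMER_KDA",
]

AVOGADRO = 6.02214076e23
#: mtSSB monomer mass; the protein binds DNA as a homotetramer of 16 kDa subunits.
MTSSB_MONOMER_KDA = 16.0


class MeanSd(NamedTuple):
    """A mean with its standard deviation."""

    mean: float
    sd: float


@dataclass(frozen=True)
class StandardCurve:
    """Least-squares calibration line ``intensity = slope * amount + intercept``."""

    slope: float
    intercept: float
    r_squared: float
    amounts: tuple[float, ...]
    intensities: tuple[float, ...]

    def amount_at(self, intensity: float) -> float:
        """Invert the curve; warns when extrapolating beyond the standards."""
        if self.slope == 0:
            raise ValueError("cannot invert a flat standard curve")
        amount = (intensity - self.intercept) / self.slope
        if not min(self.amounts) <= amount <= max(self.amounts):
            warnings.warn(
                f"interpolated amount {amount:.4g} outside standard range "
                f"[{min(self.amounts):.4g}, {max(self.amounts):.4g}]",
                stacklevel=2,
            )
        return amount


def fit_standard_curve(amounts, intensities) -> StandardCurve:
    """Fit the calibration line through known amounts of recombinant protein."""
    amounts = np.asarray(amounts, dtype=float)
    intensities = np.asarray(intensities, dtype=float)
    if amounts.size < 2:
        raise ValueError("need at least 2 standard points")
    if np.ptp(amounts) == 0:
        raise ValueError("standard amounts are identical; cannot fit")
    fit = stats.linregress(amounts, intensities)
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        amounts=tuple(amounts),
        intensities=tuple(intensities),
    )


def molecules_per_cell(
    band_intensities,
    curve: StandardCurve,
    n_cells: float,
    monomer_mass_kda: float = MTSSB_MONOMER_KDA,
    amount_unit_grams: float = 1e-9,
) -> MeanSd:
    """Protein molecules per cell from immunoblot band intensities.

    Each replicate intensity is interpolated on the calibration curve
    (amounts in ``amount_unit_grams``; default nanograms), converted to
    molecules via Avogadro's number and the monomer molar mass, and
    divided by the number of cells loaded. The sd is the spread over
    replicates (0 for a single band).
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    if monomer_mass_kda <= 0:
        raise ValueError("monomer mass must be positive")
    intensities = np.atleast_1d(np.asarray(band_intensities, dtype=float))
    molar_mass = monomer_mass_kda * 1000.0  # g/mol
    per_cell = np.array([
        curve.amount_at(i) * amount_unit_grams * AVOGADRO / molar_mass / n_cells
        for i in intensities
    ])
    sd = float(per_cell.std(ddof=1)) if per_cell.size > 1 else 0.0
    return MeanSd(float(per_cell.mean()), sd)


def ssb_per_mtdna(ssb: MeanSd, mtdna: MeanSd) -> MeanSd:
    """Ratio of per-cell means with first-order (delta-method) error propagation.

    Assumes independent errors:
    ``sd = mean * sqrt((sd_ssb/ssb)^2 + (sd_mtdna/mtdna)^2)``.
    """
    if mtdna.mean <= 0 or ssb.mean <= 0:
        raise ValueError("means must be positive")
    if ssb.sd < 0 or mtdna.sd < 0:
        raise ValueError("sds must be nonnegative")
    mean = ssb.mean / mtdna.mean
    sd = mean * sqrt((ssb.sd / ssb.mean) ** 2 + (mtdna.sd / mtdna.mean) ** 2)
    return MeanSd(mean, sd)


def tetramer_summary(
    ratio_mean: float, footprint: int = 59, genome_length: int = 16569
):
    """Tetramers per mtDNA and the single-strand length they can coat.

    ``(tetramers, coverable_nt, sufficient)`` with
    ``tetramers = floor(ratio/4)`` (mtSSB binds as a homotetramer) and
    ``sufficient`` true when the coatable length covers the genome.
    """
    if ratio_mean <= 0 or footprint <= 0 or genome_length <= 0:
        raise ValueError("inputs must be positive")
    tetramers = floor(ratio_mean / 4.0)
    coverable = tetramers * footprint
    return tetramers, coverable, coverable >= genome_length


def mtdna_copy_number(
    sample_cq: float, standard_cqs, standard_copies, n_cells: float = 1.0
) -> float:
    """mtDNA copies per cell by log-linear qPCR standard-curve interpolation."""
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    slope, intercept, flagged = fit_log_quantity_curve(standard_cqs, standard_copies)
    if flagged:
        warnings.warn("non-monotone qPCR standard curve (slope >= 0)", stacklevel=2)
    return float(2.0 ** (slope * sample_cq + intercept)) / n_cells


@dataclass(frozen=True)
class StoichiometryResult:
    """Per-cell stoichiometry summary (the quantitative-western bottom line)."""

    mtdna_per_cell: MeanSd
    ssb_per_cell: MeanSd
    ratio: MeanSd
    tetramers_per_mtdna: int
    coverable_nt: int
    sufficient: bool

    def __post_init__(self) -> None:
        if self.mtdna_per_cell.mean <= 0 or self.ssb_per_cell.mean <= 0:
            raise ValueError("per-cell means must be positive")

    def to_dict(self) -> dict:
        return {
            "mtdna_per_cell": {"mean": self.mtdna_per_cell.mean, "sd": self.mtdna_per_cell.sd},
            "ssb_per_cell": {"mean": self.ssb_per_cell.mean, "sd": self.ssb_per_cell.sd},
            "ssb_per_mtdna": {"mean": self.ratio.mean, "sd": self.ratio.sd},
            "tetramers_per_mtdna": self.tetramers_per_mtdna,
            "coverable_nt": self.coverable_nt,
            "sufficient_to_coat_genome": self.sufficient,
        }


def summarize(
    ssb: MeanSd, mtdna: MeanSd, footprint: int = 59, genome_length: int = 16569
) -> StoichiometryResult:
    """Assemble the full stoichiometry report from the two per-cell counts."""
    ratio = ssb_per_mtdna(ssb, mtdna)
    tetramers, coverable, sufficient = tetramer_summary(
        ratio.mean, footprint, genome_length
    )
    return StoichiometryResult(
        mtdna_per_cell=mtdna,
        ssb_per_cell=ssb,
        ratio=ratio,
        tetramers_per_mtdna=tetramers,
        coverable_nt=coverable,
        sufficient=sufficient,
    )
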