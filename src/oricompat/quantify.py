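"""Copy-number and retention quantification.

Digital PCR partitions a sample across ~20 000 reaction chambers; the
fraction of positive chambers p relates to the mean template load per
chamber through the Poisson occupancy correction lambda = -ln(1 - p).
Running a plasmid-specific probe (FAM) and a single-copy genomic probe
(HEX, targeting the late-replicating Ter region) on the same chip gives
plasmids per genome as lambda_plasmid / lambda_genome; the 95% interval
comes from a percentile bootstrap over binomial resampling of both
channels.

Colony-count retention: plating the same culture on single- and
double-antibiotic agar estimates the fraction of cells retaining both
plasmids, with an exact Clopper-Pearson binomial interval.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "DPCRChip",
    "CopyNumberEstimate",
    "RetentionEstimate",
    "poisson_lambda",
    "copy_number",
    "plating_retention",
]


@dataclass(frozen=True)
class DPCRChip:
    """Partition counts from one dPCR chip (two-channel TaqMan assay)."""

    n_partitions: int
    positives_plasmid: int  # FAM channel
    positives_genome: int   # HEX channel

    def __post_init__(self):
        if self.n_partitions <= 0:
            raise ValueError("n_partitions must be positive")
        for name in ("positives_plasmid", "positives_genome"):
            v = getattr(self, name)
            if not 0 <= v <= self.n_partitions:
                raise ValueError(f"{name}={v} outside [0, {self.n_partitions}]")


@dataclass(frozen=True)
class CopyNumberEstimate:
    """Plasmids per genome with a bootstrap 95% interval."""

    point: float
    ci_low: float
    ci_high: float

    def __post_init__(self):
        if not self.ci_low <= self.point <= self.ci_high:
            raise ValueError("interval must bracket the point estimate")


@dataclass(frozen=True)
class RetentionEstimate:
    fraction: float
    ci_low: float
    ci_high: float


def poisson_lambda(positives: int, n_partitions: int) -> float:
    """Mean template copies per partition from the positive fraction.

    lambda = -ln(1 - positives/n_partitions).  A saturated chip
    (positives == n_partitions) carries no quantitative information and is
    rejected rather than extrapolated.
    """
    if not 0 <= positives <= n_partitions:
        raise ValueError("positives must lie in [0, n_partitions]")
    if positives == n_partitions:
        raise ValueError("saturated chip: lambda is undefined at p = 1")
    return -math.log1p(-positives / n_partitions)


def copy_number(
    chip: DPCRChip,
    bootstrap_reps: int = 10_000,
    rng: np.random.Generator | None = None,
) -> CopyNumberEstimate:
    """Plasmid copy number per genome from a two-channel chip.

    Point estimate lambda_FAM / lambda_HEX; 95% interval by percentile
    bootstrap, resampling each channel's positives as
    Binomial(n_partitions, p_hat).  Resamples that saturate a channel or
    empty the genome channel are dropped from the percentiles (they carry
    an undefined ratio); with realistic occupancies they are vanishingly
    rare.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if chip.positives_genome == 0:
        raise ValueError("zero genome-channel positives: no denominator")
    lam_p = poisson_lambda(chip.positives_plasmid, chip.n_partitions)
    lam_g = poisson_lambda(chip.positives_genome, chip.n_partitions)
    point = lam_p / lam_g

    n = chip.n_partitions
    bp = rng.binomial(n, chip.positives_plasmid / n, size=bootstrap_reps)
    bg = rng.binomial(n, chip.positives_genome / n, size=bootstrap_reps)
    ok = (bp < n) & (bg > 0) & (bg < n)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.log1p(-bp[ok] / n) / np.log1p(-bg[ok] / n)
    ratios = ratios[np.isfinite(ratios)]
    if ratios.size == 0:
        raise ValueError("bootstrap produced no valid resamples")
    lo, hi = np.percentile(ratios, [2.5, 97.5])
    lo = min(float(lo), point)
    hi = max(float(hi), point)
    return CopyNumberEstimate(point=point, ci_low=lo, ci_high=hi)


def plating_retention(
    colonies_double: int, colonies_single: int
) -> RetentionEstimate:
    """Fraction of cells retaining both plasmids, from plate counts.

    fraction = double-antibiotic colonies / single-antibiotic colonies,
    clamped into [0, 1] with a warning when counting noise pushes the ratio
    above 1.  The 95% interval is exact Clopper-Pearson.
    """
    if colonies_single <= 0:
        raise ValueError("single-antibiotic colony count must be positive")
    if colonies_double < 0:
        raise ValueError("colony counts must be non-negative")
    if colonies_double > colonies_single:
        warnings.warn(
            f"double-plate count {colonies_double} exceeds single-plate count "
            f"{colonies_single}; clamping retention to 1 (counting noise)",
            stacklevel=2,
        )
        colonies_double = colonies_single
    frac = colonies_double / colonies_single
    lo, hi = proportion_confint(
        colonies_double, colonies_single, alpha=0.05, method="beta"
    )
    return RetentionEstimate(fraction=frac, ci_low=float(lo), ci_high=float(hi))
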