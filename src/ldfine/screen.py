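"""Decay screening: detect association signals a single causal site cannot explain.

Under a single causal variant, the chi-square association statistic at
every marker in a region is predicted by the line through the origin with
slope equal to the index variant's statistic, evaluated at each marker's
pairwise r2 with the index.  Markers lying far above that line carry more
association than their LD with the index can transmit and are candidates
for an independent causal signal.

The uncertainty band around the decay line is built by residual
resampling: the fitted values are treated as the expected response, the
observed residuals are resampled with replacement to form bootstrap
replicates, and the pointwise 0.025/0.975 quantiles of the replicates give
a 95% band.  Two band constructions are available:

``quantile`` (default)
    Band at each marker is the quantile range of its bootstrap replicate
    responses (fitted + resampled residual).  This band has ~95% pointwise
    coverage of the observations themselves, which is what an outlier
    screen needs.
``refit``
    Each bootstrap replicate is refit by least squares through the origin
    and the band is the quantile range of the refitted lines — a
    confidence band for the decay line, much narrower than the scatter.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .twosite import AssociationStat, Convention

__all__ = [
    "MarkerRecord",
    "DecayFit",
    "BootstrapBand",
    "fit_decay",
    "bootstrap_band",
    "flag_outliers",
]

logger = logging.getLogger(__name__)

BandMethod = Literal["quantile", "refit"]


@dataclass(frozen=True)
class MarkerRecord:
    """One variant's association statistic and its LD with the index variant."""

    snp: str
    chrom: str
    pos: int
    chi2: AssociationStat
    r2: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.r2 <= 1.0:
            raise ValueError(f"{self.snp}: r2={self.r2} outside [0, 1]")

    @classmethod
    def from_pvalue(
        cls, snp: str, chrom: str, pos: int, pvalue: float, r2: float
    ) -> "MarkerRecord":
        from .inference import chi2_p_convert

        stat = chi2_p_convert(pvalue, "p_to_stat", "traditional_1df")
        return cls(snp, chrom, pos, AssociationStat(stat, "traditional_1df"), r2)


@dataclass(frozen=True)
class DecayFit:
    """Origin-anchored decay fit of association against r2 with the index.

    ``slope`` is the index variant's chi-square on the fit's scale, so the
    predicted value at r2 = 1 equals the slope and the index residual is
    exactly 0.  ``ls_slope`` is the unanchored least-squares slope through
    the origin over all usable records, used by the refit bootstrap and as
    a noise-averaged estimate of the index signal.
    """

    index_snp: str
    slope: float
    convention: Convention
    table: pd.DataFrame  # columns: snp, chrom, pos, r2, observed, predicted, residual
    pearson_r: float
    spearman_rho: float
    spearman_p: float
    n_rejected: int

    @property
    def ls_slope(self) -> float:
        x = self.table["r2"].to_numpy()
        y = self.table["observed"].to_numpy()
        return float(x @ y / (x @ x))


@dataclass(frozen=True)
class BootstrapBand:
    """Pointwise 95% residual-bootstrap band aligned with a DecayFit table."""

    B: int
    seed: int
    method: BandMethod
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.lower > self.upper + 1e-12):
            raise ValueError("band lower bound exceeds upper bound")


def fit_decay(
    records: Sequence[MarkerRecord],
    index_snp: str | None = None,
    convention: Convention = "traditional_1df",
) -> DecayFit:
    """Fit the origin-anchored decay line to a region's markers.

    Records with non-finite statistics or r2 are rejected (with a logged
    reason); at least three usable records are required.  When
    ``index_snp`` is omitted the most associated variant is used, and its
    r2 is forced to 1 (a variant is in perfect LD with itself).
    """
    usable: list[MarkerRecord] = []
    n_rejected = 0
    for rec in records:
        if not math.isfinite(rec.chi2.value) or not math.isfinite(rec.r2):
            logger.warning("rejecting %s: non-finite statistic or r2", rec.snp)
            n_rejected += 1
            continue
        usable.append(rec)
    if len(usable) < 3:
        raise ValueError(f"only {len(usable)} usable records; need at least 3")

    if index_snp is None:
        index_rec = max(usable, key=lambda r: r.chi2.traditional)
        index_snp = index_rec.snp
        logger.info("index variant not specified; using most associated: %s", index_snp)
    else:
        matches = [r for r in usable if r.snp == index_snp]
        if not matches:
            raise ValueError(f"index variant {index_snp!r} not among usable records")
        index_rec = matches[0]

    def value(rec: MarkerRecord) -> float:
        return rec.chi2.to(convention).value

    slope = value(index_rec)
    rows = []
    for rec in usable:
        r2 = 1.0 if rec.snp == index_snp else rec.r2
        obs = value(rec)
        rows.append(
            {
                "snp": rec.snp,
                "chrom": rec.chrom,
                "pos": rec.pos,
                "r2": r2,
                "observed": obs,
                "predicted": slope * r2,
            }
        )
    table = pd.DataFrame(rows)
    table["residual"] = table["observed"] - table["predicted"]

    pearson = float(_stats.pearsonr(table["r2"], table["observed"]).statistic)
    spear = _stats.spearmanr(table["r2"], table["observed"])
    return DecayFit(
        index_snp=index_snp,
        slope=slope,
        convention=convention,
        table=table,
        pearson_r=pearson,
        spearman_rho=float(spear.statistic),
        spearman_p=float(spear.pvalue),
        n_rejected=n_rejected,
    )


def bootstrap_band(
    fit: DecayFit, B: int = 10_000, seed: int = 0, method: BandMethod = "quantile"
) -> BootstrapBand:
    """Residual-resampling 95% band around the decay fit.

    B below 100 is refused: empirical 2.5%/97.5% quantiles are unstable
    with fewer resamples.
    """
    if B < 100:
        raise ValueError(f"B={B} too small for stable tail quantiles (need >= 100)")
    rng = np.random.default_rng(seed)
    fitted = fit.table["predicted"].to_numpy()
    resid = fit.table["residual"].to_numpy()
    x = fit.table["r2"].to_numpy()
    n = fitted.size

    draws = rng.choice(resid, size=(B, n), replace=True)
    ystar = fitted[None, :] + draws
    if method == "quantile":
        lower, upper = np.quantile(ystar, [0.025, 0.975], axis=0)
    elif method == "refit":
        slopes = ystar @ x / (x @ x)
        lo_s, hi_s = np.quantile(slopes, [0.025, 0.975])
        lower, upper = lo_s * x, hi_s * x
    else:
        raise ValueError(f"unknown band method {method!r}")
    return BootstrapBand(B=B, seed=seed, method=method, lower=lower, upper=upper)


def flag_outliers(fit: DecayFit, band: BootstrapBand) -> pd.DataFrame:
    """Variants whose observed statistic exceeds the upper band.

    Returns a table with observed, predicted, the band bound and the
    exceedance (observed - upper), sorted by exceedance descending.
    """
    if band.upper.shape[0] != len(fit.table):
        raise ValueError("band was not computed on this fit's records")
    tab = fit.table.copy()
    tab["lower"] = band.lower
    tab["upper"] = band.upper
    tab["exceedance"] = tab["observed"] - tab["upper"]
    flagged = tab[tab["exceedance"] > 0.0].sort_values("exceedance", ascending=False)
    return flagged.reset_index(drop=True)
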