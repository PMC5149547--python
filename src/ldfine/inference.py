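"""Inference of causal-site effect size from a linked marker's statistic.

The fine-mapping identity chi2_M = r2 * chi2_D can be inverted: given the
association statistic observed at a genotyped marker, the pairwise r2
between the marker and a known-but-not-genotyped site, and that site's
general-population allele frequency p, the allelic odds ratio R the site
would need to generate the observed signal is

    R = ((1 - p) / p) * (p + Delta) / (1 - p - Delta),
    Delta = sqrt(2 p (1 - p) chi2_pp / (m r2)),

under the rare-disease approximation pC ~= p.  Two effective-sample-size
conventions for m are supported (see ``NeConvention``); the default,
m = 2 nD nC / (nD + nC) applied to the doubled-scale statistic, is the one
that reproduces the published worked example (R = 5.17 for chi2_pp = 20,
500 cases / 500 controls, p = 0.03, r2 = 0.2).  The literal corollary form
m = 4 nD nC / (nD + nC) is the algebraically exact inverse of the
expected-statistic formula under pC = p and yields 3.85 in that example;
the discrepancy between the two is a factor sqrt(2) in Delta.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import math

from scipy.stats import chi2 as _chi2_dist

from .twosite import AssociationStat, Convention, StudyDesign

__all__ = [
    "InferredEffect",
    "NeConvention",
    "chi2_p_convert",
    "causal_or_from_marker",
    "marker_chi2_from_causal_or",
    "expected_marker_chi2",
]

NeConvention = Literal["worked_example", "eq_literal"]


def _effective_m(design: StudyDesign, ne_convention: NeConvention) -> float:
    if ne_convention == "worked_example":
        return design.ne_half
    if ne_convention == "eq_literal":
        return design.ne_pp
    raise ValueError(f"unknown ne_convention {ne_convention!r}")


@dataclass(frozen=True)
class InferredEffect:
    """Allelic odds ratio at a putative causal site implied by a marker signal."""

    R: float
    pD_implied: float
    chi2_M: AssociationStat
    r2: float
    p: float
    design: StudyDesign
    ne_convention: NeConvention

    def __post_init__(self) -> None:
        if self.R <= 0.0:
            raise ValueError(f"odds ratio {self.R} must be positive")
        if not 0.0 < self.pD_implied < 1.0:
            raise ValueError(f"implied case frequency {self.pD_implied} outside (0, 1)")


def chi2_p_convert(
    value: float,
    direction: Literal["stat_to_p", "p_to_stat"],
    convention: Convention = "traditional_1df",
) -> float:
    """Convert between a 1-df chi-square statistic and its p-value.

    Doubled-scale statistics are halved before the tail probability is
    taken (and the inverse direction doubles the recovered statistic).
    The inverse uses the chi-square inverse survival function, accurate
    well beyond 1e-10 in the statistic.
    """
    if direction == "stat_to_p":
        if value < 0.0:
            raise ValueError(f"chi-square statistic {value} must be nonnegative")
        return AssociationStat(value, convention).pvalue
    if direction == "p_to_stat":
        if not 0.0 < value < 1.0:
            raise ValueError(f"p-value {value} must lie strictly in (0, 1)")
        stat = float(_chi2_dist.isf(value, df=1))
        return 2.0 * stat if convention == "pp_doubled" else stat
    raise ValueError(f"unknown direction {direction!r}")


def causal_or_from_marker(
    chi2_M: AssociationStat,
    r2: float,
    p: float,
    design: StudyDesign,
    ne_convention: NeConvention = "worked_example",
    protective: bool = False,
) -> InferredEffect:
    """Back-infer the causal-site odds ratio from a marker statistic.

    ``protective`` selects the negative root of the quadratic (an odds
    ratio below 1, depleted risk allele in cases); the default is the
    risk-direction solution R >= 1.
    """
    if not 0.0 < r2 <= 1.0:
        raise ValueError(f"r2={r2} must lie in (0, 1]")
    if not 0.0 < p < 1.0:
        raise ValueError(f"allele frequency p={p} must lie strictly in (0, 1)")
    m = _effective_m(design, ne_convention)
    delta = math.sqrt(2.0 * p * (1.0 - p) * chi2_M.doubled / (m * r2))
    if protective:
        delta = -delta
    if delta >= 1.0 - p:
        raise ValueError(
            f"implied case frequency p+Delta={p + delta} >= 1: "
            "the marker signal is too strong for a feasible effect at this site"
        )
    if delta <= -p:
        raise ValueError(f"implied case frequency p+Delta={p + delta} <= 0: infeasible")
    R = ((1.0 - p) / p) * (p + delta) / (1.0 - p - delta)
    return InferredEffect(
        R=R,
        pD_implied=p + delta,
        chi2_M=chi2_M,
        r2=r2,
        p=p,
        design=design,
        ne_convention=ne_convention,
    )


def marker_chi2_from_causal_or(
    R: float,
    r2: float,
    p: float,
    design: StudyDesign,
    ne_convention: NeConvention = "worked_example",
) -> AssociationStat:
    """Expected marker statistic generated by a causal site of odds ratio R.

    Forward counterpart of :func:`causal_or_from_marker` under the same
    pC ~= p approximation and sample-size convention: the case allele
    frequency is pD = R p / (1 - p + R p) and the doubled-scale marker
    statistic is (pD - p)^2 * m * r2 / (2 p (1 - p)).  The pair inverts
    exactly (round-trip recovery of R to machine precision).
    """
    if R <= 0.0:
        raise ValueError(f"odds ratio R={R} must be positive")
    if not 0.0 <= r2 <= 1.0:
        raise ValueError(f"r2={r2} must lie in [0, 1]")
    if not 0.0 < p < 1.0:
        raise ValueError(f"allele frequency p={p} must lie strictly in (0, 1)")
    m = _effective_m(design, ne_convention)
    pD = R * p / (1.0 - p + R * p)
    delta = pD - p
    return AssociationStat(delta * delta * m * r2 / (2.0 * p * (1.0 - p)), "pp_doubled")


def expected_marker_chi2(chi2_index: AssociationStat, r2: float) -> AssociationStat:
    """Predicted statistic at a marker in LD r2 with the index signal.

    Direct application of chi2_M = r2 * chi2_D; the scale convention of
    the input is preserved.
    """
    if not 0.0 <= r2 <= 1.0:
        raise ValueError(f"r2={r2} must lie in [0, 1]")
    return AssociationStat(r2 * chi2_index.value, chi2_index.convention)
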