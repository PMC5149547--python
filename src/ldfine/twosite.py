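"""Deterministic two-site disease model.

A biallelic causal site A (alleles A1/A2) and a closely linked biallelic
marker B (alleles B1/B2) are described by the four haplotype frequencies
P11..P22 in the general population together with genotype penetrances
f_ij = P(Case | AiAj) at the causal site.  From these the module derives
case/control allele and haplotype frequencies, the expected (parameter
level, noise free) chi-square association statistics at both sites, the
standard pairwise LD measures D and r-squared, and the exact fine-mapping
identity

    chi2_marker = r2 * chi2_causal,

which holds for every penetrance configuration (any mode of inheritance).

Statistics are carried with an explicit scale convention: ``pp_doubled``
(the Pritchard-Przeworski form, twice the traditional 1-df chi-square)
or ``traditional_1df``.  Half of a doubled statistic is chi-square
distributed with one degree of freedom under the null.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

from scipy.stats import chi2 as _chi2_dist

__all__ = [
    "TwoSiteModel",
    "HaplotypeFrequencies",
    "StudyDesign",
    "PopulationState",
    "AssociationStat",
    "Convention",
    "prevalence",
    "population_state",
    "chi_square_stats",
    "ld_measures",
    "theorem_ratio",
]

Convention = Literal["pp_doubled", "traditional_1df"]

_SUM_TOL = 1e-12


class DegenerateModelError(ValueError):
    """Raised when model parameters imply a prevalence of 0 or 1."""


class FixationError(ZeroDivisionError):
    """Raised when an allele frequency of 0 or 1 makes a statistic undefined."""


@dataclass(frozen=True)
class TwoSiteModel:
    """Penetrances of the three causal-site genotypes.

    f11, f12, f22 are P(Case | A1A1), P(Case | A1A2), P(Case | A2A2).
    No ordering is imposed: additive, multiplicative, dominant, recessive
    and arbitrary patterns are all valid.
    """

    f11: float
    f12: float
    f22: float

    def __post_init__(self) -> None:
        for name in ("f11", "f12", "f22"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"penetrance {name}={v} must lie strictly in (0, 1)")

    @property
    def is_null(self) -> bool:
        """True when all genotypes share one penetrance (no genetic effect)."""
        return self.f11 == self.f12 == self.f22


@dataclass(frozen=True)
class HaplotypeFrequencies:
    """General-population frequencies of the four two-locus haplotypes.

    P11 = P(A1B1), P12 = P(A1B2), P21 = P(A2B1), P22 = P(A2B2).
    Marginals p = P(A1) = P11 + P12 and q = P(B1) = P11 + P21 and the
    LD coefficient D = P11*P22 - P12*P21 = P11 - p*q are derived.
    """

    P11: float
    P12: float
    P21: float
    P22: float

    def __post_init__(self) -> None:
        vals = self.as_tuple()
        for name, v in zip(("P11", "P12", "P21", "P22"), vals):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"haplotype frequency {name}={v} outside [0, 1]")
        if abs(sum(vals) - 1.0) > _SUM_TOL:
            raise ValueError(f"haplotype frequencies sum to {sum(vals)!r}, not 1")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.P11, self.P12, self.P21, self.P22)

    @property
    def p(self) -> float:
        """Frequency of the A1 allele at the causal site."""
        return self.P11 + self.P12

    @property
    def q(self) -> float:
        """Frequency of the B1 allele at the marker site."""
        return self.P11 + self.P21

    @property
    def D(self) -> float:
        """LD coefficient P11*P22 - P12*P21 (== P11 - p*q)."""
        return self.P11 * self.P22 - self.P12 * self.P21

    @classmethod
    def from_pq_d(cls, p: float, q: float, D: float) -> "HaplotypeFrequencies":
        """Build from marginal allele frequencies and a feasible D.

        D must satisfy the Lewontin bounds
        max(-p*q, -(1-p)(1-q)) <= D <= min(p*(1-q), q*(1-p)).
        """
        if not 0.0 < p < 1.0 or not 0.0 < q < 1.0:
            raise ValueError("p and q must lie strictly in (0, 1)")
        lo = max(-p * q, -(1.0 - p) * (1.0 - q))
        hi = min(p * (1.0 - q), q * (1.0 - p))
        if not lo - 1e-15 <= D <= hi + 1e-15:
            raise ValueError(f"D={D} violates Lewontin bounds [{lo}, {hi}] for p={p}, q={q}")
        vals = [p * q + D, p * (1.0 - q) - D, (1.0 - p) * q - D, (1.0 - p) * (1.0 - q) + D]
        # at the Lewontin boundary rounding can leave a frequency a few ulp
        # outside [0, 1]; snap those back
        vals = [min(max(v, 0.0), 1.0) if -1e-12 < v < 1.0 + 1e-12 else v for v in vals]
        return cls(*vals)


@dataclass(frozen=True)
class StudyDesign:
    """Diploid case/control sample sizes and effective-sample-size conventions.

    ``ne_pp`` = 4*nD*nC/(nD+nC) is the effective number of independent
    diploid samples as printed in the inference corollary; ``ne_half`` is
    half that, 2*nD*nC/(nD+nC), the convention that reproduces the
    corollary's worked example.
    """

    nD: int
    nC: int

    def __post_init__(self) -> None:
        if self.nD < 1 or self.nC < 1:
            raise ValueError("need at least one case and one control")

    @property
    def n(self) -> int:
        return self.nD + self.nC

    @property
    def ne_pp(self) -> float:
        return 4.0 * self.nD * self.nC / self.n

    @property
    def ne_half(self) -> float:
        return 2.0 * self.nD * self.nC / self.n


@dataclass(frozen=True)
class PopulationState:
    """Disease-stratified frequencies implied by a model and haplotypes.

    K is the disease prevalence attributable to the causal locus (the
    monogenic total-probability sum over causal genotypes).  V are case
    haplotype frequencies, U control haplotype frequencies; p*/q* are the
    A1/B1 allele frequencies in cases (D) and controls (C).
    """

    K: float
    pD: float
    pC: float
    qD: float
    qC: float
    V: tuple[float, float, float, float]
    U: tuple[float, float, float, float]
    haps: HaplotypeFrequencies = field(repr=False)


@dataclass(frozen=True)
class AssociationStat:
    """A 1-df case/control chi-square statistic with its scale convention.

    ``pp_doubled`` values are twice the traditional statistic; the
    p-value is always the upper tail of a 1-df chi-square evaluated on
    the traditional scale, so it is invariant under conversion.
    """

    value: float
    convention: Convention = "pp_doubled"

    def __post_init__(self) -> None:
        if self.value < 0.0:
            raise ValueError(f"chi-square value {self.value} must be nonnegative")
        if self.convention not in ("pp_doubled", "traditional_1df"):
            raise ValueError(f"unknown convention {self.convention!r}")

    @property
    def traditional(self) -> float:
        return self.value / 2.0 if self.convention == "pp_doubled" else self.value

    @property
    def doubled(self) -> float:
        return self.value if self.convention == "pp_doubled" else self.value * 2.0

    @property
    def pvalue(self) -> float:
        return float(_chi2_dist.sf(self.traditional, df=1))

    def to(self, convention: Convention) -> "AssociationStat":
        """Return the same statistic expressed on another scale."""
        if convention == self.convention:
            return self
        if convention == "pp_doubled":
            return AssociationStat(self.doubled, "pp_doubled")
        return AssociationStat(self.traditional, "traditional_1df")


def prevalence(model: TwoSiteModel, p: float) -> float:
    """Disease prevalence K = f11*p^2 + 2*f12*p*(1-p) + f22*(1-p)^2.

    Assumes Hardy-Weinberg proportions at the causal site, with p the
    general-population frequency of the A1 allele.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"causal allele frequency p={p} must lie strictly in (0, 1)")
    return model.f11 * p * p + 2.0 * model.f12 * p * (1.0 - p) + model.f22 * (1.0 - p) ** 2


def population_state(model: TwoSiteModel, haps: HaplotypeFrequencies) -> PopulationState:
    """Case and control haplotype/allele frequencies by Bayes' theorem.

    Case haplotype frequencies weight each population haplotype by the
    probability of disease given the causal allele it carries,
    V_ij = P_ij * [f_i1*p + f_i2*(1-p)] / K; controls follow from the
    law of total probability, U_ij = (P_ij - K*V_ij) / (1-K).
    """
    p = haps.p
    K = prevalence(model, p)
    if not 0.0 < K < 1.0:
        raise DegenerateModelError(f"prevalence K={K} is degenerate")
    # P(Case | haplotype carries A1) and P(Case | carries A2): the partner
    # chromosome carries A1 with probability p under random mating.
    case_given_a1 = model.f11 * p + model.f12 * (1.0 - p)
    case_given_a2 = model.f12 * p + model.f22 * (1.0 - p)
    V = (
        haps.P11 * case_given_a1 / K,
        haps.P12 * case_given_a1 / K,
        haps.P21 * case_given_a2 / K,
        haps.P22 * case_given_a2 / K,
    )
    U = tuple((Pij - K * Vij) / (1.0 - K) for Pij, Vij in zip(haps.as_tuple(), V))
    pD = V[0] + V[1]
    qD = V[0] + V[2]
    pC = (p - K * pD) / (1.0 - K)
    qC = (haps.q - K * qD) / (1.0 - K)
    return PopulationState(K=K, pD=pD, pC=pC, qD=qD, qC=qC, V=V, U=U, haps=haps)


def _expected_chi2(freq_case: float, freq_ctrl: float, freq_pop: float, design: StudyDesign) -> float:
    # Doubled-convention expected statistic:
    # (fD - fC)^2 * [2n * (nD/n) * (nC/n)] / (f*(1-f))
    n = design.n
    scale = 2.0 * n * (design.nD / n) * (design.nC / n)
    return (freq_case - freq_ctrl) ** 2 * scale / (freq_pop * (1.0 - freq_pop))


def chi_square_stats(
    state: PopulationState, design: StudyDesign
) -> tuple[AssociationStat, AssociationStat]:
    """Expected association statistics at the causal and marker sites.

    Returns (chi2_causal, chi2_marker) in the doubled convention.  These
    are parameter-level values: allele frequencies are treated as fixed,
    with no sampling noise.
    """
    haps = state.haps
    p, q = haps.p, haps.q
    if not 0.0 < p < 1.0:
        raise FixationError(f"causal site fixed (p={p}); statistic undefined")
    if not 0.0 < q < 1.0:
        raise FixationError(f"marker site fixed (q={q}); statistic undefined")
    chi2_d = _expected_chi2(state.pD, state.pC, p, design)
    chi2_m = _expected_chi2(state.qD, state.qC, q, design)
    return AssociationStat(chi2_d, "pp_doubled"), AssociationStat(chi2_m, "pp_doubled")


def ld_measures(haps: HaplotypeFrequencies) -> tuple[float, float]:
    """Return (D, r2) where r2 = D^2 / (p(1-p)q(1-q))."""
    p, q = haps.p, haps.q
    if not 0.0 < p < 1.0 or not 0.0 < q < 1.0:
        raise FixationError(f"r2 undefined at fixation (p={p}, q={q})")
    D = haps.D
    r2 = D * D / (p * (1.0 - p) * q * (1.0 - q))
    # clip the tiniest float overshoot at perfect LD
    return D, min(r2, 1.0)


def theorem_ratio(
    model: TwoSiteModel, haps: HaplotypeFrequencies, design: StudyDesign
) -> float:
    """Ratio chi2_marker / chi2_causal of the expected statistics.

    By the fine-mapping identity this equals r2 for every penetrance
    configuration; both statistics are computed independently here so the
    ratio is a genuine check of that identity, not a restatement.
    """
    state = population_state(model, haps)
    chi2_d, chi2_m = chi_square_stats(state, design)
    # guard against float dust from an exactly-null model, where pD - pC
    # cancels to ~1e-17 and the ratio would be numerical garbage
    if chi2_d.value < 1e-15:
        raise ZeroDivisionError("chi2 at the causal site is 0 (null model); ratio undefined")
    return chi2_m.value / chi2_d.value
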