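"""Monte Carlo sampling of case/control haplotypes around the theorem.

Case and control haplotype counts are drawn as two independent multinomial
variates from the disease-stratified frequencies V and U.  Each diploid
individual contributes two chromosomes, so by default a study arm of n
diploid samples yields 2n haploid draws (``chrom_per_diploid`` exposes the
literal one-chromosome-per-sample reading).

Replicate statistics are standard 1-df allelic chi-squares computed from
the drawn chromosome counts with pooled (or optionally population) allele
frequencies in the denominator.  Their expectation tracks the parameter
level statistic plus one null degree of freedom, and under the null model
(equal penetrances) the traditional statistic averages to 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .recombination import RecombinationParams, recurse_haplotypes
from .twosite import (
    HaplotypeFrequencies,
    PopulationState,
    StudyDesign,
    TwoSiteModel,
    ld_measures,
    population_state,
)

__all__ = ["HaplotypeCounts", "sample_counts", "replicate_study", "summarize_replicates"]

FreqDenominator = Literal["pooled", "population"]


@dataclass(frozen=True)
class HaplotypeCounts:
    """Haploid chromosome counts of the four haplotypes per study arm."""

    x11: int
    x12: int
    x21: int
    x22: int
    y11: int
    y12: int
    y21: int
    y22: int

    @property
    def n_case_chrom(self) -> int:
        return self.x11 + self.x12 + self.x21 + self.x22

    @property
    def n_ctrl_chrom(self) -> int:
        return self.y11 + self.y12 + self.y21 + self.y22


def _as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_counts(
    state: PopulationState,
    design: StudyDesign,
    seed: int | np.random.Generator | None = None,
    chrom_per_diploid: int = 2,
) -> HaplotypeCounts:
    """Draw one multinomial sample of case and control haplotype counts."""
    rng = _as_rng(seed)
    v = np.asarray(state.V, dtype=float)
    u = np.asarray(state.U, dtype=float)
    for name, vec in (("V", v), ("U", u)):
        if np.any(vec < 0) or abs(vec.sum() - 1.0) > 1e-9:
            raise ValueError(f"{name} is not a valid probability vector: {vec}")
    x = rng.multinomial(chrom_per_diploid * design.nD, v / v.sum())
    y = rng.multinomial(chrom_per_diploid * design.nC, u / u.sum())
    return HaplotypeCounts(*map(int, x), *map(int, y))


def _allelic_chi2(
    f_case: np.ndarray,
    f_ctrl: np.ndarray,
    m_case: int,
    m_ctrl: int,
    f_denom: np.ndarray,
) -> np.ndarray:
    """Standard 1-df allelic chi-square from per-arm allele frequencies.

    ``m_case``/``m_ctrl`` are chromosome counts; ``f_denom`` is the
    frequency used in the variance denominator (pooled or population).
    Returns NaN where the denominator frequency is fixed.
    """
    var = f_denom * (1.0 - f_denom) * (1.0 / m_case + 1.0 / m_ctrl)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = (f_case - f_ctrl) ** 2 / var
    return np.where(var > 0.0, stat, np.nan)


def replicate_study(
    model: TwoSiteModel,
    haps0: HaplotypeFrequencies,
    c: float,
    t: int | Sequence[int],
    design: StudyDesign,
    n_reps: int,
    seed: int | np.random.Generator | None = None,
    chrom_per_diploid: int = 2,
    freq_denominator: FreqDenominator = "pooled",
) -> pd.DataFrame:
    """Simulate replicate case/control studies at one or more generations.

    For each generation in ``t`` the haplotype frequencies are evolved
    deterministically under recombination, the disease-stratified state is
    built, and ``n_reps`` independent pairs of multinomial samples are
    drawn.  Each replicate records the population r2 at that generation,
    sample allele frequencies, and the sampled chi-square statistics at
    both sites (traditional 1-df scale).

    Replicates in which the denominator allele frequency is fixed are kept
    with ``flagged=True`` and NaN statistics rather than dropped.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = _as_rng(seed)
    t_list: Iterable[int] = [t] if isinstance(t, (int, np.integer)) else list(t)
    m_case = chrom_per_diploid * design.nD
    m_ctrl = chrom_per_diploid * design.nC

    frames = []
    for t_now in t_list:
        haps_t = recurse_haplotypes(haps0, RecombinationParams(c, int(t_now)))
        _, r2_t = ld_measures(haps_t)
        state = population_state(model, haps_t)
        x = rng.multinomial(m_case, np.asarray(state.V), size=n_reps)
        y = rng.multinomial(m_ctrl, np.asarray(state.U), size=n_reps)

        phat_d = (x[:, 0] + x[:, 1]) / m_case
        phat_c = (y[:, 0] + y[:, 1]) / m_ctrl
        qhat_d = (x[:, 0] + x[:, 2]) / m_case
        qhat_c = (y[:, 0] + y[:, 2]) / m_ctrl
        if freq_denominator == "pooled":
            p_den = (x[:, 0] + x[:, 1] + y[:, 0] + y[:, 1]) / (m_case + m_ctrl)
            q_den = (x[:, 0] + x[:, 2] + y[:, 0] + y[:, 2]) / (m_case + m_ctrl)
        elif freq_denominator == "population":
            p_den = np.full(n_reps, haps_t.p)
            q_den = np.full(n_reps, haps_t.q)
        else:
            raise ValueError(f"unknown freq_denominator {freq_denominator!r}")

        chi2_d = _allelic_chi2(phat_d, phat_c, m_case, m_ctrl, p_den)
        chi2_m = _allelic_chi2(qhat_d, qhat_c, m_case, m_ctrl, q_den)
        frames.append(
            pd.DataFrame(
                {
                    "rep": np.arange(n_reps),
                    "t": int(t_now),
                    "r2": r2_t,
                    "chi2_D": chi2_d,
                    "chi2_M": chi2_m,
                    "phat_D": phat_d,
                    "phat_C": phat_c,
                    "qhat_D": qhat_d,
                    "qhat_C": qhat_c,
                    "flagged": np.isnan(chi2_d) | np.isnan(chi2_m),
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out.attrs["convention"] = "traditional_1df"
    out.attrs["chrom_per_diploid"] = chrom_per_diploid
    out.attrs["freq_denominator"] = freq_denominator
    return out


def summarize_replicates(results: pd.DataFrame, by: str = "r2") -> pd.DataFrame:
    """Mean and empirical 95% interval of the marker statistic per group.

    Groups with fewer than two non-missing replicates raise, since an
    empirical quantile interval is meaningless there.
    """
    rows = []
    for key, grp in results.groupby(by, sort=True):
        vals = grp["chi2_M"].dropna().to_numpy()
        if vals.size < 2:
            raise ValueError(f"group {by}={key} has {vals.size} usable replicates (need >= 2)")
        lo, hi = np.quantile(vals, [0.025, 0.975])
        rows.append(
            {
                by: key,
                "n": int(vals.size),
                "n_flagged": int(grp["flagged"].sum()),
                "mean_chi2_M": float(vals.mean()),
                "q025": float(lo),
                "q975": float(hi),
            }
        )
    return pd.DataFrame(rows)
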