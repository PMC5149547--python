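"""Synthetic fine-mapping regions for exercising the decay screen.

Generates the two inputs the screening analysis consumes — a
summary-statistics table and a PLINK-style pairwise LD table against an
index variant — under the single-causal-site model: one causal variant
drives association at every marker through its r2 with the index, with a
choice of noise source and an optional injected second, independent
signal.  The noise models:

``none``
    Observed statistics sit exactly on the decay line slope * r2.
``analytic``
    Gaussian residuals of a fixed scale are added to the line (clipped at
    0, since a chi-square cannot be negative).
``multinomial``
    Each marker's statistic is produced by one multinomial case/control
    sampling replicate at that marker's r2 with the causal site, using the
    two-site disease model — the same sampling engine as the Monte Carlo
    study, so the noise is the genuine finite-sample dispersion around the
    theorem.  Marker allele frequencies are set equal to the causal allele
    frequency so that every r2 in [0, 1] is feasible under the Lewontin
    bounds with the coupling-phase convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .simulate import _allelic_chi2, sample_counts
from .twosite import (
    HaplotypeFrequencies,
    StudyDesign,
    TwoSiteModel,
    chi_square_stats,
    population_state,
)

__all__ = ["SecondSignal", "RegionSpec", "generate_region", "write_region"]

NoiseKind = Literal["none", "analytic", "multinomial"]


@dataclass(frozen=True)
class SecondSignal:
    """An independent association signal injected at one synthetic marker.

    The marker gets pairwise LD ``r2`` with the index but an observed
    statistic ``offset_chi2`` above what the decay line predicts there —
    the signature of a second causal site the index cannot explain.
    """

    r2: float
    offset_chi2: float
    snp: str = "snp_second"

    def __post_init__(self) -> None:
        if not 0.0 <= self.r2 < 1.0:
            raise ValueError(f"second-signal r2={self.r2} must lie in [0, 1)")
        if self.offset_chi2 <= 0.0:
            raise ValueError("second-signal offset must be positive")


@dataclass(frozen=True)
class RegionSpec:
    """Parameters of one synthetic region (marker count includes the index).

    The decay slope comes either from ``index_chi2`` (traditional scale)
    or from a two-site disease model (penetrances + causal allele
    frequency + study design), which is required for multinomial noise.
    ``r2_values`` overrides the random r2 distribution with an explicit
    list for the non-index markers.
    """

    n_markers: int
    seed: int
    index_chi2: float | None = None
    model: TwoSiteModel | None = None
    causal_freq: float | None = None
    design: StudyDesign | None = None
    r2_dist: Literal["beta", "uniform"] = "beta"
    r2_values: Sequence[float] | None = None
    noise: NoiseKind = "none"
    residual_scale: float = 1.0
    second_signal: SecondSignal | None = None
    chrom: str = "16"
    start_bp: int = 53_500_000
    spacing_bp: int = 1_000
    index_snp: str = "snp_index"

    def __post_init__(self) -> None:
        if self.n_markers < 3:
            raise ValueError("need at least 3 markers")
        model_given = self.model is not None
        if model_given and (self.causal_freq is None or self.design is None):
            raise ValueError("a model requires causal_freq and design as well")
        if self.index_chi2 is None and not model_given:
            raise ValueError("provide index_chi2 or a disease model")
        if self.noise == "multinomial" and not model_given:
            raise ValueError("multinomial noise requires a disease model")
        if self.r2_values is not None:
            if len(self.r2_values) != self.n_markers - 1:
                raise ValueError(
                    f"r2_values has {len(self.r2_values)} entries; "
                    f"need n_markers-1 = {self.n_markers - 1}"
                )
            for v in self.r2_values:
                if not 0.0 <= v < 1.0:
                    raise ValueError(f"explicit r2={v} must lie in [0, 1)")
        if self.noise == "analytic" and self.residual_scale < 0.0:
            raise ValueError("residual_scale must be nonnegative")

    @property
    def slope(self) -> float:
        """Decay slope: the index variant's expected chi-square."""
        if self.index_chi2 is not None:
            return self.index_chi2
        state = population_state(self.model, _haps_at_r2(self.causal_freq, 1.0))
        chi2_d, _ = chi_square_stats(state, self.design)
        # Eq-form parameter value == noncentrality of the sampled 1-df statistic
        return chi2_d.value


def _haps_at_r2(p: float, r2: float) -> HaplotypeFrequencies:
    """Haplotypes with marker frequency q = p and coupling-phase LD r2."""
    d = np.sqrt(r2) * p * (1.0 - p)
    return HaplotypeFrequencies.from_pq_d(p, p, d)


def generate_region(spec: RegionSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (summary-statistics table, LD table) for one region.

    Deterministic given ``spec.seed``.  The sumstats table has columns
    SNP, CHR, BP, CHISQ (traditional scale); the LD table is the PLINK
    pair dialect (CHR_A BP_A SNP_A CHR_B BP_B SNP_B R2) with every pair
    anchored at the index variant.
    """
    rng = np.random.default_rng(spec.seed)
    n_other = spec.n_markers - 1

    if spec.r2_values is not None:
        r2 = np.asarray(spec.r2_values, dtype=float)
    elif spec.r2_dist == "beta":
        r2 = rng.beta(1.0, 3.0, size=n_other)
    elif spec.r2_dist == "uniform":
        r2 = rng.uniform(0.0, 1.0, size=n_other)
    else:  # pragma: no cover - guarded by dataclass Literal
        raise ValueError(f"unknown r2_dist {spec.r2_dist!r}")
    r2 = np.clip(r2, 0.0, 0.999)

    snps = [f"snp_{i:04d}" for i in range(1, n_other + 1)]
    if spec.second_signal is not None:
        # replace the last ordinary marker with the second-signal marker
        snps[-1] = spec.second_signal.snp
        r2[-1] = spec.second_signal.r2

    all_snps = [spec.index_snp] + snps
    all_r2 = np.concatenate([[1.0], r2])
    positions = spec.start_bp + spec.spacing_bp * np.arange(1, spec.n_markers + 1)

    slope = spec.slope
    if spec.noise == "none":
        observed = slope * all_r2
    elif spec.noise == "analytic":
        observed = slope * all_r2 + rng.normal(0.0, spec.residual_scale, spec.n_markers)
        observed = np.clip(observed, 0.0, None)
    else:  # multinomial
        observed = np.empty(spec.n_markers)
        m_case = 2 * spec.design.nD
        m_ctrl = 2 * spec.design.nC
        for i, r2_i in enumerate(all_r2):
            haps_i = _haps_at_r2(spec.causal_freq, r2_i)
            state = population_state(spec.model, haps_i)
            counts = sample_counts(state, spec.design, rng)
            qhat_d = (counts.x11 + counts.x21) / m_case
            qhat_c = (counts.y11 + counts.y21) / m_ctrl
            # population-frequency denominator: keeps each marker's expected
            # statistic on the decay line slope*r2 (a pooled case/control
            # frequency is shifted toward the case frequency and deflates
            # the statistic when cases are oversampled relative to K)
            stat = _allelic_chi2(
                np.array([qhat_d]), np.array([qhat_c]), m_case, m_ctrl, np.array([haps_i.q])
            )[0]
            observed[i] = 0.0 if np.isnan(stat) else stat

    if spec.second_signal is not None:
        observed[-1] += spec.second_signal.offset_chi2

    sumstats = pd.DataFrame(
        {
            "SNP": all_snps,
            "CHR": spec.chrom,
            "BP": positions,
            "CHISQ": observed,
        }
    )
    idx_bp = positions[0]
    ld = pd.DataFrame(
        {
            "CHR_A": spec.chrom,
            "BP_A": idx_bp,
            "SNP_A": spec.index_snp,
            "CHR_B": spec.chrom,
            "BP_B": positions,
            "SNP_B": all_snps,
            "R2": all_r2,
        }
    )
    return sumstats, ld


def write_region(spec: RegionSpec, prefix: str) -> tuple[str, str]:
    """Generate a region and write ``<prefix>.sumstats.tsv`` and ``<prefix>.ld``."""
    from .io import write_ld, write_sumstats

    sumstats, ld = generate_region(spec)
    ss_path = f"{prefix}.sumstats.tsv"
    ld_path = f"{prefix}.ld"
    write_sumstats(sumstats, ss_path)
    write_ld(ld, ld_path)
    return ss_path, ld_path
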