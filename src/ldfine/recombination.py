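"""Haldane recombination dynamics for the two-site haplotype system.

Each generation a fraction ``c`` of gametes are recombinant, pulling every
haplotype frequency toward linkage equilibrium:

    P11(t) = P11(t-1) * (1 - c) + c * p * q

(and analogously for the other three haplotypes).  Marginal allele
frequencies are conserved, so D decays geometrically, D(t) = D(0)*(1-c)^t,
and r2(t) = r2(0) * (1-c)^(2t).

The iteration is carried out explicitly per generation; the closed form
serves as an independent oracle in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .twosite import HaplotypeFrequencies, ld_measures

__all__ = ["RecombinationParams", "recurse_haplotypes", "r2_trajectory"]


@dataclass(frozen=True)
class RecombinationParams:
    """Per-generation recombination fraction c in [0, 0.5] and generation count t >= 0."""

    c: float
    t: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.c <= 0.5:
            raise ValueError(f"recombination fraction c={self.c} outside [0, 0.5]")
        if self.t < 0 or int(self.t) != self.t:
            raise ValueError(f"generation count t={self.t} must be a nonnegative integer")


def recurse_haplotypes(
    haps0: HaplotypeFrequencies, params: RecombinationParams
) -> HaplotypeFrequencies:
    """Apply the per-generation recursion ``t`` times.

    Equilibrium targets use the (constant) marginal frequencies of the
    input, so p and q are conserved exactly.
    """
    p, q = haps0.p, haps0.q
    eq = np.array([p * q, p * (1.0 - q), (1.0 - p) * q, (1.0 - p) * (1.0 - q)])
    freqs = np.array(haps0.as_tuple(), dtype=float)
    keep = 1.0 - params.c
    for _ in range(params.t):
        freqs = freqs * keep + params.c * eq
    # guard against accumulated rounding drift in the simplex constraint
    freqs = np.clip(freqs, 0.0, 1.0)
    freqs /= freqs.sum()
    return HaplotypeFrequencies(*freqs)


def r2_trajectory(
    haps0: HaplotypeFrequencies, c: float, t_max: int
) -> list[float]:
    """r2 with the causal site at generations t = 0 .. t_max (inclusive).

    The sequence is non-increasing for c in (0, 0.5] since marginals are
    constant and |D| shrinks by (1-c) per generation.
    """
    RecombinationParams(c, t_max)  # validate once
    p, q = haps0.p, haps0.q
    eq = np.array([p * q, p * (1.0 - q), (1.0 - p) * q, (1.0 - p) * (1.0 - q)])
    freqs = np.array(haps0.as_tuple(), dtype=float)
    out = [ld_measures(haps0)[1]]
    denom = p * (1.0 - p) * q * (1.0 - q)
    for _ in range(t_max):
        freqs = freqs * (1.0 - c) + c * eq
        D = freqs[0] * freqs[3] - freqs[1] * freqs[2]
        out.append(min(D * D / denom, 1.0))
    return out
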