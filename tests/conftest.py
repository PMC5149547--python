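import numpy as np
import pytest

from ldfine import HaplotypeFrequencies, StudyDesign, TwoSiteModel


@pytest.fixture
def running_model() -> TwoSiteModel:
    """Penetrances used throughout the worked two-site example."""
    return TwoSiteModel(f11=0.05, f12=0.03, f22=0.01)


@pytest.fixture
def running_haps() -> HaplotypeFrequencies:
    """Haplotype frequencies with p=0.3, q=0.4, D=0.13."""
    return HaplotypeFrequencies(0.25, 0.05, 0.15, 0.55)


@pytest.fixture
def running_design() -> StudyDesign:
    return StudyDesign(nD=2000, nC=2000)


@pytest.fixture
def fig_haps() -> HaplotypeFrequencies:
    """Parental causal haplotype 0.28, parental non-causal 0.70, recombinants 0.01."""
    return HaplotypeFrequencies(0.28, 0.01, 0.01, 0.70)


def random_valid_system(rng: np.random.Generator):
    """One random valid (model, haplotypes, design) triple.

    p, q drawn in [0.01, 0.99], D uniform within its Lewontin bounds,
    penetrances in (0.001, 0.999), diploid arm sizes in [100, 50000].
    """
    p = rng.uniform(0.01, 0.99)
    q = rng.uniform(0.01, 0.99)
    lo = max(-p * q, -(1 - p) * (1 - q))
    hi = min(p * (1 - q), q * (1 - p))
    D = rng.uniform(lo, hi)
    haps = HaplotypeFrequencies.from_pq_d(p, q, D)
    model = TwoSiteModel(*rng.uniform(0.001, 0.999, size=3))
    design = StudyDesign(int(rng.integers(100, 50_001)), int(rng.integers(100, 50_001)))
    return model, haps, design
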