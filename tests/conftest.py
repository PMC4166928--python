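import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from mitoclock.io import SampleClass, SampleRecord, SiteAnnotation
from mitoclock.simulate import DemographicModel, simulate_genealogy


@pytest.fixture
def rng():
    return np.random.default_rng(20_250_901)


def make_panel(n_modern, n_ancient, max_age=40_000.0, sd_frac=0.025, n_archaic=0):
    """Deterministic heterochronous sample table for tests."""
    recs = [SampleRecord(f"m{i:03d}", 0.0, 0.0, SampleClass.modern)
            for i in range(n_modern)]
    if n_ancient:
        ages = np.linspace(2_500.0, max_age, n_ancient)
        for i, a in enumerate(ages):
            recs.append(SampleRecord(f"a{i:02d}", float(a), max(100.0, sd_frac * a),
                                     SampleClass.ancient_AMH))
    for i in range(n_archaic):
        a = 45_000.0 + 5_000.0 * i
        recs.append(SampleRecord(f"x{i}", a, 0.08 * a, SampleClass.archaic))
    return recs


@pytest.fixture
def small_panel():
    return make_panel(8, 4)


@pytest.fixture
def small_tree(small_panel):
    return simulate_genealogy(small_panel, DemographicModel(), seed=11)


def flat_annotation(n_sites, group="other"):
    return SiteAnnotation([group] * n_sites)
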