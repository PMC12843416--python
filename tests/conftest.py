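"""Shared fixtures: seeded phantoms and cohorts, generated once per session."""

import numpy as np
import pytest

import emphkit as ek
from emphkit.workflow import phantom_scan_record


@pytest.fixture(scope="session")
def phantom20():
    """One emphysematous phantom: 20% planted LAA, dark parenchyma."""
    spec = ek.PhantomSpec(
        target_laa_pct=20.0, parenchyma_mean_hu=-870.0, seed=3
    )
    return ek.generate_phantom(spec)


@pytest.fixture(scope="session")
def phantom_clean():
    """Emphysema-free phantom with a bright parenchyma (healthy analog)."""
    spec = ek.PhantomSpec(
        target_laa_pct=0.0,
        parenchyma_mean_hu=-800.0,
        parenchyma_sd_hu=30.0,
        seed=5,
    )
    return ek.generate_phantom(spec)


@pytest.fixture(scope="session")
def phantom20_resampled(phantom20):
    """The emphysematous phantom on the 1 mm analysis grid."""
    vol = ek.resample_isotropic(phantom20.volume, 1.0)
    mask = ek.resample_isotropic(phantom20.lung_mask, 1.0)
    return vol, mask


@pytest.fixture(scope="session")
def cohort40():
    """Mixed 40-phantom cohort at 25% prevalence."""
    return ek.generate_cohort(40, 0.25, seed=7)


@pytest.fixture(scope="session")
def cohort40_markers(cohort40):
    """Full-pipeline markers (1 mm grid) for every cohort scan."""
    return [ek.compute_markers(t.volume, t.lung_mask) for t in cohort40]


@pytest.fixture(scope="session")
def cohort120_records():
    """Scan records (embeddings + markers + truth labels) for the
    end-to-end modeling experiments."""
    cohort = ek.generate_cohort(120, 0.25, seed=42)
    return [phantom_scan_record(t) for t in cohort]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
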