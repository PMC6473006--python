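import dataclasses

import numpy as np
import pandas as pd
import pytest

from frontoboost.spectral import eeg_features
from frontoboost.symptoms import symptom_table
from frontoboost.synthetic import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_spec() -> CohortSpec:
    """A quick cohort: 8+9 subjects, 12 s of EEG, weak EEG effect."""
    return CohortSpec(n_mtbi=8, n_control=9, duration_s=12.0, seed=42)


@pytest.fixture(scope="session")
def informative_spec() -> CohortSpec:
    """Cohort with strongly class-informative EEG band powers."""
    return CohortSpec(
        n_mtbi=10, n_control=11, duration_s=12.0, eeg_class_effect=1.5,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec)


def cohort_tables(cohort, config=None):
    """(eeg DataFrame, symptom DataFrame, labels) for a subject list."""
    eeg = pd.DataFrame(
        {s.subject_id: eeg_features(s.recording) for s in cohort}
    ).T
    sym = symptom_table(cohort)
    return eeg, sym.drop(columns="label"), sym["label"].to_numpy()


@pytest.fixture(scope="session")
def small_tables(small_cohort):
    return cohort_tables(small_cohort)


@pytest.fixture(scope="session")
def informative_tables(informative_spec):
    return cohort_tables(generate_cohort(informative_spec))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def sinusoid_spec(freq_hz: float, amp_uV: float, band: str = "alpha",
                  duration_s: float = 12.0) -> CohortSpec:
    """A noise-free single-sinusoid spec for closed-form oracles."""
    from frontoboost.synthetic import BandProfile

    profile = {b: BandProfile(0.0) for b in
               ("delta", "theta", "alpha", "beta", "sigma", "gamma")}
    profile[band] = BandProfile(amp_uV, log10_sd=0.0)
    return dataclasses.replace(
        CohortSpec(),
        duration_s=duration_s,
        band_profile=profile,
        noise_sd_uV=0.0,
        oscillator="sinusoid",
        sinusoid_freqs={band: freq_hz},
        lr_jitter_log10=0.0,
    )
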