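import pandas as pd
import pytest

from metabosvd import QCParams, SimulationConfig, qc_pipeline, simulate_study


@pytest.fixture(scope="session")
def demo_config() -> SimulationConfig:
    """A small two-cohort study with a few planted effects and QC violations."""
    em = pd.DataFrame(
        0.0,
        index=[f"met{i:04d}" for i in range(1, 41)],
        columns=["mdnph", "wmh_percent", "lacune_presence", "dementia"],
    )
    em.loc["met0001", "mdnph"] = 0.35
    em.loc["met0002", "wmh_percent"] = 0.30
    em.loc["met0003", "lacune_presence"] = 0.5
    em.loc["met0004", "dementia"] = 0.5
    return SimulationConfig(
        n_subjects_per_cohort=(60, 140),
        n_features=40,
        n_batches=2,
        qc_interval=10,
        drift_amplitude=0.12,
        tech_cv=0.08,
        bio_cv=0.6,
        frac_fail_rsd=0.1,
        frac_fail_dilution=0.1,
        effect_matrix=em,
        dementia_base_hazard=0.03,
        seed=42,
    )


@pytest.fixture(scope="session")
def demo_study(demo_config) -> dict:
    return simulate_study(demo_config)


@pytest.fixture(scope="session")
def demo_qc(demo_study) -> dict:
    return qc_pipeline(demo_study["intensities"], demo_study["manifest"],
                       QCParams())
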