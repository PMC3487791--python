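import pytest

from gistvol.cohort import LesionMeasurement, Method
from gistvol.pipeline import cohort_from_tables
from gistvol.simulate import SimulationConfig, simulate_cohort


def make_measurement(
    patient_id="P1",
    lesion_id="L1",
    timepoint_months=0,
    method=Method.SEMIAUTO,
    reader_id="S1",
    longest_diameter_mm=40.0,
    volume_mL=20.0,
    mean_density_HU=None,
    axes_mm=None,
):
    return LesionMeasurement(
        patient_id=patient_id,
        lesion_id=lesion_id,
        timepoint_months=timepoint_months,
        method=method,
        reader_id=reader_id,
        longest_diameter_mm=longest_diameter_mm,
        volume_mL=volume_mL,
        mean_density_HU=mean_density_HU,
        axes_mm=axes_mm,
    )


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_patients=40, seed=11)


@pytest.fixture(scope="session")
def small_tables(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_cohort(small_tables):
    return cohort_from_tables(small_tables)
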