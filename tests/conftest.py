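import numpy as np
import pytest

import sirtdose as sd
from sirtdose.quantify import VOIMeasurement


@pytest.fixture(scope="session")
def fixed_measurements() -> sd.PartitionMeasurements:
    """Reference measurement set: liver counts 800/150/50, tumor 500 mL,
    out-target 300 mL, LSF 0.05, population lung volume (3.3 L)."""
    return sd.PartitionMeasurements(
        tumor=VOIMeasurement.from_totals(500.0, 800.0),
        in_target=VOIMeasurement.from_totals(700.0, 150.0),
        out_target=VOIMeasurement.from_totals(300.0, 50.0),
        lung_total_counts=50.0,
        lsf=0.05,
        lung_volume_ml=3300.0,
    )


@pytest.fixture(scope="session")
def default_spec() -> sd.PhantomSpec:
    return sd.default_phantom_spec(lsf_true=0.06)


@pytest.fixture(scope="session")
def maa_truth(default_spec) -> sd.ActivityVolume:
    return sd.build_phantom(default_spec, "maa")


def random_measurements(rng: np.random.Generator) -> sd.PartitionMeasurements:
    """Random but valid measurement set for property tests."""
    volumes = rng.uniform(50.0, 1500.0, size=3)
    counts = rng.uniform(1.0, 2000.0, size=3)
    return sd.PartitionMeasurements(
        tumor=VOIMeasurement.from_totals(volumes[0], counts[0]),
        in_target=VOIMeasurement.from_totals(volumes[1], counts[1]),
        out_target=VOIMeasurement.from_totals(volumes[2], counts[2]),
        lung_total_counts=float(rng.uniform(0.0, 200.0)),
        lsf=float(rng.uniform(0.0, 0.19)),
        lung_volume_ml=float(rng.uniform(2000.0, 5000.0)),
    )
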