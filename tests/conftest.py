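import numpy as np
import pytest

from timsccs import (
    CompoundRecord,
    MobilityPhysicsContext,
    ReferenceCalibrantTable,
    SimulatedCompound,
    SimulatedSpecies,
    SimulationSpec,
)


@pytest.fixture(scope="session")
def ctx() -> MobilityPhysicsContext:
    return MobilityPhysicsContext()


@pytest.fixture(scope="session")
def rutin() -> CompoundRecord:
    return CompoundRecord(
        name="Rutin",
        molecular_formula="C27H30O16",
        compound_class="flavonol glycoside",
        retention_time=11.2,
    )


@pytest.fixture(scope="session")
def tune_mix_table() -> ReferenceCalibrantTable:
    """Synthetic tune-mix reference table at the classic calibrant m/z."""
    return ReferenceCalibrantTable(
        table_id="consensus_2017",
        rows=((301.998139, -1, 140.0), (601.978977, -1, 180.0), (1033.988109, -1, 250.0)),
    )


@pytest.fixture()
def rutin_spec(rutin) -> SimulationSpec:
    """Single-compound, noiseless [M-H]- run at the library CCS of rutin."""
    return SimulationSpec(
        compounds=(
            SimulatedCompound(rutin, (SimulatedSpecies("[M-H]-", 231.05),)),
        ),
    )


def gaussian_trace(axis: np.ndarray, center: float, sigma: float, height: float) -> np.ndarray:
    return height * np.exp(-0.5 * ((axis - center) / sigma) ** 2)
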