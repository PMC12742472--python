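from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from karstclpp import (
    CultivationCondition,
    Phase,
    PlateSeries,
    default_layout,
    standard_conditions,
)

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[
        HealthCheck.too_slow,
        # profile factories below are pure; reuse across examples is safe
        HealthCheck.function_scoped_fixture,
    ],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def layout():
    return default_layout()


@pytest.fixture(scope="session")
def aerobic_20c():
    return standard_conditions()["20C_aerobic"]


def build_series(
    layout,
    condition,
    responses_by_time: dict[float, dict[str, float]],
    control_level: float = 0.10,
    turbidity: float = 0.05,
    blocks=(0,),
    sample_id: str = "T1",
    block_offsets: dict[int, float] | None = None,
) -> PlateSeries:
    """Plate series whose blank- and turbidity-corrected responses equal the
    given per-position values exactly.

    OD590 = turbidity + control_level + response (+ per-block offset folded
    into the control level); OD750 = turbidity.
    """
    from karstclpp.model import logical_to_physical

    block_offsets = block_offsets or {}
    records = []
    for t, responses in responses_by_time.items():
        for b in blocks:
            level = control_level + block_offsets.get(b, 0.0)
            for pos in [layout.control_position] + layout.substrate_positions:
                well = logical_to_physical(b, pos)
                r = 0.0 if pos == layout.control_position else responses.get(pos, 0.0)
                records.append((well, 590, t, turbidity + level + r))
                records.append((well, 750, t, turbidity))
    data = pd.DataFrame(records, columns=["well", "wavelength_nm", "time_h", "od"])
    return PlateSeries(sample_id=sample_id, condition=condition,
                       layout=layout, data=data)


@pytest.fixture()
def uniform_profile(layout, aerobic_20c):
    """Factory for profiles with chosen responses over the 31 substrates."""
    import karstclpp as k

    def make(values) -> "k.SubstrateProfile":
        vals = np.asarray(values, dtype=float)
        if vals.ndim == 0:
            vals = np.full(31, float(vals))
        return k.SubstrateProfile(
            sample_id="P", condition=aerobic_20c, time_h=0.0,
            responses=pd.Series(vals, index=layout.substrate_positions),
            layout=layout,
        )

    return make
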