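import numpy as np
import pytest

from pidher2 import SimParams
from pidher2.io import CoreImage, CoreRecord, InvasiveMask


@pytest.fixture
def small_params():
    """Fast generator settings: 100-um cores, everything else at defaults."""
    return SimParams(core_diameter_um=100.0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_records(values_by_class, start=0):
    """CoreRecords with pid_value/dab_consensus laid out on the TMA grid."""
    records = []
    i = start
    for cls, values in values_by_class.items():
        for v in values:
            row, col = divmod(i, 16)
            records.append(
                CoreRecord(
                    core_id=f"{chr(ord('A') + row)}{col + 1}",
                    case_id=i // 2 + 1,
                    dab_consensus=cls,
                    pid_value=float(v),
                )
            )
            i += 1
    return records


def uniform_core(value, n=24, pixel_size_um=1.0, core_id="A1"):
    """Constant-intensity image with an all-true mask."""
    img = CoreImage(np.full((n, n), float(value)), pixel_size_um=pixel_size_um, core_id=core_id)
    msk = InvasiveMask(np.ones((n, n), dtype=bool), core_id=core_id)
    return img, msk
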