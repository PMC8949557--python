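import numpy as np
import pytest

from eatdry.controller import EventRecord, _dry_path_volumes, _mr_after_path
from eatdry.eat import DryerGeometry
from eatdry.kinetics import ParamMapConfig, ThinLayerParams


@pytest.fixture
def geom() -> DryerGeometry:
    return DryerGeometry()


@pytest.fixture
def ctrl_map() -> ParamMapConfig:
    return ParamMapConfig()


def make_records_from_model(
    geom: DryerGeometry,
    truth: ThinLayerParams,
    n_events: int,
    period_min: float,
    M0_db: float,
    Me_db: float = 5.0,
) -> list[EventRecord]:
    """Synthetic discharge observations generated by the controller's own
    path model under ground-truth constants: the fit oracle for the GA
    model-correction tests (single uniform air temperature, so one k)."""
    records = []
    for j in range(1, n_events + 1):
        v = min(j * geom.Vp, geom.total_volume)
        vols = np.array(_dry_path_volumes(geom, v)) / geom.Vp
        durations = (vols * period_min / 60.0)[None, :]
        mr = float(_mr_after_path((truth,) * 3, durations)[0])
        m_db = Me_db + (M0_db - Me_db) * mr
        m_wb = 100.0 * m_db / (100.0 + m_db)
        records.append(EventRecord(event=j, clock_min=j * period_min,
                                   m_out_wb=m_wb, m_out_db=m_db,
                                   period_min=period_min, u_k=0.0))
    return records
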