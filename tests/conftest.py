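from datetime import timedelta

import numpy as np
import pytest

from prefwatch import rfid, synthetic


@pytest.fixture
def layout():
    return rfid.AntennaLayout()


def make_occupancy(layout, segments):
    """Build an Occupancy from (cage_code, duration_h) segments.

    Segments must tile the run window; the last one is stretched to the
    run end if the listed durations fall short.
    """
    cages, starts, ends = [], [], []
    t = 0.0
    for cage, dur in segments:
        cages.append(cage)
        starts.append(t)
        t += dur
        ends.append(t)
    if ends[-1] < layout.span_hours:
        ends[-1] = layout.span_hours
    occ = rfid.Occupancy(
        cages=np.array(cages, dtype=int),
        start_h=np.array(starts),
        end_h=np.array(ends),
        layout=layout,
    )
    occ.validate()
    return occ


@pytest.fixture
def occupancy_factory(layout):
    def _make(segments):
        return make_occupancy(layout, segments)

    return _make


@pytest.fixture
def read_factory(layout):
    """Reads at given (hours_from_start, tube, side) triples."""

    def _make(spec):
        return [
            rfid.AntennaRead(
                timestamp=layout.start + timedelta(hours=h),
                antenna_id=layout.antenna_for(tube, side),
            )
            for h, tube, side in spec
        ]

    return _make


@pytest.fixture(scope="session")
def pop_model():
    return synthetic.default_population_model(seed=0)


@pytest.fixture(scope="session")
def cohort(pop_model):
    return synthetic.simulate_cohort(pop_model, synthetic.PedigreeSpec(), seed=11)
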