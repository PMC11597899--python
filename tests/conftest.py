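from datetime import datetime, timedelta

import pytest
from hypothesis import HealthCheck, settings
from hypothesis import strategies as st

from luxsense import CCMRecord, ChildLog, Color, Illumination, Mode, SCMRecord, Valence

settings.register_profile(
    "luxsense",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("luxsense")


SAMPLE_CCM_CSV = """date_time,color,illumination,duration_s
2024-07-23 14:35:10,B,HI,60
2024-07-23 14:36:50,R,LI,40
2024-07-23 14:38:15,G,LI,30
"""

SAMPLE_SCM_CSV = """date_time,color,illumination,response
2024-07-23 14:35:10,B,HI,P
2024-07-23 14:36:50,R,LI,N
2024-07-23 14:38:15,G,LI,N
"""


@pytest.fixture
def sample_ccm_csv() -> str:
    return SAMPLE_CCM_CSV


@pytest.fixture
def sample_scm_csv() -> str:
    return SAMPLE_SCM_CSV


@pytest.fixture
def sample_ccm_log(sample_ccm_csv):
    from luxsense import parse_log

    return parse_log(sample_ccm_csv, Mode.CCM)


@pytest.fixture
def sample_scm_log(sample_scm_csv):
    from luxsense import parse_log

    return parse_log(sample_scm_csv, Mode.SCM)


# --- hypothesis strategies for random logs ---------------------------------

colors = st.sampled_from(list(Color))
illuminations = st.sampled_from(list(Illumination))
valences = st.sampled_from(list(Valence))


@st.composite
def sessions(draw, mode: Mode, min_records: int = 1, max_records: int = 12):
    """One session of chronologically non-decreasing records."""
    n = draw(st.integers(min_records, max_records))
    gaps = draw(st.lists(st.integers(0, 120), min_size=n, max_size=n))
    t = datetime(2024, 7, 23, 10, 0, 0)
    records = []
    for gap in gaps:
        t = t + timedelta(seconds=gap)
        color = draw(colors)
        illum = draw(illuminations)
        if mode is Mode.CCM:
            records.append(CCMRecord(t, color, illum, draw(st.integers(0, 300))))
        else:
            records.append(SCMRecord(t, color, illum, draw(valences)))
    return tuple(records)


@st.composite
def child_logs(draw, mode: Mode | None = None, max_sessions: int = 3):
    mode = mode or draw(st.sampled_from(list(Mode)))
    k = draw(st.integers(1, max_sessions))
    sess = tuple(draw(sessions(mode)) for _ in range(k))
    return ChildLog(child_id="", mode=mode, sessions=sess)
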