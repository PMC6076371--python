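import numpy as np
import pandas as pd
import pytest

from keymood.simulate import SimulationConfig

UTC = "UTC"


def make_events(records, tz_offset_min=0):
    """Build an event frame from (subject, iso_time_or_epoch_s, event_class)."""
    subj, ts, cls = zip(*records)
    stamps = pd.to_datetime(
        [t if isinstance(t, str) else pd.Timestamp(t, unit="s", tz=UTC) for t in ts],
        utc=True,
    )
    return pd.DataFrame(
        {
            "subject_id": list(subj),
            "timestamp": stamps,
            "tz_offset_min": np.int64(tz_offset_min),
            "event_class": list(cls),
        }
    )


def make_accel(records, tz_offset_min=0):
    """Build an accel frame from (subject, epoch_s, x, y, z)."""
    subj, ts, x, y, z = zip(*records)
    return pd.DataFrame(
        {
            "subject_id": list(subj),
            "timestamp": pd.to_datetime(np.asarray(ts, dtype=float) * 1e9, utc=True),
            "tz_offset_min": np.int64(tz_offset_min),
            "x": list(x),
            "y": list(y),
            "z": list(z),
        }
    )


def make_assessments(records, tz_offset_min=0):
    """Build an assessment frame from (subject, iso_or_epoch_s, scale, score)."""
    subj, ts, scale, score = zip(*records)
    stamps = pd.to_datetime(
        [t if isinstance(t, str) else pd.Timestamp(t, unit="s", tz=UTC) for t in ts],
        utc=True,
    )
    return pd.DataFrame(
        {
            "subject_id": list(subj),
            "assessed_at": stamps,
            "tz_offset_min": np.int64(tz_offset_min),
            "scale": list(scale),
            "score": np.asarray(score, dtype="int64"),
        }
    )


@pytest.fixture
def light_config():
    """Small, fast cohort: full structure, reduced stream volume."""
    return SimulationConfig(
        seed=11,
        sessions_per_day_mean=4.0,
        keypresses_per_session_mean=8.0,
        accel_sample_rate=2.0,
    )
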