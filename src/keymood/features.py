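"""Session segmentation and weekly typing-feature extraction.

The unit of typing activity is the *session*: a maximal run of keypresses in
which every consecutive gap is strictly less than the gap threshold
(default 5 s). A gap greater than or equal to the threshold ends the session
and the next keypress starts a new one; a lone keypress is a session of
length 0.

Seven predictors are computed for the week preceding each mood assessment,
over the half-open window (assessed_at - 7 days, assessed_at]:

- ``avg_interkey_delay_s`` — mean gap between consecutive within-session
  keypresses, pooled across sessions (gaps >= threshold never contribute);
- ``backspace_ratio`` — backspace keypresses / total keypresses;
- ``autocorrect_rate`` — autocorrect events / total keypresses (autocorrect
  events are software events, excluded from the denominator);
- ``circadian_similarity`` — cosine of the angle between the week's
  24-dimensional hourly keypress-count vector and the subject's whole-study
  hourly vector (all weeks pooled, current week included);
- ``avg_accel_displacement`` — mean Euclidean magnitude of accelerometer
  samples in the window (m/s^2);
- ``avg_session_length_s`` — mean of (last - first keypress time) per session;
- ``session_count`` — number of sessions starting in the window.

Features that need at least one keypress (or, for the interkey delay, one
within-session pair) are NaN when the window cannot supply them.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ContractError
from .types import EventClass

logger = logging.getLogger(__name__)

#: Default sessionization gap threshold, seconds.
GAP_THRESHOLD_S = 5.0

#: Canonical predictor column order (matches the reporting tables).
PREDICTORS = [
    "avg_accel_displacement",
    "avg_interkey_delay_s",
    "backspace_ratio",
    "autocorrect_rate",
    "avg_session_length_s",
    "session_count",
    "circadian_similarity",
]

_KEYPRESS_VALUES = (
    EventClass.REGULAR.value,
    EventClass.SPACE.value,
    EventClass.BACKSPACE.value,
)


def _ts_seconds(ts: pd.Series) -> np.ndarray:
    """tz-aware datetime series -> float seconds since the Unix epoch."""
    return ts.astype("int64").to_numpy() / 1e9


def _group_indices(subject_ids: pd.Series):
    """Yield (subject, indexer) preserving within-subject order.

    The indexer is a plain slice when records are already subject-contiguous
    (cheap views downstream), an integer array otherwise.
    """
    codes, uniques = pd.factorize(subject_ids, sort=True)
    uniques = np.asarray(uniques)
    if len(codes) == 0:
        return
    diffs = np.diff(codes)
    if np.all(diffs >= 0):  # already grouped and ordered
        bounds = np.flatnonzero(diffs) + 1
        starts = np.concatenate(([0], bounds))
        ends = np.concatenate((bounds, [len(codes)]))
        for s, e in zip(starts, ends):
            yield uniques[codes[s]], slice(s, e)
        return
    order = np.argsort(codes, kind="stable")
    sorted_codes = codes[order]
    bounds = np.flatnonzero(np.diff(sorted_codes)) + 1
    starts = np.concatenate(([0], bounds))
    ends = np.concatenate((bounds, [len(codes)]))
    for s, e in zip(starts, ends):
        yield uniques[sorted_codes[s]], order[s:e]


def _session_bounds(times_s: np.ndarray, gap_threshold_s: float) -> np.ndarray:
    """Indices splitting a sorted keypress time array into sessions.

    Returns ``starts`` such that session j spans ``times_s[starts[j]:starts[j+1]]``
    (with an implicit final boundary at ``len(times_s)``). The boundary rule is
    >=: a gap of exactly the threshold splits.
    """
    if len(times_s) == 0:
        return np.array([], dtype=np.intp)
    gaps = np.diff(times_s)
    if (gaps < 0).any():
        raise ContractError("keypress times must be sorted non-decreasingly")
    return np.concatenate(([0], np.flatnonzero(gaps >= gap_threshold_s) + 1))


def segment_sessions(
    events: pd.DataFrame, gap_threshold_s: float = GAP_THRESHOLD_S
) -> pd.DataFrame:
    """Segment keypress events into sessions.

    Parameters
    ----------
    events
        Event frame (schema of :func:`keymood.io.read_event_log`), sorted by
        (subject_id, timestamp). AUTOCORRECT events are ignored; they neither
        start nor extend sessions.
    gap_threshold_s
        Gap at or above which a session ends.

    Returns
    -------
    DataFrame with columns subject_id, start, end, keypress_count, length_s,
    one row per session, in (subject, time) order.
    """
    kp = events[events["event_class"].isin(_KEYPRESS_VALUES)]
    rows = []
    for subject, grp in kp.groupby("subject_id", sort=True, observed=True):
        t = _ts_seconds(grp["timestamp"])
        starts = _session_bounds(t, gap_threshold_s)
        if len(starts) == 0:
            continue
        ends = np.concatenate((starts[1:], [len(t)]))
        first = t[starts]
        last = t[ends - 1]
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": subject,
                    "start": pd.to_datetime((first * 1e9).round().astype("int64"), utc=True),
                    "end": pd.to_datetime((last * 1e9).round().astype("int64"), utc=True),
                    "keypress_count": ends - starts,
                    "length_s": last - first,
                }
            )
        )
    if not rows:
        return pd.DataFrame(
            {
                "subject_id": pd.Series(dtype=str),
                "start": pd.Series(dtype="datetime64[ns, UTC]"),
                "end": pd.Series(dtype="datetime64[ns, UTC]"),
                "keypress_count": pd.Series(dtype="int64"),
                "length_s": pd.Series(dtype=float),
            }
        )
    return pd.concat(rows, ignore_index=True)


def average_interkey_delay(
    keypress_times_s: np.ndarray, gap_threshold_s: float = GAP_THRESHOLD_S
) -> float:
    """Mean delay between consecutive within-session keypresses, seconds.

    Pools every consecutive keypress pair whose gap is below the session
    threshold, across all sessions; NaN when no such pair exists (e.g. only
    single-keypress sessions).
    """
    t = np.asarray(keypress_times_s, dtype=float)
    if len(t) < 2:
        return float("nan")
    gaps = np.diff(t)
    if (gaps < 0).any():
        raise ContractError("keypress times must be sorted non-decreasingly")
    within = gaps[gaps < gap_threshold_s]
    return float(within.mean()) if len(within) else float("nan")


def keypress_ratios(event_classes: np.ndarray) -> tuple[float, float]:
    """(backspace_ratio, autocorrect_rate) for the window's events.

    Both denominators are the keypress count (REGULAR + SPACE + BACKSPACE);
    autocorrect events count only in the autocorrect numerator. Both NaN when
    the window has no keypresses.
    """
    cls = np.asarray(event_classes)
    n_kp = int(np.isin(cls, _KEYPRESS_VALUES).sum())
    if n_kp == 0:
        return float("nan"), float("nan")
    n_bs = int((cls == EventClass.BACKSPACE.value).sum())
    n_ac = int((cls == EventClass.AUTOCORRECT.value).sum())
    rate = n_ac / n_kp
    if rate > 1:
        logger.warning("autocorrect events outnumber keypresses in a window (rate=%.3f)", rate)
    return n_bs / n_kp, rate


def average_accel_displacement(x, y, z) -> float:
    """Mean Euclidean magnitude of (x, y, z) samples; NaN for empty input."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return float("nan")
    mags = np.sqrt(x**2 + np.asarray(y, dtype=float) ** 2 + np.asarray(z, dtype=float) ** 2)
    return float(mags.mean())


def hourly_profile(times_s: np.ndarray, tz_offset_min: np.ndarray) -> np.ndarray:
    """24-vector of keypress counts binned by subject-local clock hour."""
    t = np.asarray(times_s, dtype=float)
    off = np.asarray(tz_offset_min, dtype=float)
    hours = (np.floor((t + off * 60.0) / 3600.0) % 24).astype(np.intp)
    return np.bincount(hours, minlength=24).astype(np.int64)


def circadian_similarity(week: np.ndarray, baseline: np.ndarray) -> float:
    """Cosine similarity between two 24-hour activity profiles.

    In [0, 1] for nonnegative profiles; 1 iff proportional; NaN when either
    profile is all-zero. Scale-invariant in both arguments.
    """
    w = np.asarray(week, dtype=float)
    b = np.asarray(baseline, dtype=float)
    if w.shape != (24,) or b.shape != (24,):
        raise ContractError("hourly profiles must be 24-dimensional")
    nw = np.linalg.norm(w)
    nb = np.linalg.norm(b)
    if nw == 0.0 or nb == 0.0:
        return float("nan")
    return float(np.clip(np.dot(w, b) / (nw * nb), -1.0, 1.0))


def build_feature_table(
    events: pd.DataFrame,
    accel: pd.DataFrame,
    assessments: pd.DataFrame,
    gap_threshold_s: float = GAP_THRESHOLD_S,
) -> pd.DataFrame:
    """One feature row per (subject, assessment).

    The aggregation window for an assessment at time ``t`` is the half-open
    interval ``(t - 7 days, t]``. Rows whose window holds no keypresses keep
    ``session_count = 0`` and NaN for the keypress-derived features; an
    assessment for a subject with no stream at all is kept (all features
    missing) and logged.
    """
    # pre-split streams per subject into sorted numpy arrays (factorize +
    # stable argsort instead of DataFrame groupby: the streams are large)
    ev_by_subject: dict[str, dict[str, np.ndarray]] = {}
    if len(events):
        t_all = _ts_seconds(events["timestamp"])
        cls = events["event_class"]
        kp_all = cls.isin(_KEYPRESS_VALUES).to_numpy()
        bs_all = (cls == EventClass.BACKSPACE.value).to_numpy()
        ac_all = (cls == EventClass.AUTOCORRECT.value).to_numpy()
        off_all = events["tz_offset_min"].to_numpy()
        for subject, idx in _group_indices(events["subject_id"]):
            t = t_all[idx]
            if np.any(np.diff(t) < 0):
                raise ContractError(f"events for subject {subject} are not time-sorted")
            kp_mask = kp_all[idx]
            kp_t = t[kp_mask]
            kp_off = off_all[idx][kp_mask]
            ev_by_subject[subject] = {
                "t": t,
                "kp": kp_mask,
                "bs": bs_all[idx],
                "ac": ac_all[idx],
                "kp_t": kp_t,
                "kp_off": kp_off,
                "baseline": hourly_profile(kp_t, kp_off),
            }
    ac_by_subject: dict[str, dict[str, np.ndarray]] = {}
    if len(accel):
        at_all = _ts_seconds(accel["timestamp"])
        mag_all = np.sqrt(
            accel["x"].to_numpy() ** 2
            + accel["y"].to_numpy() ** 2
            + accel["z"].to_numpy() ** 2
        )
        for subject, idx in _group_indices(accel["subject_id"]):
            ac_by_subject[subject] = {"t": at_all[idx], "mag": mag_all[idx]}

    week_s = 7 * 86400.0
    rows = []
    for rec in assessments.itertuples(index=False):
        t_end = rec.assessed_at.value / 1e9
        t_start = t_end - week_s
        ev = ev_by_subject.get(rec.subject_id)
        if ev is None:
            logger.warning(
                "assessment for subject %s has no event stream at all", rec.subject_id
            )
        row = {
            "subject_id": rec.subject_id,
            "scale": rec.scale,
            "assessed_at": rec.assessed_at,
            "score": rec.score,
            "window_start": rec.assessed_at - pd.Timedelta(days=7),
            "window_end": rec.assessed_at,
            **{p: float("nan") for p in PREDICTORS},
            "keypress_count": 0,
            "session_count": 0,
        }
        if ev is not None:
            lo = np.searchsorted(ev["t"], t_start, side="right")
            hi = np.searchsorted(ev["t"], t_end, side="right")
            klo = np.searchsorted(ev["kp_t"], t_start, side="right")
            khi = np.searchsorted(ev["kp_t"], t_end, side="right")
            kp_t = ev["kp_t"][klo:khi]
            row["keypress_count"] = len(kp_t)
            if len(kp_t):
                starts = _session_bounds(kp_t, gap_threshold_s)
                ends = np.concatenate((starts[1:], [len(kp_t)]))
                lengths = kp_t[ends - 1] - kp_t[starts]
                row["session_count"] = len(starts)
                row["avg_session_length_s"] = float(lengths.mean())
                row["avg_interkey_delay_s"] = average_interkey_delay(kp_t, gap_threshold_s)
                n_kp = len(kp_t)
                ac_rate = float(ev["ac"][lo:hi].sum()) / n_kp
                if ac_rate > 1:
                    logger.warning(
                        "autocorrect events outnumber keypresses for subject %s "
                        "in week ending %s (rate=%.3f)",
                        rec.subject_id, rec.assessed_at, ac_rate,
                    )
                row["backspace_ratio"] = float(ev["bs"][lo:hi].sum()) / n_kp
                row["autocorrect_rate"] = ac_rate
                week_prof = hourly_profile(kp_t, ev["kp_off"][klo:khi])
                row["circadian_similarity"] = circadian_similarity(
                    week_prof, ev["baseline"]
                )
        ac = ac_by_subject.get(rec.subject_id)
        if ac is not None:
            alo = np.searchsorted(ac["t"], t_start, side="right")
            ahi = np.searchsorted(ac["t"], t_end, side="right")
            if ahi > alo:
                row["avg_accel_displacement"] = float(ac["mag"][alo:ahi].mean())
        rows.append(row)

    columns = [
        "subject_id", "scale", "assessed_at", "score", "window_start", "window_end",
        "keypress_count",
        *dict.fromkeys(["session_count", *PREDICTORS]),  # session_count is also a predictor
    ]
    out = pd.DataFrame(rows, columns=columns)
    out["keypress_count"] = out["keypress_count"].astype("int64")
    # session_count is one of the seven predictors; keep it numeric but treat
    # it as integer-valued
    out["session_count"] = out["session_count"].astype("int64")
    return out
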