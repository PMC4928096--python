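"""Reading, writing and conditioning of heartbeat event series.

Covers the raw observables of the framework: R-wave event times (or the
derived R-R intervals), single-lead ECG traces from which R peaks are
detected, and the stimulus-annotation tables that localize haptic stimuli in
time.  Internal unit is seconds everywhere; milliseconds appear only at I/O
boundaries.  The time origin is the first sample / first event and the
observation interval is (0, T].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats as sstats

log = logging.getLogger(__name__)

__all__ = [
    "EventSeries",
    "EcgTrace",
    "StimulusAnnotation",
    "ArtifactConfig",
    "read_event_series",
    "write_event_series",
    "detect_r_peaks",
    "correct_artifacts",
    "read_stimulus_annotations",
    "write_stimulus_annotations",
]

QUALITY_OK = "ok"
QUALITY_CORRECTED = "corrected"
QUALITY_INSERTED = "inserted"
QUALITY_DELETED = "deleted"


@dataclass(frozen=True)
class EventSeries:
    """R-wave event times with derived R-R intervals and quality flags.

    Attributes
    ----------
    event_times : ndarray
        Seconds from recording start, strictly increasing.
    quality_flags : tuple of str
        Per-beat label in {ok, corrected, inserted, deleted}.
    t_start, t_end : float
        Observation interval (t_start, t_end]; t_end >= last event time.
    """

    event_times: np.ndarray
    quality_flags: tuple = ()
    t_start: float = 0.0
    t_end: float | None = None

    def __post_init__(self) -> None:
        u = np.asarray(self.event_times, dtype=float)
        object.__setattr__(self, "event_times", u)
        u.setflags(write=False)
        if u.size and not np.all(np.isfinite(u)):
            raise ValueError("event times must be finite")
        if u.size > 1:
            d = np.diff(u)
            bad = np.flatnonzero(d <= 0)
            if bad.size:
                raise ValueError(
                    f"event times not strictly increasing at index {bad[0] + 1}")
        flags = self.quality_flags
        if not flags:
            flags = tuple(QUALITY_OK for _ in range(u.size))
        elif len(flags) != u.size:
            raise ValueError("quality_flags length must match event count")
        object.__setattr__(self, "quality_flags", tuple(flags))
        t_end = self.t_end
        if t_end is None:
            t_end = float(u[-1]) if u.size else 0.0
        if u.size and t_end < u[-1] - 1e-12:
            raise ValueError("t_end must be at least the last event time")
        object.__setattr__(self, "t_end", float(t_end))

    @property
    def rr_intervals(self) -> np.ndarray:
        """Successive differences of the event times, in seconds."""
        return np.diff(self.event_times)

    @property
    def n_beats(self) -> int:
        return int(self.event_times.size)

    @classmethod
    def from_rr_intervals(cls, rr: np.ndarray, t_start: float = 0.0,
                          t_end: float | None = None) -> "EventSeries":
        rr = np.asarray(rr, dtype=float)
        bad = np.flatnonzero(~(rr > 0))
        if bad.size:
            raise ValueError(f"non-positive R-R interval at index {bad[0]}")
        u = np.concatenate([[t_start], t_start + np.cumsum(rr)])
        return cls(event_times=u, t_start=t_start, t_end=t_end)

    def shifted(self, offset: float) -> "EventSeries":
        return EventSeries(event_times=self.event_times + offset,
                           quality_flags=self.quality_flags,
                           t_start=self.t_start + offset,
                           t_end=self.t_end + offset)


@dataclass(frozen=True)
class EcgTrace:
    """Raw single-lead ECG trace (amplitude in arbitrary units)."""

    samples: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        x = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", x)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if x.size and not np.all(np.isfinite(x)):
            raise ValueError("ECG samples must be finite")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate


@dataclass(frozen=True)
class StimulusAnnotation:
    """A single haptic stimulus window with its force/velocity levels."""

    onset: float
    offset: float
    force_level: float
    velocity_level: float
    subject_id: str = "s0"
    rest_windows: tuple = ()

    def __post_init__(self) -> None:
        if not self.onset < self.offset:
            raise ValueError(
                f"annotation onset ({self.onset}) must precede offset "
                f"({self.offset})")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


# ---------------------------------------------------------------------------
# plain-text event-series I/O

_DIALECTS = ("rr_seconds", "rr_milliseconds", "time_rr_columns", "beat_times")


def _sniff_dialect(rows: list[list[float]]) -> str:
    if rows and len(rows[0]) >= 2:
        return "time_rr_columns"
    vals = np.array([r[0] for r in rows]) if rows else np.array([])
    if vals.size >= 2 and np.all(np.diff(vals) > 0) and vals[-1] > 10 * np.median(np.diff(vals)):
        return "beat_times"
    if vals.size and np.median(vals) > 10.0:
        return "rr_milliseconds"
    return "rr_seconds"


def read_event_series(path, dialect: str | None = None) -> EventSeries:
    """Read an event series from a plain-text file.

    Supported dialects: ``rr_seconds`` / ``rr_milliseconds`` (one interval per
    line), ``time_rr_columns`` (event time and interval columns), and
    ``beat_times`` (one event time per line, seconds).  A ``# dialect:`` header
    line or the file structure is used when ``dialect`` is not given.
    """
    rows: list[list[float]] = []
    header_dialect = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s:
                continue
            if s.startswith("#"):
                if "dialect:" in s:
                    header_dialect = s.split("dialect:")[1].strip()
                continue
            try:
                rows.append([float(tok) for tok in s.replace(",", " ").split()])
            except ValueError as exc:
                raise ValueError(f"{path}: cannot parse line {lineno}: {s!r}") from exc
    dialect = dialect or header_dialect or _sniff_dialect(rows)
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    if dialect == "beat_times":
        u = np.array([r[0] for r in rows])
        d = np.diff(u)
        bad = np.flatnonzero(d <= 0)
        if bad.size:
            raise ValueError(
                f"{path}: non-monotone event time at line {bad[0] + 2}")
        return EventSeries(event_times=u)
    if dialect == "time_rr_columns":
        u = np.array([r[0] for r in rows])
        rr = np.array([r[1] for r in rows])
        if rr.size and np.median(rr) > 10.0:
            rr = rr / 1000.0
        bad = np.flatnonzero(np.diff(u) <= 0)
        if bad.size:
            raise ValueError(
                f"{path}: non-monotone event time at line {bad[0] + 2}")
        # each row is (event time, preceding interval): the first listed
        # interval implies an opening event at u[0] - rr[0]
        if u.size:
            u = np.concatenate([[u[0] - rr[0]], u])
        return EventSeries(event_times=u)
    scale = 1e-3 if dialect == "rr_milliseconds" else 1.0
    rr = scale * np.array([r[0] for r in rows])
    bad = np.flatnonzero(~(rr > 0))
    if bad.size:
        raise ValueError(f"{path}: non-positive interval at line {bad[0] + 1}")
    return EventSeries.from_rr_intervals(rr)


def write_event_series(path, events: EventSeries, dialect: str = "beat_times") -> None:
    """Write an event series as plain text (round-trips to 1e-9 s)."""
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w") as fh:
        fh.write(f"# dialect: {dialect}\n")
        if dialect == "beat_times":
            for t in events.event_times:
                fh.write(f"{t:.12f}\n")
        elif dialect == "time_rr_columns":
            u = events.event_times
            for t, rr in zip(u[1:], np.diff(u)):
                fh.write(f"{t:.12f} {rr:.12f}\n")
        else:
            scale = 1000.0 if dialect == "rr_milliseconds" else 1.0
            for rr in events.rr_intervals:
                fh.write(f"{scale * rr:.12f}\n")


# ---------------------------------------------------------------------------
# R-peak detection (Pan-Tompkins stages)


def detect_r_peaks(ecg: EcgTrace, refractory: float = 0.2) -> EventSeries:
    """Detect QRS fiducial points with the Pan-Tompkins stage recipe.

    Band-pass (5-15 Hz), derivative, squaring, ~150 ms moving-window
    integration, adaptive dual thresholds with a >= 200 ms refractory
    constraint, and fiducial refinement to the local maximum of the band-passed
    signal.

    Returns an :class:`EventSeries`; an all-zero trace yields zero detections.
    """
    fs = ecg.sampling_rate
    if fs <= 0:
        raise ValueError("sampling_rate must be positive")
    if fs < 100:
        raise ValueError(f"sampling_rate must be >= 100 Hz, got {fs}")
    x = ecg.samples
    if x.size < 2 * fs:
        raise ValueError("trace must be at least 2 s long")
    if not np.any(x != 0.0):
        return EventSeries(event_times=np.array([]), t_end=ecg.duration)

    nyq = fs / 2.0
    b, a = sps.butter(2, [5.0 / nyq, 15.0 / nyq], btype="band")
    bp = sps.filtfilt(b, a, x)
    deriv = np.gradient(bp) * fs
    sq = deriv**2
    mwi_len = max(int(round(0.150 * fs)), 1)
    mwi = np.convolve(sq, np.ones(mwi_len) / mwi_len, mode="same")

    min_dist = max(int(round(refractory * fs)), 1)
    cand, _ = sps.find_peaks(mwi, distance=min_dist)
    if cand.size == 0:
        return EventSeries(event_times=np.array([]), t_end=ecg.duration)

    # adaptive dual thresholds (classic SPKI/NPKI running estimates)
    init = mwi[: int(2 * fs)]
    spki = float(np.max(init)) * 0.5
    npki = float(np.mean(init)) * 0.5
    accepted = []
    for idx in cand:
        thr = npki + 0.25 * (spki - npki)
        if mwi[idx] > thr:
            accepted.append(idx)
            spki = 0.125 * mwi[idx] + 0.875 * spki
        else:
            npki = 0.125 * mwi[idx] + 0.875 * npki

    # fiducial refinement: local max of |band-passed| near the MWI peak
    half = int(round(0.10 * fs))
    peaks = []
    for idx in accepted:
        lo = max(idx - mwi_len, 0)
        hi = min(idx + half, x.size)
        peaks.append(lo + int(np.argmax(np.abs(bp[lo:hi]))))
    peaks = np.unique(peaks)
    if peaks.size > 1:
        keep = [int(peaks[0])]
        for p in peaks[1:]:
            if p - keep[-1] >= min_dist:
                keep.append(int(p))
        peaks = np.array(keep)
    return EventSeries(event_times=peaks / fs, t_end=ecg.duration)


# ---------------------------------------------------------------------------
# artifact detection and correction


@dataclass(frozen=True)
class ArtifactConfig:
    """Settings for predictive-tail artifact screening.

    A beat is suspect when its interval's probability under the local
    predictive inverse-Gaussian density (fitted on the surrounding
    ``window`` seconds, excluding the beat) falls below ``tail_prob`` per
    side.  This tail criterion is a documented stand-in for real-time
    correction algorithms whose exact policy is not published.
    """

    tail_prob: float = 1e-4
    window: float = 90.0
    max_passes: int = 5


def _local_ig(u: np.ndarray, rr: np.ndarray, k: int, window: float) -> tuple[float, float]:
    """Closed-form IG MLE on intervals near interval k, excluding k and k+1."""
    t_mid = 0.5 * (u[k] + u[k + 1])
    mask = (np.abs(u[1:] - t_mid) <= window / 2.0)
    mask[k] = False
    if k + 1 < rr.size:
        mask[k + 1] = False
    x = rr[mask]
    if x.size < 5:
        x = np.delete(rr, [k])
    mu = float(np.mean(x))
    inv_shape = float(np.mean(1.0 / x - 1.0 / mu))
    shape = 1.0 / max(inv_shape, 1e-12)
    return mu, shape


def correct_artifacts(events: EventSeries,
                      config: ArtifactConfig = ArtifactConfig()
                      ) -> tuple[EventSeries, dict]:
    """Detect and correct erroneous beat detections and missed beats.

    Spurious detections (two adjacent intervals in the low tail of the local
    predictive density) are merged by deleting the shared event; intervals in
    the high tail are split by inserting a midpoint event (missed beat).
    The operation is idempotent on corrected series.

    Returns the corrected :class:`EventSeries` and a report with counts of
    detected/merged/inserted beats.
    """
    if events.n_beats < 20:
        raise ValueError("artifact correction requires at least 20 beats")
    q = config.tail_prob
    u = list(events.event_times)
    flags = list(events.quality_flags)
    report = {"suspect": 0, "merged": 0, "inserted": 0, "passes": 0}
    for _ in range(config.max_passes):
        report["passes"] += 1
        changed = False
        ua = np.array(u)
        rr = np.diff(ua)
        k = 0
        while k < rr.size:
            mu, shape = _local_ig(ua, rr, k, config.window)
            dist = sstats.invgauss(mu / shape, scale=shape)
            p_lo = dist.cdf(rr[k])
            p_hi = dist.sf(rr[k])
            if p_lo < q and k + 1 < rr.size:
                # short interval: check merge with the following interval
                merged = rr[k] + rr[k + 1]
                if dist.cdf(merged) >= q and dist.sf(merged) >= q:
                    report["suspect"] += 1
                    report["merged"] += 1
                    del u[k + 1]
                    del flags[k + 1]
                    if k + 1 < len(flags):
                        flags[k + 1] = QUALITY_CORRECTED
                    changed = True
                    ua = np.array(u)
                    rr = np.diff(ua)
                    continue
            if p_hi < q:
                report["suspect"] += 1
                report["inserted"] += 1
                mid = 0.5 * (ua[k] + ua[k + 1])
                u.insert(k + 1, mid)
                flags.insert(k + 1, QUALITY_INSERTED)
                changed = True
                ua = np.array(u)
                rr = np.diff(ua)
                continue
            k += 1
        if not changed:
            break
    corrected = EventSeries(event_times=np.array(u), quality_flags=tuple(flags),
                            t_start=events.t_start, t_end=events.t_end)
    return corrected, report


# ---------------------------------------------------------------------------
# stimulus annotations


def read_stimulus_annotations(path) -> list[StimulusAnnotation]:
    """Read a CSV with columns onset, offset, force, velocity, subject.

    Annotations are validated (onset < offset, non-overlapping per subject)
    and returned sorted by onset.
    """
    df = pd.read_csv(path)
    required = {"onset", "offset", "force", "velocity", "subject"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    anns = [
        StimulusAnnotation(onset=float(r.onset), offset=float(r.offset),
                           force_level=float(r.force),
                           velocity_level=float(r.velocity),
                           subject_id=str(r.subject))
        for r in df.itertuples()
    ]
    anns.sort(key=lambda a: (a.subject_id, a.onset))
    for a, b in zip(anns, anns[1:]):
        if a.subject_id == b.subject_id and b.onset < a.offset:
            raise ValueError(
                f"{path}: overlapping annotations for subject {a.subject_id} "
                f"at onset {b.onset}")
    anns.sort(key=lambda a: a.onset)
    return anns


def write_stimulus_annotations(path, annotations: list[StimulusAnnotation]) -> None:
    df = pd.DataFrame(
        {
            "onset": [a.onset for a in annotations],
            "offset": [a.offset for a in annotations],
            "force": [a.force_level for a in annotations],
            "velocity": [a.velocity_level for a in annotations],
            "subject": [a.subject_id for a in annotations],
        }
    )
    df.to_csv(path, index=False)
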