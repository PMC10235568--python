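"""Firing Power smoothing, alarm generation and alarm classification.

Per-window binary classifier outputs are smoothed with the Firing Power
-- a moving average over ``tau`` windows, where ``tau`` spans the
preictal period -- and an alarm is raised when the Firing Power reaches
a threshold (0.7 by default).  Each alarm opens a refractory period of
the same length as the preictal period during which no further alarm is
raised.  An alarm counts as a true prediction only when a seizure onset
follows it by at least the seizure prediction horizon (SPH, 10 min) and
by no more than the seizure occurrence period (SOP, equal to the
preictal duration): ``sph <= onset - alarm <= sop``.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = [
    "FiringPowerSeries", "AlarmEvent", "HorizonSpec",
    "firing_power", "generate_alarms", "classify_alarms",
]

DEFAULT_THRESHOLD = 0.7


@dataclasses.dataclass(frozen=True)
class HorizonSpec:
    """Seizure prediction horizon (SPH) and occurrence period (SOP), minutes.

    An alarm at time t is correct iff some onset o satisfies
    ``sph <= o - t <= sop``.
    """

    sop_min: float
    sph_min: float = 10.0

    def __post_init__(self) -> None:
        if self.sph_min < 0:
            raise ValueError("sph_min must be >= 0")
        if not self.sop_min > self.sph_min:
            raise ValueError("sop_min must exceed sph_min")

    @property
    def sph_s(self) -> float:
        return self.sph_min * 60.0

    @property
    def sop_s(self) -> float:
        return self.sop_min * 60.0


@dataclasses.dataclass
class FiringPowerSeries:
    """Firing Power per window plus the smoothing span and threshold."""

    fp: np.ndarray
    tau: int
    threshold: float = DEFAULT_THRESHOLD
    warmup: np.ndarray | None = None  # True where fewer than tau windows seen

    def __post_init__(self) -> None:
        self.fp = np.asarray(self.fp, dtype=float)
        if self.tau < 1:
            raise ValueError("tau must be >= 1")
        if np.any((self.fp < -1e-12) | (self.fp > 1 + 1e-12)):
            raise ValueError("Firing Power out of [0, 1]")


@dataclasses.dataclass(frozen=True)
class AlarmEvent:
    """One raised alarm on the window grid."""

    index: int          # window index
    time_s: float       # window start, seconds from record start
    kind: str | None = None   # "true_positive" / "false_positive" once classified


def firing_power(outputs: np.ndarray, tau: int,
                 warmup: str = "partial",
                 threshold: float = DEFAULT_THRESHOLD) -> FiringPowerSeries:
    """Moving average of binary outputs over the preictal span.

    ``fp[n]`` is the mean of the last ``tau`` outputs.  During warm-up
    (n < tau - 1) either the partial mean over the available windows is
    used (``warmup="partial"``, default, flagged) or the sum is divided
    by the full ``tau`` (``warmup="full"``), which keeps early alarms
    conservative.  Raises for non-binary input.
    """
    o = np.asarray(outputs)
    if o.ndim != 1:
        raise ValueError("outputs must be 1-D")
    if not np.all(np.isin(o, (0, 1))):
        raise ValueError("Firing Power input must be binary 0/1")
    if tau < 1:
        raise ValueError("tau must be >= 1")
    if warmup not in ("partial", "full"):
        raise ValueError("warmup must be 'partial' or 'full'")
    c = np.concatenate([[0.0], np.cumsum(o, dtype=float)])
    n = len(o)
    idx = np.arange(n)
    lo = np.maximum(idx - tau + 1, 0)
    sums = c[idx + 1] - c[lo]
    denom = (idx + 1 - lo) if warmup == "partial" else np.full(n, float(tau))
    fp = sums / denom
    warm = idx < tau - 1
    return FiringPowerSeries(fp=fp, tau=int(tau), threshold=threshold,
                             warmup=warm)


def generate_alarms(
    fps: FiringPowerSeries | np.ndarray,
    refractory_windows: int,
    threshold: float | None = None,
    ictal_mask: np.ndarray | None = None,
    window_s: float = 5.0,
    window_start_s: np.ndarray | None = None,
) -> tuple[list[AlarmEvent], np.ndarray]:
    """Raise alarms where the Firing Power reaches the threshold.

    An alarm is raised at the first window with ``fp >= threshold`` that
    is not inside a refractory span (and not inside an ictal segment);
    the refractory span starts at the alarm window and covers
    ``refractory_windows`` windows.  If the Firing Power is still above
    threshold when the refractory span ends, a new alarm is raised
    immediately.  Returns ``(alarms, refractory_mask)``.
    """
    if isinstance(fps, FiringPowerSeries):
        fp = fps.fp
        if threshold is None:
            threshold = fps.threshold
    else:
        fp = np.asarray(fps, dtype=float)
        if threshold is None:
            threshold = DEFAULT_THRESHOLD
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    n = len(fp)
    if window_start_s is None:
        window_start_s = np.arange(n) * window_s
    refractory = np.zeros(n, dtype=bool)
    alarms: list[AlarmEvent] = []
    i = 0
    while i < n:
        blocked = ictal_mask is not None and ictal_mask[i]
        if fp[i] >= threshold and not blocked:
            alarms.append(AlarmEvent(index=i, time_s=float(window_start_s[i])))
            j = min(n, i + refractory_windows)
            refractory[i:j] = True
            i = j
        else:
            i += 1
    return alarms, refractory


def classify_alarms(
    alarms: list[AlarmEvent] | np.ndarray,
    onsets_s: np.ndarray,
    horizon: HorizonSpec,
) -> tuple[list[AlarmEvent], np.ndarray]:
    """Split alarms into true/false positives and flag predicted seizures.

    An alarm is a true positive iff some onset satisfies
    ``sph <= onset - alarm <= sop``; each alarm credits at most one
    seizure (the earliest eligible).  A seizure is predicted iff at
    least one true positive credits it.  Returns the classified alarm
    list and a boolean predicted-flag per onset.
    """
    onsets = np.sort(np.asarray(onsets_s, dtype=float))
    if isinstance(alarms, np.ndarray) or (
        len(alarms) and not isinstance(alarms[0], AlarmEvent)
    ):
        alarms = [AlarmEvent(index=k, time_s=float(t))
                  for k, t in enumerate(np.asarray(alarms, dtype=float))]
    predicted = np.zeros(len(onsets), dtype=bool)
    out: list[AlarmEvent] = []
    for a in alarms:
        lead = onsets - a.time_s
        eligible = np.flatnonzero((lead >= horizon.sph_s) & (lead <= horizon.sop_s))
        if len(eligible):
            predicted[eligible[0]] = True
            out.append(dataclasses.replace(a, kind="true_positive"))
        else:
            out.append(dataclasses.replace(a, kind="false_positive"))
    return out, predicted
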