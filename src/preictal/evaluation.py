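"""Performance metrics, surrogate significance testing and forecasting.

Prediction-mode metrics follow the alarm convention: seizure
sensitivity (SS) is the fraction of test seizures preceded by a valid
alarm; FPR/h divides the number of false alarms by the interictal
duration with the alarms' refractory time excluded from the
denominator.

Statistical significance of SS is assessed with a surrogate analysis:
seizure onsets are relocated uniformly at random within their own
seizure-data span, the (fixed) alarms are re-classified against the
surrogate onsets, and the observed SS is compared with the resulting
chance-level distribution.  The add-one empirical p-value
``(1 + #{SS_surr >= SS_obs}) / (n + 1)`` keeps the test valid at any
surrogate count.

Forecast-mode metrics drop the alarm/SPH machinery: a warning is any
window whose Firing Power reaches the alarm threshold, time under
warning (TiW) is the total warned time, and a seizure counts as
anticipated when its onset falls inside a warning.  The circadian
baseline warns every day from 30 minutes before to 30 minutes after
each training seizure's onset time of day.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import scipy.stats

from .alarms import AlarmEvent, HorizonSpec

__all__ = [
    "EvaluationReport", "SurrogateResult", "CircadianModel",
    "seizure_sensitivity", "false_positive_rate", "surrogate_test",
    "warning_timeline_from_fp", "time_in_warning", "circadian_forecast",
    "forecast_sensitivity", "compare_forecasters", "binomial_count_test",
    "SurrogateError",
]


class SurrogateError(ValueError):
    """Raised when a seizure-data span admits no valid onset relocation."""


@dataclasses.dataclass
class EvaluationReport:
    """Prediction-mode performance of one patient model."""

    ss: float
    fpr_h: float
    tiw_h: float
    n_test_seizures: int
    n_false_alarms: int
    n_true_alarms: int
    interictal_hours_counted: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.ss <= 1.0:
            raise ValueError("SS must be in [0, 1]")
        if self.fpr_h < 0:
            raise ValueError("FPR/h must be >= 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class SurrogateResult:
    """Observed SS against the chance-level surrogate distribution."""

    observed_ss: float
    surrogate_ss: np.ndarray
    p_value: float
    alpha: float
    above_chance: bool

    def to_dict(self) -> dict:
        return {
            "observed_ss": self.observed_ss,
            "surrogate_ss_mean": float(np.mean(self.surrogate_ss)),
            "n_surrogates": int(len(self.surrogate_ss)),
            "p_value": self.p_value,
            "alpha": self.alpha,
            "above_chance": self.above_chance,
        }


def seizure_sensitivity(predicted_flags: np.ndarray) -> float:
    """Fraction of test seizures predicted (ratio of flags set)."""
    flags = np.asarray(predicted_flags, dtype=bool)
    if flags.size == 0:
        raise ValueError("seizure sensitivity needs at least one test seizure")
    return float(flags.mean())


def false_positive_rate(
    n_false_alarms: int,
    interictal_s: float,
    refractory_in_interictal_s: float = 0.0,
) -> float:
    """False alarms per hour of interictal time, refractory time excluded.

    ``interictal_s`` is the evaluated interictal duration;
    ``refractory_in_interictal_s`` is the part of it spent inside
    alarms' refractory periods, which is removed from the denominator.
    """
    denom_s = interictal_s - refractory_in_interictal_s
    if denom_s <= 0:
        raise ValueError("no interictal time left after refractory exclusion")
    return float(n_false_alarms) / (denom_s / 3600.0)


def surrogate_test(
    alarm_times_s: np.ndarray | list[AlarmEvent],
    onsets_s: np.ndarray,
    seizure_spans_s: np.ndarray,
    horizon: HorizonSpec,
    n_surrogates: int = 1000,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> SurrogateResult:
    """Monte-Carlo chance level for SS by relocating seizure onsets.

    Each surrogate draw relocates every test onset uniformly within its
    own seizure-data span ``(start, end)``, constrained so that the full
    SOP fits inside the span before the relocated onset; the fixed
    alarms are then re-classified and SS recomputed.  The model and its
    alarms are never touched.

    Raises :class:`SurrogateError` when a span is too short for any
    valid relocation.
    """
    if isinstance(alarm_times_s, list):
        alarm_times_s = np.array([a.time_s for a in alarm_times_s])
    alarms = np.sort(np.asarray(alarm_times_s, dtype=float))
    onsets = np.asarray(onsets_s, dtype=float)
    spans = np.asarray(seizure_spans_s, dtype=float).reshape(-1, 2)
    if len(spans) != len(onsets):
        raise ValueError("one seizure-data span per test onset required")
    lo = spans[:, 0] + horizon.sop_s
    hi = spans[:, 1]
    for k, (a, b) in enumerate(zip(lo, hi)):
        if not b > a:
            raise SurrogateError(
                f"seizure {k}: span of {(spans[k, 1] - spans[k, 0]) / 60:.1f} min "
                f"too short to relocate an onset after a {horizon.sop_min:.0f} "
                "min occurrence period"
            )
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))

    def ss_of(onset_matrix: np.ndarray) -> np.ndarray:
        # a seizure is hit iff some alarm lies in [onset - sop, onset - sph]
        left = np.searchsorted(alarms, onset_matrix - horizon.sop_s, side="left")
        right = np.searchsorted(alarms, onset_matrix - horizon.sph_s, side="right")
        return (right > left).mean(axis=-1)

    observed = float(ss_of(onsets[None, :])[0])
    draws = rng.uniform(lo, hi, size=(n_surrogates, len(onsets)))
    surrogate_ss = ss_of(draws)
    p = (1.0 + np.sum(surrogate_ss >= observed)) / (n_surrogates + 1.0)
    return SurrogateResult(
        observed_ss=observed, surrogate_ss=surrogate_ss, p_value=float(p),
        alpha=alpha, above_chance=bool(p < alpha),
    )


# ---------------------------------------------------------------------------
# forecasting
# ---------------------------------------------------------------------------

def warning_timeline_from_fp(fp: np.ndarray, threshold: float = 0.7) -> np.ndarray:
    """Binary high-risk warning per window: Firing Power >= threshold."""
    return np.asarray(fp, dtype=float) >= threshold


def time_in_warning(warnings: np.ndarray, window_s: float = 5.0) -> float:
    """Total time under warning in hours."""
    return float(np.asarray(warnings, dtype=bool).sum()) * window_s / 3600.0


@dataclasses.dataclass
class CircadianModel:
    """Time-of-day forecaster built from the training seizures only.

    Warns every day from ``half_width_s`` before to ``half_width_s``
    after each training onset's time of day (30 min each side by
    default); overlapping daily windows merge.
    """

    train_onset_tod_s: np.ndarray
    half_width_s: float = 1800.0

    def __post_init__(self) -> None:
        self.train_onset_tod_s = np.asarray(self.train_onset_tod_s, dtype=float)
        if np.any((self.train_onset_tod_s < 0)
                  | (self.train_onset_tod_s >= 86400.0)):
            raise ValueError("times of day must be in [0, 86400) seconds")

    def in_warning(self, tod_s: np.ndarray) -> np.ndarray:
        """Whether each time of day (s) falls inside a daily warning."""
        tod = np.asarray(tod_s, dtype=float) % 86400.0
        hit = np.zeros(tod.shape, dtype=bool)
        for c in self.train_onset_tod_s:
            # signed circular difference in [-12 h, 12 h); the warning
            # interval is half-open, [c - half_width, c + half_width)
            d = (tod - c + 43200.0) % 86400.0 - 43200.0
            hit |= (d >= -self.half_width_s) & (d < self.half_width_s)
        return hit


def circadian_forecast(
    model: CircadianModel,
    window_start_s: np.ndarray,
    record_start_tod_s: float = 0.0,
) -> np.ndarray:
    """Per-window warnings of the circadian baseline on a window grid.

    ``record_start_tod_s`` is the time of day (s) of the record start so
    that window offsets map onto clock time.
    """
    if model.train_onset_tod_s.size == 0:
        raise ValueError("circadian forecaster needs at least one training onset")
    tod = (record_start_tod_s + np.asarray(window_start_s, dtype=float)) % 86400.0
    return model.in_warning(tod)


def forecast_sensitivity(
    warnings: np.ndarray,
    window_start_s: np.ndarray,
    window_s: float,
    onsets_s: np.ndarray,
) -> float:
    """Forecast-mode SS: fraction of onsets falling inside a warned window."""
    onsets = np.asarray(onsets_s, dtype=float)
    if onsets.size == 0:
        raise ValueError("needs at least one test seizure")
    starts = np.asarray(window_start_s, dtype=float)
    idx = np.searchsorted(starts, onsets, side="right") - 1
    ok = (idx >= 0) & (onsets < starts[np.clip(idx, 0, None)] + window_s)
    hit = np.zeros(onsets.shape, dtype=bool)
    valid = idx >= 0
    hit[valid] = np.asarray(warnings, dtype=bool)[idx[valid]] & ok[valid]
    return float(hit.mean())


def compare_forecasters(
    eeg_warnings: np.ndarray,
    circadian_warnings: np.ndarray,
    window_start_s: np.ndarray,
    window_s: float,
    onsets_s: np.ndarray,
    names: tuple[str, str] = ("eeg", "circadian"),
) -> pd.DataFrame:
    """Paired SS / TiW table for two forecasters on the same window grid.

    The returned frame has one row per forecaster with columns ``ss``
    and ``tiw_h`` plus a ``dominates`` flag set when a forecaster has
    simultaneously higher SS and lower TiW than the other.
    """
    eeg = np.asarray(eeg_warnings, dtype=bool)
    circ = np.asarray(circadian_warnings, dtype=bool)
    if eeg.shape != circ.shape or len(eeg) != len(window_start_s):
        raise ValueError("forecaster timelines must share the window grid")
    rows = {}
    for name, warn in zip(names, (eeg, circ)):
        rows[name] = {
            "ss": forecast_sensitivity(warn, window_start_s, window_s, onsets_s),
            "tiw_h": time_in_warning(warn, window_s),
        }
    df = pd.DataFrame(rows).T
    a, b = names
    df["dominates"] = [
        (rows[a]["ss"] > rows[b]["ss"]) and (rows[a]["tiw_h"] < rows[b]["tiw_h"]),
        (rows[b]["ss"] > rows[a]["ss"]) and (rows[b]["tiw_h"] < rows[a]["tiw_h"]),
    ]
    return df


def binomial_count_test(k: int, n: int, p0: float,
                        alpha: float = 0.05) -> tuple[float, bool]:
    """Upper-tail cumulative binomial test: P(X >= k | n, p0).

    Used for patient-count statements ("k of n patients show ...")
    against an explicit null proportion ``p0``.
    """
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    p = float(scipy.stats.binom.sf(k - 1, n, p0))
    return p, bool(p < alpha)
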