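"""Synthetic long-term scalp EEG with annotated seizures and ground truth.

Clinical long-term presurgical recordings with seizure annotations are
access-restricted, so every downstream stage of the package is exercised
on simulated patients with known ground truth.  A simulated recording is

* a 1/f-coloured noise background per channel, with a 10 Hz posterior
  alpha rhythm while awake,
* a *preictal signature*: the power of designated frequency bands is
  multiplied by a ramp over a configurable span before each seizure
  onset,
* circadian (24 h sinusoidal) broadband amplitude modulation,
* sleep intervals that boost delta-band power,
* 60 s large-amplitude 3-5 Hz ictal segments after each onset, and
* optional broadband 20-100 Hz muscle-artifact bursts on a Poisson
  schedule.

The preictal power multiplier ramps linearly from ``(E + 1) / 2`` at
the start of the span to ``(3 E - 1) / 2`` at onset (``E`` =
``effect_size``; for ``E < 1`` a constant multiplier is used).  Two
properties motivate this shape: the *time-averaged* multiplier over
the span equals ``effect_size`` exactly, and the multiplier steps up at
the preictal start (by ``(E - 1) / 2``), so the span has a detectable
beginning -- a signature that ramps up continuously from the background
level would leave the preictal onset unidentifiable to any window
classifier, and the preictal-duration search meaningless.
``effect_size = 1`` is an exact null (both ramp endpoints are 1):
preictal and interictal windows are statistically exchangeable.

Everything is reproducible bit-for-bit from ``SimulationConfig.seed``;
per-stage substreams are spawned deterministically from the master seed.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from typing import Sequence

import numpy as np

from .records import EEGRecord, SeizureAnnotation

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SchedulingError",
    "generate_patient",
    "TEN_TWENTY_CHANNELS",
]

#: The 19 standard 10-20 scalp electrode labels.
TEN_TWENTY_CHANNELS = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6", "O1", "O2",
)

#: Bands (Hz) carrying the preictal power ramp by default: the 13-30 Hz
#: band plus the gamma bands (clipped to Nyquist at low sampling rates).
DEFAULT_EFFECT_BANDS = ((13.0, 30.0), (30.0, 47.0), (53.0, 75.0),
                        (75.0, 97.0), (103.0, 128.0))


class SchedulingError(ValueError):
    """Raised when the requested seizures cannot fit in the record."""


@dataclasses.dataclass
class SimulationConfig:
    """Parameters of one simulated patient.

    The defaults mirror the recording conditions of clinical presurgical
    monitoring: 256 Hz, 19-channel 10-20 montage, multi-day records with
    at least four seizures separated by >= 4 h 30 min.
    """

    n_seizures: int = 4
    record_days: float = 5.0
    fs: float = 256.0
    channel_names: Sequence[str] = TEN_TWENTY_CHANNELS
    true_preictal_min: float = 40.0
    effect_size: float = 3.0
    effect_bands: Sequence[tuple[float, float]] = DEFAULT_EFFECT_BANDS
    circadian_amplitude: float = 0.2
    sleep_schedule: Sequence[tuple[float, float]] = ((23.0, 7.0),)
    sleep_delta_boost: float = 2.0
    artifact_rate_per_h: float = 1.0
    min_separation_h: float = 4.5
    ictal_s: float = 60.0
    alpha_hz: float = 10.0
    alpha_amplitude: float = 1.0
    noise_beta: float = 1.0
    window_s: float = 5.0
    start_time: dt.datetime = dt.datetime(2020, 1, 6, 0, 0, 0)
    seed: int = 0
    onset_times_s: Sequence[float] | None = None
    allow_fewer_seizures: bool = False

    def __post_init__(self) -> None:
        if not self.true_preictal_min > 0:
            raise ValueError("true_preictal_min must be positive")
        if not self.effect_size >= 0:
            raise ValueError("effect_size must be non-negative")
        if self.n_seizures < 4 and not self.allow_fewer_seizures:
            raise ValueError(
                "fewer than 4 seizures violates the patient inclusion "
                "criterion; pass allow_fewer_seizures=True to override"
            )

    @property
    def duration_s(self) -> float:
        return self.record_days * 86400.0


@dataclasses.dataclass
class GroundTruth:
    """Per-window generator-side truth on the analysis window grid.

    ``state`` is 0 (interictal), 1 (preictal) or 2 (ictal); preictal spans
    exactly ``true_preictal_min`` before each onset.  ``sleep`` and
    ``artifact`` are binary per window.
    """

    window_start_s: np.ndarray
    window_s: float
    state: np.ndarray       # int8: 0 interictal / 1 preictal / 2 ictal
    sleep: np.ndarray       # bool
    artifact: np.ndarray    # bool
    onsets_s: np.ndarray
    artifact_spans: np.ndarray  # (n_events, 2) seconds

    INTERICTAL, PREICTAL, ICTAL = 0, 1, 2


def _schedule_onsets(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Random onset times honouring lead-in, tail and minimum separation."""
    if cfg.onset_times_s is not None:
        onsets = np.sort(np.asarray(cfg.onset_times_s, dtype=float))
        _check_schedule(cfg, onsets)
        return onsets
    lead = cfg.true_preictal_min * 60.0 + 600.0
    tail = cfg.ictal_s + 600.0
    min_sep = cfg.min_separation_h * 3600.0
    slack = cfg.duration_s - lead - tail - (cfg.n_seizures - 1) * min_sep
    if slack < 0:
        raise SchedulingError(
            f"{cfg.n_seizures} seizures with {cfg.min_separation_h} h "
            f"separation do not fit in {cfg.record_days} days"
        )
    extras = np.sort(rng.uniform(0.0, slack, size=cfg.n_seizures))
    onsets = lead + np.arange(cfg.n_seizures) * min_sep + extras
    return onsets


def _check_schedule(cfg: SimulationConfig, onsets: np.ndarray) -> None:
    min_sep = cfg.min_separation_h * 3600.0
    if len(onsets) and (onsets[0] < cfg.true_preictal_min * 60.0
                        or onsets[-1] + cfg.ictal_s > cfg.duration_s):
        raise SchedulingError("explicit onset outside the feasible record span")
    gaps = np.diff(onsets)
    if len(gaps) and gaps.min() < min_sep:
        raise SchedulingError(
            f"explicit onsets violate the {cfg.min_separation_h} h separation"
        )


def _time_of_day_s(cfg: SimulationConfig, t_s: np.ndarray) -> np.ndarray:
    t0 = (cfg.start_time.hour * 3600 + cfg.start_time.minute * 60
          + cfg.start_time.second)
    return (t0 + t_s) % 86400.0


def _sleep_mask(cfg: SimulationConfig, t_s: np.ndarray) -> np.ndarray:
    tod_h = _time_of_day_s(cfg, t_s) / 3600.0
    mask = np.zeros(t_s.shape, dtype=bool)
    for start, end in cfg.sleep_schedule:
        if start <= end:
            mask |= (tod_h >= start) & (tod_h < end)
        else:  # interval wraps midnight
            mask |= (tod_h >= start) | (tod_h < end)
    return mask


def _band_fft_mask(freqs: np.ndarray, bands, nyquist: float) -> np.ndarray:
    mask = np.zeros(freqs.shape, dtype=bool)
    for lo, hi in bands:
        if lo >= nyquist:
            continue
        mask |= (freqs >= lo) & (freqs < min(hi, nyquist))
    return mask


def _preictal_power_multiplier(cfg: SimulationConfig, t_s: np.ndarray,
                               onsets: np.ndarray) -> np.ndarray:
    """Power multiplier m(t) of the designated bands; mean over each
    preictal span equals ``effect_size``."""
    m = np.ones(t_s.shape)
    pre_s = cfg.true_preictal_min * 60.0
    E = cfg.effect_size
    for onset in onsets:
        inside = (t_s >= onset - pre_s) & (t_s < onset)
        if E >= 1.0:
            frac = (t_s[inside] - (onset - pre_s)) / pre_s
            m[inside] = (E + 1.0) / 2.0 + frac * (E - 1.0)
        else:
            m[inside] = E
    return m


def generate_patient(
    config: SimulationConfig,
) -> tuple[EEGRecord, SeizureAnnotation, GroundTruth]:
    """Simulate one patient: record, seizure annotation and ground truth.

    Identical ``config`` (including ``seed``) reproduces the output
    bit-for-bit.  Raises :class:`SchedulingError` when the seizure
    schedule cannot fit in the record.
    """
    cfg = config
    n = int(round(cfg.duration_s * cfg.fs))
    n_ch = len(cfg.channel_names)
    ss = np.random.SeedSequence(cfg.seed)
    s_sched, s_art, s_alpha, s_chan = ss.spawn(4)
    onsets = _schedule_onsets(cfg, np.random.default_rng(s_sched))

    t = np.arange(n) / cfg.fs
    nyq = cfg.fs / 2.0

    # slow (per-sample) modulation envelopes, shared across channels
    sqrt_m = np.sqrt(_preictal_power_multiplier(cfg, t, onsets))
    sleep = _sleep_mask(cfg, t)
    awake = ~sleep
    circ = 1.0 + cfg.circadian_amplitude * np.sin(
        2.0 * np.pi * _time_of_day_s(cfg, t) / 86400.0
    )
    delta_gain = 1.0 + (np.sqrt(cfg.sleep_delta_boost) - 1.0) * sleep

    # artifact schedule (Poisson events, each on a random channel subset)
    rng_art = np.random.default_rng(s_art)
    n_events = rng_art.poisson(cfg.artifact_rate_per_h * cfg.duration_s / 3600.0)
    art_starts = np.sort(rng_art.uniform(0.0, cfg.duration_s, size=n_events))
    art_durs = rng_art.uniform(0.5, 2.0, size=n_events)
    art_durs = np.minimum(art_durs, cfg.duration_s - art_starts)
    art_channels = [
        rng_art.choice(n_ch, size=max(1, n_ch // 3), replace=False)
        for _ in range(n_events)
    ]
    art_lo, art_hi = 20.0, min(100.0, 0.95 * nyq)

    rng_alpha = np.random.default_rng(s_alpha)
    alpha_phases = rng_alpha.uniform(0.0, 2.0 * np.pi, size=n_ch)
    chan_seeds = s_chan.spawn(n_ch)

    rfreqs = np.fft.rfftfreq(n, d=1.0 / cfg.fs)
    with np.errstate(divide="ignore"):
        shape = rfreqs ** (-cfg.noise_beta / 2.0)
    shape[0] = 0.0
    band_mask = _band_fft_mask(rfreqs, cfg.effect_bands, nyq)
    delta_mask = _band_fft_mask(rfreqs, [(0.5, 4.0)], nyq) & ~band_mask
    rest_mask = ~band_mask & ~delta_mask

    signal = np.empty((n_ch, n), dtype=np.float32)
    for ch, name in enumerate(cfg.channel_names):
        rng_ch = np.random.default_rng(chan_seeds[ch])
        spec = np.fft.rfft(rng_ch.standard_normal(n)) * shape
        base = np.fft.irfft(spec * rest_mask, n=n)
        scale = 10.0 / max(np.fft.irfft(spec, n=n).std(), 1e-12)  # ~10 uV rms
        x = base
        x = x + np.fft.irfft(spec * band_mask, n=n) * sqrt_m
        x = x + np.fft.irfft(spec * delta_mask, n=n) * delta_gain
        x *= scale
        if name.startswith(("O", "P", "T5", "T6")):
            x = x + (
                cfg.alpha_amplitude * 10.0
                * np.sin(2.0 * np.pi * cfg.alpha_hz * t + alpha_phases[ch])
                * awake
            )
        x *= circ
        # ictal segments: large-amplitude 3-5 Hz oscillation after each onset
        for k, onset in enumerate(onsets):
            i0 = int(round(onset * cfg.fs))
            i1 = min(n, int(round((onset + cfg.ictal_s) * cfg.fs)))
            f_ict = 3.0 + 2.0 * ((k + ch) % 3) / 2.0
            x[i0:i1] += 80.0 * np.sin(2.0 * np.pi * f_ict * t[i0:i1])
        signal[ch] = x.astype(np.float32)

    # muscle-artifact bursts: broadband high-frequency noise, tapered
    for ev in range(n_events):
        i0 = int(round(art_starts[ev] * cfg.fs))
        i1 = min(n, int(round((art_starts[ev] + art_durs[ev]) * cfg.fs)))
        if i1 - i0 < 4:
            continue
        m = i1 - i0
        w = rng_art.standard_normal(m)
        fb = np.fft.rfftfreq(m, d=1.0 / cfg.fs)
        keep = (fb >= art_lo) & (fb <= art_hi)
        burst = np.fft.irfft(np.fft.rfft(w) * keep, n=m)
        sd = burst.std()
        if sd > 0:
            burst *= 30.0 / sd
        burst *= np.hanning(m)
        for ch in art_channels[ev]:
            signal[ch, i0:i1] += burst.astype(np.float32)

    record = EEGRecord(
        signal=signal, fs=cfg.fs, channel_names=list(cfg.channel_names),
        start_time=cfg.start_time,
    )
    ann = SeizureAnnotation.from_seconds(
        onsets, cfg.start_time, offsets_s=onsets + cfg.ictal_s
    )

    # ground truth on the analysis window grid
    n_win = int(np.floor(cfg.duration_s / cfg.window_s))
    wstart = np.arange(n_win) * cfg.window_s
    wend = wstart + cfg.window_s
    state = np.zeros(n_win, dtype=np.int8)
    pre_s = cfg.true_preictal_min * 60.0
    for onset in onsets:
        state[(wstart >= onset - pre_s) & (wstart < onset)] = GroundTruth.PREICTAL
    for onset in onsets:
        state[(wend > onset) & (wstart < onset + cfg.ictal_s)] = GroundTruth.ICTAL
    sleep_w = _sleep_mask(cfg, wstart + cfg.window_s / 2.0)
    art_w = np.zeros(n_win, dtype=bool)
    spans = np.column_stack([art_starts, art_starts + art_durs]) \
        if n_events else np.empty((0, 2))
    for a0, a1 in spans:
        art_w |= (wend > a0) & (wstart < a1)
    truth = GroundTruth(
        window_start_s=wstart, window_s=cfg.window_s, state=state,
        sleep=sleep_w, artifact=art_w, onsets_s=onsets, artifact_spans=spans,
    )
    return record, ann, truth
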