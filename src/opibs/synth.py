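"""Synthetic pulse-interval recordings with controllable apnea severity.

The generator emulates the beat-interval structure relevant to the index: a
baseline pulse period modulated by a low-frequency (Mayer-wave, 0.1 Hz) and a
high-frequency (respiratory sinus arrhythmia, 0.25 Hz) sinusoid, white
beat-to-beat noise, and — the apnea signature — cyclic bradycardia–tachycardia
events: at Poisson-distributed times, one deceleration half-cycle followed by
a symmetric acceleration half-cycle (a zero-mean sine over ``event_period_s``)
is added to the pulse period.  The event rate per hour doubles as the
recording's AHI label, so cohorts with the three clinical severity strata can
be drawn directly.  An optional PPG renderer places one asymmetric pulse per
beat for exercising the peak-detection front end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .preprocess import PPGSignal, PPISeries
from .screen import group_from_ahi

__all__ = [
    "SynthConfig",
    "SynthRecording",
    "generate_recording",
    "generate_cohort",
    "generate_ppg",
]


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; amplitudes in seconds of pulse-period modulation."""

    duration_s: float = 21600.0  # 6 h, ~72 five-minute epochs
    base_pp_s: float = 1.0
    rsa_amp_s: float = 0.03
    rsa_freq_hz: float = 0.25
    lf_amp_s: float = 0.02
    lf_freq_hz: float = 0.10
    event_rate_per_h: float = 0.0
    event_amp_s: float = 0.15
    event_period_s: float = 45.0
    noise_sd_s: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rsa_amp_s", "lf_amp_s", "event_amp_s", "noise_sd_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.base_pp_s <= self.rsa_amp_s + self.lf_amp_s + self.event_amp_s:
            raise ValueError(
                "base_pp_s must exceed the summed modulation amplitudes "
                "so intervals stay positive"
            )
        if self.duration_s < 600:
            raise ValueError("duration_s must be at least 600 s")


@dataclass
class SynthRecording:
    recording_id: str
    ppi: PPISeries
    ahi: float
    group: str


def _event_starts(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    n = rng.poisson(cfg.event_rate_per_h * cfg.duration_s / 3600.0)
    return np.sort(rng.uniform(0.0, cfg.duration_s, size=n))


def generate_recording(cfg: SynthConfig) -> tuple[PPISeries, float]:
    """Draw one beat-by-beat recording; returns the series and its AHI label.

    Beats are generated sequentially: the j-th pulse period is the baseline
    plus the sinusoidal modulations and any active event waveform evaluated at
    the current beat time, plus Gaussian noise; intervals are floored at a
    quarter of the baseline so pathological noise draws cannot produce
    non-positive beats.  Fully reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    starts = _event_starts(cfg, rng)
    n_max = int(cfg.duration_s / (cfg.base_pp_s * 0.5)) + 16
    noise = rng.normal(0.0, cfg.noise_sd_s, size=n_max) if cfg.noise_sd_s else np.zeros(n_max)

    two_pi = 2.0 * math.pi
    w_lf = two_pi * cfg.lf_freq_hz
    w_rsa = two_pi * cfg.rsa_freq_hz
    period = cfg.event_period_s
    floor = 0.25 * cfg.base_pp_s
    ev = starts.tolist()
    n_ev = len(ev)

    pps = []
    times = [0.0]
    t = 0.0
    j = 0
    ptr = 0
    while t < cfg.duration_s and j < n_max:
        pp = (
            cfg.base_pp_s
            + cfg.lf_amp_s * math.sin(w_lf * t)
            + cfg.rsa_amp_s * math.sin(w_rsa * t)
            + noise[j]
        )
        while ptr < n_ev and ev[ptr] + period < t:
            ptr += 1
        k = ptr
        while k < n_ev and ev[k] <= t:
            pp += cfg.event_amp_s * math.sin(two_pi * (t - ev[k]) / period)
            k += 1
        pp = max(pp, floor)
        pps.append(pp)
        t += pp
        times.append(t)
        j += 1
    ppi = PPISeries(intervals=np.array(pps), beat_times=np.array(times))
    return ppi, float(cfg.event_rate_per_h)


#: AHI ranges the three severity strata are drawn from, events/hour.
GROUP_RATE_RANGES = {"N": (0.0, 5.0), "OSA-m": (5.0, 30.0), "OSA-s": (30.0, 60.0)}


def generate_cohort(
    n_per_group: tuple[int, int, int] = (29, 39, 24),
    seed: int = 0,
    base_config: SynthConfig | None = None,
) -> list[SynthRecording]:
    """Draw a labelled cohort across the N / OSA-m / OSA-s strata.

    Event rates are uniform within each stratum's AHI range; the baseline
    pulse period additionally varies between subjects (U(0.85, 1.1) s).  All
    randomness flows from ``seed``.
    """
    if min(n_per_group) < 2:
        raise ValueError("need at least 2 recordings per group")
    base = base_config or SynthConfig()
    rng = np.random.default_rng(seed)
    cohort: list[SynthRecording] = []
    i = 0
    for group, n in zip(("N", "OSA-m", "OSA-s"), n_per_group):
        lo, hi = GROUP_RATE_RANGES[group]
        for _ in range(n):
            rate = float(rng.uniform(lo, hi))
            cfg = replace(
                base,
                event_rate_per_h=rate,
                base_pp_s=float(rng.uniform(0.85, 1.10)),
                seed=int(rng.integers(2**31)),
            )
            ppi, ahi = generate_recording(cfg)
            rid = f"rec{i:03d}"
            assert group_from_ahi(ahi) == group
            cohort.append(SynthRecording(rid, ppi, ahi, group))
            i += 1
    return cohort


def generate_ppg(ppi: PPISeries, fs: float = 100.0) -> PPGSignal:
    """Render a PPG-like waveform with one asymmetric pulse per beat.

    Each beat contributes a two-sided Gaussian bump (fast 40 ms rise, slow
    90 ms decay) centred exactly on the beat time, so peak-to-peak spacing
    equals the interval series.
    """
    if fs < 25:
        raise ValueError("sampling rate must be at least 25 Hz")
    if len(ppi) == 0:
        raise ValueError("cannot render a PPG from an empty interval series")
    beat_times = (
        ppi.beat_times
        if ppi.beat_times is not None
        else np.concatenate(([0.0], np.cumsum(ppi.intervals)))
    )
    beat_times = beat_times - beat_times[0] + 1.0  # 1 s lead-in
    total = beat_times[-1] + 1.0
    n = int(round(total * fs)) + 1
    sig = np.zeros(n)
    sigma_r, sigma_f = 0.040, 0.090
    half = int(round(4 * sigma_f * fs))
    for tb in beat_times:
        c = int(round(tb * fs))
        lo, hi = max(0, c - half), min(n, c + half + 1)
        rel = (np.arange(lo, hi) - c) / fs
        sigma = np.where(rel < 0, sigma_r, sigma_f)
        sig[lo:hi] += np.exp(-0.5 * (rel / sigma) ** 2)
    return PPGSignal(samples=sig, fs=fs)
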