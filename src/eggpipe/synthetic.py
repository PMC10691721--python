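"""Seeded synthetic EGG generator.

Emulates the statistical structure of serosal electrogastrograms from
freely moving animals: a gastric slow wave near 10 cycles/minute with a
weak second harmonic and Ornstein-Uhlenbeck frequency jitter, pink (1/f)
background noise, and three artifact classes --

* physiologically implausible spikes (|x| in 2e8..1e9 uV) from electrode
  disconnections, which exercise the 1e8 uV excision stage;
* motion-artifact bumps (3000..10000 uV, a few seconds long), which
  exercise the 2000 uV clamp stage;
* biphasic stimulation pulse trains at 10 or 30 Hz during VNS, rendered
  as adjacent positive/negative single-sample pairs (a 0.1 ms pulse is
  sub-sample at 2 kHz), which exercise the band-pass stage.

Condition effects mirror the two stimulation regimes: VNS at 10 Hz
multiplies the slow-wave amplitude (``amp_effect``); VNS at 30 Hz shifts
the dominant frequency (``freq_shift_cpm``) and increases irregularity
(``complexity_effect`` scales both the frequency jitter and the broadband
noise).  Effect sizes are free parameters of the simulator, not values
calibrated to any animal.

Every component draws from its own child of the recording seed, so equal
(params, seed) pairs give bit-identical output and individual components
can be toggled without disturbing the others' streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import lfilter

from .preprocessing import Recording

__all__ = ["GeneratorParams", "StudyDesign", "generate_recording", "generate_study"]


@dataclass
class GeneratorParams:
    """Knobs of the synthetic slow-wave model and its artifact channels.

    Amplitudes in uV, frequencies of the slow wave in cycles/minute (cpm),
    stimulation frequency in Hz, event rates per minute.
    """

    slow_wave_freq_cpm: float = 10.0
    slow_wave_amp_uv: float = 200.0
    harmonic_weight: float = 0.1
    freq_jitter_sd_cpm: float = 0.5
    pink_noise_sd_uv: float = 30.0
    spike_rate_per_min: float = 0.2
    motion_artifact_rate_per_min: float = 0.5
    vns_pulse_freq_hz: float = 0.0
    vns_pulse_amp_uv: float = 5000.0
    amp_effect: float = 1.5
    freq_shift_cpm: float = -2.0
    complexity_effect: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vns_pulse_freq_hz not in (0, 10, 30):
            raise ValueError("vns_pulse_freq_hz must be 0, 10 or 30")
        for name in (
            "freq_jitter_sd_cpm", "pink_noise_sd_uv", "spike_rate_per_min",
            "motion_artifact_rate_per_min", "vns_pulse_amp_uv",
            "amp_effect", "complexity_effect",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.harmonic_weight <= 1:
            raise ValueError("harmonic_weight must lie in [0, 1]")


@dataclass
class StudyDesign:
    """Within-subject crossover: per (subject, stim freq) session, one
    baseline segment then one VNS segment."""

    n_subjects: int = 7
    stim_freqs_hz: tuple = (10, 30)
    segment_duration_s: float = 600.0
    fs_hz: float = 2000.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.stim_freqs_hz = tuple(self.stim_freqs_hz)
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if len(self.stim_freqs_hz) == 0:
            raise ValueError("stim_freqs_hz must be non-empty")
        if any(f not in (10, 30) for f in self.stim_freqs_hz):
            raise ValueError("stimulation frequencies must be 10 or 30 Hz")


def _component_rngs(seed: int) -> dict:
    """Independent child streams, one per signal component."""
    names = ("jitter", "pink", "spikes", "motion")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _ou_process(rng: np.random.Generator, n: int, dt: float, sd: float,
                tau_s: float = 10.0) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck path with sd ``sd`` and correlation
    time ``tau_s``, computed as an AR(1) filter for speed."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    a = np.exp(-dt / tau_s)
    innov_sd = sd * np.sqrt(1.0 - a * a)
    x0 = rng.normal(0.0, sd)
    w = rng.normal(0.0, innov_sd, size=n)
    w[0] = x0
    return lfilter([1.0], [1.0, -a], w)


def _pink_noise(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    """1/f-amplitude-shaped Gaussian noise, rescaled to the target sd."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    k = np.arange(len(spec), dtype=float)
    k[0] = 1.0
    spec /= np.sqrt(k)
    spec[0] = 0.0
    pink = np.fft.irfft(spec, n=n)
    s = pink.std()
    return pink * (sd / s) if s > 0 else pink


def generate_recording(
    condition: str,
    params: GeneratorParams,
    duration_s: float = 600.0,
    fs_hz: float = 2000.0,
    subject_id: str = "s00",
    session_id: str = "sess00",
) -> Recording:
    """Synthesize one EGG segment under ``condition`` in {baseline, vns}.

    Baseline requires ``vns_pulse_freq_hz == 0`` and vice versa (the pulse
    train exists exactly when stimulation is on).  The 10 Hz amplitude
    effect and the 30 Hz frequency/complexity effects apply only during
    their own stimulation regime.
    """
    if duration_s <= 0 or fs_hz <= 0:
        raise ValueError("duration_s and fs_hz must be positive")
    if condition not in ("baseline", "vns"):
        raise ValueError(f"unknown condition {condition!r}")
    if (condition == "baseline") != (params.vns_pulse_freq_hz == 0):
        raise ValueError(
            "vns_pulse_freq_hz must be 0 for baseline and 10/30 for vns"
        )

    n = round(duration_s * fs_hz)
    dt = 1.0 / fs_hz
    rngs = _component_rngs(params.seed)

    f0 = params.slow_wave_freq_cpm
    amp = params.slow_wave_amp_uv
    jitter_sd = params.freq_jitter_sd_cpm
    pink_sd = params.pink_noise_sd_uv
    if condition == "vns":
        if params.vns_pulse_freq_hz == 10:
            amp *= params.amp_effect
        elif params.vns_pulse_freq_hz == 30:
            f0 += params.freq_shift_cpm
            jitter_sd *= 1.0 + params.complexity_effect
            pink_sd *= 1.0 + params.complexity_effect

    # slow wave: integrated instantaneous frequency (cpm -> Hz via /60)
    f_inst_cpm = f0 + _ou_process(rngs["jitter"], n, dt, jitter_sd)
    phase = 2.0 * np.pi * np.cumsum(f_inst_cpm / 60.0) * dt
    x = amp * (np.sin(phase) + params.harmonic_weight * np.sin(2.0 * phase))

    x += _pink_noise(rngs["pink"], n, pink_sd)

    if condition == "vns" and params.vns_pulse_amp_uv > 0:
        period = round(fs_hz / params.vns_pulse_freq_hz)
        idx = np.arange(0, n - 1, period)
        x[idx] += params.vns_pulse_amp_uv
        x[idx + 1] -= params.vns_pulse_amp_uv

    # motion artifacts: raised-cosine bumps, 2-5 s, 3000-10000 uV
    rng_m = rngs["motion"]
    n_motion = rng_m.poisson(params.motion_artifact_rate_per_min * duration_s / 60.0)
    for _ in range(n_motion):
        dur = rng_m.uniform(2.0, 5.0)
        a = rng_m.uniform(3000.0, 10000.0) * rng_m.choice([-1.0, 1.0])
        i0 = rng_m.integers(0, max(1, n - round(dur * fs_hz)))
        m = round(dur * fs_hz)
        bump = a * 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(m) / m))
        x[i0 : i0 + m] += bump[: len(x[i0 : i0 + m])]

    # implausible spikes: overwrite single samples, |x| in [2e8, 1e9] uV
    rng_s = rngs["spikes"]
    n_spikes = rng_s.poisson(params.spike_rate_per_min * duration_s / 60.0)
    if n_spikes > 0:
        pos = rng_s.choice(n, size=min(n_spikes, n), replace=False)
        amps = rng_s.uniform(2e8, 1e9, size=len(pos)) * rng_s.choice(
            [-1.0, 1.0], size=len(pos)
        )
        x[pos] = amps

    return Recording(
        samples=x,
        fs_hz=fs_hz,
        subject_id=subject_id,
        session_id=session_id,
        condition=condition,
        stim_freq_hz=float(params.vns_pulse_freq_hz),
        channel_label="gastric2",
    )


def generate_study(
    design: StudyDesign, params: GeneratorParams | None = None
) -> list[Recording]:
    """Generate the full crossover study.

    Each (subject, stimulation frequency) session yields one baseline and
    one VNS recording, so the study holds ``2 * n_subjects *
    len(stim_freqs_hz)`` recordings.  Per-recording seeds are spawned
    deterministically from the design seed.
    """
    base = params or GeneratorParams()
    ss = np.random.SeedSequence(design.seed)
    children = ss.spawn(design.n_subjects * len(design.stim_freqs_hz) * 2)
    it = iter(children)
    out: list[Recording] = []
    for s in range(design.n_subjects):
        subject_id = f"s{s:02d}"
        for f in design.stim_freqs_hz:
            session_id = f"{subject_id}_vns{int(f)}"
            for condition in ("baseline", "vns"):
                seed = int(next(it).generate_state(1)[0] % (2**31))
                p = replace(
                    base,
                    seed=seed,
                    vns_pulse_freq_hz=(f if condition == "vns" else 0),
                )
                rec = generate_recording(
                    condition,
                    p,
                    duration_s=design.segment_duration_s,
                    fs_hz=design.fs_hz,
                    subject_id=subject_id,
                    session_id=session_id,
                )
                rec.stim_freq_hz = float(f)  # session label, both conditions
                out.append(rec)
    return out
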