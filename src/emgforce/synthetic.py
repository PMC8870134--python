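"""Synthetic grip-force / surface-EMG generator with known ground truth.

Emulates a handgrip experiment: a subject tracks one of six prescribed
force profiles while three forearm EMG channels (extensor carpi radialis,
flexor digitorum superficialis, flexor carpi radialis) are recorded at
1000 Hz, band-limited to 20-500 Hz.

The EMG model is multiplicative amplitude modulation of band-limited
noise: each channel's carrier is white noise band-passed to 20-500 Hz with
unit RMS, modulated by a nonlinear monotone function of force,

    EMG(k) = gain * m_h(k) * carrier(k) + floor * gain * noise(k),
    m(k)   = (F(k) / F_max) ** gamma,

with m_h an optional first-order lag of m (hysteresis: the envelope trails
the force differently on rising and falling phases).  Distinct gains and
exponents per channel mimic the differing recruitment curves of the three
muscles.  Everything is driven by a master seed and regenerates
bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .signals import SignalTrace

__all__ = [
    "ProfileSpec",
    "MuscleParams",
    "DatasetConfig",
    "Trial",
    "SyntheticDataset",
    "gen_force_profile",
    "gen_emg_from_force",
    "gen_dataset",
    "default_channels",
    "PROFILE_KINDS",
]

PROFILE_KINDS = ("step", "saw", "vol", "single_level", "circle")

#: Default trial duration (s) per profile kind.  The step profile is five
#: 10 s increments of 10 N each; the circle profile is a single slow 10 s
#: rise and fall.
DEFAULT_DURATIONS = {"step": 50.0, "saw": 40.0, "vol": 30.0,
                     "single_level": 30.0, "circle": 10.0}


@dataclass(frozen=True)
class ProfileSpec:
    """Prescribed grip-force trajectory of one trial.

    ``peak`` is the maximum force in newtons (the single-level profile
    holds it steady; the step staircase reaches it at the last level).
    """

    kind: str
    peak: float = 50.0
    duration: float | None = None
    fs: float = 1000.0
    level_duration: float = 10.0
    level_increment: float = 10.0

    def __post_init__(self) -> None:
        if self.kind not in PROFILE_KINDS:
            raise ValueError(f"unknown profile kind {self.kind!r}")
        if self.peak < 0:
            raise ValueError("peak amplitude must be >= 0")
        dur = self.duration if self.duration is not None else DEFAULT_DURATIONS[self.kind]
        if not dur > 0:
            raise ValueError("duration must be positive")
        if not self.fs > 0:
            raise ValueError("fs must be positive")

    @property
    def resolved_duration(self) -> float:
        if self.kind == "step" and self.duration is None:
            return 5 * self.level_duration
        return self.duration if self.duration is not None else DEFAULT_DURATIONS[self.kind]


def gen_force_profile(spec: ProfileSpec, rng: np.random.Generator | None = None) -> SignalTrace:
    """Generate the prescribed force trajectory for one trial.

    step: staircase of five levels (10, 20, ..., 50 N by default), each
    held ``level_duration`` seconds.  saw: two back-to-back linear ramps
    0 -> peak.  single_level: constant at ``peak``.  circle: half-cosine
    rise and fall, zero at both ends, maximum at mid-trial.  vol: a
    seeded, smoothed random walk clipped to [0, peak] ("freely varying").
    """
    n = int(round(spec.resolved_duration * spec.fs))
    if n < 1:
        raise ValueError("zero-length profile")
    t = np.arange(n) / spec.fs
    kind = spec.kind
    if kind == "step":
        level = np.minimum(np.floor(t / spec.level_duration) + 1, 5)
        f = level * spec.level_increment
    elif kind == "saw":
        half = spec.resolved_duration / 2
        phase = np.mod(t, half) / half
        f = phase * spec.peak
    elif kind == "single_level":
        f = np.full(n, spec.peak)
    elif kind == "circle":
        f = 0.5 * spec.peak * (1 - np.cos(2 * np.pi * t / spec.resolved_duration))
    else:  # vol
        if rng is None:
            rng = np.random.default_rng(0)
        walk = np.cumsum(rng.standard_normal(n))
        sos = sps.butter(2, min(0.2, 0.45 * spec.fs / 2), btype="low", fs=spec.fs,
                         output="sos")
        walk = sps.sosfiltfilt(sos, walk)
        sd = np.std(walk)
        if sd > 0:
            walk = (walk - np.mean(walk)) / sd
        f = np.clip(0.5 * spec.peak + 0.25 * spec.peak * walk, 0.0, spec.peak)
    return SignalTrace(f, fs=spec.fs, label="force", kind="force")


@dataclass(frozen=True)
class MuscleParams:
    """Per-channel EMG generator parameters.

    gain: carrier amplitude at maximum force (arbitrary volts).
    gamma: exponent of the force -> envelope recruitment curve.
    noise_floor: additive band-limited noise, as a fraction of gain.
    band: carrier pass-band in Hz (must fit under Nyquist).
    hysteresis_tau: time constant (s) of the first-order lag applied to
    the modulator; 0 disables it.
    """

    gain: float = 1.0
    gamma: float = 1.0
    noise_floor: float = 0.05
    band: tuple[float, float] = (20.0, 500.0)
    hysteresis_tau: float = 0.1

    def __post_init__(self) -> None:
        if not self.gain > 0:
            raise ValueError("gain must be positive")
        if not self.gamma > 0:
            raise ValueError("gamma must be positive")
        if not 0 < self.band[0] < self.band[1]:
            raise ValueError("carrier band must satisfy 0 < low < high")


def default_channels() -> dict[str, MuscleParams]:
    """Three channels mimicking ECR / FDS / FCR recruitment differences."""
    return {
        "emg_ecr": MuscleParams(gain=1.0, gamma=0.8),
        "emg_fds": MuscleParams(gain=0.8, gamma=1.0),
        "emg_fcr": MuscleParams(gain=1.2, gamma=1.3),
    }


def _band_noise(n: int, band: tuple[float, float], fs: float,
                rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS white noise band-passed to *band* (band clipped under Nyquist)."""
    hi = min(band[1], 0.45 * fs)
    lo = min(band[0], 0.5 * hi)
    sos = sps.butter(4, (lo, hi), btype="band", fs=fs, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n))
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def gen_emg_from_force(
    force: SignalTrace,
    params: MuscleParams | list[MuscleParams] | dict[str, MuscleParams],
    seed: int | np.random.Generator = 0,
    f_max: float = 50.0,
) -> list[SignalTrace]:
    """Generate one EMG trace per channel from a force trajectory."""
    if len(force) < 1:
        raise ValueError("empty force trace")
    if np.any(force.samples < 0):
        raise ValueError("force must be non-negative")
    if isinstance(params, MuscleParams):
        channels = {"emg": params}
    elif isinstance(params, dict):
        channels = params
    else:
        channels = {f"emg_{i + 1}": p for i, p in enumerate(params)}
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fs, n = force.fs, len(force)
    out = []
    for label, p in channels.items():
        m = (np.clip(force.samples, 0.0, None) / f_max) ** p.gamma
        if p.hysteresis_tau > 0:
            alpha = float(np.exp(-1.0 / (fs * p.hysteresis_tau)))
            m = sps.lfilter([1.0 - alpha], [1.0, -alpha], m)
        carrier = _band_noise(n, p.band, fs, rng)
        floor = _band_noise(n, p.band, fs, rng)
        emg = p.gain * m * carrier + p.noise_floor * p.gain * floor
        out.append(SignalTrace(emg, fs=fs, label=label, kind="emg_raw"))
    return out


@dataclass(frozen=True)
class DatasetConfig:
    """Shape of the synthetic experiment: subjects x profiles x trials."""

    n_subjects: int = 1
    profiles: tuple[str, ...] = PROFILE_KINDS
    n_trials: int = 4
    fs: float = 1000.0
    peak: float = 50.0
    duration_scale: float = 1.0
    gain_jitter: float = 0.05   # lognormal sd of the per-trial gain factor
    force_noise_n: float = 0.3  # dynamometer noise sd in newtons

    def profile_spec(self, kind: str) -> ProfileSpec:
        dur = DEFAULT_DURATIONS[kind] * self.duration_scale
        return ProfileSpec(kind=kind, peak=self.peak, duration=dur, fs=self.fs,
                           level_duration=10.0 * self.duration_scale)


@dataclass
class Trial:
    """One recorded trial: paired EMG channels and measured force."""

    subject: int
    profile_kind: str
    index: int
    seed: int
    emg: dict[str, SignalTrace]
    force: SignalTrace

    @property
    def ref(self) -> str:
        return f"s{self.subject}_{self.profile_kind}_t{self.index}"

    def to_frame(self):
        import pandas as pd

        cols = {"time_s": self.force.time}
        for label, tr in self.emg.items():
            cols[label] = tr.samples
        cols["force_n"] = self.force.samples
        return pd.DataFrame(cols)


@dataclass
class SyntheticDataset:
    """Generated trials plus the ground-truth generator configuration."""

    trials: list[Trial]
    config: DatasetConfig
    channels: dict[str, MuscleParams]
    master_seed: int

    def select(self, profile_kind: str | None = None, subject: int | None = None) -> list[Trial]:
        out = [t for t in self.trials
               if (profile_kind is None or t.profile_kind == profile_kind)
               and (subject is None or t.subject == subject)]
        return out

    def to_dir(self, path: str | Path) -> list[Path]:
        """Write one CSV per trial plus a JSON manifest; returns written paths."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        written = []
        manifest = {"master_seed": self.master_seed,
                    "fs": self.config.fs,
                    "channels": {k: asdict(v) for k, v in self.channels.items()},
                    "trials": []}
        for t in self.trials:
            fname = f"{t.ref}.csv"
            t.to_frame().to_csv(path / fname, index=False, float_format="%.8g")
            manifest["trials"].append({"file": fname, "subject": t.subject,
                                       "profile_kind": t.profile_kind,
                                       "trial": t.index, "seed": t.seed})
            written.append(path / fname)
        (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
        written.append(path / "manifest.json")
        return written


def gen_dataset(
    config: DatasetConfig | None = None,
    seed: int = 0,
    channels: dict[str, MuscleParams] | None = None,
) -> SyntheticDataset:
    """Generate the full experiment: subjects x profiles x trials.

    Per-trial random streams are derived deterministically from the master
    seed and the (subject, profile, trial) coordinates, so regeneration
    with the same seed is bit-identical and independent of iteration order.
    """
    config = config or DatasetConfig()
    channels = channels or default_channels()
    trials: list[Trial] = []
    for s in range(config.n_subjects):
        for p_idx, kind in enumerate(config.profiles):
            spec = config.profile_spec(kind)
            for t_idx in range(config.n_trials):
                ss = np.random.SeedSequence([seed, s, p_idx, t_idx])
                trial_seed = int(ss.generate_state(1)[0] % (2**31))
                rng = np.random.default_rng(ss)
                force = gen_force_profile(spec, rng=rng)
                # per-trial session variability: small lognormal gain jitter
                jitter = {label: MuscleParams(
                            gain=mp.gain * float(np.exp(config.gain_jitter
                                                        * rng.standard_normal())),
                            gamma=mp.gamma, noise_floor=mp.noise_floor,
                            band=mp.band, hysteresis_tau=mp.hysteresis_tau)
                          for label, mp in channels.items()}
                emg = gen_emg_from_force(force, jitter, seed=rng, f_max=config.peak)
                measured = force.with_samples(
                    np.clip(force.samples
                            + config.force_noise_n * rng.standard_normal(len(force)),
                            0.0, None))
                trials.append(Trial(subject=s, profile_kind=kind, index=t_idx,
                                    seed=trial_seed,
                                    emg={tr.label: tr for tr in emg},
                                    force=measured))
    return SyntheticDataset(trials=trials, config=config, channels=channels,
                            master_seed=seed)
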