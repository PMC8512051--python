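"""Synthetic wearable-accelerometer trials for fall-detection experiments.

Real fall corpora (e.g. SisFall: waist-worn tri-axial accelerometer sampled
at 200 Hz, many ADL recordings per fall recording) cannot be redistributed
here, so this module generates trials with the same *structure*: activities
of daily life (ADL) whose signal-magnitude-vector (SMV) peak stays within a
bounded envelope around gravity, and falls showing the canonical two-stage
signature — a free-fall interval where the SMV drops toward zero followed by
a single dominant impact peak well above the ADL range — with a configurable
class-imbalance ratio.

Signals are in m/s^2 by default (gravity = 9.81). Only the first three
channels (accelerometer x, y, z) carry signal; extra channels, if requested,
are zero-filled, mirroring multi-sensor recordings where downstream stages
use the primary accelerometer only.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

GRAVITY = 9.81  # m/s^2

DEFAULT_ADL_KINDS = ("standing", "sitting", "walking", "jogging")
DEFAULT_FALL_KINDS = ("forward_fall", "backward_fall", "lateral_fall")

# Per-kind oscillation around gravity: (fundamental frequency Hz, amplitude
# as a fraction of the headroom between gravity and the ADL peak cap).
_ADL_PROFILES = {
    "standing": (0.3, 0.02),
    "sitting": (0.2, 0.02),
    "walking": (2.0, 0.35),
    "jogging": (2.8, 0.75),
}


class SimulationError(ValueError):
    """Invalid simulation request (unknown kind, bad duration, ...)."""


@dataclass(frozen=True)
class SensorTrial:
    """One recorded or simulated activity trial.

    samples is a (n_timesteps, n_channels) float array; channels 0..2 are
    accelerometer x, y, z in ``unit``.
    """

    samples: np.ndarray
    fs: float
    activity_class: str
    trial_id: str
    seed: int | None = None
    unit: str = "m/s2"

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 2 or samples.shape[1] < 3:
            raise SimulationError(
                f"trial {self.trial_id!r}: samples must be (n, >=3), got {samples.shape}"
            )
        if not self.fs > 0:
            raise SimulationError(f"trial {self.trial_id!r}: fs must be > 0")
        object.__setattr__(self, "samples", samples)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class SimulationConfig:
    """Corpus-level generation settings.

    ``impact_peak_range`` and ``adl_peak_range`` (m/s^2) must be disjoint
    with the impact range above the ADL range, so the two classes are
    separable in per-trial SMVmax — the property real fall corpora exhibit
    and threshold-style detectors exploit.
    """

    n_adl: int = 100
    n_fall: int = 10
    fs: float = 200.0
    adl_kinds: tuple[str, ...] = DEFAULT_ADL_KINDS
    fall_kinds: tuple[str, ...] = DEFAULT_FALL_KINDS
    noise_sd: float = 0.3
    impact_peak_range: tuple[float, float] = (30.0, 60.0)
    adl_peak_range: tuple[float, float] = (9.9, 25.0)
    adl_duration_s: float = 10.0
    fall_duration_s: float = 12.0
    n_channels: int = 3
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_adl < 0 or self.n_fall < 0 or self.n_adl + self.n_fall < 1:
            raise SimulationError("need n_adl >= 0, n_fall >= 0, n_adl + n_fall >= 1")
        if not self.impact_peak_range[0] > self.adl_peak_range[1]:
            raise SimulationError(
                "impact_peak_range.lo must exceed adl_peak_range.hi "
                "(classes must be separable in SMVmax)"
            )
        if self.n_adl > 0 and not self.adl_kinds:
            raise SimulationError("n_adl > 0 but adl_kinds is empty")
        if self.n_fall > 0 and not self.fall_kinds:
            raise SimulationError("n_fall > 0 but fall_kinds is empty")

    @property
    def imbalance_ratio(self) -> float:
        if self.n_fall == 0:
            return float("inf")
        return self.n_adl / self.n_fall


def _check_positive(duration_s: float, fs: float) -> None:
    if not duration_s > 0:
        raise SimulationError(f"duration_s must be > 0, got {duration_s}")
    if not fs > 0:
        raise SimulationError(f"fs must be > 0, got {fs}")


def _tilted_gravity_direction(rng: np.random.Generator, max_tilt_deg: float = 25.0) -> np.ndarray:
    """Unit vector near +z: sensor orientation varies between wearings."""
    tilt = np.deg2rad(rng.uniform(0.0, max_tilt_deg))
    azim = rng.uniform(0.0, 2.0 * np.pi)
    return np.array(
        [np.sin(tilt) * np.cos(azim), np.sin(tilt) * np.sin(azim), np.cos(tilt)]
    )


def _compose(
    magnitude: np.ndarray,
    direction: np.ndarray,
    rng: np.random.Generator,
    noise_sd: float,
    n_channels: int,
) -> np.ndarray:
    """Project a scalar SMV profile onto a 3D direction and add sensor noise."""
    n = magnitude.shape[0]
    acc = magnitude[:, None] * direction[None, :]
    acc = acc + rng.normal(0.0, noise_sd, size=(n, 3))
    if n_channels > 3:
        acc = np.hstack([acc, np.zeros((n, n_channels - 3))])
    return acc


def generate_adl_trial(
    kind: str,
    duration_s: float,
    fs: float = 200.0,
    seed: int = 0,
    *,
    adl_peak_range: tuple[float, float] = (9.9, 25.0),
    noise_sd: float = 0.3,
    n_channels: int = 3,
    trial_id: str | None = None,
) -> SensorTrial:
    """Generate one ADL trial whose SMV stays in a bounded envelope around gravity.

    Static kinds (standing, sitting) are gravity plus sensor noise; locomotion
    kinds (walking, jogging) add a periodic step oscillation whose amplitude is
    scaled so the per-trial SMVmax lands inside ``adl_peak_range``.
    Deterministic given ``seed``.
    """
    _check_positive(duration_s, fs)
    if kind not in _ADL_PROFILES:
        raise SimulationError(
            f"unknown ADL kind {kind!r}; known: {sorted(_ADL_PROFILES)}"
        )
    rng = np.random.default_rng(seed)
    n = round(duration_s * fs)
    t = np.arange(n) / fs

    lo, hi = adl_peak_range
    freq, amp_frac = _ADL_PROFILES[kind]
    # Leave a 4-sigma noise margin so additive noise cannot push SMVmax out.
    margin = 4.0 * noise_sd
    headroom = max(hi - margin - GRAVITY, 0.1)
    amp = amp_frac * headroom * rng.uniform(0.8, 1.0)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    # Step oscillation with a softer first harmonic; envelope varies slowly.
    envelope = 1.0 + 0.1 * np.sin(2.0 * np.pi * 0.2 * t + rng.uniform(0, 2 * np.pi))
    magnitude = GRAVITY + amp * envelope * (
        np.sin(2.0 * np.pi * freq * t + phase)
        + 0.3 * np.sin(2.0 * np.pi * 2.0 * freq * t + 2.0 * phase)
    ) / 1.3
    direction = _tilted_gravity_direction(rng)
    samples = _compose(magnitude, direction, rng, noise_sd, n_channels)
    return SensorTrial(
        samples=samples,
        fs=fs,
        activity_class=kind,
        trial_id=trial_id or f"adl_{kind}_{seed}",
        seed=seed,
    )


def generate_fall_trial(
    kind: str,
    duration_s: float,
    fs: float = 200.0,
    seed: int = 0,
    *,
    impact_peak_range: tuple[float, float] = (30.0, 60.0),
    noise_sd: float = 0.3,
    n_channels: int = 3,
    trial_id: str | None = None,
) -> SensorTrial:
    """Generate one fall trial with the two-stage free-fall/impact signature.

    The SMV profile is, in order: pre-fall walking around gravity, a free-fall
    interval decaying toward ~0, a single sharp impact peak (the global SMV
    maximum, inside ``impact_peak_range``), a short damped bounce, then
    low-motion rest (lying still at gravity). Deterministic given ``seed``.
    """
    _check_positive(duration_s, fs)
    if duration_s < 3.0:
        raise SimulationError(
            f"fall trials must be >= 3 s so a peak-centred 3 s segment exists; got {duration_s}"
        )
    known = set(DEFAULT_FALL_KINDS)
    if kind not in known:
        raise SimulationError(f"unknown fall kind {kind!r}; known: {sorted(known)}")
    rng = np.random.default_rng(seed)
    n = round(duration_s * fs)
    t = np.arange(n) / fs

    lo, hi = impact_peak_range
    margin = 4.0 * noise_sd
    peak = rng.uniform(lo + margin, max(hi - margin, lo + margin + 0.1))

    # Phase boundaries (seconds); impact sits past the midpoint so the
    # peak-centred 3 s extraction exercises the interior case.
    t_ff_start = 0.55 * duration_s + rng.uniform(-0.05, 0.05) * duration_s
    ff_dur = rng.uniform(0.30, 0.45)
    impact_dur = 0.05  # 50 ms half-sine: sharp, unique argmax
    bounce_dur = 0.30
    t_impact = t_ff_start + ff_dur
    t_rest = t_impact + impact_dur + bounce_dur

    magnitude = np.empty(n)
    pre = t < t_ff_start
    walk_amp = rng.uniform(2.0, 4.0)
    phase = rng.uniform(0, 2 * np.pi)
    magnitude[pre] = GRAVITY + walk_amp * np.sin(2 * np.pi * 2.0 * t[pre] + phase)

    ff = (t >= t_ff_start) & (t < t_impact)
    dip_min = rng.uniform(0.3, 1.5)
    frac = (t[ff] - t_ff_start) / ff_dur
    magnitude[ff] = GRAVITY + (dip_min - GRAVITY) * np.sin(0.5 * np.pi * frac) ** 2 / (
        np.sin(0.5 * np.pi) ** 2
    )
    # Hold near the dip floor at the end of free fall.
    magnitude[ff] = np.minimum(magnitude[ff], GRAVITY)

    imp = (t >= t_impact) & (t < t_impact + impact_dur)
    frac = (t[imp] - t_impact) / impact_dur
    magnitude[imp] = dip_min + (peak - dip_min) * np.sin(np.pi * frac)

    bounce = (t >= t_impact + impact_dur) & (t < t_rest)
    frac = (t[bounce] - (t_impact + impact_dur)) / bounce_dur
    magnitude[bounce] = GRAVITY + 0.25 * (peak - GRAVITY) * np.exp(-5.0 * frac) * np.cos(
        2 * np.pi * 8.0 * frac
    )

    rest = t >= t_rest
    magnitude[rest] = GRAVITY

    # Guarantee a unique global argmax at the impact crest even under noise:
    # the half-sine is sampled sharply, but the exact crest sample may tie on
    # coarse grids, so nudge the analytic crest sample to the target peak.
    crest = int(np.argmax(magnitude))
    magnitude[crest] = peak

    direction = _tilted_gravity_direction(rng)
    samples = _compose(magnitude, direction, rng, noise_sd, n_channels)
    return SensorTrial(
        samples=samples,
        fs=fs,
        activity_class=kind,
        trial_id=trial_id or f"fall_{kind}_{seed}",
        seed=seed,
    )


def generate_corpus(config: SimulationConfig) -> tuple[list[SensorTrial], pd.DataFrame]:
    """Generate n_adl ADL + n_fall fall trials with a reproducible manifest.

    Per-trial seeds are derived from ``master_seed`` via a seed sequence, so
    the whole corpus is byte-identical across runs with the same config.
    Kinds are assigned round-robin over the configured kind sets. The manifest
    records trial_id, activity_class, binary label, kind, fs, unit, seed and
    sample count, plus the corpus imbalance ratio as metadata.
    """
    ss = np.random.SeedSequence(config.master_seed)
    n_total = config.n_adl + config.n_fall
    seeds = [int(s) & 0x7FFFFFFF for s in ss.generate_state(n_total)]

    trials: list[SensorTrial] = []
    rows = []
    for i in range(config.n_adl):
        kind = config.adl_kinds[i % len(config.adl_kinds)]
        trial = generate_adl_trial(
            kind,
            config.adl_duration_s,
            config.fs,
            seeds[i],
            adl_peak_range=config.adl_peak_range,
            noise_sd=config.noise_sd,
            n_channels=config.n_channels,
            trial_id=f"adl_{i:05d}",
        )
        trials.append(trial)
        rows.append((trial.trial_id, kind, 0, config.fs, trial.unit, seeds[i], trial.n_samples))
    for j in range(config.n_fall):
        kind = config.fall_kinds[j % len(config.fall_kinds)]
        trial = generate_fall_trial(
            kind,
            config.fall_duration_s,
            config.fs,
            seeds[config.n_adl + j],
            impact_peak_range=config.impact_peak_range,
            noise_sd=config.noise_sd,
            n_channels=config.n_channels,
            trial_id=f"fall_{j:05d}",
        )
        trials.append(trial)
        rows.append(
            (trial.trial_id, kind, 1, config.fs, trial.unit, seeds[config.n_adl + j], trial.n_samples)
        )

    manifest = pd.DataFrame(
        rows,
        columns=["trial_id", "activity_class", "label", "fs", "unit", "seed", "n_samples"],
    )
    manifest.attrs["imbalance_ratio"] = config.imbalance_ratio
    return trials, manifest


# ---------------------------------------------------------------------------
# Trial file dialect: one CSV per trial (no header, one row per timestep,
# columns = channels) plus a manifest CSV.
# ---------------------------------------------------------------------------

def write_corpus(trials: Sequence[SensorTrial], manifest: pd.DataFrame, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = manifest.copy()
    paths = []
    for trial in trials:
        path = out_dir / f"{trial.trial_id}.csv"
        np.savetxt(path, trial.samples, delimiter=",", fmt="%.6f")
        paths.append(path.name)
    manifest["path"] = paths
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return out_dir


def read_corpus(in_dir: str | Path) -> tuple[list[SensorTrial], pd.DataFrame]:
    in_dir = Path(in_dir)
    manifest = pd.read_csv(in_dir / "manifest.csv")
    trials = []
    for row in manifest.itertuples():
        samples = np.loadtxt(in_dir / row.path, delimiter=",", ndmin=2)
        trials.append(
            SensorTrial(
                samples=samples,
                fs=float(row.fs),
                activity_class=str(row.activity_class),
                trial_id=str(row.trial_id),
                seed=int(row.seed),
                unit=str(row.unit),
            )
        )
    return trials, manifest
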