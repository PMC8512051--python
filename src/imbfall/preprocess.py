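"""Turn raw trials into labeled fixed-length windows.

Pipeline: signal-magnitude-vector (SMV) computation, 3 s peak-centred
extraction of fall trials (the informative part of a long fall recording is
the free-fall/impact neighbourhood of the SMV peak), 1 s sliding-window
augmentation, binary labeling (0 = ADL, 1 = fall), and a stratified
6:2:2 train/validation/test split.

Windows use 0-based, half-open [start, start+W) indexing; argmax ties break
to the first occurrence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .simulate import SensorTrial


class PreprocessError(ValueError):
    """Invalid preprocessing request."""


@dataclass(frozen=True)
class WindowedSample:
    """A fixed-length window cut from a trial, with its binary label.

    window is (n_timesteps, n_channels); label is 0 for ADL, 1 for fall and
    is determined solely by the source trial's activity class.
    """

    window: np.ndarray
    label: int
    source_trial: str
    offset: int


@dataclass
class SplitCorpus:
    """Disjoint train/validation/test partitions of windowed samples."""

    train: list[WindowedSample]
    validation: list[WindowedSample]
    test: list[WindowedSample]
    ratio: tuple[float, float, float] = (6.0, 2.0, 2.0)
    seed: int | None = None

    def class_counts(self, split: str) -> dict[int, int]:
        part: list[WindowedSample] = getattr(self, split)
        counts: dict[int, int] = {0: 0, 1: 0}
        for w in part:
            counts[w.label] = counts.get(w.label, 0) + 1
        return counts

    @property
    def n_total(self) -> int:
        return len(self.train) + len(self.validation) + len(self.test)


def smv(ax, ay, az):
    """Signal magnitude vector: Euclidean norm of the tri-axial acceleration.

    Accepts scalars or arrays (elementwise); the result carries the input
    unit. Raises on non-finite input.
    """
    ax = np.asarray(ax, dtype=float)
    ay = np.asarray(ay, dtype=float)
    az = np.asarray(az, dtype=float)
    if not (np.all(np.isfinite(ax)) and np.all(np.isfinite(ay)) and np.all(np.isfinite(az))):
        raise PreprocessError("smv: non-finite acceleration input")
    out = np.sqrt(ax * ax + ay * ay + az * az)
    return float(out) if out.ndim == 0 else out


def smv_trace(trial: SensorTrial) -> np.ndarray:
    """Per-timestep SMV over the trial's first three channels."""
    s = trial.samples
    return smv(s[:, 0], s[:, 1], s[:, 2])


def smv_max(trial: SensorTrial) -> tuple[float, int]:
    """Maximum SMV over the trial and the (first) index attaining it."""
    if trial.n_samples == 0:
        raise PreprocessError("smv_max: empty trial")
    trace = smv_trace(trial)
    idx = int(np.argmax(trace))  # np.argmax returns the first maximizer
    return float(trace[idx]), idx


def extract_fall_segment(trial: SensorTrial, span_s: float = 3.0) -> SensorTrial:
    """Contiguous ``span_s`` segment centred on the trial's SMV peak.

    When the peak lies within span/2 of either edge the segment is shifted
    toward the interior rather than shrunk, so segments are always full
    length and the parent's global SMV maximum is always inside.
    """
    n_seg = round(span_s * trial.fs)
    if trial.n_samples < n_seg:
        raise PreprocessError(
            f"trial {trial.trial_id!r} has {trial.n_samples} samples, "
            f"shorter than the {n_seg}-sample extraction span"
        )
    _, peak = smv_max(trial)
    start = peak - n_seg // 2
    start = min(max(start, 0), trial.n_samples - n_seg)
    return SensorTrial(
        samples=trial.samples[start : start + n_seg],
        fs=trial.fs,
        activity_class=trial.activity_class,
        trial_id=trial.trial_id,
        seed=trial.seed,
        unit=trial.unit,
    )


def sliding_windows(
    segment: SensorTrial,
    label: int,
    width_s: float = 1.0,
    stride_s: float = 0.5,
) -> list[WindowedSample]:
    """Cut a trial/segment into overlapping fixed-width windows.

    Windows start at offsets 0, S, 2S, ... ; the count is
    floor((L - W)/S) + 1 (trailing partial windows dropped); every window
    inherits the given label.
    """
    if not stride_s > 0:
        raise PreprocessError("stride_s must be > 0")
    w = round(width_s * segment.fs)
    s = round(stride_s * segment.fs)
    n = segment.n_samples
    if w > n:
        raise PreprocessError(
            f"window width {w} exceeds segment length {n} (trial {segment.trial_id!r})"
        )
    count = (n - w) // s + 1
    return [
        WindowedSample(
            window=segment.samples[off : off + w],
            label=label,
            source_trial=segment.trial_id,
            offset=off,
        )
        for off in (i * s for i in range(count))
    ]


def imbalance_ratio(n_majority: int, n_minority: int) -> float:
    """Majority-class count over minority-class count (the caller orders them)."""
    if n_minority <= 0:
        raise PreprocessError("imbalance_ratio: minority count must be > 0")
    return n_majority / n_minority


def windows_from_trials(
    trials: Iterable[SensorTrial],
    labels: Iterable[int],
    width_s: float = 1.0,
    stride_s: float = 0.5,
    fall_span_s: float = 3.0,
) -> list[WindowedSample]:
    """Window a whole corpus: ADL trials over their full length, fall trials
    over the ``fall_span_s`` peak-centred segment only."""
    out: list[WindowedSample] = []
    for trial, label in zip(trials, labels):
        src = extract_fall_segment(trial, fall_span_s) if label == 1 else trial
        out.extend(sliding_windows(src, label, width_s, stride_s))
    return out


def split_corpus(
    windows: Sequence[WindowedSample],
    ratio: tuple[float, float, float] = (6.0, 2.0, 2.0),
    seed: int = 0,
) -> SplitCorpus:
    """Random stratified train/validation/test split.

    Each class is shuffled with the given seed and cut proportionally, so
    per-split class proportions match the corpus within one window and the
    minority class cannot vanish from a split at high imbalance. Splits are
    disjoint and their union is the input.
    """
    if any(r <= 0 for r in ratio):
        raise PreprocessError("split ratio entries must be positive")
    total = float(sum(ratio))
    fracs = np.array(ratio, dtype=float) / total
    rng = np.random.default_rng(seed)

    parts: tuple[list[WindowedSample], ...] = ([], [], [])
    for label in sorted({w.label for w in windows}):
        idx = np.array([i for i, w in enumerate(windows) if w.label == label])
        rng.shuffle(idx)
        n = len(idx)
        n_train = round(n * fracs[0])
        n_val = round(n * (fracs[0] + fracs[1])) - n_train
        cuts = (idx[:n_train], idx[n_train : n_train + n_val], idx[n_train + n_val :])
        for part, cut in zip(parts, cuts):
            part.extend(windows[i] for i in cut)
    return SplitCorpus(train=parts[0], validation=parts[1], test=parts[2], ratio=ratio, seed=seed)


def stack_windows(windows: Sequence[WindowedSample]) -> tuple[np.ndarray, np.ndarray]:
    """Windows -> (X, y) with X channel-major (n, channels, timesteps)."""
    if len(windows) == 0:
        return np.zeros((0, 0, 0)), np.zeros((0,), dtype=int)
    X = np.stack([w.window.T for w in windows]).astype(float)
    y = np.array([w.label for w in windows], dtype=int)
    return X, y
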