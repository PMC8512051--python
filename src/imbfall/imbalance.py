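"""Class-imbalance handling: output-threshold moving and comparison strategies.

The centrepiece is output-threshold moving: a classifier trained on
imbalanced data under-predicts the minority (fall) class, so instead of the
default 0.5 cutoff on the minority posterior the decision threshold λ is
moved toward the minority class. Two routes are provided:

* empirical: λ̂ = argmin_λ |f − f_λ|, where f is the minority frequency in
  the training set and f_λ the fraction of held-out posteriors at or above
  λ — the threshold that matches the predicted class distribution to the
  training distribution;
* closed form: λ* = k·exp(−ρ/(10k)) + k/10, a fitted map from the imbalance
  ratio ρ to the threshold (k is the default threshold, usually 0.5). λ*
  decays from ≈k at ρ=0 toward k/10 as ρ→∞; at ρ≈11 it is ≈0.1.

Also implemented, as runnable comparators: inverse-frequency class weights,
focal loss, and SMOTE minority oversampling.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .preprocess import SplitCorpus, WindowedSample


class ImbalanceError(ValueError):
    pass


@dataclass(frozen=True)
class ThresholdPolicy:
    """A decision threshold on the minority-class posterior, with provenance."""

    lam: float
    k: float = 0.5
    rho: float | None = None
    provenance: str = "default"  # default | empirical | closed_form

    def __post_init__(self) -> None:
        if not 0.0 < self.lam < 1.0:
            raise ImbalanceError(f"threshold must lie in (0,1), got {self.lam}")

    def to_text(self) -> str:
        lines = [f"lambda={self.lam!r}", f"k={self.k!r}", f"provenance={self.provenance}"]
        if self.rho is not None:
            lines.insert(2, f"rho={self.rho!r}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "ThresholdPolicy":
        kv = dict(line.split("=", 1) for line in text.strip().splitlines())
        return cls(
            lam=float(kv["lambda"]),
            k=float(kv["k"]),
            rho=float(kv["rho"]) if "rho" in kv else None,
            provenance=kv.get("provenance", "default"),
        )


def minority_frequency(split: SplitCorpus) -> float:
    """Frequency f of minority (fall, label 1) samples in the train split."""
    labels = np.array([w.label for w in split.train])
    if labels.size == 0:
        raise ImbalanceError("empty train split")
    return float((labels == 1).mean())


def default_grid(posteriors: np.ndarray | None = None) -> np.ndarray:
    """Candidate thresholds: a 0.01 lattice over (0,1) plus the observed
    posterior values, so the empirical search is exact and reproducible."""
    grid = np.arange(0.01, 1.0, 0.01)
    if posteriors is not None:
        obs = np.asarray(posteriors, dtype=float)
        obs = obs[(obs > 0.0) & (obs < 1.0)]
        grid = np.union1d(grid, obs)
    return grid


def empirical_threshold(
    posteriors: np.ndarray,
    f: float,
    grid: np.ndarray | None = None,
) -> ThresholdPolicy:
    """λ̂ = argmin over the grid of |f − f_λ|, f_λ = fraction of minority
    posteriors ≥ λ. Ties break to the smallest λ."""
    p = np.asarray(posteriors, dtype=float).ravel()
    if p.size == 0:
        raise ImbalanceError("empirical_threshold: empty posterior batch")
    grid = default_grid(p) if grid is None else np.sort(np.asarray(grid, dtype=float))
    if grid.size == 0 or grid.min() <= 0.0 or grid.max() >= 1.0:
        raise ImbalanceError("grid must be non-empty with values in (0,1)")
    f_lam = (p[None, :] >= grid[:, None]).mean(axis=1)
    best = int(np.argmin(np.abs(f - f_lam)))  # argmin takes the first == smallest λ
    return ThresholdPolicy(lam=float(grid[best]), provenance="empirical")


def closed_form_threshold(rho: float, k: float = 0.5) -> ThresholdPolicy:
    """λ* = k·exp(−ρ/(10k)) + k/10.

    Strictly decreasing in the imbalance ratio ρ; λ* → k/10 as ρ → ∞;
    λ* = k(1 + 1/10) at ρ = 0. At ρ = 11.23, k = 0.5: λ* ≈ 0.103.
    """
    if rho < 0:
        raise ImbalanceError("imbalance ratio must be >= 0")
    if not 0.0 < k < 1.0:
        raise ImbalanceError("default threshold k must lie in (0,1)")
    lam = k * np.exp(-rho / (10.0 * k)) + k / 10.0
    return ThresholdPolicy(lam=float(lam), k=k, rho=float(rho), provenance="closed_form")


def apply_threshold(posteriors: np.ndarray, policy: ThresholdPolicy) -> np.ndarray:
    """Label 1 (fall) iff the minority posterior is ≥ λ; order-preserving.

    Accepts either a 1D array of minority posteriors or a (n, 2) posterior
    batch whose column 1 is the minority class.
    """
    p = np.asarray(posteriors, dtype=float)
    if p.ndim == 2:
        p = p[:, 1]
    return (p >= policy.lam).astype(int)


def class_weights(split: SplitCorpus) -> np.ndarray:
    """Inverse-frequency loss weights w_c = n_total / (2 n_c), indexed by
    label; the frequency-weighted mean over training samples is 1."""
    labels = np.array([w.label for w in split.train])
    counts = np.array([(labels == 0).sum(), (labels == 1).sum()], dtype=float)
    if np.any(counts == 0):
        raise ImbalanceError("class_weights: both classes must be present")
    return labels.size / (2.0 * counts)


def focal_loss(posterior, true_label, gamma: float = 2.0, alpha: float = 0.75):
    """Focal loss −α_t (1−p_t)^γ log(p_t) of a minority posterior.

    p_t is the posterior of the true class (the minority posterior for label
    1, its complement for label 0); α_t = α for the minority, 1−α otherwise.
    γ = 0 recovers the α-weighted cross-entropy. Scalar or elementwise.
    """
    p = np.asarray(posterior, dtype=float)
    y = np.asarray(true_label)
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ImbalanceError("posterior must lie strictly in (0,1)")
    pt = np.where(y == 1, p, 1.0 - p)
    at = np.where(y == 1, alpha, 1.0 - alpha)
    out = -at * (1.0 - pt) ** gamma * np.log(pt)
    return float(out) if out.ndim == 0 else out


def smote_windows(
    minority_windows: Sequence[WindowedSample],
    n_new: int,
    k_neighbors: int = 5,
    seed: int = 0,
) -> list[WindowedSample]:
    """Synthetic minority oversampling: each new window is x + u·(x_nn − x)
    with u ~ Uniform(0,1) and x_nn one of x's k nearest minority neighbours
    under Euclidean distance on the flattened window."""
    if n_new == 0:
        return []
    m = len(minority_windows)
    if m <= k_neighbors:
        raise ImbalanceError(
            f"need more than k_neighbors={k_neighbors} minority windows, have {m}"
        )
    rng = np.random.default_rng(seed)
    flat = np.stack([w.window.ravel() for w in minority_windows])
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(flat)
    _, idx = nn.kneighbors(flat)  # column 0 is the point itself
    shape = minority_windows[0].window.shape
    out = []
    for j in range(n_new):
        i = int(rng.integers(m))
        neighbor = int(idx[i, 1 + rng.integers(k_neighbors)])
        u = rng.uniform()
        synth = flat[i] + u * (flat[neighbor] - flat[i])
        out.append(
            WindowedSample(
                window=synth.reshape(shape),
                label=1,
                source_trial=f"smote:{minority_windows[i].source_trial}",
                offset=-1,
            )
        )
    return out
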