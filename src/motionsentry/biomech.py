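"""Energy-based anomaly scoring and biomechanical feature refinement.

The scoring pipeline has two complementary references, both reported:

* a *per-joint window baseline* — the mean energy over a short reference
  window of normal motion — from which the absolute anomaly score
  S_t^j = |E_t^j - baseline_j| is computed (the localization signal);
* *population statistics* mu_E, sigma_E estimated from a corpus of normal
  motion, giving the calibrated z-score z = (E - mu_E) / sigma_E whose
  |z| >= 2.5 threshold corresponds to a 98.8% two-sided Gaussian interval.

The sigmoid confidence beta = 1 / (1 + exp(-z)) maps deviations into (0, 1),
0.5 at typical behavior, and rescales fused features joint-wise so that
statistically unlikely joints are attenuated downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erf, expit

from . import _ops as am
from .motion import EnergyProfile

Z_THRESHOLD = 2.5
SIGMA_FLOOR = 1e-6  # joules; below this a training corpus is degenerate
DEFAULT_WINDOW = 50  # frames (~2 s at 25 Hz)


def gaussian_inlier_mass(threshold: float = Z_THRESHOLD) -> float:
    """Two-sided standard-normal mass inside |z| <= threshold (exact, via erf)."""
    return float(erf(threshold / np.sqrt(2.0)))


@dataclass
class BaselineStats:
    """Reference-window baseline plus population energy statistics.

    ``mu`` and ``sigma`` may be per-joint vectors (default) or scalars when
    pooled across joints.
    """

    window: tuple[int, int]  # [start, stop) frame range of the reference window
    expected_energy: np.ndarray  # (J,) mean energy over the window
    mu: np.ndarray  # per-joint (J,) or scalar population mean
    sigma: np.ndarray  # same shape as mu, >= SIGMA_FLOOR

    def __post_init__(self):
        start, stop = self.window
        if stop - start < 2:
            raise ValueError("reference window must span at least 2 frames")
        self.expected_energy = np.asarray(self.expected_energy, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if np.any(self.sigma < SIGMA_FLOOR):
            raise ValueError(
                f"sigma below the {SIGMA_FLOOR} J floor: degenerate normal corpus"
            )


def expected_energy(profile: EnergyProfile, window: tuple[int, int]) -> np.ndarray:
    """Per-joint mean energy over the reference window [start, stop)."""
    start, stop = window
    T = profile.energy.shape[0]
    if not (0 <= start < stop <= T):
        raise ValueError(f"window {window} out of range for T={T}")
    if stop - start < 2:
        raise ValueError("reference window must span at least 2 frames")
    return profile.energy[start:stop].mean(axis=0)


def fit_baseline_stats(
    profiles: list[EnergyProfile],
    window: tuple[int, int] = (0, DEFAULT_WINDOW),
    pooled: bool = False,
) -> BaselineStats:
    """Estimate population mu_E, sigma_E from a corpus of normal-motion energies.

    Per-joint statistics by default; ``pooled=True`` collapses joints into a
    single population. The window baseline comes from the first profile.
    """
    if not profiles:
        raise ValueError("need at least one normal energy profile")
    stacked = np.concatenate([p.energy for p in profiles], axis=0)  # (sum T, J)
    if pooled:
        mu = stacked.mean()
        sigma = stacked.std()
    else:
        mu = stacked.mean(axis=0)
        sigma = stacked.std(axis=0)
    sigma = np.maximum(sigma, 0.0)
    start = min(window[0], profiles[0].energy.shape[0] - 2)
    stop = min(window[1], profiles[0].energy.shape[0])
    base = expected_energy(profiles[0], (start, stop))
    return BaselineStats(window=(start, stop), expected_energy=base, mu=mu, sigma=sigma)


def anomaly_score(profile: EnergyProfile, baseline: np.ndarray) -> np.ndarray:
    """S_t^j = |E_t^j - baseline_j|, (T, J), nonnegative."""
    return np.abs(profile.energy - np.asarray(baseline)[None, :])


def zscore(profile: EnergyProfile, stats: BaselineStats) -> np.ndarray:
    """(E - mu_E) / sigma_E against the population statistics, (T, J)."""
    return (profile.energy - stats.mu) / stats.sigma


def confidence_weight(z):
    """beta = sigmoid(z), elementwise, strictly increasing, 0.5 at z = 0."""
    if am.is_tensor(z):
        return am.sigmoid(z)
    return expit(np.asarray(z, dtype=float))


def flag_anomalies(z: np.ndarray, z_threshold: float = Z_THRESHOLD):
    """Threshold |z| >= z_threshold (inclusive).

    Returns ``(flags, summary)``: a (T, J) boolean map and a list of flagged
    ``(joint, frame, z)`` records sorted by |z| descending, ties broken by
    (frame, joint) ascending.
    """
    z = np.asarray(z, dtype=float)
    flags = np.abs(z) >= z_threshold
    t_idx, j_idx = np.nonzero(flags)
    records = sorted(
        zip(j_idx.tolist(), t_idx.tolist(), z[t_idx, j_idx].tolist()),
        key=lambda r: (-abs(r[2]), r[1], r[0]),
    )
    summary = [
        {"joint": j, "frame": t, "z": zval} for j, t, zval in records
    ]
    return flags, summary


def refine_features(x_fused, beta, neutral_rescale: bool = False):
    """Joint-wise confidence rescaling of fused features.

    ``x_fused`` is (T, J, F), ``beta`` (T, J); beta broadcasts across channels.
    With ``neutral_rescale`` the factor is 2*beta, making z = 0 the identity
    (otherwise a perfectly typical joint is scaled by 0.5, which downstream
    linear layers absorb).
    """
    if am.asdata(x_fused).shape[:2] != am.asdata(beta).shape:
        raise ValueError("beta must be (T, J) matching the fused features")
    factor = beta * 2.0 if neutral_rescale else beta
    if am.is_tensor(x_fused) or am.is_tensor(beta):
        return x_fused * factor.reshape(factor.shape + (1,)) if am.is_tensor(
            factor
        ) else x_fused * am.asdata(factor)[:, :, None]
    return x_fused * np.asarray(factor)[:, :, None]


def energy_smoothness_reg(energy):
    """sum_t sum_j (E_t^j - E_{t+1}^j)^2 — penalizes high-frequency energy jumps."""
    E = energy.energy if isinstance(energy, EnergyProfile) else energy
    if am.asdata(E).shape[0] < 2:
        return 0.0
    d = E[1:] - E[:-1]
    return am.summation(d * d)
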