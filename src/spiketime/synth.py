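"""Synthetic data with the statistical structure of real recordings.

Emulates the canonical systems-neuroscience fixtures: a freely rotating
head direction following a wrapped Gaussian random walk, an ensemble of
von Mises-tuned units firing as inhomogeneous Poisson processes driven by
that trajectory, and single-exponential calcium-like fluorescence traces.
Ground-truth tuning parameters are returned so parameter-recovery tests
(preferred direction, decoding error) can be scored against truth.

All generators are deterministic under a fixed seed; multi-unit
simulations draw per-unit child seeds from one ``numpy.random.SeedSequence``
so each unit is reproducible on its own.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import EpochSet, TimestampSeries, ValuedSeries
from .group import EventGroup

__all__ = [
    "VonMisesTuning",
    "simulate_hd_trajectory",
    "simulate_poisson_from_rate",
    "make_hd_population",
    "make_calcium_trace",
]

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class VonMisesTuning:
    """Circular tuning: f(θ) = r_base + (r_max − r_base)·exp(κ(cos(θ−μ) − 1)).

    ``f(mu) = r_max``; for κ=0 the curve is flat at ``r_max``. All rates in
    events/s, ``mu`` in radians, ``kappa`` ≥ 0 (dimensionless concentration).
    """
    mu: float
    kappa: float
    r_max: float
    r_base: float = 0.5

    def __post_init__(self):
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.r_max < self.r_base or self.r_base < 0:
            raise ValueError("need 0 <= r_base <= r_max")

    def rate_at(self, theta) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        return self.r_base + (self.r_max - self.r_base) * np.exp(
            self.kappa * (np.cos(theta - self.mu) - 1.0))


def simulate_hd_trajectory(duration: float, dt: float, sigma: float = 1.2,
                           seed=None, theta0: float = 0.0) -> ValuedSeries:
    """Head-direction angle as a wrapped Gaussian random walk on [0, 2π).

    θ_{k+1} = wrap(θ_k + N(0, σ²·dt)); ``sigma`` is the angular diffusion in
    rad/√s. The default 1.2 rad/√s explores the full circle many times over
    a few minutes, as a foraging rodent's heading does.
    """
    if duration <= 0 or dt <= 0 or sigma <= 0:
        raise ValueError("duration, dt and sigma must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration / dt))
    steps = rng.normal(0.0, sigma * np.sqrt(dt), size=n - 1)
    theta = np.mod(theta0 + np.concatenate([[0.0], np.cumsum(steps)]), TWO_PI)
    times = np.arange(n) * dt
    return ValuedSeries(times, theta,
                        time_support=EpochSet([0.0], [duration]))


def simulate_poisson_from_rate(rate: ValuedSeries, seed=None) -> TimestampSeries:
    """Inhomogeneous Poisson spike train by thinning.

    The instantaneous rate is held piecewise constant at the left sample
    between rate samples. Homogeneous candidates at the peak rate are drawn
    over each support interval and accepted with probability r(t)/r_max —
    exact for a piecewise-constant rate.
    """
    if len(rate) == 0:
        return TimestampSeries([], time_support=rate.time_support)
    if np.any(rate.values < 0):
        raise ValueError("rates must be non-negative")
    rng = np.random.default_rng(seed)
    rmax = float(np.max(rate.values))
    support = rate.time_support
    if rmax == 0.0:
        return TimestampSeries([], time_support=support)
    spikes = []
    for s, e in support:
        n = rng.poisson(rmax * (e - s))
        cand = np.sort(rng.uniform(s, e, size=n))
        idx = np.searchsorted(rate.times, cand, side="right") - 1
        ok = idx >= 0
        r = np.zeros(cand.size)
        r[ok] = rate.values[idx[ok]]
        keep = rng.uniform(0.0, rmax, size=n) < r
        spikes.append(cand[keep])
    times = np.concatenate(spikes) if spikes else np.array([])
    return TimestampSeries(np.sort(times), time_support=support)


def make_hd_population(n_units: int, duration: float, dt: float = 0.05,
                       tunings="random", sigma: float = 1.2, seed=None,
                       kappa_range=(2.0, 6.0), r_max_range=(8.0, 25.0),
                       r_base: float = 0.5):
    """Simulate an ensemble of head-direction cells.

    Returns ``(group, trajectory, tunings)``: an :class:`EventGroup` of
    Poisson spike trains driven by f_i(θ(t)), the angle trajectory, and the
    ground-truth :class:`VonMisesTuning` list. With ``tunings='random'``,
    preferred directions are evenly spaced around the circle (with a random
    common rotation) and κ, r_max are drawn uniformly from the given ranges —
    the regime of a typical thalamic head-direction ensemble.
    """
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    ss = np.random.SeedSequence(seed)
    traj_seed, rot_seed, *unit_seeds = ss.spawn(n_units + 2)
    traj = simulate_hd_trajectory(duration, dt, sigma, seed=traj_seed)
    if tunings == "random":
        rng = np.random.default_rng(rot_seed)
        mus = np.mod(np.arange(n_units) * TWO_PI / n_units
                     + rng.uniform(0, TWO_PI), TWO_PI)
        kappas = rng.uniform(*kappa_range, size=n_units)
        rmaxs = rng.uniform(*r_max_range, size=n_units)
        tunings = [VonMisesTuning(float(m), float(k), float(r), r_base)
                   for m, k, r in zip(mus, kappas, rmaxs)]
    else:
        tunings = list(tunings)
        if len(tunings) != n_units:
            raise ValueError("need one tuning per unit")
    units = {}
    for i, (tun, child) in enumerate(zip(tunings, unit_seeds)):
        rate = ValuedSeries(traj.times, tun.rate_at(traj.values),
                            time_support=traj.time_support)
        units[i] = simulate_poisson_from_rate(rate, seed=child)
    group = EventGroup(units, time_support=traj.time_support)
    return group, traj, tunings


def make_calcium_trace(spikes: TimestampSeries, tau_decay: float,
                       dt: float = 0.033, noise_sd: float = 0.0,
                       seed=None) -> ValuedSeries:
    """Fluorescence-like trace: unit-amplitude exponential transient per spike.

    The spike train is binned onto a grid with step ``dt`` over the spike
    train's time support, convolved with exp(−t/τ) (causal), and Gaussian
    noise of SD ``noise_sd`` added. A crude but standard surrogate for a
    slow calcium indicator; it ignores saturation and rise time.
    """
    if tau_decay <= 0 or dt <= 0:
        raise ValueError("tau_decay and dt must be positive")
    support = spikes.time_support
    if len(support) == 0:
        raise ValueError("spike train has empty time support")
    t0 = support.starts[0]
    t1 = support.ends[-1]
    n = int(np.floor((t1 - t0) / dt)) + 1
    times = t0 + np.arange(n) * dt
    impulses = np.zeros(n)
    if len(spikes):
        idx = np.clip(np.round((spikes.times - t0) / dt).astype(int), 0, n - 1)
        np.add.at(impulses, idx, 1.0)
    decay = np.exp(-dt / tau_decay)
    # recursive exponential filter: y[k] = impulses[k] + decay * y[k-1]
    from scipy.signal import lfilter
    trace = lfilter([1.0], [1.0, -decay], impulses)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        trace = trace + rng.normal(0.0, noise_sd, size=n)
    return ValuedSeries(times, trace, time_support=EpochSet([t0], [t1]))
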