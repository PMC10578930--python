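"""Shared fixtures and independent brute-force oracles.

The oracles here are deliberately naive (nested loops, boolean masks on a
1 ms lattice) and share no code with the library paths they check.
"""

import numpy as np
import pytest

from spiketime import EpochSet

# 1 ms lattice over [0, 100] s used by the interval-algebra mask oracle
LATTICE_N = 100_000
LATTICE_DT = 0.001


def ep_to_mask(ep: EpochSet) -> np.ndarray:
    """Boolean occupancy of each 1 ms lattice cell [k ms, (k+1) ms)."""
    mask = np.zeros(LATTICE_N, dtype=bool)
    for s, e in ep:
        mask[int(round(s / LATTICE_DT)):int(round(e / LATTICE_DT))] = True
    return mask


def mask_to_intervals(mask: np.ndarray):
    """(starts, ends) in seconds of the maximal runs of True cells."""
    d = np.diff(np.r_[0, mask.astype(int), 0])
    starts = np.nonzero(d == 1)[0] * LATTICE_DT
    ends = np.nonzero(d == -1)[0] * LATTICE_DT
    return starts, ends


def random_lattice_epochset(rng, max_intervals=20) -> EpochSet:
    """Random epoch set with endpoints on the 1 ms lattice in [0, 100] s."""
    n = rng.integers(1, max_intervals + 1)
    pts = np.sort(rng.choice(LATTICE_N + 1, size=2 * n, replace=False))
    return EpochSet(pts[0::2] * LATTICE_DT, pts[1::2] * LATTICE_DT)


# ---- naive nested-loop oracles for the core series methods ---------------

def oracle_restrict(times, ep):
    return np.array([t for t in times
                     if any(s <= t <= e for s, e in ep)])


def oracle_nearest(target_times, source_times, source_values):
    out = []
    for t in target_times:
        best, bi = None, None
        for j, s in enumerate(source_times):
            d = abs(t - s)
            if best is None or d < best:  # strict: earlier sample wins ties
                best, bi = d, j
        out.append(source_values[bi])
    return np.array(out)


def oracle_count(times, ep, b):
    centers, counts = [], []
    for s, e in ep:
        k = 0
        while s + (k + 1) * b <= e + 1e-12:
            lo, hi = s + k * b, s + (k + 1) * b
            counts.append(sum(1 for t in times if lo <= t < hi))
            centers.append(lo + b / 2)
            k += 1
    return np.array(centers), np.array(counts, dtype=float)


def oracle_threshold_support(times, values, level, mode):
    keep = [v > level if mode == "above" else v < level for v in values]
    runs, cur = [], None
    for t, k in zip(times, keep):
        if k:
            cur = [t, t] if cur is None else [cur[0], t]
        elif cur is not None:
            runs.append(cur)
            cur = None
    if cur is not None:
        runs.append(cur)
    return runs


@pytest.fixture(scope="session")
def hd_session_small():
    """A small simulated head-direction session shared across tests."""
    from spiketime import make_hd_population
    group, traj, tunings = make_hd_population(8, 120.0, dt=0.05, seed=42)
    return group, traj, tunings
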