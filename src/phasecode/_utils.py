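"""Small shared helpers: seeding, run-length encoding, angle conversion."""

from __future__ import annotations

import numpy as np

TWO_PI = 2.0 * np.pi


def as_rng(seed) -> np.random.Generator:
    """Accept an int seed, a SeedSequence, a Generator, or None."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn_seeds(master_seed: int, n: int) -> list[int]:
    """Derive ``n`` independent child seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def wrap_angle(theta: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles to (-pi, pi]."""
    wrapped = -(np.mod(-np.asarray(theta, dtype=float) + np.pi, TWO_PI) - np.pi)
    return wrapped


def deg_to_rad(deg):
    return np.deg2rad(deg)


def rad_to_deg_0_360(rad):
    """Radians -> degrees in [0, 360). Used only at reporting boundaries."""
    return np.mod(np.rad2deg(rad), 360.0)


def boolean_runs(mask: np.ndarray) -> np.ndarray:
    """Maximal contiguous True runs of a boolean vector.

    Returns an (n_runs, 2) int array of half-open [start, end) intervals.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return np.empty((0, 2), dtype=int)
    diff = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(diff == 1) + 1
    ends = np.flatnonzero(diff == -1) + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        ends = np.r_[ends, mask.size]
    return np.column_stack([starts, ends])


def split_runs_at(runs: np.ndarray, boundaries: np.ndarray) -> np.ndarray:
    """Split [start, end) runs at the given sorted boundary sample indices."""
    if len(runs) == 0 or len(boundaries) == 0:
        return runs
    out = []
    for start, end in runs:
        cuts = boundaries[(boundaries > start) & (boundaries < end)]
        edges = np.r_[start, cuts, end]
        for a, b in zip(edges[:-1], edges[1:]):
            out.append((int(a), int(b)))
    return np.array(out, dtype=int).reshape(-1, 2)
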