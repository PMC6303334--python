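"""Independent brute-force oracles shared by the test modules."""

import numpy as np

from morphosym.geometry import _center_and_scale


def rotate(x, t):
    c, s = np.cos(t), np.sin(t)
    return x @ np.array([[c, s], [-s, c]])


def best_angle_grid(x, target, refinements=8, width=60):
    """Grid-search (with nested refinement to ~1e-6 rad) for the rotation
    minimising ||rotate(x, t) - target||^2."""
    lo, hi = 0.0, 2 * np.pi
    best = 0.0
    for _ in range(refinements):
        grid = np.linspace(lo, hi, width)
        errs = [np.sum((rotate(x, t) - target) ** 2) for t in grid]
        b = int(np.argmin(errs))
        best = grid[b]
        step = grid[1] - grid[0]
        lo, hi = best - step, best + step
    return best


def gpa_grid_oracle(configs, n_sweeps=200):
    """Brute-force partial GPA: alternate grid-searched per-configuration
    rotations with consensus re-estimation; returns the residual SS."""
    pre = [_center_and_scale(np.asarray(c, float))[0] for c in configs]
    cons = pre[0]
    for _ in range(n_sweeps):
        aligned = [rotate(x, best_angle_grid(x, cons)) for x in pre]
        new, _ = _center_and_scale(np.mean(aligned, axis=0))
        done = np.sum((new - cons) ** 2) < 1e-16
        cons = new
        if done:
            break
    aligned = [rotate(x, best_angle_grid(x, cons)) for x in pre]
    return sum(np.sum((a - cons) ** 2) for a in aligned)
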