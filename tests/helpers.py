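"""Independent oracles used across the test suite.

Each function here recomputes a quantity by a route deliberately different
from the implementation under test: closed forms, exhaustive search, or
quadrature.
"""

import numpy as np
from skimage.filters import sobel


def three_point_stokes(i0, i60, i120):
    """Closed-form Stokes parameters from analyzer frames at 0/60/120 deg.

    For I(theta) = 0.5*(S0 + S1 cos 2theta + S2 sin 2theta), summing the
    three equally spaced measurements cancels the harmonics:
    S0 = (2/3)(I0+I60+I120), S1 = (4/3)(I0 - I60/2 - I120/2),
    S2 = (2/sqrt(3))(I60 - I120).
    """
    s0 = 2.0 / 3.0 * (i0 + i60 + i120)
    s1 = 4.0 / 3.0 * (i0 - 0.5 * i60 - 0.5 * i120)
    s2 = 2.0 / np.sqrt(3.0) * (i60 - i120)
    return s0, s1, s2


def exhaustive_shift_search(reference, moving, max_shift=10):
    """Brute-force integer translation maximizing gradient correlation.

    Scores every (dy, dx) in [-max_shift, max_shift]^2 on an interior crop
    (so wrap-around from np.roll never enters the score) and returns the
    argmax — the translation to apply to `moving` to align it.
    """
    r, m = sobel(reference), sobel(moving)
    interior = slice(max_shift, -max_shift)
    best, best_shift = -np.inf, (0, 0)
    for dy in range(-max_shift, max_shift + 1):
        rolled_y = np.roll(m, dy, axis=0)
        for dx in range(-max_shift, max_shift + 1):
            shifted = np.roll(rolled_y, dx, axis=1)
            score = float(np.sum(r[interior, interior] * shifted[interior, interior]))
            if score > best:
                best, best_shift = score, (dy, dx)
    return best_shift


def axial_distance_brute(a_deg, b_deg):
    """Axial (period-180) angular distance by direct minimization."""
    d = abs(a_deg - b_deg) % 180.0
    return min(d, 180.0 - d)


def marginal_learning_curve(x, beta0, beta1, sigma_b, sigma_s, n_nodes=60):
    """Population-average P(correct | x) by Gauss-Hermite quadrature.

    Integrates the logistic over the bivariate normal random effects —
    an independent numerical route to the marginal curve the simulator's
    empirical frequencies should converge to.
    """
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    b = np.sqrt(2.0) * sigma_b * nodes
    s = np.sqrt(2.0) * sigma_s * nodes
    w = weights / np.sqrt(np.pi)
    x = np.atleast_1d(np.asarray(x, dtype=float))
    logits = (
        beta0
        + b[:, None, None]
        + (beta1 + s[None, :, None]) * x[None, None, :]
    )
    probs = 1.0 / (1.0 + np.exp(-logits))
    return np.einsum("i,j,ijt->t", w, w, probs)


def check_rearrangement_constraints(previous, new):
    """Brute-force verification of the three bout-rearrangement rules.

    (1) no physical target in its previous place, (2) no place holds the
    same condition as before, (3) the new condition grid is a Latin square.
    Returns a dict of booleans.
    """
    grid, prev_grid = np.asarray(new.grid), np.asarray(previous.grid)
    latin = all(
        sorted(line) == [1, 2, 3, 4]
        for lines in (grid, grid.T)
        for line in lines
    )
    no_same_condition = bool(np.all(grid != prev_grid))
    if previous.target_grid is not None and new.target_grid is not None:
        no_same_target = bool(np.all(new.target_grid != previous.target_grid))
    else:
        no_same_target = no_same_condition  # targets keep their condition
    return {
        "no_same_target": no_same_target,
        "no_same_condition": no_same_condition,
        "latin": latin,
    }
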