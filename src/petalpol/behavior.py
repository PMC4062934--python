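"""Behavioral analysis of forager choice sequences.

Covers the quantitative machinery of a differential-conditioning experiment
in which bees choose between rewarding and aversive targets over a session:

* random-effects logistic learning-curve models (random intercept and,
  optionally, random slope on experience per bee), fitted by maximizing the
  Laplace-approximate marginal likelihood;
* nested model comparison via the change in deviance (chi-square likelihood
  ratio test) and AIC;
* the test for an intensity-contrast x experience interaction, used to ask
  whether brightness cues rather than polarization drive learning;
* binned learning curves with Wilson 95% confidence intervals;
* the constrained Latin-square rearrangement of a 4x4 target grid between
  foraging bouts.

The learning model for bee :math:`i` at trial :math:`t` is

.. math:: \\mathrm{logit}\\,P(y_{it}=1) = (\\beta_0 + b_i) + (\\beta_1 + s_i)\\,x_t,

with :math:`b_i \\sim N(0, \\sigma_b^2)`, :math:`s_i \\sim N(0, \\sigma_s^2)`
independent, and :math:`x_t = (t-1)/(T-1)` the experience covariate scaled to
[0, 1]. Deviance is :math:`-2` times the maximized (Laplace) log-likelihood;
AIC counts fixed effects plus variance components as parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "TrialLayout",
    "LearningFit",
    "all_latin_squares_4",
    "random_layout",
    "shuffle_layout",
    "validate_choice_table",
    "read_choices",
    "write_choices",
    "fit_learning_model",
    "likelihood_ratio_test",
    "compare_nested",
    "interaction_test",
    "learning_curve",
    "intensity_of_condition",
]

MODEL_SPECS = ("null", "experience", "experience+condition", "experience*condition")

# DFIC conditions 1-4: polarization contrast/plain crossed with darker/lighter
# outer ring; 1 and 3 share the darker outer ring, 2 and 4 the lighter one.
_INTENSITY_OF_CONDITION = {1: "darker", 2: "lighter", 3: "darker", 4: "lighter"}


# ---------------------------------------------------------------------------
# Latin-square trial layouts


@dataclass
class TrialLayout:
    """4x4 grid of DFIC condition labels (1-4), one Latin square per bout.

    ``target_grid`` optionally records which of the 16 physical targets sits
    in each cell; target ``4*(c-1) + k`` is the k-th target of condition c.
    """

    grid: np.ndarray
    target_grid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=int)
        if self.grid.shape != (4, 4):
            raise ValueError("layout must be 4x4")
        for axis in (0, 1):
            lines = self.grid if axis == 0 else self.grid.T
            for line in lines:
                if sorted(line) != [1, 2, 3, 4]:
                    raise ValueError("each condition must appear once per row and column")
        if self.target_grid is not None:
            self.target_grid = np.asarray(self.target_grid, dtype=int)
            if sorted(self.target_grid.ravel()) != list(range(16)):
                raise ValueError("target grid must place each of 16 targets once")
            if np.any(self.target_grid // 4 + 1 != self.grid):
                raise ValueError("target conditions disagree with the condition grid")


@lru_cache(maxsize=1)
def all_latin_squares_4() -> tuple[np.ndarray, ...]:
    """Every order-4 Latin square over labels 1-4 (there are 576)."""
    perms = [np.array(p) for p in permutations(range(4))]
    squares: list[np.ndarray] = []

    def extend(rows: list[np.ndarray]) -> None:
        if len(rows) == 4:
            squares.append(np.stack(rows) + 1)
            return
        for p in perms:
            if all(np.all(p != r) for r in rows):
                extend(rows + [p])

    extend([])
    out = tuple(sq for sq in squares)
    assert len(out) == 576
    return out


def _assign_targets(grid: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    target_grid = np.empty((4, 4), dtype=int)
    for cond in range(1, 5):
        cells = np.argwhere(grid == cond)
        for k, (r, c) in zip(rng.permutation(4), cells):
            target_grid[r, c] = 4 * (cond - 1) + int(k)
    return target_grid


def random_layout(seed: int | None = None, rng: np.random.Generator | None = None) -> TrialLayout:
    """A uniformly random order-4 Latin square with targets assigned."""
    rng = np.random.default_rng(seed) if rng is None else rng
    squares = all_latin_squares_4()
    grid = squares[int(rng.integers(len(squares)))]
    return TrialLayout(grid=grid.copy(), target_grid=_assign_targets(grid, rng))


def shuffle_layout(
    previous: TrialLayout,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> TrialLayout:
    """Rearrange the target grid between foraging bouts.

    The new layout satisfies the three rearrangement constraints: (1) no
    physical target is in its previous place, (2) no place holds a target of
    the same condition as before, and (3) the four conditions again form a
    Latin square. Constraint (2) is enforced by rejection-sampling Latin
    squares until one is discordant with the previous grid (differs at every
    cell); since each target keeps its condition, discordance makes the old
    and new cell sets of every condition disjoint, so any assignment of the
    four physical targets of a condition onto its four new cells — here a
    seeded random permutation — already satisfies constraint (1).

    A discordant order-4 Latin square always exists, so this never fails.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    squares = all_latin_squares_4()
    while True:
        grid = squares[int(rng.integers(len(squares)))]
        if np.all(grid != previous.grid):
            break
    return TrialLayout(grid=grid.copy(), target_grid=_assign_targets(grid, rng))


# ---------------------------------------------------------------------------
# Choice tables


def validate_choice_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check a choice table's contract and return it sorted by bee and trial.

    Required columns: ``bee_id``, ``trial`` (1-based, contiguous per bee),
    ``condition``, ``correct`` (0/1).
    """
    required = {"bee_id", "trial", "condition", "correct"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"choice table missing columns: {sorted(missing)}")
    if len(table) == 0:
        raise ValueError("choice table is empty")
    if not table["correct"].isin([0, 1]).all():
        raise ValueError("correct must be binary 0/1")
    table = table.sort_values(["bee_id", "trial"]).reset_index(drop=True)
    for bee, sub in table.groupby("bee_id"):
        t = sub["trial"].to_numpy()
        if not np.array_equal(t, np.arange(1, len(t) + 1)):
            raise ValueError(f"trial indices not contiguous from 1 for bee {bee!r}")
    return table


def read_choices(path: str | Path) -> pd.DataFrame:
    return validate_choice_table(pd.read_csv(path))


def write_choices(path: str | Path, table: pd.DataFrame) -> None:
    validate_choice_table(table).to_csv(path, index=False)


def intensity_of_condition(condition: pd.Series) -> pd.Series:
    """Map DFIC condition labels 1-4 to their intensity-contrast type.

    Conditions 1/3 have the darker outer ring, 2/4 the lighter one. Labels
    that are not the canonical 1-4 are passed through unchanged (they are
    then treated as already being intensity levels).
    """
    numeric = pd.to_numeric(condition, errors="coerce")
    if numeric.isin([1, 2, 3, 4]).all():
        return numeric.astype(int).map(_INTENSITY_OF_CONDITION)
    return condition.astype(str)


# ---------------------------------------------------------------------------
# Random-effects logistic learning model (Laplace approximation)


@dataclass
class LearningFit:
    """A fitted random-effects logistic learning model."""

    spec: str
    fixed_effects: dict[str, float]
    sigma_b: float
    sigma_s: float | None
    deviance: float
    aic: float
    n_params: int
    converged: bool
    n_bees: int
    n_obs: int
    random_slope: bool
    fixed_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.fixed_names:
            self.fixed_names = tuple(self.fixed_effects)


def _experience(table: pd.DataFrame) -> pd.Series:
    """Experience covariate x_t = (t-1)/(T-1) in [0, 1], per bee."""

    def scale(t: pd.Series) -> pd.Series:
        T = t.max()
        return (t - 1) / (T - 1) if T > 1 else t * 0.0

    return table.groupby("bee_id")["trial"].transform(scale)


def _fixed_design(table: pd.DataFrame, spec: str) -> tuple[np.ndarray, tuple[str, ...]]:
    x = _experience(table).to_numpy()
    cols: list[np.ndarray] = [np.ones(len(table))]
    names: list[str] = ["intercept"]
    if spec != "null":
        cols.append(x)
        names.append("experience")
    if spec in ("experience+condition", "experience*condition"):
        intensity = intensity_of_condition(table["condition"])
        levels = sorted(intensity.unique())
        if len(levels) < 2:
            raise ValueError("condition covariate has a single level")
        for lev in levels[1:]:
            d = (intensity == lev).to_numpy(dtype=float)
            cols.append(d)
            names.append(f"condition[{lev}]")
            if spec == "experience*condition":
                cols.append(d * x)
                names.append(f"experience:condition[{lev}]")
    return np.column_stack(cols), tuple(names)


def _to_arrays(table: pd.DataFrame, X: np.ndarray):
    """Reshape long-format rows into (n_bees, T_max) arrays with a mask."""
    bees = table["bee_id"].to_numpy()
    uniq, inv = np.unique(bees, return_inverse=True)
    counts = np.bincount(inv)
    n, T = len(uniq), int(counts.max())
    pos = table["trial"].to_numpy() - 1
    y = np.zeros((n, T))
    mask = np.zeros((n, T))
    Xb = np.zeros((n, T, X.shape[1]))
    xexp = np.zeros((n, T))
    y[inv, pos] = table["correct"].to_numpy(dtype=float)
    mask[inv, pos] = 1.0
    Xb[inv, pos] = X
    xexp[inv, pos] = _experience(table).to_numpy()
    return y, mask, Xb, xexp, n


def _laplace_neg2ll(
    theta: np.ndarray,
    y: np.ndarray,
    mask: np.ndarray,
    Xf: np.ndarray,
    Z: np.ndarray,
    p_fixed: int,
    d: int,
    u_store: np.ndarray,
) -> float:
    """-2 x Laplace-approximate marginal log-likelihood at parameters theta.

    theta = (beta_1..beta_p, log sigma_b [, log sigma_s]). The per-bee random
    effect mode is found by damped Newton on the penalized log-likelihood
    (globally concave) and cached in ``u_store`` to warm-start the next call.
    """
    beta = theta[:p_fixed]
    sig2 = np.exp(2.0 * theta[p_fixed:])
    eta_fixed = Xf @ beta
    u = u_store.copy()
    inv_sig2 = 1.0 / sig2
    for _ in range(60):
        eta = eta_fixed + np.einsum("ntd,nd->nt", Z, u)
        p = special.expit(eta)
        grad = np.einsum("ntd,nt->nd", Z, (y - p) * mask) - u * inv_sig2
        w = p * (1.0 - p) * mask
        H = np.einsum("ntd,nt,nte->nde", Z, w, Z)
        H[:, np.arange(d), np.arange(d)] += inv_sig2
        step = np.linalg.solve(H, grad[..., None])[..., 0]
        norm = np.sqrt(np.sum(step**2, axis=1, keepdims=True))
        step = step * np.minimum(1.0, 5.0 / np.maximum(norm, 5.0))
        u = u + step
        if np.max(np.abs(step)) < 1e-10:
            break
    u_store[:] = u
    eta = eta_fixed + np.einsum("ntd,nd->nt", Z, u)
    p = special.expit(eta)
    loglik = np.sum((y * eta - np.logaddexp(0.0, eta)) * mask)
    penalty = 0.5 * np.sum(u**2 * inv_sig2)
    w = p * (1.0 - p) * mask
    H = np.einsum("ntd,nt,nte->nde", Z, w, Z)
    H[:, np.arange(d), np.arange(d)] += inv_sig2
    if d == 2:
        logdet = np.log(H[:, 0, 0] * H[:, 1, 1] - H[:, 0, 1] ** 2)
    else:
        logdet = np.log(H[:, 0, 0])
    n = y.shape[0]
    ll = loglik - penalty - 0.5 * np.sum(logdet) - 0.5 * n * np.sum(np.log(sig2))
    return -2.0 * ll


_ZETA_BOUNDS = (np.log(1e-3), np.log(30.0))


def fit_learning_model(
    table: pd.DataFrame,
    spec: str = "experience",
    *,
    random_slope: bool = True,
) -> LearningFit:
    """Fit a random-effects logistic learning model to a choice table.

    ``spec`` selects the fixed-effect structure: ``"null"`` (intercept only),
    ``"experience"`` (adds the scaled trial-index slope),
    ``"experience+condition"`` (adds intensity-contrast main effects), or
    ``"experience*condition"`` (adds the condition x experience interaction;
    ``"experience_x_condition"`` is accepted as an alias). Every spec keeps
    the same random structure — per-bee random intercept plus, by default, an
    uncorrelated per-bee random slope on experience — so nested fits differ
    only in fixed effects and are comparable by :func:`compare_nested`.

    The marginal likelihood integrates the random effects out per bee by a
    Laplace approximation at the penalized-likelihood mode; the result is
    deterministic given the data (fixed starting values, no randomness).
    """
    if spec == "experience_x_condition":
        spec = "experience*condition"
    if spec not in MODEL_SPECS:
        raise ValueError(f"unknown model spec {spec!r}; expected one of {MODEL_SPECS}")
    table = validate_choice_table(table)
    if table["bee_id"].nunique() < 2:
        raise ValueError("variance components need at least 2 bees")
    X, names = _fixed_design(table, spec)
    y, mask, Xf, xexp, n = _to_arrays(table, X)
    d = 2 if random_slope else 1
    Z = np.ones((n, y.shape[1], d))
    if random_slope:
        Z[..., 1] = xexp
    Z *= mask[..., None]
    p_fixed = X.shape[1]
    u_store = np.zeros((n, d))
    theta0 = np.concatenate([np.zeros(p_fixed), np.full(d, np.log(0.3))])
    pbar = np.clip(table["correct"].mean(), 0.02, 0.98)
    theta0[0] = special.logit(pbar)
    bounds = [(-30.0, 30.0)] * p_fixed + [_ZETA_BOUNDS] * d
    args = (y, mask, Xf, Z, p_fixed, d, u_store)
    res = optimize.minimize(
        _laplace_neg2ll,
        theta0,
        args=args,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 300, "ftol": 1e-11, "gtol": 1e-7},
    )
    if not res.success:  # one deterministic restart from the incumbent
        res2 = optimize.minimize(
            _laplace_neg2ll, res.x, args=args, method="Nelder-Mead",
            options={"maxiter": 2000, "xatol": 1e-8, "fatol": 1e-9},
        )
        if res2.fun <= res.fun:
            res = res2
    theta = res.x
    deviance = float(res.fun)
    sigma = np.exp(theta[p_fixed:])
    n_params = p_fixed + d
    return LearningFit(
        spec=spec,
        fixed_effects=dict(zip(names, map(float, theta[:p_fixed]))),
        sigma_b=float(sigma[0]),
        sigma_s=float(sigma[1]) if random_slope else None,
        deviance=deviance,
        aic=deviance + 2 * n_params,
        n_params=n_params,
        converged=bool(res.success or res.fun < np.inf),
        n_bees=n,
        n_obs=int(mask.sum()),
        random_slope=random_slope,
        fixed_names=names,
    )


def likelihood_ratio_test(delta_deviance: float, delta_df: int) -> float:
    """Upper-tail chi-square p-value for a nested-model deviance change."""
    if delta_df < 1:
        raise ValueError("delta_df must be >= 1")
    return float(stats.chi2.sf(max(delta_deviance, 0.0), delta_df))


def compare_nested(
    full: LearningFit, null: LearningFit, *, tolerance: float = 0.05
) -> dict[str, float]:
    """Compare nested learning models by deviance change and AIC.

    Returns ``delta_deviance`` (null minus full), ``delta_df``, the
    chi-square ``p_value`` and ``delta_aic = delta_deviance - 2*delta_df``
    (positive when the full model is AIC-preferred).
    """
    if full.random_slope != null.random_slope:
        raise ValueError("models differ in random-effect structure; not nested")
    if not set(null.fixed_names) < set(full.fixed_names):
        raise ValueError(
            f"{null.spec!r} is not nested in {full.spec!r} (fixed effects not a subset)"
        )
    delta_df = full.n_params - null.n_params
    delta_dev = null.deviance - full.deviance
    if delta_dev < -tolerance:
        raise ValueError(
            f"null deviance {null.deviance:.4f} below full {full.deviance:.4f}: "
            "models not nested or fit not converged"
        )
    delta_dev = max(delta_dev, 0.0)
    return {
        "delta_deviance": delta_dev,
        "delta_df": delta_df,
        "p_value": likelihood_ratio_test(delta_dev, delta_df),
        "delta_aic": delta_dev - 2 * delta_df,
    }


def interaction_test(table: pd.DataFrame, *, random_slope: bool = True) -> dict[str, float]:
    """Test the intensity-contrast x experience interaction.

    Fits the learning model with and without the condition x experience
    interaction term (both retain condition and experience main effects) and
    returns the :func:`compare_nested` result. A small p-value would indicate
    that the intensity-contrast type modulates the learning rate — i.e. that
    brightness, not polarization, carries the learned information.
    """
    table = validate_choice_table(table)
    if intensity_of_condition(table["condition"]).nunique() < 2:
        raise ValueError("interaction test needs >= 2 condition levels")
    full = fit_learning_model(table, "experience*condition", random_slope=random_slope)
    reduced = fit_learning_model(table, "experience+condition", random_slope=random_slope)
    return compare_nested(full, reduced)


def fit_report(table: pd.DataFrame, *, treatment: str = "synthetic") -> dict[str, float]:
    """Null-vs-experience comparison bundled as a JSON-ready report."""
    full = fit_learning_model(table, "experience")
    null = fit_learning_model(table, "null")
    comp = compare_nested(full, null)
    return {
        "treatment": treatment,
        "deviance_null": null.deviance,
        "deviance_full": full.deviance,
        "delta_deviance": comp["delta_deviance"],
        "df": comp["delta_df"],
        "p": comp["p_value"],
        "aic_null": null.aic,
        "aic_full": full.aic,
    }


# ---------------------------------------------------------------------------
# Learning curves


def learning_curve(table: pd.DataFrame, bin_size: int = 10) -> pd.DataFrame:
    """Binned proportion of correct choices pooled across bees.

    Trials are grouped into consecutive bins of ``bin_size`` (the last bin
    may be partial); within each bin, successes are pooled over bees and a
    Wilson score 95% confidence interval is attached.
    """
    table = validate_choice_table(table)
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    bins = (table["trial"] - 1) // bin_size
    grouped = table.groupby(bins)["correct"]
    out = grouped.agg(successes="sum", n="count").reset_index(names="bin")
    out["trial_start"] = out["bin"] * bin_size + 1
    out["trial_end"] = np.minimum((out["bin"] + 1) * bin_size, table["trial"].max())
    out["proportion"] = out["successes"] / out["n"]
    lo, hi = proportion_confint(out["successes"], out["n"], alpha=0.05, method="wilson")
    out["ci_low"] = lo
    out["ci_high"] = hi
    return out[
        ["bin", "trial_start", "trial_end", "n", "successes", "proportion", "ci_low", "ci_high"]
    ]
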