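"""Markov-chain Monte Carlo simulation of the saturated pairwise
interaction model.

A birth-death-move Metropolis-Hastings chain targets the unnormalized
density restricted to patterns with at most ``max_points`` points.  The
truncation makes the target well-defined even for attractive (positive)
interaction coefficients, where the untruncated density need not be
integrable; the default cap is four times the expected count of the
interaction-free (Poisson) sub-model.  Acceptance ratios are computed
from the Papangelou conditional intensity, so the normalizing constant
never appears.

Proposals: birth (uniform location, uniform type), death (uniform point),
move (Gaussian jitter reflected at the window boundary), with
probabilities 0.4 / 0.4 / 0.2 by default.  The returned state is the
single final state after ``burn_in + n_steps`` steps (no thinning); set
``trajectory_every`` to additionally collect every k-th post-burn-in
state for diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .gibbs import ModelSpec, Parameters, PatternState, _covariate_values
from .patterns import MultitypePointPattern, Window


@dataclass
class SamplerConfig:
    n_steps: int = 10_000
    burn_in: int = 10_000
    p_birth: float = 0.4
    p_death: float = 0.4
    p_move: float = 0.2
    move_sd: float = 10.0  # microns
    max_points: int | None = None  # default: 4x Poisson-limit expected count
    seed: int = 0
    init_pattern: MultitypePointPattern | None = None
    trajectory_every: int | None = None

    def __post_init__(self):
        total = self.p_birth + self.p_death + self.p_move
        if not np.isclose(total, 1.0):
            raise ValueError("proposal probabilities must sum to 1")
        if self.n_steps < 0 or self.burn_in < 0:
            raise ValueError("step counts must be non-negative")


def _reflect(v: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold coordinates back into [lo, hi] by mirror reflection."""
    w = hi - lo
    y = np.mod(v - lo, 2 * w)
    y = np.where(y > w, 2 * w - y, y)
    return lo + y


def _mean_intensities(model: ModelSpec, params: Parameters, covariates,
                      window: Window, grid: int = 8) -> np.ndarray:
    """Per-type window-averaged first-order intensity exp(beta0 + beta.X)."""
    if model.n_covariates == 0:
        return np.exp(params.beta0)
    xs = window.x_min + (np.arange(grid) + 0.5) * window.width / grid
    ys = window.y_min + (np.arange(grid) + 0.5) * window.height / grid
    gx, gy = np.meshgrid(xs, ys)
    X = _covariate_values(covariates, model, gx.ravel(), gy.ravel())
    lam = np.exp(params.beta0[None, :] + X @ params.beta.T)
    return lam.mean(axis=0)


def mh_sample(model: ModelSpec, params: Parameters, covariates,
              window: Window, config: SamplerConfig):
    """Draw one pattern from the model (or a trajectory of patterns).

    Returns the final :class:`MultitypePointPattern`, or a list of
    patterns when ``config.trajectory_every`` is set (every k-th
    post-burn-in state, final state last).
    """
    rng = np.random.default_rng(config.seed)
    p = model.n_types
    area = window.area
    lam_bar = _mean_intensities(model, params, covariates, window)
    expected = float(lam_bar.sum() * area)
    max_points = config.max_points
    if max_points is None:
        max_points = max(int(np.ceil(4 * expected)), 16)

    interacting = bool(np.any(params.alpha) or np.any(params.gamma))

    # initial state: Poisson draw from the first-order intensities
    if config.init_pattern is not None:
        init = config.init_pattern
        lut = {t: i for i, t in enumerate(model.type_set)}
        coords = init.coords.copy()
        type_idx = np.array([lut[t] for t in init.types], dtype=np.intp)
    else:
        counts = rng.poisson(lam_bar * area)
        counts = np.minimum(counts, max_points)
        type_idx = np.repeat(np.arange(p), counts)
        n0 = len(type_idx)
        coords = np.column_stack([
            rng.uniform(window.x_min, window.x_max, n0),
            rng.uniform(window.y_min, window.y_max, n0),
        ])
    if len(coords) > max_points:
        keep = rng.choice(len(coords), max_points, replace=False)
        coords, type_idx = coords[keep], type_idx[keep]

    state = PatternState(coords, model, type_idx=type_idx, window=window) \
        if interacting else None
    if not interacting:
        coords = coords.copy()
        type_idx = type_idx.copy()

    def first_order(y, t):
        v = params.beta0[t]
        if model.n_covariates:
            X = _covariate_values(covariates, model, [y[0]], [y[1]])
            v += float(X[0] @ params.beta[t])
        return float(v)

    def loglam_birth(y, t):
        v = first_order(y, t)
        if interacting:
            ds, dm = state.birth_delta(y, t)
            v += float(params.alpha[t] @ ds) + float(params.gamma[t] @ dm)
        return v

    def loglam_removal(i):
        t = int(type_idx_view()[i])
        y = coords_view()[i]
        v = first_order(y, t)
        if interacting:
            ds, dm = state.removal_delta(i)
            v += float(params.alpha[t] @ ds) + float(params.gamma[t] @ dm)
        return v

    def coords_view():
        return state.coords if interacting else coords

    def type_idx_view():
        return state.type_idx if interacting else type_idx

    def n_current():
        return len(type_idx_view())

    def do_birth(y, t):
        nonlocal coords, type_idx
        if interacting:
            state.apply_birth(y, t)
        else:
            coords = np.vstack([coords, [y]])
            type_idx = np.append(type_idx, t)

    def do_death(i):
        nonlocal coords, type_idx
        if interacting:
            state.apply_death(i)
        else:
            coords = np.delete(coords, i, axis=0)
            type_idx = np.delete(type_idx, i)

    log_pW = np.log(p * area)
    log_bd = np.log(config.p_death / config.p_birth) if config.p_birth > 0 else 0.0

    def snapshot():
        labels = [model.type_set[i] for i in type_idx_view()]
        return MultitypePointPattern(coords_view().copy(), labels, window,
                                     type_set=model.type_set)

    trajectory = []
    total = config.burn_in + config.n_steps
    n_birth_proposals = 0
    n_blocked = 0
    thresholds = np.array([config.p_birth,
                           config.p_birth + config.p_death])
    for step in range(total):
        u = rng.random()
        n = n_current()
        if u < thresholds[0]:  # birth
            n_birth_proposals += 1
            if n + 1 > max_points:
                n_blocked += 1
            else:
                y = np.array([rng.uniform(window.x_min, window.x_max),
                              rng.uniform(window.y_min, window.y_max)])
                t = int(rng.integers(p))
                log_a = (loglam_birth(y, t) + log_pW + log_bd
                         - np.log(n + 1))
                if np.log(rng.random()) < log_a:
                    do_birth(y, t)
        elif u < thresholds[1]:  # death
            if n > 0:
                i = int(rng.integers(n))
                log_a = (np.log(n) - log_pW - log_bd - loglam_removal(i))
                if np.log(rng.random()) < log_a:
                    do_death(i)
        else:  # move
            if n > 0:
                i = int(rng.integers(n))
                t = int(type_idx_view()[i])
                old = coords_view()[i].copy()
                new = old + rng.normal(0.0, config.move_sd, 2)
                new[0] = _reflect(new[0], window.x_min, window.x_max)
                new[1] = _reflect(new[1], window.y_min, window.y_max)
                log_old = loglam_removal(i)
                do_death(i)
                log_new = loglam_birth(new, t)
                if np.log(rng.random()) < log_new - log_old:
                    do_birth(new, t)
                else:
                    do_birth(old, t)
        if (config.trajectory_every is not None and step >= config.burn_in
                and (step - config.burn_in + 1) % config.trajectory_every == 0):
            trajectory.append(snapshot())

    if n_birth_proposals and n_blocked / n_birth_proposals > 0.10:
        warnings.warn(
            f"max_points={max_points} blocked "
            f"{n_blocked}/{n_birth_proposals} birth proposals; the density "
            "may be explosive for the given positive interaction "
            "coefficients",
            RuntimeWarning,
        )

    final = snapshot()
    if config.trajectory_every is not None:
        if not trajectory or trajectory[-1].n_points != final.n_points:
            trajectory.append(final)
        return trajectory
    return final
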