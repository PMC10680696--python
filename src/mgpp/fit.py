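"""Fitting the model by logistic composite likelihood (pseudo-likelihood).

The intractable normalizing constant is bypassed by conditional-intensity
estimation: data points (response 1) and per-type dummy points (response
0, stratified-uniform over the window at rate ``rho_t = n_dummy / area``)
enter a Bernoulli regression with

``logit P(response = 1 | u, t) = log lambda(u, t | x) - log rho_t``

so the linear predictor of the GLM, plus the offset ``-log rho_t``, is the
log Papangelou conditional intensity.  The interaction columns of the
design are the exact per-pair changes of the saturated pair statistics
(including saturation effects on existing points), shared with
:mod:`mgpp.gibbs`.

Standard errors are observed-information (naive GLM) Wald errors; under
strong interaction these can be anti-conservative relative to corrected
composite-likelihood variances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .gibbs import ModelSpec, Parameters, PatternState, model_to_dict
from .patterns import (
    MultitypePointPattern,
    PixelImage,
    Window,
    distance_map,
    empty_region_mask,
)

DEFAULT_N_DUMMY = 5000
DEFAULT_MIN_CELLS = 20


# -- data preparation ----------------------------------------------------


def filter_types(pattern: MultitypePointPattern,
                 min_cells: int = DEFAULT_MIN_CELLS):
    """Keep only cell types with at least ``min_cells`` points (inclusive).

    Returns ``(filtered_pattern, kept_type_labels)``.  Sparse types are
    dropped entirely: their interactions cannot be estimated reliably.
    """
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    counts = pattern.counts()
    kept = [t for t in pattern.type_set if counts[t] >= min_cells]
    if not kept:
        raise ValueError(
            f"no type has >= {min_cells} cells (counts: {counts})"
        )
    return pattern.subset(kept), kept


def stratified_uniform(window: Window, n: int, rng: np.random.Generator) -> np.ndarray:
    """``n`` points, one uniform draw in each of ``n`` cells of a jittered
    grid over the window (lower variance than i.i.d. uniform)."""
    g = int(np.ceil(np.sqrt(n)))
    cells = rng.choice(g * g, size=n, replace=False)
    row, col = np.divmod(cells, g)
    u = rng.random((n, 2))
    xs = window.x_min + (col + u[:, 0]) * window.width / g
    ys = window.y_min + (row + u[:, 1]) * window.height / g
    return np.column_stack([xs, ys])


@dataclass
class QuadratureScheme:
    """Data + dummy points for the logistic estimator.

    ``data_index`` maps each row to its index in the source pattern
    (-1 for dummy rows).  ``offset`` is ``-log(rho_type)`` with
    ``rho_type = n_dummy / window area``.
    """

    coords: np.ndarray
    types: np.ndarray
    response: np.ndarray
    offset: np.ndarray
    data_index: np.ndarray

    def __post_init__(self):
        if set(np.unique(self.response)) - {0, 1}:
            raise ValueError("responses must be 0 or 1")


def make_quadrature(pattern: MultitypePointPattern,
                    n_dummy: int = DEFAULT_N_DUMMY,
                    seed: int = 0) -> QuadratureScheme:
    """Data rows plus ``n_dummy`` stratified-uniform dummy rows per type."""
    if n_dummy < 1:
        raise ValueError("n_dummy must be >= 1")
    rng = np.random.default_rng(seed)
    rho = n_dummy / pattern.window.area
    coords = [pattern.coords]
    types = [pattern.types]
    response = [np.ones(pattern.n_points)]
    data_index = [np.arange(pattern.n_points)]
    for t in pattern.type_set:
        pts = stratified_uniform(pattern.window, n_dummy, rng)
        coords.append(pts)
        types.append(np.full(n_dummy, t, dtype=object))
        response.append(np.zeros(n_dummy))
        data_index.append(np.full(n_dummy, -1))
    coords = np.vstack(coords)
    return QuadratureScheme(
        coords=coords,
        types=np.concatenate(types),
        response=np.concatenate(response),
        offset=np.full(len(coords), -np.log(rho)),
        data_index=np.concatenate(data_index).astype(np.intp),
    )


# -- design matrix -------------------------------------------------------


def _column_names(model: ModelSpec):
    names = [f"beta0({t})" for t in model.type_set]
    for name in model.covariate_names:
        names += [f"beta({name},{t})" for t in model.type_set]
    for i, j in model.pairs():
        names.append(f"alpha({model.type_set[i]},{model.type_set[j]})")
    for i, j in model.pairs():
        names.append(f"gamma({model.type_set[i]},{model.type_set[j]})")
    return names


def build_design(q: QuadratureScheme, pattern: MultitypePointPattern,
                 model: ModelSpec, covariates=None) -> pd.DataFrame:
    """Design matrix of the logistic estimator, one row per quadrature
    point, with columns named after the coefficients they multiply.

    The linear predictor of any row under given Parameters equals the log
    Papangelou conditional intensity at that row (data rows condition on
    the pattern minus the point itself).
    """
    state = PatternState(pattern, model)
    p = model.n_types
    pairs = model.pairs()
    M = len(q.coords)
    t_codes = np.array([model.type_index(t) for t in q.types], dtype=np.intp)

    Ds = np.zeros((M, p))
    Dm = np.zeros((M, p))
    is_data = q.data_index >= 0
    if np.any(is_data):
        idx = np.flatnonzero(is_data)
        Ds[idx], Dm[idx] = state.removal_delta_batch(q.data_index[idx])
    for t in range(p):
        rows = np.flatnonzero(~is_data & (t_codes == t))
        if len(rows):
            Ds[rows], Dm[rows] = state.birth_delta_batch(q.coords[rows], t)

    cols = {}
    for t, lab in enumerate(model.type_set):
        cols[f"beta0({lab})"] = (t_codes == t).astype(float)
    if model.n_covariates:
        from .gibbs import _covariate_values
        X = _covariate_values(covariates, model, q.coords[:, 0], q.coords[:, 1])
        for k, name in enumerate(model.covariate_names):
            for t, lab in enumerate(model.type_set):
                cols[f"beta({name},{lab})"] = X[:, k] * (t_codes == t)
    for D, kind in ((Ds, "alpha"), (Dm, "gamma")):
        for i, j in pairs:
            col = np.zeros(M)
            mask_i = t_codes == i
            col[mask_i] = D[mask_i, j]
            if j != i:
                mask_j = t_codes == j
                col[mask_j] = D[mask_j, i]
            cols[f"{kind}({model.type_set[i]},{model.type_set[j]})"] = col
    return pd.DataFrame(cols)


# -- fitted model container ----------------------------------------------


@dataclass
class FittedModel:
    """Point estimates, Wald uncertainties and diagnostics of one fit.

    ``table`` has one row per coefficient: kind (beta0/beta/alpha/gamma),
    type1, type2 (pair rows), covariate (beta rows), scale, estimate, se,
    ci_low, ci_high, significant.  The significance flag at level 0.05 is
    equivalent to the 95% CI excluding zero.
    """

    model: ModelSpec
    params: Parameters
    table: pd.DataFrame
    level: float
    converged: bool
    n_dummy: int
    seed: int

    def coefficient(self, kind: str, t1: str, t2: str = None,
                    covariate: str = None) -> pd.Series:
        """Row of ``table`` for one coefficient (pair order-insensitive)."""
        tab = self.table[self.table["kind"] == kind]
        if kind in ("alpha", "gamma"):
            hit = tab[((tab.type1 == t1) & (tab.type2 == t2))
                      | ((tab.type1 == t2) & (tab.type2 == t1))]
        elif kind == "beta":
            hit = tab[(tab.type1 == t1) & (tab.covariate == covariate)]
        else:
            hit = tab[tab.type1 == t1]
        if len(hit) != 1:
            raise KeyError(f"no unique {kind} coefficient for ({t1}, {t2})")
        return hit.iloc[0]

    def to_dict(self) -> dict:
        return {
            "model": model_to_dict(self.model, self.params),
            "table": self.table.to_dict(orient="list"),
            "level": self.level,
            "converged": self.converged,
            "n_dummy": self.n_dummy,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedModel":
        from .gibbs import model_from_dict
        model, params = model_from_dict(d["model"])
        return cls(model=model, params=params,
                   table=pd.DataFrame(d["table"]), level=d["level"],
                   converged=d["converged"], n_dummy=d["n_dummy"],
                   seed=d["seed"])

    def to_json(self) -> str:
        import json
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, doc: str) -> "FittedModel":
        import json
        return cls.from_dict(json.loads(doc))

    def write_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _coefficient_rows(model: ModelSpec):
    """(kind, type1, type2, covariate, scale) per design column, in
    design-column order."""
    rows = []
    for t in model.type_set:
        rows.append(("beta0", t, None, None, None))
    for name in model.covariate_names:
        for t in model.type_set:
            rows.append(("beta", t, None, name, None))
    for kind, scale in (("alpha", "short"), ("gamma", "medium")):
        for i, j in model.pairs():
            rows.append((kind, model.type_set[i], model.type_set[j], None, scale))
    return rows


def fit_mgpp(pattern: MultitypePointPattern, model: ModelSpec,
             covariates=None, n_dummy: int = DEFAULT_N_DUMMY,
             seed: int = 0, level: float = 0.95,
             interactions: bool = True) -> FittedModel:
    """Fit the saturated pairwise interaction model to one pattern.

    The pattern should already have passed :func:`filter_types`.  Columns
    whose statistic is identically zero (a pair never within potential
    range) are unidentifiable and reported with estimate 0 and infinite
    standard error; separation or non-convergence is flagged rather than
    raised.  With ``interactions=False`` the alpha and gamma coefficients
    are frozen at 0 and only the first-order (inhomogeneous Poisson)
    sub-model is estimated.
    """
    q = make_quadrature(pattern, n_dummy=n_dummy, seed=seed)
    X = build_design(q, pattern, model, covariates)
    names = list(X.columns)
    frozen = () if interactions else tuple(
        c for c in names if c.startswith(("alpha(", "gamma(")))
    active = [c for c in names
              if c not in frozen and np.any(X[c].to_numpy() != 0.0)]
    est = pd.Series(0.0, index=names)
    se = pd.Series(np.inf, index=names)
    converged = True
    try:
        glm = sm.GLM(q.response, X[active], family=sm.families.Binomial(),
                     offset=q.offset)
        res = glm.fit(maxiter=200)
        converged = bool(getattr(res, "converged", True))
        est[active] = np.asarray(res.params)
        bse = np.asarray(res.bse)
        bse = np.where(np.isfinite(bse), bse, np.inf)
        se[active] = bse
    except Exception:
        converged = False
    if not np.all(np.isfinite(est)):
        est[~np.isfinite(est)] = 0.0
        converged = False
    z = norm.ppf(0.5 + level / 2)
    lo = est - z * se
    hi = est + z * se
    sig = (lo > 0) | (hi < 0)

    meta = _coefficient_rows(model)
    table = pd.DataFrame(meta, columns=["kind", "type1", "type2",
                                        "covariate", "scale"])
    table["estimate"] = est.to_numpy()
    table["se"] = se.to_numpy()
    table["ci_low"] = lo.to_numpy()
    table["ci_high"] = hi.to_numpy()
    table["significant"] = sig.to_numpy()

    p, K = model.n_types, model.n_covariates
    beta0 = est.iloc[:p].to_numpy()
    beta = est.iloc[p:p + p * K].to_numpy().reshape(K, p).T if K else None
    alpha = np.zeros((p, p))
    gamma = np.zeros((p, p))
    off = p + p * K
    n_pairs = len(model.pairs())
    for k, (i, j) in enumerate(model.pairs()):
        alpha[i, j] = alpha[j, i] = est.iloc[off + k]
        gamma[i, j] = gamma[j, i] = est.iloc[off + n_pairs + k]
    params = Parameters(beta0=beta0, beta=beta, alpha=alpha, gamma=gamma)
    return FittedModel(model=model, params=params, table=table, level=level,
                       converged=converged, n_dummy=n_dummy, seed=seed)


# -- covariate assembly --------------------------------------------------


def assemble_covariates(pattern: MultitypePointPattern,
                        distance_to: str | None = "vasculature",
                        empty_region: bool = True,
                        grid=(128, 128),
                        empty_threshold: float = 30.0):
    """Build the standard spatial covariates and the modeled pattern.

    ``distance_to`` names a reference type (typically the vasculature);
    the distance-to-nearest-point raster becomes a covariate and the
    reference type is removed from the modeled pattern (it defines an
    environmental variable, not a response).  ``empty_region`` adds the
    binary devoid-of-cells mask computed from *all* cells.

    Returns ``(covariates, modeled_pattern)`` where covariates maps name
    -> :class:`PixelImage`.
    """
    covariates: dict[str, PixelImage] = {}
    modeled = pattern
    if empty_region:
        covariates["empty_region"] = empty_region_mask(
            pattern, grid=grid, threshold=empty_threshold
        )
    if distance_to is not None:
        if distance_to not in pattern.type_set:
            raise ValueError(
                f"reference type {distance_to!r} absent: distance covariate "
                "undefined"
            )
        covariates[f"dist_to_{distance_to}"] = distance_map(
            pattern, distance_to, grid=grid
        )
        modeled = pattern.subset([t for t in pattern.type_set
                                  if t != distance_to])
    return covariates, modeled
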