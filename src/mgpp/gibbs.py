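"""The saturated pairwise interaction multitype Gibbs point process.

The model assigns a multitype point pattern ``x`` the unnormalized density

``log f(x) = sum_t sum_{x in x_t} [beta0_t + sum_k beta_{k,t} X_k(x)]
           + sum_{t1<=t2} alpha_{t1,t2} * S_short(t1,t2; x)
           + sum_{t1<=t2} gamma_{t1,t2} * S_medium(t1,t2; x)``

where ``S_scale(t1,t2; x)`` is the *saturated* pair statistic: every point
``z`` of type ``t1`` accumulates the sum of the N largest potential values
it has with points of type ``t2`` (and vice versa for cross pairs).
Capping at the N largest — the saturation parameter — keeps the density
integrable under attraction (positive coefficients), so the model can
express both clustering and repulsion.

The normalizing constant is never computed; inference and prediction work
through the Papangelou conditional intensity
``lambda(y | x) = f(x U {y}) / f(x)``, which cancels it.  Adding a point
``y`` changes not only the potentials ``y`` itself accumulates but also the
saturated sums of *existing* points (a neighbour of ``y`` may swap a weaker
partner out of its top-N set); :class:`PatternState` tracks the per-point
top-(N+1) potential values so both effects are computed exactly in O(n)
per evaluation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .patterns import MultitypePointPattern, Window
from .potentials import (
    PotentialSpec,
    medium_potential,
    medium_values,
    short_potential,
    short_values,
)

DEFAULT_SATURATION = 2


@dataclass
class ModelSpec:
    """Structure of a saturated pairwise interaction model.

    Parameters
    ----------
    type_set : ordered cell-type labels (length p)
    covariate_names : names of the K spatial covariates, in the column
        order of ``Parameters.beta``
    saturation : the saturation parameter N (>= 1)
    short, medium : the two :class:`PotentialSpec` families.  Their radii
        are scalars shared by all type pairs; pass ``short_radii`` /
        ``medium_radii`` for full symmetric per-pair matrices
        ((p, p) and (p, p, 2) respectively).
    """

    type_set: list
    covariate_names: list = field(default_factory=list)
    saturation: int = DEFAULT_SATURATION
    short: PotentialSpec = field(default_factory=short_potential)
    medium: PotentialSpec = field(default_factory=medium_potential)
    short_radii: np.ndarray | None = None
    medium_radii: np.ndarray | None = None

    def __post_init__(self):
        self.type_set = [str(t) for t in self.type_set]
        if len(set(self.type_set)) != len(self.type_set):
            raise ValueError("type_set labels must be distinct")
        if self.saturation < 1:
            raise ValueError("saturation N must be >= 1")
        p = self.n_types
        if self.short_radii is not None:
            self.short_radii = np.asarray(self.short_radii, dtype=float)
            if self.short_radii.shape != (p, p) or not np.allclose(
                self.short_radii, self.short_radii.T
            ):
                raise ValueError("short_radii must be a symmetric (p, p) matrix")
        if self.medium_radii is not None:
            self.medium_radii = np.asarray(self.medium_radii, dtype=float)
            if self.medium_radii.shape != (p, p, 2) or not np.allclose(
                self.medium_radii, np.swapaxes(self.medium_radii, 0, 1)
            ):
                raise ValueError("medium_radii must be a symmetric (p, p, 2) array")

    @property
    def n_types(self) -> int:
        return len(self.type_set)

    @property
    def n_covariates(self) -> int:
        return len(self.covariate_names)

    def type_index(self, label: str) -> int:
        try:
            return self.type_set.index(str(label))
        except ValueError:
            raise ValueError(f"unknown type label {label!r}") from None

    def short_radius_matrix(self) -> np.ndarray:
        if self.short_radii is not None:
            return self.short_radii
        p = self.n_types
        return np.full((p, p), float(self.short.radii))

    def medium_radius_matrices(self):
        """(inner, outer) per-pair matrices, each (p, p)."""
        p = self.n_types
        if self.medium_radii is not None:
            return self.medium_radii[..., 0], self.medium_radii[..., 1]
        inner, outer = self.medium.radii
        return np.full((p, p), inner), np.full((p, p), outer)

    def pairs(self):
        """Unordered type-index pairs (i, j) with i <= j, canonical order."""
        p = self.n_types
        return [(i, j) for i in range(p) for j in range(i, p)]


@dataclass
class Parameters:
    """Coefficients of the model.

    beta0 : (p,) per-type log-intensity intercepts
    alpha : (p, p) symmetric short-range interaction coefficients
    gamma : (p, p) symmetric medium-range interaction coefficients
    beta  : (p, K) spatial-covariate coefficients (omit when K = 0)
    """

    beta0: np.ndarray
    alpha: np.ndarray
    gamma: np.ndarray
    beta: np.ndarray | None = None

    def __post_init__(self):
        self.beta0 = np.asarray(self.beta0, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        p = len(self.beta0)
        for name, m in (("alpha", self.alpha), ("gamma", self.gamma)):
            if m.shape != (p, p):
                raise ValueError(f"{name} must be a (p, p) matrix")
            if not np.array_equal(m, m.T):
                raise ValueError(f"{name} must be exactly symmetric")
        if self.beta is None:
            self.beta = np.zeros((p, 0))
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.ndim != 2 or self.beta.shape[0] != p:
            raise ValueError("beta must be a (p, K) matrix")
        for name, m in (("beta0", self.beta0), ("beta", self.beta),
                        ("alpha", self.alpha), ("gamma", self.gamma)):
            if not np.all(np.isfinite(m)):
                raise ValueError(f"{name} entries must be finite")

    @classmethod
    def zeros(cls, n_types: int, n_covariates: int = 0) -> "Parameters":
        return cls(
            beta0=np.zeros(n_types),
            alpha=np.zeros((n_types, n_types)),
            gamma=np.zeros((n_types, n_types)),
            beta=np.zeros((n_types, n_covariates)),
        )


# -- serialization -------------------------------------------------------


def model_to_dict(model: ModelSpec, params: Parameters) -> dict:
    d = {
        "type_set": model.type_set,
        "covariate_names": model.covariate_names,
        "saturation": model.saturation,
        "short": {"family": model.short.family, "radius": model.short.radii},
        "medium": {"family": model.medium.family, "radii": list(model.medium.radii)},
        "beta0": params.beta0.tolist(),
        "beta": params.beta.tolist(),
        "alpha": params.alpha.tolist(),
        "gamma": params.gamma.tolist(),
    }
    if model.short_radii is not None:
        d["short"]["radii_matrix"] = model.short_radii.tolist()
    if model.medium_radii is not None:
        d["medium"]["radii_matrix"] = model.medium_radii.tolist()
    return d


def model_from_dict(d: dict):
    model = ModelSpec(
        type_set=d["type_set"],
        covariate_names=d["covariate_names"],
        saturation=int(d["saturation"]),
        short=short_potential(radius=d["short"]["radius"],
                              family=d["short"]["family"]),
        medium=medium_potential(radii=tuple(d["medium"]["radii"]),
                                family=d["medium"]["family"]),
        short_radii=(np.asarray(d["short"]["radii_matrix"])
                     if "radii_matrix" in d["short"] else None),
        medium_radii=(np.asarray(d["medium"]["radii_matrix"])
                      if "radii_matrix" in d["medium"] else None),
    )
    params = Parameters(
        beta0=np.asarray(d["beta0"]),
        beta=np.asarray(d["beta"]),
        alpha=np.asarray(d["alpha"]),
        gamma=np.asarray(d["gamma"]),
    )
    return model, params


def model_to_json(model: ModelSpec, params: Parameters) -> str:
    """JSON document; float repr is shortest-round-trip, so bit-exact."""
    return json.dumps(model_to_dict(model, params))


def model_from_json(doc: str):
    return model_from_dict(json.loads(doc))


# -- saturated pair statistics ------------------------------------------


def _top_sum(values: np.ndarray, n: int) -> float:
    """Sum of the n largest entries (all of them if fewer), accumulated
    in descending order so the result is reproducible bit-for-bit."""
    k = len(values)
    if k == 0:
        return 0.0
    sel = values if k <= n else np.partition(values, k - n)[k - n:]
    return float(np.sort(sel)[::-1].sum())


def saturated_potential(x, target, potential: PotentialSpec, N: int) -> float:
    """Sum of the N largest potential values between ``x`` and ``target``.

    ``x`` is a single (x, y) location; ``target`` is a (k, 2) array of
    points of one type, excluding ``x`` itself.  Returns 0 for an empty
    target.  This is the u (short-scale) or v (medium-scale) statistic.
    """
    if N < 1:
        raise ValueError("saturation N must be >= 1")
    target = np.asarray(target, dtype=float).reshape(-1, 2)
    if len(target) == 0:
        return 0.0
    d = np.hypot(target[:, 0] - x[0], target[:, 1] - x[1])
    return _top_sum(potential.evaluate(d), N)


def _pair_potential_matrix(model: ModelSpec, scale: str, i: int, j: int,
                           D: np.ndarray) -> np.ndarray:
    if scale == "short":
        return short_values(D, model.short_radius_matrix()[i, j],
                            model.short.family)
    if scale == "medium":
        inner, outer = model.medium_radius_matrices()
        return medium_values(D, inner[i, j], outer[i, j], model.medium.family)
    raise ValueError("scale must be 'short' or 'medium'")


def _directed_statistic(A: np.ndarray, B: np.ndarray, model: ModelSpec,
                        scale: str, i: int, j: int, same: bool) -> float:
    """T_{a->b} = sum over z in A of the top-N potential sum toward B."""
    if len(A) == 0 or len(B) == 0:
        return 0.0
    D = cdist(A, B)
    if same:
        np.fill_diagonal(D, np.inf)
    P = _pair_potential_matrix(model, scale, i, j, D)
    N = model.saturation
    if P.shape[1] <= N:
        return float(P.sum())
    return float(np.partition(P, P.shape[1] - N, axis=1)[:, P.shape[1] - N:].sum())


def pair_statistic(pattern: MultitypePointPattern, t1: str, t2: str,
                   scale: str, model: ModelSpec) -> float:
    """The sufficient statistic multiplying alpha (short) or gamma
    (medium) for the unordered pair {t1, t2} in ``log f``.

    For distinct types this is ``T_{t1->t2} + T_{t2->t1}``; within a type
    it is ``T_{t1->t1}`` (self-potentials excluded).
    """
    i, j = model.type_index(t1), model.type_index(t2)
    A = pattern.points_of_type(model.type_set[i])
    B = pattern.points_of_type(model.type_set[j])
    if i == j:
        return _directed_statistic(A, A, model, scale, i, i, same=True)
    return (_directed_statistic(A, B, model, scale, i, j, same=False)
            + _directed_statistic(B, A, model, scale, j, i, same=False))


# -- log density ---------------------------------------------------------


def _covariate_values(covariates, model: ModelSpec, xs, ys) -> np.ndarray:
    """(n, K) matrix of covariate lookups at the given locations."""
    n = len(np.atleast_1d(xs))
    out = np.zeros((n, model.n_covariates))
    for k, name in enumerate(model.covariate_names):
        if covariates is None or name not in covariates:
            raise ValueError(f"covariate {name!r} not supplied")
        out[:, k] = covariates[name].lookup(xs, ys)
    return out


def log_density_unnormalized(pattern: MultitypePointPattern, model: ModelSpec,
                             params: Parameters, covariates=None) -> float:
    """log f(x) up to the (never computed) normalizing constant."""
    total = 0.0
    for t_i, label in enumerate(model.type_set):
        pts = pattern.points_of_type(label)
        if len(pts) == 0:
            continue
        total += len(pts) * params.beta0[t_i]
        if model.n_covariates:
            X = _covariate_values(covariates, model, pts[:, 0], pts[:, 1])
            total += float(X @ params.beta[t_i])
    for i, j in model.pairs():
        a = params.alpha[i, j]
        g = params.gamma[i, j]
        li, lj = model.type_set[i], model.type_set[j]
        if a != 0.0:
            total += a * pair_statistic(pattern, li, lj, "short", model)
        if g != 0.0:
            total += g * pair_statistic(pattern, li, lj, "medium", model)
    return float(total)


# -- incremental pattern state ------------------------------------------


def _top_desc_rows(P: np.ndarray, k: int) -> np.ndarray:
    """Per-row k largest values, sorted descending, zero-padded."""
    m, c = P.shape
    if c < k:
        P = np.pad(P, ((0, 0), (0, k - c)))
    elif c > k:
        P = np.partition(P, c - k, axis=1)[:, c - k:]
    return -np.sort(-P, axis=1)


class PatternState:
    """Incremental bookkeeping for conditional-intensity evaluation.

    For every point ``z``, every type ``a`` and both scales, the state
    stores the N+1 largest potential values ``z`` has toward points of
    type ``a`` (self excluded), sorted descending and zero-padded.  With
    these, the exact change of every saturated pair statistic caused by
    inserting or deleting one point is an O(n) computation:

    * insertion of ``y``:  an existing point gains
      ``max(0, q - L[N-1])`` where ``q`` is its potential with ``y`` and
      ``L[N-1]`` its current N-th largest value;
    * deletion of ``y``:  an existing point loses
      ``max(0, q - L[N])`` — the (N+1)-th value steps in as replacement.

    The same deltas are the interaction columns of the pseudo-likelihood
    design matrix, so fitting, prediction and MCMC all share this code
    path.
    """

    def __init__(self, pattern_or_coords, model: ModelSpec, type_idx=None,
                 window: Window | None = None):
        self.model = model
        self.N = model.saturation
        if isinstance(pattern_or_coords, MultitypePointPattern):
            pat = pattern_or_coords
            for lab in pat.type_set:
                if lab not in model.type_set:
                    raise ValueError(
                        f"pattern label {lab!r} not in model type_set"
                    )
            lut = {t: i for i, t in enumerate(model.type_set)}
            self.coords = pat.coords.astype(float).copy()
            self.type_idx = np.array([lut[t] for t in pat.types], dtype=np.intp)
            self.window = pat.window
        else:
            self.coords = np.asarray(pattern_or_coords, float).reshape(-1, 2).copy()
            self.type_idx = np.asarray(type_idx, dtype=np.intp).copy()
            self.window = window
        self._Rs = model.short_radius_matrix()
        self._Rm_in, self._Rm_out = model.medium_radius_matrices()
        self._rebuild()

    # potentials between a query of type t and points with codes tz
    def _pot(self, d, t, tz, scale):
        if scale == "short":
            return short_values(d, self._Rs[t, tz], self.model.short.family)
        return medium_values(d, self._Rm_in[t, tz], self._Rm_out[t, tz],
                             self.model.medium.family)

    @property
    def n_points(self) -> int:
        return len(self.coords)

    def counts(self) -> np.ndarray:
        return np.bincount(self.type_idx, minlength=self.model.n_types)

    def to_pattern(self) -> MultitypePointPattern:
        labels = [self.model.type_set[i] for i in self.type_idx]
        return MultitypePointPattern(self.coords.copy(), labels, self.window,
                                     type_set=self.model.type_set)

    def _rebuild(self):
        n, p, N = self.n_points, self.model.n_types, self.N
        self.top_short = np.zeros((n, p, N + 1))
        self.top_medium = np.zeros((n, p, N + 1))
        for a in range(p):
            rows_a = np.flatnonzero(self.type_idx == a)
            if len(rows_a) == 0:
                continue
            for b in range(p):
                rows_b = np.flatnonzero(self.type_idx == b)
                if len(rows_b) == 0:
                    continue
                D = cdist(self.coords[rows_a], self.coords[rows_b])
                if a == b:
                    D[np.arange(len(rows_a)), np.arange(len(rows_a))] = np.inf
                Ps = short_values(D, self._Rs[a, b], self.model.short.family)
                Pm = medium_values(D, self._Rm_in[a, b], self._Rm_out[a, b],
                                   self.model.medium.family)
                self.top_short[rows_a, b] = _top_desc_rows(Ps, N + 1)
                self.top_medium[rows_a, b] = _top_desc_rows(Pm, N + 1)

    # -- deltas (no mutation) -------------------------------------------
    def _forward(self, q: np.ndarray) -> np.ndarray:
        """Per-type top-N sums of a query point's potentials."""
        p, N = self.model.n_types, self.N
        out = np.zeros(p)
        for a in range(p):
            out[a] = _top_sum(q[self.type_idx == a], N)
        return out

    def _grouped_sum(self, values: np.ndarray) -> np.ndarray:
        return np.bincount(self.type_idx, weights=values,
                           minlength=self.model.n_types)

    def birth_delta(self, y, t: int):
        """Change of every pair statistic when a point of type ``t`` is
        added at ``y``; returns (delta_short, delta_medium), each (p,)
        indexed by the other type of the pair."""
        N = self.N
        if self.n_points == 0:
            p = self.model.n_types
            return np.zeros(p), np.zeros(p)
        d = np.hypot(self.coords[:, 0] - y[0], self.coords[:, 1] - y[1])
        out = []
        for scale, tops in (("short", self.top_short),
                            ("medium", self.top_medium)):
            q = self._pot(d, t, self.type_idx, scale)
            gains = np.maximum(q - tops[:, t, N - 1], 0.0)
            out.append(self._forward(q) + self._grouped_sum(gains))
        return tuple(out)

    def removal_delta(self, i: int):
        """Change of every pair statistic attributable to point ``i``:
        the birth delta of re-inserting it into the pattern without it."""
        N = self.N
        t = int(self.type_idx[i])
        others = np.arange(self.n_points) != i
        d = np.hypot(self.coords[:, 0] - self.coords[i, 0],
                     self.coords[:, 1] - self.coords[i, 1])
        out = []
        for scale, tops in (("short", self.top_short),
                            ("medium", self.top_medium)):
            q = self._pot(d, t, self.type_idx, scale)
            losses = np.where(others, np.maximum(q - tops[:, t, N], 0.0), 0.0)
            forward = tops[i, :, :N].sum(axis=1)
            out.append(forward + self._grouped_sum(losses))
        return tuple(out)

    # -- batched deltas (static pattern) --------------------------------
    def birth_delta_batch(self, ys: np.ndarray, t: int, chunk: int = 2048):
        """Birth deltas for many candidate locations of one type.

        Returns (Ds, Dm), each of shape (m, p).
        """
        ys = np.asarray(ys, float).reshape(-1, 2)
        m, p, N = len(ys), self.model.n_types, self.N
        Ds = np.zeros((m, p))
        Dm = np.zeros((m, p))
        if self.n_points == 0:
            return Ds, Dm
        onehot = (self.type_idx[:, None] == np.arange(p)[None, :]).astype(float)
        masks = [self.type_idx == a for a in range(p)]
        for lo in range(0, m, chunk):
            sl = slice(lo, min(lo + chunk, m))
            D = cdist(ys[sl], self.coords)
            for scale, tops, out in (("short", self.top_short, Ds),
                                     ("medium", self.top_medium, Dm)):
                Q = self._pot(D, t, self.type_idx[None, :], scale)
                gains = np.maximum(Q - tops[:, t, N - 1][None, :], 0.0)
                block = gains @ onehot
                for a in range(p):
                    sub = Q[:, masks[a]]
                    if sub.shape[1]:
                        block[:, a] += _top_desc_rows(sub, N)[:, :N].sum(axis=1)
                out[sl] = block
        return Ds, Dm

    def removal_delta_batch(self, indices: np.ndarray):
        """Removal deltas for many existing points; (m, p) per scale."""
        indices = np.asarray(indices, dtype=np.intp)
        m, p, N = len(indices), self.model.n_types, self.N
        Ds = np.zeros((m, p))
        Dm = np.zeros((m, p))
        onehot = (self.type_idx[:, None] == np.arange(p)[None, :]).astype(float)
        for t in range(p):
            rows = np.flatnonzero(self.type_idx[indices] == t)
            if len(rows) == 0:
                continue
            idx_t = indices[rows]
            D = cdist(self.coords[idx_t], self.coords)
            for scale, tops, out in (("short", self.top_short, Ds),
                                     ("medium", self.top_medium, Dm)):
                Q = self._pot(D, t, self.type_idx[None, :], scale)
                Q[np.arange(len(rows)), idx_t] = 0.0  # self contributes nothing
                losses = np.maximum(Q - tops[:, t, N][None, :], 0.0)
                out[rows] = tops[idx_t, :, :N].sum(axis=2) + losses @ onehot
        return Ds, Dm

    # -- mutations -------------------------------------------------------
    def apply_birth(self, y, t: int):
        N, p = self.N, self.model.n_types
        y = np.asarray(y, float)
        if self.n_points:
            d = np.hypot(self.coords[:, 0] - y[0], self.coords[:, 1] - y[1])
        else:
            d = np.zeros(0)
        new_rows = {"short": np.zeros((p, N + 1)), "medium": np.zeros((p, N + 1))}
        for scale, tops in (("short", self.top_short),
                            ("medium", self.top_medium)):
            q = self._pot(d, t, self.type_idx, scale) if self.n_points else d
            if self.n_points:
                block = np.concatenate([tops[:, t, :], q[:, None]], axis=1)
                tops[:, t, :] = -np.sort(-block, axis=1)[:, :N + 1]
            for a in range(p):
                va = q[self.type_idx == a]
                new_rows[scale][a] = _top_desc_rows(va[None, :], N + 1)[0] \
                    if len(va) else 0.0
        self.coords = np.vstack([self.coords, y[None, :]])
        self.type_idx = np.append(self.type_idx, t)
        self.top_short = np.concatenate(
            [self.top_short, new_rows["short"][None]], axis=0)
        self.top_medium = np.concatenate(
            [self.top_medium, new_rows["medium"][None]], axis=0)

    def apply_death(self, i: int):
        N = self.N
        t = int(self.type_idx[i])
        others = np.arange(self.n_points) != i
        d = np.hypot(self.coords[:, 0] - self.coords[i, 0],
                     self.coords[:, 1] - self.coords[i, 1])
        affected = {}
        for scale, tops in (("short", self.top_short),
                            ("medium", self.top_medium)):
            q = self._pot(d, t, self.type_idx, scale)
            # 1-ulp slack: distances from different BLAS paths can differ
            # in the last bit; recomputing too often is harmless
            aff = others & (q > 0.0) & (q >= tops[:, t, N] - 1e-12)
            affected[scale] = np.flatnonzero(aff)
        # drop the point
        keep = np.flatnonzero(others)
        remap = -np.ones(self.n_points, dtype=np.intp)
        remap[keep] = np.arange(len(keep))
        self.coords = self.coords[keep]
        self.type_idx = self.type_idx[keep]
        self.top_short = self.top_short[keep]
        self.top_medium = self.top_medium[keep]
        rows_t = np.flatnonzero(self.type_idx == t)
        for scale, tops in (("short", self.top_short),
                            ("medium", self.top_medium)):
            rows = remap[affected[scale]]
            rows = rows[rows >= 0]
            if len(rows) == 0:
                continue
            if len(rows_t) == 0:
                tops[rows, t, :] = 0.0
                continue
            D = cdist(self.coords[rows], self.coords[rows_t])
            # exclude self-pairs by identity, not by distance
            pos_in_t = {idx: k for k, idx in enumerate(rows_t)}
            for r_local, r in enumerate(rows):
                if self.type_idx[r] == t and r in pos_in_t:
                    D[r_local, pos_in_t[r]] = np.inf
            P = self._pot(D, t, self.type_idx[rows_t][None, :], scale)
            tops[rows, t, :] = _top_desc_rows(P, N + 1)


# -- conditional intensity ----------------------------------------------


def _first_order(y, t: int, model: ModelSpec, params: Parameters,
                 covariates) -> float:
    v = params.beta0[t]
    if model.n_covariates:
        X = _covariate_values(covariates, model, [y[0]], [y[1]])
        v += float(X[0] @ params.beta[t])
    return float(v)


def log_papangelou(y, t: str, pattern, model: ModelSpec, params: Parameters,
                   covariates=None, state: PatternState | None = None) -> float:
    """log of the Papangelou conditional intensity lambda(y | x).

    ``y`` must lie inside the window; if ``y`` coincides with a data point
    of type ``t``, remove that point from the pattern first.
    """
    if state is None:
        state = PatternState(pattern, model)
    if state.window is not None and not bool(state.window.contains(y[0], y[1])):
        raise ValueError(f"location {tuple(y)} is outside the window")
    ti = model.type_index(t)
    ds, dm = state.birth_delta(y, ti)
    return (_first_order(y, ti, model, params, covariates)
            + float(params.alpha[ti] @ ds) + float(params.gamma[ti] @ dm))


def papangelou(y, t: str, pattern, model: ModelSpec, params: Parameters,
               covariates=None, state: PatternState | None = None) -> float:
    """Papangelou conditional intensity ``f(x U {y}) / f(x)``."""
    return float(np.exp(log_papangelou(y, t, pattern, model, params,
                                       covariates, state)))


def contribution_decomposition(y, t: str, pattern, model: ModelSpec,
                               params: Parameters, covariates=None,
                               state: PatternState | None = None) -> dict:
    """Per-type signed contributions to the interaction part of the
    log conditional intensity of type ``t`` at ``y``.

    ``c_{t2}(y) = alpha[t, t2] * delta_short(t2) + gamma[t, t2] *
    delta_medium(t2)``; the values sum to ``log lambda(y|x)`` minus the
    first-order terms, exactly.
    """
    if state is None:
        state = PatternState(pattern, model)
    ti = model.type_index(t)
    ds, dm = state.birth_delta(y, ti)
    contrib = params.alpha[ti] * ds + params.gamma[ti] * dm
    return {lab: float(contrib[a]) for a, lab in enumerate(model.type_set)}
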