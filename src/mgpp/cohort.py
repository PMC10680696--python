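"""Cohort-level aggregation of per-image fitted models.

Stacks per-image coefficient tables into one long table, and computes the
descriptive cohort analyses: between-group differences of median
interaction strength, median-absolute-deviation (MAD) heterogeneity
maps, per-pixel top-contributor decompositions of the conditional
intensity, and AUC goodness-of-fit with its correlation against cell-type
abundance.

Pairs are stored unordered with labels in lexicographic canonical order,
so estimates of the same pair from images with different type orderings
aggregate correctly.  MAD is the raw median absolute deviation about the
median (no 1.4826 normal-consistency factor): the maps are comparative,
so the constant is immaterial.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .fit import FittedModel, stratified_uniform
from .gibbs import PatternState, _covariate_values
from .patterns import MultitypePointPattern, PixelImage

#: sentinel label for pixels with no nonzero contribution
NO_CONTRIBUTION = "none"


def _canonical_pair(t1, t2):
    if t2 is None:
        return t1, t2
    a, b = sorted((str(t1), str(t2)))
    return a, b


def extract_parameters(fits) -> pd.DataFrame:
    """Stack per-image :class:`FittedModel` tables into a long cohort table.

    ``fits`` is an iterable of ``(fitted_model, image_id, patient_id,
    group)`` tuples.  One row per coefficient per image; types absent from
    an image (filtered out before fitting) are simply absent, not zero.
    """
    frames = []
    seen = set()
    for fitted, image_id, patient_id, group in fits:
        if image_id in seen:
            raise ValueError(f"duplicate image id {image_id!r}")
        seen.add(image_id)
        tab = fitted.table.copy()
        pairs = [_canonical_pair(a, b)
                 for a, b in zip(tab["type1"], tab["type2"])]
        tab["type1"] = [p[0] for p in pairs]
        tab["type2"] = [p[1] for p in pairs]
        tab.insert(0, "image_id", image_id)
        tab.insert(1, "patient_id", patient_id)
        tab.insert(2, "group", group)
        frames.append(tab)
    table = pd.concat(frames, ignore_index=True)
    dup = table.duplicated(
        subset=["image_id", "kind", "type1", "type2", "covariate", "scale"])
    if dup.any():
        raise ValueError("duplicate (image, coefficient) rows in cohort table")
    return table


def _pair_table(table: pd.DataFrame, kind: str) -> pd.DataFrame:
    if kind not in ("alpha", "gamma"):
        raise ValueError("kind must be 'alpha' or 'gamma'")
    return table[table["kind"] == kind]


def _types_in(tab: pd.DataFrame) -> list:
    return sorted(set(tab["type1"]) | set(tab["type2"]))


def group_median_difference(table: pd.DataFrame, group_a: str, group_b: str,
                            kind: str = "alpha") -> pd.DataFrame:
    """Per-pair ``median(group_a) - median(group_b)`` of the estimates.

    Returns a symmetric types x types DataFrame; a cell is NaN when either
    group has no estimate for that pair.  Swapping the groups negates the
    matrix.
    """
    tab = _pair_table(table, kind)
    for g in (group_a, group_b):
        if g not in set(table["group"]):
            raise ValueError(f"unknown group label {g!r}")
    types = _types_in(tab)
    out = pd.DataFrame(np.nan, index=types, columns=types)
    for (t1, t2), sub in tab.groupby(["type1", "type2"]):
        ests_a = sub.loc[sub["group"] == group_a, "estimate"]
        ests_b = sub.loc[sub["group"] == group_b, "estimate"]
        if len(ests_a) and len(ests_b):
            d = float(ests_a.median() - ests_b.median())
            out.loc[t1, t2] = d
            out.loc[t2, t1] = d
    return out


def mad(values) -> float:
    """Raw median absolute deviation about the median (no scale factor)."""
    values = np.asarray(values, dtype=float)
    return float(np.median(np.abs(values - np.median(values))))


def mad_heterogeneity(table: pd.DataFrame, grouping: str = "all",
                      kind: str = "alpha"):
    """MAD of each interaction estimate across images.

    ``grouping="all"`` pools the whole cohort and returns one symmetric
    matrix; ``grouping="per-group"`` returns ``{group: matrix}``.  Cells
    with fewer than two estimates are NaN.
    """
    tab = _pair_table(table, kind)

    def one(sub_all: pd.DataFrame) -> pd.DataFrame:
        types = _types_in(tab)
        out = pd.DataFrame(np.nan, index=types, columns=types)
        for (t1, t2), sub in sub_all.groupby(["type1", "type2"]):
            if len(sub) >= 2:
                v = mad(sub["estimate"])
                out.loc[t1, t2] = v
                out.loc[t2, t1] = v
        return out

    if grouping == "all":
        return one(tab)
    if grouping == "per-group":
        return {g: one(sub) for g, sub in tab.groupby("group")}
    raise ValueError("grouping must be 'all' or 'per-group'")


# -- conditional-intensity based diagnostics ----------------------------


def _log_papangelou_scores(state: PatternState, fitted: FittedModel,
                           t: int, locations: np.ndarray,
                           covariates, removal_indices=None) -> np.ndarray:
    """Vectorized log conditional intensity at many locations.

    With ``removal_indices`` the locations are existing data points and
    the pattern-minus-self convention is used.
    """
    model, params = fitted.model, fitted.params
    if removal_indices is not None:
        Ds, Dm = state.removal_delta_batch(removal_indices)
    else:
        Ds, Dm = state.birth_delta_batch(locations, t)
    scores = np.full(len(locations), params.beta0[t])
    if model.n_covariates:
        X = _covariate_values(covariates, model, locations[:, 0],
                              locations[:, 1])
        scores += X @ params.beta[t]
    scores += Ds @ params.alpha[t] + Dm @ params.gamma[t]
    return scores


def top_contributor_map(fitted: FittedModel, pattern: MultitypePointPattern,
                        target_type: str, grid=(64, 64), covariates=None):
    """Which other cell type dominates the conditional intensity of
    ``target_type`` at each point in space.

    At every pixel center the interaction part of the log conditional
    intensity is decomposed into per-type contributions
    ``c_t2 = alpha[t,t2]*delta_short + gamma[t,t2]*delta_medium``; the
    label image records the type of largest |c_t2| over t2 != target
    (ties broken by type_set order), with sentinel ``"none"`` where all
    contributions vanish.  Returns ``(labels, magnitude)`` where labels
    is an (n_rows, n_cols) object array and magnitude a
    :class:`PixelImage` holding the signed winning contribution.
    """
    model, params = fitted.model, fitted.params
    t = model.type_index(target_type)
    state = PatternState(pattern, model)
    n_rows, n_cols = grid
    img = PixelImage(pattern.window, np.zeros(grid))
    xs, ys = img.pixel_centers()
    gx, gy = np.meshgrid(xs, ys)
    centers = np.column_stack([gx.ravel(), gy.ravel()])

    # a data point of the target type exactly at a pixel center must be
    # removed from the conditioning pattern first
    target_pts = state.coords[state.type_idx == t]
    coincident = {}
    if len(target_pts):
        key = {(x, y): i for i, (x, y) in
               enumerate(map(tuple, state.coords))
               if state.type_idx[i] == t}
        for m, (cx, cy) in enumerate(map(tuple, centers)):
            if (cx, cy) in key:
                coincident[m] = key[(cx, cy)]

    Ds, Dm = state.birth_delta_batch(centers, t)
    if coincident:
        idx = np.array(list(coincident.values()), dtype=np.intp)
        rDs, rDm = state.removal_delta_batch(idx)
        rows = np.array(list(coincident.keys()), dtype=np.intp)
        Ds[rows], Dm[rows] = rDs, rDm

    C = Ds * params.alpha[t][None, :] + Dm * params.gamma[t][None, :]
    C_other = C.copy()
    C_other[:, t] = 0.0  # the within-type contribution is excluded
    winner = np.argmax(np.abs(C_other), axis=1)
    best = C_other[np.arange(len(C_other)), winner]
    labels = np.array([model.type_set[w] if b != 0.0 else NO_CONTRIBUTION
                       for w, b in zip(winner, best)], dtype=object)
    return (labels.reshape(grid),
            PixelImage(pattern.window, best.reshape(grid)))


def mann_whitney_auc(positives, negatives) -> float:
    """P(positive score > negative score) with half credit for ties."""
    pos = np.asarray(positives, dtype=float)
    neg = np.asarray(negatives, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both score sets must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    return float((ranks[:len(pos)].sum() - len(pos) * (len(pos) + 1) / 2)
                 / (len(pos) * len(neg)))


def model_auc(fitted: FittedModel, pattern: MultitypePointPattern,
              type_label: str, covariates=None, n_reference: int = 10_000,
              seed: int = 0) -> float:
    """Discrimination AUC of the predicted conditional intensity for one
    cell type.

    Positives are the log conditional intensities at the observed points
    of the type (each conditioning on the pattern minus that point);
    negatives are evaluated at stratified-uniform reference locations
    given the full pattern.  The AUC is the Mann-Whitney probability that
    a positive outscores a negative, with half credit for ties — a
    constant-intensity model therefore scores exactly 0.5.
    """
    model = fitted.model
    t = model.type_index(type_label)
    state = PatternState(pattern, model)
    pos_idx = np.flatnonzero(state.type_idx == t)
    if len(pos_idx) == 0:
        raise ValueError(f"no points of type {type_label!r}")
    rng = np.random.default_rng(seed)
    ref = stratified_uniform(pattern.window, n_reference, rng)
    pos = _log_papangelou_scores(state, fitted, t, state.coords[pos_idx],
                                 covariates, removal_indices=pos_idx)
    neg = _log_papangelou_scores(state, fitted, t, ref, covariates)
    return mann_whitney_auc(pos, neg)


def auc_abundance_correlation(auc_table: pd.DataFrame,
                              abundance_table: pd.DataFrame) -> pd.Series:
    """Pearson correlation of per-image (AUC, cell count) pairs, per type.

    Both tables need columns ``image_id, type`` plus ``auc`` or ``count``.
    Types with fewer than 3 paired observations, or zero variance in
    either variable, get NaN.
    """
    merged = auc_table.merge(abundance_table, on=["image_id", "type"])
    out = {}
    for t, sub in merged.groupby("type"):
        a = sub["auc"].to_numpy(float)
        c = sub["count"].to_numpy(float)
        if len(sub) < 3 or np.std(a) == 0 or np.std(c) == 0:
            out[t] = np.nan
        else:
            out[t] = float(np.corrcoef(a, c)[0, 1])
    return pd.Series(out, name="pearson_r")
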