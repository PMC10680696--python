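"""Shared fixtures and independent brute-force oracles.

The oracles implement the literal subset-enumeration definition of the
saturated pair statistics and never share code with the package's sorted
top-N implementation.
"""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from mgpp import (
    CohortConfig,
    FittedModel,
    ModelSpec,
    MultitypePointPattern,
    Parameters,
    Window,
    extract_parameters,
    filter_types,
    fit_mgpp,
    generate_cohort,
)

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


# -- independent oracles -------------------------------------------------


def brute_saturated_potential(x, target, potential, N) -> float:
    """Max over all size-min(N, k) subsets of the subset potential sum —
    the literal definition of the saturated statistic."""
    target = np.asarray(target, dtype=float).reshape(-1, 2)
    if len(target) == 0:
        return 0.0
    d = np.hypot(target[:, 0] - x[0], target[:, 1] - x[1])
    vals = potential.evaluate(d)
    m = min(N, len(vals))
    return max(
        float(np.sort(np.asarray(c))[::-1].sum())
        for c in combinations(vals, m)
    )


def brute_pair_statistic(pattern, t1, t2, scale, model) -> float:
    """Double sum over points with the subset-enumeration statistic."""
    pot = model.short if scale == "short" else model.medium
    N = model.saturation
    A = pattern.points_of_type(t1)
    B = pattern.points_of_type(t2)

    def directed(src, dst, same):
        total = 0.0
        for i, z in enumerate(src):
            tgt = np.delete(dst, i, axis=0) if same else dst
            total += brute_saturated_potential(z, tgt, pot, N)
        return total

    if t1 == t2:
        return directed(A, A, True)
    return directed(A, B, False) + directed(B, A, False)


def brute_log_density(pattern, model, params) -> float:
    """Term-by-term expansion of the unnormalized log density using the
    brute-force pair statistics (no spatial covariates)."""
    total = 0.0
    for t_i, lab in enumerate(model.type_set):
        total += len(pattern.points_of_type(lab)) * params.beta0[t_i]
    for i in range(model.n_types):
        for j in range(i, model.n_types):
            li, lj = model.type_set[i], model.type_set[j]
            total += params.alpha[i, j] * brute_pair_statistic(
                pattern, li, lj, "short", model)
            total += params.gamma[i, j] * brute_pair_statistic(
                pattern, li, lj, "medium", model)
    return total


# -- random scenario builders -------------------------------------------


def random_small_scene(seed, n_types=2, max_points=8, side=120.0,
                       saturation=None):
    """A small random pattern + model + nonzero parameters for oracle
    comparisons, at scales where saturation binds."""
    rng = np.random.default_rng(seed)
    p = n_types
    n = int(rng.integers(2, max_points + 1))
    window = Window(0.0, side, 0.0, side)
    coords = rng.uniform(0.0, side, (n, 2))
    labels = [f"T{rng.integers(p)}" for _ in range(n)]
    type_set = [f"T{i}" for i in range(p)]
    pattern = MultitypePointPattern(coords, labels, window, type_set=type_set)
    N = saturation if saturation is not None else int(rng.integers(1, 4))
    model = ModelSpec(type_set=type_set, saturation=N)
    alpha = rng.normal(0.0, 0.8, (p, p))
    alpha = (alpha + alpha.T) / 2
    gamma = rng.normal(0.0, 0.5, (p, p))
    gamma = (gamma + gamma.T) / 2
    params = Parameters(beta0=rng.normal(-4.0, 1.0, p), alpha=alpha,
                        gamma=gamma)
    return pattern, model, params


def fitted_from_params(model: ModelSpec, params: Parameters,
                       se: float = 0.1) -> FittedModel:
    """A FittedModel wrapping known coefficients (for cohort-stage tests
    that do not need an actual fit)."""
    from mgpp.fit import _coefficient_rows

    rows = _coefficient_rows(model)
    table = pd.DataFrame(rows, columns=["kind", "type1", "type2",
                                        "covariate", "scale"])
    est = list(params.beta0)
    for k in range(model.n_covariates):
        est += list(params.beta[:, k])
    for kind_m in (params.alpha, params.gamma):
        est += [kind_m[i, j] for i, j in model.pairs()]
    est = np.asarray(est, dtype=float)
    table["estimate"] = est
    table["se"] = se
    table["ci_low"] = est - 1.96 * se
    table["ci_high"] = est + 1.96 * se
    table["significant"] = (table["ci_low"] > 0) | (table["ci_high"] < 0)
    return FittedModel(model=model, params=params, table=table, level=0.95,
                       converged=True, n_dummy=0, seed=0)


# -- end-to-end pipeline fixture ----------------------------------------


@pytest.fixture(scope="session")
def pipeline_cohort():
    """A pinned-seed synthetic cohort run through the full chain:
    generate -> per-image covariates + type filter + fit -> cohort table.

    Shared across test modules; 4 patients per group x 3 images keeps the
    whole chain to a couple of minutes.
    """
    from mgpp import assemble_covariates

    config = CohortConfig(n_patients_per_group=4, images_per_patient=3)
    cohort = generate_cohort(config, seed=20)
    fits = []
    for img in cohort.images:
        covs, modeled = assemble_covariates(
            img.pattern, distance_to=config.vasculature_type,
            empty_region=True, grid=(64, 64))
        modeled, kept = filter_types(modeled, min_cells=20)
        model = ModelSpec(type_set=kept,
                          covariate_names=sorted(covs),
                          saturation=config.saturation)
        fitted = fit_mgpp(modeled, model, covariates=covs, n_dummy=400,
                          seed=101)
        fits.append((fitted, img.image_id, img.patient_id, img.group,
                     modeled, covs))
    table = extract_parameters([f[:4] for f in fits])
    return {"config": config, "cohort": cohort, "fits": fits,
            "table": table}
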