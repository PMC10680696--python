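"""Association of spatial interaction estimates with patient survival.

For every eligible (cell-type pair, scale) the per-image interaction
estimates enter a Cox proportional hazards model

``lambda(t | a_ijk) = lambda0(t) * exp(b0 + b1*a_ijk + b2*Age_i + b3*Sex_i)``

with one observation per *image* and cluster-robust sandwich variance
with clusters = patients, which accounts for the correlation between the
several interaction estimates of the same patient.  Pairs estimated in
fewer than ``min_images`` images (default 10) are screened out, and the
Wald p-values are adjusted jointly across all (pair, scale) tests with
the Benjamini-Hochberg step-up procedure.

The partial likelihood uses lifelines' Efron tie handling; simulated
survival times are continuous, so ties — where Efron and Breslow
differ — do not arise there.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from statsmodels.stats.multitest import multipletests

DEFAULT_MIN_IMAGES = 10

_KIND_TO_SCALE = {"alpha": "short", "gamma": "medium"}
_SCALE_TO_KIND = {v: k for k, v in _KIND_TO_SCALE.items()}


@dataclass
class CoxResult:
    """Per-(pair, scale) hazard-ratio inference."""

    type1: str
    type2: str
    scale: str
    log_hr: float  # b1, per unit interaction estimate
    robust_se: float
    p_value: float
    q_value: float  # filled by the screen; NaN until then
    n_images: int
    n_patients: int
    converged: bool


def _pair_rows(table: pd.DataFrame, pair, scale: str) -> pd.DataFrame:
    kind = _SCALE_TO_KIND[scale]
    t1, t2 = sorted(str(t) for t in pair)
    return table[(table["kind"] == kind) & (table["type1"] == t1)
                 & (table["type2"] == t2)]


def screen_pairs(table: pd.DataFrame,
                 min_images: int = DEFAULT_MIN_IMAGES) -> list:
    """(type1, type2, scale) combinations with estimates from at least
    ``min_images`` images (boundary inclusive)."""
    if min_images < 1:
        raise ValueError("min_images must be >= 1")
    tab = table[table["kind"].isin(_KIND_TO_SCALE)]
    out = []
    for (kind, t1, t2), sub in tab.groupby(["kind", "type1", "type2"]):
        if sub["image_id"].nunique() >= min_images:
            out.append((t1, t2, _KIND_TO_SCALE[kind]))
    return sorted(out)


def fit_cox_interaction(table: pd.DataFrame, survival: pd.DataFrame,
                        pair, scale: str) -> CoxResult:
    """Cox model of survival on one pair's per-image estimates.

    Observations are images (no averaging within patients); each image
    row joins the patient's age, sex, time and event indicator, and the
    variance is the cluster-robust sandwich with clusters = patients.
    Non-convergence or an event-free cohort yields a flagged result with
    missing p-value instead of an exception.
    """
    rows = _pair_rows(table, pair, scale)
    t1, t2 = sorted(str(t) for t in pair)
    df = rows.merge(survival, on="patient_id", how="left",
                    suffixes=("", "_surv"))
    if df["time"].isna().any():
        missing = df.loc[df["time"].isna(), "patient_id"].unique()
        raise ValueError(f"no survival record for patient(s) {list(missing)}")
    n_images = int(df["image_id"].nunique())
    n_patients = int(df["patient_id"].nunique())
    result = CoxResult(type1=t1, type2=t2, scale=scale, log_hr=np.nan,
                       robust_se=np.nan, p_value=np.nan, q_value=np.nan,
                       n_images=n_images, n_patients=n_patients,
                       converged=False)
    if df["event"].sum() == 0:
        return result
    data = df[["time", "event", "estimate", "age", "sex",
               "patient_id"]].copy()
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(data, duration_col="time", event_col="event",
                    cluster_col="patient_id", robust=True)
        row = cph.summary.loc["estimate"]
        result.log_hr = float(row["coef"])
        result.robust_se = float(row["se(coef)"])
        result.p_value = float(row["p"])
        result.converged = np.isfinite(result.log_hr) and \
            np.isfinite(result.robust_se)
    except Exception:
        pass
    return result


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone in p-rank)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_survival_screen(table: pd.DataFrame, survival: pd.DataFrame,
                        min_images: int = DEFAULT_MIN_IMAGES,
                        fdr_family: str = "joint") -> pd.DataFrame:
    """Screen pairs, fit a Cox model per (pair, scale) and FDR-adjust.

    ``fdr_family="joint"`` pools the short- and medium-range tests into a
    single Benjamini-Hochberg family (the default); ``"per-scale"``
    adjusts the two scales separately.
    """
    eligible = screen_pairs(table, min_images=min_images)
    results = [fit_cox_interaction(table, survival, (t1, t2), scale)
               for t1, t2, scale in eligible]
    out = pd.DataFrame([vars(r) for r in results])
    if len(out) == 0:
        return out
    if fdr_family == "joint":
        families = [np.ones(len(out), dtype=bool)]
    elif fdr_family == "per-scale":
        families = [(out["scale"] == s).to_numpy()
                    for s in out["scale"].unique()]
    else:
        raise ValueError("fdr_family must be 'joint' or 'per-scale'")
    for fam in families:
        mask = fam & out["p_value"].notna().to_numpy()
        if mask.any():
            out.loc[mask, "q_value"] = bh_adjust(out.loc[mask, "p_value"])
    return out
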