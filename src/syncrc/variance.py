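"""Variance decomposition of signature exposure proportions.

Random-intercept mixed model ``Y = m + MMRstatus + Individual + Tumour``:
fixed intercept and MMR status, random Individual (patient) intercept,
Tumour-level residual. Fitted by REML via statsmodels MixedLM with a
method-of-moments fallback for degenerate inputs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class VarianceDecomposition:
    var_individual: float
    var_tumour: float  # residual
    individual_share: float  # var_individual / (var_individual + var_tumour)
    fixed_effects: dict[str, float]
    method: str  # "reml" | "moments" | "degenerate"

    def __post_init__(self) -> None:
        assert self.var_individual >= 0 and self.var_tumour >= 0
        assert 0.0 <= self.individual_share <= 1.0


def _fixed_design(mmr: np.ndarray, covariates: pd.DataFrame | None) -> pd.DataFrame:
    X = pd.DataFrame({"intercept": np.ones(len(mmr))})
    if len(set(mmr)) > 1:
        X["mmr_msi"] = (np.asarray(mmr) == "MSI").astype(float)
    if covariates is not None:
        for col in covariates.columns:
            vals = covariates[col]
            if vals.dtype == object:
                vals = pd.factorize(vals)[0].astype(float)
            if np.std(vals) > 0:
                X[col] = np.asarray(vals, dtype=float)
    return X


def _moments_decomposition(resid: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """ANOVA-type estimator on fixed-effect residuals (Searle's method of
    moments for the unbalanced one-way layout)."""
    df = pd.DataFrame({"y": resid, "g": groups})
    sizes = df.groupby("g")["y"].count().to_numpy(dtype=float)
    means = df.groupby("g")["y"].mean()
    n = float(len(df))
    a = float(len(sizes))
    ssw = float(((df["y"] - df["g"].map(means)) ** 2).sum())
    grand = float(df["y"].mean())
    ssb = float((sizes * (means.to_numpy() - grand) ** 2).sum())
    msw = ssw / max(n - a, 1.0)
    msb = ssb / max(a - 1.0, 1.0)
    n0 = (n - float((sizes**2).sum()) / n) / max(a - 1.0, 1.0)
    var_ind = max((msb - msw) / max(n0, 1e-12), 0.0)
    return var_ind, max(msw, 0.0)


def decompose_variance(
    proportions: np.ndarray,
    patient_of: np.ndarray,
    mmr_of: np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> VarianceDecomposition:
    """Decompose exposure-proportion variance into Individual (patient)
    and Tumour (residual) components after removing intercept + MMR (and
    any extra fixed covariates, e.g. sample preparation).

    Requires at least two patients, each contributing at least two
    tumours. Variance components are truncated at zero.
    """
    y = np.asarray(proportions, dtype=float)
    groups = np.asarray(patient_of)
    mmr = np.asarray(mmr_of)
    if y.ndim != 1 or len(y) != len(groups) or len(y) != len(mmr):
        raise ValueError("proportions, patient and MMR arrays must be 1-D and aligned")
    sizes = pd.Series(groups).value_counts()
    if len(sizes) < 2 or (sizes < 2).any():
        raise ValueError("need >=2 patients with >=2 tumours each (singular design)")

    X = _fixed_design(mmr, covariates)
    beta, *_ = np.linalg.lstsq(X.to_numpy(), y, rcond=None)
    resid = y - X.to_numpy() @ beta
    fixed = dict(zip(X.columns, map(float, beta)))

    within_var = float(
        pd.DataFrame({"r": resid, "g": groups}).groupby("g")["r"].var(ddof=1).mean()
    )
    if within_var < 1e-14:
        between = float(np.var(pd.DataFrame({"r": resid, "g": groups}).groupby("g")["r"].mean()))
        share = 1.0 if between > 1e-14 else 0.0
        return VarianceDecomposition(between, 0.0, share, fixed, "degenerate")

    try:
        import statsmodels.api as sm

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = sm.MixedLM(y, X.to_numpy(), groups=groups)
            res = md.fit(reml=True)
        var_ind = max(float(np.asarray(res.cov_re)[0, 0]), 0.0)
        var_res = max(float(res.scale), 0.0)
        fixed = dict(zip(X.columns, map(float, res.fe_params)))
        method = "reml"
    except Exception as exc:  # fall back to moments on any fit failure
        logger.warning("REML fit failed (%s); using method-of-moments", exc)
        var_ind, var_res = _moments_decomposition(resid, groups)
        method = "moments"

    total = var_ind + var_res
    share = var_ind / total if total > 0 else 0.0
    return VarianceDecomposition(var_ind, var_res, share, fixed, method)
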