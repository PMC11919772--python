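"""Per-cohort association: covariate residualisation, case-control variance
tests with signed Z-scores, and mean-effect EWAS.

All three variance tests (Brown-Forsythe/Levene, Bartlett, Fligner-Killeen)
are implemented vectorised across probes, since a cohort can carry several
hundred thousand probes. Sign convention: positive Z means greater dispersion
(or methylation) in cases.

Two-sided P-values are converted to signed Z via ``sign * Phi^-1(1 - P/2)``
with P floored at 1e-300 so Z stays finite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300
VARIANCE_TESTS = ("levene", "bartlett", "fligner_killeen")


@dataclass
class CovariateSpec:
    """Which sample-sheet columns enter the design matrix and how.

    ``categorical`` columns are dummy-encoded dropping the first level;
    for ``cell_proportion_prefix`` columns one is dropped to avoid the
    sum-to-one collinearity.
    """

    numeric: tuple[str, ...] = ("horvath_age", "smoking_score")
    categorical: tuple[str, ...] = ("predicted_sex", "sentrix_id",
                                    "sentrix_position")
    cell_proportion_prefix: str = "cell_prop_"

    def columns(self, samplesheet: pd.DataFrame) -> list[str]:
        cells = sorted(c for c in samplesheet.columns
                       if c.startswith(self.cell_proportion_prefix))
        return list(self.numeric) + list(self.categorical) + cells


def build_design(samplesheet: pd.DataFrame,
                 spec: CovariateSpec | None = None,
                 include_diagnosis: bool = False) -> pd.DataFrame:
    """Dummy-encoded, full-rank design matrix with an intercept.

    Raises on rank deficiency, naming the offending columns. Samples with
    missing covariates are dropped (logged).
    """
    spec = spec or CovariateSpec()
    cols = spec.columns(samplesheet)
    missing_cols = [c for c in list(spec.numeric) + list(spec.categorical)
                    if c not in samplesheet.columns]
    if missing_cols:
        raise ValueError(f"covariate columns absent from sample sheet: "
                         f"{missing_cols}")
    sub = samplesheet[cols].copy()
    complete = sub.notna().all(axis=1)
    if not complete.all():
        logger.info("dropping %d samples with missing covariates",
                    int((~complete).sum()))
        sub = sub[complete]

    parts = [pd.Series(1.0, index=sub.index, name="intercept")]
    if include_diagnosis:
        diag = samplesheet.loc[sub.index, "diagnosis"]
        parts.append((diag == "case").astype(float).rename("diagnosis_case"))
    for c in spec.numeric:
        parts.append(sub[c].astype(float))
    for c in spec.categorical:
        # single-level factors contribute nothing beyond the intercept
        dummies = pd.get_dummies(sub[c], prefix=c, drop_first=True, dtype=float)
        for col in dummies.columns:
            parts.append(dummies[col])
    cell_cols = sorted(c for c in sub.columns
                       if c.startswith(spec.cell_proportion_prefix))
    for c in cell_cols[1:]:  # drop first: proportions sum to one
        parts.append(sub[c].astype(float))

    design = pd.concat(parts, axis=1)
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        culprits = _collinear_columns(design)
        raise ValueError(f"rank-deficient design (rank {rank} < "
                         f"{design.shape[1]} columns); collinear columns: "
                         f"{culprits}")
    return design


def _collinear_columns(design: pd.DataFrame) -> list[str]:
    """Columns whose removal restores full rank, via pivoted QR."""
    from scipy.linalg import qr
    arr = design.to_numpy()
    _, r, piv = qr(arr, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(arr.shape) * np.finfo(float).eps
    bad = piv[np.where(diag < tol)[0]] if (diag < tol).any() else piv[np.linalg.matrix_rank(arr):]
    return [design.columns[i] for i in np.atleast_1d(bad)]


def residualize(beta: pd.DataFrame, samplesheet: pd.DataFrame,
                spec: CovariateSpec | None = None) -> pd.DataFrame:
    """OLS residuals of each probe's beta values on the shared covariate
    design (diagnosis is never in the design)."""
    design = build_design(samplesheet, spec, include_diagnosis=False)
    common = beta.columns.intersection(design.index)
    if len(common) < design.shape[1] + 1:
        raise ValueError("fewer samples than design columns")
    y = beta[common].to_numpy().T                      # samples x probes
    x = design.loc[common].to_numpy()
    q, _ = np.linalg.qr(x)
    resid = y - q @ (q.T @ y)
    out = pd.DataFrame(resid.T, index=beta.index, columns=common)
    out.attrs["design_columns"] = list(design.columns)
    return out


# ---------------------------------------------------------------------------
# variance tests (vectorised over probes; rows = probes)

def _signed_z(p: np.ndarray, sign: np.ndarray) -> np.ndarray:
    p = np.clip(p, P_FLOOR, 1.0)
    return np.where(sign < 0, -1.0, 1.0) * stats.norm.isf(p / 2.0)


def levene_test(case: np.ndarray, control: np.ndarray,
                center: str = "median"):
    """Levene / Brown-Forsythe test on rows.

    Returns ``(W, p, z)`` arrays. ``center`` is ``"median"`` (Brown-Forsythe,
    default) or ``"mean"``. Probes whose within-group absolute deviations are
    all zero get NaN.
    """
    case = np.atleast_2d(np.asarray(case, dtype=float))
    control = np.atleast_2d(np.asarray(control, dtype=float))
    n1, n0 = case.shape[1], control.shape[1]
    if n1 < 2 or n0 < 2:
        raise ValueError("need >=2 values per group")
    centre = {"median": np.median, "mean": np.mean}[center]
    z1 = np.abs(case - centre(case, axis=1, keepdims=True))
    z0 = np.abs(control - centre(control, axis=1, keepdims=True))
    m1, m0 = z1.mean(axis=1), z0.mean(axis=1)
    n = n1 + n0
    grand = (n1 * m1 + n0 * m0) / n
    between = n1 * (m1 - grand) ** 2 + n0 * (m0 - grand) ** 2
    within = ((z1 - m1[:, None]) ** 2).sum(axis=1) + \
             ((z0 - m0[:, None]) ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = (n - 2) / 1.0 * between / within
    w = np.where(within > 0, w, np.nan)
    p = stats.f.sf(w, 1, n - 2)
    z = _signed_z(p, np.sign(m1 - m0))
    z = np.where(np.isnan(w), np.nan, z)
    return w, p, z


def bartlett_test(case: np.ndarray, control: np.ndarray):
    """Bartlett's test on rows; returns ``(T, p, z)``."""
    case = np.atleast_2d(np.asarray(case, dtype=float))
    control = np.atleast_2d(np.asarray(control, dtype=float))
    n1, n0 = case.shape[1], control.shape[1]
    if n1 < 2 or n0 < 2:
        raise ValueError("need >=2 values per group")
    v1 = case.var(axis=1, ddof=1)
    v0 = control.var(axis=1, ddof=1)
    n = n1 + n0
    sp2 = ((n1 - 1) * v1 + (n0 - 1) * v0) / (n - 2)
    c = 1.0 + (1.0 / (n1 - 1) + 1.0 / (n0 - 1) - 1.0 / (n - 2)) / 3.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = ((n - 2) * np.log(sp2)
             - (n1 - 1) * np.log(v1) - (n0 - 1) * np.log(v0)) / c
    t = np.where((v1 > 0) & (v0 > 0), t, np.nan)
    p = stats.chi2.sf(t, 1)
    z = _signed_z(p, np.sign(v1 - v0))
    z = np.where(np.isnan(t), np.nan, z)
    return t, p, z


def fligner_killeen_test(case: np.ndarray, control: np.ndarray):
    """Fligner-Killeen normal-scores test on rows; returns ``(X2, p, z)``.

    Pooled ranks of within-group absolute deviations from the group median
    are mapped through ``Phi^-1(1/2 + r / (2(N+1)))``.
    """
    case = np.atleast_2d(np.asarray(case, dtype=float))
    control = np.atleast_2d(np.asarray(control, dtype=float))
    n1, n0 = case.shape[1], control.shape[1]
    if n1 < 2 or n0 < 2:
        raise ValueError("need >=2 values per group")
    d1 = np.abs(case - np.median(case, axis=1, keepdims=True))
    d0 = np.abs(control - np.median(control, axis=1, keepdims=True))
    pooled = np.concatenate([d1, d0], axis=1)
    n = n1 + n0
    ranks = stats.rankdata(pooled, method="average", axis=1)
    a = stats.norm.ppf(0.5 + ranks / (2.0 * (n + 1)))
    abar = a.mean(axis=1, keepdims=True)
    v = a.var(axis=1, ddof=1)
    a1 = a[:, :n1].mean(axis=1)
    a0 = a[:, n1:].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        x2 = (n1 * (a1 - abar[:, 0]) ** 2 + n0 * (a0 - abar[:, 0]) ** 2) / v
    x2 = np.where(v > 0, x2, np.nan)
    p = stats.chi2.sf(x2, 1)
    z = _signed_z(p, np.sign(a1 - a0))
    z = np.where(np.isnan(x2), np.nan, z)
    return x2, p, z


_TEST_FUNCS = {"levene": levene_test, "bartlett": bartlett_test,
               "fligner_killeen": fligner_killeen_test}


# ---------------------------------------------------------------------------
# mean-effect EWAS

def mean_ewas(beta: pd.DataFrame, samplesheet: pd.DataFrame,
              spec: CovariateSpec | None = None) -> pd.DataFrame:
    """Per-probe OLS of methylation on diagnosis + covariates.

    Returns a frame with ``beta`` (case-control methylation difference),
    ``se``, ``p_mean`` (two-sided t) and ``z_mean`` = beta/se.
    """
    design = build_design(samplesheet, spec, include_diagnosis=True)
    common = beta.columns.intersection(design.index)
    x = design.loc[common].to_numpy()
    y = beta[common].to_numpy().T                      # samples x probes
    n, p = x.shape
    if n <= p:
        raise ValueError("fewer samples than design columns")
    xtx_inv = np.linalg.inv(x.T @ x)
    coefs = xtx_inv @ (x.T @ y)                        # p x probes
    resid = y - x @ coefs
    dof = n - p
    sigma2 = (resid ** 2).sum(axis=0) / dof
    j = design.columns.get_loc("diagnosis_case")
    b = coefs[j]
    se = np.sqrt(sigma2 * xtx_inv[j, j])
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = b / se
    pval = 2.0 * stats.t.sf(np.abs(tstat), dof)
    return pd.DataFrame({"beta": b, "se": se, "p_mean": pval,
                         "z_mean": tstat}, index=beta.index)


# ---------------------------------------------------------------------------
# orchestration

def run_cohort_association(beta: pd.DataFrame, samplesheet: pd.DataFrame,
                           spec: CovariateSpec | None = None,
                           tests: tuple[str, ...] = VARIANCE_TESTS,
                           levene_center: str = "median") -> pd.DataFrame:
    """Full per-cohort analysis: residualise, run the selected variance
    tests on residuals, and the mean EWAS on raw betas.

    Returns one row per probe. Probes where a test is undefined carry NaN
    for that test and an ``na_reason`` code.
    """
    unknown = set(tests) - set(_TEST_FUNCS)
    if unknown:
        raise ValueError(f"unknown variance tests: {sorted(unknown)}")
    resid = residualize(beta, samplesheet, spec)
    diag = samplesheet.loc[resid.columns, "diagnosis"]
    case_ids = resid.columns[diag == "case"]
    ctrl_ids = resid.columns[diag == "control"]
    if len(case_ids) < 2 or len(ctrl_ids) < 2:
        raise ValueError("need >=2 cases and >=2 controls after design cleanup")
    case = resid[case_ids].to_numpy()
    control = resid[ctrl_ids].to_numpy()

    out = pd.DataFrame(index=beta.index)
    out["n_case"] = len(case_ids)
    out["n_control"] = len(ctrl_ids)
    na_mask = np.zeros(len(beta), dtype=bool)
    for name in tests:
        func = _TEST_FUNCS[name]
        if name == "levene":
            stat, p, z = func(case, control, center=levene_center)
        else:
            stat, p, z = func(case, control)
        out[f"stat_{name}"] = stat
        out[f"p_{name}"] = p
        out[f"z_{name}"] = z
        na_mask |= np.isnan(stat)

    mean_stats = mean_ewas(beta, samplesheet, spec)
    out = out.join(mean_stats)
    out["na_reason"] = np.where(na_mask, "degenerate_dispersion", "")
    return out
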