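"""Cross-cohort meta-analysis of variance and mean-effect statistics.

Variance Z-scores are combined by Stouffer's method weighted by the square
root of each cohort's analysed sample size; mean effects by inverse-variance
weighting, fixed and random effects (DerSimonian-Laird tau^2). Probes present
in fewer than two cohorts are excluded. Multiplicity control is
Benjamini-Hochberg FDR plus a Bonferroni threshold at the per-phenotype test
count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

FDR_ALPHA = 0.05


def stouffer_meta(z_by_cohort: np.ndarray, n_by_cohort: np.ndarray):
    """Sample-size weighted Stouffer combination along the last axis.

    ``z_by_cohort`` may contain NaN for cohorts not reporting a probe; such
    entries contribute nothing. Rows with fewer than 2 contributing cohorts
    get NaN. Returns ``(z_meta, p_meta, n_studies)``.
    """
    z = np.atleast_2d(np.asarray(z_by_cohort, dtype=float))
    n = np.broadcast_to(np.asarray(n_by_cohort, dtype=float), z.shape)
    ok = np.isfinite(z)
    w = np.where(ok, np.sqrt(n), 0.0)
    num = np.nansum(w * np.where(ok, z, 0.0), axis=-1)
    den = np.sqrt((w ** 2).sum(axis=-1))
    k = ok.sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z_meta = num / den
    z_meta = np.where(k >= 2, z_meta, np.nan)
    p_meta = 2.0 * stats.norm.sf(np.abs(z_meta))
    return z_meta, p_meta, k


def ivw_meta(beta_by_cohort: np.ndarray, se_by_cohort: np.ndarray):
    """Inverse-variance-weighted meta-analysis along the last axis.

    Fixed effects plus DerSimonian-Laird random effects. NaN entries are
    cohorts not reporting the probe; rows with <2 studies get NaN. Returns a
    dict of arrays: beta_fe, se_fe, p_fe, beta_re, se_re, p_re, tau2, q, i2,
    n_studies.
    """
    b = np.atleast_2d(np.asarray(beta_by_cohort, dtype=float))
    s = np.atleast_2d(np.asarray(se_by_cohort, dtype=float))
    if np.any(s[np.isfinite(s)] <= 0):
        raise ValueError("standard errors must be positive")
    ok = np.isfinite(b) & np.isfinite(s)
    w = np.where(ok, 1.0 / s ** 2, 0.0)
    k = ok.sum(axis=-1)
    sw = w.sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta_fe = (w * np.where(ok, b, 0.0)).sum(axis=-1) / sw
        se_fe = 1.0 / np.sqrt(sw)
        q = (w * (np.where(ok, b, 0.0) - beta_fe[..., None]) ** 2).sum(axis=-1)
        denom = sw - (w ** 2).sum(axis=-1) / sw
        tau2 = np.maximum(0.0, (q - (k - 1)) / denom)
        w_re = np.where(ok, 1.0 / (s ** 2 + tau2[..., None]), 0.0)
        sw_re = w_re.sum(axis=-1)
        beta_re = (w_re * np.where(ok, b, 0.0)).sum(axis=-1) / sw_re
        se_re = 1.0 / np.sqrt(sw_re)
        i2 = np.where(q > 0, np.maximum(0.0, (q - (k - 1)) / q), 0.0)
    bad = k < 2
    for arr in (beta_fe, se_fe, q, tau2, beta_re, se_re, i2):
        arr[bad] = np.nan
    p_fe = 2.0 * stats.norm.sf(np.abs(beta_fe / se_fe))
    p_re = 2.0 * stats.norm.sf(np.abs(beta_re / se_re))
    return {"beta_fe": beta_fe, "se_fe": se_fe, "p_fe": p_fe,
            "beta_re": beta_re, "se_re": se_re, "p_re": p_re,
            "tau2": tau2, "q": q, "i2": i2, "n_studies": k}


def bonferroni_threshold(alpha: float, m: int) -> float:
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def multiplicity(p_values: np.ndarray, alpha: float = FDR_ALPHA):
    """BH step-up q-values, Bonferroni threshold and significance flags.

    Returns ``(q_values, threshold, fdr_flags, bonferroni_flags)``; the
    per-phenotype test count m is ``len(p_values)``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty P-value vector")
    if np.nanmin(p) <= 0 or np.nanmax(p) > 1:
        raise ValueError("P-values must lie in (0, 1]")
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    m = int(ok.sum())
    _, q_ok, _, _ = multipletests(p[ok], alpha=alpha, method="fdr_bh")
    q[ok] = q_ok
    threshold = bonferroni_threshold(alpha, m)
    fdr_flags = np.where(ok, q < alpha, False)
    bonf_flags = np.where(ok, p < threshold, False)
    return q, threshold, fdr_flags, bonf_flags


def _direction_string(z_row: np.ndarray) -> str:
    return "".join("?" if not np.isfinite(z) else ("+" if z > 0 else "-")
                   for z in z_row)


def meta_analyse(cohort_stats: dict[str, pd.DataFrame],
                 n_by_cohort: dict[str, int] | None = None,
                 variance_test: str = "levene",
                 use_adjusted: bool = True,
                 alpha: float = FDR_ALPHA) -> pd.DataFrame:
    """Combine per-cohort summary frames into one MetaStats table.

    ``cohort_stats`` maps cohort name -> frame indexed by probe_id with the
    association/adjustment columns. ``n_by_cohort`` defaults to
    n_case + n_control read from each frame. Probes reported in fewer than
    two cohorts are dropped (count logged).
    """
    names = list(cohort_stats)
    if len(names) < 2:
        raise ValueError("need at least two cohorts")
    suffix = "_adj" if use_adjusted else ""
    zcol = f"z_{variance_test}{suffix}"
    bcol, scol = f"beta{suffix}", f"se{suffix}"
    for nm, df in cohort_stats.items():
        if zcol not in df.columns:
            raise ValueError(f"cohort {nm!r} lacks column {zcol!r}")

    universe = cohort_stats[names[0]].index
    for nm in names[1:]:
        universe = universe.union(cohort_stats[nm].index)
    z = np.column_stack([cohort_stats[nm].reindex(universe)[zcol].to_numpy()
                         for nm in names])
    if n_by_cohort is None:
        n_by_cohort = {
            nm: int(cohort_stats[nm][["n_case", "n_control"]].iloc[0].sum())
            for nm in names}
    n = np.array([n_by_cohort[nm] for nm in names], dtype=float)

    z_meta, p_meta, k = stouffer_meta(z, n)
    has_mean = all({bcol, scol}.issubset(cohort_stats[nm].columns)
                   for nm in names)
    out = pd.DataFrame(index=universe)
    out["n_studies"] = k
    out["z_meta"] = z_meta
    out["p_meta"] = p_meta
    out["direction"] = [_direction_string(row) for row in z]

    if has_mean:
        b = np.column_stack([cohort_stats[nm].reindex(universe)[bcol].to_numpy()
                             for nm in names])
        s = np.column_stack([cohort_stats[nm].reindex(universe)[scol].to_numpy()
                             for nm in names])
        ivw = ivw_meta(b, s)
        for key, col in [("beta_fe", "beta_ivw_fe"), ("se_fe", "se_ivw_fe"),
                         ("p_fe", "p_ivw_fe"), ("beta_re", "beta_ivw_re"),
                         ("se_re", "se_ivw_re"), ("p_re", "p_ivw_re"),
                         ("tau2", "tau2"), ("q", "q_het"), ("i2", "i2")]:
            out[col] = ivw[key]
        out["direction_mean"] = [_direction_string(row) for row in b]

    dropped = int((out["n_studies"] < 2).sum())
    if dropped:
        logger.info("excluded %d probes reported in <2 studies", dropped)
    out = out[out["n_studies"] >= 2].copy()
    ok = out["p_meta"].notna()
    # clip P=0 into (0,1] before multiplicity (Z floored upstream keeps P>0)
    out.loc[ok, "p_meta"] = out.loc[ok, "p_meta"].clip(lower=1e-300)
    q, threshold, fdr, bonf = multiplicity(out["p_meta"].to_numpy(), alpha)
    out["q_meta"] = q
    out["fdr_significant"] = fdr
    out["bonferroni_significant"] = bonf
    out.attrs["m_tests"] = int(out["p_meta"].notna().sum())
    out.attrs["bonferroni_threshold"] = threshold
    if has_mean:
        qm, _, fdrm, bonfm = multiplicity(
            out["p_ivw_re"].clip(lower=1e-300).to_numpy(), alpha)
        out["q_ivw_re"] = qm
        out["fdr_significant_mean"] = fdrm
        out["bonferroni_significant_mean"] = bonfm
    return out


def classify(meta_table: pd.DataFrame, alpha: float = FDR_ALPHA
             ) -> tuple[pd.DataFrame, pd.Series]:
    """Label each probe VMP / DMP / both / neither from a combined meta table
    and summarise counts (including the share of VMPs with increased
    variance)."""
    needed = {"fdr_significant", "fdr_significant_mean"}
    if not needed.issubset(meta_table.columns):
        raise ValueError(f"meta table lacks columns {sorted(needed)}")
    vmp = meta_table["fdr_significant"].astype(bool)
    dmp = meta_table["fdr_significant_mean"].astype(bool)
    label = np.select([vmp & dmp, vmp, dmp], ["both", "VMP", "DMP"],
                      default="neither")
    out = meta_table.copy()
    out["label"] = label
    n_vmp = int((vmp).sum())
    n_up = int((vmp & (out["z_meta"] > 0)).sum())
    summary = pd.Series({
        "n_vmp": n_vmp,
        "n_dmp": int(dmp.sum()),
        "n_both": int((vmp & dmp).sum()),
        "n_vmp_variance_up": n_up,
        "pct_vmp_variance_up": 100.0 * n_up / n_vmp if n_vmp else np.nan,
    })
    return out, summary
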