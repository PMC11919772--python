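"""Sample- and probe-level quality control and cohort demographics.

Filters applied (each producing an auditable reason):

* samples with detection P > 0.01 at more than 10% of probes;
* samples with median methylated or unmethylated intensity below 2500;
* samples whose reported and predicted sex disagree, or whose predicted sex
  is undefined (missing reported sex with a conclusive prediction is kept);
* probes with detection P > 0.01 in more than 10% of samples;
* probes carrying any annotation blacklist flag.

The demographics summary reproduces case-control 2x2 sex chi-square tests
(with continuity correction) and Welch two-sample t-tests on epigenetic age.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DETECTION_P_THRESHOLD = 0.01
DETECTION_FAIL_FRACTION = 0.10
MIN_MEDIAN_INTENSITY = 2500.0

BLACKLIST_FLAGS = ("flag_non_autosomal", "flag_non_cpg",
                   "flag_cross_hybridising", "flag_snp_proximal")


@dataclass
class QCReport:
    """Per-item QC bookkeeping; ``table`` has one row per sample or probe."""

    table: pd.DataFrame
    n_before: int
    n_after: int

    @property
    def kept_ids(self) -> pd.Index:
        return self.table.index[self.table["kept"]]

    @property
    def removed_ids(self) -> pd.Index:
        return self.table.index[~self.table["kept"]]

    def __post_init__(self) -> None:
        assert self.n_before == len(self.table)
        assert self.n_after == int(self.table["kept"].sum())


def _check_alignment(beta: pd.DataFrame, detp: pd.DataFrame | None,
                     samplesheet: pd.DataFrame | None) -> None:
    if beta.empty:
        raise ValueError("empty beta matrix")
    if detp is not None:
        if not beta.columns.equals(detp.columns) or not beta.index.equals(detp.index):
            raise ValueError("beta and detection-P matrices are misaligned")
    if samplesheet is not None:
        missing = beta.columns.difference(samplesheet.index)
        if len(missing):
            raise ValueError(f"samples absent from sample sheet: "
                             f"{missing.tolist()[:10]}")


def filter_samples(beta: pd.DataFrame, detp: pd.DataFrame | None,
                   intensity_summary: pd.DataFrame | None,
                   samplesheet: pd.DataFrame,
                   exclusion_list: list[str] | None = None
                   ) -> tuple[pd.Index, QCReport]:
    """Apply the sample-level filters; returns kept sample IDs and a report.

    ``intensity_summary`` needs columns ``median_methylated`` and
    ``median_unmethylated``; if None the intensity rule is skipped with a
    warning. The sex rule is skipped if ``predicted_sex`` is absent.
    ``exclusion_list`` carries externally identified outlier samples.
    """
    _check_alignment(beta, detp, samplesheet)
    samples = beta.columns
    reasons: dict[str, list[str]] = {s: [] for s in samples}

    if detp is not None:
        fail_frac = (detp.to_numpy() > DETECTION_P_THRESHOLD).mean(axis=0)
        fail_frac = pd.Series(fail_frac, index=samples)
        for s in samples[fail_frac > DETECTION_FAIL_FRACTION]:
            reasons[s].append("detection")
    else:
        fail_frac = pd.Series(np.nan, index=samples)
        logger.warning("no detection-P matrix: sample detection rule skipped")

    med_m = med_u = pd.Series(np.nan, index=samples)
    if intensity_summary is not None:
        missing = samples.difference(intensity_summary.index)
        if len(missing):
            raise ValueError(f"samples absent from intensity summary: "
                             f"{missing.tolist()[:10]}")
        med_m = intensity_summary.loc[samples, "median_methylated"]
        med_u = intensity_summary.loc[samples, "median_unmethylated"]
        low = (med_m < MIN_MEDIAN_INTENSITY) | (med_u < MIN_MEDIAN_INTENSITY)
        for s in samples[low]:
            reasons[s].append("intensity")
    else:
        logger.warning("no intensity summary: intensity rule skipped")

    if "predicted_sex" in samplesheet.columns:
        predicted = samplesheet.loc[samples, "predicted_sex"]
        reported = (samplesheet.loc[samples, "reported_sex"]
                    if "reported_sex" in samplesheet.columns
                    else pd.Series(pd.NA, index=samples))
        undefined = predicted.isna() | (predicted == "unknown")
        mismatch = (reported.notna() & predicted.notna()
                    & (predicted != "unknown") & (reported != predicted))
        for s in samples[undefined]:
            reasons[s].append("undefined predicted sex")
        for s in samples[mismatch]:
            reasons[s].append("sex mismatch")
    else:
        logger.warning("no predicted_sex column: sex rule skipped")

    for s in exclusion_list or []:
        if s in reasons:
            reasons[s].append("external exclusion")

    table = pd.DataFrame({
        "detection_fail_fraction": fail_frac,
        "median_methylated": med_m,
        "median_unmethylated": med_u,
        "removal_reasons": [";".join(reasons[s]) for s in samples],
        "kept": [not reasons[s] for s in samples],
    }, index=samples.rename("sample_id"))
    report = QCReport(table, n_before=len(samples),
                      n_after=int(table["kept"].sum()))
    return report.kept_ids, report


def filter_probes(beta: pd.DataFrame, detp: pd.DataFrame | None,
                  annotation: pd.DataFrame) -> tuple[pd.Index, QCReport]:
    """Apply probe-level detection and blacklist filters."""
    _check_alignment(beta, detp, None)
    probes = beta.index
    missing = probes.difference(annotation.index)
    if len(missing):
        raise ValueError(f"probes missing from annotation: "
                         f"{missing.tolist()[:10]}"
                         + ("..." if len(missing) > 10 else ""))
    reasons: dict[str, list[str]] = {p: [] for p in probes}

    if detp is not None:
        fail_frac = (detp.to_numpy() > DETECTION_P_THRESHOLD).mean(axis=1)
        fail_frac = pd.Series(fail_frac, index=probes)
        for p in probes[fail_frac > DETECTION_FAIL_FRACTION]:
            reasons[p].append("detection")
    else:
        fail_frac = pd.Series(np.nan, index=probes)
        logger.warning("no detection-P matrix: probe detection rule skipped")

    annot = annotation.loc[probes]
    for flag in BLACKLIST_FLAGS:
        if flag not in annot.columns:
            continue
        for p in probes[annot[flag].fillna(False).astype(bool)]:
            reasons[p].append(flag.removeprefix("flag_"))

    table = pd.DataFrame({
        "detection_fail_fraction": fail_frac,
        "removal_reasons": [";".join(reasons[p]) for p in probes],
        "kept": [not reasons[p] for p in probes],
    }, index=probes.rename("probe_id"))
    report = QCReport(table, n_before=len(probes),
                      n_after=int(table["kept"].sum()))
    return report.kept_ids, report


# ---------------------------------------------------------------------------
# demographics

def chi2_sex_test(n_ctrl_male: int, n_ctrl_female: int,
                  n_case_male: int, n_case_female: int) -> tuple[float, float, int]:
    """2x2 chi-square with continuity correction, |O-E| reduced by
    min(0.5, |O-E|) before squaring."""
    obs = np.array([[n_ctrl_male, n_ctrl_female],
                    [n_case_male, n_case_female]], dtype=float)
    if (obs.sum(axis=1) == 0).any() or (obs.sum(axis=0) == 0).any():
        raise ValueError("a margin of the 2x2 table is zero")
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    diff = np.abs(obs - expected)
    diff = diff - np.minimum(0.5, diff)
    chi2 = float((diff ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, p, 1


def welch_t_from_summaries(mean1: float, sd1: float, n1: int,
                           mean2: float, sd2: float, n2: int
                           ) -> tuple[float, float, float]:
    """Welch t-statistic, two-sided P and Welch-Satterthwaite df from
    group summary statistics (group1 - group2)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need >=2 samples per group")
    v1, v2 = sd1 ** 2 / n1, sd2 ** 2 / n2
    t = (mean1 - mean2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return float(t), p, float(df)


def summarize_cohort(samplesheet: pd.DataFrame) -> pd.Series:
    """Demographics for one cohort: group sizes, sex counts, continuity-
    corrected sex chi-square, Horvath-age means/SDs and Welch t-test.

    Mean difference follows the control-minus-case printing convention.
    """
    diag = samplesheet["diagnosis"]
    ctrl = samplesheet[diag == "control"]
    case = samplesheet[diag == "case"]
    if len(ctrl) < 2 or len(case) < 2:
        raise ValueError("need >=2 samples in each diagnosis group")
    sex_col = ("predicted_sex" if "predicted_sex" in samplesheet.columns
               else "reported_sex")
    counts = {
        "n_controls": len(ctrl), "n_cases": len(case),
        "n_controls_male": int((ctrl[sex_col] == "male").sum()),
        "n_controls_female": int((ctrl[sex_col] == "female").sum()),
        "n_cases_male": int((case[sex_col] == "male").sum()),
        "n_cases_female": int((case[sex_col] == "female").sum()),
    }
    chi2, chi2_p, df = chi2_sex_test(counts["n_controls_male"],
                                     counts["n_controls_female"],
                                     counts["n_cases_male"],
                                     counts["n_cases_female"])
    age_c, age_k = ctrl["horvath_age"], case["horvath_age"]
    t, t_p, t_df = welch_t_from_summaries(
        age_c.mean(), age_c.std(ddof=1), len(age_c),
        age_k.mean(), age_k.std(ddof=1), len(age_k))
    return pd.Series({
        **counts,
        "chi2_statistic": chi2, "chi2_p": chi2_p, "chi2_df": df,
        "age_mean_controls": age_c.mean(), "age_sd_controls": age_c.std(ddof=1),
        "age_mean_cases": age_k.mean(), "age_sd_cases": age_k.std(ddof=1),
        "age_mean_difference": age_c.mean() - age_k.mean(),
        "t_statistic": t, "t_p": t_p, "t_df": t_df,
    })
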