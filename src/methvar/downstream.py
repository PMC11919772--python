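"""Enrichment and epigenetic-covariance analyses of significant probes.

* Fisher's exact overrepresentation of hit genes/probes in gene sets or
  genomic-feature sets, with Haldane-Anscombe corrected odds ratios and
  BH control within each analysis panel, optionally stratified by the sign
  of the variance Z-score.
* Tissue-enriched gene sets from an expression table (top fraction of genes
  per tissue).
* Phenome-wide covariance: Pearson correlation between meta-analysis
  Z-scores and standardised external-catalog effect sizes per trait,
  restricted to traits intersecting at least ``min_probes`` probes.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

MIN_CATALOG_PROBES = 10


def tissue_enriched_sets(expression: pd.DataFrame,
                         top_fraction: float = 0.05) -> dict[str, list[str]]:
    """Per tissue, the genes in the top ``top_fraction`` by expression.

    Ties at the cutoff are broken by stable gene-ID order: genes are ranked
    by (-expression, gene_id) and the first ``ceil(fraction * n)`` taken.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    if (expression.to_numpy() < 0).any():
        raise ValueError("expression values must be nonnegative")
    n_top = int(np.ceil(top_fraction * len(expression)))
    out = {}
    for tissue in expression.columns:
        ranked = expression[tissue].sort_values(
            ascending=False, kind="mergesort")  # stable: ties keep ID order
        out[tissue] = ranked.index[:n_top].tolist()
    return out


def _odds_ratio_ci(table: np.ndarray, z975: float = 1.959963984540054):
    """Sample OR with Haldane-Anscombe 0.5 correction when any cell is 0,
    and its Woolf logit 95% CI."""
    a, b, c, d = table.ravel().astype(float)
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se_log = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = np.exp(np.log(or_) - z975 * se_log)
    hi = np.exp(np.log(or_) + z975 * se_log)
    return or_, lo, hi


def fisher_enrichment(hits: Sequence[str], universe: Sequence[str],
                      sets: Mapping[str, Sequence[str]],
                      stratify_by_direction: pd.Series | None = None,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Two-sided Fisher's exact enrichment of ``hits`` within each set.

    Set members outside the universe are ignored; a set with no members in
    the universe raises. ``stratify_by_direction`` maps hit IDs to signed
    Z-scores; when given, additional ``variance_up`` / ``variance_down``
    strata are computed (BH applies within each stratum panel).
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty universe")
    hit_set = set(hits)
    if not hit_set <= universe_set:
        raise ValueError("hits must be a subset of the universe")

    strata: dict[str, set[str]] = {"all": hit_set}
    if stratify_by_direction is not None:
        signs = stratify_by_direction.reindex(list(hit_set))
        strata["variance_up"] = set(signs.index[signs > 0])
        strata["variance_down"] = set(signs.index[signs < 0])

    rows = []
    for stratum, stratum_hits in strata.items():
        for name, members in sets.items():
            inset = set(members) & universe_set
            if not inset:
                raise ValueError(f"set {name!r} has no members in the universe")
            a = len(stratum_hits & inset)
            b = len(stratum_hits) - a
            c = len(inset) - a
            d = len(universe_set) - len(stratum_hits) - c
            table = np.array([[a, b], [c, d]])
            _, p = stats.fisher_exact(table, alternative="two-sided")
            or_, lo, hi = _odds_ratio_ci(table)
            rows.append({"set": name, "stratum": stratum,
                         "n_hit_in_set": a, "n_hit_not_set": b,
                         "n_nonhit_in_set": c, "n_nonhit_not_set": d,
                         "odds_ratio": or_, "ci_low": lo, "ci_high": hi,
                         "p": p})
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    for stratum in out["stratum"].unique():
        mask = out["stratum"] == stratum
        _, q, _, _ = multipletests(out.loc[mask, "p"], alpha=alpha,
                                   method="fdr_bh")
        out.loc[mask, "q"] = q
    return out


def epigenetic_covariance(meta_z: pd.Series, catalog: pd.DataFrame,
                          min_probes: int = MIN_CATALOG_PROBES,
                          alpha: float = 0.05) -> pd.DataFrame:
    """Per-trait Pearson correlation between meta Z-scores and standardised
    catalog effect sizes over intersecting probes.

    ``catalog`` columns: ``trait``, ``probe_id``, ``effect``. Traits with
    fewer than ``min_probes`` intersecting probes are excluded; traits with
    fewer than 2 are skipped with a log entry. The Bonferroni line is
    ``alpha / n_traits_tested``.
    """
    needed = {"trait", "probe_id", "effect"}
    if not needed.issubset(catalog.columns):
        raise ValueError(f"catalog lacks columns {sorted(needed - set(catalog.columns))}")
    z = meta_z.dropna()
    rows = []
    for trait, grp in catalog.groupby("trait"):
        grp = grp.drop_duplicates("probe_id")
        common = grp["probe_id"][grp["probe_id"].isin(z.index)]
        n = len(common)
        if n < 2:
            logger.info("trait %r has %d intersecting probes; skipped",
                        trait, n)
            continue
        if n < min_probes:
            continue
        effects = grp.set_index("probe_id").loc[common, "effect"].to_numpy()
        scaled = (effects - effects.mean()) / effects.std(ddof=0)
        r, p = stats.pearsonr(z.loc[common].to_numpy(), scaled)
        rows.append({"trait": trait, "n_probes": n, "r": float(r),
                     "p": float(p)})
    out = pd.DataFrame(rows, columns=["trait", "n_probes", "r", "p"])
    if len(out):
        _, q, _, _ = multipletests(out["p"], alpha=alpha, method="fdr_bh")
        out["q"] = q
        out["bonferroni_significant"] = out["p"] < alpha / len(out)
        out.attrs["bonferroni_line"] = alpha / len(out)
    return out


def zscore_correlation(stats_a: pd.Series, stats_b: pd.Series,
                       probe_subset: Sequence[str] | None = None
                       ) -> tuple[float, float, int]:
    """Pearson correlation of two Z-score series over shared (optionally
    subset) probes; used for replication and cross-phenotype checks."""
    common = stats_a.dropna().index.intersection(stats_b.dropna().index)
    if probe_subset is not None:
        common = common.intersection(pd.Index(probe_subset))
    if len(common) < 3:
        raise ValueError(f"only {len(common)} shared probes; need >=3")
    r, p = stats.pearsonr(stats_a.loc[common], stats_b.loc[common])
    return float(r), float(p), len(common)


def probes_to_genes(probe_ids: Sequence[str],
                    annotation: pd.DataFrame) -> list[str]:
    """Unique nearest-gene labels for a probe list (enrichment unit mapping)."""
    genes = annotation.loc[annotation.index.intersection(pd.Index(probe_ids)),
                           "nearest_gene"].dropna()
    return sorted(set(genes))
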