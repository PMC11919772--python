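"""Aggregation of probe-level statistics into spatially localised regions.

A comb-p-style procedure: seed at probes below ``seed_p``, extend over
neighbouring probes below ``extend_p`` within ``window_bp``, combine member
P-values by the Stouffer-Liptak method under a genomic-distance correlation
model estimated from the data, and apply a Sidak correction scaled by the
ratio of the total tested span to the region span. Reported regions require
at least two probes and P_Sidak < 0.05.

Coordinates are 1-based inclusive throughout; the BED writer converts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class RegionParams:
    seed_p: float = 0.05
    extend_p: float = 0.05
    window_bp: int = 500
    sidak_alpha: float = 0.05
    min_probes: int = 2
    acf_max_lag_bp: int = 1000
    acf_bin_width: int = 100

    def to_dict(self) -> dict:
        return asdict(self)


def estimate_autocorrelation(z: np.ndarray, positions: np.ndarray,
                             chromosomes: np.ndarray,
                             max_lag_bp: int = 1000,
                             bin_width: int = 100) -> pd.DataFrame:
    """Binned Pearson correlation of Z-scores between probe pairs as a
    function of genomic distance, truncated at zero.

    Returns a frame with ``lag_low``, ``lag_high``, ``correlation``,
    ``n_pairs``. The implicit lag-0 correlation is 1.
    """
    z = np.asarray(z, dtype=float)
    positions = np.asarray(positions)
    chromosomes = np.asarray(chromosomes)
    n_bins = int(np.ceil(max_lag_bp / bin_width))
    pairs_a: list[list[float]] = [[] for _ in range(n_bins)]
    pairs_b: list[list[float]] = [[] for _ in range(n_bins)]
    for chrom in pd.unique(chromosomes):
        mask = chromosomes == chrom
        if mask.sum() < 2:
            raise ValueError(f"fewer than 2 probes on {chrom}")
        order = np.argsort(positions[mask])
        pos = positions[mask][order]
        zc = z[mask][order]
        # all pairs within max_lag_bp of each other, windowed scan
        for i in range(len(pos)):
            for j in range(i + 1, len(pos)):
                d = pos[j] - pos[i]
                if d > max_lag_bp:
                    break
                if d == 0:
                    continue
                b = int((d - 1) // bin_width)
                pairs_a[b].append(zc[i])
                pairs_b[b].append(zc[j])
    rows = []
    for b in range(n_bins):
        lo, hi = b * bin_width + 1, (b + 1) * bin_width
        if len(pairs_a[b]) >= 3:
            ok = (np.isfinite(pairs_a[b]) & np.isfinite(pairs_b[b]))
            a = np.asarray(pairs_a[b])[ok]
            bb = np.asarray(pairs_b[b])[ok]
            if len(a) >= 3 and a.std() > 0 and bb.std() > 0:
                r = float(np.corrcoef(a, bb)[0, 1])
            else:
                r = 0.0
        else:
            r = 0.0
        rows.append({"lag_low": lo, "lag_high": hi,
                     "correlation": max(0.0, r), "n_pairs": len(pairs_a[b])})
    return pd.DataFrame(rows)


def _acf_lookup(acf: pd.DataFrame | None, dist: float) -> float:
    if dist <= 0:
        return 1.0
    if acf is None or acf.empty:
        return 0.0
    row = acf[(acf["lag_low"] <= dist) & (dist <= acf["lag_high"])]
    return float(row["correlation"].iloc[0]) if len(row) else 0.0


def stouffer_liptak(p_values: np.ndarray, corr: np.ndarray | None = None
                    ) -> tuple[float, float]:
    """Correlation-adjusted Stouffer combination of two-sided P-values.

    Each P maps to a positive score ``Phi^-1(1 - p/2)``; the combined score is
    ``sum(z) / sqrt(1' C 1)`` with C the member correlation matrix (identity
    recovers plain Stouffer). Returns ``(z_combined, p_combined)`` with a
    one-sided upper-tail P, as the scores are positive by construction.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no P-values to combine")
    z = stats.norm.isf(np.clip(p, 1e-300, 1.0) / 2.0)
    if corr is None:
        denom = float(p.size)
    else:
        corr = np.asarray(corr, dtype=float)
        denom = float(corr.sum())
        if denom <= 0:
            denom = float(p.size)
    z_comb = z.sum() / np.sqrt(denom)
    return float(z_comb), float(stats.norm.sf(z_comb))


def sidak_correct(p: float, region_span: int, total_span: int) -> float:
    """P_Sidak = 1 - (1 - p)^(total_span / region_span)."""
    if region_span <= 0 or total_span <= 0:
        raise ValueError("spans must be positive")
    exponent = total_span / region_span
    # log1p form keeps precision for tiny p
    return float(-np.expm1(exponent * np.log1p(-min(p, 1.0 - 1e-16))))


def find_regions(meta_table: pd.DataFrame, annotation: pd.DataFrame,
                 params: RegionParams | None = None,
                 p_column: str = "p_meta",
                 z_column: str = "z_meta") -> pd.DataFrame:
    """Seed-and-extend region detection over a meta-analysis table.

    ``meta_table``: indexed by probe_id, with ``p_column`` and ``z_column``.
    ``annotation``: indexed by probe_id with ``chr`` and ``pos``. Probes
    without annotation are dropped with a warning.
    """
    params = params or RegionParams()
    known = meta_table.index.intersection(annotation.index)
    dropped = len(meta_table) - len(known)
    if dropped:
        logger.warning("dropping %d probes without annotation", dropped)
    df = meta_table.loc[known, [p_column, z_column]].join(
        annotation.loc[known, ["chr", "pos"]])
    df = df.dropna(subset=[p_column, "pos"]).sort_values(["chr", "pos"])

    # total span for the Sidak correction: bases covered by tested probes
    # extended by the window on each side, merged per chromosome
    total_span = 0
    for _, grp in df.groupby("chr", sort=False):
        pos = grp["pos"].to_numpy()
        gaps = np.diff(pos)
        covered = 2 * params.window_bp + 1 + np.minimum(
            gaps, 2 * params.window_bp + 1).sum()
        total_span += int(covered)

    acf = None
    multi = df.groupby("chr")["pos"].count()
    if (multi >= 2).all() and len(df) >= 10:
        acf = estimate_autocorrelation(df[z_column].to_numpy(),
                                       df["pos"].to_numpy(),
                                       df["chr"].to_numpy(),
                                       params.acf_max_lag_bp,
                                       params.acf_bin_width)

    regions = []
    for chrom, grp in df.groupby("chr", sort=False):
        pos = grp["pos"].to_numpy()
        pvals = grp[p_column].to_numpy()
        zvals = grp[z_column].to_numpy()
        ids = grp.index.to_numpy()
        used = np.zeros(len(pos), dtype=bool)
        seeds = np.where(pvals < params.seed_p)[0]
        for s in seeds:
            if used[s]:
                continue
            members = [s]
            # extend left then right over sub-threshold probes within window
            i = s
            while i - 1 >= 0 and not used[i - 1] \
                    and pos[i] - pos[i - 1] <= params.window_bp \
                    and pvals[i - 1] < params.extend_p:
                i -= 1
                members.insert(0, i)
            i = s
            while i + 1 < len(pos) and not used[i + 1] \
                    and pos[i + 1] - pos[i] <= params.window_bp \
                    and pvals[i + 1] < params.extend_p:
                i += 1
                members.append(i)
            used[members] = True
            if len(members) < params.min_probes:
                continue
            mpos = pos[members]
            mp = pvals[members]
            mz = zvals[members]
            corr = np.eye(len(members))
            for a in range(len(members)):
                for b in range(a + 1, len(members)):
                    corr[a, b] = corr[b, a] = _acf_lookup(
                        acf, abs(mpos[b] - mpos[a]))
            z_comb, p_comb = stouffer_liptak(mp, corr)
            span = int(mpos[-1] - mpos[0] + 1)
            p_sidak = sidak_correct(p_comb, span, total_span)
            regions.append({
                "chrom": chrom, "start": int(mpos[0]), "end": int(mpos[-1]),
                "n_probes": len(members),
                "probe_ids": ",".join(ids[members]),
                "z_combined": z_comb, "p_combined": p_comb,
                "p_sidak": p_sidak,
                "direction": "".join("+" if z > 0 else "-" for z in mz),
            })
    out = pd.DataFrame(regions, columns=["chrom", "start", "end", "n_probes",
                                         "probe_ids", "z_combined",
                                         "p_combined", "p_sidak", "direction"])
    out = out[out["p_sidak"] < params.sidak_alpha].reset_index(drop=True)
    out.attrs["total_span"] = total_span
    return out
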