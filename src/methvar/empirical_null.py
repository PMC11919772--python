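"""Empirical-null estimation of bias and inflation in test statistics.

A three-component Gaussian mixture

    p0 * N(mu0, sigma0^2) + p1 * N(mu1, sigma1^2) + p2 * N(mu2, sigma2^2)

is fitted to a vector of signed Z-scores by Gibbs sampling with conjugate
priors (Dirichlet on proportions, normal on means, inverse-gamma on
variances). Components are identified each sweep by ordering their means
(mu1 < mu0 < mu2); the central component is the empirical null, whose
posterior-mean location and scale give the bias and inflation used to
rescale statistics:  z' = (z - bias) / inflation.

A closed-form genomic-control style estimator is provided as a clearly
non-default fallback for inputs too small for the sampler.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

RECOMMENDED_MIN_N = 1000


@dataclass
class NullSettings:
    n_iter: int = 5000
    burnin: int = 2000
    seed: int = 0
    # pseudo-counts for (null, negative, positive) component proportions
    dirichlet_alpha: tuple[float, float, float] = (90.0, 5.0, 5.0)
    # normal priors (mean, sd) on component means, order (null, neg, pos).
    # Side components are pushed well away from zero so they cannot absorb
    # the tails of a pure null and shrink the inflation estimate.
    mean_priors: tuple[tuple[float, float], ...] = ((0.0, 1.0), (-5.0, 0.5),
                                                    (5.0, 0.5))
    # inverse-gamma priors (shape, scale) on component variances; the side
    # components are kept broad for the same reason.
    var_priors: tuple[tuple[float, float], ...] = ((2.0, 1.0), (6.0, 20.0),
                                                   (6.0, 20.0))
    min_null_proportion: float = 0.05

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class NullEstimate:
    bias: float
    inflation: float
    null_proportion: float
    proportions: tuple[float, float, float]     # (null, neg, pos)
    means: tuple[float, float, float]
    sds: tuple[float, float, float]
    posterior_sd_bias: float
    posterior_sd_inflation: float
    settings: NullSettings
    method: str = "gibbs"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["settings"] = self.settings.to_dict()
        return d


def fit_empirical_null(z: np.ndarray,
                       settings: NullSettings | None = None) -> NullEstimate:
    """Fit the three-component mixture to signed Z-scores by Gibbs sampling."""
    settings = settings or NullSettings()
    z = np.asarray(z, dtype=float).ravel()
    if z.size == 0 or not np.all(np.isfinite(z)):
        raise ValueError("input must be non-empty and finite")
    if z.size < RECOMMENDED_MIN_N:
        import warnings
        warnings.warn(f"only {z.size} statistics; empirical-null fit is "
                      f"unreliable below {RECOMMENDED_MIN_N}", stacklevel=2)

    rng = np.random.default_rng(settings.seed)
    n = z.size
    alpha = np.asarray(settings.dirichlet_alpha, dtype=float)
    prior_mean = np.array([m for m, _ in settings.mean_priors])
    prior_mean_var = np.array([s ** 2 for _, s in settings.mean_priors])
    a0 = np.array([a for a, _ in settings.var_priors])
    b0 = np.array([b for _, b in settings.var_priors])

    # initialise at a perturbed empirical split
    mu = np.array([np.median(z), np.quantile(z, 0.05), np.quantile(z, 0.95)])
    var = np.full(3, max(z.var(), 1e-6))
    pi = np.array([0.9, 0.05, 0.05])

    keep = settings.n_iter - settings.burnin
    if keep <= 0:
        raise ValueError("n_iter must exceed burnin")
    trace_mu = np.empty(keep)
    trace_sd = np.empty(keep)
    trace_pi = np.empty((keep, 3))
    trace_side_mu = np.empty((keep, 2))
    trace_side_sd = np.empty((keep, 2))

    log2pi = np.log(2.0 * np.pi)
    for it in range(settings.n_iter):
        # responsibilities and assignment draw
        logp = (np.log(pi)[:, None]
                - 0.5 * (log2pi + np.log(var))[:, None]
                - 0.5 * (z[None, :] - mu[:, None]) ** 2 / var[:, None])
        logp -= logp.max(axis=0, keepdims=True)
        w = np.exp(logp)
        w /= w.sum(axis=0, keepdims=True)
        u = rng.random(n)
        assign = (u > w[0]).astype(np.int8) + (u > w[0] + w[1]).astype(np.int8)

        counts = np.bincount(assign, minlength=3).astype(float)
        sums = np.bincount(assign, weights=z, minlength=3)

        pi = rng.dirichlet(alpha + counts)

        # means given variances (conjugate normal)
        prec = counts / var + 1.0 / prior_mean_var
        post_mean = (sums / var + prior_mean / prior_mean_var) / prec
        mu = post_mean + rng.standard_normal(3) / np.sqrt(prec)

        # variances given means (conjugate inverse-gamma)
        sq = np.bincount(assign, weights=(z - mu[assign]) ** 2, minlength=3)
        shape = a0 + counts / 2.0
        scale = b0 + sq / 2.0
        var = scale / rng.gamma(shape)

        # identify components: order by mean, central one is the null
        order = np.argsort(mu)
        mu, var, pi = mu[order], var[order], pi[order]
        mu = mu[[1, 0, 2]]; var = var[[1, 0, 2]]; pi = pi[[1, 0, 2]]
        # layout now (null, neg, pos)

        if it >= settings.burnin:
            k = it - settings.burnin
            trace_mu[k] = mu[0]
            trace_sd[k] = np.sqrt(var[0])
            trace_pi[k] = pi
            trace_side_mu[k] = mu[1:]
            trace_side_sd[k] = np.sqrt(var[1:])

    p_null = float(trace_pi[:, 0].mean())
    if p_null < settings.min_null_proportion:
        raise RuntimeError(
            f"empirical-null identification failed: central component "
            f"proportion {p_null:.3f} below floor "
            f"{settings.min_null_proportion}; adjust priors or iterations")

    est = NullEstimate(
        bias=float(trace_mu.mean()),
        inflation=float(trace_sd.mean()),
        null_proportion=p_null,
        proportions=tuple(trace_pi.mean(axis=0)),
        means=(float(trace_mu.mean()), float(trace_side_mu[:, 0].mean()),
               float(trace_side_mu[:, 1].mean())),
        sds=(float(trace_sd.mean()), float(trace_side_sd[:, 0].mean()),
             float(trace_side_sd[:, 1].mean())),
        posterior_sd_bias=float(trace_mu.std(ddof=1)),
        posterior_sd_inflation=float(trace_sd.std(ddof=1)),
        settings=settings,
    )
    return est


def genomic_control_estimate(z: np.ndarray) -> NullEstimate:
    """Robust closed-form fallback: bias = median(z), inflation =
    MAD(z) / Phi^-1(0.75). Non-default; for tiny inputs only."""
    z = np.asarray(z, dtype=float).ravel()
    if z.size == 0 or not np.all(np.isfinite(z)):
        raise ValueError("input must be non-empty and finite")
    bias = float(np.median(z))
    mad = float(np.median(np.abs(z - bias)))
    inflation = mad / stats.norm.ppf(0.75)
    if inflation <= 0:
        raise ValueError("degenerate input: zero dispersion")
    return NullEstimate(bias=bias, inflation=inflation, null_proportion=1.0,
                        proportions=(1.0, 0.0, 0.0), means=(bias, 0.0, 0.0),
                        sds=(inflation, 0.0, 0.0), posterior_sd_bias=np.nan,
                        posterior_sd_inflation=np.nan,
                        settings=NullSettings(), method="genomic_control")


def adjust_z(z: np.ndarray, est: NullEstimate):
    """Rescale Z-scores by the empirical null: z' = (z - bias)/inflation,
    P' two-sided normal."""
    if est.inflation <= 0:
        raise ValueError("inflation must be positive")
    z = np.asarray(z, dtype=float)
    z_adj = (z - est.bias) / est.inflation
    p_adj = 2.0 * stats.norm.sf(np.abs(z_adj))
    return z_adj, p_adj


def adjust_effects(beta: np.ndarray, se: np.ndarray, est: NullEstimate):
    """Adjust effect/SE pairs: beta' = beta - bias*se, se' = se*inflation."""
    if est.inflation <= 0:
        raise ValueError("inflation must be positive")
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    beta_adj = beta - est.bias * se
    se_adj = se * est.inflation
    with np.errstate(divide="ignore", invalid="ignore"):
        z_adj = beta_adj / se_adj
    p_adj = 2.0 * stats.norm.sf(np.abs(z_adj))
    return beta_adj, se_adj, p_adj


def adjust_cohort_stats(cohort_stats: pd.DataFrame,
                        tests: tuple[str, ...] = ("levene", "bartlett",
                                                  "fligner_killeen"),
                        settings: NullSettings | None = None,
                        adjust_mean: bool = True
                        ) -> tuple[pd.DataFrame, dict]:
    """Apply the empirical-null correction to every variance test's signed Z
    column (``z_<test>``) and, optionally, to the mean-effect beta/SE pair.

    Returns the augmented frame (``z_<test>_adj``, ``p_<test>_adj``, ...)
    and a dict of NullEstimates keyed by statistic name.
    """
    settings = settings or NullSettings()
    out = cohort_stats.copy()
    estimates: dict[str, NullEstimate] = {}
    for name in tests:
        col = f"z_{name}"
        if col not in out.columns:
            continue
        ok = out[col].notna()
        est = fit_empirical_null(out.loc[ok, col].to_numpy(), settings)
        z_adj, p_adj = adjust_z(out.loc[ok, col].to_numpy(), est)
        out.loc[ok, f"{col}_adj"] = z_adj
        out.loc[ok, f"p_{name}_adj"] = p_adj
        estimates[name] = est
    if adjust_mean and {"beta", "se"}.issubset(out.columns):
        ok = out["beta"].notna() & out["se"].notna() & (out["se"] > 0)
        z = (out.loc[ok, "beta"] / out.loc[ok, "se"]).to_numpy()
        est = fit_empirical_null(z, settings)
        b_adj, se_adj, p_adj = adjust_effects(out.loc[ok, "beta"].to_numpy(),
                                              out.loc[ok, "se"].to_numpy(), est)
        out.loc[ok, "beta_adj"] = b_adj
        out.loc[ok, "se_adj"] = se_adj
        out.loc[ok, "p_mean_adj"] = p_adj
        estimates["mean"] = est
    return out, estimates
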