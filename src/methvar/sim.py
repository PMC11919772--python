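"""Synthetic multi-cohort methylation data with known ground truth.

The generator uses a latent-logistic (logit-normal) model: covariate, batch
and disease effects are additive on a Gaussian latent scale and mapped to
beta values through the logistic function. Planted effects are therefore
exactly recoverable by linear residualisation on the latent scale:

    m_ij = mu_j + a_j*age_i + s_j*sex_i + k_j*smoke_i + sum_c w_jc*cell_ic
           + b_batch(i) + eps_ij
    eps_ij ~ Normal(0, sigma_j^2)          controls
    eps_ij ~ Normal(0, sigma_j^2 * rho_j)  cases
    beta_ij = 1 / (1 + exp(-m_ij))

Cases additionally receive a latent shift ``delta_j`` at mean-shift probes.
Per-probe parameters and the planted effect classes are drawn from
substreams that depend only on the global seed, so all cohorts share the
same ground truth; sample-level draws use a per-cohort substream.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd

EFFECT_NULL = "null"
EFFECT_VAR_UP = "variance_up"
EFFECT_VAR_DOWN = "variance_down"
EFFECT_MEAN = "mean_shift"

# fixed substream keys, one per generation stage
_KEY_PROBE, _KEY_TRUTH, _KEY_ANNOT, _KEY_CATALOG, _KEY_EXPR = 0, 1, 2, 3, 4
_KEY_COHORT_BASE = 100


@dataclass
class SimConfig:
    """Parameters of the synthetic multi-cohort generator."""

    n_cohorts: int = 3
    n_cases: int = 100
    n_controls: int = 100
    n_probes: int = 1000
    fraction_vmp_up: float = 0.0
    fraction_vmp_down: float = 0.0
    fraction_dmp: float = 0.0
    variance_ratio: float = 2.0      # case/control residual variance at VMPs
    mean_shift: float = 0.5          # latent-scale case offset at DMPs
    age_slope_sd: float = 0.01
    sex_offset_sd: float = 0.1
    smoking_slope_sd: float = 0.1
    cell_weight_sd: float = 0.3
    n_cell_types: int = 3
    n_batches: int = 4
    batch_sd: float = 0.1
    mu_range: tuple[float, float] = (-2.0, 2.0)
    sigma_range: tuple[float, float] = (0.2, 0.5)
    detection_failure_rate: float = 0.0
    intensity_mean: float = 5000.0
    intensity_sd: float = 300.0
    male_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fraction_vmp_up", "fraction_vmp_down", "fraction_dmp",
                     "detection_failure_rate"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {val}")
        total = self.fraction_vmp_up + self.fraction_vmp_down + self.fraction_dmp
        if total > 1.0:
            raise ValueError(f"effect fractions sum to {total} > 1")
        if self.variance_ratio <= 0:
            raise ValueError("variance_ratio must be positive")
        if self.n_cases < 2 or self.n_controls < 2:
            raise ValueError("need at least 2 cases and 2 controls")
        if self.n_probes < 1 or self.n_cohorts < 1:
            raise ValueError("n_probes and n_cohorts must be >= 1")
        if self.sigma_range[0] <= 0:
            raise ValueError("residual SD must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


def _rng(seed: int, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                        spawn_key=(key,)))


def probe_ids(n: int) -> pd.Index:
    return pd.Index([f"cg{i:08d}" for i in range(n)], name="probe_id")


def generate_ground_truth(config: SimConfig) -> pd.DataFrame:
    """Assign effect classes and magnitudes to probes (shared across cohorts)."""
    rng = _rng(config.seed, _KEY_TRUTH)
    n = config.n_probes
    n_up = int(round(config.fraction_vmp_up * n))
    n_down = int(round(config.fraction_vmp_down * n))
    n_dmp = int(round(config.fraction_dmp * n))
    order = rng.permutation(n)
    classes = np.array([EFFECT_NULL] * n, dtype=object)
    classes[order[:n_up]] = EFFECT_VAR_UP
    classes[order[n_up:n_up + n_down]] = EFFECT_VAR_DOWN
    classes[order[n_up + n_down:n_up + n_down + n_dmp]] = EFFECT_MEAN

    rho = np.ones(n)
    rho[classes == EFFECT_VAR_UP] = config.variance_ratio
    rho[classes == EFFECT_VAR_DOWN] = 1.0 / config.variance_ratio
    delta = np.zeros(n)
    delta[classes == EFFECT_MEAN] = config.mean_shift
    return pd.DataFrame({"effect_class": classes, "variance_ratio": rho,
                         "mean_shift": delta}, index=probe_ids(n))


def _probe_params(config: SimConfig) -> dict[str, np.ndarray]:
    rng = _rng(config.seed, _KEY_PROBE)
    n = config.n_probes
    return {
        "mu": rng.uniform(*config.mu_range, size=n),
        "sigma": rng.uniform(*config.sigma_range, size=n),
        "age_slope": rng.normal(0.0, config.age_slope_sd, size=n),
        "sex_offset": rng.normal(0.0, config.sex_offset_sd, size=n),
        "smoke_slope": rng.normal(0.0, config.smoking_slope_sd, size=n),
        "cell_weights": rng.normal(0.0, config.cell_weight_sd,
                                   size=(n, config.n_cell_types)),
    }


def generate_cohort(config: SimConfig, cohort_index: int,
                    return_latent: bool = False):
    """Generate one cohort's beta matrix, detection P, intensities, sample
    sheet and the (shared) ground truth.

    With ``return_latent=True`` an extra matrix of the raw noise draws
    ``eps_ij`` is appended, for moment-recovery oracles in tests.
    """
    if not 0 <= cohort_index < config.n_cohorts:
        raise ValueError(f"cohort_index {cohort_index} outside "
                         f"[0, {config.n_cohorts})")
    truth = generate_ground_truth(config)
    params = _probe_params(config)
    rng = _rng(config.seed, _KEY_COHORT_BASE + cohort_index)

    n_case, n_ctrl = config.n_cases, config.n_controls
    n_samp = n_case + n_ctrl
    is_case = np.zeros(n_samp, dtype=bool)
    is_case[:n_case] = True

    age = rng.normal(45.0, 10.0, size=n_samp)
    sex_male = rng.random(n_samp) < config.male_fraction
    smoke = rng.normal(0.0, 1.0, size=n_samp)
    cells = rng.dirichlet(np.full(config.n_cell_types, 5.0), size=n_samp)
    batch = rng.integers(0, config.n_batches, size=n_samp)
    batch_offsets = rng.normal(0.0, config.batch_sd, size=config.n_batches)
    position = rng.integers(0, 6, size=n_samp)  # 6 sentrix positions

    n_probes = config.n_probes
    rho = truth["variance_ratio"].to_numpy()
    delta = truth["mean_shift"].to_numpy()

    # latent fixed part, probes x samples
    latent = (params["mu"][:, None]
              + params["age_slope"][:, None] * (age - 45.0)[None, :]
              + params["sex_offset"][:, None] * sex_male[None, :].astype(float)
              + params["smoke_slope"][:, None] * smoke[None, :]
              + params["cell_weights"] @ cells.T
              + batch_offsets[batch][None, :])
    latent[:, is_case] += delta[:, None]

    scale = np.repeat(params["sigma"][:, None], n_samp, axis=1)
    scale[:, is_case] *= np.sqrt(rho)[:, None]
    eps = rng.normal(0.0, 1.0, size=(n_probes, n_samp)) * scale
    beta_vals = 1.0 / (1.0 + np.exp(-(latent + eps)))

    sample_ids = [f"C{cohort_index}_{'case' if c else 'ctrl'}_{i:04d}"
                  for i, c in enumerate(is_case)]
    pidx = probe_ids(n_probes)
    beta = pd.DataFrame(beta_vals, index=pidx, columns=sample_ids)

    detp_vals = rng.uniform(0.0, 0.005, size=(n_probes, n_samp))
    if config.detection_failure_rate > 0:
        fail = rng.random((n_probes, n_samp)) < config.detection_failure_rate
        detp_vals[fail] = rng.uniform(0.011, 1.0, size=int(fail.sum()))
    detp = pd.DataFrame(detp_vals, index=pidx, columns=sample_ids)

    intensity = pd.DataFrame({
        "median_methylated": rng.normal(config.intensity_mean,
                                        config.intensity_sd, size=n_samp),
        "median_unmethylated": rng.normal(config.intensity_mean,
                                          config.intensity_sd, size=n_samp),
    }, index=pd.Index(sample_ids, name="sample_id"))

    sheet = pd.DataFrame({
        "cohort": f"cohort{cohort_index}",
        "diagnosis": np.where(is_case, "case", "control"),
        "predicted_sex": np.where(sex_male, "male", "female"),
        "reported_sex": np.where(sex_male, "male", "female"),
        "horvath_age": age,
        "smoking_score": smoke,
        "sentrix_id": [f"sentrix{cohort_index}_{b}" for b in batch],
        "sentrix_position": [f"R{p + 1:02d}C01" for p in position],
    }, index=pd.Index(sample_ids, name="sample_id"))
    for c in range(config.n_cell_types):
        sheet[f"cell_prop_{c}"] = cells[:, c]

    out = (beta, detp, intensity, sheet, truth)
    if return_latent:
        out = out + (pd.DataFrame(eps, index=pidx, columns=sample_ids),)
    return out


def generate_dataset(config: SimConfig) -> dict:
    """All cohorts plus shared annotation and ground truth."""
    cohorts = {}
    for i in range(config.n_cohorts):
        beta, detp, intensity, sheet, _ = generate_cohort(config, i)
        cohorts[f"cohort{i}"] = {"beta": beta, "detp": detp,
                                 "intensity": intensity, "samplesheet": sheet}
    annot = generate_annotation(config.n_probes, AnnotationConfig(seed=config.seed))
    return {"cohorts": cohorts, "annotation": annot,
            "truth": generate_ground_truth(config)}


# ---------------------------------------------------------------------------
# annotation

@dataclass
class AnnotationConfig:
    n_chromosomes: int = 22
    base_gap_bp: int = 10_000          # spacing between non-clustered probes
    cluster_fraction: float = 0.0      # fraction of probes placed in clusters
    cluster_size: int = 5
    cluster_gap_bp: int = 50           # spacing inside a cluster
    fraction_blacklisted: float = 0.0
    n_genes: int = 200
    probes_per_gene: int = 5
    seed: int = 0

    GENIC_FEATURES = ("TSS1500", "TSS200", "5'UTR", "1stExon", "Body",
                      "3'UTR", "intergenic")
    CPG_RELATIONS = ("island", "shore", "shelf", "open_sea")
    FLAG_COLUMNS = ("flag_non_autosomal", "flag_non_cpg",
                    "flag_cross_hybridising", "flag_snp_proximal")


def generate_annotation(n_probes: int,
                        config: AnnotationConfig | None = None) -> pd.DataFrame:
    """Manifest-style probe annotation with configurable spatial clustering.

    Probes are laid along chromosomes left to right. A ``cluster_fraction``
    of probes is emitted in runs of ``cluster_size`` spaced ``cluster_gap_bp``
    apart; remaining probes are spaced ``base_gap_bp`` or more apart, so with
    clustering off no two probes fall within a typical region window.
    """
    if n_probes < 1:
        raise ValueError("n_probes must be >= 1")
    config = config or AnnotationConfig()
    rng = _rng(config.seed, _KEY_ANNOT)

    n_clustered = int(round(config.cluster_fraction * n_probes))
    n_clusters = n_clustered // config.cluster_size if config.cluster_size else 0
    cluster_budget = n_clusters * config.cluster_size

    chroms = np.empty(n_probes, dtype=object)
    positions = np.empty(n_probes, dtype=np.int64)
    per_chrom = int(np.ceil(n_probes / config.n_chromosomes))
    i = 0
    clusters_left = n_clusters
    for c in range(1, config.n_chromosomes + 1):
        pos = int(rng.integers(10_000, 50_000))
        placed = 0
        while i < n_probes and placed < per_chrom:
            emit_cluster = (clusters_left > 0
                            and rng.random() < 0.5
                            and n_probes - i >= config.cluster_size)
            run = config.cluster_size if emit_cluster else 1
            gap = config.cluster_gap_bp if emit_cluster else None
            for j in range(run):
                if i >= n_probes:
                    break
                chroms[i] = f"chr{c}"
                positions[i] = pos
                pos += int(gap if (emit_cluster and j < run - 1)
                           else rng.integers(config.base_gap_bp,
                                             2 * config.base_gap_bp))
                i += 1
                placed += 1
            if emit_cluster:
                clusters_left -= 1
        if i >= n_probes:
            break

    genes = np.array([f"GENE{g:05d}" for g in range(config.n_genes)])
    gene_assign = genes[(np.arange(n_probes) // config.probes_per_gene)
                        % config.n_genes]
    features = rng.choice(AnnotationConfig.GENIC_FEATURES, size=n_probes)
    cpg_rel = rng.choice(AnnotationConfig.CPG_RELATIONS, size=n_probes)

    annot = pd.DataFrame({
        "chr": chroms, "pos": positions, "nearest_gene": gene_assign,
        "genic_feature": features, "cpg_relation": cpg_rel,
    }, index=probe_ids(n_probes))
    for col in AnnotationConfig.FLAG_COLUMNS:
        annot[col] = False
    if config.fraction_blacklisted > 0:
        n_black = int(round(config.fraction_blacklisted * n_probes))
        idx = rng.choice(n_probes, size=n_black, replace=False)
        reasons = rng.integers(0, len(AnnotationConfig.FLAG_COLUMNS),
                               size=n_black)
        for r, col in enumerate(AnnotationConfig.FLAG_COLUMNS):
            annot.iloc[idx[reasons == r],
                       annot.columns.get_loc(col)] = True
        annot.loc[annot["flag_non_autosomal"], "chr"] = "chrX"
    return annot


# ---------------------------------------------------------------------------
# external fixtures

def generate_external_catalog(meta_z: pd.Series,
                              trait_specs: Sequence[dict],
                              seed: int = 0) -> pd.DataFrame:
    """EWAS-catalog-style table whose per-trait effects correlate with
    ``meta_z`` at a target Pearson r (in expectation).

    ``trait_specs``: dicts with keys ``name``, ``n_probes``, ``target_r``.
    """
    rng = _rng(seed, _KEY_CATALOG)
    z = meta_z.dropna()
    rows = []
    for spec in trait_specs:
        name, n, r = spec["name"], int(spec["n_probes"]), float(spec["target_r"])
        if n > len(z):
            raise ValueError(f"trait {name!r} requests {n} probes but only "
                             f"{len(z)} available")
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"target_r for {name!r} outside [-1, 1]")
        chosen = rng.choice(len(z), size=n, replace=False)
        zs = z.iloc[chosen].to_numpy()
        zs_std = (zs - zs.mean()) / zs.std(ddof=0) if zs.std(ddof=0) > 0 else zs
        noise = rng.normal(size=n)
        effects = r * zs_std + np.sqrt(max(0.0, 1.0 - r ** 2)) * noise
        for pid, eff in zip(z.index[chosen], effects):
            rows.append((name, pid, eff))
    return pd.DataFrame(rows, columns=["trait", "probe_id", "effect"])


def generate_expression_table(n_genes: int, tissues: Sequence[str],
                              seed: int = 0) -> pd.DataFrame:
    """Nonnegative gene-by-tissue expression fixture for enrichment tests."""
    rng = _rng(seed, _KEY_EXPR)
    genes = [f"GENE{g:05d}" for g in range(n_genes)]
    vals = rng.gamma(shape=2.0, scale=10.0, size=(n_genes, len(tissues)))
    return pd.DataFrame(vals, index=pd.Index(genes, name="gene"),
                        columns=list(tissues))
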