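"""Synthetic county tables with a known latent cluster structure.

Real inputs for this kind of analysis are multi-agency extracts (census,
labor, food-access atlases) that cannot be redistributed; this module
generates tables with the same column roster and the statistical features the
downstream pipeline assumes, so every stage is testable end to end with known
ground truth:

* the four clustering variables (population density, median income, SES,
  supermarket access) carry a K-component Gaussian mixture on the
  standardized scale, mapped onto realistic raw scales (density is
  log-normal, the others affine);
* an "unemployment" analog is drawn independently of the latent labels — the
  clustering-irrelevant variable that variable selection should discard;
* the four raw SES components are drawn through a Gaussian copula whose
  latent correlation is adjusted so their total correlation matches the
  configured matrix while their summed z-scores track the SES clustering
  coordinate;
* the two outcome rates are cluster-dependent means plus Gaussian noise; and
* an NCHS urban-rural class is sampled per county from a cluster-specific
  frequency table (metadata only, never used in fitting).

The default configuration is a 129-county, five-cluster study: mixing
weights 38/59/5/16/11 out of 129, cluster means on the standardized scale at
low = −1, medium = 0, high = +2 following the qualitative low/medium/high
profile of the five clusters, spherical within-cluster variance 0.04 (SD 0.2, so unit mean gaps
are 5-SD separations).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .data import ConfigurationError, FeatureMatrix
from .indices import SES_COMPONENTS

#: Clustering-variable names, in generation order.
CLUSTERING_VARIABLES = ("pop_density", "median_income", "ses", "low_access")

#: Default correlation of the four raw SES components
#: (less-HS education, single-female households, non-white, poverty).
DEFAULT_SES_CORR = np.array([
    [1.000, 0.538, 0.476, 0.690],
    [0.538, 1.000, 0.724, 0.648],
    [0.476, 0.724, 1.000, 0.493],
    [0.690, 0.648, 0.493, 1.000],
])

#: Raw (mean, SD) scales for the SES component percentages.
SES_COMPONENT_SCALES = {
    "pct_less_hs": (12.0, 3.5),
    "pct_single_female_hh": (10.0, 2.5),
    "pct_nonwhite": (20.0, 8.0),
    "poverty_rate": (14.0, 4.0),
}

# low = -1, medium = 0, high = +2 on the standardized scale; rows are the
# five default clusters, columns follow CLUSTERING_VARIABLES.
_L, _M, _H = -1.0, 0.0, 2.0
DEFAULT_CLUSTER_MEANS = np.array([
    [_L, _M, _L, _H],
    [_L, _L, _L, _M],
    [_H, _L, _H, _L],
    [_L, _M, _L, _M],
    [_L, _H, _L, _H],
])

#: Cluster-level outcome means (obesity %, diabetes %).
DEFAULT_OUTCOME_EFFECTS = np.array([
    [31.5, 11.2],
    [31.5, 11.2],
    [25.5, 10.1],
    [31.5, 10.1],
    [25.5, 9.0],
])

#: Cluster -> NCHS class (1..6) sampling probabilities.
DEFAULT_NCHS_PROBS = np.array([
    [0.00, 0.00, 0.40, 0.40, 0.15, 0.05],   # small-medium metro
    [0.00, 0.00, 0.00, 0.10, 0.45, 0.45],   # non-metro
    [1.00, 0.00, 0.00, 0.00, 0.00, 0.00],   # large central metro
    [0.00, 0.40, 0.30, 0.30, 0.00, 0.00],   # fringe-to-small metro
    [0.50, 0.50, 0.00, 0.00, 0.00, 0.00],   # large central + fringe
])


def _as_cov_matrices(covariance_spec, k: int, d: int) -> np.ndarray:
    """Expand a (name, value) covariance spec into (k, d, d) matrices."""
    name, value = covariance_spec
    value = np.asarray(value, dtype=float)
    covs = np.zeros((k, d, d))
    eye = np.eye(d)
    if name == "spherical":
        sig2 = np.broadcast_to(value, (k,))
        for j in range(k):
            covs[j] = sig2[j] * eye
    elif name == "diagonal":
        var = np.broadcast_to(value, (k, d))
        for j in range(k):
            covs[j] = np.diag(var[j])
    elif name == "full":
        covs[:] = np.broadcast_to(value, (k, d, d))
    else:
        raise ConfigurationError(f"unknown covariance spec name: {name!r}")
    for j in range(k):
        sym = np.allclose(covs[j], covs[j].T)
        try:
            if not sym:
                raise np.linalg.LinAlgError("asymmetric")
            np.linalg.cholesky(covs[j])
        except np.linalg.LinAlgError:
            raise ConfigurationError(
                f"covariance for component {j + 1} is not symmetric "
                "positive-definite")
    return covs


@dataclass
class SimulationConfig:
    """All knobs of the synthetic county generator (defaults = study scale)."""

    n_units: int = 129
    k_true: int = 5
    weights: np.ndarray | None = None
    cluster_means: np.ndarray | None = None
    covariance_spec: tuple = ("spherical", 0.04)
    n_noise_vars: int = 0
    outcome_effects: np.ndarray | None = None
    outcome_noise_sd: np.ndarray = field(
        default_factory=lambda: np.array([1.5, 0.6]))
    ses_component_corr: np.ndarray = field(
        default_factory=lambda: DEFAULT_SES_CORR.copy())
    ses_loading: float = 0.7
    nchs_class_probs: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self):
        k = self.k_true
        if self.weights is None:
            self.weights = (np.array([38, 59, 5, 16, 11]) / 129.0 if k == 5
                            else np.full(k, 1.0 / k))
        if self.cluster_means is None:
            if k != 5:
                raise ConfigurationError(
                    "cluster_means has no default for k_true != 5")
            self.cluster_means = DEFAULT_CLUSTER_MEANS.copy()
        if self.outcome_effects is None:
            self.outcome_effects = (DEFAULT_OUTCOME_EFFECTS.copy() if k == 5
                                    else np.tile([28.9, 10.13], (k, 1)))
        if self.nchs_class_probs is None:
            self.nchs_class_probs = (DEFAULT_NCHS_PROBS.copy() if k == 5
                                     else np.full((k, 6), 1.0 / 6.0))
        self.weights = np.asarray(self.weights, dtype=float)
        self.cluster_means = np.atleast_2d(
            np.asarray(self.cluster_means, dtype=float))
        self.outcome_effects = np.atleast_2d(
            np.asarray(self.outcome_effects, dtype=float))
        self.outcome_noise_sd = np.broadcast_to(
            np.asarray(self.outcome_noise_sd, dtype=float), (2,)).copy()
        self.ses_component_corr = np.asarray(self.ses_component_corr, float)
        self.nchs_class_probs = np.atleast_2d(
            np.asarray(self.nchs_class_probs, dtype=float))
        self.validate()

    def validate(self):
        if self.n_units < 1:
            raise ConfigurationError("n_units must be positive")
        if self.k_true < 1:
            raise ConfigurationError("k_true must be >= 1")
        if self.weights.shape != (self.k_true,):
            raise ConfigurationError("weights must have length k_true")
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1) > 1e-12:
            raise ConfigurationError("weights must be nonnegative and sum to 1")
        if self.cluster_means.shape[0] != self.k_true:
            raise ConfigurationError("cluster_means must have k_true rows")
        if self.n_noise_vars < 0:
            raise ConfigurationError("n_noise_vars must be >= 0")
        if self.outcome_effects.shape != (self.k_true, 2):
            raise ConfigurationError("outcome_effects must be k_true x 2")
        if np.any(self.outcome_noise_sd <= 0):
            raise ConfigurationError("outcome_noise_sd must be positive")
        R = self.ses_component_corr
        if R.shape != (4, 4) or not np.allclose(R, R.T):
            raise ConfigurationError("ses_component_corr must be symmetric 4x4")
        if not np.allclose(np.diag(R), 1.0):
            raise ConfigurationError("ses_component_corr must have unit diagonal")
        if np.linalg.eigvalsh(R).min() <= 0:
            raise ConfigurationError("ses_component_corr must be positive-definite")
        if not 0 <= self.ses_loading < 1:
            raise ConfigurationError("ses_loading must be in [0, 1)")
        # residual latent correlation implied by the cluster-tracking loading
        lam2 = self.ses_loading ** 2
        resid = (R - lam2) / (1 - lam2)
        np.fill_diagonal(resid, 1.0)
        if np.linalg.eigvalsh(resid).min() <= 0:
            raise ConfigurationError(
                "ses_component_corr is incompatible with ses_loading: the "
                "residual copula correlation is not positive-definite")
        if self.nchs_class_probs.shape != (self.k_true, 6):
            raise ConfigurationError("nchs_class_probs must be k_true x 6")
        if np.any(self.nchs_class_probs < 0) or np.any(
                np.abs(self.nchs_class_probs.sum(axis=1) - 1) > 1e-9):
            raise ConfigurationError("nchs_class_probs rows must sum to 1")
        # materializing validates PD-ness per component
        _as_cov_matrices(self.covariance_spec, self.k_true,
                         self.cluster_means.shape[1])

    def to_dict(self) -> dict:
        d = asdict(self)
        for key, val in d.items():
            if isinstance(val, np.ndarray):
                d[key] = val.tolist()
        name, value = d["covariance_spec"]
        d["covariance_spec"] = [name, np.asarray(value).tolist()]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "covariance_spec" in d:
            name, value = d["covariance_spec"]
            d["covariance_spec"] = (name, np.asarray(value, dtype=float))
        return cls(**d)


@dataclass
class SyntheticDataset:
    """A generated county table, its latent labels, and the generating config."""

    county_table: pd.DataFrame
    true_labels: np.ndarray
    generating_config: SimulationConfig

    def __post_init__(self):
        self.true_labels = np.asarray(self.true_labels, dtype=int)
        if self.true_labels.size != len(self.county_table):
            raise ValueError("true_labels length must equal table row count")
        k = self.generating_config.k_true
        if self.true_labels.min() < 1 or self.true_labels.max() > k:
            raise ValueError("true_labels must lie in 1..k_true")


# fixed substream layout so adding a column never perturbs earlier columns
_STREAMS = ("labels", "clustering", "unemployment", "ses_components",
            "obesity", "diabetes", "nchs", "noise")


def _substreams(seed):
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(c)
            for name, c in zip(_STREAMS, children)}


def generate_mixture(config: SimulationConfig):
    """Draw the latent-cluster feature matrix plus independent noise columns.

    Returns (FeatureMatrix, true_labels) where labels are 1-based. The matrix
    holds the Gaussian-mixture draws on the configured (standardized) scale
    with `n_noise_vars` extra iid standard-normal columns appended.
    """
    k, d = config.cluster_means.shape
    covs = _as_cov_matrices(config.covariance_spec, k, d)
    chol = np.linalg.cholesky(covs)
    rngs = _substreams(config.seed)
    n = config.n_units
    labels = rngs["labels"].choice(k, size=n, p=config.weights) + 1
    z = rngs["clustering"].standard_normal((n, d))
    X = config.cluster_means[labels - 1] + np.einsum(
        "nij,nj->ni", chol[labels - 1], z)
    names = [f"v{j + 1}" for j in range(d)]
    if config.n_noise_vars:
        noise = rngs["noise"].standard_normal((n, config.n_noise_vars))
        X = np.column_stack([X, noise])
        names += [f"noise{j + 1}" for j in range(config.n_noise_vars)]
    return FeatureMatrix(X, names), labels


def _ses_component_block(s_cluster: np.ndarray, config: SimulationConfig,
                         rng) -> np.ndarray:
    """Correlated raw SES components whose summed z-scores track s_cluster.

    Latent column j is lam·s̃ + sqrt(1−lam²)·g_j with s̃ the standardized SES
    clustering coordinate and g drawn from the residual copula correlation
    (R − lam²)/(1 − lam²), so the total latent correlation equals the
    configured matrix. Columns are mapped to raw percent scales and clamped
    to [0, 100].
    """
    n = s_cluster.size
    lam = config.ses_loading
    lam2 = lam ** 2
    resid = (config.ses_component_corr - lam2) / (1 - lam2)
    np.fill_diagonal(resid, 1.0)
    L = np.linalg.cholesky(resid)
    g = rng.standard_normal((n, 4)) @ L.T
    sd = s_cluster.std(ddof=1)
    s_std = (s_cluster - s_cluster.mean()) / (sd if sd > 0 else 1.0)
    latent = lam * s_std[:, None] + np.sqrt(1 - lam2) * g
    out = np.empty((n, 4))
    for j, name in enumerate(SES_COMPONENTS):
        mu, sigma = SES_COMPONENT_SCALES[name]
        out[:, j] = np.clip(mu + sigma * latent[:, j], 0.0, 100.0)
    return out


def generate_county_table(config: SimulationConfig) -> SyntheticDataset:
    """Generate a full county table with the configured latent structure."""
    if config.cluster_means.shape[1] != len(CLUSTERING_VARIABLES):
        raise ConfigurationError(
            "county-table generation requires cluster means for the "
            f"{len(CLUSTERING_VARIABLES)} clustering variables "
            f"{CLUSTERING_VARIABLES}")
    rngs = _substreams(config.seed)
    mix_cfg_dict = config.to_dict()
    mix_cfg_dict["n_noise_vars"] = 0
    fm, labels = generate_mixture(SimulationConfig.from_dict(mix_cfg_dict))
    s_pop, s_inc, s_ses, s_acc = fm.values.T
    n = config.n_units

    # raw-scale mappings (density log-normal; others affine, percents clamped)
    pop_density = np.exp(4.85 + 1.2 * s_pop)
    median_income = np.maximum(49367.0 + 11405.0 * s_inc, 10000.0)
    low_access = np.clip(16.4 + 10.24 * s_acc, 0.0, 100.0)
    unemployment = np.clip(
        8.68 + 1.23 * rngs["unemployment"].standard_normal(n), 0.0, 100.0)
    ses_block = _ses_component_block(s_ses, config, rngs["ses_components"])

    eff = config.outcome_effects[labels - 1]
    obesity = np.clip(
        eff[:, 0] + config.outcome_noise_sd[0]
        * rngs["obesity"].standard_normal(n), 0.0, 100.0)
    diabetes = np.clip(
        eff[:, 1] + config.outcome_noise_sd[1]
        * rngs["diabetes"].standard_normal(n), 0.0, 100.0)

    nchs_rng = rngs["nchs"]
    nchs = np.array([
        nchs_rng.choice(6, p=config.nchs_class_probs[lab - 1]) + 1
        for lab in labels])

    n_pa = int(round(n * 67 / 129))  # two-state stratum labels, metadata only
    state = np.where(np.arange(n) < n_pa, "PA", "NY")
    df = pd.DataFrame({
        "county_id": [f"C{i + 1:04d}" for i in range(n)],
        "state": state,
        "nchs_class": nchs,
        "unemployment_pct": unemployment,
        "pop_density": pop_density,
        "median_income": median_income,
        "pct_less_hs": ses_block[:, 0],
        "pct_single_female_hh": ses_block[:, 1],
        "pct_nonwhite": ses_block[:, 2],
        "poverty_rate": ses_block[:, 3],
        "low_access_pct": low_access,
        "obesity_pct": obesity,
        "diabetes_pct": diabetes,
    })
    return SyntheticDataset(df, labels, config)


def adjusted_rand(labels_a, labels_b) -> float:
    """Chance-corrected pair-counting agreement between two labelings.

    ARI = (Index − E[Index]) / (Max − E[Index]) over the pair-count
    contingency table; 1 for identical partitions (up to renaming), ≈0 for
    independent ones. Degenerate cases where Max equals E[Index] (both
    partitions trivial) return 1.0.
    """
    a = np.asarray(labels_a).ravel()
    b = np.asarray(labels_b).ravel()
    if a.size != b.size:
        raise ValueError("labelings must have equal length")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    contingency = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(contingency, (ai, bi), 1)

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(contingency).sum()
    sum_a = comb2(contingency.sum(axis=1)).sum()
    sum_b = comb2(contingency.sum(axis=0)).sum()
    total = comb2(a.size)
    expected = sum_a * sum_b / total if total > 0 else 0.0
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def write_dataset(dataset: SyntheticDataset, outdir):
    """Write county.csv, true_labels.csv and config.json side by side."""
    from pathlib import Path
    from .data import write_county_csv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_county_csv(dataset.county_table, outdir / "county.csv")
    pd.DataFrame({
        "county_id": dataset.county_table["county_id"],
        "true_label": dataset.true_labels,
    }).to_csv(outdir / "true_labels.csv", index=False)
    with open(outdir / "config.json", "w") as fh:
        json.dump(dataset.generating_config.to_dict(), fh, indent=2)
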