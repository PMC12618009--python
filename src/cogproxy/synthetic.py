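"""Synthetic multi-site, multi-family, two-wave cohort generator.

The generator emulates the tabulated structure of a large developmental
cohort study: children nested in families nested in data-collection sites,
assessed at a baseline visit and a two-year follow-up.  A latent general
cognitive ability ``g`` produces six task scores through a second-order
factor model, and named feature blocks (mental health, neuroimaging,
polygenic scores, environment) carry heterogeneous, partially overlapping
signal for ``g`` through three correlated latent sources:

* ``E`` — a family-shared environment latent,
* ``G`` — an additive-genetic latent with a family component,
* ``M`` — a mental-health liability latent.

``g`` is a fixed linear combination of (E, G, M) plus an orthogonal
residual, scaled to unit marginal variance.  Because the whole model is
linear-Gaussian, the population covariance of every observed feature with
``g`` is available in closed form, which gives exact population values for
the best-linear-predictor R-squared of any combination of feature sources
and for its commonality (unique/common) partition.  Those closed-form
targets are what downstream estimates are validated against.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BlockSpec",
    "PgsSpec",
    "LatentStructure",
    "CovariateEffects",
    "GenerativeConfig",
    "CohortFrame",
    "SyntheticTruth",
    "generate_cohort",
    "population_r2",
    "population_commonality",
    "default_config",
]

LATENTS = ("g", "E", "G", "M")
#: canonical proxy-source labels: mental health, brain, polygenic, environment
SOURCES = ("mh", "b", "g_pgs", "s")

TASK_NAMES = (
    "picvocab", "reading",        # language
    "flanker", "pattern_speed",   # mental flexibility
    "picseq", "ravlt",            # memory recall
)
FACTOR_OF_TASK = (0, 0, 1, 1, 2, 2)

MED_CATEGORIES = 14  # ATC top-level functionality groups


class ConfigurationError(ValueError):
    """Raised when a generative configuration violates its invariants."""


@dataclass(frozen=True)
class BlockSpec:
    """One named feature block.

    ``signal`` maps latent names ('g', 'E', 'G', 'M') to the loading that
    every feature of the block puts on that latent.  Features within a
    block are exchangeable: x_j = a'z + site_batch + e_j with independent
    Gaussian noise e_j of standard deviation ``noise_sd``.
    """

    name: str
    n_features: int
    signal: Mapping[str, float]
    noise_sd: float
    missing_rate: float = 0.0       # whole-block missingness per participant
    site_batch_sd: float = 0.0      # additive site batch effect (shared per site)
    role: str = "b"                 # one of SOURCES
    cell_missing_rate: float = 0.0  # per-cell missingness (imputation target)
    n_categorical: int = 0          # trailing features discretised to 3 levels
    qc_flag_rate: float = 0.0       # per-participant QC exclusion flag

    def loading_vector(self) -> np.ndarray:
        return np.array([float(self.signal.get(l, 0.0)) for l in LATENTS])


@dataclass(frozen=True)
class PgsSpec:
    """Polygenic-score panel: score families at candidate p-value thresholds.

    Each definition ``d`` at threshold ``t`` yields a Z-scored column
    ``w[t] * G + stratification * PC1 + e``.  The loading profile peaks at
    ``best_threshold``, emulating the usual inverted-U of predictive power
    across thresholds.
    """

    n_definitions: int = 3
    thresholds: Sequence[float] = (
        0.5, 0.1, 0.05, 0.01, 0.001, 1e-4, 1e-5, 1e-6, 1e-7, 1e-8)
    best_threshold: float = 0.01
    best_loading: float = 0.8
    off_peak_loading: float = 0.45
    stratification: float = 0.15    # loading of each score on ancestry PC1
    n_pcs: int = 4

    def loading_at(self, threshold: float) -> float:
        return self.best_loading if threshold == self.best_threshold else self.off_peak_loading


@dataclass(frozen=True)
class LatentStructure:
    """Covariance among latent sources and the definition of g.

    ``source_corr`` is the 3x3 correlation among (E, G, M); ``g_cov`` the
    desired covariance of g with each of (E, G, M).  The residual weight is
    solved so Var(g) = 1; a target covariance that would require negative
    residual variance is rejected.  ``g_family_share`` / ``g_site_share``
    route part of the residual variance through family / site random
    intercepts so mixed-model variance components are non-trivial.
    """

    source_corr: np.ndarray = field(
        default_factory=lambda: np.array([
            [1.00, 0.15, -0.30],
            [0.15, 1.00, -0.10],
            [-0.30, -0.10, 1.00],
        ]))
    g_cov: np.ndarray = field(default_factory=lambda: np.array([0.58, 0.30, -0.44]))
    g_family_share: float = 0.18
    g_site_share: float = 0.02
    # family-sharing of the sources themselves (E mostly household-shared)
    family_share: Mapping[str, float] = field(
        default_factory=lambda: {"E": 0.8, "G": 0.5, "M": 0.3})

    def latent_covariance(self) -> np.ndarray:
        """4x4 covariance over (g, E, G, M); raises if not PSD."""
        L = np.asarray(self.source_corr, dtype=float)
        if L.shape != (3, 3) or not np.allclose(L, L.T):
            raise ConfigurationError("source_corr must be a symmetric 3x3 matrix")
        evals = np.linalg.eigvalsh(L)
        if evals.min() < -1e-10:
            raise ConfigurationError(
                "latent source correlation (E,G,M) is not positive semi-definite")
        sigma = np.asarray(self.g_cov, dtype=float)
        explained = float(sigma @ np.linalg.solve(L, sigma))
        if explained > 1.0 + 1e-12:
            raise ConfigurationError(
                "g covariance targets imply Var(g) > 1 given the (E,G,M) block")
        full = np.empty((4, 4))
        full[0, 0] = 1.0
        full[0, 1:] = sigma
        full[1:, 0] = sigma
        full[1:, 1:] = L
        evals = np.linalg.eigvalsh(full)
        if evals.min() < -1e-10:
            raise ConfigurationError(
                "implied (g, E, G, M) covariance is not positive semi-definite")
        return full

    def level_covariances(self) -> tuple[np.ndarray, np.ndarray]:
        """Exact split of the source covariance into family-level and
        individual-level parts: Sigma_fam = D^1/2 L D^1/2 with D the
        family-share fractions, Sigma_ind = L - Sigma_fam.  The sum equals
        L for any shares; the split itself must be PSD to be drawable."""
        L = np.asarray(self.source_corr, dtype=float)
        d = np.sqrt(np.array([self.family_share.get(k, 0.0) for k in ("E", "G", "M")]))
        fam = np.outer(d, d) * L
        ind = L - fam
        if np.linalg.eigvalsh(ind).min() < -1e-10:
            raise ConfigurationError(
                "family_share fractions leave a non-PSD individual-level "
                "covariance for (E,G,M)")
        return fam, ind

    @property
    def g_residual_var(self) -> float:
        sigma = np.asarray(self.g_cov, dtype=float)
        L = np.asarray(self.source_corr, dtype=float)
        return 1.0 - float(sigma @ np.linalg.solve(L, sigma))


@dataclass(frozen=True)
class CovariateEffects:
    """Additive covariate effects on the cognition score fed to the tasks."""

    sex: float = 0.08               # effect of female (coded 1) vs male
    age_per_sd: float = 0.12        # per standard deviation of age
    medication: Sequence[float] = (0.0,) * 9 + (-0.15,) + (0.0,) * 4  # nervous system


@dataclass(frozen=True)
class GenerativeConfig:
    n_sites: int = 21
    site_size_range: tuple[int, int] = (120, 230)   # families per site
    family_size_probs: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.70, 2: 0.25, 3: 0.05})
    first_order_loadings: Sequence[float] = (0.82, 0.84, 0.64, 0.68, 0.74, 0.76)
    second_order_loadings: Sequence[float] = (0.94, 0.76, 0.86)
    block_specs: Sequence[BlockSpec] = ()
    pgs: PgsSpec = field(default_factory=PgsSpec)
    latent: LatentStructure = field(default_factory=LatentStructure)
    covariates: CovariateEffects = field(default_factory=CovariateEffects)
    followup_retention: float = 0.60
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.followup_retention <= 1.0):
            raise ConfigurationError("followup_retention must be in (0, 1]")
        if self.site_size_range[0] < 2:
            raise ConfigurationError("sites must hold at least 2 families")
        probs = np.array(list(self.family_size_probs.values()), dtype=float)
        if probs.min() < 0 or abs(probs.sum() - 1.0) > 1e-9:
            raise ConfigurationError("family_size_probs must be a distribution")
        for lam in list(self.first_order_loadings) + list(self.second_order_loadings):
            if not (0.0 < lam < 1.0):
                raise ConfigurationError("task loadings must lie in (0, 1)")
        for spec in self.block_specs:
            if spec.noise_sd < 0 or spec.site_batch_sd < 0:
                raise ConfigurationError(f"block {spec.name!r}: negative variance parameter")
            if spec.role not in SOURCES:
                raise ConfigurationError(f"block {spec.name!r}: unknown role {spec.role!r}")
        self.latent.latent_covariance()  # raises on non-PSD
        self.latent.level_covariances()


def default_config(seed: int = 0, scale: float = 1.0) -> GenerativeConfig:
    """Default study conditions.

    Block signal strengths are set so that the population R-squared of each
    proxy source sits near the out-of-sample performance the pipeline is
    meant to exhibit (mental health r ~ 0.36, neuroimaging r ~ 0.54,
    polygenic r ~ 0.25, environment r ~ 0.49).  ``scale`` shrinks the
    per-site family counts for quick tests.
    """
    lo, hi = (max(4, int(round(120 * scale))), max(6, int(round(230 * scale))))
    blocks = [
        BlockSpec("cbcl", 8, {"M": 0.50}, noise_sd=np.sqrt(0.75),
                  role="mh", missing_rate=0.02),
        BlockSpec("temperament", 9, {"M": 0.42}, noise_sd=np.sqrt(1 - 0.42 ** 2),
                  role="mh", missing_rate=0.02),
        BlockSpec("smri_thickness", 15, {"g": 0.1325}, noise_sd=np.sqrt(1 - 0.1325 ** 2 - 0.15 ** 2),
                  role="b", missing_rate=0.10, site_batch_sd=0.15, qc_flag_rate=0.02),
        BlockSpec("smri_volume", 15, {"g": 0.1238}, noise_sd=np.sqrt(1 - 0.1238 ** 2 - 0.15 ** 2),
                  role="b", missing_rate=0.12, site_batch_sd=0.15, qc_flag_rate=0.02),
        BlockSpec("task_fmri_nback", 15, {"g": 0.1126, "M": 0.05},
                  noise_sd=np.sqrt(1 - 0.1126 ** 2 - 0.18 ** 2),
                  role="b", missing_rate=0.18, site_batch_sd=0.18, qc_flag_rate=0.03),
        BlockSpec("dti_fa", 12, {"g": 0.099}, noise_sd=np.sqrt(1 - 0.099 ** 2 - 0.15 ** 2),
                  role="b", missing_rate=0.15, site_batch_sd=0.15, qc_flag_rate=0.02),
        BlockSpec("ses_lifestyle", 30, {"E": 0.45}, noise_sd=np.sqrt(1 - 0.45 ** 2),
                  role="s", missing_rate=0.0, cell_missing_rate=0.04, n_categorical=4),
    ]
    return GenerativeConfig(site_size_range=(lo, hi), block_specs=tuple(blocks), seed=seed)


# ---------------------------------------------------------------------------
# cohort container


@dataclass
class CohortFrame:
    """Per-participant rows for both waves plus named feature blocks.

    ``data`` is indexed by (participant_id, wave) and carries site, family,
    covariates, the six task scores, and hidden truth columns prefixed with
    ``true_``.  ``blocks[name]`` shares that index; missing cells are NaN.
    ``qc`` holds one boolean per (participant, wave) x block.
    """

    data: pd.DataFrame
    blocks: dict[str, pd.DataFrame]
    qc: pd.DataFrame
    pgs_panel: pd.DataFrame | None
    roles: dict[str, list[str]]
    truth: "SyntheticTruth"

    @property
    def task_columns(self) -> list[str]:
        return list(TASK_NAMES)

    @property
    def med_columns(self) -> list[str]:
        return [c for c in self.data.columns if c.startswith("med_")]

    def wave(self, wave: str) -> pd.DataFrame:
        return self.data.xs(wave, level="wave")

    def blocks_for(self, source: str) -> list[str]:
        return list(self.roles.get(source, []))

    def write_tsv(self, outdir: str | Path) -> None:
        """Tab-delimited tables (one per wave) plus a JSON truth sidecar."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for wave in self.data.index.get_level_values("wave").unique():
            wide = self.wave(wave)
            for name, block in self.blocks.items():
                try:
                    sub = block.xs(wave, level="wave")
                except KeyError:
                    continue
                sub = sub.add_prefix(f"{name}__")
                wide = wide.join(sub, how="left")
            wide.to_csv(outdir / f"cohort_{wave}.tsv", sep="\t")
        if self.pgs_panel is not None:
            self.pgs_panel.to_csv(outdir / "pgs_panel.tsv", sep="\t")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth.to_dict(), fh, indent=2)


# ---------------------------------------------------------------------------
# closed-form population quantities


@dataclass
class SyntheticTruth:
    """Generative covariance structure with closed-form population targets.

    Population R-squared values come in two flavours: ``target='g'``
    predicts the latent g itself, while ``target='score'`` predicts the
    factor score that the measurement model can actually deliver (the
    pipeline's operational target).  The two differ exactly by the squared
    factor-score validity, which follows from the task loadings.
    """

    latent_covariance: np.ndarray           # 4x4 over (g, E, G, M)
    block_specs: Sequence[BlockSpec]
    pgs: PgsSpec
    roles: dict[str, list[str]]
    first_order_loadings: np.ndarray | None = None
    second_order_loadings: np.ndarray | None = None

    def score_validity(self) -> float:
        """Population correlation between the regression factor score of g
        and g itself, implied by the task measurement model."""
        if self.first_order_loadings is None:
            return 1.0
        lam1 = np.asarray(self.first_order_loadings, dtype=float)
        lam2 = np.asarray(self.second_order_loadings, dtype=float)
        lam = np.zeros((6, 3))
        for t, f in enumerate(FACTOR_OF_TASK):
            lam[t, f] = lam1[t]
        phi = np.outer(lam2, lam2) + np.diag(1.0 - lam2 ** 2)
        common = lam @ phi @ lam.T
        sigma = common + np.diag(1.0 - np.diag(common))
        cov_xg = lam @ lam2
        w = np.linalg.solve(sigma, cov_xg)
        return float(w @ cov_xg / np.sqrt(w @ sigma @ w))

    def to_dict(self) -> dict:
        return {
            "latent_covariance": self.latent_covariance.tolist(),
            "latents": list(LATENTS),
            "roles": self.roles,
            "score_validity": self.score_validity(),
            "population_r2": {
                "+".join(sorted(s)): population_r2(self, s)
                for s in _nonempty_subsets(SOURCES)
            },
        }

    def _source_loadings(self, src: str) -> tuple[np.ndarray, list[tuple[int, float, float]]]:
        """Loading matrix over (g,E,G,M) and (k, batch_var, noise_var) per block."""
        sigma_z = self.latent_covariance
        loadings: list[np.ndarray] = []
        extras: list[tuple[int, float, float]] = []
        if src == "g_pgs":
            # one best-threshold score per definition, after PC residualisation
            w = self.pgs.best_loading
            k = self.pgs.n_definitions
            a = np.zeros(4)
            a[LATENTS.index("G")] = w
            loadings.append(np.tile(a, (k, 1)))
            extras.append((k, 0.0, 1.0 - w ** 2 * sigma_z[2, 2]))
        else:
            for spec in self.block_specs:
                if spec.role != src:
                    continue
                a = spec.loading_vector()
                loadings.append(np.tile(a, (spec.n_features, 1)))
                extras.append((spec.n_features, spec.site_batch_sd ** 2,
                               spec.noise_sd ** 2))
        if not loadings:
            return np.zeros((0, 4)), []
        return np.vstack(loadings), extras

    @staticmethod
    def _own_covariance(A: np.ndarray, extras, sigma_z: np.ndarray) -> np.ndarray:
        cov = A @ sigma_z @ A.T
        pos = 0
        for k, batch_var, noise_var in extras:
            sl = slice(pos, pos + k)
            cov[sl, sl] += batch_var          # batch shared across the block
            cov[sl, sl][np.diag_indices(k)] += noise_var
            pos += k
        return cov

    def _feature_moments(self, sources: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        """Covariance of all features of the given sources and their cov with g."""
        sigma_z = self.latent_covariance
        mats, all_extras = [], []
        for src in sources:
            A, extras = self._source_loadings(src)
            if len(A):
                mats.append(A)
                all_extras.extend(extras)
        if not mats:
            return np.zeros((0, 0)), np.zeros(0)
        A = np.vstack(mats)
        cov = self._own_covariance(A, all_extras, sigma_z)
        sigma_fg = A @ sigma_z[:, 0]
        return cov, sigma_fg

    def _proxy_moments(self, sources: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        """Moments of the per-source population proxies.

        Each source is summarised by its own best linear predictor of g
        (the population analogue of a separately trained per-source model);
        cross-source covariance flows through the latent space only."""
        sigma_z = self.latent_covariance
        weights, loadings = {}, {}
        usable = []
        for src in sources:
            A, extras = self._source_loadings(src)
            if not len(A) or not np.any(A @ sigma_z[:, 0]):
                continue
            C = self._own_covariance(A, extras, sigma_z)
            sigma_fg = A @ sigma_z[:, 0]
            weights[src] = np.linalg.solve(C, sigma_fg)
            loadings[src] = (A, C)
            usable.append(src)
        if not usable:
            return np.zeros((0, 0)), np.zeros(0)
        m = len(usable)
        P = np.empty((m, m))
        q = np.empty(m)
        for i, s in enumerate(usable):
            A_s, C_s = loadings[s]
            w_s = weights[s]
            q[i] = w_s @ (A_s @ sigma_z[:, 0])
            for j, t in enumerate(usable):
                if t == s:
                    P[i, j] = w_s @ C_s @ w_s
                else:
                    A_t, _ = loadings[t]
                    P[i, j] = w_s @ (A_s @ sigma_z @ A_t.T) @ weights[t]
        return P, q


def _nonempty_subsets(items: Sequence[str]) -> list[tuple[str, ...]]:
    out = []
    n = len(items)
    for mask in range(1, 2 ** n):
        out.append(tuple(items[i] for i in range(n) if mask >> i & 1))
    return out


def population_r2(truth: SyntheticTruth, sources: Sequence[str],
                  target: str = "g", basis: str = "features") -> float:
    """Population R-squared of the best linear predictor from ``sources``.

    Computed by covariance algebra: R2 = s' C^+ s with C the predictor
    covariance and s the predictor-g covariance (Var(g) = 1).  A singular C
    falls back to the pseudo-inverse with a warning.

    ``basis='features'`` predicts from every feature of the subset jointly
    (the information-theoretic ceiling).  ``basis='proxies'`` first
    collapses each source to its own best linear predictor and regresses g
    on those scalars — the population analogue of a proxy-measure analysis,
    where per-source models are trained separately and only their outputs
    enter the joint model.  The two coincide for single sources and the
    proxy basis is never larger.

    ``target='score'`` rescales by the squared factor-score validity: the
    score equals validity * g plus measurement noise independent of the
    features, so every subset R2 attenuates by the same factor.
    """
    sources = tuple(sources)
    if not sources:
        raise ValueError("sources must be a non-empty subset of " + str(SOURCES))
    for s in sources:
        if s not in SOURCES:
            raise ValueError(f"unknown proxy source {s!r}")
    if target not in ("g", "score"):
        raise ValueError("target must be 'g' or 'score'")
    if basis not in ("features", "proxies"):
        raise ValueError("basis must be 'features' or 'proxies'")
    if basis == "features":
        cov, sigma = truth._feature_moments(sources)
    else:
        cov, sigma = truth._proxy_moments(sources)
    if cov.size == 0 or not np.any(sigma):
        return 0.0
    try:
        sol = np.linalg.solve(cov, sigma)
    except np.linalg.LinAlgError:
        import warnings

        warnings.warn("singular feature covariance; using pseudo-inverse")
        sol = np.linalg.pinv(cov) @ sigma
    r2 = float(sigma @ sol)
    if target == "score":
        r2 *= truth.score_validity() ** 2
    return r2


def population_commonality(truth: SyntheticTruth, target: str = "g",
                           basis: str = "features") -> "pd.DataFrame":
    """Unique/common partition of the full-set population R-squared.

    Applies the same inclusion-exclusion decomposition used for fitted
    mixed-model R-squared values to the closed-form population values.
    """
    from .commonality import commonality_partition

    r2 = {frozenset(s): population_r2(truth, s, target=target, basis=basis)
          for s in _nonempty_subsets(SOURCES)}
    return commonality_partition(r2, SOURCES)


# ---------------------------------------------------------------------------
# generation


def generate_cohort(config: GenerativeConfig) -> CohortFrame:
    """Draw a two-wave cohort from the generative model.

    Deterministic given ``config.seed``: the same configuration and seed
    produce byte-identical tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lat = config.latent
    sigma_z = lat.latent_covariance()

    # --- family / site skeleton -------------------------------------------
    sizes = rng.integers(config.site_size_range[0], config.site_size_range[1] + 1,
                         size=config.n_sites)
    fam_sizes_choices = np.array(sorted(config.family_size_probs))
    fam_sizes_probs = np.array([config.family_size_probs[k] for k in fam_sizes_choices],
                               dtype=float)
    site_ids, family_ids, child_idx = [], [], []
    fam_counter = 0
    for s in range(config.n_sites):
        for _ in range(int(sizes[s])):
            k = int(rng.choice(fam_sizes_choices, p=fam_sizes_probs))
            for c in range(k):
                site_ids.append(s)
                family_ids.append(fam_counter)
                child_idx.append(c)
            fam_counter += 1
    site = np.array(site_ids)
    family = np.array(family_ids)
    n = len(site)
    n_fam = fam_counter
    pid = np.array([f"P{i:06d}" for i in range(n)])

    # --- latent sources with family sharing -------------------------------
    # family-level and individual-level components drawn separately; their
    # covariances sum exactly to the specified (E,G,M) correlation.
    fam_cov, ind_cov = lat.level_covariances()
    eps = 1e-10 * np.eye(3)
    chol_fam = np.linalg.cholesky(fam_cov + eps)
    chol_ind = np.linalg.cholesky(ind_cov + eps)
    fam_draw = (chol_fam @ rng.standard_normal((3, n_fam))).T[family]
    ind_draw = (chol_ind @ rng.standard_normal((3, n))).T
    z_sources = fam_draw + ind_draw

    # g = c'(E,G,M) + residual split into site/family/individual parts
    c = np.linalg.solve(lat.source_corr, lat.g_cov)
    resid_var = lat.g_residual_var
    site_var = lat.g_site_share * resid_var
    fam_var = lat.g_family_share * resid_var
    ind_var = resid_var - site_var - fam_var
    if ind_var < 0:
        raise ConfigurationError("g_family_share + g_site_share exceed the g residual")
    g = (z_sources @ c
         + np.sqrt(site_var) * rng.standard_normal(config.n_sites)[site]
         + np.sqrt(fam_var) * rng.standard_normal(n_fam)[family]
         + np.sqrt(ind_var) * rng.standard_normal(n))
    z = np.column_stack([g, z_sources])  # (g, E, G, M)

    # --- covariates --------------------------------------------------------
    sex = (rng.random(n) < 0.48).astype(int)
    age = rng.normal(119.0, 7.5, size=n)
    med_rates = np.array([0.012, 0.001, 0.010, 0.009, 0.006, 0.002, 0.005,
                          0.0004, 0.012, 0.060, 0.0004, 0.061, 0.0035, 0.0001])
    meds = (rng.random((n, MED_CATEGORIES)) < med_rates).astype(int)
    cov_eff = (config.covariates.sex * (sex - sex.mean())
               + config.covariates.age_per_sd * (age - age.mean()) / age.std()
               + meds @ np.asarray(config.covariates.medication, dtype=float))
    # keep the score-generating variable marginally standardized so the
    # configured task loadings are exactly the standardized loadings
    med_p = med_rates
    beta_med = np.asarray(config.covariates.medication, dtype=float)
    cov_var = (config.covariates.sex ** 2 * 0.48 * 0.52
               + config.covariates.age_per_sd ** 2
               + float(beta_med ** 2 @ (med_p * (1 - med_p))))
    g_for_tasks = (g + cov_eff) / np.sqrt(1.0 + cov_var)

    lam1 = np.asarray(config.first_order_loadings, dtype=float)
    lam2 = np.asarray(config.second_order_loadings, dtype=float)

    def draw_tasks(local_rng: np.random.Generator) -> np.ndarray:
        """Six task scores from the second-order factor model (fresh noise)."""
        dist = np.sqrt(1.0 - lam2 ** 2)
        factors = lam2[None, :] * g_for_tasks[:, None] \
            + dist[None, :] * local_rng.standard_normal((n, 3))
        tasks = np.empty((n, 6))
        for t in range(6):
            f = FACTOR_OF_TASK[t]
            theta = np.sqrt(1.0 - lam1[t] ** 2)
            tasks[:, t] = lam1[t] * factors[:, f] + theta * local_rng.standard_normal(n)
        return tasks

    # --- feature blocks (per wave) ----------------------------------------
    waves = ["baseline", "followup"]
    retained = rng.random(n) < config.followup_retention

    def draw_block(spec: BlockSpec, local_rng: np.random.Generator) -> np.ndarray:
        a = spec.loading_vector()
        batch = spec.site_batch_sd * local_rng.standard_normal(
            (config.n_sites, spec.n_features))
        x = z @ a[:, None] + batch[site] \
            + spec.noise_sd * local_rng.standard_normal((n, spec.n_features))
        if spec.n_categorical:
            # discretise the trailing features into 3 ordinal levels
            for j in range(spec.n_features - spec.n_categorical, spec.n_features):
                x[:, j] = np.digitize(x[:, j], [-0.6, 0.6])
        return x

    rows, block_data, qc_rows = [], {spec.name: [] for spec in config.block_specs}, []
    pgs_rows = None
    for wave in waves:
        keep = np.ones(n, dtype=bool) if wave == "baseline" else retained
        tasks = draw_tasks(rng)
        df = pd.DataFrame({
            "participant_id": pid, "wave": wave,
            "site_id": [f"site{(s + 1):02d}" for s in site],
            "family_id": [f"fam{f:05d}" for f in family],
            "sex": sex, "age_months": np.round(age + (24.0 if wave == "followup" else 0.0), 1),
        })
        for j in range(MED_CATEGORIES):
            df[f"med_{j + 1:02d}"] = meds[:, j]
        for t, name in enumerate(TASK_NAMES):
            df[name] = tasks[:, t]
        df["true_g"] = g
        df["true_E"], df["true_G"], df["true_M"] = z_sources.T
        rows.append(df[keep])
        qc = pd.DataFrame({"participant_id": pid, "wave": wave})
        for spec in config.block_specs:
            x = draw_block(spec, rng)
            missing_block = rng.random(n) < spec.missing_rate
            x[missing_block] = np.nan
            if spec.cell_missing_rate:
                cell = rng.random(x.shape) < spec.cell_missing_rate
                x[cell] = np.nan
            bdf = pd.DataFrame(
                x, columns=[f"{spec.name}_{j + 1:03d}" for j in range(spec.n_features)])
            bdf.insert(0, "participant_id", pid)
            bdf.insert(1, "wave", wave)
            block_data[spec.name].append(bdf[keep])
            qc[spec.name] = rng.random(n) < spec.qc_flag_rate
        qc_rows.append(qc[keep])

    data = pd.concat(rows).set_index(["participant_id", "wave"]).sort_index()
    blocks = {name: pd.concat(parts).set_index(["participant_id", "wave"]).sort_index()
              for name, parts in block_data.items()}
    qc = pd.concat(qc_rows).set_index(["participant_id", "wave"]).sort_index()

    # --- polygenic panel (time-invariant) ----------------------------------
    pspec = config.pgs
    pcs = rng.standard_normal((n, pspec.n_pcs))
    panel_cols = {"participant_id": pid,
                  "family_id": data.xs("baseline", level="wave")["family_id"].reindex(pid).values,
                  "site_id": data.xs("baseline", level="wave")["site_id"].reindex(pid).values}
    G_lat = z_sources[:, 1]
    for d in range(pspec.n_definitions):
        for t in pspec.thresholds:
            w = pspec.loading_at(t)
            noise_sd = np.sqrt(max(1.0 - w ** 2 - pspec.stratification ** 2, 1e-6))
            scores = (w * G_lat + pspec.stratification * pcs[:, 0]
                      + noise_sd * rng.standard_normal(n))
            panel_cols[f"pgs{d + 1}_thr{t:g}"] = scores
    for j in range(pspec.n_pcs):
        panel_cols[f"PC{j + 1}"] = pcs[:, j]
    pgs_rows = pd.DataFrame(panel_cols).set_index("participant_id")

    roles: dict[str, list[str]] = {src: [] for src in SOURCES}
    for spec in config.block_specs:
        roles[spec.role].append(spec.name)
    roles["g_pgs"] = ["pgs_panel"]

    truth = SyntheticTruth(latent_covariance=sigma_z,
                           block_specs=tuple(config.block_specs),
                           pgs=pspec, roles=roles,
                           first_order_loadings=lam1.copy(),
                           second_order_loadings=lam2.copy())
    return CohortFrame(data=data, blocks=blocks, qc=qc, pgs_panel=pgs_rows,
                       roles=roles, truth=truth)
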