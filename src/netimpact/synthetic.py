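"""Synthetic study generator: every input the pipeline consumes, with known truth.

No imaging or cohort data ship with this package, so all stages are exercised
on a simulated study whose generative parameters mirror the multicenter
stroke cohort the score was validated in:

* a miniature "brain": an ellipsoidal mask on a 64-cubed 1 mm grid whose
  grey matter (an outer shell plus nothing else) is tessellated into 90
  contiguous regions — background (0) plays the role of white matter and
  infratentorial tissue outside the network atlas;
* a hub-structured connectome: distance-dependent connections between
  region centroids plus a designated hub subset with dense strong edges,
  so that betweenness concentrates on hubs as it does in real connectomes;
* quasi-spherical lesions grown from a random seed voxel to a target volume
  drawn log-normally with median 3.7 mL and IQR 1.2-16.1 mL (the cohort's
  normalized infarct volume distribution);
* longitudinal binary PSCI outcomes from a marginal logistic model (score,
  age per decade, prior stroke, volume per 10 mL, sex, education, site)
  with within-subject correlation induced by a shared subject-level normal
  term. The stated coefficients are MARGINAL (population-averaged — what a
  GEE estimates): the conditional linear predictor is inflated by
  sqrt(1 + 0.346 * sigma_b^2), the standard logit attenuation factor, so
  the marginal model carries the configured coefficients.

Covariate marginals are anchored to the cohort table: age ~ N(66.7, 11.7)
truncated to [18, 100], 59.8% male, education frequencies (56.7 / 21.7 /
7.9 / 13.8 %), prior stroke 11.3%, visit-count mixture (52.2% single visit,
..., 5.6% six visits). Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from . import atlas as atlas_mod
from . import impact as impact_mod
from .cognition import DOMAIN_COLUMNS
from .errors import ValidationError

__all__ = [
    "SimulationConfig",
    "generate_parcellation",
    "generate_connectome",
    "generate_lesions",
    "generate_covariates",
    "generate_outcomes",
    "simulate_cohort_table",
    "simulate_study",
    "calibrate_intercept",
    "LesionSet",
    "SimulationResult",
]

# logit attenuation constant c^2 with c = 16*sqrt(3)/(15*pi)
_ATTENUATION_C2 = (16.0 * math.sqrt(3.0) / (15.0 * math.pi)) ** 2


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study, with cohort-anchored defaults."""

    seed: int = 0
    # geometry
    shape: tuple = (64, 64, 64)
    voxel_size_mm: float = 1.0
    n_regions: int = 90
    shell_fraction: float = 0.55  # inner-core scale; shell = ellipsoid minus core
    # connectome
    n_hubs: int = 8
    connection_scale: float = 0.35  # distance-decay length as fraction of grid diagonal
    base_connection_prob: float = 0.9
    hub_weight_boost: float = 5.0
    hub_fanout: float = 0.6  # fraction of nodes each hub connects to
    max_connectome_retries: int = 10
    # cohort
    n_patients: int = 2341
    visit_mixture: tuple = (0.522, 0.264, 0.069, 0.049, 0.040, 0.056)
    visits_fixed: int | None = None
    moca_fraction: float = 0.25
    indeterminate_fraction: float = 0.03
    # lesion volumes (mL): log-normal anchored to median 3.7, IQR 1.2-16.1
    volume_log_mu: float = math.log(3.7)
    volume_log_sigma: float = math.log(16.1 / 1.2) / (2 * 0.6744897501960817)
    max_lesion_fraction: float = 0.5  # cap: lesion <= this fraction of the brain mask
    # score distribution used by the non-imaging cohort shortcut; matches the
    # imaging chain's log-score distribution under the default geometry
    score_mu: float = 4.3
    score_sigma: float = 2.55
    # covariates
    age_mean: float = 66.7
    age_sd: float = 11.7
    male_fraction: float = 0.598
    education_probs: tuple = (0.567, 0.217, 0.079, 0.138)
    prior_stroke_prob: float = 0.113
    n_sites: int = 12
    site_probs: tuple = (0.20, 0.15, 0.12, 0.10, 0.08, 0.08, 0.07, 0.06, 0.05, 0.04, 0.03, 0.02)
    site_effect_sd: float = 0.3
    # outcome model (MARGINAL log-odds; see module docstring)
    # marginal intercept from calibrate_intercept(target_prevalence=0.40),
    # the middle of the observed per-interval prevalence band
    beta_intercept: float = -2.503
    beta_score: float = 0.239
    beta_age: float = math.log(1.17)  # per decade
    beta_male: float = math.log(0.85)
    beta_education: tuple = (math.log(0.88), math.log(0.83), math.log(1.01))
    beta_prior_stroke: float = math.log(1.76)
    beta_volume: float = math.log(1.10)  # per 10 mL
    sigma_subject: float = 1.481  # latent ICC 0.4 on the logistic scale
    # assessment timing (days)
    first_visit_log_mu: float = math.log(104.0)
    first_visit_log_sigma: float = 0.8
    first_visit_max_day: int = 452
    gap_min_days: int = 120
    gap_max_days: int = 540

    def validate(self) -> "SimulationConfig":
        if self.n_regions < 1 or self.n_regions > int(np.prod(self.shape)):
            raise ValidationError("n_regions must be in [1, voxel count]")
        if self.n_patients < 1:
            raise ValidationError("n_patients must be positive")
        if abs(sum(self.visit_mixture) - 1.0) > 1e-6:
            raise ValidationError("visit_mixture must sum to 1")
        if self.volume_log_sigma <= 0:
            raise ValidationError("volume_log_sigma must be positive")
        for p in (self.moca_fraction, self.male_fraction, self.prior_stroke_prob):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"probability {p} outside [0, 1]")
        return self


EDUCATION_CATEGORIES = [
    "less_than_high_school",
    "high_school",
    "technical_college",
    "university_or_higher",
]


# --------------------------------------------------------------------------
# geometry: brain mask, parcellation
# --------------------------------------------------------------------------

def _ellipsoid_mask(shape, semi_fractions=(0.45, 0.38, 0.34)) -> np.ndarray:
    center = (np.asarray(shape) - 1) / 2.0
    semi = np.asarray(shape) * np.asarray(semi_fractions)
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    d2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi))
    return d2 <= 1.0


def brain_mask(config: SimulationConfig) -> np.ndarray:
    """Full ellipsoidal brain mask (grey shell + unlabelled core)."""
    return _ellipsoid_mask(config.shape)


def _grey_shell(config: SimulationConfig) -> np.ndarray:
    outer = _ellipsoid_mask(config.shape)
    f = config.shell_fraction
    inner = _ellipsoid_mask(config.shape, semi_fractions=(0.45 * f, 0.38 * f, 0.34 * f))
    return outer & ~inner


_NEIGHBOURS = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]


def generate_parcellation(config: SimulationConfig) -> np.ndarray:
    """Tessellate the grey-matter shell into ``n_regions`` contiguous labels.

    Seed voxels are sampled uniformly in the shell; labels grow outward by
    multi-source breadth-first search over the 6-connected shell (a geodesic
    Voronoi tessellation, so every region is contiguous by construction and
    nonempty because it contains its own seed). Background is 0. Fully
    deterministic under the config seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    shell = _grey_shell(config)
    shell_idx = np.argwhere(shell)
    if len(shell_idx) < config.n_regions:
        raise ValidationError(
            f"shell has {len(shell_idx)} voxels < n_regions={config.n_regions}"
        )
    pick = rng.choice(len(shell_idx), size=config.n_regions, replace=False)
    labels = np.zeros(config.shape, dtype=np.int32)
    queue = deque()
    for r, i in enumerate(pick, start=1):
        x, y, z = shell_idx[i]
        labels[x, y, z] = r
        queue.append((int(x), int(y), int(z)))
    shape = config.shape
    while queue:
        x, y, z = queue.popleft()
        lab = labels[x, y, z]
        for dx, dy, dz in _NEIGHBOURS:
            nx_, ny_, nz_ = x + dx, y + dy, z + dz
            if 0 <= nx_ < shape[0] and 0 <= ny_ < shape[1] and 0 <= nz_ < shape[2]:
                if shell[nx_, ny_, nz_] and labels[nx_, ny_, nz_] == 0:
                    labels[nx_, ny_, nz_] = lab
                    queue.append((nx_, ny_, nz_))
    # isolated shell voxels unreachable by BFS (diagonal-only contact) stay 0;
    # they behave as background, which the scoring path tolerates
    return labels


def region_centroids(parcellation: np.ndarray) -> pd.DataFrame:
    labels = np.unique(parcellation[parcellation > 0])
    rows = []
    for lab in labels:
        rows.append((int(lab), *np.argwhere(parcellation == lab).mean(axis=0)))
    return pd.DataFrame(rows, columns=["region_id", "x", "y", "z"]).set_index("region_id")


# --------------------------------------------------------------------------
# connectome
# --------------------------------------------------------------------------

def generate_connectome(
    config: SimulationConfig, parcellation: np.ndarray | None = None
) -> atlas_mod.Connectome:
    """Hub-structured weighted connectome over the parcellation regions.

    Connection probability decays with centroid distance; a designated set
    of hub nodes (those nearest the brain's centre of mass) receives dense,
    strong long-range edges so hub betweenness exceeds the median node's.
    Disconnected draws are retried with an incremented sub-seed (bounded);
    with three or fewer regions the graph is complete (a triangle at 3).
    """
    config.validate()
    if config.n_regions < 3:
        raise ValidationError("connectome generation needs n_regions >= 3")
    if parcellation is None:
        parcellation = generate_parcellation(config)
    cents = region_centroids(parcellation)
    ids = cents.index.to_numpy()
    pos = cents.to_numpy(dtype=float)
    n = len(ids)
    diag = float(np.linalg.norm(config.shape))
    lam = config.connection_scale * diag
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)

    center = pos.mean(axis=0)
    hub_order = np.argsort(np.linalg.norm(pos - center, axis=1), kind="stable")
    hubs = set(int(i) for i in hub_order[: min(config.n_hubs, n)])

    for attempt in range(config.max_connectome_retries):
        rng = np.random.default_rng(config.seed + 1000 + attempt)
        edges = []
        if n <= 3:
            for a in range(n):
                for b in range(a + 1, n):
                    edges.append((ids[a], ids[b], 1.0))
        else:
            prob = config.base_connection_prob * np.exp(-d / lam)
            draw = rng.random((n, n))
            base_w = rng.lognormal(mean=0.0, sigma=0.4, size=(n, n))
            fan = rng.random((n, n))
            n_fan = config.hub_fanout
            for a in range(n):
                for b in range(a + 1, n):
                    is_hub_edge = a in hubs or b in hubs
                    connected = draw[a, b] < prob[a, b]
                    if is_hub_edge and not connected:
                        connected = fan[a, b] < n_fan
                    if connected:
                        w = base_w[a, b] * (config.hub_weight_boost if is_hub_edge else 1.0)
                        edges.append((ids[a], ids[b], float(w)))
        conn = atlas_mod.Connectome.from_edges(edges, node_labels=list(ids))
        import networkx as nx

        if nx.is_connected(conn.graph):
            return conn
    raise ValidationError(
        f"no connected connectome in {config.max_connectome_retries} draws"
    )


# --------------------------------------------------------------------------
# lesions
# --------------------------------------------------------------------------

@dataclass
class LesionSet:
    """Cohort of lesion masks stored sparsely (flat voxel indices per patient)."""

    shape: tuple
    voxel_size_mm: float
    voxel_indices: dict = field(repr=False)
    target_volumes_ml: dict = field(repr=False, default_factory=dict)

    def patient_ids(self):
        return sorted(self.voxel_indices)

    def mask(self, patient_id) -> np.ndarray:
        out = np.zeros(self.shape, dtype=bool)
        out.ravel()[self.voxel_indices[patient_id]] = True
        return out


def generate_lesions(
    config: SimulationConfig,
    parcellation: np.ndarray | None = None,
    centrality: pd.Series | None = None,
) -> tuple[LesionSet, pd.DataFrame, pd.DataFrame]:
    """Grow one quasi-spherical lesion per patient and score it.

    Target volumes (mL) are drawn log-normally (median 3.7, IQR ~1.2-16.1,
    capped at half the brain mask so a draw from the far tail cannot swallow
    the miniature brain). Each lesion takes the target number of brain-mask
    voxels nearest (under a mild random anisotropy) to a random seed voxel —
    a deterministic quasi-spherical growth that lands within +-5% of target
    whenever the cap is not hit. Lesions confined to the unlabelled core
    (no grey-matter overlap) are regenerated from a fresh seed voxel, with
    bounded retries; a patient whose retries are exhausted keeps the last
    draw and will surface in the scoring exclusion report.

    Returns ``(lesions, scores, exclusions)`` where scores/exclusions come
    from the batch scorer run against the generated atlas binding.
    """
    config.validate()
    if parcellation is None:
        parcellation = generate_parcellation(config)
    rng = np.random.default_rng(config.seed + 2000)
    mask = brain_mask(config)
    coords = np.argwhere(mask).astype(np.float64)
    flat = np.flatnonzero(mask.ravel())
    grey_of_mask = (parcellation > 0).ravel()[flat]  # grey flag per mask voxel
    n_mask = len(flat)
    voxel_vol = config.voxel_size_mm ** 3
    cap_vox = int(config.max_lesion_fraction * n_mask)

    indices: dict = {}
    targets: dict = {}
    width = len(str(config.n_patients))
    for i in range(config.n_patients):
        pid = f"P{i + 1:0{width}d}"
        target_ml = float(
            np.exp(rng.normal(config.volume_log_mu, config.volume_log_sigma))
        )
        target_vox = int(round(target_ml * 1000.0 / voxel_vol))
        target_vox = min(max(target_vox, 1), cap_vox)
        for _retry in range(20):
            seed_i = int(rng.integers(n_mask))
            aniso = rng.uniform(0.75, 1.35, size=3)
            delta = (coords - coords[seed_i]) * aniso
            dist = np.einsum("ij,ij->i", delta, delta)
            if target_vox < n_mask:
                part = np.argpartition(dist, target_vox)[:target_vox]
            else:
                part = np.arange(n_mask)
            if grey_of_mask[part].any():
                break
        indices[pid] = np.sort(flat[part])
        targets[pid] = target_ml
    lesions = LesionSet(
        shape=config.shape,
        voxel_size_mm=config.voxel_size_mm,
        voxel_indices=indices,
        target_volumes_ml=targets,
    )
    if centrality is None:
        centrality = atlas_mod.betweenness_centrality(
            generate_connectome(config, parcellation), weighted=True
        )
    scores, exclusions = impact_mod.score_batch(
        {pid: pid for pid in lesions.patient_ids()},
        parcellation,
        centrality,
        voxel_volume_mm3=voxel_vol,
        loader=lesions.mask,
    )
    return lesions, scores, exclusions


# --------------------------------------------------------------------------
# covariates and longitudinal outcomes
# --------------------------------------------------------------------------

def generate_covariates(config: SimulationConfig, patient_ids) -> pd.DataFrame:
    """Draw per-patient demographics from the cohort-anchored marginals."""
    config.validate()
    rng = np.random.default_rng(config.seed + 3000)
    n = len(patient_ids)
    age = rng.normal(config.age_mean, config.age_sd, size=n)
    age = np.clip(age, 18.0, 100.0)
    sex = np.where(rng.random(n) < config.male_fraction, "male", "female")
    edu_p = np.asarray(config.education_probs, dtype=float)
    edu = rng.choice(EDUCATION_CATEGORIES, size=n, p=edu_p / edu_p.sum())
    prior = (rng.random(n) < config.prior_stroke_prob).astype(int)
    site_p = np.asarray(config.site_probs[: config.n_sites], dtype=float)
    site = rng.choice(
        [f"site_{i + 1:02d}" for i in range(config.n_sites)], size=n, p=site_p / site_p.sum()
    )
    return pd.DataFrame(
        {
            "patient_id": list(patient_ids),
            "age_years": np.round(age, 1),
            "sex": sex,
            "education_category": edu,
            "prior_stroke": prior,
            "site_id": site,
        }
    )


def site_effects(config: SimulationConfig) -> dict:
    rng = np.random.default_rng(config.seed + 4000)
    eff = rng.normal(0.0, config.site_effect_sd, size=config.n_sites)
    eff -= eff.mean()  # centre so the intercept keeps its meaning
    return {f"site_{i + 1:02d}": float(eff[i]) for i in range(config.n_sites)}


def _conditional_inflation(sigma_b: float) -> float:
    return math.sqrt(1.0 + _ATTENUATION_C2 * sigma_b * sigma_b)


def marginal_linear_predictor(config: SimulationConfig, frame: pd.DataFrame, effects: dict) -> np.ndarray:
    """Population-averaged log-odds of PSCI per row of ``frame``."""
    edu_terms = np.zeros(len(frame))
    for level, beta in zip(EDUCATION_CATEGORIES[1:], config.beta_education):
        edu_terms += np.where(frame["education_category"] == level, beta, 0.0)
    return (
        config.beta_intercept
        + config.beta_score * frame["log_score"].to_numpy(float)
        + config.beta_age * frame["age_years"].to_numpy(float) / 10.0
        + config.beta_male * (frame["sex"] == "male").to_numpy(float)
        + edu_terms
        + config.beta_prior_stroke * frame["prior_stroke"].to_numpy(float)
        + config.beta_volume * frame["infarct_volume_ml"].to_numpy(float) / 10.0
        + np.asarray([effects[s] for s in frame["site_id"]])
    )


def generate_outcomes(
    config: SimulationConfig, scores: pd.DataFrame, covariates: pd.DataFrame
) -> pd.DataFrame:
    """Emit the long cohort table of visits with PSCI-consistent percentiles.

    ``scores`` needs columns patient_id, log_score, lesion_volume_ml (the
    batch-scorer output); ``covariates`` is :func:`generate_covariates`
    output. Per visit, PSCI ~ Bernoulli on the conditional logistic scale
    (marginal coefficients inflated, plus the subject's shared latent term
    and its site effect). Domain percentiles (or the MoCA percentile for
    MoCA-only patients) are then drawn consistently with the binary status:
    impaired domains below the 5th percentile, spared ones above. A small
    fraction of unimpaired full-battery visits record only two domains and
    are therefore indeterminate downstream, exercising that code path.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 5000)
    effects = site_effects(config)
    base = covariates.merge(
        scores.rename(columns={"lesion_volume_ml": "infarct_volume_ml"})[
            ["patient_id", "log_score", "infarct_volume_ml"]
        ],
        on="patient_id",
        how="inner",
    ).sort_values("patient_id", kind="mergesort")
    n = len(base)
    kappa = _conditional_inflation(config.sigma_subject)
    eta_marginal = marginal_linear_predictor(config, base, effects)
    b_subject = rng.normal(0.0, config.sigma_subject, size=n)
    if config.visits_fixed is not None:
        n_visits = np.full(n, config.visits_fixed, dtype=int)
    else:
        mix = np.asarray(config.visit_mixture)
        n_visits = rng.choice(np.arange(1, 7), size=n, p=mix / mix.sum())
    moca_only = rng.random(n) < config.moca_fraction

    rows = []
    for i in range(n):
        rec = base.iloc[i]
        day = int(
            min(
                round(np.exp(rng.normal(config.first_visit_log_mu, config.first_visit_log_sigma))),
                config.first_visit_max_day,
            )
        )
        p_cond = expit(kappa * eta_marginal[i] + b_subject[i])
        instrument = "moca" if moca_only[i] else "full_battery"
        for visit in range(1, int(n_visits[i]) + 1):
            psci = bool(rng.random() < p_cond)
            row = {
                "patient_id": rec["patient_id"],
                "visit": visit,
                "days_post_stroke": day,
                "moca_percentile": np.nan,
                "instrument": instrument,
                "age_years": rec["age_years"],
                "sex": rec["sex"],
                "education_category": rec["education_category"],
                "prior_stroke": int(rec["prior_stroke"]),
                "infarct_volume_ml": rec["infarct_volume_ml"],
                "site_id": rec["site_id"],
            }
            for col in DOMAIN_COLUMNS:
                row[col] = np.nan
            if instrument == "moca":
                row["moca_percentile"] = (
                    rng.uniform(0.0, 5.0) if psci else rng.uniform(5.0, 100.0)
                )
            else:
                if psci:
                    n_impaired = 1 + rng.binomial(5, 0.3)
                    impaired = rng.choice(6, size=n_impaired, replace=False)
                    for k in range(6):
                        row[DOMAIN_COLUMNS[k]] = (
                            rng.uniform(0.0, 5.0)
                            if k in impaired
                            else rng.uniform(5.0, 100.0)
                        )
                else:
                    if rng.random() < config.indeterminate_fraction:
                        assessed = rng.choice(6, size=2, replace=False)
                    else:
                        assessed = np.arange(6)
                    for k in assessed:
                        row[DOMAIN_COLUMNS[int(k)]] = rng.uniform(5.0, 100.0)
            rows.append(row)
            day += int(rng.integers(config.gap_min_days, config.gap_max_days + 1))
    columns = [
        "patient_id",
        "visit",
        "days_post_stroke",
        *DOMAIN_COLUMNS,
        "moca_percentile",
        "instrument",
        "age_years",
        "sex",
        "education_category",
        "prior_stroke",
        "infarct_volume_ml",
        "site_id",
    ]
    return pd.DataFrame(rows, columns=columns)


def _volume_cap_ml(config: SimulationConfig) -> float:
    n_mask = int(brain_mask(config).sum())
    return config.max_lesion_fraction * n_mask * config.voxel_size_mm ** 3 / 1000.0


def _draw_volumes(config: SimulationConfig, rng, n: int) -> np.ndarray:
    raw = np.exp(rng.normal(config.volume_log_mu, config.volume_log_sigma, size=n))
    return np.minimum(raw, _volume_cap_ml(config))


def simulate_cohort_table(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Cohort table without the imaging stage (scores drawn directly).

    For statistical simulations the voxel pipeline is unnecessary: log
    scores are drawn normal with the configured (score_mu, score_sigma) —
    matching the imaging chain's score distribution — and volumes from the
    configured log-normal, capped as lesion growth caps them. Returns
    ``(cohort, scores, truth)``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 6000)
    width = len(str(config.n_patients))
    pids = [f"P{i + 1:0{width}d}" for i in range(config.n_patients)]
    log_score = rng.normal(config.score_mu, config.score_sigma, size=config.n_patients)
    vols = _draw_volumes(config, rng, config.n_patients)
    scores = pd.DataFrame(
        {
            "patient_id": pids,
            "raw_score": np.exp(log_score),
            "log_score": log_score,
            "argmax_region": 0,
            "lesion_volume_ml": vols,
        }
    )
    cov = generate_covariates(config, pids)
    cohort = generate_outcomes(config, scores, cov)
    truth = generative_truth(config)
    return cohort, scores, truth


def generative_truth(config: SimulationConfig) -> dict:
    """The generative parameters, for truth.json provenance files."""
    return {
        "seed": config.seed,
        "beta_intercept": config.beta_intercept,
        "beta_score": config.beta_score,
        "beta_age_per_decade": config.beta_age,
        "beta_male": config.beta_male,
        "beta_education": list(config.beta_education),
        "beta_prior_stroke": config.beta_prior_stroke,
        "beta_volume_per_10ml": config.beta_volume,
        "sigma_subject": config.sigma_subject,
        "conditional_inflation": _conditional_inflation(config.sigma_subject),
        "site_effects": site_effects(config),
        "n_patients": config.n_patients,
    }


def calibrate_intercept(
    config: SimulationConfig, target_prevalence: float, n_probe: int = 4000
) -> float:
    """Find the marginal intercept giving a target per-visit PSCI prevalence.

    Uses a seeded probe cohort (scores and covariates drawn as in
    :func:`simulate_cohort_table`) and solves for the intercept by bisection
    on the simulated mean of the conditional response probability.
    """
    from scipy.optimize import brentq

    probe = replace(config, n_patients=n_probe, beta_intercept=0.0)
    rng = np.random.default_rng(config.seed + 7000)
    width = len(str(n_probe))
    pids = [f"P{i + 1:0{width}d}" for i in range(n_probe)]
    scores = pd.DataFrame(
        {
            "patient_id": pids,
            "log_score": rng.normal(config.score_mu, config.score_sigma, size=n_probe),
            "lesion_volume_ml": _draw_volumes(config, rng, n_probe),
        }
    )
    cov = generate_covariates(probe, pids)
    frame = cov.merge(
        scores.rename(columns={"lesion_volume_ml": "infarct_volume_ml"}),
        on="patient_id",
    )
    eta0 = marginal_linear_predictor(probe, frame, site_effects(probe))
    b = rng.normal(0.0, config.sigma_subject, size=n_probe)
    kappa = _conditional_inflation(config.sigma_subject)

    def gap(b0: float) -> float:
        return float(np.mean(expit(kappa * (eta0 + b0) + b))) - target_prevalence

    return float(brentq(gap, -12.0, 12.0, xtol=1e-6))


# --------------------------------------------------------------------------
# end-to-end
# --------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Everything one simulated study produced, inputs and truth included."""

    config: SimulationConfig
    parcellation: np.ndarray = field(repr=False)
    connectome: atlas_mod.Connectome = field(repr=False)
    centrality: pd.Series = field(repr=False)
    lesions: LesionSet = field(repr=False)
    scores: pd.DataFrame = field(repr=False)
    exclusions: pd.DataFrame = field(repr=False)
    cohort: pd.DataFrame = field(repr=False)
    truth: dict = field(repr=False)


def simulate_study(config: SimulationConfig) -> SimulationResult:
    """Run the full generation chain: parcellation -> connectome ->
    lesions -> scores -> covariates -> longitudinal outcomes."""
    config.validate()
    parcellation = generate_parcellation(config)
    connectome = generate_connectome(config, parcellation)
    centrality = atlas_mod.betweenness_centrality(connectome, weighted=True)
    lesions, scores, exclusions = generate_lesions(config, parcellation, centrality)
    covariates = generate_covariates(config, lesions.patient_ids())
    cohort = generate_outcomes(config, scores, covariates)
    truth = generative_truth(config)
    truth["true_scores"] = dict(zip(scores["patient_id"], scores["log_score"]))
    return SimulationResult(
        config=config,
        parcellation=parcellation,
        connectome=connectome,
        centrality=centrality,
        lesions=lesions,
        scores=scores,
        exclusions=exclusions,
        cohort=cohort,
        truth=truth,
    )
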