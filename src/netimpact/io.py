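"""Volume and table I/O, run configuration, and the end-to-end pipeline.

NIfTI (.nii / .nii.gz) is the only volume format. Binary masks are
thresholded at 0.5 on read; label volumes are cast to integers with a
lossiness check (a value like 1.4 is a format error, not a label). Tables
are UTF-8 comma-separated CSV with a header row and '.' decimals.

``run_pipeline`` ties the stages together — score, classify, analyze — and
writes a provenance record (config, seed, package and library versions)
next to its outputs. Every exclusion is logged at INFO with the patient id
and reason, so the run log doubles as the study's inclusion flow-chart.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import betweenness_centrality, read_centrality_csv, write_centrality_csv
from .cognition import INTERVAL_LABELS, classify_cohort, classify_transitions
from .errors import FormatError, NetImpactError, ValidationError
from .impact import SCORE_COLUMNS, score_batch
from .stats import ModelSpec, fit_gee_logistic, fit_stratified_logistic, fit_transition_logistic
from .synthetic import SimulationConfig, simulate_study

logger = logging.getLogger(__name__)

__all__ = [
    "VolumeMeta",
    "read_volume",
    "read_mask",
    "read_labels",
    "write_volume",
    "RunConfig",
    "run_pipeline",
]


@dataclass(frozen=True)
class VolumeMeta:
    shape: tuple
    voxel_sizes: tuple
    affine: np.ndarray = field(repr=False)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_sizes))


def read_volume(path) -> tuple[np.ndarray, VolumeMeta]:
    """Load a NIfTI volume as a float array plus grid metadata."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"volume not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    meta = VolumeMeta(
        shape=tuple(data.shape),
        voxel_sizes=tuple(float(z) for z in img.header.get_zooms()[:3]),
        affine=np.asarray(img.affine),
    )
    return data, meta


def read_mask(path) -> tuple[np.ndarray, VolumeMeta]:
    """Binary lesion mask: values thresholded at 0.5."""
    data, meta = read_volume(path)
    return data > 0.5, meta


def read_labels(path) -> tuple[np.ndarray, VolumeMeta]:
    """Integer label volume, with a cast-lossiness check.

    Values must be within 1e-6 of an integer; anything else (e.g. an
    interpolated 1.4) indicates a resampled parcellation and is rejected.
    """
    data, meta = read_volume(path)
    rounded = np.rint(data)
    drift = np.abs(data - rounded).max()
    if drift > 1e-6:
        raise FormatError(f"label volume {path} has non-integer values (max drift {drift:g})")
    if rounded.min() < 0:
        raise FormatError(f"label volume {path} has negative labels")
    return rounded.astype(np.int32), meta


def write_volume(data: np.ndarray, affine: np.ndarray | None, path) -> None:
    if affine is None:
        affine = np.eye(4)
    arr = np.asarray(data)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    nib.save(nib.Nifti1Image(arr, affine), str(path))


# --------------------------------------------------------------------------
# run configuration and pipeline
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Paths and options for an end-to-end run.

    With ``simulate=True`` inputs are generated in-memory from the seed;
    otherwise ``lesion_paths``/``parcellation_path``/``centrality_path``/
    ``cohort_path`` must point at existing files (validated before any
    computation starts).
    """

    output_dir: str = "netimpact_out"
    seed: int = 0
    simulate: bool = True
    n_patients: int | None = None
    lesion_paths: dict = field(default_factory=dict)  # patient_id -> path
    parcellation_path: str | None = None
    centrality_path: str | None = None
    connectome_path: str | None = None
    cohort_path: str | None = None
    log_base: float | None = None  # None = natural log
    correlation: str = "ar1"
    exclude_sites: tuple = ()
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "exclude_sites" in raw and raw["exclude_sites"] is not None:
            raw["exclude_sites"] = tuple(raw["exclude_sites"])
        return cls(**raw)

    def validate_paths(self) -> None:
        if self.simulate:
            return
        missing = []
        for label, p in [
            ("parcellation", self.parcellation_path),
            ("centrality", self.centrality_path),
            ("cohort", self.cohort_path),
        ]:
            if p is None or not Path(p).exists():
                missing.append(f"{label}: {p}")
        for pid, p in self.lesion_paths.items():
            if not Path(p).exists():
                missing.append(f"lesion {pid}: {p}")
        if missing:
            raise ValidationError("missing inputs -> " + "; ".join(missing))


def _provenance(config: RunConfig) -> dict:
    import networkx
    import scipy
    import statsmodels

    return {
        "netimpact_version": __version__,
        "seed": config.seed,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "statsmodels": statsmodels.__version__,
            "networkx": networkx.__version__,
            "nibabel": nib.__version__,
        },
    }


def _write_model(result_or_error, path: Path) -> None:
    if isinstance(result_or_error, NetImpactError):
        payload = {
            "error": type(result_or_error).__name__,
            "message": str(result_or_error),
        }
    else:
        payload = result_or_error.to_dict()
    path.write_text(json.dumps(payload, indent=2, default=float) + "\n", encoding="utf-8")


def run_pipeline(config: RunConfig) -> dict:
    """Execute score -> classify -> analyze and write all artifacts.

    Returns a summary dict (paths, counts, per-model status). Core-stage
    typed errors propagate; per-model failures in the stratified and
    transition analyses are captured into the model JSON and the run log so
    one sparse stratum cannot void an otherwise complete run.
    """
    logging.basicConfig(level=getattr(logging, config.verbosity, logging.INFO))
    config.validate_paths()
    out = Path(config.output_dir)
    (out / "models").mkdir(parents=True, exist_ok=True)

    if config.simulate:
        sim_cfg = SimulationConfig(seed=config.seed)
        if config.n_patients is not None:
            sim_cfg = dataclasses.replace(sim_cfg, n_patients=config.n_patients)
        sim = simulate_study(sim_cfg)
        scores, exclusions, cohort = sim.scores, sim.exclusions, sim.cohort
        write_centrality_csv(sim.centrality, out / "centrality.csv")
        (out / "truth.json").write_text(
            json.dumps(sim.truth, indent=2, default=float) + "\n", encoding="utf-8"
        )
    else:
        parc, meta = read_labels(config.parcellation_path)
        centrality = read_centrality_csv(config.centrality_path)
        scores, exclusions = score_batch(
            dict(config.lesion_paths),
            parc,
            centrality,
            voxel_volume_mm3=meta.voxel_volume_mm3,
            log_base=config.log_base,
            loader=lambda p: read_mask(p)[0],
        )
        cohort = pd.read_csv(config.cohort_path)

    if config.log_base is not None and config.simulate:
        scores = scores.copy()
        scores["log_score"] = np.log(scores["raw_score"]) / np.log(config.log_base)

    scores.to_csv(out / "scores.csv", index=False, columns=SCORE_COLUMNS)
    exclusions.to_csv(out / "exclusions.csv", index=False)
    for _, row in exclusions.iterrows():
        logger.info("excluded %s: %s", row["patient_id"], row["reason"])

    classified = classify_cohort(cohort).merge(
        scores[["patient_id", "log_score"]], on="patient_id", how="inner"
    )
    classified.to_csv(out / "psci_long.csv", index=False)
    transitions = classify_transitions(classified)
    transitions.to_csv(out / "transitions.csv", index=False)

    model_status = {}
    models: dict = {}
    core = {
        "gee_univariable": lambda: fit_gee_logistic(
            classified,
            ModelSpec(univariable=True, correlation=config.correlation,
                      exclude_sites=config.exclude_sites),
        ),
        "gee_multivariable": lambda: fit_gee_logistic(
            classified,
            ModelSpec(correlation=config.correlation, exclude_sites=config.exclude_sites),
        ),
    }
    for name, fit in core.items():
        result = fit()  # typed errors propagate: the GEE models are required
        models[name] = result
        model_status[name] = "ok"
        _write_model(result, out / "models" / f"{name}.json")

    optional = {}
    for label in INTERVAL_LABELS:
        slug = label.replace("<", "lt").replace(">", "gt").replace(" ", "_").replace("-", "_")
        optional[f"stratified_{slug}"] = (
            lambda lab=label: fit_stratified_logistic(
                classified, ModelSpec(interval=lab, exclude_sites=config.exclude_sites)
            )
        )
    for outcome in ("recovery", "decline"):
        optional[f"transition_{outcome}_univariable"] = (
            lambda oc=outcome: fit_transition_logistic(
                classified, oc,
                ModelSpec(univariable=True, exclude_sites=config.exclude_sites),
            )
        )
        optional[f"transition_{outcome}_multivariable"] = (
            lambda oc=outcome: fit_transition_logistic(
                classified, oc, ModelSpec(exclude_sites=config.exclude_sites)
            )
        )
    for name, fit in optional.items():
        try:
            result = fit()
            models[name] = result
            model_status[name] = "ok"
        except NetImpactError as exc:
            result = exc
            model_status[name] = f"{type(exc).__name__}: {exc}"
            logger.info("model %s failed: %s", name, exc)
        _write_model(result, out / "models" / f"{name}.json")

    provenance = _provenance(config)
    provenance["n_scored"] = int(len(scores))
    provenance["n_excluded_unscorable"] = int(len(exclusions))
    provenance["model_status"] = model_status
    (out / "run_log.json").write_text(
        json.dumps(provenance, indent=2, default=float) + "\n", encoding="utf-8"
    )
    return {
        "output_dir": str(out),
        "n_scored": int(len(scores)),
        "n_excluded": int(len(exclusions)),
        "models": models,
        "model_status": model_status,
    }
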