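"""Network impact score of an acute infarct.

The score quantifies how strongly a lesion disrupts the structural brain
network, using only the lesion's location in template space and a fixed
network atlas. For a binary lesion mask L and a parcellation with regions
r = 1..R carrying betweenness centralities c_r:

1. p_r = |L intersect region r| / |region r|   (proportion lesioned, in [0, 1])
2. impact_r = p_r * c_r
3. raw score = max_r impact_r ; network impact score = log(raw)

The log is natural by default; the base only rescales downstream regression
coefficients and is configurable. A lesion whose raw score is 0 — one that
touches no region of the atlas, e.g. a purely white-matter or infratentorial
infarct — is not scorable and raises :class:`UnscorableLesionError` rather
than producing -inf, mirroring how such infarcts are excluded from cohorts.

Proportions are voxel-count ratios on the shared template grid (all-or-none
label membership, no partial-volume weighting), matching a 1 mm isotropic
grid where voxels are small relative to regions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import BoundAtlas, bind_centrality
from .errors import GridMismatchError, NetImpactError, UnscorableLesionError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkImpactScore",
    "region_overlap",
    "impact_vector",
    "network_impact_score",
    "score_lesion",
    "score_batch",
    "SCORE_COLUMNS",
]

#: Fixed column order of the per-patient score table.
SCORE_COLUMNS = ["patient_id", "raw_score", "log_score", "argmax_region", "lesion_volume_ml"]


@dataclass(frozen=True)
class NetworkImpactScore:
    """Patient-level result: max regional impact and its log transform."""

    raw: float
    log_score: float
    argmax_region: int


def _as_binary_mask(lesion) -> np.ndarray:
    arr = np.asarray(lesion)
    if arr.dtype == bool:
        return arr
    return arr > 0.5


def region_overlap(lesion, parcellation, region_sizes: pd.Series | None = None) -> pd.Series:
    """Proportion of each parcellation region covered by the lesion.

    Parameters
    ----------
    lesion
        Binary 3-D mask (non-boolean arrays are thresholded at 0.5).
    parcellation
        Integer label volume on the same grid; 0 is background.
    region_sizes
        Optional precomputed voxel counts per region (from a
        :class:`~netimpact.atlas.BoundAtlas`); recomputed when omitted.

    Returns a Series indexed by region id with values in [0, 1].
    """
    mask = _as_binary_mask(lesion)
    parc = np.asarray(parcellation)
    if mask.shape != parc.shape:
        raise GridMismatchError(
            f"lesion grid {mask.shape} != parcellation grid {parc.shape}"
        )
    if region_sizes is None:
        labels, counts = np.unique(parc[parc > 0], return_counts=True)
        if labels.size == 0:
            raise ValidationError("parcellation contains no nonzero labels")
        region_sizes = pd.Series(counts, index=labels.astype(int), name="n_voxels")
    if (region_sizes <= 0).any():
        raise ValidationError("every region must have at least one voxel")
    n_labels = int(region_sizes.index.max()) + 1
    hit = np.bincount(parc[mask].ravel(), minlength=n_labels)
    props = pd.Series(
        hit[region_sizes.index.to_numpy()] / region_sizes.to_numpy(dtype=float),
        index=region_sizes.index,
        name="proportion",
    )
    props.index.name = "region_id"
    return props


def impact_vector(proportions: pd.Series, centrality: pd.Series) -> pd.DataFrame:
    """Per-region impact: proportion lesioned times betweenness centrality.

    The two inputs must cover identical region sets; no thresholding and no
    summation — the elementwise product is kept per region.
    """
    from .errors import BindingError

    prop_ids = set(int(i) for i in proportions.index)
    cent_ids = set(int(i) for i in centrality.index)
    if prop_ids != cent_ids:
        raise BindingError(
            "region sets differ: "
            f"only-in-proportions={sorted(prop_ids - cent_ids)}, "
            f"only-in-centrality={sorted(cent_ids - prop_ids)}",
            missing_labels=sorted(prop_ids ^ cent_ids),
        )
    cent = centrality.reindex(proportions.index).astype(float)
    out = pd.DataFrame(
        {
            "proportion": proportions.astype(float),
            "centrality": cent,
            "impact": proportions.to_numpy(dtype=float) * cent.to_numpy(),
        }
    )
    out.index.name = "region_id"
    return out


def network_impact_score(impacts: pd.DataFrame | pd.Series, log_base: float | None = None) -> NetworkImpactScore:
    """Reduce a per-region impact vector to the patient's score.

    raw = max impact; ties in the maximum are broken by smallest region id
    (the tie-break affects only the reported argmax, never the score).
    ``log_base`` of ``None`` means the natural log.
    """
    col = impacts["impact"] if isinstance(impacts, pd.DataFrame) else impacts
    if len(col) == 0:
        raise ValidationError("impact vector is empty")
    values = col.to_numpy(dtype=float)
    order = np.argsort(col.index.to_numpy())  # smallest region id wins ties
    best = order[np.argmax(values[order])]
    raw = float(values[best])
    if raw <= 0.0:
        raise UnscorableLesionError(
            "lesion overlaps no region with positive centrality (raw score 0)"
        )
    log_score = math.log(raw) if log_base is None else math.log(raw, log_base)
    return NetworkImpactScore(raw=raw, log_score=log_score, argmax_region=int(col.index[best]))


def score_lesion(lesion, atlas: BoundAtlas, log_base: float | None = None) -> NetworkImpactScore:
    """Full per-lesion pipeline: overlap -> impact vector -> max -> log."""
    props = region_overlap(lesion, atlas.parcellation, atlas.region_sizes)
    impacts = impact_vector(props, atlas.centrality)
    return network_impact_score(impacts, log_base=log_base)


def score_batch(
    lesions,
    parcellation,
    centrality: pd.Series,
    voxel_volume_mm3: float = 1.0,
    log_base: float | None = None,
    loader=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score a cohort of lesion masks against one bound atlas.

    Parameters
    ----------
    lesions
        Mapping ``patient_id -> lesion`` where each lesion is an array or,
        with ``loader`` given, an opaque reference (e.g. a file path) that
        ``loader`` turns into an array.
    voxel_volume_mm3
        Volume of one voxel; lesion volume in mL is
        ``nonzero voxels * voxel_volume_mm3 / 1000``.

    Returns ``(scores, exclusions)``: the score table in the fixed column
    order, and an exclusion report (patient_id, reason) covering unscorable
    and unreadable lesions — nothing is silently dropped. Both frames are
    sorted by patient id, so repeated runs on the same inputs are
    byte-identical when written.
    """
    atlas = bind_centrality(np.asarray(parcellation), centrality)
    rows, excluded = [], []
    for patient_id in sorted(lesions):
        ref = lesions[patient_id]
        try:
            arr = loader(ref) if loader is not None else ref
            mask = _as_binary_mask(arr)
            volume_ml = float(mask.sum()) * voxel_volume_mm3 / 1000.0
            result = score_lesion(mask, atlas, log_base=log_base)
        except UnscorableLesionError as exc:
            excluded.append((patient_id, f"unscorable: {exc}"))
            logger.info("excluded %s: %s", patient_id, exc)
            continue
        except (OSError, NetImpactError) as exc:
            excluded.append((patient_id, f"io_or_validation: {exc}"))
            logger.info("excluded %s: %s", patient_id, exc)
            continue
        rows.append(
            (patient_id, result.raw, result.log_score, result.argmax_region, volume_ml)
        )
    scores = pd.DataFrame(rows, columns=SCORE_COLUMNS)
    exclusions = pd.DataFrame(excluded, columns=["patient_id", "reason"])
    return scores, exclusions
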