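"""Coordinate correction, mirroring, similarity filtering and region assignment.

Tissue samples carry MNI-style mm coordinates (left hemisphere x < 0).  The
operations here prepare samples for aggregation into atlas regions:

* optional replacement of the original coordinates with corrected values from
  an improved nonlinear registration;
* optional hemispheric mirroring — duplicating samples across the midline to
  compensate for the mostly left-lateralized sampling of the source data;
* optional inter-areal similarity filtering — removing samples whose
  expression profile is dissimilar from every other sample of the same donor;
* assignment of each sample to an atlas region, volumetric (mm tolerance) or
  surface (standard-deviation tolerance on sample-to-surface distances).

Assignment applies a hemisphere and structure-class compatibility gate: a
sample can only match a region on its own side of the midline with the same
structural class, which prevents cross-midline matches after mirroring.
"""

from __future__ import annotations

import logging
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ConfigurationError, MappingError, ParameterError
from .io import voxel_to_world, world_to_voxel
from .types import Atlas

logger = logging.getLogger("braintx")

MIRROR_MODES = ("none", "bidirectional", "left_to_right", "right_to_left")

COORD_COLUMNS = ["mni_x", "mni_y", "mni_z"]

#: numerical slack when comparing candidate voxel distances for ties
_TIE_EPS = 1e-9


def apply_corrected_coordinates(
    samples: pd.DataFrame, use_corrected: bool, table: Optional[pd.DataFrame]
) -> pd.DataFrame:
    """Replace MNI coordinates with corrected values when the flag is set.

    ``table`` has columns well_id, donor_id, x, y, z and must cover every
    sample of every donor present.
    """
    if not use_corrected:
        return samples.copy()
    if table is None:
        raise MappingError("corrected coordinates requested but no table given")
    keyed = table.set_index(["donor_id", "well_id"])
    if keyed.index.has_duplicates:
        raise MappingError("corrected-coordinates table has duplicate keys")
    out = samples.copy()
    wanted = pd.MultiIndex.from_arrays([out["donor_id"], out.index])
    missing = wanted.difference(keyed.index)
    if len(missing):
        raise MappingError(
            f"corrected-coordinates table missing {len(missing)} sample(s), "
            f"e.g. {tuple(missing[0])}"
        )
    coords = keyed.loc[wanted, ["x", "y", "z"]].to_numpy(float)
    out[COORD_COLUMNS] = coords
    return out


def mirror_samples(
    samples: pd.DataFrame, expression: pd.DataFrame, mode: str
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Mirror samples across the left-right hemisphere boundary.

    Mirrored copies have x negated, hemisphere flipped, identical expression
    and fresh synthetic well_ids.  ``bidirectional`` mirrors every sample
    once; samples with x exactly 0 are flagged and excluded from mirroring.

    ``expression`` is this donor's gene x sample matrix (columns = well_id).
    """
    if mode not in MIRROR_MODES:
        raise ParameterError(f"unknown mirror mode {mode!r}")
    if mode == "none":
        return samples.copy(), expression.copy()
    x = samples["mni_x"]
    midline = x == 0
    if midline.any():
        logger.warning(
            "%d sample(s) at x=0 excluded from mirroring", int(midline.sum())
        )
    if mode == "bidirectional":
        to_mirror = samples.index[~midline]
    elif mode == "left_to_right":
        to_mirror = samples.index[(x < 0)]
    else:  # right_to_left
        to_mirror = samples.index[(x > 0)]

    mirrored = samples.loc[to_mirror].copy()
    mirrored["mni_x"] = -mirrored["mni_x"]
    mirrored["hemisphere"] = mirrored["hemisphere"].map({"L": "R", "R": "L"})
    next_id = int(samples.index.max()) + 1
    new_ids = pd.Index(range(next_id, next_id + len(mirrored)), name=samples.index.name)
    mirrored.index = new_ids

    expr_mirror = expression[to_mirror].copy()
    expr_mirror.columns = new_ids
    return (
        pd.concat([samples, mirrored]),
        pd.concat([expression, expr_mirror], axis=1),
    )


def filter_samples_by_similarity(
    expression: pd.DataFrame, threshold: Optional[float]
) -> pd.Index:
    """Keep samples whose mean Spearman correlation with the donor's other
    samples reaches ``threshold``; ``None`` disables filtering.

    ``expression`` is one donor's sample x gene matrix.
    """
    if threshold is None:
        return expression.index.copy()
    if not (-1 <= threshold <= 1):
        raise ParameterError(
            f"similarity threshold must be in [-1, 1]; got {threshold}"
        )
    if len(expression) < 3:
        raise ParameterError(
            "similarity filtering requires at least 3 samples per donor"
        )
    ranks = rankdata(expression.to_numpy(float), axis=1)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(ranks)
    np.fill_diagonal(corr, np.nan)
    with np.errstate(invalid="ignore"):
        score = np.nanmean(corr, axis=1)
    keep = ~(score < threshold)  # NaN scores (constant profiles) are kept
    return expression.index[keep]


# ---------------------------------------------------------------------------
# region assignment
# ---------------------------------------------------------------------------

def _compatible_regions(atlas: Atlas, hemisphere: str, structure_class: str):
    meta = atlas.regions
    mask = (meta["hemisphere"] == hemisphere) & (
        meta["structure_class"] == structure_class
    )
    return set(int(i) for i in meta.index[mask])


def assign_volumetric(
    samples: pd.DataFrame, atlas: Atlas, tolerance_mm: float
) -> pd.DataFrame:
    """Assign each sample to a volumetric atlas region within ``tolerance_mm``.

    A sample whose containing voxel is labeled with a compatible region is
    assigned at distance 0; otherwise the nearest compatible labeled voxel
    (Euclidean mm) within tolerance is used, with ties resolved by the most
    frequent label among equidistant voxels and then the lowest region_id.
    Samples with no compatible region within tolerance are left unassigned.
    """
    if atlas.space != "volume":
        raise ConfigurationError("assign_volumetric requires a volume atlas")
    if tolerance_mm < 0:
        raise ParameterError("tolerance must be non-negative")
    labels = atlas.label_array
    ijk_all = np.argwhere(labels > 0)
    vox_labels = labels[tuple(ijk_all.T)]
    vox_mm = voxel_to_world(atlas.affine, ijk_all)

    xyz = samples[COORD_COLUMNS].to_numpy(float)
    nearest_idx = np.rint(world_to_voxel(atlas.affine, xyz)).astype(int)

    region_col = np.full(len(samples), np.nan)
    dist_col = np.full(len(samples), np.nan)
    for row, (wid, sample) in enumerate(samples.iterrows()):
        compatible = _compatible_regions(
            atlas, sample["hemisphere"], sample["structure_class"]
        )
        if not compatible:
            continue
        ijk = nearest_idx[row]
        inside = np.all((ijk >= 0) & (ijk < labels.shape))
        if inside:
            lab = int(labels[tuple(ijk)])
            if lab != 0 and lab in compatible:
                region_col[row], dist_col[row] = lab, 0.0
                continue
        ok = np.isin(vox_labels, sorted(compatible))
        if not ok.any():
            continue
        dists = np.linalg.norm(vox_mm[ok] - xyz[row], axis=1)
        dmin = dists.min()
        if dmin > tolerance_mm + _TIE_EPS:
            continue
        cand = vox_labels[ok][dists <= dmin + _TIE_EPS]
        counts = pd.Series(cand).value_counts().sort_index()
        best = counts.sort_values(ascending=False, kind="stable").index[0]
        region_col[row], dist_col[row] = int(best), float(dmin)

    unassigned = int(np.isnan(region_col).sum())
    if unassigned:
        logger.info("%d sample(s) unassigned at tolerance %.1f mm",
                    unassigned, tolerance_mm)
    out = pd.DataFrame(
        {
            "donor_id": samples["donor_id"].to_numpy(),
            "region_id": pd.array(
                [None if np.isnan(r) else int(r) for r in region_col],
                dtype="Int64",
            ),
            "distance_mm": dist_col,
        },
        index=samples.index,
    )
    return out


def assign_surface(
    samples: pd.DataFrame, atlas: Atlas, tolerance_sd: float
) -> pd.DataFrame:
    """Assign each sample to the nearest labeled surface vertex in its
    hemisphere, excluding samples unusually far from the surface.

    Let d_i be each sample's distance to its nearest labeled vertex; samples
    of a donor with d_i > mean(d) + k * sd(d) (k = ``tolerance_sd``, (n-1)
    sd, statistics per donor) are left unassigned.  k = 0 excludes every
    sample farther than the mean distance.
    """
    if atlas.space != "surface":
        raise ConfigurationError("assign_surface requires a surface atlas")
    if tolerance_sd < 0:
        raise ParameterError("tolerance must be non-negative")
    labeled = {}
    for hemi, data in atlas.vertices.items():
        mask = np.asarray(data["labels"]) > 0
        if not mask.any():
            raise ConfigurationError(f"hemisphere {hemi} has no labeled vertices")
        labeled[hemi] = (
            np.asarray(data["coords"], float)[mask],
            np.asarray(data["labels"], int)[mask],
        )

    xyz = samples[COORD_COLUMNS].to_numpy(float)
    region_col = np.zeros(len(samples), int)
    dist_col = np.full(len(samples), np.nan)
    for row, (wid, sample) in enumerate(samples.iterrows()):
        coords, labs = labeled[sample["hemisphere"]]
        dists = np.linalg.norm(coords - xyz[row], axis=1)
        order = np.argmin(dists)
        dmin = dists[order]
        cand = labs[dists <= dmin + _TIE_EPS]
        region_col[row] = int(np.min(cand))
        dist_col[row] = float(dmin)

    assigned = pd.array(region_col, dtype="Int64")
    out = pd.DataFrame(
        {
            "donor_id": samples["donor_id"].to_numpy(),
            "region_id": assigned,
            "distance_mm": dist_col,
        },
        index=samples.index,
    )
    # exclusion statistics computed per donor across its samples
    for donor, idx in out.groupby("donor_id").groups.items():
        d = out.loc[idx, "distance_mm"].to_numpy(float)
        sd = d.std(ddof=1) if len(d) > 1 else 0.0
        cutoff = d.mean() + tolerance_sd * sd
        far = out.loc[idx].index[d > cutoff + _TIE_EPS]
        out.loc[far, "region_id"] = pd.NA
        if len(far):
            logger.info("donor %s: %d sample(s) beyond %.1f sd of surface "
                        "distance excluded", donor, len(far), tolerance_sd)
    return out


def assign_samples(
    samples: pd.DataFrame, atlas: Atlas, tolerance: float
) -> pd.DataFrame:
    """Dispatch on atlas space (mm tolerance for volumes, sd for surfaces)."""
    if atlas.space == "volume":
        return assign_volumetric(samples, atlas, tolerance)
    return assign_surface(samples, atlas, tolerance)
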