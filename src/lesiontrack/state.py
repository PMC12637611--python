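"""Myeloid organizational state, recruitment index, cluster area, NADH profile.

Intratumoral myeloid cells occupy one of four organizational states —
basally confined, scattered, multifocal, confluent — originally scored by eye.
Here the call is made from quantitative features of the segmented GFP channel:
the fraction of myeloid voxels in a basal band above the basement membrane, the
number of niche-forming components and the volume share of the largest one.

The peri-lesion recruitment index is the mean GFP intensity inside a 250 um
radius disk centred on the (future) lesion, normalized to the tongue-wide mean,
measured on sum projections.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from sklearn.base import BaseEstimator

from .types import MYELOID_STATES, StateFeatures, VoxelVolume

__all__ = [
    "MyeloidStateClassifier",
    "classify_myeloid_state",
    "compute_state_features",
    "basal_band_mask",
    "recruitment_index",
    "cluster_area_fraction",
    "nadh_profile",
]

_STRUCT_2D = np.ones((3, 3), dtype=bool)  # 8-connectivity


class MyeloidStateClassifier(BaseEstimator):
    """Rule cascade mapping state features to one of the four myeloid states.

    Order of evaluation:

    1. ``basal_fraction >= basal_fraction_min`` (default 0.8)
       -> ``basally_confined``;
    2. ``largest_component_fraction >= largest_fraction_min`` (default 0.5)
       and at least one niche-forming component -> ``confluent``;
    3. at least ``multifocal_min_niches`` (default 2) niche-forming components
       -> ``multifocal``;
    4. otherwise -> ``scattered``.

    Deterministic and total over the feature space.
    """

    def __init__(
        self,
        basal_fraction_min: float = 0.8,
        largest_fraction_min: float = 0.5,
        multifocal_min_niches: int = 2,
    ):
        self.basal_fraction_min = basal_fraction_min
        self.largest_fraction_min = largest_fraction_min
        self.multifocal_min_niches = multifocal_min_niches

    def fit(self, X=None, y=None):  # noqa: ARG002 - stateless rule classifier
        self.classes_ = np.asarray(MYELOID_STATES, dtype=object)
        return self

    def _classify_one(self, f: StateFeatures) -> str:
        if f.basal_fraction >= self.basal_fraction_min:
            return "basally_confined"
        if f.largest_component_fraction >= self.largest_fraction_min and f.n_niche_components >= 1:
            return "confluent"
        if f.n_niche_components >= self.multifocal_min_niches:
            return "multifocal"
        return "scattered"

    def predict(self, X) -> np.ndarray:
        """Classify rows of a feature DataFrame (or a list of StateFeatures)."""
        if isinstance(X, pd.DataFrame):
            feats = [
                StateFeatures(
                    displacement=row.displacement,
                    n_niche_components=int(row.n_niche_components),
                    largest_component_fraction=row.largest_component_fraction,
                    basal_fraction=row.basal_fraction,
                )
                for row in X.itertuples()
            ]
        else:
            feats = list(X)
        return np.asarray([self._classify_one(f) for f in feats], dtype=object)


def classify_myeloid_state(features: StateFeatures, **thresholds) -> str:
    """Classify a single lesion's myeloid organization. See MyeloidStateClassifier."""
    return MyeloidStateClassifier(**thresholds).fit().predict([features])[0]


def basal_band_mask(
    shape: tuple[int, int, int],
    voxel_size,
    membrane_depth_um,
    width_um: float = 15.0,
) -> np.ndarray:
    """Boolean mask of the basal band just above the basement membrane.

    The membrane is given as its depth from the tissue surface (scalar for a
    flat membrane or 2D (y, x) height map in micrometres); the band spans
    ``width_um`` (default 15 um, about one cell diameter) on the epithelial
    side, i.e. depths in ``[membrane - width, membrane]``.
    """
    z_um = np.arange(shape[0], dtype=float)[:, None, None] * voxel_size[0]
    depth = np.asarray(membrane_depth_um, dtype=float)
    if depth.ndim == 2:
        depth = depth[None, :, :]
    return (z_um >= depth - width_um) & (z_um <= depth)


def compute_state_features(
    components: pd.DataFrame,
    label_volume: np.ndarray,
    voxel_size,
    lesion_volume_um3: float,
    basal_band: np.ndarray,
) -> StateFeatures:
    """Derive the state-classifier features from a myeloid segmentation.

    ``components`` and ``label_volume`` come from the segmenter restricted to
    one lesion; ``basal_band`` is a boolean mask of the basal band (see
    :func:`basal_band_mask`).
    """
    from .segmentation import myeloid_displacement

    myeloid = label_volume > 0
    n_vox = int(np.count_nonzero(myeloid))
    if n_vox == 0:
        return StateFeatures(0.0, 0, 0.0, 0.0)
    basal_fraction = float(np.count_nonzero(myeloid & basal_band)) / n_vox
    total = float(components["volume_um3"].sum())
    largest = float(components["volume_um3"].max()) / total if total > 0 else 0.0
    n_niche = int((components["niche_class"] == "niche_forming").sum())
    disp = myeloid_displacement(components, lesion_volume_um3)
    return StateFeatures(
        displacement=disp,
        n_niche_components=n_niche,
        largest_component_fraction=largest,
        basal_fraction=basal_fraction,
    )


def recruitment_index(
    projection: np.ndarray,
    center_um: tuple[float, float],
    tongue_mask: np.ndarray,
    pixel_size_um: float,
    radius_um: float = 250.0,
) -> float:
    """Peri-lesion GFP recruitment index on a 2D sum projection.

    Mean intensity inside the disk of ``radius_um`` (default 250 um) centred
    at ``center_um`` (y, x in micrometres), intersected with the tongue mask,
    divided by the mean intensity over the whole tongue mask. Dimensionless
    and invariant under global intensity rescaling.
    """
    projection = np.asarray(projection, dtype=float)
    tongue_mask = np.asarray(tongue_mask, dtype=bool)
    if projection.shape != tongue_mask.shape:
        raise ValueError("projection and tongue_mask shapes differ")
    if not tongue_mask.any():
        raise ValueError("tongue mask is empty")
    yy, xx = np.indices(projection.shape)
    cy, cx = (c / pixel_size_um for c in center_um)
    disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= (radius_um / pixel_size_um) ** 2
    roi = disk & tongue_mask
    if not roi.any():
        raise ValueError("disk does not intersect the tongue mask")
    return float(projection[roi].mean() / projection[tongue_mask].mean())


def cluster_area_fraction(
    projection: np.ndarray,
    threshold: float,
    region_mask: np.ndarray,
    pixel_size_um: float,
    min_area_um2: float = 0.0,
) -> float:
    """Percent of a region covered by suprathreshold myeloid clusters.

    8-connected components of ``projection > threshold`` within the region are
    kept if their area reaches ``min_area_um2``; their summed area is reported
    as percent of the region area. Always in [0, 100].
    """
    projection = np.asarray(projection, dtype=float)
    region_mask = np.asarray(region_mask, dtype=bool)
    if not region_mask.any():
        raise ValueError("region mask is empty")
    px_area = pixel_size_um**2
    mask = (projection > threshold) & region_mask
    labels, n = ndi.label(mask, structure=_STRUCT_2D)
    if n == 0:
        return 0.0
    counts = np.bincount(labels.ravel())[1:]
    kept = counts[counts * px_area >= min_area_um2].sum()
    return 100.0 * float(kept) / float(np.count_nonzero(region_mask))


def nadh_profile(
    nadh_series: list[VoxelVolume],
    lesion_masks: list[np.ndarray],
    reference_masks: list[np.ndarray],
    weeks=None,
    decline_fraction: float = 0.8,
    persistence: int = 2,
) -> tuple[pd.DataFrame, float | None]:
    """Normalized NADH intensity per week and the decline-onset week.

    Per session, mean NADH inside the lesion is divided by the mean in the
    reference mask (adjacent healthy epithelium). The decline onset is the
    first week at which the ratio drops below ``decline_fraction`` (default
    0.8) of its own first-session baseline and stays below for at least
    ``persistence`` consecutive sessions; ``None`` if no such week exists.

    Returns (DataFrame with columns week, ratio; onset week or None).
    """
    if not (len(nadh_series) == len(lesion_masks) == len(reference_masks)):
        raise ValueError("series and mask lists must have equal length")
    if weeks is None:
        weeks = [v.week for v in nadh_series]
    ratios = []
    for vol, lmask, rmask in zip(nadh_series, lesion_masks, reference_masks):
        lmask = np.asarray(lmask, dtype=bool)
        rmask = np.asarray(rmask, dtype=bool)
        if vol.shape != lmask.shape or vol.shape != rmask.shape:
            raise ValueError("mask shape does not match volume")
        if not rmask.any():
            raise ValueError("reference mask is empty")
        if not lmask.any():
            raise ValueError("lesion mask is empty")
        ratios.append(float(vol.values[lmask].mean() / vol.values[rmask].mean()))
    out = pd.DataFrame({"week": np.asarray(weeks, dtype=float), "ratio": ratios})
    baseline = ratios[0]
    below = np.asarray(ratios) < decline_fraction * baseline
    onset = None
    run = 0
    for i in range(len(below) - 1, -1, -1):  # scan right-to-left to find run starts
        run = run + 1 if below[i] else 0
        if run >= persistence:
            onset = float(out["week"].iloc[i])
    return out, onset
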