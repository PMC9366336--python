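"""White-matter-hyperintensity detection and regional mapping.

Candidate lesions are FLAIR-hyperintense outliers under a two-channel
(T1, FLAIR) Gaussian mixture fitted within the brain mask, with the component
count chosen by BIC up to a cap. Connected components are filtered by minimum
size and (optionally) by anatomical location — components sitting essentially
on the cortical surface are treated as artifacts.

Lesion load is then aggregated into the regional scheme used for
small-vessel-disease mapping: the closest cortical lobe crossed with four
equidistant layers of normalized ventricle-to-cortex depth
d = dv / (dv + dc), where dv and dc are Euclidean distances (in mm, so
anisotropic voxels are respected) to the ventricular and cortical surfaces.
Layer k covers d in ((k-1)/4, k/4], with d = 0 assigned to layer 1. The
"parieto-occipital" aggregate is the union of the parietal and occipital
lobe labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.mixture import GaussianMixture

from .grids import VoxelGrid
from .phantoms import LOBE_LABELS

_LABEL_TO_LOBE = {v: k for k, v in LOBE_LABELS.items()}


@dataclass
class LesionDetectionConfig:
    max_components: int = 6        # BIC-capped mixture size
    mahalanobis_threshold: float = 3.0
    min_component_voxels: int = 5
    max_centroid_depth: float = 0.95  # components deeper than this are artifacts
    max_fit_voxels: int = 30000    # subsample cap for the mixture fit
    fit_seed: int = 0              # deterministic subsample + GMM init


@dataclass
class LesionMask:
    """Binary lesion mask plus per-component bookkeeping."""

    mask: VoxelGrid
    labels: np.ndarray                      # int component labels, 0 = none
    components: pd.DataFrame                # label, n_voxels, volume_ml, centroid
    total_volume_ml: float
    n_components_gmm: int


@dataclass
class DepthLayerMap:
    """Normalized ventricle-to-cortex depth and its four-layer quantization."""

    depth: VoxelGrid                        # float d in [0, 1]
    layer: VoxelGrid                        # int 1..4 everywhere
    band: np.ndarray                        # bool: strictly between surfaces


@dataclass
class RegionalLesionLoad:
    """Lesion volumes (mL): total, headline regions, and lobe x layer matrix."""

    total_ml: float
    frontal_ml: float
    parieto_occipital_ml: float
    by_lobe_layer: pd.DataFrame             # index lobe name, columns layer 1..4

    def to_csv_row(self, subject_id: str = "") -> pd.DataFrame:
        row = {"subject_id": subject_id, "les_total_ml": self.total_ml,
               "les_frontal_ml": self.frontal_ml,
               "les_po_ml": self.parieto_occipital_ml}
        for lobe in self.by_lobe_layer.index:
            for layer in self.by_lobe_layer.columns:
                row[f"les_{lobe}_l{layer}_ml"] = self.by_lobe_layer.loc[lobe, layer]
        return pd.DataFrame([row])


def _check_same_grid(*grids: VoxelGrid) -> None:
    ref = grids[0]
    for g in grids[1:]:
        if g.shape != ref.shape or not np.allclose(g.affine, ref.affine, atol=1e-6):
            raise ValueError("inputs must share one voxel grid "
                             "(rigid registration is assumed done upstream)")


def detect_lesions(t1: VoxelGrid, flair: VoxelGrid, brain_mask: VoxelGrid,
                   depth_map: DepthLayerMap | None = None,
                   config: LesionDetectionConfig | None = None) -> LesionMask:
    """Candidate lesions as FLAIR-hyperintense Gaussian-mixture outliers.

    A full-covariance mixture on (T1, FLAIR) pairs within the brain mask is
    selected by BIC over 1..``max_components`` components. Voxels whose
    Mahalanobis distance to every component exceeds the threshold *and* whose
    FLAIR intensity lies above the mean of their closest component become
    candidates; components below the minimum size, or whose centroid lies in
    the cortical surface band (normalized depth > ``max_centroid_depth``, when
    a depth map is supplied), are removed as artifacts.
    """
    cfg = config or LesionDetectionConfig()
    _check_same_grid(t1, flair, brain_mask)
    brain = brain_mask.values.astype(bool)
    if not brain.any():
        raise ValueError("empty brain mask")

    X = np.stack([np.asarray(t1.values, float)[brain],
                  np.asarray(flair.values, float)[brain]], axis=1)
    rng = np.random.default_rng(cfg.fit_seed)
    fit_X = X if len(X) <= cfg.max_fit_voxels else \
        X[rng.choice(len(X), cfg.max_fit_voxels, replace=False)]

    best, best_bic = None, np.inf
    for k in range(1, cfg.max_components + 1):
        gm = GaussianMixture(n_components=k, covariance_type="full",
                             random_state=cfg.fit_seed, n_init=1, reg_covar=1e-4)
        try:
            gm.fit(fit_X)
        except Exception as exc:  # pragma: no cover - fit failure diagnostics
            raise RuntimeError(f"Gaussian-mixture fit failed at k={k}: {exc}")
        bic = gm.bic(fit_X)
        if bic < best_bic:
            best, best_bic = gm, bic
    assert best is not None

    # per-component Mahalanobis distance for every brain voxel
    d2 = np.empty((len(X), best.n_components))
    for c in range(best.n_components):
        diff = X - best.means_[c]
        prec = np.linalg.inv(best.covariances_[c])
        d2[:, c] = np.einsum("ij,jk,ik->i", diff, prec, diff)
    closest = np.argmin(d2, axis=1)
    min_maha = np.sqrt(d2[np.arange(len(X)), closest])
    hyper = X[:, 1] > best.means_[closest, 1]
    cand_flat = (min_maha > cfg.mahalanobis_threshold) & hyper

    cand = np.zeros(brain.shape, dtype=bool)
    cand[brain] = cand_flat
    labels, n_lab = ndimage.label(cand, structure=np.ones((3, 3, 3)))

    keep_mask = np.zeros_like(cand)
    rows = []
    vox_ml = t1.voxel_volume_ml
    next_label = 0
    for lab in range(1, n_lab + 1):
        comp = labels == lab
        n_vox = int(comp.sum())
        if n_vox < cfg.min_component_voxels:
            continue
        centroid_vox = np.array(ndimage.center_of_mass(comp))
        if depth_map is not None:
            ci = tuple(np.round(centroid_vox).astype(int))
            if float(depth_map.depth.values[ci]) > cfg.max_centroid_depth:
                continue
        next_label += 1
        keep_mask[comp] = True
        rows.append({"label": next_label, "n_voxels": n_vox,
                     "volume_ml": n_vox * vox_ml,
                     "centroid_world": tuple(t1.voxel_to_world(centroid_vox))})
    out_labels, _ = ndimage.label(keep_mask, structure=np.ones((3, 3, 3)))
    comp_df = pd.DataFrame(rows, columns=["label", "n_voxels", "volume_ml",
                                          "centroid_world"])
    return LesionMask(
        mask=VoxelGrid(keep_mask.astype(np.uint8), t1.affine),
        labels=out_labels,
        components=comp_df,
        total_volume_ml=float(comp_df["volume_ml"].sum()) if len(comp_df) else 0.0,
        n_components_gmm=best.n_components,
    )


def depth_layers(ventricle_mask: VoxelGrid, cortex_mask: VoxelGrid) -> DepthLayerMap:
    """Normalized depth d = dv/(dv+dc) and its four equidistant layers.

    Distances are Euclidean in mm (anisotropic voxels respected). Layer
    k <=> d in ((k-1)/4, k/4], with d = 0 in layer 1; voxels inside the
    surface masks get the clipped limit (ventricle -> 1, cortex -> 4) so the
    layer volume is defined everywhere, but only the strictly-between band is
    flagged in ``band``.
    """
    _check_same_grid(ventricle_mask, cortex_mask)
    vent = ventricle_mask.values.astype(bool)
    ctx = cortex_mask.values.astype(bool)
    if np.any(vent & ctx):
        raise ValueError("ventricle and cortex masks overlap")
    band = ~vent & ~ctx
    if not band.any():
        raise ValueError("empty band between ventricular and cortical surfaces")

    spacing = ventricle_mask.spacing
    dv = ndimage.distance_transform_edt(~vent, sampling=spacing)
    dc = ndimage.distance_transform_edt(~ctx, sampling=spacing)
    denom = dv + dc
    denom[denom == 0] = np.inf  # cannot happen for disjoint masks, but safe
    d = dv / denom
    layer = np.clip(np.ceil(d * 4.0), 1, 4).astype(np.int8)

    return DepthLayerMap(
        depth=VoxelGrid(d.astype(np.float32), ventricle_mask.affine),
        layer=VoxelGrid(layer, ventricle_mask.affine),
        band=band,
    )


def regional_load(lesions: LesionMask, lobes: VoxelGrid,
                  layers: DepthLayerMap) -> RegionalLesionLoad:
    """Aggregate lesion volume by closest cortical lobe x depth layer.

    Every lesion voxel is assigned the label of its nearest cortical-lobe
    voxel (Euclidean in mm) and its depth layer; volumes are voxel counts
    times voxel volume, so the lobe x layer matrix sums exactly to the total.
    """
    _check_same_grid(lesions.mask, lobes, layers.depth)
    lab_vals = np.unique(np.asarray(lobes.values))
    known = set(LOBE_LABELS.values()) | {0}
    unknown = [int(v) for v in lab_vals if int(v) not in known]
    if unknown:
        raise ValueError(f"unknown lobe labels {unknown}; known labels: "
                         f"{dict(LOBE_LABELS)}")
    if not np.any(np.asarray(lobes.values) > 0):
        raise ValueError("lobe map has no labelled voxels")

    spacing = lobes.spacing
    # nearest labelled voxel for every voxel, metric in mm
    _, nearest = ndimage.distance_transform_edt(
        np.asarray(lobes.values) == 0, sampling=spacing, return_indices=True)
    nearest_label = np.asarray(lobes.values)[tuple(nearest)]

    mask = lesions.mask.values.astype(bool)
    vox_ml = lesions.mask.voxel_volume_ml
    lobe_at = nearest_label[mask]
    layer_at = np.asarray(layers.layer.values)[mask]

    lobe_names = list(LOBE_LABELS)
    mat = pd.DataFrame(0.0, index=lobe_names, columns=[1, 2, 3, 4])
    for lobe_name, lobe_lab in LOBE_LABELS.items():
        for layer in (1, 2, 3, 4):
            n = int(np.sum((lobe_at == lobe_lab) & (layer_at == layer)))
            mat.loc[lobe_name, layer] = n * vox_ml

    total = float(mat.to_numpy().sum())
    return RegionalLesionLoad(
        total_ml=total,
        frontal_ml=float(mat.loc["frontal"].sum()),
        parieto_occipital_ml=float(mat.loc["parietal"].sum()
                                   + mat.loc["occipital"].sum()),
        by_lobe_layer=mat,
    )
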