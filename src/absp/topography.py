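"""Spatial distribution of NM and iron in the SNc: quadrant partition,
probabilistic maps, common space and left-right asymmetry.

The SNc is an elongated crescent; its long axis is estimated as the first
principal component of the voxel world coordinates and an elliptical-section
cylinder is fitted around it (per-slice in-plane covariance gives the
ellipse).  The two in-plane principal axes split the structure into four
quadrants which are then named anatomically:

* Q1 -- ventral SNc
* Q2 -- (mostly) lateral SNc
* Q3 -- medial-rostral SNc
* Q4 -- medial-caudal SNc

Anatomical assignment uses world directions (RAS+): ventral = anterior
(+y) for the brainstem, lateral = away from the midline (|x|), rostral =
superior (+z).  All quantitative measures are computed in subject space;
the common (reference) space is used only for probabilistic maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .image import LabelMask, SpatialTransform, Volume, apply_transform
from . import quantify

__all__ = [
    "QuadrantPartition",
    "ProbabilisticMap",
    "CommonSpace",
    "fit_quadrants",
    "quadrant_profile",
    "probabilistic_map",
    "render_map",
    "asymmetry_table",
    "build_common_space",
]

QUADRANT_NAMES = {1: "ventral", 2: "lateral", 3: "medial-rostral", 4: "medial-caudal"}


@dataclass
class QuadrantPartition:
    """Elliptical-cylinder frame and Q1-Q4 labelling of one SNc side."""

    axis: np.ndarray              # unit vector, world mm (cylinder axis)
    centroid: np.ndarray          # world mm
    in_plane_axes: np.ndarray     # 2 x 3, the ellipse principal directions
    labels: np.ndarray            # int array on the mask grid, 0 = outside
    affine: np.ndarray
    slice_ellipses: pd.DataFrame = field(default_factory=pd.DataFrame)

    def quadrant_mask(self, q: int, template: LabelMask) -> LabelMask:
        return template.with_data(self.labels == q)


def _principal_frame(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and descending-variance orthonormal frame of point cloud."""
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    cov = centered.T @ centered / len(coords)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    frame = evecs[:, order].T  # rows = PC1, PC2, PC3
    if np.min(evals) < 1e-9:
        raise ValueError(
            "mask is rank-deficient (too thin for a principal-axis fit)"
        )
    # deterministic sign: largest-magnitude component positive
    for i in range(3):
        j = np.argmax(np.abs(frame[i]))
        if frame[i, j] < 0:
            frame[i] = -frame[i]
    return centroid, frame


def fit_quadrants(snc_mask: LabelMask) -> QuadrantPartition:
    """Fit the elliptical-section cylinder and label quadrants Q1-Q4.

    One side at a time; the partition is exact (disjoint quadrants whose
    union is the mask).  Raises for empty or degenerate (plane/line) masks.
    """
    if snc_mask.n_voxels == 0:
        raise ValueError("cannot fit quadrants on an empty mask")
    idx = np.argwhere(snc_mask.data)
    A = snc_mask.affine
    coords = idx @ A[:3, :3].T + A[:3, 3]
    centroid, frame = _principal_frame(coords)
    axis, p2, p3 = frame

    centered = coords - centroid
    c2 = centered @ p2
    c3 = centered @ p3
    combo = (c2 >= 0).astype(int) * 2 + (c3 >= 0).astype(int)  # 0..3

    # anatomical naming from the world direction each sign-combo points to;
    # the in-plane frame is stable under small mask changes, so this
    # assignment is too (combo centroids are not: near-ties flip them)
    directions = {
        c: ((1.0 if c >= 2 else -1.0) * p2 + (1.0 if c % 2 else -1.0) * p3)
        / np.sqrt(2.0)
        for c in range(4)
    }
    lateral_sign = 1.0 if centroid[0] >= 0 else -1.0  # +x is the right side
    remaining = list(range(4))
    assign: dict[int, int] = {}
    # Q1 ventral: points most anterior (+y)
    q1 = max(remaining, key=lambda c: directions[c][1])
    assign[q1] = 1
    remaining.remove(q1)
    # Q2 lateral: points furthest away from the midline
    q2 = max(remaining, key=lambda c: lateral_sign * directions[c][0])
    assign[q2] = 2
    remaining.remove(q2)
    # Q3 medial-rostral (superior), Q4 medial-caudal
    remaining.sort(key=lambda c: directions[c][2], reverse=True)
    for name, c in zip((3, 4), remaining):
        assign[c] = name

    labels = np.zeros(snc_mask.shape, dtype=np.int8)
    labels[tuple(idx.T)] = [assign.get(c, 0) for c in combo]

    # per-slice elliptical cross-section (half-axis lengths from in-plane SD)
    t = centered @ axis
    n_slices = max(int(np.ceil(np.ptp(t) / max(snc_mask.spacing.min(), 1e-6))), 1)
    edges = np.linspace(t.min() - 1e-9, t.max() + 1e-9, n_slices + 1)
    rows = []
    for s in range(n_slices):
        sel = (t >= edges[s]) & (t < edges[s + 1])
        if sel.sum() < 3:
            continue
        rows.append(
            {
                "slice": s,
                "t_mm": float((edges[s] + edges[s + 1]) / 2),
                "a_mm": float(2.0 * c2[sel].std()),
                "b_mm": float(2.0 * c3[sel].std()),
                "n_voxels": int(sel.sum()),
            }
        )
    return QuadrantPartition(
        axis=axis,
        centroid=centroid,
        in_plane_axes=np.stack([p2, p3]),
        labels=labels,
        affine=A.copy(),
        slice_ellipses=pd.DataFrame(rows),
    )


def quadrant_profile(
    volumes: dict[str, Volume],
    snc_masks: dict[str, LabelMask],
    partitions: dict[str, QuadrantPartition],
    brainstems: dict[str, LabelMask],
    gm_volume: float,
    subject_id: str = "subject",
    group: str = "",
    k: float = quantify.DEFAULT_THRESHOLD_K,
) -> pd.DataFrame:
    """Per-quadrant and per-axial-slice CR and nVol of the SNc.

    ``snc_masks``/``partitions`` are keyed by side; ``volumes`` holds the NM
    volume and the iron volume resampled onto the same (NM) grid.  Empty
    quadrants after thresholding yield flagged NaN CR rows; quadrant nVols
    are additive (they sum to the whole-SNc nVol at the same threshold).
    """
    rows = []
    for side, snc in snc_masks.items():
        part = partitions[side]
        for sequence, volume in volumes.items():
            polarity = "hyper" if sequence == "NM" else "hypo"
            bs = brainstems[sequence]
            thr_all, thr = quantify.threshold_structure(
                volume, snc, bs, polarity, k=k, reference_exclude=[snc]
            )
            for q in (1, 2, 3, 4):
                qmask = snc.with_data((part.labels == q) & thr_all.data)
                cr = quantify.contrast_ratio(
                    volume, qmask, bs, sequence, reference_exclude=[snc]
                )
                rows.append(
                    {
                        "subject_id": subject_id,
                        "group": group,
                        "side": side,
                        "sequence": sequence,
                        "quadrant": f"Q{q}",
                        "slice": "all",
                        "cr": cr,
                        "nvol": quantify.normalized_volume(qmask, gm_volume),
                        "n_voxels": qmask.n_voxels,
                        "flags": "" if qmask.n_voxels else "empty_quadrant",
                    }
                )
            # axial (k-index) slices of the subject grid
            ks = np.unique(np.argwhere(snc.data)[:, 2])
            for kz in ks:
                sl = np.zeros(snc.shape, dtype=bool)
                sl[:, :, kz] = True
                smask = snc.with_data(thr_all.data & sl)
                cr = quantify.contrast_ratio(
                    volume, smask, bs, sequence, reference_exclude=[snc]
                )
                rows.append(
                    {
                        "subject_id": subject_id,
                        "group": group,
                        "side": side,
                        "sequence": sequence,
                        "quadrant": "all",
                        "slice": int(kz),
                        "cr": cr,
                        "nvol": quantify.normalized_volume(smask, gm_volume),
                        "n_voxels": smask.n_voxels,
                        "flags": "" if smask.n_voxels else "empty_slice",
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Probabilistic maps and common space
# ---------------------------------------------------------------------------


@dataclass
class ProbabilisticMap:
    """Voxelwise fraction of subjects whose mask covers each voxel."""

    data: np.ndarray
    affine: np.ndarray
    structure: str
    sequence: str
    group: str
    n_subjects: int

    def as_volume(self) -> Volume:
        return Volume(self.data.astype(np.float32), self.affine)


def probabilistic_map(
    masks: list[LabelMask],
    group: str = "",
    sequence: str = "none",
) -> ProbabilisticMap:
    """Average the binary masks (already in a common space) voxelwise."""
    if not masks:
        raise ValueError("need at least one mask")
    first = masks[0]
    for m in masks[1:]:
        if not m.same_grid(first):
            raise ValueError("probabilistic_map requires masks on one grid")
    stack = np.mean([m.data.astype(np.float32) for m in masks], axis=0)
    return ProbabilisticMap(
        data=stack,
        affine=first.affine.copy(),
        structure=first.structure,
        sequence=sequence,
        group=group,
        n_subjects=len(masks),
    )


def render_map(pmap: ProbabilisticMap, upsample: int = 4) -> Volume:
    """In-plane bicubic upsampling for display; values clipped to [0, 1].

    Quantitative outputs never pass through this function.
    """
    if upsample < 1:
        raise ValueError("upsample must be >= 1")
    if upsample == 1:
        return pmap.as_volume()
    out = ndimage.zoom(pmap.data, (upsample, upsample, 1), order=3)
    out = np.clip(out, 0.0, 1.0)
    A = pmap.affine.copy()
    A[:3, 0] /= upsample
    A[:3, 1] /= upsample
    # keep voxel-centre alignment of the first voxel
    A[:3, 3] = pmap.affine[:3, 3] - (
        pmap.affine[:3, 0] * (0.5 - 0.5 / upsample)
        + pmap.affine[:3, 1] * (0.5 - 0.5 / upsample)
    )
    return Volume(out, A)


@dataclass
class CommonSpace:
    """Reference grid and per-subject transforms into it.

    The reference is the healthy-control subject whose SNc segmentation
    scored the highest QC Dice (ties broken by lowest subject id).
    Transforms map reference-grid world points to each subject's NM world
    (the resampling convention), so masks are pulled into the reference grid
    with :func:`absp.image.apply_transform`.
    """

    reference_id: str
    reference: Volume
    transforms: dict[str, SpatialTransform]

    def to_reference(self, subject_id: str, obj: LabelMask | Volume):
        return apply_transform(obj, self.transforms[subject_id], self.reference)


def select_reference(qc_scores: dict[str, float]) -> str:
    """Highest-QC subject; deterministic lowest-id tie-break."""
    best = max(qc_scores.values())
    candidates = sorted(s for s, v in qc_scores.items() if v >= best - 1e-12)
    return candidates[0]


def build_common_space(
    nm_volumes: dict[str, Volume],
    qc_scores: dict[str, float],
    stages: tuple[str, ...] = ("rigid", "affine", "deformable"),
) -> CommonSpace:
    """Register every subject's NM volume to the reference NM volume."""
    from .atlas import register_pair  # local import: atlas also stands alone

    ref_id = select_reference(qc_scores)
    ref = nm_volumes[ref_id]
    transforms: dict[str, SpatialTransform] = {}
    for sid, vol in nm_volumes.items():
        if sid == ref_id:
            transforms[sid] = SpatialTransform.identity()
        else:
            transforms[sid] = register_pair(moving=vol, fixed=ref, stages=stages)
    return CommonSpace(reference_id=ref_id, reference=ref, transforms=transforms)


def asymmetry_table(measures: pd.DataFrame) -> pd.DataFrame:
    """Paired left/right values per subject, structure and sequence.

    Input is the tidy measure table from :mod:`absp.quantify`.  Subjects
    missing one side for a structure are dropped from that structure's
    pairs (logged in the ``n_dropped`` attribute of the result).
    """
    sided = measures[measures["side"].isin(["L", "R"])]
    wide = sided.pivot_table(
        index=["subject_id", "group", "structure", "sequence"],
        columns="side",
        values=["cr", "nvol"],
        aggfunc="first",
    )
    wide.columns = [f"{v}_{s}" for v, s in wide.columns]
    wide = wide.reset_index()
    complete = wide.dropna(subset=["nvol_L", "nvol_R"])
    n_dropped = len(wide) - len(complete)
    out = complete.copy()
    out["nvol_lr_ratio"] = out["nvol_L"] / out["nvol_R"].replace(0, np.nan)
    out["nvol_lr_diff"] = out["nvol_L"] - out["nvol_R"]
    out["cr_lr_diff"] = out["cr_L"] - out["cr_R"]
    out.attrs["n_dropped"] = n_dropped
    return out
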