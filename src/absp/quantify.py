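"""Contrast ratio (CR) and gray-matter-normalized volume (nVol) measurement.

The two scalar read-outs of the pipeline are computed per structure, side
and sequence:

* ``CR = (mean intensity in the structure - mean brainstem intensity) /
  mean brainstem intensity`` -- the relative brightness of the structure
  against the brainstem reference.  For the iron-sensitive sequence the CR
  is sign-inverted so that *larger CR always means more pigment/iron*
  (iron-rich tissue is hypointense on SWI).
* ``nVol = structure volume (mm^3) / total gray-matter volume (mm^3)``.

Structure masks are first restricted to signal voxels: hyperintense voxels
for neuromelanin, hypointense voxels for iron, using a ``mean +/- k * SD``
threshold computed over the brainstem reference region.  The brainstem
reference can exclude the labelled nuclei themselves so that bright/dark
structures do not drag their own reference (``reference_exclude``).
Undefined measures (empty thresholded mask, missing structure) propagate as
NaN with an explanatory flag, never as silent zeros.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .image import LabelMask, Volume

__all__ = [
    "StructureMeasure",
    "brainstem_reference_stats",
    "threshold_structure",
    "contrast_ratio",
    "normalized_volume",
    "measure_subject",
    "DEFAULT_THRESHOLD_K",
]

DEFAULT_THRESHOLD_K = 2.0

# the eight headline measures plus the SNc/SNr iron compartments
MEASURE_PLAN = (
    ("NM", "SNc", "hyper"),
    ("NM", "LC", "hyper"),
    ("iron", "SNc", "hypo"),
    ("iron", "SNr", "hypo"),
    ("iron", "SN", "hypo"),
    ("iron", "RN", "hypo"),
)


@dataclass
class StructureMeasure:
    subject_id: str
    group: str
    structure: str
    side: str
    sequence: str
    cr: float
    nvol: float
    n_voxels: int
    threshold: float
    flags: str = ""

    def as_row(self) -> dict:
        return self.__dict__.copy()


def brainstem_reference_stats(
    volume: Volume,
    brainstem: LabelMask,
    reference_exclude: list[LabelMask] | None = None,
) -> tuple[float, float]:
    """Mean and SD of the brainstem reference region.

    ``reference_exclude`` masks (typically the labelled nuclei) are removed
    from the reference so the normalizing mean reflects unlabelled brainstem
    tissue.
    """
    if not brainstem.same_grid(volume):
        raise ValueError("brainstem mask and volume must share one grid")
    ref = brainstem.data.copy()
    for m in reference_exclude or ():
        if not m.same_grid(volume):
            raise ValueError("reference_exclude masks must live on the volume grid")
        ref &= ~m.data
    if not ref.any():
        raise ValueError("brainstem reference region is empty")
    vals = volume.data[ref]
    return float(vals.mean()), float(vals.std())


def threshold_structure(
    volume: Volume,
    mask: LabelMask,
    brainstem: LabelMask,
    polarity: str,
    k: float = DEFAULT_THRESHOLD_K,
    reference_exclude: list[LabelMask] | None = None,
) -> tuple[LabelMask, float]:
    """Restrict ``mask`` to signal voxels.

    ``polarity='hyper'`` keeps voxels strictly brighter than
    ``mu_bs + k * sd_bs`` (neuromelanin); ``'hypo'`` keeps voxels strictly
    darker than ``mu_bs - k * sd_bs`` (iron).  Returns the thresholded mask
    and the threshold used.
    """
    if polarity not in ("hyper", "hypo"):
        raise ValueError("polarity must be 'hyper' or 'hypo'")
    mu, sd = brainstem_reference_stats(volume, brainstem, reference_exclude)
    if polarity == "hyper":
        thr = mu + k * sd
        keep = mask.data & (volume.data > thr)
    else:
        thr = mu - k * sd
        keep = mask.data & (volume.data < thr)
    return mask.with_data(keep), float(thr)


def contrast_ratio(
    volume: Volume,
    thresholded_mask: LabelMask,
    brainstem: LabelMask,
    sequence: str,
    reference_exclude: list[LabelMask] | None = None,
) -> float:
    """CR of the (already thresholded) mask; NaN when the mask is empty.

    Iron CRs are sign-inverted: SWI-hypointense iron gives a negative raw
    contrast, reported positive so that more iron reads as a larger CR.
    """
    if thresholded_mask.n_voxels == 0:
        return float("nan")
    mu_bs, _ = brainstem_reference_stats(volume, brainstem, reference_exclude)
    mu_st = float(volume.data[thresholded_mask.data].mean())
    cr = (mu_st - mu_bs) / mu_bs
    return -cr if sequence == "iron" else cr


def normalized_volume(thresholded_mask: LabelMask, gm_volume: float) -> float:
    """Structure volume normalized by total gray-matter volume (mm^3/mm^3)."""
    if gm_volume <= 0:
        raise ValueError("gm_volume must be positive")
    return thresholded_mask.volume_mm3 / gm_volume


def _measure_one(
    volume: Volume,
    mask: LabelMask,
    brainstem: LabelMask,
    sequence: str,
    polarity: str,
    gm_volume: float,
    k: float,
    reference_exclude: list[LabelMask] | None,
    subject_id: str,
    group: str,
) -> StructureMeasure:
    thr_mask, thr = threshold_structure(
        volume, mask, brainstem, polarity, k=k, reference_exclude=reference_exclude
    )
    flags = []
    if mask.n_voxels == 0:
        flags.append("empty_structure")
    elif thr_mask.n_voxels == 0:
        flags.append("empty_after_threshold")
    cr = contrast_ratio(volume, thr_mask, brainstem, sequence, reference_exclude)
    if sequence == "NM" and np.isfinite(cr) and cr < 0:
        flags.append("negative_nm_cr")
    return StructureMeasure(
        subject_id=subject_id,
        group=group,
        structure=mask.structure,
        side=mask.side,
        sequence=sequence,
        cr=cr,
        nvol=normalized_volume(thr_mask, gm_volume),
        n_voxels=thr_mask.n_voxels,
        threshold=thr,
        flags=";".join(flags),
    )


def measure_subject(
    volumes: dict[str, Volume],
    masks: dict[tuple[str, str, str], LabelMask],
    brainstems: dict[str, LabelMask],
    gm_volume: float,
    subject_id: str = "subject",
    group: str = "",
    k: float = DEFAULT_THRESHOLD_K,
    exclude_structures_from_reference: bool = True,
) -> pd.DataFrame:
    """Measure CR and nVol for every available structure, side and sequence.

    Parameters
    ----------
    volumes : ``{"NM": Volume, "iron": Volume}`` (iron optional).
    masks : ``{(sequence, structure, side): LabelMask}`` -- per-side masks;
        bilateral ("both") rows are derived as the voxel-pooled union of the
        side masks, so nVol is additive over sides by construction.
    brainstems : ``{sequence: brainstem LabelMask}`` on each grid.
    gm_volume : total gray-matter volume in mm^3.

    Missing or degenerate structures yield flagged NaN rows; the other
    measures are unaffected.
    """
    rows: list[dict] = []
    for sequence, structure, polarity in MEASURE_PLAN:
        if sequence not in volumes:
            continue
        volume = volumes[sequence]
        brainstem = brainstems[sequence]
        if exclude_structures_from_reference:
            excl = [
                m
                for (seq, st, _sd), m in masks.items()
                if seq == sequence and st != "brainstem" and m.same_grid(volume)
            ]
        else:
            excl = None
        side_masks = {
            sd: m
            for (seq, st, sd), m in masks.items()
            if seq == sequence and st == structure
        }
        if not side_masks:
            continue
        if "L" in side_masks and "R" in side_masks and "both" not in side_masks:
            both = side_masks["L"].with_data(
                side_masks["L"].data | side_masks["R"].data
            )
            side_masks["both"] = LabelMask(
                both.data, both.affine, structure=structure, side="both"
            )
        for side, mask in sorted(side_masks.items()):
            rows.append(
                _measure_one(
                    volume,
                    mask,
                    brainstem,
                    sequence,
                    polarity,
                    gm_volume,
                    k,
                    excl,
                    subject_id,
                    group,
                ).as_row()
            )
    return pd.DataFrame(rows)
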