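"""Intra-subject rigid alignment of the iron volume to the NM volume, and
partition of the SN iron deposit into SNc and SNr compartments.

The NM and iron acquisitions of one subject differ by head motion between
sequences: a rigid transform suffices.  Because the two contrasts differ,
the rigid registration uses Mattes mutual information.  Alignment quality
is scored as the Dice between the NM brainstem mask and the iron brainstem
mask brought onto the NM grid; low scores are flagged, not fatal.

With the sequences aligned, the SNc mask drawn on the NM image can be
applied to the iron image: the SN iron deposit splits exactly into an SNc
compartment (SN intersect SNc) and the SNr remainder.  The partition is
computed on the NM grid, where the SNc was segmented and which is finer
along the slice axis.
"""

from __future__ import annotations

from dataclasses import dataclass

from .image import LabelMask, SpatialTransform, Volume, apply_transform, dice_coefficient
from .atlas import register_pair

__all__ = ["SubjectAlignment", "align_sequences", "partition_sn"]

DEFAULT_ALIGN_QC_DICE = 0.85


@dataclass
class SubjectAlignment:
    """Rigid mapping between a subject's sequences plus its QC score.

    ``nm_to_iron`` maps NM-grid world points to iron world points -- the
    transform used to resample the iron volume (or its masks) onto the NM
    grid.  ``qc_dice`` is the brainstem overlap after alignment (NaN when
    no brainstem masks were supplied).
    """

    nm_to_iron: SpatialTransform
    iron_on_nm: Volume
    qc_dice: float
    flagged: bool


def align_sequences(
    nm: Volume,
    iron: Volume,
    nm_brainstem: LabelMask | None = None,
    iron_brainstem: LabelMask | None = None,
    iterations: int = 80,
    qc_threshold: float = DEFAULT_ALIGN_QC_DICE,
) -> SubjectAlignment:
    """Estimate the rigid NM-iron transform and resample iron to the NM grid."""
    t = register_pair(
        moving=iron, fixed=nm, stages=("rigid",), metric="mi",
        iterations=iterations,
    )
    iron_on_nm = apply_transform(iron, t, nm)
    qc = float("nan")
    flagged = not t.converged
    if nm_brainstem is not None and iron_brainstem is not None:
        moved = apply_transform(iron_brainstem, t, nm)
        qc = dice_coefficient(nm_brainstem, moved)
        flagged = flagged or qc < qc_threshold
    return SubjectAlignment(nm_to_iron=t, iron_on_nm=iron_on_nm, qc_dice=qc, flagged=flagged)


def partition_sn(
    sn_iron_mask: LabelMask,
    snc_mask_from_nm: LabelMask,
    alignment: SubjectAlignment | None = None,
    target_grid: Volume | LabelMask | None = None,
) -> tuple[LabelMask, LabelMask]:
    """Split the SN iron deposit into SNc-iron and SNr on the NM grid.

    ``sn_iron_mask`` lives on the iron grid; ``snc_mask_from_nm`` on the NM
    grid.  The SN mask is brought onto the NM grid through the subject
    alignment (skip when the masks already share a grid).  Returns
    ``(snc_iron, snr)`` -- an exact partition: disjoint, union equal to the
    (resampled) SN.  An SNc disjoint from the SN leaves the SNc compartment
    empty (degenerate alignment; callers should treat it as a QC failure).
    """
    if sn_iron_mask.same_grid(snc_mask_from_nm):
        sn_on_nm = sn_iron_mask
    else:
        if alignment is None or target_grid is None:
            raise ValueError(
                "masks on different grids: need the subject alignment and target grid"
            )
        sn_on_nm = apply_transform(
            sn_iron_mask, alignment.nm_to_iron, target_grid, interpolation="nearest"
        )
    if sn_on_nm.n_voxels == 0:
        raise ValueError("SN mask is empty on the target grid")
    snc_iron = LabelMask(
        sn_on_nm.data & snc_mask_from_nm.data,
        sn_on_nm.affine,
        structure="SNc",
        side=sn_iron_mask.side,
    )
    snr = LabelMask(
        sn_on_nm.data & ~snc_mask_from_nm.data,
        sn_on_nm.affine,
        structure="SNr",
        side=sn_iron_mask.side,
    )
    return snc_iron, snr
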