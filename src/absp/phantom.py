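"""Synthetic brainstem phantom cohorts with exact NM/iron ground truth.

The generator emulates the imaging substrate of the pipeline: paired
NM-sensitive (0.6 x 0.6 x 1.0 mm) and iron-sensitive (0.7 x 0.7 x 2.0 mm)
volumes of a brainstem carrying bilateral hyperintense SNc and LC on the NM
sequence and hypointense SN iron deposit and RN on the iron sequence.
Geometry is parametric-analytic (ellipsoids, a crescent SNc, cylindrical
LC): only the relative topology (SNc inside SN, RN disjoint from SN, all
inside the brainstem) matters for exercising the pipeline, not anatomical
realism.

Ground truth is exact by construction:

* group effects on volume are implemented as depth-ordered *erosion* of the
  template mask (optionally concentrated in specific SNc quadrants), so the
  true nVol is the eroded voxel count times the voxel volume over the
  subject's gray-matter volume;
* group effects on contrast are a uniform intensity offset inside the
  (eroded) mask, so the true CR is the prescribed per-subject contrast;
* per-subject anatomy is individualized with a smooth divergence-free
  (volume-preserving to first order) sinusoidal deformation field;
* the NM and iron grids are related by a known small rigid transform,
  recorded with the subject;
* noise is additive Gaussian (the field reports no noise model for these
  sequences).

Every random draw flows from a single seed through
``numpy.random.SeedSequence``, so identical (seed, spec) produce
byte-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .image import LabelMask, SpatialTransform, Volume, write_mask, write_volume
from .topography import fit_quadrants

__all__ = [
    "GroupSignature",
    "PhantomSpec",
    "SubjectPhantom",
    "PhantomTemplate",
    "DegenerateGeometryError",
    "default_signatures",
    "build_template_geometry",
    "synthesize_subject",
    "generate_cohort",
]


class DegenerateGeometryError(ValueError):
    """Requested geometry cannot be represented (empty or sub-resolution)."""


# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------


@dataclass
class GroupSignature:
    """Prescribed contrast/volume behavior of one diagnostic group.

    Contrast ratios are dimensionless uplifts (NM) or depressions (iron)
    relative to the brainstem baseline; volume scales are the fraction of
    the template structure volume that survives erosion; ``asymmetry`` is
    the left/right volume ratio (>= 1, left larger, as consistently seen in
    vivo); ``quadrant_loss_weights`` distribute the SNc NM volume loss over
    quadrants Q1-Q4 (ventral, lateral, medial-rostral, medial-caudal).
    """

    group: str
    snc_nm_cr: float = 0.22
    snc_nm_vol_scale: float = 0.88
    lc_nm_cr: float = 0.20
    lc_nm_vol_scale: float = 0.90
    snc_iron_cr: float = 0.10
    snc_iron_vol_scale: float = 0.75
    rn_iron_cr: float = 0.15
    quadrant_loss_weights: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    asymmetry: float = 1.10

    def __post_init__(self) -> None:
        for name in ("snc_nm_vol_scale", "lc_nm_vol_scale", "snc_iron_vol_scale"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.asymmetry < 1:
            raise ValueError("asymmetry is the L/R ratio and must be >= 1")
        w = np.asarray(self.quadrant_loss_weights, dtype=float)
        if w.shape != (4,) or (w < 0).any() or (w > 1).any():
            raise ValueError("quadrant_loss_weights must be four values in [0, 1]")


def default_signatures() -> dict[str, GroupSignature]:
    """Cohort conditions patterned on the reported group behavior.

    Relative to HC: both PD groups lose SNc NM contrast and volume (about
    25% nVol loss in iPD, 21% in LRRK2), with the loss concentrated in the
    ventral/lateral quadrants (Q1, Q2); iPD additionally loses LC NM while
    LRRK2 preserves the LC; both PD groups carry more SN iron (higher CR
    and nVol), LRRK2 slightly more; RN iron CR is elevated in LRRK2 only;
    RN volume does not differ.  Left/right volume asymmetry 1.10 in all
    groups.
    """
    pd_quadrants = (0.35, 0.35, 0.15, 0.15)
    return {
        "HC": GroupSignature(group="HC"),
        "iPD": GroupSignature(
            group="iPD",
            snc_nm_cr=0.165,
            snc_nm_vol_scale=0.66,
            lc_nm_cr=0.145,
            lc_nm_vol_scale=0.63,
            snc_iron_cr=0.145,
            snc_iron_vol_scale=0.90,
            rn_iron_cr=0.15,
            quadrant_loss_weights=pd_quadrants,
        ),
        "LRRK2": GroupSignature(
            group="LRRK2",
            snc_nm_cr=0.17,
            snc_nm_vol_scale=0.695,
            lc_nm_cr=0.20,
            lc_nm_vol_scale=0.90,
            snc_iron_cr=0.15,
            snc_iron_vol_scale=0.95,
            rn_iron_cr=0.185,
            quadrant_loss_weights=pd_quadrants,
        ),
    }


@dataclass
class PhantomSpec:
    """Cohort-level generation parameters.

    ``noise_sd`` is in intensity units against a brainstem baseline of
    ``baseline`` (default 100); ``deform_amplitude`` is the RMS voxel
    displacement of the per-subject anatomy deformation in mm;
    ``snc_effect_d`` is the prescribed standardized HC-vs-PD difference of
    the true SNc NM nVol (the planning effect size), realised by drawing
    each subject's SNc volume scale from a Beta law whose spread is solved
    from the target d; GM volume is log-normal.
    """

    n_per_group: int = 4
    nm_spacing: tuple[float, float, float] = (0.6, 0.6, 1.0)
    iron_spacing: tuple[float, float, float] = (0.7, 0.7, 2.0)
    noise_sd: float = 2.0
    deform_amplitude: float = 0.5
    rng_seed: int = 0
    gm_volume_mean: float = 620_000.0
    gm_volume_sd: float = 45_000.0
    baseline: float = 100.0
    background: float = 60.0
    snc_effect_d: float = 1.20
    cr_sd: float = 0.02
    scale_sd: float = 0.06
    inter_seq_rotation_deg: float = 2.0
    inter_seq_translation_mm: float = 1.5

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if min(self.nm_spacing) <= 0 or min(self.iron_spacing) <= 0:
            raise ValueError("voxel spacings must be positive")


# ---------------------------------------------------------------------------
# Analytic template geometry (world mm, RAS+)
# ---------------------------------------------------------------------------

_BRAINSTEM_SEMI = np.array([13.0, 14.0, 22.0])
_SNC_CENTER = np.array([6.0, 3.0, 10.0])       # mirrored in x for the left side
_SNC_SEMI = np.array([4.5, 3.2, 4.5])
_SNC_BITE_OFFSET = np.array([0.0, 2.5, 0.0])   # removed lobe -> crescent
_SNC_BITE_SEMI = np.array([4.5, 3.2, 6.0])
_SN_SEMI = np.array([5.0, 4.0, 5.0])
_RN_CENTER = np.array([3.6, -4.5, 10.0])
_RN_RADIUS = 3.0
_LC_CENTER_XY = np.array([3.2, -2.0])
_LC_RADIUS = 1.4
_LC_Z = (-10.0, -3.0)

_FOV_HALF = np.array([16.2, 16.2, 26.0])


def _ellipsoid(x: np.ndarray, center: np.ndarray, semi: np.ndarray) -> np.ndarray:
    return (((x - center) / semi) ** 2).sum(axis=-1) <= 1.0


@dataclass
class PhantomTemplate:
    """Voxelized template masks plus the analytic geometry used to build them."""

    spec: PhantomSpec
    asymmetry: float
    nm_grid: Volume
    iron_grid: Volume
    nm_masks: dict[tuple[str, str], LabelMask]    # (structure, side) on NM grid
    iron_masks: dict[tuple[str, str], LabelMask]  # (structure, side) on iron grid


def _side_params(side: str, asymmetry: float) -> tuple[float, float]:
    """Mirror sign and isotropic size scale for one side.

    The left structures are inflated by ``asymmetry ** (1/3)`` per axis so
    the L/R volume ratio equals ``asymmetry``.
    """
    sign = -1.0 if side == "L" else 1.0  # RAS: +x is the subject's right
    scale = asymmetry ** (1.0 / 3.0) if side == "L" else 1.0
    return sign, scale


def _structure_masks(points: np.ndarray, asymmetry: float) -> dict[tuple[str, str], np.ndarray]:
    """Evaluate all implicit structures at world ``points`` (..., 3)."""
    bs = _ellipsoid(points, np.zeros(3), _BRAINSTEM_SEMI)
    out: dict[tuple[str, str], np.ndarray] = {("brainstem", "both"): bs}
    for side in ("L", "R"):
        sign, s = _side_params(side, asymmetry)
        mirror = np.array([sign, 1.0, 1.0])
        c_snc = _SNC_CENTER * mirror
        # the whole crescent scales isotropically about its own centre, so
        # the left/right voxel-count ratio equals the asymmetry parameter
        snc = _ellipsoid(points, c_snc, _SNC_SEMI * s) & ~_ellipsoid(
            points, c_snc + _SNC_BITE_OFFSET * s * mirror, _SNC_BITE_SEMI * s
        )
        sn = _ellipsoid(points, c_snc, _SN_SEMI * s)
        rn = _ellipsoid(points, _RN_CENTER * mirror, np.full(3, _RN_RADIUS * s)) & ~sn
        xy = points[..., :2] - _LC_CENTER_XY * mirror[:2]
        lc_mid = 0.5 * (_LC_Z[0] + _LC_Z[1])
        lc_half = 0.5 * (_LC_Z[1] - _LC_Z[0]) * s
        lc = ((xy**2).sum(axis=-1) <= (_LC_RADIUS * s) ** 2) & (
            np.abs(points[..., 2] - lc_mid) <= lc_half
        )
        out[("SNc", side)] = snc & bs
        out[("SN", side)] = sn & bs
        out[("RN", side)] = rn & bs
        out[("LC", side)] = lc & bs
    return out


def _make_grid(spacing: tuple[float, float, float], sequence: str) -> Volume:
    spacing_arr = np.asarray(spacing, dtype=float)
    shape = np.ceil(2 * _FOV_HALF / spacing_arr).astype(int) + 1
    affine = np.diag([*spacing_arr, 1.0])
    affine[:3, 3] = -(shape - 1) * spacing_arr / 2.0
    return Volume(np.zeros(shape, np.float32), affine, sequence=sequence)


def build_template_geometry(
    spec: PhantomSpec, asymmetry: float = 1.10
) -> PhantomTemplate:
    """Voxelize the template structures on the NM and iron grids.

    Guarantees SNc inside SN inside brainstem, LC and RN inside brainstem,
    RN disjoint from SN.  Raises :class:`DegenerateGeometryError` when the
    in-plane spacing is too coarse to represent the LC with at least three
    voxels across.
    """
    if max(spec.nm_spacing[:2]) > 2.0 * _LC_RADIUS / 3.0:
        raise DegenerateGeometryError(
            "NM in-plane spacing too coarse: LC would span fewer than 3 voxels"
        )
    nm_grid = _make_grid(spec.nm_spacing, "NM")
    iron_grid = _make_grid(spec.iron_spacing, "iron")

    def voxelize(grid: Volume, wanted: dict[str, str]) -> dict[tuple[str, str], LabelMask]:
        pts = grid.world_coordinates()
        values = _structure_masks(pts, asymmetry)
        masks = {}
        for (structure, side), arr in values.items():
            if structure in wanted:
                masks[(structure, side)] = LabelMask(
                    arr, grid.affine, structure=structure, side=side
                )
        return masks

    nm_masks = voxelize(nm_grid, {"brainstem", "SNc", "LC"})
    iron_masks = voxelize(iron_grid, {"brainstem", "SN", "RN", "SNc"})
    return PhantomTemplate(
        spec=spec,
        asymmetry=asymmetry,
        nm_grid=nm_grid,
        iron_grid=iron_grid,
        nm_masks=nm_masks,
        iron_masks=iron_masks,
    )


# ---------------------------------------------------------------------------
# Per-subject synthesis
# ---------------------------------------------------------------------------


def _divergence_free_field(
    rng: np.random.Generator, amplitude: float, n_modes: int = 3
):
    """Random smooth displacement field u(x) with div u = 0.

    u is the curl of a sinusoidal vector potential, so subject anatomy is
    individualized while structure volumes are preserved to first order.
    Returns a callable mapping (N, 3) world points to (N, 3) displacements.
    """
    if amplitude <= 0:
        return lambda x: np.zeros_like(x)
    ks, cs, phis = [], [], []
    for _ in range(n_modes):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        wavelength = rng.uniform(22.0, 38.0)
        k = 2 * np.pi / wavelength * direction
        a = rng.normal(size=3)
        c = np.cross(k, a)  # coefficient of the curl term
        ks.append(k)
        cs.append(c)
        phis.append(rng.uniform(0, 2 * np.pi))
    cs_arr = np.array(cs)
    # RMS of sum of independent cosines: sqrt(sum |c|^2 / 2)
    rms = np.sqrt((cs_arr**2).sum() / 2.0)
    cs_arr *= amplitude / max(rms, 1e-12)
    ks_arr = np.array(ks)
    phis_arr = np.array(phis)

    def displacement(x: np.ndarray) -> np.ndarray:
        phase = x @ ks_arr.T + phis_arr  # (N, modes)
        return np.cos(phase) @ cs_arr

    return displacement


def _erode_mask(
    data: np.ndarray,
    spacing: np.ndarray,
    n_remove: int,
    quadrant_labels: np.ndarray | None = None,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Remove ``n_remove`` voxels from a mask, shallowest (surface) first.

    With quadrant labels and weights the removals are apportioned across
    quadrants; shortfalls in small quadrants spill over to the globally
    shallowest remaining voxels.  Fully deterministic (depth, then index
    order).
    """
    total = int(data.sum())
    if n_remove <= 0:
        return data.copy()
    if n_remove >= total:
        raise DegenerateGeometryError(
            f"volume scale would empty the structure ({n_remove} >= {total})"
        )
    depth = ndimage.distance_transform_edt(data, sampling=spacing)
    idx = np.argwhere(data)
    d = depth[tuple(idx.T)]
    order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0], d))
    out = data.copy()
    if quadrant_labels is None:
        kill = idx[order[:n_remove]]
        out[tuple(kill.T)] = False
        return out
    w = np.asarray(weights, dtype=float)
    w = w / w.sum() if w.sum() > 0 else np.full(4, 0.25)
    q = quadrant_labels[tuple(idx.T)]
    targets = np.floor(n_remove * w).astype(int)
    # distribute the rounding remainder to the largest fractional parts
    frac = n_remove * w - targets
    for j in np.argsort(frac)[::-1][: n_remove - targets.sum()]:
        targets[j] += 1
    removed = np.zeros(len(idx), dtype=bool)
    for qi in range(4):
        members = order[q[order] == qi + 1]
        take = min(targets[qi], max(len(members) - 1, 0))
        removed[members[:take]] = True
    shortfall = n_remove - removed.sum()
    if shortfall > 0:
        for j in order:
            if shortfall == 0:
                break
            if not removed[j]:
                removed[j] = True
                shortfall -= 1
    out[tuple(idx[removed].T)] = False
    return out


@dataclass
class SubjectPhantom:
    """One synthetic subject: paired volumes, truth masks and truth measures."""

    subject_id: str
    group: str
    nm_volume: Volume
    iron_volume: Volume
    truth_masks: dict[tuple[str, str, str], LabelMask]  # (sequence, structure, side)
    truth_measures: pd.DataFrame
    gm_volume: float
    nm_to_iron: SpatialTransform  # maps NM world points to iron world points
    params: dict = field(default_factory=dict)


def _beta_draw(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Beta sample on (0, 1] with the requested mean and (capped) sd."""
    mean = min(max(mean, 1e-3), 1.0)
    if mean >= 1.0 or sd <= 0:
        return mean
    max_var = mean * (1 - mean)
    var = min(sd**2, 0.95 * max_var)
    nu = max_var / var - 1.0
    return float(rng.beta(mean * nu, (1 - mean) * nu))


def solve_scale_sd(
    signatures: dict[str, GroupSignature],
    spec: PhantomSpec,
    group_sizes: dict[str, int] | None = None,
) -> float:
    """SD of the per-subject SNc NM volume scale that realises the target
    standardized HC-vs-PD difference (``spec.snc_effect_d``) of true nVol.

    Uses the delta-method variance of ``nVol = s * V0 / G`` with log-normal
    G; the between-PD-subgroup mean gap contributes to the PD arm variance.
    """
    hc = [s for s in signatures.values() if s.group == "HC"]
    pds = [s for s in signatures.values() if s.group != "HC"]
    if not hc or not pds or spec.snc_effect_d <= 0:
        return spec.scale_sd
    sizes = group_sizes or {g: 1 for g in signatures}
    m_h = hc[0].snc_nm_vol_scale
    w = np.array([sizes.get(s.group, 1) for s in pds], dtype=float)
    w /= w.sum()
    pd_means = np.array([s.snc_nm_vol_scale for s in pds])
    m_p = float(w @ pd_means)
    between_pd = float(w @ (pd_means - m_p) ** 2)
    cv_g2 = (spec.gm_volume_sd / spec.gm_volume_mean) ** 2
    target_sigma2 = ((m_h - m_p) / spec.snc_effect_d) ** 2
    mean_s2 = (m_h**2 + m_p**2) / 2.0
    sigma_s2 = target_sigma2 - mean_s2 * cv_g2 - between_pd / 2.0
    return float(np.sqrt(max(sigma_s2, 1e-6)))


def synthesize_subject(
    template: PhantomTemplate,
    signature: GroupSignature,
    spec: PhantomSpec,
    subject_seed: int,
    subject_id: str | None = None,
    snc_scale_sd: float | None = None,
) -> SubjectPhantom:
    """Generate one subject: deformed anatomy, eroded structures, intensities.

    ``subject_seed`` drives every draw (deformation, per-subject contrast
    and volume scales, GM volume, inter-sequence rigid offset, noise); the
    same seed reproduces the subject bit for bit.
    """
    ss = np.random.SeedSequence(subject_seed)
    (rng_geom, rng_draw, rng_noise_nm, rng_noise_iron) = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    subject_id = subject_id or f"sub-{subject_seed:06d}"
    if snc_scale_sd is None:
        snc_scale_sd = spec.scale_sd

    warp = _divergence_free_field(rng_geom, spec.deform_amplitude)

    # inter-sequence rigid offset (NM world -> iron world)
    rot = rng_geom.uniform(
        -spec.inter_seq_rotation_deg, spec.inter_seq_rotation_deg, size=3
    )
    trans = rng_geom.uniform(
        -spec.inter_seq_translation_mm, spec.inter_seq_translation_mm, size=3
    )
    nm_to_iron = SpatialTransform.rigid_from_parameters(tuple(rot), tuple(trans))
    iron_to_nm_matrix = np.linalg.inv(nm_to_iron.matrix)

    # per-subject prescribed effects
    draws = {
        "snc_nm_cr": max(signature.snc_nm_cr + rng_draw.normal(0, spec.cr_sd), 0.01),
        "lc_nm_cr": max(signature.lc_nm_cr + rng_draw.normal(0, spec.cr_sd), 0.01),
        "snc_iron_cr": max(signature.snc_iron_cr + rng_draw.normal(0, spec.cr_sd), 0.01),
        "rn_iron_cr": max(signature.rn_iron_cr + rng_draw.normal(0, spec.cr_sd), 0.01),
        "snc_nm_vol_scale": _beta_draw(rng_draw, signature.snc_nm_vol_scale, snc_scale_sd),
        "lc_nm_vol_scale": _beta_draw(rng_draw, signature.lc_nm_vol_scale, spec.scale_sd),
        "snc_iron_vol_scale": _beta_draw(
            rng_draw, signature.snc_iron_vol_scale, spec.scale_sd
        ),
    }
    mu = np.log(spec.gm_volume_mean**2 / np.sqrt(spec.gm_volume_mean**2 + spec.gm_volume_sd**2))
    sg = np.sqrt(np.log(1 + (spec.gm_volume_sd / spec.gm_volume_mean) ** 2))
    gm_volume = float(np.exp(rng_draw.normal(mu, sg)))

    def voxelize(grid: Volume, to_nm_world: np.ndarray | None):
        pts = grid.world_coordinates().reshape(-1, 3)
        if to_nm_world is not None:
            pts = pts @ to_nm_world[:3, :3].T + to_nm_world[:3, 3]
        pts = pts + warp(pts)
        vals = _structure_masks(pts, signature.asymmetry)
        return {k: v.reshape(grid.shape) for k, v in vals.items()}

    nm_raw = voxelize(template.nm_grid, None)
    iron_raw = voxelize(template.iron_grid, iron_to_nm_matrix)

    nm_spacing = np.asarray(spec.nm_spacing)
    iron_spacing = np.asarray(spec.iron_spacing)

    masks: dict[tuple[str, str, str], LabelMask] = {}
    masks[("NM", "brainstem", "both")] = LabelMask(
        nm_raw[("brainstem", "both")], template.nm_grid.affine, "brainstem", "both"
    )
    masks[("iron", "brainstem", "both")] = LabelMask(
        iron_raw[("brainstem", "both")], template.iron_grid.affine, "brainstem", "both"
    )

    for side in ("L", "R"):
        # SNc on NM: quadrant-weighted erosion
        snc_full = nm_raw[("SNc", side)]
        if not snc_full.any():
            raise DegenerateGeometryError(f"SNc {side} empty after deformation")
        part = fit_quadrants(
            LabelMask(snc_full, template.nm_grid.affine, "SNc", side)
        )
        n_rm = int(round((1 - draws["snc_nm_vol_scale"]) * snc_full.sum()))
        snc = _erode_mask(
            snc_full,
            nm_spacing,
            n_rm,
            quadrant_labels=part.labels,
            weights=np.asarray(signature.quadrant_loss_weights, float),
        )
        masks[("NM", "SNc", side)] = LabelMask(
            snc, template.nm_grid.affine, "SNc", side
        )
        # LC on NM: plain surface erosion
        lc_full = nm_raw[("LC", side)]
        n_rm = int(round((1 - draws["lc_nm_vol_scale"]) * lc_full.sum()))
        lc = _erode_mask(lc_full, nm_spacing, n_rm)
        masks[("NM", "LC", side)] = LabelMask(lc, template.nm_grid.affine, "LC", side)
        # SN iron deposit: plain erosion; RN kept whole
        sn_full = iron_raw[("SN", side)]
        n_rm = int(round((1 - draws["snc_iron_vol_scale"]) * sn_full.sum()))
        sn = _erode_mask(sn_full, iron_spacing, n_rm)
        masks[("iron", "SN", side)] = LabelMask(
            sn, template.iron_grid.affine, "SN", side
        )
        masks[("iron", "RN", side)] = LabelMask(
            iron_raw[("RN", side)], template.iron_grid.affine, "RN", side
        )
        # iron inside the SNc region and the SNr remainder (exact partition)
        snc_on_iron = iron_raw[("SNc", side)]
        masks[("iron", "SNc", side)] = LabelMask(
            sn & snc_on_iron, template.iron_grid.affine, "SNc", side
        )
        masks[("iron", "SNr", side)] = LabelMask(
            sn & ~snc_on_iron, template.iron_grid.affine, "SNr", side
        )

    # intensities: piecewise-constant anatomy + optional Gaussian noise
    nm_img = np.full(template.nm_grid.shape, spec.background, dtype=np.float64)
    nm_img[masks[("NM", "brainstem", "both")].data] = spec.baseline
    for side in ("L", "R"):
        nm_img[masks[("NM", "SNc", side)].data] = spec.baseline * (1 + draws["snc_nm_cr"])
        nm_img[masks[("NM", "LC", side)].data] = spec.baseline * (1 + draws["lc_nm_cr"])
    iron_img = np.full(template.iron_grid.shape, spec.background, dtype=np.float64)
    iron_img[masks[("iron", "brainstem", "both")].data] = spec.baseline
    for side in ("L", "R"):
        iron_img[masks[("iron", "SN", side)].data] = spec.baseline * (
            1 - draws["snc_iron_cr"]
        )
        iron_img[masks[("iron", "RN", side)].data] = spec.baseline * (
            1 - draws["rn_iron_cr"]
        )
    if spec.noise_sd > 0:
        nm_img = nm_img + rng_noise_nm.normal(0, spec.noise_sd, nm_img.shape)
        iron_img = iron_img + rng_noise_iron.normal(0, spec.noise_sd, iron_img.shape)

    nm_volume = Volume(nm_img, template.nm_grid.affine, sequence="NM")
    iron_volume = Volume(iron_img, template.iron_grid.affine, sequence="iron")

    # exact truth table
    cr_of = {
        ("NM", "SNc"): draws["snc_nm_cr"],
        ("NM", "LC"): draws["lc_nm_cr"],
        ("iron", "SN"): draws["snc_iron_cr"],
        ("iron", "SNc"): draws["snc_iron_cr"],
        ("iron", "SNr"): draws["snc_iron_cr"],
        ("iron", "RN"): draws["rn_iron_cr"],
    }
    rows = []
    for (seq, st), cr in cr_of.items():
        vox = nm_spacing.prod() if seq == "NM" else iron_spacing.prod()
        for side in ("L", "R", "both"):
            if side == "both":
                n = masks[(seq, st, "L")].n_voxels + masks[(seq, st, "R")].n_voxels
            else:
                n = masks[(seq, st, side)].n_voxels
            rows.append(
                {
                    "subject_id": subject_id,
                    "group": signature.group,
                    "structure": st,
                    "side": side,
                    "sequence": seq,
                    "cr_true": cr,
                    "nvol_true": n * vox / gm_volume,
                    "n_voxels_true": n,
                    "gm_volume": gm_volume,
                }
            )
    truth = pd.DataFrame(rows)
    return SubjectPhantom(
        subject_id=subject_id,
        group=signature.group,
        nm_volume=nm_volume,
        iron_volume=iron_volume,
        truth_masks=masks,
        truth_measures=truth,
        gm_volume=gm_volume,
        nm_to_iron=nm_to_iron,
        params=draws,
    )


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


def _simulate_covariates(
    rng: np.random.Generator, subject_id: str, group: str
) -> dict:
    """Clinical covariates with simple documented distributions.

    Age ~ N(64, 9) years; sex Bernoulli(0.5); PD disease duration
    ~ 2 + Gamma(shape 2, scale 3.3) years; binary comorbidity rates follow
    the cohort frequencies (RBD 0.6 iPD / 0.25 LRRK2, hyposmia 0.5 / 0.3,
    psychiatric symptoms 0.05 / 0.17, other sleep disorders 0.55 / 0.65);
    UPDRS-III ~ N(21, 8) iPD, N(17, 9) LRRK2.
    """
    is_pd = group != "HC"
    rates = {
        "iPD": dict(rbd=0.60, hyposmia=0.50, psychiatric=0.05, sleep=0.55),
        "LRRK2": dict(rbd=0.25, hyposmia=0.30, psychiatric=0.17, sleep=0.65),
    }.get(group, dict(rbd=0.05, hyposmia=0.05, psychiatric=0.02, sleep=0.3))
    duration = float(2 + rng.gamma(2.0, 3.3)) if is_pd else np.nan
    updrs_mu, updrs_sd = (21, 8) if group == "iPD" else (17, 9)
    return {
        "subject_id": subject_id,
        "group": group,
        "age": float(np.clip(rng.normal(64, 9), 39, 85)),
        "sex": "F" if rng.random() < 0.5 else "M",
        "disease_duration": duration,
        "updrs_iii": float(np.clip(rng.normal(updrs_mu, updrs_sd), 0, 60)) if is_pd else np.nan,
        "rbd": int(rng.random() < rates["rbd"]),
        "hyposmia": int(rng.random() < rates["hyposmia"]),
        "psychiatric": int(rng.random() < rates["psychiatric"]),
        "other_sleep": int(rng.random() < rates["sleep"]),
    }


def sample_truth_nvols(
    spec: PhantomSpec,
    signatures: dict[str, GroupSignature] | None = None,
    n_per_group: int = 20_000,
    structure: str = "SNc",
) -> pd.DataFrame:
    """Monte-Carlo sample of true NM nVol under the generative conditions.

    Draws per-subject volume scales and GM volumes exactly as the full
    synthesizer does and applies the erosion arithmetic to the template
    voxel counts, but skips per-subject voxelization (the deformation
    model is volume-preserving to first order, so the template counts are
    the correct baseline).  This makes large-sample checks of the
    prescribed effect size and subtype volume loss cheap.  Returns one row
    per subject with ``group`` and ``nvol_true``.
    """
    signatures = signatures or default_signatures()
    template = build_template_geometry(
        spec, asymmetry=next(iter(signatures.values())).asymmetry
    )
    key = {"SNc": "SNc", "LC": "LC"}[structure]
    n_template = sum(
        template.nm_masks[(key, side)].n_voxels for side in ("L", "R")
    )
    voxvol = float(np.prod(spec.nm_spacing))
    sizes = {g: n_per_group for g in signatures}
    snc_sd = solve_scale_sd(signatures, spec, sizes)
    rng = np.random.default_rng(np.random.SeedSequence(spec.rng_seed).spawn(1)[0])
    mu = np.log(
        spec.gm_volume_mean**2 / np.sqrt(spec.gm_volume_mean**2 + spec.gm_volume_sd**2)
    )
    sg = np.sqrt(np.log(1 + (spec.gm_volume_sd / spec.gm_volume_mean) ** 2))
    frames = []
    for sig in signatures.values():
        mean = sig.snc_nm_vol_scale if structure == "SNc" else sig.lc_nm_vol_scale
        sd = snc_sd if structure == "SNc" else spec.scale_sd
        max_var = mean * (1 - mean)
        var = min(sd**2, 0.95 * max_var) if mean < 1 else 0.0
        if var > 0:
            nu = max_var / var - 1.0
            s = rng.beta(mean * nu, (1 - mean) * nu, size=n_per_group)
        else:
            s = np.full(n_per_group, mean)
        counts = n_template - np.round((1 - s) * n_template)
        gm = np.exp(rng.normal(mu, sg, size=n_per_group))
        frames.append(
            pd.DataFrame(
                {"group": sig.group, "nvol_true": counts * voxvol / gm}
            )
        )
    return pd.concat(frames, ignore_index=True)


def generate_cohort(
    spec: PhantomSpec,
    signatures: dict[str, GroupSignature] | None = None,
    out_dir: str | Path | None = None,
    truth_only: bool = False,
) -> tuple[list[SubjectPhantom], pd.DataFrame, pd.DataFrame]:
    """Generate ``n_per_group`` subjects per signature.

    Returns ``(subjects, truth_table, covariates)``.  With ``out_dir`` the
    NM/iron NIfTI pairs, truth CSV and covariate CSV are written there.
    ``truth_only`` skips the intensity synthesis (masks and truth tables
    only), for fast Monte-Carlo checks of the generative conditions.
    """
    signatures = signatures or default_signatures()
    if not signatures:
        raise ValueError("need at least one group signature")
    template = build_template_geometry(
        spec, asymmetry=next(iter(signatures.values())).asymmetry
    )
    sizes = {g: spec.n_per_group for g in signatures}
    snc_sd = solve_scale_sd(signatures, spec, sizes)
    root = np.random.SeedSequence(spec.rng_seed)
    subject_seeds = root.generate_state(len(signatures) * spec.n_per_group * 2)
    cov_rng = np.random.default_rng(root.spawn(1)[0])

    subjects: list[SubjectPhantom] = []
    covariates = []
    i = 0
    base_spec = replace(spec, noise_sd=spec.noise_sd if not truth_only else 0.0)
    for gname, sig in signatures.items():
        for j in range(spec.n_per_group):
            sid = f"sub-{gname}-{j:03d}"
            subj = synthesize_subject(
                template,
                sig,
                base_spec,
                int(subject_seeds[i] % (2**31 - 1)),
                subject_id=sid,
                snc_scale_sd=snc_sd,
            )
            subjects.append(subj)
            covariates.append(_simulate_covariates(cov_rng, sid, gname))
            i += 1
    truth = pd.concat([s.truth_measures for s in subjects], ignore_index=True)
    cov = pd.DataFrame(covariates)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for s in subjects:
            write_volume(s.nm_volume, out / f"{s.subject_id}_nm.nii.gz")
            write_volume(s.iron_volume, out / f"{s.subject_id}_iron.nii.gz")
            for (seq, st, side), m in s.truth_masks.items():
                write_mask(m, out / "masks" / f"{s.subject_id}_{seq}_{st}_{side}.nii.gz")
            s.nm_to_iron.save(out / "transforms" / f"{s.subject_id}_nm_to_iron.tfm")
        truth.to_csv(out / "truth.csv", index=False)
        cov.to_csv(out / "covariates.csv", index=False)
    return subjects, truth, cov
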