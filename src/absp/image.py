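"""Volume and mask data model, NIfTI I/O, spatial transforms, resampling, Dice.

Conventions
-----------
* Arrays are indexed ``(i, j, k)`` matching NIfTI data order; the affine maps
  0-based voxel indices to world millimetres in RAS+ (right, anterior,
  superior positive), as nibabel does.
* Anatomical side (L/R) is decided from the sign of the world x coordinate,
  never from the array index.
* :class:`SpatialTransform` maps points of the *fixed/target* world to the
  *moving* world (the resampling convention used by ITK); internally a
  SimpleITK transform in LPS coordinates is stored, and helpers convert from
  and to RAS matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk

__all__ = [
    "Volume",
    "LabelMask",
    "SpatialTransform",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "dice_coefficient",
    "apply_transform",
    "volume_to_sitk",
    "sitk_to_volume",
]

# RAS <-> LPS flip of the first two world axes (homogeneous form below).
_FLIP = np.diag([-1.0, -1.0, 1.0])


class GridMismatchError(ValueError):
    """Two objects expected on one voxel grid live on different grids."""


@dataclass
class Volume:
    """A 3D scalar image with world geometry.

    Parameters
    ----------
    data : 3D float array of intensities.
    affine : 4x4 voxel-to-world (RAS+ mm) matrix.
    sequence : acquisition tag, one of ``"NM"``, ``"iron"``, ``"none"``.
    """

    data: np.ndarray
    affine: np.ndarray
    sequence: str = "none"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"Volume requires 3D data, got {self.data.ndim}D")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        if self.sequence not in ("NM", "iron", "none"):
            raise ValueError(f"unknown sequence tag {self.sequence!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        """Voxel spacing in mm from the affine column norms."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def same_grid(self, other: "Volume | LabelMask", atol: float = 1e-4) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def world_coordinates(self) -> np.ndarray:
        """World (RAS mm) coordinates of every voxel centre, shape (*grid, 3)."""
        idx = np.stack(
            np.meshgrid(*(np.arange(n) for n in self.shape), indexing="ij"), axis=-1
        )
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]


@dataclass
class LabelMask:
    """A binary mask on a :class:`Volume` grid with anatomical identity."""

    data: np.ndarray
    affine: np.ndarray
    structure: str = "brainstem"
    side: str = "both"

    STRUCTURES = ("brainstem", "SNc", "SNr", "SN", "LC", "RN")
    SIDES = ("L", "R", "both")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("LabelMask requires 3D data")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.structure not in self.STRUCTURES:
            raise ValueError(f"unknown structure {self.structure!r}")
        if self.side not in self.SIDES:
            raise ValueError(f"unknown side {self.side!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * self.voxel_volume

    def same_grid(self, other: "Volume | LabelMask", atol: float = 1e-4) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def with_data(self, data: np.ndarray) -> "LabelMask":
        return replace(self, data=data)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------


def read_volume(path: str | Path, sequence: str = "none") -> Volume:
    """Read a 3D NIfTI-1 file.

    Raises an error for 4D (or higher) series; this pipeline operates on
    single 3D acquisitions.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data) if data.ndim > 3 and all(
        s == 1 for s in data.shape[3:]
    ) else data
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a 3D volume, got shape {data.shape}; "
            "4D series are not supported"
        )
    return Volume(data=data.astype(np.float32), affine=img.affine, sequence=sequence)


def write_volume(volume: Volume, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(volume.data.astype(np.float32), volume.affine)
    nib.save(img, str(path))
    return path


def read_mask(path: str | Path, structure: str = "brainstem", side: str = "both") -> LabelMask:
    vol = read_volume(path)
    return LabelMask(data=vol.data > 0.5, affine=vol.affine, structure=structure, side=side)


def write_mask(mask: LabelMask, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine)
    nib.save(img, str(path))
    return path


# ---------------------------------------------------------------------------
# Dice
# ---------------------------------------------------------------------------


def dice_coefficient(a: LabelMask, b: LabelMask) -> float:
    """Dice similarity 2|A∩B| / (|A|+|B|).

    Both masks must live on the same grid.  When both masks are empty the
    coefficient is defined as 1.0: two annotators who both find nothing
    agree perfectly (QC on structures that may vanish on coarse grids must
    not crash or report failure).
    """
    if not a.same_grid(b):
        raise GridMismatchError("dice_coefficient requires masks on one grid")
    na, nb = a.n_voxels, b.n_voxels
    if na == 0 and nb == 0:
        return 1.0
    inter = int(np.logical_and(a.data, b.data).sum())
    return 2.0 * inter / (na + nb)


# ---------------------------------------------------------------------------
# SimpleITK interop
# ---------------------------------------------------------------------------


def volume_to_sitk(obj: Volume | LabelMask) -> sitk.Image:
    """Convert to a SimpleITK image (LPS world), preserving geometry."""
    arr = obj.data.astype(np.float32)
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr.transpose(2, 1, 0)))
    A = obj.affine
    spacing = np.linalg.norm(A[:3, :3], axis=0)
    direction = _FLIP @ (A[:3, :3] / spacing)
    origin = _FLIP @ A[:3, 3]
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetDirection(tuple(direction.flatten()))
    img.SetOrigin(tuple(float(o) for o in origin))
    return img


def sitk_to_volume(img: sitk.Image, sequence: str = "none") -> Volume:
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    spacing = np.array(img.GetSpacing())
    direction = np.array(img.GetDirection()).reshape(3, 3)
    origin = np.array(img.GetOrigin())
    A = np.eye(4)
    A[:3, :3] = _FLIP @ direction * spacing
    A[:3, 3] = _FLIP @ origin
    return Volume(data=arr, affine=A, sequence=sequence)


# ---------------------------------------------------------------------------
# Spatial transforms
# ---------------------------------------------------------------------------


@dataclass
class SpatialTransform:
    """A spatial mapping from target (fixed) world points to moving world points.

    ``kind`` is one of ``rigid``, ``affine``, ``deformable``, ``composite``.
    The wrapped SimpleITK transform operates in LPS coordinates; the
    :attr:`matrix` property exposes linear transforms as a 4x4 RAS matrix.
    """

    kind: str
    sitk_transform: sitk.Transform
    converged: bool = True
    metric_values: list = field(default_factory=list)

    @staticmethod
    def identity() -> "SpatialTransform":
        return SpatialTransform("rigid", sitk.Euler3DTransform())

    @staticmethod
    def from_matrix(matrix_ras: np.ndarray, kind: str = "affine") -> "SpatialTransform":
        """Build a linear transform from a 4x4 RAS world matrix."""
        M = np.asarray(matrix_ras, dtype=float)
        if M.shape != (4, 4):
            raise ValueError("expected a 4x4 matrix")
        R = _FLIP @ M[:3, :3] @ _FLIP
        t = _FLIP @ M[:3, 3]
        if kind == "rigid":
            if not np.allclose(R @ R.T, np.eye(3), atol=1e-6) or np.linalg.det(R) < 0:
                raise ValueError("rigid transform requires a proper rotation matrix")
            tf = sitk.Euler3DTransform()
            tf.SetMatrix(tuple(R.flatten()))
            tf.SetTranslation(tuple(t))
        else:
            tf = sitk.AffineTransform(3)
            tf.SetMatrix(tuple(R.flatten()))
            tf.SetTranslation(tuple(t))
        return SpatialTransform(kind, tf)

    @staticmethod
    def rigid_from_parameters(
        rotation_deg: tuple[float, float, float],
        translation_mm: tuple[float, float, float],
        center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0),
    ) -> "SpatialTransform":
        """Rigid transform from Euler angles (degrees, about RAS axes) and a
        translation (RAS mm), rotating about ``center_mm``."""
        rx, ry, rz = np.deg2rad(rotation_deg)
        Rx = np.array([[1, 0, 0], [0, np.cos(rx), -np.sin(rx)], [0, np.sin(rx), np.cos(rx)]])
        Ry = np.array([[np.cos(ry), 0, np.sin(ry)], [0, 1, 0], [-np.sin(ry), 0, np.cos(ry)]])
        Rz = np.array([[np.cos(rz), -np.sin(rz), 0], [np.sin(rz), np.cos(rz), 0], [0, 0, 1]])
        R = Rz @ Ry @ Rx
        c = np.asarray(center_mm, dtype=float)
        t = np.asarray(translation_mm, dtype=float) + c - R @ c
        M = np.eye(4)
        M[:3, :3] = R
        M[:3, 3] = t
        return SpatialTransform.from_matrix(M, kind="rigid")

    @property
    def matrix(self) -> np.ndarray:
        """4x4 RAS world matrix for linear transforms."""
        tf = self.sitk_transform
        if isinstance(tf, sitk.CompositeTransform):
            M = np.eye(4)
            # composite applies last-added first; flatten only if all linear
            for i in range(tf.GetNumberOfTransforms()):
                sub = SpatialTransform("affine", tf.GetNthTransform(i))
                M = sub.matrix @ M
            return M
        try:
            R = np.array(tf.GetMatrix()).reshape(3, 3)
            t = np.array(tf.GetTranslation())
            c = np.array(tf.GetCenter()) if hasattr(tf, "GetCenter") else np.zeros(3)
        except AttributeError as exc:  # pragma: no cover
            raise ValueError(f"{self.kind} transform has no matrix form") from exc
        t_eff = t + c - R @ c
        M = np.eye(4)
        M[:3, :3] = _FLIP @ R @ _FLIP
        M[:3, 3] = _FLIP @ t_eff
        return M

    @property
    def rotation_angle_deg(self) -> float:
        """Total rotation angle of the rigid/affine part, degrees."""
        R = self.matrix[:3, :3]
        # polar decomposition guards against tiny scaling from optimisation
        u, _, vt = np.linalg.svd(R)
        Rr = u @ vt
        ang = np.arccos(np.clip((np.trace(Rr) - 1.0) / 2.0, -1.0, 1.0))
        return float(np.rad2deg(ang))

    @property
    def translation_mm(self) -> np.ndarray:
        """Displacement of the world origin region: evaluated at 0 (RAS mm)."""
        return self.matrix[:3, 3].copy()

    def transform_point(self, point_ras: np.ndarray) -> np.ndarray:
        p_lps = _FLIP @ np.asarray(point_ras, dtype=float)
        q = np.array(self.sitk_transform.TransformPoint(tuple(p_lps)))
        return _FLIP @ q

    def inverse(self) -> "SpatialTransform":
        return SpatialTransform(self.kind, self.sitk_transform.GetInverse())

    def compose(self, inner: "SpatialTransform") -> "SpatialTransform":
        """Return the map ``x -> inner(self(x))`` ... i.e. self applied first.

        For resampling chains: if ``self`` maps reference->subject NM and
        ``inner`` maps subject NM->iron, the composite maps reference->iron.
        """
        comp = sitk.CompositeTransform(3)
        comp.AddTransform(inner.sitk_transform)
        comp.AddTransform(self.sitk_transform)
        return SpatialTransform("composite", comp)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        sitk.WriteTransform(self.sitk_transform, str(path))
        return path

    @staticmethod
    def load(path: str | Path, kind: str = "composite") -> "SpatialTransform":
        return SpatialTransform(kind, sitk.ReadTransform(str(path)))


def apply_transform(
    obj: Volume | LabelMask,
    transform: SpatialTransform,
    target_grid: Volume | LabelMask,
    interpolation: str | None = None,
) -> Volume | LabelMask:
    """Resample ``obj`` onto ``target_grid`` through ``transform``.

    ``transform`` maps target world points to ``obj`` world points.
    Intensities are interpolated linearly, label masks with nearest
    neighbour (so the output stays binary); pass ``interpolation`` to
    override.
    """
    is_mask = isinstance(obj, LabelMask)
    if interpolation is None:
        interpolation = "nearest" if is_mask else "linear"
    interp = {
        "nearest": sitk.sitkNearestNeighbor,
        "linear": sitk.sitkLinear,
        "bspline": sitk.sitkBSpline,
    }[interpolation]
    moving = volume_to_sitk(obj)
    reference = volume_to_sitk(
        target_grid
        if isinstance(target_grid, Volume)
        else Volume(np.zeros(target_grid.shape, np.float32), target_grid.affine)
    )
    out = sitk.Resample(moving, reference, transform.sitk_transform, interp, 0.0)
    arr = sitk.GetArrayFromImage(out).transpose(2, 1, 0)
    if is_mask:
        return LabelMask(
            data=arr > 0.5,
            affine=np.asarray(target_grid.affine, float),
            structure=obj.structure,
            side=obj.side,
        )
    return Volume(data=arr, affine=np.asarray(target_grid.affine, float), sequence=obj.sequence)
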