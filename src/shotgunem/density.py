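"""Volume and image numerics for single-particle work.

Conventions, fixed package-wide:

* Volumes are cubic numpy arrays indexed ``(z, y, x)`` with an even side N;
  the rotation centre sits at voxel index ``(N/2, N/2, N/2)`` (0-based).
* Euler angles ``(rot, tilt, psi)`` are degrees, intrinsic ZYZ, rotating the
  reference frame into the particle frame (the dominant single-particle
  convention).  ``tilt`` lies in [0, 180].
* 2D shifts ``(dx, dy)`` are applied to the projected image: a particle with
  shift (dx, dy) appears displaced by +dx along x (columns) and +dy along y
  (rows).
* A projection is the z-axis line integral of the rotated volume, so image
  mass equals volume mass up to interpolation loss.
* MRC/CCP4 files are written mode 2 (float32); on disk the fastest axis is
  x, matching the in-memory ``(z, y, x)`` layout.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass

import gemmi
import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

__all__ = [
    "DensityVolume",
    "Orientation",
    "ProjectionImage",
    "load_density",
    "save_density",
    "atoms_to_density",
    "lowpass",
    "project",
    "rotate_image",
    "backproject_reconstruct",
    "align_volumes",
    "volume_cc",
    "ring_diameter",
]


@dataclass
class DensityVolume:
    """Cubic 3D density grid with voxel size in Å/px."""

    grid: np.ndarray
    voxel_size: float

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float64)
        if self.grid.ndim != 3 or len(set(self.grid.shape)) != 1:
            raise ValueError("volume grid must be cubic (N, N, N)")
        if self.grid.shape[0] % 2 != 0:
            raise ValueError("volume side length must be even")
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("volume contains non-finite values")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")

    @property
    def n(self) -> int:
        return self.grid.shape[0]

    def copy(self) -> "DensityVolume":
        return DensityVolume(self.grid.copy(), self.voxel_size)


@dataclass
class Orientation:
    """Euler angles (rot, tilt, psi) in degrees, ZYZ intrinsic, plus 2D shift."""

    rot: float = 0.0
    tilt: float = 0.0
    psi: float = 0.0
    shift: tuple[float, float] = (0.0, 0.0)  # (dx, dy) px

    def __post_init__(self) -> None:
        if not 0.0 <= self.tilt <= 180.0:
            raise ValueError(f"tilt {self.tilt} outside [0, 180]")
        if not np.all(np.isfinite(self.shift)):
            raise ValueError("shifts must be finite")

    def matrix(self) -> np.ndarray:
        """3x3 rotation matrix acting on (x, y, z) column vectors."""
        return Rotation.from_euler(
            "ZYZ", [self.rot, self.tilt, self.psi], degrees=True
        ).as_matrix()


@dataclass
class ProjectionImage:
    """Square 2D projection with pixel size in Å/px."""

    image: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=np.float64)
        if self.image.ndim != 2 or self.image.shape[0] != self.image.shape[1]:
            raise ValueError("projection image must be square")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


# ---------------------------------------------------------------------------
# rotation helpers
# ---------------------------------------------------------------------------

def _rotate_array(arr: np.ndarray, mat_xyz: np.ndarray, order: int = 1) -> np.ndarray:
    """Sample ``arr`` at coordinates mapped by ``mat_xyz`` about the centre.

    ``out(u) = arr(M (u - c) + c)`` where u, c are (x, y[, z]) vectors and c
    is the N/2 centre.  Array axes are reversed relative to (x, y, z), so the
    index-space matrix is ``mat_xyz`` with rows and columns flipped.
    """
    m = np.ascontiguousarray(mat_xyz[::-1, ::-1])
    c = np.array(arr.shape, dtype=np.float64) / 2.0
    offset = c - m @ c
    return ndimage.affine_transform(
        arr, m, offset=offset, order=order, mode="constant", cval=0.0, prefilter=False
    )


def rotate_volume(grid: np.ndarray, rotmat: np.ndarray) -> np.ndarray:
    """Rotate a volume by ``rotmat`` (trilinear): out(u) = grid(R^-1 u)."""
    return _rotate_array(grid, rotmat.T)


def rotate_image(image: np.ndarray, angle_deg: float) -> np.ndarray:
    """In-plane rotation consistent with a Rz(angle) object rotation."""
    r = np.deg2rad(angle_deg)
    rot2 = np.array([[np.cos(r), -np.sin(r)], [np.sin(r), np.cos(r)]])
    return _rotate_array(np.asarray(image, dtype=np.float64), rot2.T)


def shift_image(image: np.ndarray, dx: float, dy: float) -> np.ndarray:
    """Displace image content by (+dx, +dy) pixels (bilinear)."""
    return ndimage.shift(
        np.asarray(image, dtype=np.float64), (dy, dx), order=1, mode="constant",
        cval=0.0, prefilter=False,
    )


# ---------------------------------------------------------------------------
# MRC / CCP4 I/O (gemmi-backed)
# ---------------------------------------------------------------------------

def load_density(path: str, require_cubic: bool = True) -> DensityVolume:
    """Read an MRC/CCP4 map (modes 0/1/2) into a DensityVolume."""
    try:
        m = gemmi.read_ccp4_map(str(path))
        m.setup(0.0)
    except (RuntimeError, OSError) as exc:
        raise ValueError(f"cannot read MRC/CCP4 map {path!r}: {exc}") from exc
    arr = np.array(m.grid, copy=True)  # gemmi axis order (x, y, z)
    arr = np.ascontiguousarray(arr.T)  # -> (z, y, x)
    sp = m.grid.spacing
    if require_cubic and (len(set(arr.shape)) != 1 or abs(sp[0] - sp[2]) > 1e-4):
        raise ValueError(
            f"map {path!r} is not cubic with isotropic voxels (shape {arr.shape})"
        )
    return DensityVolume(arr.astype(np.float64), float(sp[0]))


def save_density(volume: DensityVolume, path: str) -> None:
    """Write a DensityVolume as an MRC map, mode 2 (float32)."""
    n = volume.n
    g = gemmi.FloatGrid(n, n, n)
    np.array(g, copy=False)[:] = np.ascontiguousarray(
        volume.grid.T.astype(np.float32)
    )
    a = n * volume.voxel_size
    g.set_unit_cell(gemmi.UnitCell(a, a, a, 90.0, 90.0, 90.0))
    m = gemmi.Ccp4Map()
    m.grid = g
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


# ---------------------------------------------------------------------------
# atomic models -> density
# ---------------------------------------------------------------------------

def atoms_to_density(
    structure: "gemmi.Structure | str | os.PathLike",
    box_size: int,
    voxel_size: float,
    sigma: float = 2.0,
    center: bool = True,
) -> DensityVolume:
    """Rasterize an atomic model (PDB/mmCIF) on a cubic grid.

    Every non-hydrogen atom contributes a unit-weight isotropic 3D Gaussian
    of width ``sigma`` Å (immaterial in shape terms once the map is low-pass
    filtered to tens of Å).  With ``center=True`` the structure's centre of
    geometry is moved to the box centre first.
    """
    if not isinstance(structure, gemmi.Structure):
        structure = gemmi.read_structure(str(structure))
    pos = []
    for model in structure:
        for chain in model:
            for res in chain:
                for atom in res:
                    if atom.element.is_hydrogen:
                        continue
                    pos.append([atom.pos.x, atom.pos.y, atom.pos.z])
        break  # first model only
    if not pos:
        raise ValueError("structure has no non-hydrogen atoms")
    pos = np.array(pos, dtype=np.float64)
    if center:
        pos = pos - pos.mean(axis=0)
    n = int(box_size)
    vox = pos / voxel_size + n / 2.0  # (x, y, z) voxel coordinates
    if np.any(vox < 1) or np.any(vox > n - 2):
        raise ValueError(
            f"structure extent does not fit in a {n}^3 box at {voxel_size} A/px"
        )
    grid = np.zeros((n, n, n), dtype=np.float64)
    sig_vox = sigma / voxel_size
    mass = (2.0 * np.pi) ** 1.5 * sig_vox**3  # integral of unit-height Gaussian
    # trilinear splat of point masses, then Gaussian blur (sum-preserving)
    zyx = vox[:, ::-1]
    base = np.floor(zyx).astype(int)
    frac = zyx - base
    for dz in (0, 1):
        for dy in (0, 1):
            for dx in (0, 1):
                w = (
                    (frac[:, 0] if dz else 1 - frac[:, 0])
                    * (frac[:, 1] if dy else 1 - frac[:, 1])
                    * (frac[:, 2] if dx else 1 - frac[:, 2])
                )
                np.add.at(
                    grid, (base[:, 0] + dz, base[:, 1] + dy, base[:, 2] + dx), w * mass
                )
    grid = ndimage.gaussian_filter(grid, sig_vox, mode="constant")
    return DensityVolume(grid, voxel_size)


# ---------------------------------------------------------------------------
# low-pass filtering
# ---------------------------------------------------------------------------

def _lowpass_array(arr: np.ndarray, spacing: float, resolution: float) -> np.ndarray:
    if resolution <= 2.0 * spacing:
        raise ValueError(
            f"resolution {resolution} A is at or below Nyquist ({2 * spacing} A)"
        )
    n = arr.shape[0]
    fc = 1.0 / resolution
    w = 2.0 / (n * spacing)  # two Fourier-pixel widths
    freqs = np.fft.fftfreq(n, d=spacing)
    grids = np.meshgrid(*([freqs] * arr.ndim), indexing="ij")
    f = np.sqrt(sum(g**2 for g in grids))
    gain = np.clip((fc + w - f) / (2.0 * w), 0.0, 1.0)
    gain = 0.5 * (1.0 - np.cos(np.pi * gain))  # raised cosine edge
    out = np.fft.ifftn(np.fft.fftn(arr) * gain).real
    return out


def lowpass(obj, resolution: float):
    """Low-pass filter a DensityVolume or ProjectionImage to ``resolution`` Å.

    The Fourier amplitudes are multiplied by a raised-cosine edge that is 1
    below f_c - w and 0 above f_c + w, with f_c = 1/resolution and w equal to
    two Fourier-pixel widths.  The DC term is untouched, so the mean value is
    preserved exactly.
    """
    if isinstance(obj, DensityVolume):
        return DensityVolume(_lowpass_array(obj.grid, obj.voxel_size, resolution),
                             obj.voxel_size)
    if isinstance(obj, ProjectionImage):
        return ProjectionImage(_lowpass_array(obj.image, obj.pixel_size, resolution),
                               obj.pixel_size)
    raise TypeError("lowpass expects a DensityVolume or ProjectionImage")


# ---------------------------------------------------------------------------
# projection / back-projection
# ---------------------------------------------------------------------------

def project(volume: DensityVolume, orientation: Orientation) -> ProjectionImage:
    """Project a volume along z after rotating it into the particle frame."""
    rotated = rotate_volume(volume.grid, orientation.matrix())
    img = rotated.sum(axis=0)
    dx, dy = orientation.shift
    if dx != 0.0 or dy != 0.0:
        img = shift_image(img, dx, dy)
    return ProjectionImage(img, volume.voxel_size)


def backproject_reconstruct(
    images: "list[np.ndarray] | np.ndarray",
    orientations: list[Orientation],
    voxel_size: float = 1.0,
    weight_floor: float = 1e-6,
) -> DensityVolume:
    """Real-space back-projection of aligned particle images.

    Each image is un-shifted, smeared along its viewing axis into the volume
    with trilinear interpolation, and the accumulated density is normalised
    voxelwise by an identically smeared sampling-weight volume (clamped below
    at ``weight_floor`` of its maximum).  A deliberately simple, unfiltered
    reconstruction: adequate for consistency scoring and toy-scale fidelity,
    not for resolution claims.
    """
    images = [np.asarray(im, dtype=np.float64) for im in images]
    if len(images) == 0:
        raise ValueError("empty image stack")
    if len(images) != len(orientations):
        raise ValueError("images and orientations differ in length")
    n = images[0].shape[0]
    num = np.zeros((n, n, n), dtype=np.float64)
    wgt = np.zeros((n, n, n), dtype=np.float64)
    ones = np.ones((n, n), dtype=np.float64)
    for img, ori in zip(images, orientations):
        dx, dy = ori.shift
        if dx != 0.0 or dy != 0.0:
            img = shift_image(img, -dx, -dy)
        smear = np.broadcast_to(img, (n, n, n))
        wsmear = np.broadcast_to(ones, (n, n, n))
        rmat = ori.matrix()
        # contribution(u) = smear(R u): inverse rotation of the smear volume
        num += _rotate_array(np.ascontiguousarray(smear), rmat)
        wgt += _rotate_array(np.ascontiguousarray(wsmear), rmat)
    if wgt.max() <= 0:
        return DensityVolume(np.zeros((n, n, n)), voxel_size)
    recon = num / np.maximum(wgt, weight_floor * wgt.max())
    return DensityVolume(recon, voxel_size)


# ---------------------------------------------------------------------------
# rigid 3D alignment and correlation
# ---------------------------------------------------------------------------

def _euler_grid(angular_step: float) -> list[tuple[float, float, float]]:
    rots = np.arange(0.0, 360.0, angular_step)
    tilts = np.arange(0.0, 180.0 + 1e-9, angular_step)
    psis = np.arange(0.0, 360.0, angular_step)
    out = []
    for tilt in tilts:
        if tilt in (0.0, 180.0):
            # rot and psi degenerate: scan their sum only
            out.extend((0.0, tilt, p) for p in psis)
        else:
            out.extend((r, tilt, p) for r in rots for p in psis)
    return out


def align_volumes(
    fixed: DensityVolume,
    moving: DensityVolume,
    angular_step: float = 15.0,
    resolution: float = 30.0,
) -> tuple[Orientation, np.ndarray, float]:
    """Exhaustive rigid alignment of ``moving`` onto ``fixed``.

    Both maps are low-pass filtered to ``resolution`` Å, rotations are
    scanned on a ZYZ grid with ``angular_step`` degree spacing, and the
    translation for each rotation is solved by FFT cross-correlation
    (integer voxels).  Returns the best Orientation (rotation only), the
    shift in index order (dz, dy, dx), and the masked map-to-map
    cross-correlation at the optimum.
    """
    if not 5.0 <= angular_step <= 45.0:
        raise ValueError("angular_step must lie in [5, 45] degrees")
    if abs(fixed.voxel_size - moving.voxel_size) > 1e-6:
        raise ValueError("voxel sizes differ; resample first")
    flp = lowpass(fixed, resolution).grid
    mlp = lowpass(moving, resolution).grid
    f0 = flp - flp.mean()
    Ff = np.fft.fftn(f0)
    nf = np.linalg.norm(f0)
    best = (-np.inf, None, None)
    for rot, tilt, psi in _euler_grid(angular_step):
        ori = Orientation(rot, tilt, psi)
        rm = rotate_volume(mlp, ori.matrix())
        rm0 = rm - rm.mean()
        nm = np.linalg.norm(rm0)
        if nm == 0 or nf == 0:
            continue
        cc = np.fft.ifftn(Ff * np.conj(np.fft.fftn(rm0))).real
        idx = np.unravel_index(np.argmax(cc), cc.shape)
        score = cc[idx] / (nf * nm)
        if score > best[0]:
            n = flp.shape[0]
            shift = np.array([(i if i <= n // 2 else i - n) for i in idx])
            best = (score, ori, shift)
    score, ori, shift = best
    moved = np.roll(rotate_volume(mlp, ori.matrix()), shift, axis=(0, 1, 2))
    cc = volume_cc(DensityVolume(flp, fixed.voxel_size),
                   DensityVolume(moved, fixed.voxel_size))
    return ori, shift, cc


def _robust_sigma(arr: np.ndarray) -> float:
    med = np.median(arr)
    return 1.4826 * np.median(np.abs(arr - med))


def volume_cc(a: DensityVolume, b: DensityVolume) -> float:
    """Masked zero-mean cross-correlation of two maps on the same grid.

    The mask is taken from whichever map has the larger support — the greater
    count of voxels above 3x its robust (MAD-based) noise sigma — so the
    comparison region always covers the bigger structure.
    """
    if a.grid.shape != b.grid.shape or abs(a.voxel_size - b.voxel_size) > 1e-6:
        raise ValueError("maps must share grid and voxel size")
    masks = []
    for v in (a, b):
        s = _robust_sigma(v.grid)
        thr = 3.0 * s if s > 0 else 0.0
        masks.append(v.grid > thr)
    mask = masks[0] if masks[0].sum() >= masks[1].sum() else masks[1]
    if not mask.any():
        raise ValueError("support mask is empty; cannot correlate")
    x = a.grid[mask].astype(np.float64)
    y = b.grid[mask].astype(np.float64)
    x = x - x.mean()
    y = y - y.mean()
    denom = np.linalg.norm(x) * np.linalg.norm(y)
    if denom == 0:
        raise ValueError("zero variance inside the mask")
    return float(np.dot(x, y) / denom)


# ---------------------------------------------------------------------------
# ring diameter
# ---------------------------------------------------------------------------

def ring_diameter(obj, frac_of_max: float = 0.2) -> float:
    """Diameter (Å) of a ring-like particle from its top view.

    Takes the z-axis projection (for a volume) or the image itself, computes
    the circularly averaged radial intensity profile about the image centre,
    and reports twice the largest radius at which the profile still reaches
    ``frac_of_max`` of its maximum.  Meaningful on maps low-pass filtered to
    the scale of interest (e.g. 30 Å); a warning is emitted when substantial
    high-frequency power suggests the input was not filtered.
    """
    if isinstance(obj, DensityVolume):
        img = obj.grid.sum(axis=0)
        spacing = obj.voxel_size
    elif isinstance(obj, ProjectionImage):
        img = obj.image
        spacing = obj.pixel_size
    else:
        raise TypeError("ring_diameter expects a DensityVolume or ProjectionImage")
    if not np.any(img != 0):
        raise ValueError("all-zero image: ring diameter undefined")
    n = img.shape[0]
    ps = np.abs(np.fft.fftn(img)) ** 2
    f = np.sqrt(sum(g**2 for g in np.meshgrid(
        *([np.fft.fftfreq(n, d=spacing)] * 2), indexing="ij")))
    hi = ps[f > 1.0 / 25.0].sum() / ps.sum()
    if hi > 0.2:
        warnings.warn(
            "ring_diameter input carries substantial power above 25 A; "
            "low-pass filter it first", stacklevel=2,
        )
    c = n / 2.0
    yy, xx = np.indices(img.shape)
    r = np.sqrt((yy - c) ** 2 + (xx - c) ** 2)
    rbin = np.rint(r).astype(int)
    profile = np.bincount(rbin.ravel(), weights=img.ravel()) / np.bincount(rbin.ravel())
    profile = profile[: n // 2]
    mx = profile.max()
    if mx <= 0:
        raise ValueError("non-positive radial profile; ring diameter undefined")
    above = np.nonzero(profile >= frac_of_max * mx)[0]
    return float(2.0 * above[-1] * spacing)
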