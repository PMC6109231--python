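"""Synthetic ground-truth generators for both halves of the pipeline.

The MS side emulates shotgun proteomics of a fractionated lysate: a complex
database with a known variant hierarchy (base complexes drawn from disjoint
accession pools, so inter-group similarity is exactly zero), and protein
observations whose spectral counts follow a Poisson model with mean
proportional to ``abundance x length``, with detection dropout below a count
floor and log-normal peptide areas.

The EM side provides parametric 3D phantoms — sphere, barrel (stacked
annular rings with a central channel), capped barrel (barrel plus an
off-axis rectangular cap, breaking the z mirror), and a C7 heptameric ring —
plus renderers for particle stacks and whole simulated micrographs with
stored ground truth.  Protein density is HIGH intensity (white particles on
dark background) throughout, matching the displayed contrast of negative
stain.

None of the distributional choices claim fidelity to a particular
instrument; they are parameterized stand-ins that give every downstream
stage a testable ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .complexome import ComplexRecord
from .density import DensityVolume, Orientation, project
from .em2d import ParticleStack
from .quant import ProteinObservation

__all__ = [
    "GroundTruthComplexDB",
    "Phantom",
    "SimulatedMicrograph",
    "make_complex_db",
    "simulate_ms_observations",
    "make_phantom",
    "make_ring_structure",
    "render_particle_stack",
    "render_micrograph",
    "PHANTOM_SHAPES",
]

PHANTOM_SHAPES = ("sphere", "barrel", "capped_barrel", "heptamer_ring")


@dataclass
class GroundTruthComplexDB:
    """Complex database with known hierarchy, abundances, and lengths."""

    complexes: list[ComplexRecord]
    group_label: dict[str, int]
    true_abundance: dict[str, float]
    protein_lengths: dict[str, int]

    def accessions(self) -> set[str]:
        out: set[str] = set()
        for c in self.complexes:
            out |= c.subunits
        return out


@dataclass
class Phantom:
    """Parametric 3D test particle."""

    volume: DensityVolume
    shape_name: str
    symmetry: str  # point-group tag: C1 or C7


@dataclass
class SimulatedMicrograph:
    """Simulated field of particles with placement/orientation ground truth."""

    image: np.ndarray
    pixel_size: float
    truth: list[tuple[int, int, int, Orientation]] = field(default_factory=list)
    # truth entries: (center_x px, center_y px, phantom label, orientation)


# ---------------------------------------------------------------------------
# complex database
# ---------------------------------------------------------------------------

def make_complex_db(
    n_base: int,
    variants_per_base: int,
    size_range: tuple[int, int] = (4, 20),
    seed: int = 0,
) -> GroundTruthComplexDB:
    """Build a complex database with a known variant hierarchy.

    ``n_base`` base complexes draw subunits from disjoint accession pools
    (inter-group similarity is therefore exactly 0).  Each of the
    ``variants_per_base`` variants of a base is its parent with at most 10%
    of subunits removed, or with one extra pool subunit added, so the
    similarity of parent or variant toward the other is always >= 0.9.
    Group label = parent index.  Deterministic for a fixed seed.
    """
    lo, hi = size_range
    if n_base < 1:
        raise ValueError("n_base must be >= 1")
    if lo > hi or lo < 2 or hi > 100:
        raise ValueError("size_range must be ordered and within [2, 100]")
    rng = np.random.default_rng(seed)
    complexes: list[ComplexRecord] = []
    group_label: dict[str, int] = {}
    true_abundance: dict[str, float] = {}
    protein_lengths: dict[str, int] = {}
    for g in range(n_base):
        size = int(rng.integers(lo, hi + 1))
        pool = [f"G{g:03d}P{i:03d}" for i in range(size + variants_per_base + 2)]
        for acc in pool:
            protein_lengths[acc] = int(rng.integers(150, 1200))
        base = frozenset(pool[:size])
        spares = pool[size:]
        cid = f"CPX{g:04d}.0"
        complexes.append(ComplexRecord(cid, f"base{g}", base))
        group_label[cid] = g
        true_abundance[cid] = float(rng.lognormal(0.0, 0.5))
        for v in range(variants_per_base):
            removable = len(base) // 10
            if removable >= 1 and rng.random() < 0.5:
                k = int(rng.integers(1, removable + 1))
                drop = rng.choice(sorted(base), size=k, replace=False)
                subunits = base - set(drop.tolist())
            else:
                subunits = base | {spares[v % len(spares)]}
            cid = f"CPX{g:04d}.{v + 1}"
            complexes.append(ComplexRecord(cid, f"base{g}_var{v}", frozenset(subunits)))
            group_label[cid] = g
            true_abundance[cid] = float(rng.lognormal(0.0, 0.5))
    return GroundTruthComplexDB(complexes, group_label, true_abundance, protein_lengths)


def simulate_ms_observations(
    db: GroundTruthComplexDB,
    count_scale: float = 50.0,
    detection_floor: int = 0,
    peptide_area_sigma: float = 0.5,
    seed: int = 0,
) -> list[ProteinObservation]:
    """Simulate MS observation of the proteins in a complex database.

    Per protein, the expected spectral count is
    ``count_scale x (sum of true abundances of complexes containing it)
    x length/1000``; the observed count is Poisson, and the protein is
    reported only when the count exceeds ``detection_floor``.  Reported
    proteins carry ``max(1, count)`` peptide areas drawn log-normally with
    location log(expected count) and scale ``peptide_area_sigma``.
    """
    if count_scale <= 0:
        raise ValueError("count_scale must be positive")
    rng = np.random.default_rng(seed)
    abundance_of: dict[str, float] = {}
    for c in db.complexes:
        a = db.true_abundance.get(c.complex_id, 0.0)
        for acc in c.subunits:
            abundance_of[acc] = abundance_of.get(acc, 0.0) + a
    out: list[ProteinObservation] = []
    for acc in sorted(db.protein_lengths):
        length = db.protein_lengths[acc]
        lam = count_scale * abundance_of.get(acc, 0.0) * length / 1000.0
        count = int(rng.poisson(lam)) if lam > 0 else 0
        if count <= detection_floor:
            continue
        k = max(1, count)
        mu = np.log(max(lam, 1e-12))
        areas = rng.lognormal(mu, peptide_area_sigma, size=k)
        out.append(ProteinObservation(acc, length, count, [float(a) for a in areas]))
    return out


# ---------------------------------------------------------------------------
# phantoms
# ---------------------------------------------------------------------------

def _coords(n: int, voxel_size: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ax = (np.arange(n) - n / 2.0) * voxel_size
    return np.meshgrid(ax, ax, ax, indexing="ij")  # (z, y, x) in A


def make_phantom(
    shape_name: str,
    box_size: int = 48,
    voxel_size: float = 4.0,
    diameter: float = 120.0,
    smooth_vox: float = 1.2,
) -> Phantom:
    """Build a parametric phantom volume.

    * ``sphere`` — uniform ball of the requested diameter.
    * ``barrel`` — two stacked annular rings with a central channel.
    * ``capped_barrel`` — barrel plus an off-axis rectangular cap at +z
      (not mirror-symmetric along z).
    * ``heptamer_ring`` — seven Gaussian blobs on a circle of the requested
      diameter, exactly C7-symmetric about the box z-axis.

    Densities are non-negative; a light Gaussian smoothing (``smooth_vox``
    voxels, default 1.2) keeps hard-edged shapes interpolation-friendly.
    """
    if shape_name not in PHANTOM_SHAPES:
        raise ValueError(f"unknown phantom shape {shape_name!r}")
    if box_size % 2 != 0:
        raise ValueError("box_size must be even")
    r = diameter / 2.0
    half_extent = (box_size / 2.0 - 2.0) * voxel_size
    if shape_name == "heptamer_ring":
        needed = r + 3 * 0.2 * r
    elif shape_name == "capped_barrel":
        needed = 1.55 * r
    else:
        needed = 1.05 * r
    if needed >= half_extent:
        raise ValueError(
            f"diameter {diameter} A does not fit a {box_size}px box at "
            f"{voxel_size} A/px"
        )
    zz, yy, xx = _coords(box_size, voxel_size)
    rho = np.sqrt(xx**2 + yy**2)
    symmetry = "C1"
    if shape_name == "sphere":
        grid = (np.sqrt(xx**2 + yy**2 + zz**2) <= r).astype(np.float64)
    elif shape_name in ("barrel", "capped_barrel"):
        annulus = (rho <= r) & (rho >= 0.35 * r)
        bands = (np.abs(zz) >= 0.08 * r) & (np.abs(zz) <= 0.68 * r)
        grid = (annulus & bands).astype(np.float64)
        if shape_name == "capped_barrel":
            # a substantial off-axis cap (~25% of the particle mass), echoing
            # a regulatory particle docked on one end of the barrel
            cap = (
                (zz > 0.7 * r)
                & (zz <= 1.5 * r)
                & (np.abs(xx - 0.15 * r) <= 0.6 * r)
                & (np.abs(yy) <= 0.45 * r)
            )
            grid += cap.astype(np.float64)
    else:  # heptamer_ring
        symmetry = "C7"
        sig = 0.2 * r
        grid = np.zeros_like(xx)
        for k in range(7):
            ang = 2.0 * np.pi * k / 7.0
            cx, cy = r * np.cos(ang), r * np.sin(ang)
            grid += np.exp(
                -((xx - cx) ** 2 + (yy - cy) ** 2 + zz**2) / (2.0 * sig**2)
            )
    if smooth_vox > 0:
        grid = ndimage.gaussian_filter(grid, smooth_vox)
    grid = np.clip(grid, 0.0, None)
    return Phantom(DensityVolume(grid, voxel_size), shape_name, symmetry)


def make_ring_structure(
    outer_diameter: float,
    n_subunits: int = 7,
    subunit_radius: float = 18.0,
    atoms_per_subunit: int = 80,
    height: float = 30.0,
    seed: int = 0,
):
    """Synthetic pseudo-atomic ring model with a known outer diameter (Å).

    A stand-in for a ring-forming oligomer (chaperonin-like or protease-ring
    scale): ``n_subunits`` blobs of uniformly scattered pseudo-atoms placed
    Cn-symmetrically so the outermost atomic radius equals
    ``outer_diameter / 2``.  Used to exercise the rasterize → low-pass →
    ring-diameter chain where a real crystal structure is not bundled.
    Returns a ``gemmi.Structure``.
    """
    import gemmi

    rng = np.random.default_rng(seed)
    rc = outer_diameter / 2.0 - subunit_radius
    if rc <= 0:
        raise ValueError("outer_diameter too small for the subunit radius")
    st = gemmi.Structure()
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    idx = 1
    for k in range(n_subunits):
        ang = 2.0 * np.pi * k / n_subunits
        cx, cy = rc * np.cos(ang), rc * np.sin(ang)
        for _ in range(atoms_per_subunit):
            while True:
                p = rng.uniform(-1.0, 1.0, 3)
                if p[0] ** 2 + p[1] ** 2 <= 1.0:
                    break
            res = gemmi.Residue()
            res.name = "ALA"
            res.seqid = gemmi.SeqId(idx, " ")
            idx += 1
            a = gemmi.Atom()
            a.name = "CA"
            a.element = gemmi.Element("C")
            a.pos = gemmi.Position(
                cx + subunit_radius * p[0],
                cy + subunit_radius * p[1],
                height / 2.0 * p[2],
            )
            res.add_atom(a)
            chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    return st


# ---------------------------------------------------------------------------
# particle rendering
# ---------------------------------------------------------------------------

def _random_orientation(rng: np.random.Generator, max_shift: int = 0) -> Orientation:
    """Uniform over SO(3): uniform rot/psi, cos(tilt) uniform in [-1, 1]."""
    rot = float(rng.uniform(0.0, 360.0))
    psi = float(rng.uniform(0.0, 360.0))
    tilt = float(np.degrees(np.arccos(rng.uniform(-1.0, 1.0))))
    if max_shift > 0:
        dx = int(rng.integers(-max_shift, max_shift + 1))
        dy = int(rng.integers(-max_shift, max_shift + 1))
    else:
        dx = dy = 0
    return Orientation(rot, tilt, psi, (float(dx), float(dy)))


def _check_mixture(phantoms, mixture) -> np.ndarray:
    mixture = np.asarray(mixture, dtype=np.float64)
    if len(mixture) != len(phantoms):
        raise ValueError("mixture and phantoms differ in length")
    if abs(mixture.sum() - 1.0) > 1e-9:
        raise ValueError("mixture fractions must sum to 1")
    sizes = {p.volume.n for p in phantoms} | {p.volume.voxel_size for p in phantoms}
    if len({p.volume.n for p in phantoms}) != 1:
        raise ValueError("all phantoms must share a box size")
    if len({p.volume.voxel_size for p in phantoms}) != 1:
        raise ValueError("all phantoms must share a voxel size")
    return mixture


def render_particle_stack(
    phantoms: list[Phantom],
    mixture,
    n: int,
    noise_sigma: float = 0.0,
    max_shift: int = 0,
    seed: int = 0,
) -> tuple[ParticleStack, np.ndarray, list[Orientation]]:
    """Render a mixed particle stack with stored ground truth.

    Each particle draws a phantom label (multinomial over ``mixture``), a
    uniform SO(3) orientation, a random integer in-plane shift in
    ``[-max_shift, max_shift]^2``, and i.i.d. Gaussian pixel noise of width
    ``noise_sigma``.  Returns (stack, labels, orientations).
    """
    mixture = _check_mixture(phantoms, mixture)
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    labels = rng.choice(len(phantoms), size=n, p=mixture)
    box = phantoms[0].volume.n
    px = phantoms[0].volume.voxel_size
    images = np.empty((n, box, box), dtype=np.float64)
    orientations: list[Orientation] = []
    for i in range(n):
        ori = _random_orientation(rng, max_shift)
        img = project(phantoms[labels[i]].volume, ori).image
        if noise_sigma > 0:
            img = img + rng.normal(0.0, noise_sigma, img.shape)
        images[i] = img
        orientations.append(ori)
    return ParticleStack(images, px), labels, orientations


def render_micrograph(
    phantoms: list[Phantom],
    mixture,
    n_particles: int,
    image_size: tuple[int, int] = (1024, 1024),
    noise_sigma: float = 0.0,
    min_distance: int = 64,
    seed: int = 0,
    max_attempts: int = 10_000,
) -> SimulatedMicrograph:
    """Place randomly oriented phantom projections on a simulated micrograph.

    Centers are rejection-sampled to keep pairwise distances >= ``min_distance``
    and every center at least half a box from the edges; exceeding
    ``max_attempts`` rejections raises a capacity error.  Protein density is
    high intensity; Gaussian noise is added over the whole field.
    """
    mixture = _check_mixture(phantoms, mixture)
    rng = np.random.default_rng(seed)
    h, w = image_size
    box = phantoms[0].volume.n
    half = box // 2
    if w - 2 * half <= 0 or h - 2 * half <= 0:
        raise ValueError("image too small for the particle box")
    centers: list[tuple[int, int]] = []
    attempts = 0
    while len(centers) < n_particles:
        if attempts >= max_attempts:
            raise ValueError(
                f"cannot place {n_particles} particles with min_distance="
                f"{min_distance} in {image_size} after {max_attempts} attempts"
            )
        cx = int(rng.integers(half, w - half))
        cy = int(rng.integers(half, h - half))
        attempts += 1
        if all((cx - x) ** 2 + (cy - y) ** 2 >= min_distance**2 for x, y in centers):
            centers.append((cx, cy))
    image = np.zeros((h, w), dtype=np.float64)
    truth: list[tuple[int, int, int, Orientation]] = []
    labels = rng.choice(len(phantoms), size=n_particles, p=mixture) if n_particles else []
    for (cx, cy), label in zip(centers, labels):
        ori = _random_orientation(rng)
        img = project(phantoms[label].volume, ori).image
        image[cy - half : cy + half, cx - half : cx + half] += img
        truth.append((cx, cy, int(label), ori))
    if noise_sigma > 0:
        image = image + rng.normal(0.0, noise_sigma, image.shape)
    return SimulatedMicrograph(image, phantoms[0].volume.voxel_size, truth)
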