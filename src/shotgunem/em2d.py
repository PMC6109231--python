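"""2D single-particle processing of heterogeneous mixtures.

Covers the image-side pipeline between raw micrographs and identified class
averages: difference-of-Gaussians particle picking, particle extraction,
reference-free alignment-and-classification of a mixed particle stack, and
identification of class averages by exhaustive matching against a library of
reprojections (simulated projections of known structures).

The 2D classifier here is a deterministic multireference-alignment / k-means
hybrid: particles are aligned to every class average over a grid of in-plane
rotations and integer shifts (FFT cross-correlation), assigned to the best
class, and the averages are recomputed from the aligned members.  It is NOT
a reimplementation of regularized-likelihood classification as done by the
mainstream Bayesian packages; it is adequate for the moderate-noise regimes
of synthetic and negative-stain-like data this package targets.

Rotation convention: the reported ``in_plane_rotation`` is the angle applied
to the particle (or class) image that brings it into register with the
reference, followed by the reported ``(dx, dy)`` shift.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from skimage.feature import peak_local_max

from .density import rotate_image, shift_image

logger = logging.getLogger(__name__)

__all__ = [
    "ParticleStack",
    "ClassAverage",
    "ClassMatch",
    "StateCount",
    "dog_pick",
    "extract_particles",
    "classify_2d",
    "match_class_averages",
    "count_state_ratio",
    "soft_circular_mask",
]


@dataclass
class ParticleStack:
    """Boxed particle images (P, N, N) with pixel size and stable ids."""

    images: np.ndarray
    pixel_size: float
    ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float64)
        if self.images.ndim != 3 or self.images.shape[1] != self.images.shape[2]:
            raise ValueError("particle stack must be (P, N, N)")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.ids is None:
            self.ids = np.arange(len(self.images))
        self.ids = np.asarray(self.ids, dtype=int)
        if len(self.ids) != len(self.images):
            raise ValueError("ids and images differ in length")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def box(self) -> int:
        return self.images.shape[1]


@dataclass
class ClassAverage:
    """Mean of mutually aligned member particles."""

    image: np.ndarray
    member_ids: list[int] = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.member_ids)


@dataclass(frozen=True)
class ClassMatch:
    """Best library reference for one class average."""

    class_id: int
    reference_id: str
    in_plane_rotation: float
    shift: tuple[int, int]
    ncc: float


@dataclass(frozen=True)
class StateCount:
    """Particle counts for two states with the A-fraction confidence interval."""

    ratio: float
    count_a: int
    count_b: int
    ci_low: float
    ci_high: float


def soft_circular_mask(n: int, radius_frac: float = 0.45, edge_px: float = 3.0) -> np.ndarray:
    """Soft-edged circular mask: 1 inside, cosine falloff over ``edge_px``."""
    c = n / 2.0
    yy, xx = np.indices((n, n))
    r = np.sqrt((yy - c) ** 2 + (xx - c) ** 2)
    radius = radius_frac * n
    t = np.clip((radius - r) / edge_px + 1.0, 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * t))


# ---------------------------------------------------------------------------
# picking and extraction
# ---------------------------------------------------------------------------

def dog_pick(
    micrograph,
    r_min: float,
    r_max: float,
    threshold: float = 3.0,
    min_distance: int = 20,
) -> np.ndarray:
    """Difference-of-Gaussians particle picking.

    The band-pass response ``G(sigma1) - G(sigma2)`` with ``sigma1 =
    r_min/sqrt(2)`` and ``sigma2 = r_max/sqrt(2)`` peaks on bright blobs with
    radii between r_min and r_max (particles are high intensity by package
    convention).  Local maxima above ``threshold`` times the response's
    standard deviation are kept, suppressing weaker peaks within
    ``min_distance`` pixels of a stronger one.  Returns centers as an (M, 2)
    array of (x, y) pixel coordinates ordered by decreasing response.
    """
    if r_min >= r_max:
        raise ValueError("r_min must be smaller than r_max")
    img = np.asarray(getattr(micrograph, "image", micrograph), dtype=np.float64)
    s1 = r_min / np.sqrt(2.0)
    s2 = r_max / np.sqrt(2.0)
    resp = ndimage.gaussian_filter(img, s1) - ndimage.gaussian_filter(img, s2)
    sd = resp.std()
    if sd == 0:
        return np.empty((0, 2), dtype=int)
    peaks = peak_local_max(
        resp,
        min_distance=int(min_distance),
        threshold_abs=threshold * sd,
        exclude_border=False,
    )
    return peaks[:, ::-1].copy()  # (row, col) -> (x, y)


def extract_particles(
    micrograph, centers: np.ndarray, box: int, pixel_size: float = 1.0
) -> ParticleStack:
    """Cut square boxes around picked centers; skip boxes that cross an edge."""
    if box % 2 != 0:
        raise ValueError("box size must be even")
    img = np.asarray(getattr(micrograph, "image", micrograph), dtype=np.float64)
    if box > min(img.shape):
        raise ValueError("box larger than micrograph")
    h = box // 2
    boxes, kept = [], []
    skipped = 0
    for i, (cx, cy) in enumerate(np.asarray(centers, dtype=int)):
        if cx - h < 0 or cy - h < 0 or cx + h > img.shape[1] or cy + h > img.shape[0]:
            skipped += 1
            continue
        boxes.append(img[cy - h : cy + h, cx - h : cx + h])
        kept.append(i)
    if skipped:
        logger.info("extract_particles: skipped %d center(s) too close to an edge", skipped)
    images = np.stack(boxes) if boxes else np.empty((0, box, box))
    return ParticleStack(images, pixel_size, np.array(kept, dtype=int))


# ---------------------------------------------------------------------------
# alignment core
# ---------------------------------------------------------------------------

def _zero_mean_norm(
    a: np.ndarray, mask: np.ndarray | None = None
) -> tuple[np.ndarray, float]:
    """Zero-mean (mask-weighted if masked) then apply the mask.

    Subtracting the weighted mean before masking keeps the correlation
    invariant under affine intensity rescaling of the input.
    """
    if mask is None:
        a0 = a - a.mean()
    else:
        a0 = (a - (a * mask).sum() / mask.sum()) * mask
    return a0, float(np.linalg.norm(a0))


def _rotated_ffts(images: np.ndarray, rotations: np.ndarray, mask: np.ndarray | None):
    """Precompute zero-meaned rotated copies of every image and their rFFTs."""
    p, n = images.shape[0], images.shape[1]
    nrot = len(rotations)
    rot_imgs = np.empty((p, nrot, n, n), dtype=np.float32)
    norms = np.empty((p, nrot), dtype=np.float64)
    for j, ang in enumerate(rotations):
        for i in range(p):
            im = images[i] if ang == 0.0 else rotate_image(images[i], ang)
            im0, _ = _zero_mean_norm(im, mask)
            rot_imgs[i, j] = im0
            # norm of the float32-stored copy, so ncc stays <= 1 exactly
            norms[i, j] = np.linalg.norm(rot_imgs[i, j].astype(np.float64))
    ffts = np.fft.rfft2(rot_imgs.astype(np.float64))
    return rot_imgs, ffts, norms


def _shift_window(n: int, max_shift: int) -> np.ndarray:
    """Boolean (n, n) window of circular-shift indices within +-max_shift."""
    idx = np.fft.fftfreq(n, d=1.0 / n).astype(int)  # 0,1,...,-1
    ok = np.abs(idx) <= max_shift
    return np.outer(ok, ok)


def _align_stack_to_refs(
    images: np.ndarray,
    refs: np.ndarray,
    angular_step: float,
    max_shift: int,
    mask: np.ndarray | None = None,
    precomp=None,
):
    """Best (ref, rotation, shift, ncc) per image over an exhaustive search.

    Returns arrays: ref_idx (P,), rot_deg (P,), dx (P,), dy (P,), ncc (P,).
    ``precomp`` may carry the cached output of :func:`_rotated_ffts` so that
    iterative classification does not re-rotate particles.
    """
    n = images.shape[1]
    rotations = np.arange(0.0, 360.0, angular_step)
    if precomp is None:
        precomp = _rotated_ffts(images, rotations, mask)
    _, ffts, norms = precomp
    p, nrot = norms.shape
    window = _shift_window(n, int(max_shift))
    sidx = np.fft.fftfreq(n, d=1.0 / n).astype(int)

    best_ncc = np.full(p, -np.inf)
    best = np.zeros((p, 4))  # ref, rotidx, dy, dx
    for r, ref in enumerate(refs):
        ref0, nref = _zero_mean_norm(np.asarray(ref, dtype=np.float64), mask)
        if nref == 0:
            continue
        fref = np.fft.rfft2(ref0)
        # cc[i, j, sy, sx] = sum_q rot_img[i,j](q) * ref(q + s)
        cc = np.fft.irfft2(np.conj(ffts) * fref[None, None], s=(n, n))
        denom = np.where(norms > 0, norms, np.inf)
        cc /= denom[:, :, None, None] * nref  # normalized before the argmax
        cc = np.where(window[None, None], cc, -np.inf)
        flat = cc.reshape(p, nrot * n * n)
        am = flat.argmax(axis=1)
        ncc = flat[np.arange(p), am]
        jj, rest = np.divmod(am, n * n)
        syy, sxx = np.divmod(rest, n)
        upd = ncc > best_ncc
        best_ncc[upd] = ncc[upd]
        best[upd, 0] = r
        best[upd, 1] = jj[upd]
        best[upd, 2] = sidx[syy[upd]]
        best[upd, 3] = sidx[sxx[upd]]
    ref_idx = best[:, 0].astype(int)
    rot_deg = rotations[best[:, 1].astype(int)]
    dy = best[:, 2].astype(int)
    dx = best[:, 3].astype(int)
    return ref_idx, rot_deg, dx, dy, best_ncc


def _apply_alignment(img: np.ndarray, rot: float, dx: int, dy: int) -> np.ndarray:
    out = rotate_image(img, rot) if rot != 0.0 else img
    if dx or dy:
        out = shift_image(out, dx, dy)
    return out


# ---------------------------------------------------------------------------
# 2D classification
# ---------------------------------------------------------------------------

def classify_2d(
    stack: ParticleStack,
    K: int,
    angular_step: float = 15.0,
    max_shift: int = 4,
    n_iter: int = 10,
    seed: int = 0,
):
    """Reference-free 2D alignment and classification.

    Starts from a seeded random partition into K classes and alternates
    (a) exhaustive alignment of every particle against every class average,
    (b) assignment to the best-correlating class, and (c) recomputation of
    class averages from the aligned members.  Stops after ``n_iter``
    iterations or when assignments no longer change.  Empty classes are
    reseeded from the worst-fitting particles.

    Returns ``(classes, assignments, alignments)`` where ``classes`` is a
    list of :class:`ClassAverage`, ``assignments`` maps particle index to
    class index, and ``alignments`` is a (P, 4) array of (rotation_deg, dx,
    dy, ncc) per particle.
    """
    p = len(stack)
    if K < 1 or K > p:
        raise ValueError("K must satisfy 1 <= K <= number of particles")
    rng = np.random.default_rng(seed)
    images = stack.images
    n = stack.box
    rotations = np.arange(0.0, 360.0, angular_step)
    precomp = _rotated_ffts(images, rotations, None)

    perm = rng.permutation(p)
    assignments = np.empty(p, dtype=int)
    assignments[perm] = np.arange(p) % K
    averages = np.stack([images[assignments == k].mean(axis=0) for k in range(K)])
    alignments = np.zeros((p, 4))

    for _ in range(n_iter):
        ref_idx, rot_deg, dx, dy, ncc = _align_stack_to_refs(
            images, averages, angular_step, max_shift, precomp=precomp
        )
        new_assign = ref_idx.copy()
        # reseed empty classes from the worst-fitting particles
        empty = [k for k in range(K) if not np.any(new_assign == k)]
        if empty:
            order = np.argsort(ncc)  # worst first
            cursor = 0
            for k in empty:
                while cursor < p and np.sum(new_assign == new_assign[order[cursor]]) <= 1:
                    cursor += 1
                if cursor >= p:
                    break
                pid = order[cursor]
                new_assign[pid] = k
                rot_deg[pid] = 0.0
                dx[pid] = dy[pid] = 0
                cursor += 1
        unchanged = np.array_equal(new_assign, assignments)
        assignments = new_assign
        alignments = np.column_stack([rot_deg, dx, dy, ncc])
        aligned = np.stack(
            [
                _apply_alignment(images[i], rot_deg[i], int(dx[i]), int(dy[i]))
                for i in range(p)
            ]
        )
        averages = np.stack(
            [
                aligned[assignments == k].mean(axis=0)
                if np.any(assignments == k)
                else np.zeros((n, n))
                for k in range(K)
            ]
        )
        if unchanged:
            break

    classes = [
        ClassAverage(averages[k], [int(i) for i in stack.ids[assignments == k]])
        for k in range(K)
    ]
    return classes, assignments, alignments


# ---------------------------------------------------------------------------
# class identification against a reprojection library
# ---------------------------------------------------------------------------

def match_class_averages(
    classes,
    reference_library,
    angular_step: float = 10.0,
    max_shift: int = 4,
) -> list[ClassMatch]:
    """Identify class averages by exhaustive matching to reprojections.

    ``reference_library`` is a list of ``(reference_id, ProjectionImage)``
    pairs (or bare 2D arrays).  For every class the full grid of in-plane
    rotations and shifts is searched against every reference; the best
    normalized cross-correlation wins.  Images are compared under a soft
    circular mask of radius 0.45x the box to suppress corner artefacts.
    """
    if not reference_library:
        raise ValueError("empty reference library")
    class_imgs = np.stack(
        [np.asarray(getattr(c, "image", c), dtype=np.float64) for c in classes]
    )
    n = class_imgs.shape[1]
    ids, refs = [], []
    for rid, ref in reference_library:
        arr = np.asarray(getattr(ref, "image", ref), dtype=np.float64)
        if arr.shape != (n, n):
            zoom = n / arr.shape[0]
            arr = ndimage.zoom(arr, zoom, order=1)
        ids.append(rid)
        refs.append(arr)
    mask = soft_circular_mask(n)
    ref_idx, rot_deg, dx, dy, ncc = _align_stack_to_refs(
        class_imgs, np.stack(refs), angular_step, max_shift, mask=mask
    )
    return [
        ClassMatch(
            class_id=i,
            reference_id=ids[ref_idx[i]],
            in_plane_rotation=float(rot_deg[i]),
            shift=(int(dx[i]), int(dy[i])),
            ncc=float(ncc[i]),
        )
        for i in range(len(classes))
    ]


# ---------------------------------------------------------------------------
# particle-count stoichiometry
# ---------------------------------------------------------------------------

def count_state_ratio(
    assignments: np.ndarray,
    class_to_state: dict[int, str],
    stateA: str,
    stateB: str,
) -> StateCount:
    """Particle-count ratio between two structural states.

    Sums particles over classes labelled ``stateA`` and ``stateB`` (the
    caller decides which classes represent which state, e.g. restricting to
    side views) and returns the A:B ratio with raw counts and an exact 95%
    Clopper-Pearson interval on the A fraction.
    """
    assignments = np.asarray(assignments, dtype=int)
    count_a = int(sum(class_to_state.get(int(k)) == stateA for k in assignments))
    count_b = int(sum(class_to_state.get(int(k)) == stateB for k in assignments))
    if count_a + count_b == 0 or count_b == 0 or count_a == 0:
        raise ValueError("both states need at least one assigned particle")
    n = count_a + count_b
    lo = float(stats.beta.ppf(0.025, count_a, n - count_a + 1)) if count_a > 0 else 0.0
    hi = float(stats.beta.ppf(0.975, count_a + 1, n - count_a)) if count_a < n else 1.0
    return StateCount(count_a / count_b, count_a, count_b, lo, hi)
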