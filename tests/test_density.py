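"""Volume numerics: I/O, rasterization, filtering, projection, alignment."""

import numpy as np
import pytest

import gemmi

from shotgunem.density import (
    DensityVolume,
    Orientation,
    ProjectionImage,
    align_volumes,
    atoms_to_density,
    backproject_reconstruct,
    load_density,
    lowpass,
    project,
    ring_diameter,
    rotate_image,
    rotate_volume,
    save_density,
    volume_cc,
)
from shotgunem.synthdata import make_phantom, render_particle_stack


def make_structure(atom_xyz):
    """Tiny in-memory atomic model for rasterization tests."""
    st = gemmi.Structure()
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for i, (x, y, z) in enumerate(atom_xyz):
        res = gemmi.Residue()
        res.name = "ALA"
        res.seqid = gemmi.SeqId(i + 1, " ")
        a = gemmi.Atom()
        a.name = "CA"
        a.element = gemmi.Element("C")
        a.pos = gemmi.Position(x, y, z)
        res.add_atom(a)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    return st


def binary_ball(n=64, vox=3.0, radius=60.0):
    ax = (np.arange(n) - n / 2) * vox
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    return DensityVolume((np.sqrt(xx**2 + yy**2 + zz**2) <= radius).astype(float), vox)


class TestMRCRoundtrip:
    def test_roundtrip_to_float32(self, tmp_path, barrel):
        p = tmp_path / "b.mrc"
        save_density(barrel.volume, p)
        back = load_density(p)
        assert np.allclose(back.grid, barrel.volume.grid.astype(np.float32), atol=1e-6)

    def test_voxel_size_preserved(self, tmp_path):
        v = DensityVolume(np.random.default_rng(0).random((16, 16, 16)), 3.62)
        p = tmp_path / "v.mrc"
        save_density(v, p)
        assert load_density(p).voxel_size == pytest.approx(3.62, abs=1e-4)

    def test_truncated_file_raises_format_error(self, tmp_path):
        p = tmp_path / "bad.mrc"
        p.write_bytes(b"not an mrc map at all")
        with pytest.raises(ValueError, match="bad.mrc"):
            load_density(p)


class TestAtomsToDensity:
    def test_single_atom_peak_at_center(self):
        v = atoms_to_density(make_structure([(5.0, -3.0, 2.0)]), 32, 1.0)
        assert np.unravel_index(np.argmax(v.grid), v.grid.shape) == (16, 16, 16)

    def test_linearity(self):
        two = atoms_to_density(make_structure([(2, 0, 0), (-2, 0, 0)]), 32, 1.0,
                               center=False)
        a = atoms_to_density(make_structure([(2, 0, 0)]), 32, 1.0, center=False)
        b = atoms_to_density(make_structure([(-2, 0, 0)]), 32, 1.0, center=False)
        assert np.abs(two.grid - (a.grid + b.grid)).max() < 1e-10

    def test_total_integral_matches_gaussian_mass(self):
        sigma, vox = 2.0, 1.0
        atoms = [(0, 0, 0), (4, 2, -1), (-3, -3, 3)]
        v = atoms_to_density(make_structure(atoms), 48, vox, sigma=sigma)
        expect = len(atoms) * (2 * np.pi) ** 1.5 * sigma**3 / vox**3
        assert v.grid.sum() == pytest.approx(expect, rel=0.01)

    def test_structure_too_large_rejected(self):
        with pytest.raises(ValueError, match="does not fit"):
            atoms_to_density(make_structure([(0, 0, 0), (200, 0, 0)]), 32, 1.0)


class TestLowpass:
    def test_constant_volume_unchanged(self):
        v = DensityVolume(np.full((16, 16, 16), 2.5), 4.0)
        out = lowpass(v, 30.0)
        assert np.abs(out.grid - 2.5).max() < 1e-10

    def test_white_noise_power_above_cutoff_suppressed(self):
        rng = np.random.default_rng(1)
        v = DensityVolume(rng.normal(size=(32, 32, 32)), 4.0)
        res = 30.0
        out = lowpass(v, res)
        n, vox = 32, 4.0
        f = np.sqrt(
            sum(
                g**2
                for g in np.meshgrid(*([np.fft.fftfreq(n, d=vox)] * 3), indexing="ij")
            )
        )
        w = 2.0 / (n * vox)
        ps = np.abs(np.fft.fftn(out.grid)) ** 2
        frac = ps[f > 1.0 / res + w].sum() / ps.sum()
        assert frac < 1e-6

    def test_idempotent_outside_edge_band(self):
        # gain is exactly 0 or 1 outside the raised-cosine edge, so repeated
        # filtering only changes the edge band
        rng = np.random.default_rng(2)
        n, vox, res = 32, 4.0, 30.0
        v = DensityVolume(rng.normal(size=(n, n, n)), vox)
        once = np.fft.fftn(lowpass(v, res).grid)
        twice = np.fft.fftn(lowpass(lowpass(v, res), res).grid)
        f = np.sqrt(
            sum(
                g**2
                for g in np.meshgrid(*([np.fft.fftfreq(n, d=vox)] * 3), indexing="ij")
            )
        )
        w = 2.0 / (n * vox)
        outside = (f < 1.0 / res - w) | (f > 1.0 / res + w)
        num = np.linalg.norm((twice - once)[outside])
        den = np.linalg.norm(once[outside])
        assert num / den < 1e-6

    def test_at_nyquist_rejected(self):
        v = DensityVolume(np.zeros((16, 16, 16)), 4.0)
        with pytest.raises(ValueError):
            lowpass(v, 8.0)


class TestProjection:
    def test_sphere_projections_orientation_invariant(self):
        sph = make_phantom("sphere", 64, 3.0, 120.0)
        ref = project(sph.volume, Orientation(0, 0, 0)).image
        for euler in [(77, 45, 10), (200, 120, 300)]:
            img = project(sph.volume, Orientation(*euler)).image
            rel = np.sqrt(((img - ref) ** 2).mean()) / np.sqrt((ref**2).mean())
            assert rel < 0.01

    def test_mass_conserved(self, capped_barrel):
        img = project(capped_barrel.volume, Orientation(33, 61, 120)).image
        assert img.sum() == pytest.approx(capped_barrel.volume.grid.sum(), rel=0.005)

    def test_ball_central_profile_matches_chord_length(self):
        n, vox, r = 64, 3.0, 60.0
        ball = binary_ball(n, vox, r)
        img = project(ball, Orientation(0, 0, 0)).image * vox
        ax = (np.arange(n) - n / 2) * vox
        expect = np.where(np.abs(ax) <= r,
                          2 * np.sqrt(np.maximum(r**2 - ax**2, 0.0)), 0.0)
        rms = np.sqrt(((img[n // 2] - expect) ** 2).mean()) / (2 * r)
        assert rms < 0.03

    def test_projection_rotation_commutation(self):
        cap = make_phantom("capped_barrel", 48, 4.0, 100.0)
        p1 = project(cap.volume, Orientation(25, 60, 40)).image
        p2 = rotate_image(project(cap.volume, Orientation(0, 60, 40)).image, 25)
        rel = np.sqrt(((p1 - p2) ** 2).mean()) / np.sqrt((p1**2).mean())
        assert rel < 0.01


class TestBackprojection:
    def test_sphere_fidelity_and_monotone_information(self, sphere):
        stack, _, oris = render_particle_stack([sphere], [1.0], 200, 0.0, 0, seed=1)
        ccs = []
        for n in (1, 10, 50, 200):
            rec = backproject_reconstruct(stack.images[:n], oris[:n],
                                          sphere.volume.voxel_size)
            ccs.append(np.corrcoef(rec.grid.ravel(),
                                   sphere.volume.grid.ravel())[0, 1])
        assert ccs[-1] >= 0.9
        assert ccs[0] < ccs[-1]
        assert all(b >= a - 1e-6 for a, b in zip(ccs[1:], ccs[2:]))

    def test_zero_stack_gives_zero_volume(self):
        images = np.zeros((4, 16, 16))
        oris = [Orientation(0, 0, 0)] * 4
        rec = backproject_reconstruct(images, oris, 1.0)
        assert np.all(rec.grid == 0)

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            backproject_reconstruct([], [], 1.0)


class TestAlignVolumes:
    def test_self_alignment_identity(self, capped_barrel):
        ori, shift, cc = align_volumes(capped_barrel.volume, capped_barrel.volume,
                                       30.0, 30.0)
        assert (ori.rot, ori.tilt, ori.psi) == (0.0, 0.0, 0.0)
        assert np.all(shift == 0)
        assert cc == pytest.approx(1.0, abs=1e-6)

    def test_recovers_30_degree_z_rotation(self, capped_barrel):
        moved = DensityVolume(
            rotate_volume(capped_barrel.volume.grid, Orientation(0, 0, 30).matrix()),
            capped_barrel.volume.voxel_size,
        )
        ori, shift, cc = align_volumes(capped_barrel.volume, moved, 15.0, 30.0)
        # inverse in-plane angle, modulo the rot/psi degeneracy at tilt 0
        ang = (ori.rot + ori.psi) % 360.0
        assert min(abs(ang - 330.0), abs(ang - 330.0 + 360), abs(ang - 330.0 - 360)) <= 15.0
        assert cc >= 0.95

    def test_cross_shape_cc_below_self(self, barrel, heptamer):
        _, _, cc_cross = align_volumes(barrel.volume, heptamer.volume, 30.0, 30.0)
        _, _, cc_b = align_volumes(barrel.volume, barrel.volume, 30.0, 30.0)
        _, _, cc_h = align_volumes(heptamer.volume, heptamer.volume, 30.0, 30.0)
        assert cc_cross < cc_b and cc_cross < cc_h

    def test_bad_angular_step_rejected(self, barrel):
        with pytest.raises(ValueError):
            align_volumes(barrel.volume, barrel.volume, 60.0, 30.0)


class TestVolumeCC:
    def test_self_is_one_and_negation_minus_one(self, barrel):
        assert volume_cc(barrel.volume, barrel.volume) == pytest.approx(1.0)
        neg = DensityVolume(-barrel.volume.grid, barrel.volume.voxel_size)
        assert volume_cc(barrel.volume, neg) == pytest.approx(-1.0)

    def test_matches_brute_force_pearson_on_toy(self):
        rng = np.random.default_rng(3)
        a = DensityVolume(rng.normal(size=(8, 8, 8)) + 1.0, 1.0)
        b = DensityVolume(rng.normal(size=(8, 8, 8)) + 1.0, 1.0)
        cc = volume_cc(a, b)
        # recompute the mask and the Pearson by hand
        def mad_sigma(x):
            med = np.median(x)
            return 1.4826 * np.median(np.abs(x - med))

        masks = [v.grid > 3 * mad_sigma(v.grid) for v in (a, b)]
        mask = masks[0] if masks[0].sum() >= masks[1].sum() else masks[1]
        x, y = a.grid[mask], b.grid[mask]
        expect = np.mean((x - x.mean()) * (y - y.mean())) / (x.std() * y.std())
        assert cc == pytest.approx(expect, abs=1e-12)

    def test_affine_rescale_invariance(self, barrel):
        scaled = DensityVolume(3.0 * barrel.volume.grid + 0.5,
                               barrel.volume.voxel_size)
        assert volume_cc(barrel.volume, scaled) == pytest.approx(1.0, abs=1e-9)

    def test_grid_mismatch_rejected(self, barrel):
        other = DensityVolume(np.zeros((16, 16, 16)), barrel.volume.voxel_size)
        with pytest.raises(ValueError):
            volume_cc(barrel.volume, other)


class TestRingDiameter:
    def test_synthetic_annulus(self):
        # sharp annulus isolates the 20%-of-max measurement rule itself
        import warnings

        n, vox = 96, 2.0
        ax = (np.arange(n) - n / 2) * vox
        yy, xx = np.meshgrid(ax, ax, indexing="ij")
        rho = np.hypot(xx, yy)
        img = ((rho >= 40.0) & (rho <= 60.0)).astype(float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d = ring_diameter(ProjectionImage(img, vox))
        assert abs(d - 120.0) <= 2 * vox

    def test_lowpassed_annulus_within_field_tolerance(self):
        # after a 30 A low-pass the 20% crossing moves outward slightly;
        # the measurement stays within the +-10 A band used for real maps
        n, vox = 96, 2.0
        ax = (np.arange(n) - n / 2) * vox
        yy, xx = np.meshgrid(ax, ax, indexing="ij")
        rho = np.hypot(xx, yy)
        img = ((rho >= 40.0) & (rho <= 60.0)).astype(float)
        d = ring_diameter(lowpass(ProjectionImage(img, vox), 30.0))
        assert abs(d - 120.0) <= 10.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            ring_diameter(ProjectionImage(np.zeros((32, 32)), 2.0))

    def test_warns_on_unfiltered_sharp_input(self):
        rng = np.random.default_rng(0)
        img = rng.normal(size=(64, 64)) + 1.0
        with pytest.warns(UserWarning, match="low-pass"):
            ring_diameter(ProjectionImage(img, 3.0))
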