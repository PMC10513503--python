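"""Boundary-element forward model against analytic sphere oracles."""

import dataclasses

import numpy as np
import pytest
import trimesh as _trimesh
from scipy.special import eval_legendre, lpmv

from ecgidipole import (
    PhantomSpec,
    TriMesh,
    VolumeConductor,
    assemble_bem,
    build_transfer_matrix,
    build_transfer_stack,
    forward_bsp,
    infinite_medium_potential,
    load_transfer_stack,
    make_phantom,
    place_electrode_strips,
    save_transfer_stack,
)


def sphere_surface_series(points, R, sigma, b, moment, n_terms=60):
    """Legendre-series surface potential of a dipole at (0, 0, b) inside an
    insulated homogeneous sphere of radius R — the independent oracle.

    phi = 1/(4 pi sigma R^2) * sum_n (2n+1)/n * (b/R)^(n-1)
            * [ n p_r P_n(cos t) + p_t P_n^1(cos t) cos(az) ]
    with the dipole's radial component p_r along z, tangential p_t along x,
    and P_n^1 taken without the Condon-Shortley phase (hence -lpmv).
    """
    x, y, z = np.asarray(points).T
    r = np.linalg.norm(points, axis=1)
    ct = z / r
    az = np.arctan2(y, x)
    f = b / R
    p_r, p_t = moment[2], moment[0]
    out = np.zeros(len(points))
    for n in range(1, n_terms + 1):
        out += (2 * n + 1) / n * f ** (n - 1) * (
            n * p_r * eval_legendre(n, ct) - p_t * lpmv(1, n, ct) * np.cos(az)
        )
    return out / (4 * np.pi * sigma * R**2)


def sphere_mesh(sub, R):
    tm = _trimesh.creation.icosphere(subdivisions=sub, radius=R)
    return TriMesh(np.asarray(tm.vertices), np.asarray(tm.faces), "sphere").validate()


class TestInfiniteMedium:
    def test_zero_moment(self, rng):
        pts = rng.normal(size=(5, 3))
        np.testing.assert_array_equal(
            infinite_medium_potential([0, 0, 0], [0, 0, 0], pts, 0.2), np.zeros(5)
        )

    def test_on_axis_closed_form(self):
        p, d, sigma = 2.0, 5.0, 0.3
        phi = infinite_medium_potential([0, 0, 0], [0, 0, p], [[0, 0, d], [0, 0, -d]], sigma)
        want = p / (4 * np.pi * sigma * d**2)
        np.testing.assert_allclose(phi, [want, -want], rtol=1e-12)

    def test_conductivity_scaling(self, rng):
        pts = rng.normal(scale=10, size=(7, 3))
        a = infinite_medium_potential([1, 0, 0], [1, 2, 3], pts, 0.2)
        b = infinite_medium_potential([1, 0, 0], [1, 2, 3], pts, 0.4)
        np.testing.assert_allclose(a, 2 * b, rtol=1e-12)

    def test_coincident_point_raises(self):
        with pytest.raises(ValueError, match="coincides"):
            infinite_medium_potential([1, 1, 1], [1, 0, 0], [[1, 1, 1]], 0.2)


class TestSphereOracle:
    def test_zero_mean_reference(self, sphere_system):
        system, R, sigma = sphere_system
        phi = system.solve_sources(np.array([[10.0, -5.0, 20.0]]))[0]
        np.testing.assert_allclose(phi.sum(axis=0), 0.0, atol=1e-12)

    def test_central_dipole_closed_form(self, sphere_system):
        """Unit central dipole: surface potential 3 p cos(theta)/(4 pi sigma R^2)."""
        system, R, sigma = sphere_system
        phi = system.solve_sources(np.zeros((1, 3)))[0]
        rhat = system.all_vertices / R
        exact = 3.0 * rhat / (4 * np.pi * sigma * R**2)
        exact -= exact.mean(axis=0)
        err = np.linalg.norm(phi - exact) / np.linalg.norm(exact)
        assert err < 0.05

    def test_eccentric_dipole_series(self, sphere_system):
        system, R, sigma = sphere_system
        src = np.array([0.0, 0.0, 0.55 * R])
        moment = np.array([1.0, 0.0, 1.0]) / np.sqrt(2)
        phi = system.solve_sources(src[None])[0] @ moment
        exact = sphere_surface_series(system.all_vertices, R, sigma, src[2], moment)
        exact -= exact.mean()
        err = np.linalg.norm(phi - exact) / np.linalg.norm(exact)
        assert err < 0.05

    def test_refinement_decreases_error(self):
        """Eccentric-dipole error shrinks monotonically over 3 refinement levels."""
        R, sigma = 100.0, 0.2
        src = np.array([0.0, 0.0, 50.0])
        moment = np.array([1.0, 0.0, 1.0]) / np.sqrt(2)
        errs = []
        for sub in (2, 3, 4):
            torso = sphere_mesh(sub, R)
            vc = VolumeConductor((torso,), [sigma], [0.0], place_electrode_strips(torso, 4, 4))
            system = assemble_bem(vc)
            phi = system.solve_sources(src[None])[0] @ moment
            exact = sphere_surface_series(torso.vertices, R, sigma, src[2], moment)
            exact -= exact.mean()
            errs.append(np.linalg.norm(phi - exact) / np.linalg.norm(exact))
        assert errs[0] > errs[1] > errs[2]
        assert errs[1] < 0.05


class TestTransferStack:
    def test_block_shapes_and_order(self, small_phantom):
        _, vc, heart, system, stack = small_phantom
        assert stack.blocks.shape == (heart.n_vertices, 128, 3)
        np.testing.assert_array_equal(stack.positions, heart.vertices)

    def test_permuting_sources_permutes_blocks(self, sphere_system, rng):
        system, R, sigma = sphere_system
        pts = rng.normal(scale=0.2 * R, size=(6, 3))
        perm = rng.permutation(6)
        a = system.solve_sources(pts)
        b = system.solve_sources(pts[perm])
        np.testing.assert_allclose(a[perm], b, atol=1e-13)

    def test_full_column_rank(self, small_phantom):
        _, _, _, _, stack = small_phantom
        s3 = np.linalg.svd(stack.blocks, compute_uv=False)[:, 2]
        assert np.all(s3 > 0)

    def test_source_outside_torso_rejected(self, sphere_system):
        system, R, _ = sphere_system
        with pytest.raises(ValueError, match="outside the torso"):
            build_transfer_matrix(system, [2 * R, 0, 0])

    def test_source_inside_organ_rejected(self):
        spec = PhantomSpec(include_lungs=True)
        vc, heart = make_phantom(spec)
        system = assemble_bem(vc)
        with pytest.raises(ValueError, match="inside organ"):
            build_transfer_matrix(system, np.asarray(spec.lung_centers[0]))

    def test_hdf5_round_trip(self, small_phantom, tmp_path):
        _, _, _, _, stack = small_phantom
        p = tmp_path / "stack.h5"
        save_transfer_stack(stack, p)
        back = load_transfer_stack(p)
        np.testing.assert_array_equal(back.blocks, stack.blocks)
        np.testing.assert_array_equal(back.positions, stack.positions)
        assert back.conductor_id == stack.conductor_id


class TestForwardMap:
    def test_zero_moments_zero_map(self, small_phantom):
        _, _, _, _, stack = small_phantom
        bsp = forward_bsp(stack.blocks[0], np.zeros((3, 5)))
        np.testing.assert_array_equal(bsp.potentials, 0.0)

    def test_identity_moments_reproduce_columns(self, small_phantom):
        _, _, _, _, stack = small_phantom
        bsp = forward_bsp(stack.blocks[3], np.eye(3))
        np.testing.assert_array_equal(bsp.potentials, stack.blocks[3])

    def test_linearity(self, small_phantom, rng):
        _, _, _, _, stack = small_phantom
        m1, m2 = rng.normal(size=(2, 3, 30))
        a, b = 0.7, -2.3
        lhs = forward_bsp(stack.blocks[5], a * m1 + b * m2).potentials
        rhs = a * forward_bsp(stack.blocks[5], m1).potentials + b * forward_bsp(stack.blocks[5], m2).potentials
        np.testing.assert_allclose(lhs, rhs, rtol=1e-12, atol=1e-15)

    def test_shape_mismatch(self, small_phantom):
        _, _, _, _, stack = small_phantom
        with pytest.raises(ValueError, match="shape"):
            forward_bsp(stack.blocks[0], np.zeros((2, 5)))


class TestConductorConsistency:
    def test_homogeneous_limit(self, rng):
        """Setting every organ's conductivity ratio to 1 reproduces the
        homogeneous transfer matrix."""
        spec = PhantomSpec(include_lungs=True, include_cavities=True)
        vc, heart = make_phantom(spec)
        sigma = spec.torso_conductivity
        vc_unit = dataclasses.replace(
            vc, sigma_in=np.full(vc.n_surfaces, sigma), sigma_out=np.r_[0.0, np.full(vc.n_surfaces - 1, sigma)]
        )
        vc_hom = VolumeConductor((vc.surfaces[0],), [sigma], [0.0], vc.montage)
        src = heart.vertices[42]
        t_unit = build_transfer_matrix(vc_unit, src)
        t_hom = build_transfer_matrix(vc_hom, src)
        assert np.linalg.norm(t_unit - t_hom) / np.linalg.norm(t_hom) < 1e-6

    def test_bad_conductor_configs(self, sphere_conductor):
        vc, R, sigma = sphere_conductor
        torso = vc.surfaces[0]
        with pytest.raises(ValueError, match="insulating"):
            VolumeConductor((torso,), [sigma], [0.1], vc.montage)
        with pytest.raises(ValueError, match="positive"):
            VolumeConductor((torso,), [0.0], [0.0], vc.montage)
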