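import numpy as np
import pytest

from neodot.head_forward import (
    PhotonDiffusionModel,
    analytic_semi_infinite,
    build_jacobian,
    build_jacobian_set,
    default_tissue_properties,
    finite_difference_jacobian,
    fresnel_parameter,
    graded_coords,
    make_layer_mesh,
    make_slab_mesh,
    place_optodes_hemisphere,
    read_msh,
    stack_multispectral,
    write_msh,
)
from neodot.haemoglobin import default_extinction_table
from neodot.probe_and_io import ProbeGeometry


GREY = {"grey": {780.0: (0.01, 0.5), 850.0: (0.009, 0.45)}}


@pytest.fixture(scope="module")
def tiny_slab():
    """Single-tissue 5 mm slab small enough for brute-force checks."""
    xs = np.linspace(-30, 30, 13)
    ys = np.linspace(-30, 30, 13)
    zs = np.linspace(0, 30, 7)
    return make_slab_mesh(xs, ys, zs, layer_thicknesses=None,
                          tissue_names=("grey",), properties=GREY)


@pytest.fixture(scope="module")
def tiny_probe():
    return ProbeGeometry(
        source_positions=[[10.0, 0.0, 0.0], [-10.0, 0.0, 0.0]],
        detector_positions=[[0.0, 10.0, 0.0], [0.0, -10.0, 0.0]],
        channel_list=[[0, 0], [0, 1], [1, 0], [1, 1]],
        wavelengths=[780.0, 850.0],
    )


class TestMeshGeometry:
    def test_graded_coords(self):
        c = graded_coords(-5.0, 45.0, 1.0, -60.0, 100.0)
        assert np.all(np.diff(c) > 0)
        core = c[(c >= -5.0) & (c <= 45.0)]
        assert np.allclose(np.diff(core), 1.0)
        assert c[0] == -60.0 and c[-1] == 100.0

    def test_slab_volume_exact(self, tiny_slab):
        # Kuhn subdivision tiles each hexahedral cell exactly
        assert tiny_slab.tet_volumes().sum() == pytest.approx(60 * 60 * 30, rel=1e-12)
        assert tiny_slab.node_volumes().sum() == pytest.approx(60 * 60 * 30, rel=1e-12)

    def test_positive_volumes(self, tiny_slab):
        assert np.all(tiny_slab.tet_volumes() > 0)
        assert tiny_slab.quality_min_dihedral_deg() > 5.0

    def test_boundary_watertight(self, tiny_slab):
        faces = tiny_slab.boundary_faces()
        # boundary area equals the box surface area
        p = tiny_slab.nodes[faces]
        area = 0.5 * np.linalg.norm(
            np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
        ).sum()
        assert area == pytest.approx(2 * (60 * 60 + 60 * 30 + 60 * 30), rel=1e-12)
        # every boundary edge is shared by exactly two boundary faces
        edges = np.sort(faces[:, [[0, 1], [1, 2], [0, 2]]].reshape(-1, 2), axis=1)
        _, counts = np.unique(edges, axis=0, return_counts=True)
        assert np.all(counts == 2)

    def test_layer_labels_by_depth(self):
        xs = ys = np.linspace(-10, 10, 5)
        zs = np.linspace(0, 16, 9)
        props = default_tissue_properties()
        mesh = make_slab_mesh(xs, ys, zs, layer_thicknesses=(5.0, 2.0, 4.0),
                              properties=props)
        cz = mesh.nodes[mesh.tets].mean(axis=1)[:, 2]
        names = np.asarray(mesh.tissue_names)[mesh.tissue_label]
        assert set(names) == {"extracerebral", "csf", "grey", "white"}
        assert np.all(names[cz < 5.0] == "extracerebral")
        assert np.all(names[(cz > 5.0) & (cz < 7.0)] == "csf")
        assert np.all(names[(cz > 7.0) & (cz < 11.0)] == "grey")
        assert np.all(names[cz > 11.0] == "white")

    def test_locate_roundtrip(self, tiny_slab, rng):
        for _ in range(20):
            p = rng.uniform([-25, -25, 2], [25, 25, 25])
            ti, lam = tiny_slab.locate(p)
            assert lam.sum() == pytest.approx(1.0)
            assert np.all(lam >= 0)
            rec = lam @ tiny_slab.nodes[tiny_slab.tets[ti]]
            assert np.allclose(rec, p, atol=1e-8)

    def test_optical_coefficient_lookup(self, tiny_slab):
        mua, musp = tiny_slab.optical_coefficients(780.0)
        assert np.allclose(mua, 0.01) and np.allclose(musp, 0.5)
        with pytest.raises(KeyError):
            tiny_slab.optical_coefficients(800.0)

    def test_layer_mesh_validation(self):
        with pytest.raises(ValueError, match="coarse"):
            make_layer_mesh(target_edge_mm=8.0)
        with pytest.raises(ValueError, match="geometry_spec"):
            make_layer_mesh(geometry_spec="cube")

    def test_hemisphere_mesh(self, hemi_mesh):
        radius = 340.0 / (2 * np.pi)
        r = np.linalg.norm(hemi_mesh.nodes, axis=1)
        assert r.max() <= radius + 1e-6
        assert hemi_mesh.nodes[:, 2].min() >= -1e-9
        names = set(np.asarray(hemi_mesh.tissue_names)[hemi_mesh.tissue_label])
        assert names == {"extracerebral", "csf", "grey", "white"}
        # grey-matter surface sits beneath the scalp and CSF layers
        gm_r = np.linalg.norm(hemi_mesh.gm_nodes, axis=1)
        assert np.allclose(gm_r, radius - 7.0, atol=1.0)
        assert len(hemi_mesh.gm_tris) > 0


class TestMeshIO:
    def test_msh_roundtrip(self, tiny_slab, tmp_path):
        path = tmp_path / "mesh.msh"
        write_msh(tiny_slab, path)
        back = read_msh(path, properties=GREY)
        assert np.allclose(back.nodes, tiny_slab.nodes, atol=1e-9)
        assert np.array_equal(back.tets, tiny_slab.tets)
        assert np.array_equal(back.tissue_label, tiny_slab.tissue_label)
        assert back.tissue_names == tiny_slab.tissue_names
        assert back.meta.get("geometry") == tiny_slab.meta.get("geometry")
        assert back.refractive_index == tiny_slab.refractive_index
        assert np.allclose(
            np.asarray(back.gm_nodes).reshape(-1, 3),
            np.asarray(tiny_slab.gm_nodes).reshape(-1, 3),
            atol=1e-9,
        )


class TestFresnelAndAnalytic:
    def test_fresnel_reference_value(self):
        # Groenhuis fit at n = 1.4 gives A ~ 3.25
        assert fresnel_parameter(1.4) == pytest.approx(3.25, abs=0.15)
        # no refractive mismatch: A -> 1
        assert fresnel_parameter(1.0) == pytest.approx(1.0, abs=0.01)

    def test_monotone_decay(self):
        rho = np.linspace(10, 50, 30)
        phi = analytic_semi_infinite(rho, 0.01, 1.0)
        assert np.all(phi > 0)
        assert np.all(np.diff(phi) < 0)

    def test_image_overestimates_exact(self):
        rho = np.array([20.0, 25.0, 30.0, 35.0, 40.0])
        exact = analytic_semi_infinite(rho, 0.01, 1.0, method="exact")
        image = analytic_semi_infinite(rho, 0.01, 1.0, method="image")
        ratio = image / exact - 1.0
        assert np.all(ratio > 0.02) and np.all(ratio < 0.07)

    def test_matched_index_limits_agree(self):
        # with A ~ 1 the image construction nearly matches the exact solution
        rho = np.array([20.0, 30.0, 40.0])
        exact = analytic_semi_infinite(rho, 0.01, 1.0, n_tissue=1.0001)
        image = analytic_semi_infinite(rho, 0.01, 1.0, n_tissue=1.0001,
                                       method="image")
        assert np.allclose(image / exact, 1.0, atol=0.01)

    def test_short_separation_warns(self):
        with pytest.warns(UserWarning, match="diffusion"):
            analytic_semi_infinite(np.array([2.0]), 0.01, 1.0)

    def test_bad_method(self):
        with pytest.raises(ValueError):
            analytic_semi_infinite(np.array([20.0]), 0.01, 1.0, method="dipole")


class TestFEM:
    def test_measurement_positive_and_reciprocal(self, tiny_slab, tiny_probe):
        model = PhotonDiffusionModel(tiny_slab, 780.0)
        m_sd = model.measure(tiny_probe.source_positions[0],
                             tiny_probe.detector_positions[0])
        m_ds = model.measure(tiny_probe.detector_positions[0],
                             tiny_probe.source_positions[0])
        assert m_sd > 0
        # symmetric system matrix makes source/detector exchange exact
        assert m_sd == pytest.approx(m_ds, rel=1e-8)

    def test_fluence_decays_with_distance(self, tiny_slab):
        model = PhotonDiffusionModel(tiny_slab, 780.0)
        src = np.array([0.0, 0.0, 0.0])
        near = model.measure(src, np.array([10.0, 0.0, 0.0]))
        far = model.measure(src, np.array([20.0, 0.0, 0.0]))
        assert near > far > 0


class TestJacobian:
    def test_adjoint_matches_finite_difference(self, tiny_slab, tiny_probe):
        J, amps = build_jacobian(tiny_slab, tiny_probe, 780.0)
        assert np.all(amps > 0)
        # probe the most sensitive nodes, where FD is best conditioned
        node_ids = np.argsort(np.abs(J).max(axis=0))[-10:]
        fd = finite_difference_jacobian(tiny_slab, tiny_probe, 780.0, node_ids)
        rel = np.abs(J[:, node_ids] - fd) / np.abs(fd).max()
        assert rel.max() < 0.05

    def test_total_sensitivity_positive(self, tiny_slab, tiny_probe):
        J, _ = build_jacobian(tiny_slab, tiny_probe, 780.0)
        # increasing absorption everywhere must increase every channel's OD
        assert np.all(J.sum(axis=1) > 0)

    def test_channel_mask_zeroes_rows(self, tiny_slab, tiny_probe):
        mask = np.array([True, False, True, True])
        J, amps = build_jacobian(tiny_slab, tiny_probe, 780.0, channel_mask=mask)
        assert np.all(J[1] == 0) and amps[1] == 0
        assert np.any(J[0] != 0)

    def test_stack_multispectral_layout(self, tiny_slab, tiny_probe):
        jset = build_jacobian_set(tiny_slab, tiny_probe)
        ext = default_extinction_table()
        S = stack_multispectral(jset, ext)
        nc, nn = jset.n_channels, jset.n_nodes
        assert S.shape == (2 * nc, 2 * nn)
        E = ext.matrix(jset.wavelengths)
        assert np.allclose(S[:nc, :nn], jset.jacobians[780.0] * E[0, 0])
        assert np.allclose(S[nc:, nn:], jset.jacobians[850.0] * E[1, 1])


class TestOptodePlacement:
    def test_default_layout(self, hemi_probe):
        assert hemi_probe.n_channels == 58
        seps = hemi_probe.separations()
        assert np.all((seps >= 20.0) & (seps <= 40.0))
        radius = 340.0 / (2 * np.pi)
        for pts in (hemi_probe.source_positions, hemi_probe.detector_positions):
            assert np.allclose(np.linalg.norm(pts, axis=1), radius, atol=1e-6)

    def test_deterministic(self):
        a = place_optodes_hemisphere()
        b = place_optodes_hemisphere()
        assert np.array_equal(a.channel_list, b.channel_list)
        assert np.allclose(a.source_positions, b.source_positions)

    def test_impossible_range(self):
        with pytest.raises(ValueError, match="separation range"):
            place_optodes_hemisphere(separation_range_mm=(0.1, 0.2))
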