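"""Mesh construction, refinement, labels and cross-sections."""

import numpy as np
import pytest

from rhinoflow import (PhantomSpec, ResolutionError, box_phantom, build_mesh,
                       cross_section, generate_phantom, refine_mesh)
from rhinoflow import meshing
from rhinoflow.airway_geometry import UM, airway_metrics
from rhinoflow.meshing import (EmptySectionError, MeshSizeError, OLFACTORY,
                               SQUAMOUS, WALL)


@pytest.fixture(scope="module")
def phantom_mesh():
    return build_mesh(PhantomSpec(), 50)


class TestBuildMesh:
    def test_box_cell_counts(self):
        mesh = build_mesh(box_phantom(30_000, 1_000), 50)
        assert mesh.active.shape == (600, 20)
        assert mesh.n_cells == 600 * 20

    def test_box_volume_analytic(self):
        mesh = build_mesh(box_phantom(30_000, 1_000, depth_um=10_000), 50)
        assert mesh.total_volume() == pytest.approx(30e-3 * 1e-3 * 1e-2,
                                                    rel=0.02)

    def test_phantom_volume_matches_stack_metrics(self, phantom_mesh):
        stack = generate_phantom(PhantomSpec())
        vol = airway_metrics(stack)["volume_m3"]
        area_stack = vol / (PhantomSpec().depth * UM)
        area_mesh = phantom_mesh.total_volume() / phantom_mesh.depth
        assert area_mesh == pytest.approx(area_stack, rel=0.02)

    def test_graded_wall_layers_geometric(self):
        mesh = build_mesh(box_phantom(5_000, 2_000), 100, wall_layers=5,
                          growth_ratio=1.2)
        heights = np.diff(mesh.y_edges)[:5]
        ratios = heights / heights[0]
        assert np.allclose(ratios, 1.2 ** np.arange(5), rtol=1e-12)
        # symmetric at the far wall
        assert np.allclose(np.diff(mesh.y_edges)[-5:][::-1], heights)

    def test_underresolved_channel_raises(self):
        with pytest.raises(ResolutionError, match="dorsal"):
            build_mesh(PhantomSpec(), 120)

    def test_stack_mesh_matches_spec_mesh_cells(self):
        spec = PhantomSpec()
        stack = generate_phantom(spec)
        ms = build_mesh(stack, 50)
        mp = build_mesh(spec, 50)
        assert abs(ms.total_volume() - mp.total_volume()) \
            / mp.total_volume() < 0.02


class TestFaceConsistency:
    def test_closed_cells_have_zero_net_area(self, phantom_mesh):
        m = phantom_mesh
        net = np.zeros((m.n_cells, 2))
        for ax in (0, 1):
            sel = m.int_axis == ax
            np.add.at(net[:, ax], m.int_owner[sel], m.int_area[sel])
            np.add.at(net[:, ax], m.int_neigh[sel], -m.int_area[sel])
            bsel = m.b_axis == ax
            np.add.at(net[:, ax], m.b_owner[bsel],
                      m.b_sign[bsel] * m.b_area[bsel])
        assert np.abs(net).max() < 1e-12 * m.int_area.mean()

    def test_every_boundary_face_has_one_owner(self, phantom_mesh):
        m = phantom_mesh
        assert (m.b_owner >= 0).all() and (m.b_owner < m.n_cells).all()
        assert m.inlet_area > 0 and m.outlet_area > 0

    def test_region_labels_partition_wall_faces(self, phantom_mesh):
        m = phantom_mesh
        wall = m.b_type == WALL
        assert (m.b_region[wall] >= 0).all()
        assert (m.b_region[~wall] == -1).all()
        spec = PhantomSpec()
        olf = wall & (m.b_region == OLFACTORY)
        assert m.b_x[olf].min() >= spec.olfactory_start * UM - 1e-12
        assert m.b_x[olf].max() <= spec.olfactory_end * UM + 1e-12
        squam = wall & (m.b_region == SQUAMOUS)
        assert m.b_x[squam].max() <= spec.squamous_end * UM + 1e-12


class TestRefineMesh:
    def test_factor_two_doubles_counts(self):
        mesh = build_mesh(box_phantom(10_000, 1_000), 50)
        fine = refine_mesh(mesh, 2)
        assert fine.active.shape == (mesh.active.shape[0] * 2,
                                     mesh.active.shape[1] * 2)

    def test_inlet_area_preserved(self, phantom_mesh):
        fine = refine_mesh(phantom_mesh, 2)
        assert fine.inlet_area == pytest.approx(phantom_mesh.inlet_area,
                                                rel=1e-9)
        assert abs(fine.total_volume() - phantom_mesh.total_volume()) \
            / phantom_mesh.total_volume() < 0.01

    def test_invalid_factor(self, phantom_mesh):
        with pytest.raises(ValueError):
            refine_mesh(phantom_mesh, 5)

    def test_cell_guard(self, phantom_mesh, monkeypatch):
        monkeypatch.setattr(meshing, "MAX_CELLS", 1000)
        with pytest.raises(MeshSizeError):
            refine_mesh(phantom_mesh, 4)


class TestCrossSection:
    def test_partition_covers_section(self, phantom_mesh):
        sec = cross_section(phantom_mesh, 12e-3)
        assert (sec.dorsal | sec.ventral).all()
        assert not (sec.dorsal & sec.ventral).any()
        # dorsal + ventral areas = local lumen area (both channels)
        spec = PhantomSpec()
        lumen = (spec.dorsal_width + spec.ventral_width) * UM \
            * phantom_mesh.depth
        assert sec.area == pytest.approx(lumen, rel=1e-9)

    def test_single_lumen_split_above_top(self, phantom_mesh):
        sec = cross_section(phantom_mesh, 1e-3, split_y=10.0)
        assert not sec.dorsal.any()          # everything below the split

    def test_box_section_area(self):
        mesh = build_mesh(box_phantom(10_000, 1_000, depth_um=10_000), 50)
        sec = cross_section(mesh, 5e-3)
        assert sec.area == pytest.approx(1e-3 * 1e-2, rel=1e-9)

    def test_outside_domain_rejected(self, phantom_mesh):
        with pytest.raises(ValueError):
            cross_section(phantom_mesh, 25e-3)

    def test_solid_region_is_empty_section(self):
        from rhinoflow.airway_geometry import ImageStack
        sl = np.zeros((10, 14, 9), np.uint8)
        sl[:4, 2:12, 2:7] = 1                # lumen ends at slice 4
        stack = ImageStack(sl, 100.0, 300.0)
        mesh = build_mesh(stack, 100, depth_um=500)
        with pytest.raises(EmptySectionError):
            cross_section(mesh, 2.5e-3)


class TestPersistence:
    def test_save_load_round_trip(self, phantom_mesh, tmp_path):
        path = tmp_path / "mesh.npz"
        phantom_mesh.save(path)
        back = meshing.Mesh.load(path)
        assert np.array_equal(back.active, phantom_mesh.active)
        assert np.allclose(back.x_edges, phantom_mesh.x_edges)
        assert back.depth == phantom_mesh.depth
        assert back.meta["regions"] == phantom_mesh.meta["regions"]
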