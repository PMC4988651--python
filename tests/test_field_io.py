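import json

import numpy as np
import pytest

from ventriflow import phantom as ph
from ventriflow.field_io import (
    ValidationError,
    VelocityField4D,
    export_pathlines,
    load_flow_study,
    read_pathlines_csv,
    sample_velocity,
    save_flow_study,
)
from ventriflow.tracing import trace_cycle


def small_field(velocity, rr_ms=1000.0, frame_times=None, spacing=2.0, origin=(0.0, 0.0, 0.0)):
    velocity = np.asarray(velocity, float)
    nt = velocity.shape[3]
    if frame_times is None:
        frame_times = rr_ms * np.arange(nt) / nt
    return VelocityField4D(velocity, np.array([spacing] * 3), np.asarray(origin, float),
                           rr_ms=rr_ms, frame_times_ms=np.asarray(frame_times, float))


class TestSampling:
    def test_constant_field_everywhere(self):
        vel = np.zeros((4, 4, 4, 2, 3))
        vel[...] = [3.0, -2.0, 0.5]
        f = small_field(vel)
        for pos, t in [((1.0, 1.0, 1.0), 0.0), ((5.9, 0.1, 4.4), 637.3), ((0, 0, 0), 999.0)]:
            assert np.allclose(sample_velocity(f, pos, t), [3.0, -2.0, 0.5])

    def test_cyclic_wrap(self):
        vel = np.random.default_rng(0).normal(size=(4, 4, 4, 3, 3))
        f = small_field(vel, rr_ms=900.0)
        p = (2.3, 4.1, 1.7)
        assert np.allclose(sample_velocity(f, p, 10.0), sample_velocity(f, p, 910.0))
        # continuity at the cycle seam: t -> rr^- approaches t = 0
        assert np.allclose(
            sample_velocity(f, p, 900.0 - 1e-9), sample_velocity(f, p, 0.0), atol=1e-6
        )

    def test_midpoint_between_frames(self):
        rng = np.random.default_rng(1)
        A, B = rng.normal(size=(4, 4, 4, 3)), rng.normal(size=(4, 4, 4, 3))
        vel = np.stack([A, B], axis=3)
        f = small_field(vel, rr_ms=1000.0, frame_times=[0.0, 500.0])
        got = sample_velocity(f, (2.0, 2.0, 2.0), 250.0)  # voxel (1,1,1) centre
        assert np.allclose(got, 0.5 * (A[1, 1, 1] + B[1, 1, 1]))

    def test_frame_values_exact_at_voxel_centers(self):
        rng = np.random.default_rng(2)
        vel = rng.normal(size=(5, 4, 3, 3, 3))
        f = small_field(vel, rr_ms=990.0, frame_times=[0.0, 330.0, 660.0])
        for ijk in [(0, 0, 0), (4, 3, 2), (2, 1, 1)]:
            for k, t in enumerate(f.frame_times_ms):
                got = sample_velocity(f, np.array(ijk) * 2.0, t)
                assert np.allclose(got, vel[ijk][k])

    def test_affine_field_reproduced_exactly(self):
        # trilinear/linear interpolation is exact for fields affine in x,y,z and t
        n, dx = 6, 2.0
        xs = dx * np.arange(n)
        X, Y, Z = np.meshgrid(xs, xs, xs, indexing="ij")
        frame_times = [0.0, 400.0]
        vel = np.zeros((n, n, n, 2, 3))
        for k, t in enumerate(frame_times):
            vel[..., k, 0] = 1.0 + 2.0 * X - Y + 0.5 * Z + 0.01 * t
            vel[..., k, 1] = -3.0 + X + 4.0 * Z - 0.02 * t
            vel[..., k, 2] = 0.25 * Y
        f = small_field(vel, rr_ms=800.0, frame_times=frame_times)
        rng = np.random.default_rng(3)
        pts = rng.uniform(0.0, dx * (n - 1), size=(20, 3))
        for t in (0.0, 123.4, 399.9):
            got, ok = np.array([sample_velocity(f, p, t) for p in pts]), True
            want = np.stack(
                [
                    1.0 + 2.0 * pts[:, 0] - pts[:, 1] + 0.5 * pts[:, 2] + 0.01 * t,
                    -3.0 + pts[:, 0] + 4.0 * pts[:, 2] - 0.02 * t,
                    0.25 * pts[:, 1],
                ],
                axis=1,
            )
            assert np.allclose(got, want, atol=1e-9)

    def test_out_of_grid_returns_zero_and_flag(self):
        vel = np.ones((4, 4, 4, 2, 3))
        f = small_field(vel)
        v, ok = sample_velocity(f, (-1.0, 2.0, 2.0), 0.0, return_status=True)
        assert not ok and np.all(v == 0.0)
        v, ok = sample_velocity(f, (2.0, 2.0, 2.0), 0.0, return_status=True)
        assert ok and np.all(v == 1.0)

    def test_nonfinite_arguments_rejected(self):
        f = small_field(np.ones((4, 4, 4, 2, 3)))
        with pytest.raises(ValueError):
            sample_velocity(f, (np.nan, 0, 0), 0.0)
        with pytest.raises(ValueError):
            sample_velocity(f, (0, 0, 0), np.inf)


class TestFieldValidation:
    def test_frame_times_must_increase(self):
        with pytest.raises(ValidationError):
            small_field(np.zeros((4, 4, 4, 2, 3)), frame_times=[0.0, 0.0])

    def test_frame_times_inside_cycle(self):
        with pytest.raises(ValidationError):
            small_field(np.zeros((4, 4, 4, 2, 3)), rr_ms=500.0, frame_times=[0.0, 500.0])

    def test_nonpositive_spacing(self):
        with pytest.raises(ValidationError):
            VelocityField4D(np.zeros((4, 4, 4, 2, 3)), np.array([2.0, 0.0, 2.0]),
                            np.zeros(3), 1000.0, np.array([0.0, 500.0]))


class TestStudyRoundTrip:
    def test_round_trip_identity(self, tmp_path, plug_default_study):
        save_flow_study(plug_default_study, tmp_path / "study")
        back = load_flow_study(tmp_path / "study")
        assert np.array_equal(back.field.velocity, plug_default_study.field.velocity)
        assert np.array_equal(back.geometry.mask_ed, plug_default_study.geometry.mask_ed)
        assert np.allclose(back.field.spacing, plug_default_study.field.spacing)
        assert np.allclose(back.field.origin, plug_default_study.field.origin)
        assert back.timing.i_ed == plug_default_study.timing.i_ed
        assert np.allclose(back.geometry.basal_plane.normal,
                           plug_default_study.geometry.basal_plane.normal)

    def test_missing_file_names_the_file(self, tmp_path, plug_default_study):
        save_flow_study(plug_default_study, tmp_path / "study")
        (tmp_path / "study" / "velocity_y.nii.gz").unlink()
        with pytest.raises(FileNotFoundError, match="velocity_y"):
            load_flow_study(tmp_path / "study")

    def test_ed_index_out_of_bounds_rejected(self, tmp_path, plug_default_study):
        d = save_flow_study(plug_default_study, tmp_path / "study")
        sidecar = json.loads((d / "study.json").read_text())
        sidecar["i_ed"] = plug_default_study.field.nt  # one past the last frame
        (d / "study.json").write_text(json.dumps(sidecar))
        with pytest.raises(ValidationError):
            load_flow_study(d)

    def test_mask_grid_mismatch_rejected(self, tmp_path, plug_default_study):
        import nibabel as nib

        d = save_flow_study(plug_default_study, tmp_path / "study")
        img = nib.load(d / "mask_ed.nii.gz")
        small = np.asarray(img.dataobj)[:-2]
        nib.save(nib.Nifti1Image(small.astype(np.uint8), img.affine), d / "mask_ed.nii.gz")
        with pytest.raises(ValidationError, match="does not match"):
            load_flow_study(d)


class TestPathlineExport:
    @pytest.fixture(scope="class")
    def tiny_traced(self):
        study = ph.make_plug_flow_phantom(
            ph.PlugFlowParams(L=25.0, v=20.0, T_d=1000.0, T_s=1000.0, spacing=2.5, nt=4)
        )
        return trace_cycle(study)

    def test_csv_row_and_id_counts(self, tmp_path, tiny_traced):
        out = export_pathlines(tiny_traced, tmp_path / "pl.csv", format="csv")
        df = read_pathlines_csv(out)
        assert len(df) == tiny_traced.n_pathlines * len(tiny_traced.times_ms)
        assert df["pathline_id"].nunique() == tiny_traced.n_pathlines

    def test_csv_round_trip_positions(self, tmp_path, tiny_traced):
        out = export_pathlines(tiny_traced, tmp_path / "pl.csv", format="csv")
        df = read_pathlines_csv(out)
        first = df[df["pathline_id"] == 0][["x_mm", "y_mm", "z_mm"]].to_numpy()
        assert np.allclose(first, tiny_traced.positions[0], atol=1e-5)

    def test_vtk_structure(self, tmp_path, tiny_traced):
        out = export_pathlines(tiny_traced, tmp_path / "pl.vtk", format="vtk")
        text = out.read_text()
        assert "DATASET POLYDATA" in text
        assert f"LINES {tiny_traced.n_pathlines}" in text

    def test_unknown_format_rejected(self, tmp_path, tiny_traced):
        with pytest.raises(ValueError, match="format"):
            export_pathlines(tiny_traced, tmp_path / "pl.xyz", format="xyz")

    def test_empty_set_rejected(self, tmp_path, tiny_traced):
        import copy

        empty = copy.copy(tiny_traced)
        empty.seeds = np.empty((0, 3))
        with pytest.raises(ValueError):
            export_pathlines(empty, tmp_path / "pl.csv")
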