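"""Scalar metrics: strain energy, contractility, stress scalars, line tension."""

import numpy as np
import pytest

from tfmsm.fields import StressTensorField, VectorField2D
from tfmsm.metrics import (
    ResultsRecord,
    contractility,
    line_tension,
    read_results,
    strain_energy,
    stress_scalars,
    write_results,
)

UM = 1e-6


class TestStrainEnergy:
    def test_zero_traction_gives_zero_energy(self):
        u = VectorField2D(np.ones((8, 8)), np.ones((8, 8)), 1.0)
        t = VectorField2D(np.zeros((8, 8)), np.zeros((8, 8)), 1.0)
        assert strain_energy(u, t) == 0.0

    def test_uniform_parallel_fields_closed_form(self):
        """U = 1/2 |u||t| A for aligned uniform fields."""
        n, a = 10, 2.0
        u0, t0 = 3.0, 50.0  # um, Pa
        u = VectorField2D(np.full((n, n), u0), np.zeros((n, n)), a)
        t = VectorField2D(np.full((n, n), t0), np.zeros((n, n)), a)
        area = np.zeros((n, n), bool)
        area[2:7, 1:9] = True
        expected = 0.5 * (u0 * UM) * t0 * area.sum() * (a * UM) ** 2
        assert strain_energy(u, t, area) == pytest.approx(expected, rel=1e-12)

    def test_matches_parseval_evaluation(self):
        """Real-space energy equals the Fourier-domain (Parseval) integral."""
        from tfmsm.synthetic import SyntheticSpec, ground_truth

        spec = SyntheticSpec(field_size_um=128.0, patch_width_um=50.0)
        gt = ground_truth(spec, pad_factor=1)
        u, t = gt["deformation"], gt["traction"]
        real = strain_energy(u, t)
        fu = np.stack([np.fft.fft2(u.vx * UM), np.fft.fft2(u.vy * UM)])
        ft = np.stack([np.fft.fft2(t.vx), np.fft.fft2(t.vy)])
        n_tot = u.vx.size
        fourier = 0.5 * np.sum(fu * ft.conj()).real / n_tot * (u.grid_spacing * UM) ** 2
        assert real == pytest.approx(fourier, rel=0.01)

    def test_mismatched_grids_rejected(self):
        u = VectorField2D(np.ones((8, 8)), np.ones((8, 8)), 1.0)
        t = VectorField2D(np.ones((9, 9)), np.ones((9, 9)), 1.0)
        with pytest.raises(ValueError):
            strain_energy(u, t)


def _two_point_field(n=64, mag=100.0, sep=20):
    tx = np.zeros((n, n))
    c = n // 2
    tx[c, c - sep // 2] = mag    # pulls right, toward the midpoint
    tx[c, c + sep // 2] = -mag   # pulls left
    return VectorField2D(tx, np.zeros_like(tx), 1.0)


class TestContractility:
    def test_opposing_forces_pulling_inward(self):
        t = _two_point_field()
        epi, c = contractility(t)
        force = 100.0 * UM**2
        assert c == pytest.approx(2 * force, rel=1e-9)
        assert epi[0] == pytest.approx(32.5, abs=1e-6)  # midpoint, pixel centers

    def test_outward_forces_give_negative_contractility(self):
        t = _two_point_field()
        t_out = VectorField2D(-t.vx, -t.vy, 1.0)
        _, c_in = contractility(t)
        _, c_out = contractility(t_out)
        assert c_out == pytest.approx(-c_in, rel=1e-12)

    def test_epicenter_matches_brute_force_search(self, rng):
        """Forces aimed at one point: C = sum|F| and the linear solve matches
        a brute-force grid minimization of the line-distance objective."""
        n = 60
        target = np.array([25.3, 31.7])
        tx = np.zeros((n, n))
        ty = np.zeros((n, n))
        pix = rng.choice(n * n, size=40, replace=False)
        rows, cols = np.unravel_index(pix, (n, n))
        mags = rng.uniform(10.0, 200.0, size=40)
        x = (cols + 0.5)
        y = (rows + 0.5)
        d = np.stack([target[0] - x, target[1] - y], axis=1)
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        tx[rows, cols] = mags * d[:, 0]
        ty[rows, cols] = mags * d[:, 1]
        t = VectorField2D(tx, ty, 1.0)
        epi, c = contractility(t)
        assert epi == pytest.approx(target, abs=1e-6)
        assert c == pytest.approx(mags.sum() * UM**2, rel=1e-9)
        # independent brute-force search of the epicenter objective
        def objective(px, py):
            return np.sum((tx[rows, cols] * (py - y) - ty[rows, cols] * (px - x)) ** 2)

        gx, gy = np.meshgrid(np.linspace(20, 30, 41), np.linspace(27, 37, 41))
        obj = np.vectorize(objective)(gx, gy)
        best = np.unravel_index(obj.argmin(), obj.shape)
        assert gx[best] == pytest.approx(epi[0], abs=0.25)
        assert gy[best] == pytest.approx(epi[1], abs=0.25)

    def test_continuity_under_vanishing_balanced_noise(self, rng):
        t = _two_point_field()
        _, c0 = contractility(t)
        noise_x = rng.normal(size=t.shape)
        noise_x -= noise_x.mean()
        noise_y = rng.normal(size=t.shape)
        noise_y -= noise_y.mean()
        for amp, tol in ((1e-3, 1e-4), (1e-6, 1e-7)):
            tn = VectorField2D(t.vx + amp * noise_x, t.vy + amp * noise_y, 1.0)
            _, c = contractility(tn)
            assert abs(c - c0) / abs(c0) < tol * 1e4

    def test_parallel_forces_through_no_common_point_degenerate(self):
        tx = np.zeros((16, 16))
        tx[4, :] = 1.0
        tx[10, :] = 1.0  # parallel lines of action that never intersect
        with pytest.raises(ValueError, match="degenerate"):
            contractility(VectorField2D(tx, np.zeros_like(tx), 1.0))


class TestStressScalars:
    def test_uniform_isotropic_tensor(self):
        n, s0 = 12, 4.2
        stress = StressTensorField(np.full((n, n), s0), np.full((n, n), s0),
                                   np.zeros((n, n)), 1.0)
        out = stress_scalars(stress)
        assert out["avg_max_normal_stress"] == pytest.approx(s0)
        assert out["avg_max_shear_stress"] == pytest.approx(0.0, abs=1e-15)
        assert out["avg_mean_normal_stress"] == pytest.approx(s0)
        assert out["cv_normal_stress"] == pytest.approx(0.0, abs=1e-15)

    def test_pure_shear_tensor(self):
        n, s = 8, 1.7
        stress = StressTensorField(np.zeros((n, n)), np.zeros((n, n)),
                                   np.full((n, n), s), 1.0)
        out = stress_scalars(stress)
        assert out["avg_max_normal_stress"] == pytest.approx(s)
        assert out["avg_max_shear_stress"] == pytest.approx(s)

    def test_empty_mask_rejected(self):
        stress = StressTensorField(np.ones((4, 4)), np.ones((4, 4)), np.zeros((4, 4)), 1.0)
        with pytest.raises(ValueError, match="empty"):
            stress_scalars(stress, np.zeros((4, 4), bool))


class TestLineTension:
    def test_isotropic_stress_gives_pure_normal_tension(self):
        n, s0 = 20, 2.0
        stress = StressTensorField(np.full((n, n), s0), np.full((n, n), s0),
                                   np.zeros((n, n)), 1.0)
        poly = np.array([[3.0, 4.0], [9.0, 13.0], [15.0, 6.0]])
        segments, avg = line_tension(stress, [poly])
        assert avg["avg_normal_line_tension"] == pytest.approx(s0, rel=1e-9)
        assert avg["avg_shear_line_tension"] == pytest.approx(0.0, abs=1e-12)
        assert avg["avg_line_tension"] == pytest.approx(s0, rel=1e-9)
        for seg in segments:
            assert np.hypot(*seg.tension) ** 2 == pytest.approx(
                seg.normal_component**2 + seg.shear_component**2
            )

    def test_uniaxial_stress_on_axis_aligned_boundary(self):
        n, s = 20, 3.3
        stress = StressTensorField(np.full((n, n), s), np.zeros((n, n)),
                                   np.zeros((n, n)), 1.0)
        poly = np.array([[10.0, 3.0], [10.0, 17.0]])  # along y, normal = +-x
        _, avg = line_tension(stress, [poly])
        assert avg["avg_line_tension"] == pytest.approx(s, rel=1e-9)
        assert abs(avg["avg_normal_line_tension"]) == pytest.approx(s, rel=1e-9)
        assert avg["avg_shear_line_tension"] == pytest.approx(0.0, abs=1e-12)

    def test_reversing_vertex_order_flips_normal_convention_only(self, rng):
        """Reversal flips n, but T.n and T.tangent are quadratic in the frame
        so every reported quantity is unchanged."""
        n = 24
        sxx = rng.normal(size=(n, n))
        syy = rng.normal(size=(n, n))
        sxy = rng.normal(size=(n, n))
        stress = StressTensorField(sxx, syy, sxy, 1.0)
        poly = np.array([[4.0, 5.0], [12.0, 9.0], [18.0, 16.0]])
        seg_f, fwd = line_tension(stress, [poly])
        seg_r, rev = line_tension(stress, [poly[::-1]])
        assert seg_r[-1].normal == pytest.approx(-seg_f[0].normal)
        for key in fwd:
            assert rev[key] == pytest.approx(fwd[key]), key

    def test_segment_outside_valid_region_skipped_with_warning(self):
        n = 16
        mask = np.zeros((n, n), bool)
        mask[:, :8] = True
        stress = StressTensorField(np.ones((n, n)), np.ones((n, n)),
                                   np.zeros((n, n)), 1.0, mask=mask)
        poly = np.array([[2.0, 2.0], [2.0, 12.0], [14.0, 12.0]])
        with pytest.warns(UserWarning, match="skipped"):
            segments, _ = line_tension(stress, [poly])
        assert len(segments) == 1


class TestRotationEquivariance:
    def test_quarter_turn_leaves_scalars_unchanged(self, rng):
        """Rotating tensor field + boundary by 90 deg preserves all outputs."""
        n = 30
        sxx = rng.normal(size=(n, n)) + 2.0
        syy = rng.normal(size=(n, n)) + 2.0
        sxy = 0.3 * rng.normal(size=(n, n))
        mask = np.zeros((n, n), bool)
        mask[5:25, 8:22] = True
        stress = StressTensorField(sxx, syy, sxy, 1.0, mask=mask)
        # image-convention quarter turn: (x, y) -> (y, S - x), arrays rot90(k=1)
        rot = StressTensorField(
            np.rot90(syy), np.rot90(sxx), -np.rot90(sxy), 1.0, mask=np.rot90(mask)
        )
        out0 = stress_scalars(stress, mask)
        out1 = stress_scalars(rot, np.rot90(mask))
        for key in out0:
            assert out1[key] == pytest.approx(out0[key], rel=1e-12), key

        poly = np.array([[9.0, 6.0], [15.0, 12.0], [20.0, 20.0]])
        s_len = n * 1.0
        poly_rot = np.stack([poly[:, 1], s_len - poly[:, 0]], axis=1)
        _, avg0 = line_tension(stress, [poly])
        _, avg1 = line_tension(rot, [poly_rot])
        for key in avg0:
            assert avg1[key] == pytest.approx(avg0[key], rel=1e-9), key


class TestResultsIO:
    def test_roundtrip_through_tsv(self, tmp_path):
        rec = ResultsRecord(
            contractility=6.4e-7, strain_energy=1.1e-13,
            avg_max_normal_stress=2.62e-3, avg_max_shear_stress=7.8e-4,
            cv_normal_stress=0.38, avg_line_tension=2.04e-3,
            avg_normal_line_tension=1.94e-3, avg_shear_line_tension=5.6e-4,
            patch_area=1234.5,
        )
        path = write_results(rec, tmp_path / "results.tsv")
        back = read_results(path)
        for key, val in rec.to_dict().items():
            if val is None:
                assert getattr(back, key) is None
            else:
                assert getattr(back, key) == pytest.approx(val, rel=1e-15), key
        # labels readable by generic tools: two tab-separated columns
        for line in path.read_text().splitlines():
            assert len(line.split("\t")) == 2
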