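"""Forward 2TCM, whole-brain inversion, Feng input, and macroparameter algebra."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mdifkit.kinetics import (
    TAC,
    FengParams,
    MdifModel,
    MicroParams,
    TimeGrid,
    expconv_pl,
    feng_input,
    feng_value,
    ki_of,
    mdif_from_wb,
    twotcm_forward,
    twotcm_forward_matrix,
)
from mdifkit.simulate import REFERENCE_AIF, clinical_grid


def fine_grid(dt=0.01, t_end=60.0):
    starts = np.arange(0.0, t_end, dt)
    return TimeGrid(starts, np.full(starts.size, dt))


# ---------------------------------------------------------------------------
# TimeGrid / TAC contracts
# ---------------------------------------------------------------------------


class TestTimeGrid:
    def test_clinical_schedule_is_60_minutes_of_50_frames(self):
        grid = clinical_grid()
        assert len(grid) == 50
        assert grid.total_duration == pytest.approx(60.0)
        assert np.all(np.diff(grid.mid_time) > 0)

    @pytest.mark.parametrize(
        "starts, durs",
        [
            ([0.0, 1.0], [2.0, 1.0]),  # overlap
            ([1.0, 0.5], [0.2, 0.2]),  # non-increasing
            ([0.0, 1.0], [1.0, -1.0]),  # negative duration
            ([-1.0, 1.0], [0.5, 0.5]),  # negative start
        ],
    )
    def test_invalid_schedules_rejected(self, starts, durs):
        with pytest.raises(ValueError):
            TimeGrid(starts, durs)

    def test_gapped_frames_allowed(self):
        grid = TimeGrid([0.0, 2.0], [1.0, 1.0])
        assert grid.mid_time == pytest.approx([0.5, 2.5])

    def test_tac_length_and_finiteness_checked(self):
        grid = TimeGrid([0.0, 1.0], [1.0, 1.0])
        with pytest.raises(ValueError):
            TAC(grid, [1.0])
        with pytest.raises(ValueError):
            TAC(grid, [np.nan, 1.0])
        with pytest.raises(ValueError):
            TAC(grid, [-1.0, 1.0])


# ---------------------------------------------------------------------------
# Convolution primitive and forward model
# ---------------------------------------------------------------------------


class TestForwardModel:
    def test_expconv_matrix_equals_operator(self):
        rng = np.random.default_rng(5)
        grid = clinical_grid()
        c = rng.uniform(0, 30, len(grid))
        p = MicroParams(0.1, 0.12, 0.05, 0.06)
        M = twotcm_forward_matrix(p, grid.mid_time, R=0.9)
        cp = TAC(grid, c)
        direct = twotcm_forward(p, cp, R=0.9).values
        assert M @ c == pytest.approx(direct, rel=1e-12)
        assert np.allclose(np.triu(M, k=1), 0.0)  # causal

    def test_no_uptake_reduces_to_blood_term(self):
        grid = clinical_grid()
        cp = feng_input(REFERENCE_AIF, grid)
        cb = cp.with_values(0.9 * cp.values)
        out = twotcm_forward(MicroParams(0.0, 0.1, 0.05, 0.05), cp, cb)
        assert out.values == pytest.approx(0.05 * cb.values)

    def test_zero_inputs_give_zero_output(self):
        grid = clinical_grid()
        zero = TAC(grid, np.zeros(len(grid)))
        out = twotcm_forward(MicroParams(0.1, 0.1, 0.05, 0.05), zero, zero)
        assert out.values == pytest.approx(0.0, abs=1e-15)

    def test_matches_quadrature_oracle(self):
        """Analytic piecewise-linear convolution vs dense trapezoid quadrature.

        The oracle integrates kernel(t - s) * Cp(s) on a 0.5 ms sub-grid
        using only analytic expressions, independent of the recursion under
        test.
        """
        p = MicroParams(0.105, 0.148, 0.074, 0.05)
        grid = fine_grid(0.01)
        cp = feng_input(REFERENCE_AIF, grid)
        model = twotcm_forward(p, cp, R=1.0)
        for i in (50, 100, 500, 2000, 5900):
            ti = grid.mid_time[i]
            s = np.linspace(0.0, ti, 120_001)
            kernel = (1 - p.Vb) * (p.K1 / p.kf) * (p.k3 + p.k2 * np.exp(-p.kf * (ti - s)))
            integ = np.trapezoid(kernel * feng_value(REFERENCE_AIF, s), s)
            expected = integ + p.Vb * feng_value(REFERENCE_AIF, ti)
            assert model.values[i] == pytest.approx(expected, rel=1e-3)

    def test_pure_trapping_limit(self):
        """kf -> 0: the kernel collapses to constant K1 (running integral)."""
        grid = fine_grid(0.05)
        cp = feng_input(REFERENCE_AIF, grid)
        p = MicroParams(0.1, 0.0, 0.0, 0.0)
        out = twotcm_forward(p, cp, R=1.0)
        expected = 0.1 * expconv_pl(0.0, grid.mid_time, cp.values)
        assert out.values == pytest.approx(expected, rel=1e-12)

    def test_linearity_in_plasma_input(self):
        rng = np.random.default_rng(11)
        grid = clinical_grid()
        c1 = TAC(grid, rng.uniform(0, 40, len(grid)))
        c2 = TAC(grid, rng.uniform(0, 40, len(grid)))
        p = MicroParams(0.09, 0.12, 0.07, 0.06)
        a, b = 1.7, -0.4
        combo = TAC(grid, a * c1.values + b * c2.values + 50)  # keep first frame >= 0
        c3 = TAC(grid, np.full(len(grid), 50.0))
        lhs = twotcm_forward(p, combo, R=1.0).values
        rhs = (
            a * twotcm_forward(p, c1, R=1.0).values
            + b * twotcm_forward(p, c2, R=1.0).values
            + twotcm_forward(p, c3, R=1.0).values
        )
        assert lhs == pytest.approx(rhs, rel=1e-10, abs=1e-10)

    def test_grid_mismatch_rejected(self):
        g1, g2 = clinical_grid(), fine_grid(0.5)
        cp = TAC(g1, np.ones(len(g1)))
        cb = TAC(g2, np.ones(len(g2)))
        with pytest.raises(ValueError):
            twotcm_forward(MicroParams(0.1, 0.1, 0.05, 0.05), cp, cb)

    def test_frame_average_close_to_midpoint_on_smooth_curves(self):
        grid = clinical_grid()
        cp = feng_input(REFERENCE_AIF, grid)
        p = MicroParams(0.09, 0.12, 0.07, 0.06)
        mid = twotcm_forward(p, cp, R=1.0).values
        avg = twotcm_forward(p, cp, R=1.0, frame_average=True).values
        # tissue curves are smooth: frame averages deviate only slightly
        assert avg[5:] == pytest.approx(mid[5:], rel=0.05)
        assert not np.allclose(avg, mid)


# ---------------------------------------------------------------------------
# Whole-brain inversion
# ---------------------------------------------------------------------------


class TestMdifInversion:
    def test_zero_wb_gives_zero_input(self):
        grid = clinical_grid()
        model = MdifModel(MicroParams(0.09, 0.117, 0.066, 0.067), R=1.0)
        out = mdif_from_wb(model, TAC(grid, np.zeros(len(grid))))
        assert out.values == pytest.approx(0.0, abs=1e-12)

    def test_k1_zero_reduces_to_scaling(self):
        grid = clinical_grid()
        wb = TAC(grid, np.linspace(0, 30, len(grid)))
        model = MdifModel(MicroParams(0.0, 0.1, 0.05, 0.05), R=0.9)
        out = mdif_from_wb(model, wb)
        assert out.values == pytest.approx(wb.values / (0.9 * 0.05))

    @pytest.mark.parametrize("scheme, tol", [("kernel", 1e-3), ("exact", 1e-10)])
    def test_forward_inverse_duality_fine_grid(self, scheme, tol):
        """Round trip Cp -> Cwb -> Cp on a 0.01-min grid."""
        grid = fine_grid(0.01)
        cp = feng_input(REFERENCE_AIF, grid)
        wb = MicroParams(0.090, 0.117, 0.066, 0.067)
        cwb = twotcm_forward(wb, cp, R=1.0)
        rec = mdif_from_wb(MdifModel(wb, R=1.0), cwb, scheme=scheme)
        sel = grid.mid_time >= 0.5
        rel = np.abs(rec.values[sel] - cp.values[sel]) / cp.values[sel]
        assert rel.max() < tol

    def test_duality_on_clinical_grid(self):
        """Kernel scheme stays within 2% on the coarse schedule; the exact
        discrete inverse is exact by construction."""
        grid = clinical_grid()
        cp = feng_input(REFERENCE_AIF, grid)
        wb = MicroParams(0.090, 0.117, 0.066, 0.067)
        cwb = twotcm_forward(wb, cp, R=1.0)
        model = MdifModel(wb, R=1.0)
        sel = grid.mid_time >= 0.5
        rec_k = mdif_from_wb(model, cwb, scheme="kernel")
        rec_e = mdif_from_wb(model, cwb, scheme="exact")
        assert np.max(np.abs(rec_k.values - cp.values)[sel] / cp.values[sel]) < 0.02
        assert rec_e.values == pytest.approx(cp.values, rel=1e-9)

    @settings(max_examples=60, deadline=None)
    @given(
        K1=st.floats(0.01, 0.2),
        k2=st.floats(0.01, 0.4),
        k3=st.floats(0.01, 0.2),
        Vb=st.floats(0.01, 0.2),
        R=st.floats(0.8, 1.2),
    )
    def test_alpha_identities(self, K1, k2, k3, Vb, R):
        """alpha1 + alpha2 = 2a and alpha1 * alpha2 = b; 0 <= a1 <= a2."""
        m = MdifModel(MicroParams(K1, k2, k3, Vb), R=R)
        a1, a2 = m.alpha1, m.alpha2
        assert a1 + a2 == pytest.approx(2 * m.a, rel=1e-12)
        assert a1 * a2 == pytest.approx(m.b, rel=1e-9, abs=1e-15)
        assert 0 <= a1 <= a2

    def test_randomized_duality_property(self):
        """Forward-inverse round trip holds across random parameter draws."""
        rng = np.random.default_rng(2)
        grid = fine_grid(0.02)
        cp = feng_input(REFERENCE_AIF, grid)
        sel = grid.mid_time >= 0.5
        for _ in range(10):
            wb = MicroParams(
                rng.uniform(0.02, 0.18),
                rng.uniform(0.02, 0.35),
                rng.uniform(0.02, 0.18),
                rng.uniform(0.02, 0.2),
            )
            R = rng.uniform(0.8, 1.2)
            cwb = twotcm_forward(wb, cp, R=R)
            rec = mdif_from_wb(MdifModel(wb, R=R), cwb, scheme="kernel")
            rel = np.abs(rec.values[sel] - cp.values[sel]) / cp.values[sel]
            assert rel.max() < 1e-3

    def test_confluent_kernel_branch(self):
        """Coalescing decay constants: the confluent limit stays finite and
        matches the exact discrete inverse."""
        # k2 = 0 and g*K1 = k3 makes the discriminant exactly zero
        Vb, R = 0.5, 1.0
        g = (1 - Vb) / (R * Vb)
        wb = MicroParams(0.05, 0.0, g * 0.05, Vb)
        model = MdifModel(wb, R=R)
        assert model.discriminant <= 1e-10 * model.a**2
        grid = fine_grid(0.05, 30.0)
        cp = feng_input(REFERENCE_AIF, grid)
        cwb = twotcm_forward(wb, cp, R=R)
        rec = mdif_from_wb(model, cwb, scheme="kernel")
        exact = mdif_from_wb(model, cwb, scheme="exact")
        assert np.all(np.isfinite(rec.values))
        sel = grid.mid_time >= 0.5
        assert rec.values[sel] == pytest.approx(exact.values[sel], rel=5e-3)

    def test_invalid_inversions_rejected(self):
        with pytest.raises(ValueError):
            MdifModel(MicroParams(0.1, 0.1, 0.05, 0.0), R=1.0)  # Vb = 0
        with pytest.raises(ValueError):
            MdifModel(MicroParams(0.1, 0.1, 0.05, 0.05), R=0.0)  # R = 0


# ---------------------------------------------------------------------------
# Feng input model
# ---------------------------------------------------------------------------


class TestFengInput:
    def test_value_vanishes_at_delay(self):
        p = FengParams(850, 22, 21, 4, 0.12, 0.01, delay=0.7)
        assert feng_value(p, 0.7) == pytest.approx(0.0)
        assert feng_value(p, 0.3) == 0.0  # before the delay

    def test_zero_amplitudes_give_zero_curve(self):
        p = FengParams(0, 0, 0, 4, 0.12, 0.01)
        grid = clinical_grid()
        assert feng_input(p, grid).values == pytest.approx(0.0)

    def test_single_early_peak_then_decay(self):
        """Shape check against a dense-grid argmax oracle."""
        t = np.linspace(0, 60, 600_001)
        v = feng_value(REFERENCE_AIF, t)
        peak_t = t[np.argmax(v)]
        assert 0.1 < peak_t < 1.0  # sharp first-pass peak
        grid = clinical_grid()
        sampled = feng_input(REFERENCE_AIF, grid)
        i_peak = int(np.argmax(sampled.values))
        assert abs(grid.mid_time[i_peak] - peak_t) < 0.1
        # monotone decay well past the peak
        late = sampled.values[grid.mid_time > 5]
        assert np.all(np.diff(late) < 0)


# ---------------------------------------------------------------------------
# Macroparameter algebra
# ---------------------------------------------------------------------------


class TestKiAlgebra:
    @pytest.mark.parametrize(
        "params, expected",
        [
            (MicroParams(0.105, 0.148, 0.074), 0.035),
            (MicroParams(0.123, 0.121, 0.079), 0.049),
            (MicroParams(0.1, 0.2, 0.0), 0.0),
        ],
    )
    def test_values(self, params, expected):
        assert ki_of(params) == pytest.approx(expected, abs=5e-4)

    def test_reported_wb_ki_is_the_column_mean(self):
        """The whole-brain Ki quoted for the reference study (0.033) is the
        mean over the six regional Ki values at printed precision."""
        from mdifkit.simulate import REFERENCE_REGIONS

        mean_ki = np.mean([ki_of(p) for p in REFERENCE_REGIONS.values()])
        assert mean_ki == pytest.approx(0.033, abs=5e-4)

    def test_undefined_when_nothing_clears(self):
        with pytest.raises(ZeroDivisionError):
            ki_of(MicroParams(0.1, 0.0, 0.0))
        assert ki_of(MicroParams(0.0, 0.0, 0.0)) == 0.0

    @settings(max_examples=40, deadline=None)
    @given(
        K1=st.floats(0.01, 0.3),
        k2=st.floats(0.01, 0.4),
        k3=st.floats(0.001, 0.2),
        dk=st.floats(0.001, 0.1),
    )
    def test_monotone_in_k3_and_bounded_by_k1(self, K1, k2, k3, dk):
        lo = ki_of(MicroParams(K1, k2, k3))
        hi = ki_of(MicroParams(K1, k2, k3 + dk))
        assert hi > lo
        assert hi <= K1

    def test_derived_quantities(self):
        p = MicroParams(0.105, 0.148, 0.074, 0.05)
        assert p.kf == pytest.approx(0.222)
        assert p.Vd == pytest.approx(0.105 / 0.222)
        assert p.Ki == pytest.approx(0.035, abs=5e-4)
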