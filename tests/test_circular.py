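import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize

from antwalks.angles import angle_in_arc
from antwalks.circular import (
    CircTestResult,
    HeadingSet,
    condition_summary,
    final_heading,
    kappa_mle,
    mean_ci,
    mean_ci_test,
    rayleigh_test,
    v_test,
    vonmises_lrt,
    watson_williams_test,
    wedge_histogram,
)
from antwalks.errors import InsufficientDataError
from antwalks.synthetic import gen_headings
from conftest import make_traj


def _release_traj(release, head_offset):
    """Two-frame trajectory sitting at the release point with a fixed body axis."""
    th = np.array([release, release], dtype=float)
    head = th + np.asarray(head_offset)
    return make_traj(th, head=head)


class TestFinalHeading:
    # released 2 m North of the nest: the nest bearing is due South
    def test_pointing_at_nest_is_zero(self):
        traj = _release_traj((0, 200), (0, -0.4))  # head South of thorax
        ang, flagged = final_heading(traj, release_point=(0, 200), arena_radius=50)
        assert ang == pytest.approx(0.0)
        assert flagged  # never left the arena

    def test_pointing_away_is_180(self):
        traj = _release_traj((0, 200), (0, 0.4))
        ang, _ = final_heading(traj, release_point=(0, 200), arena_radius=50)
        assert ang == pytest.approx(180.0)

    def test_head_due_east_is_270(self):
        traj = _release_traj((0, 200), (0.4, 0))
        ang, _ = final_heading(traj, release_point=(0, 200), arena_radius=50)
        assert ang == pytest.approx(270.0)

    def test_uses_last_frame_inside_arena(self):
        th = np.column_stack([np.linspace(0, 120, 61), np.full(61, 200.0)])
        head = th + [0, -0.4]
        head[40:] = th[40:] + [0.4, 0]  # axis turns East right before exit
        traj = make_traj(th, head=head)
        ang, flagged = final_heading(traj, release_point=(0, 200), arena_radius=100)
        assert not flagged
        assert ang == pytest.approx(270.0)


class TestWedgeHistogram:
    def test_bin_edges(self):
        counts = wedge_histogram(HeadingSet([0.0, 14.9]))
        assert counts[0] == 2 and counts.sum() == 2
        assert wedge_histogram(HeadingSet([15.0]))[1] == 1

    def test_one_per_wedge(self):
        counts = wedge_histogram(HeadingSet(7.5 + 15.0 * np.arange(24)))
        assert (counts == 1).all()

    @settings(deadline=None, max_examples=20)
    @given(seed=st.integers(0, 2**16), n=st.integers(1, 60))
    def test_counts_sum_to_n(self, seed, n):
        h = gen_headings(n, 40.0, 1.0, seed=seed)
        assert wedge_histogram(h).sum() == n


class TestRayleigh:
    def test_maximal_concentration(self):
        res = rayleigh_test(HeadingSet(np.full(20, 37.0)))
        assert res.rbar == pytest.approx(1.0)
        assert res.z == pytest.approx(20.0)
        assert res.mu == pytest.approx(37.0)

    def test_perfect_uniformity(self):
        res = rayleigh_test(HeadingSet(np.arange(8) * 45.0))
        assert res.z == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0, abs=1e-6)

    def test_needs_two_angles(self):
        with pytest.raises(InsufficientDataError):
            rayleigh_test(HeadingSet([10.0]))

    def test_power_on_concentrated_samples(self):
        rejected = sum(
            rayleigh_test(gen_headings(20, 0.0, 2.0, seed=s)).p < 0.05
            for s in range(300)
        )
        assert rejected >= 0.95 * 300

    def test_agrees_with_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        for s in range(20):
            h = gen_headings(15, 120.0, 1.5, seed=s)
            z, p = pingouin.circ_rayleigh(h.radians)
            res = rayleigh_test(h)
            assert res.z == pytest.approx(z, abs=1e-9)
            # pingouin uses Zar's closed-form p approximation; ours is the
            # series expansion — the approximations track each other on the
            # log scale but diverge in relative terms at tiny p
            assert abs(np.log(res.p + 1e-300) - np.log(p + 1e-300)) < 0.25


class TestVTest:
    def test_all_at_target(self):
        res = v_test(HeadingSet(np.full(20, 42.0)), 42.0)
        assert res.z == pytest.approx(np.sqrt(40.0))

    def test_orthogonal_mean_gives_zero(self):
        h = HeadingSet([85.0, 95.0])  # mean 90°, target 0°
        assert v_test(h, 0.0).z == pytest.approx(0.0, abs=1e-9)

    def test_agrees_with_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        for s in range(20):
            h = gen_headings(15, 20.0, 2.0, seed=s)
            out = pingouin.circ_vtest(h.radians, dir=0.0)
            res = v_test(h, 0.0)
            # pingouin reports V*n; our statistic is u = V*sqrt(2n)
            assert res.z == pytest.approx(out[0] * np.sqrt(2.0 / h.n), abs=1e-9)
            assert res.p == pytest.approx(out[1], abs=1e-9)


class TestMeanCI:
    def test_identical_angles_zero_width(self):
        res, inside = mean_ci_test(HeadingSet(np.full(6, 77.0)), target=77.0)
        assert res.ci_lo == res.ci_hi == pytest.approx(77.0)
        assert inside
        _, outside = mean_ci_test(HeadingSet(np.full(6, 77.0)), target=0.0)
        assert not outside

    def test_wraparound_inclusion_logic(self):
        # interval straddling North, as in a nestward-oriented condition
        assert angle_in_arc(0.0, 335.67, 5.01)
        assert angle_in_arc(359.0, 335.67, 5.01)
        assert not angle_in_arc(180.0, 335.67, 5.01)

    def test_needs_five(self):
        with pytest.raises(InsufficientDataError):
            mean_ci_test(HeadingSet([0.0, 1.0, 2.0, 3.0]))

    def test_bootstrap_interval_reproducible_and_similar(self):
        h = gen_headings(30, 10.0, 4.0, seed=5)
        mu1, lo1, hi1, fl1 = mean_ci(h, method="bootstrap", seed=7)
        mu2, lo2, hi2, _ = mean_ci(h, method="bootstrap", seed=7)
        assert (lo1, hi1) == (lo2, hi2)
        _, lo_f, hi_f, _ = mean_ci(h, method="fisher")
        # same order of width as the dispersion interval
        w_b = (hi1 - lo1) % 360
        w_f = (hi_f - lo_f) % 360
        assert 0.5 * w_f < w_b < 2.0 * w_f


class TestWatsonWilliams:
    def test_identical_samples(self):
        h = gen_headings(20, 30.0, 8.0, seed=1)
        res = watson_williams_test(h, HeadingSet(h.angles.copy()))
        assert res.z == pytest.approx(0.0, abs=1e-9)
        assert res.p == pytest.approx(1.0, abs=1e-6)

    def test_separated_means_detected(self):
        a = gen_headings(20, 0.0, 8.0, seed=2)
        b = gen_headings(20, 90.0, 8.0, seed=3)
        assert watson_williams_test(a, b).p < 0.01

    def test_diffuse_samples_flagged(self):
        a = gen_headings(20, 0.0, 0.2, seed=4)
        b = gen_headings(20, 0.0, 0.2, seed=5)
        res = watson_williams_test(a, b)
        assert "ww_diffuse_assumption" in res.flags


class TestVonMisesLRT:
    def test_mean_at_target_gives_zero_chi2(self):
        h = HeadingSet([350.0, 355.0, 0.0, 5.0, 10.0])  # mean exactly 0
        res = vonmises_lrt(h, 0.0)
        assert res.chi2 == pytest.approx(0.0, abs=1e-9)
        assert res.p == pytest.approx(1.0, abs=1e-6)

    def test_offset_mean_detected(self):
        rejected = sum(
            vonmises_lrt(gen_headings(20, 60.0, 2.0, seed=s), 0.0).p < 0.05
            for s in range(200)
        )
        assert rejected >= 0.90 * 200

    def test_chi2_matches_numeric_profile_likelihood(self):
        h = gen_headings(10, 35.0, 2.0, seed=8)
        rad = h.radians

        def nll(params):
            mu, kappa = params
            kappa = abs(kappa)
            from scipy.special import i0e
            return -(kappa * np.cos(rad - mu).sum()
                     - rad.size * (np.log(2 * np.pi) + np.log(i0e(kappa)) + kappa))

        free = optimize.minimize(nll, [0.5, 1.0], method="Nelder-Mead",
                                 options={"xatol": 1e-12, "fatol": 1e-14}).fun
        con = optimize.minimize_scalar(
            lambda k: nll([0.0, k]), bounds=(1e-9, 50), method="bounded",
            options={"xatol": 1e-13},
        ).fun
        expected = 2.0 * (con - free)
        assert vonmises_lrt(h, 0.0).chi2 == pytest.approx(expected, abs=1e-8)

    def test_uniform_sample_flagged(self):
        h = HeadingSet(np.arange(8) * 45.0)
        assert "lrt_degenerate_uniform" in vonmises_lrt(h, 0.0).flags


class TestRotationEquivariance:
    @settings(deadline=None, max_examples=25)
    @given(delta=st.floats(-720, 720), seed=st.integers(0, 2**16))
    def test_shift_moves_mu_only(self, delta, seed):
        h = gen_headings(15, 75.0, 3.0, seed=seed)
        g = HeadingSet((h.angles + delta) % 360.0)
        r1, r2 = rayleigh_test(h), rayleigh_test(g)
        assert r2.rbar == pytest.approx(r1.rbar, abs=1e-10)
        assert r2.z == pytest.approx(r1.z, abs=1e-10)
        assert (r2.mu - r1.mu - delta) % 360.0 == pytest.approx(0.0, abs=1e-7) or \
               (r2.mu - r1.mu - delta) % 360.0 == pytest.approx(360.0, abs=1e-7)
        k1 = vonmises_lrt(h, 0.0).kappa
        k2 = vonmises_lrt(g, 0.0).kappa
        assert k2 == pytest.approx(k1, abs=1e-9)


class TestConditionSummary:
    def test_table_row_fields(self):
        h = gen_headings(20, 0.0, 3.0, seed=2, condition="2mN")
        row = condition_summary(h)
        assert row["condition"] == "2mN"
        assert row["n"] == 20
        for key in ("mu", "ci_lo", "ci_hi", "rayleigh_z", "rayleigh_p",
                    "v_u", "v_p", "lrt_chi2", "lrt_kappa", "lrt_p"):
            assert np.isfinite(row[key])
        assert row["target_in_ci"] in (True, False)
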