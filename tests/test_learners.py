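"""Learner update rules: hand-checked steps, clipping, and engine consistency."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from visuomotor import (
    FirstConfig,
    Mapping,
    SecondConfig,
    ZerothConfig,
    run_block,
    run_experiment,
    simulate_blocks,
)
from visuomotor.learners import (
    FirstState,
    SecondState,
    ShotRecord,
    ZerothState,
    act,
    init_state,
    update_first,
    update_second,
    update_zeroth,
)
from visuomotor.task import ExperimentDesign, TARGET_BOUND, W_STAR_RANGE, B_STAR_RANGE


def _record(x=0.0, j=0.0, c=0.0, e=0.0, g=0.0, L=None):
    return ShotRecord(block=0, shot=2, x=x, j=j, c=c, e=e, L=e * e if L is None else L,
                      noise_draw=g)


class TestZerothUpdate:
    def test_hand_step(self):
        """w <- w - eta*(L - L_prev)*g*x, b <- b - eta*(L - L_prev)*g."""
        st_ = ZerothState(w=1.0, b=0.0, config=ZerothConfig(sigma_g=0.1, eta=0.5), L_prev=0.09)
        update_zeroth(st_, _record(x=0.4, g=0.1, L=0.04))
        assert st_.w == pytest.approx(1.0 + 0.5 * 0.05 * 0.1 * 0.4, abs=1e-12)  # 1.001
        assert st_.b == pytest.approx(0.5 * 0.05 * 0.1, abs=1e-12)  # 0.0025
        assert st_.L_prev == 0.04

    def test_zero_loss_difference_is_no_op(self):
        st_ = ZerothState(w=1.2, b=-0.1, config=ZerothConfig(0.1, 5.0), L_prev=0.04)
        update_zeroth(st_, _record(x=0.3, g=0.2, L=0.04))
        assert (st_.w, st_.b) == (1.2, -0.1)

    def test_first_shot_seeds_L_prev_without_update(self):
        st_ = ZerothState(w=1.0, b=0.0, config=ZerothConfig(0.1, 5.0))
        update_zeroth(st_, _record(x=0.3, g=0.2, L=0.25))
        assert (st_.w, st_.b) == (1.0, 0.0)
        assert st_.L_prev == 0.25

    def test_clipping(self):
        st_ = ZerothState(w=1.74, b=0.24, config=ZerothConfig(0.1, 100.0), L_prev=1.0)
        update_zeroth(st_, _record(x=0.4, g=0.5, L=0.0))  # big negative dL pushes w, b up
        assert st_.w == 1.75
        assert st_.b == 0.25

    @given(e=st.floats(0.01, 2.0), g=st.floats(-0.3, 0.3), x=st.floats(-0.4, 0.4))
    @settings(max_examples=100, deadline=None)
    def test_sign_of_error_is_invisible(self, e, g, x):
        """Node perturbation sees only L = e^2: flipping e changes nothing."""
        cfg = ZerothConfig(sigma_g=0.1, eta=2.0)
        s1 = ZerothState(1.0, 0.0, cfg, L_prev=0.5)
        s2 = ZerothState(1.0, 0.0, cfg, L_prev=0.5)
        update_zeroth(s1, _record(x=x, g=g, e=e))
        update_zeroth(s2, _record(x=x, g=g, e=-e))
        assert s1.w == s2.w and s1.b == s2.b


class TestFirstUpdate:
    def test_hand_step(self):
        """m_est <- m_est + eta_m*e*j, s_est <- s_est + eta_s*e (gradient step on
        the forward-model prediction error), then w = 1/m_est, b = -s_est/m_est."""
        st_ = FirstState(m_est=1.0, s_est=0.0, config=FirstConfig(0.1, 0.1, 0.0))
        update_first(st_, _record(j=0.5, e=0.2))
        assert st_.m_est == pytest.approx(1.01, abs=1e-12)
        assert st_.s_est == pytest.approx(0.02, abs=1e-12)
        assert st_.w == pytest.approx(1 / 1.01, abs=1e-12)
        assert st_.b == pytest.approx(-0.02 / 1.01, abs=1e-12)

    def test_zero_error_is_no_op(self):
        st_ = FirstState(m_est=0.8, s_est=0.1, config=FirstConfig(0.3, 0.3, 0.0))
        update_first(st_, _record(j=0.4, e=0.0))
        assert st_.m_est == pytest.approx(0.8, abs=1e-15)
        assert st_.s_est == pytest.approx(0.1, abs=1e-15)

    def test_clip_and_back_correction(self):
        # a large update drives w above 1.75; w clips and m_est back-corrects
        st_ = FirstState(m_est=0.6, s_est=0.0, config=FirstConfig(2.0, 0.0, 0.0))
        update_first(st_, _record(j=0.5, e=-0.5))  # m_est -> 0.6 - 0.5 = 0.1, w -> 10
        assert st_.w == 1.75
        assert st_.m_est == pytest.approx(1 / 1.75, abs=1e-12)


class TestSecondUpdate:
    def test_hand_step(self):
        st_ = SecondState(m_est=1.0, s_est=0.0, config=SecondConfig(mu=1.0))
        update_second(st_, _record(j=0.5, e=0.1))
        # y=(0.5,1), v=y, y'v=1.25, k=v/2.25=(2/9, 4/9)
        np.testing.assert_allclose(
            st_.P, [[1 - 0.5 * 2 / 9, -0.5 * 4 / 9], [-2 / 9, 1 - 4 / 9]], atol=1e-12
        )
        assert st_.m_est == pytest.approx(1.0 + 0.1 * 2 / 9, abs=1e-12)
        assert st_.s_est == pytest.approx(0.1 * 4 / 9, abs=1e-12)

    def test_zero_error_still_sharpens_P(self):
        st_ = SecondState(m_est=1.0, s_est=0.0, config=SecondConfig(mu=0.8))
        P_before = st_.P.copy()
        update_second(st_, _record(j=0.5, e=0.0))
        assert st_.m_est == 1.0 and st_.s_est == 0.0
        assert not np.allclose(st_.P, P_before)

    def test_P_stays_symmetric(self):
        rng = np.random.default_rng(0)
        st_ = SecondState(m_est=1.0, s_est=0.0, config=SecondConfig(mu=0.5))
        for _ in range(20):
            update_second(st_, _record(j=rng.uniform(-1, 1), e=rng.uniform(-0.5, 0.5)))
            np.testing.assert_allclose(st_.P, st_.P.T, atol=1e-12)

    def test_rls_equals_batch_ridge(self):
        """mu=1, sigma_r=0 RLS reproduces ridge-regularized least squares.

        Oracle: theta_n = theta0 + (I + Y'Y)^-1 Y'(c - Y theta0) with prior
        P0 = I, over the block's (j, c) history, on 5-shot blocks chosen so
        clipping never binds.
        """
        rng = np.random.default_rng(5)
        for _ in range(20):
            mp = Mapping.from_optimal(rng.uniform(0.8, 1.2), rng.uniform(-0.05, 0.05))
            targets = rng.uniform(-TARGET_BOUND, TARGET_BOUND, 5)
            cfg = SecondConfig(mu=1.0, sigma_r=0.0)
            w0, b0 = 1.15, 0.0
            recs = run_block(cfg, w0, b0, mp, targets, rng)
            # recompute the final state by replaying updates
            state = init_state(cfg, w0, b0)
            for r in recs:
                update_second(state, r)
            Y = np.array([[r.j, 1.0] for r in recs])
            c = np.array([r.c for r in recs])
            theta0 = np.array([1.0 / w0, -b0 / w0])
            theta = theta0 + np.linalg.solve(np.eye(2) + Y.T @ Y, Y.T @ (c - Y @ theta0))
            assert state.m_est == pytest.approx(theta[0], abs=1e-10)
            assert state.s_est == pytest.approx(theta[1], abs=1e-10)

    def test_textbook_variant_rescales_P(self):
        cfg = SecondConfig(mu=0.5, textbook_update=True)
        st_ = SecondState(m_est=1.0, s_est=0.0, config=cfg)
        ref = SecondState(m_est=1.0, s_est=0.0, config=SecondConfig(mu=0.5))
        update_second(st_, _record(j=0.5, e=0.0))
        update_second(ref, _record(j=0.5, e=0.0))
        np.testing.assert_allclose(st_.P, ref.P / 0.5, atol=1e-12)


class TestAct:
    def test_zero_noise_is_linear_policy(self):
        st_ = ZerothState(1.0, 0.0, ZerothConfig(sigma_g=0.0, eta=1.0))
        j, g = act(st_, 0.2, np.random.default_rng(0))
        assert j == 0.2 and g == 0.0

    def test_converged_noiseless_learner_never_misses(self, design):
        mp = design.test_blocks[0].mapping
        cfg = FirstConfig(0.3, 0.3, sigma_r=0.0)
        recs = run_block(cfg, mp.w_star, mp.b_star, mp, design.test_blocks[0].targets,
                         np.random.default_rng(0))
        assert all(abs(r.e) < 1e-12 for r in recs)

    def test_noise_sd(self):
        st_ = ZerothState(1.0, 0.0, ZerothConfig(sigma_g=0.08, eta=1.0))
        rng = np.random.default_rng(1)
        draws = np.array([act(st_, 0.2, rng)[0] for _ in range(100_000)])
        assert np.std(draws) == pytest.approx(0.08, rel=0.02)


class _StreamRng:
    """Replays a fixed standard-normal stream through the Generator.normal API."""

    def __init__(self, z):
        self._it = iter(np.asarray(z, dtype=float).ravel())

    def normal(self, loc, scale):
        return loc + scale * next(self._it)


class TestEngineConsistency:
    @pytest.mark.parametrize(
        "config",
        [
            ZerothConfig(sigma_g=0.06, eta=6.0),
            FirstConfig(eta_m=2.0, eta_s=0.18, sigma_r=0.07),
            SecondConfig(mu=0.1, sigma_r=0.07),
        ],
        ids=["zeroth", "first", "second"],
    )
    def test_scalar_and_vector_paths_agree(self, config, design):
        """The per-shot reference loop and the vectorized engine are the same model."""
        m, s, x = design.test_arrays()
        rng = np.random.default_rng(7)
        z = rng.standard_normal(x.shape)
        vec = simulate_blocks(config, 1.1, -0.05, m, s, x, z)
        for blk in range(design.n_test):
            recs = run_block(
                config, 1.1, -0.05, design.test_blocks[blk].mapping,
                design.test_blocks[blk].targets, _StreamRng(z[blk]),
            )
            np.testing.assert_allclose(vec[blk], [abs(r.e) for r in recs], atol=1e-12)

    def test_disabled_learning_reduces_to_static_policy(self, design):
        """eta = 0: the error on every shot is exactly the no-learning error."""
        m, s, x = design.test_arrays()
        z = np.random.default_rng(3).standard_normal(x.shape)
        cfg = ZerothConfig(sigma_g=0.05, eta=0.0)
        err = simulate_blocks(cfg, 1.0, 0.0, m, s, x, z)
        static = np.abs(m[:, None] * (1.0 * x + 0.0 + 0.05 * z) + s[:, None] - x)
        np.testing.assert_allclose(err, static, atol=1e-12)


class TestRunExperiment:
    def test_shapes_and_nonnegativity(self, design):
        curves = run_experiment(ZerothConfig(0.05, 5.0), design, 1.0, 0.0, 7,
                                np.random.default_rng(0))
        assert curves.shape == (7, 15)
        assert np.all(curves >= 0)

    def test_determinism(self, design):
        cfg = SecondConfig(mu=0.1, sigma_r=0.07)
        c1 = run_experiment(cfg, design, 1.0, 0.0, 50, np.random.default_rng(12))
        c2 = run_experiment(cfg, design, 1.0, 0.0, 50, np.random.default_rng(12))
        np.testing.assert_array_equal(c1, c2)

    def test_chunking_invariance(self, design):
        cfg = FirstConfig(2.0, 0.18, 0.07)
        c1 = run_experiment(cfg, design, 1.0, 0.0, 40, np.random.default_rng(5), chunk_reps=7)
        c2 = run_experiment(cfg, design, 1.0, 0.0, 40, np.random.default_rng(5), chunk_reps=40)
        np.testing.assert_array_equal(c1, c2)

    def test_curves_export_round_trip(self, design, tmp_path):
        import pandas as pd

        from visuomotor.learners import curves_to_csv

        curves = run_experiment(FirstConfig(2.0, 0.18, 0.07), design, 1.0, 0.0, 5,
                                np.random.default_rng(0))
        curves_to_csv(curves, tmp_path / "curves.csv")
        df = pd.read_csv(tmp_path / "curves.csv", float_precision="round_trip")
        assert len(df) == 5 * 15
        np.testing.assert_array_equal(
            df.mean_error.to_numpy().reshape(5, 15), curves
        )

    def test_noiseless_second_order_error_decays(self, design):
        curve = run_experiment(SecondConfig(mu=1.0), design, 1.0, 0.0, 1,
                               np.random.default_rng(0))[0]
        assert curve[1:5].mean() > curve[11:15].mean()
        assert curve[14] < curve[1]

    def test_noiseless_optimized_rls_is_near_perfect(self):
        """With heavy forgetting and no response noise, shot-15 error ~ 0."""
        rng = np.random.default_rng(2)
        w = rng.uniform(*W_STAR_RANGE, 1000)
        bst = rng.uniform(*B_STAR_RANGE, 1000)
        x = rng.uniform(-TARGET_BOUND, TARGET_BOUND, (1000, 15))
        err = simulate_blocks(SecondConfig(mu=0.002), 1.0, 0.0, 1 / w, -bst / w, x,
                              np.zeros((1000, 15)))
        assert err[:, -1].mean() < 1e-2

    def test_order_separation_early_error(self, design):
        """Matched start and noise: zeroth > first > second in mean early error."""
        n = 1000
        curves = {
            "zeroth": run_experiment(ZerothConfig(0.053, 6.4), design, 1.0, 0.0, n,
                                     np.random.default_rng(21)),
            "first": run_experiment(FirstConfig(2.0, 0.18, 0.0705), design, 1.0, 0.0, n,
                                    np.random.default_rng(22)),
            "second": run_experiment(SecondConfig(0.07, 0.0705), design, 1.0, 0.0, n,
                                     np.random.default_rng(23)),
        }
        early = {k: v[:, 2:7].mean(axis=1) for k, v in curves.items()}
        se = {k: v.std(ddof=1) / np.sqrt(n) for k, v in early.items()}
        assert early["zeroth"].mean() - early["first"].mean() > 3 * (se["zeroth"] + se["first"])
        assert early["first"].mean() - early["second"].mean() > 3 * (se["first"] + se["second"])

    @given(
        w0=st.floats(0.3, 1.7),
        b0=st.floats(-0.2, 0.2),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=25, deadline=None)
    def test_policy_stays_in_clip_box(self, w0, b0, seed):
        """After every update the derived policy is inside the hypothesis space."""
        rng = np.random.default_rng(seed)
        mp = Mapping.from_optimal(rng.uniform(0.25, 1.75), rng.uniform(-0.25, 0.25))
        targets = rng.uniform(-TARGET_BOUND, TARGET_BOUND, 15)
        for cfg in (ZerothConfig(0.1, 50.0), FirstConfig(5.0, 1.0, 0.1),
                    SecondConfig(0.05, 0.1)):
            state = init_state(cfg, w0, b0)
            for t, x in enumerate(targets):
                j, n = act(state, x, rng)
                e = mp.m * j + mp.s - x
                from visuomotor.learners import update

                update(state, ShotRecord(0, t + 1, x, j, mp.m * j + mp.s, e, e * e, n))
                assert 0.25 - 1e-12 <= state.w <= 1.75 + 1e-12
                assert -0.25 - 1e-12 <= state.b <= 0.25 + 1e-12
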