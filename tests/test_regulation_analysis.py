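import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit, logit

from evspan.regulation_analysis import (
    PolyTerm,
    binned_curve,
    build_design,
    build_sfd_frame,
    fit_logistic,
    fit_loglinear_sfd,
    orthopoly,
)


class TestBinnedCurve:
    def test_constant_outcome_all_ones(self):
        rng = np.random.default_rng(0)
        df = binned_curve(rng.normal(size=500), np.ones(500), n_bins=5)
        assert (df["proportion"] == 1.0).all()
        assert df["count"].sum() == 500

    def test_independent_outcome_flat_within_ci(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=10_000)
        y = rng.random(10_000) < 0.5
        df = binned_curve(x, y.astype(float), n_bins=10)
        assert ((df["ci_low"] <= 0.5) & (0.5 <= df["ci_high"])).all()

    def test_monotone_logistic_generator_gives_increasing_curve(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=20_000)
        y = (rng.random(20_000) < expit(-1.0 + 1.5 * x)).astype(float)
        df = binned_curve(x, y, n_bins=8)
        p = df["proportion"].to_numpy()
        assert (np.diff(p) > -0.02).all() and p[-1] > p[0] + 0.3

    def test_few_distinct_values_reduces_bins_with_warning(self):
        x = np.repeat([0.0, 1.0, 2.0], 30)
        y = np.zeros(90)
        with pytest.warns(UserWarning, match="distinct"):
            df = binned_curve(x, y, n_bins=10)
        assert len(df) <= 3


class TestOrthopoly:
    def test_columns_centered_and_orthonormal(self):
        rng = np.random.default_rng(3)
        x = rng.normal(2.0, 5.0, 400)
        B = orthopoly(x, 3)
        assert np.abs(B.mean(axis=0)).max() < 1e-12
        gram = B.T @ B
        assert np.abs(gram - np.eye(3)).max() < 1e-10

    def test_degree2_on_small_grid_matches_classical_contrasts(self):
        """Discrete orthogonal polynomials on x = 1..5: linear
        (-2,-1,0,1,2)/sqrt(10), quadratic (2,-1,-2,-1,2)/sqrt(14)."""
        B = orthopoly(np.arange(1.0, 6.0), 2)
        lin = np.array([-2, -1, 0, 1, 2]) / math.sqrt(10)
        quad = np.array([2, -1, -2, -1, 2]) / math.sqrt(14)
        assert np.abs(B[:, 0] - lin).max() < 1e-10
        assert np.abs(np.abs(B[:, 1]) - np.abs(quad)).max() < 1e-10

    def test_insufficient_distinct_values_error(self):
        with pytest.raises(ValueError, match="distinct"):
            orthopoly(np.array([1.0, 1.0, 2.0]), 2)


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        y = np.array([1.0] * 25 + [0.0] * 75)
        frame = pd.DataFrame({"y": y})
        fit = fit_logistic(frame, "y", terms=[])
        assert fit.converged
        assert fit.estimates[0] == pytest.approx(math.log(0.25 / 0.75), abs=1e-8)

    def test_slope_recovery_within_ci(self):
        rng = np.random.default_rng(4)
        n = 20_000
        evs = rng.normal(10.0, 5.0, n)
        y = (rng.random(n) < expit(-3.0 + 0.15 * evs)).astype(float)
        frame = pd.DataFrame({"y": y, "evs": evs})
        fit = fit_logistic(frame, "y", terms=[PolyTerm("evs", 1, raw=True)])
        b, se = fit.estimates[1], fit.standard_errors[1]
        assert b - 1.96 * se <= 0.15 <= b + 1.96 * se

    def test_agreement_with_reference_glm(self):
        """Coefficients match statsmodels' logistic GLM to 1e-8 on 20
        random datasets."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(80, 400))
            X = rng.normal(size=(n, 2))
            eta = -0.5 + X @ np.array([0.8, -1.2])
            y = (rng.random(n) < expit(eta)).astype(float)
            frame = pd.DataFrame({"y": y, "a": X[:, 0], "b": X[:, 1]})
            fit = fit_logistic(
                frame, "y",
                terms=[PolyTerm("a", 1, raw=True), PolyTerm("b", 1, raw=True)],
            )
            ref = sm.GLM(y, sm.add_constant(X), family=sm.families.Binomial()).fit()
            assert np.abs(fit.estimates - ref.params).max() < 1e-8
            assert np.abs(fit.standard_errors - ref.bse).max() < 1e-5

    def test_complete_separation_flagged_not_silent(self):
        x = np.concatenate([np.full(30, -2.0), np.full(30, 2.0)])
        y = (x > 0).astype(float)
        frame = pd.DataFrame({"y": y, "x": x + 0.001 * np.arange(60)})
        fit = fit_logistic(frame, "y", terms=[PolyTerm("x", 1, raw=True)])
        assert not fit.converged
        assert "separation" in fit.message


def _sim_word_frame(rng, n_trials=10, n_words=6, beta_freq=0.0, beta_evs=0.0,
                    n_sentences=3):
    """Single-fixation word table + corpus with a known log-SFD model."""
    corpus_rows, word_rows = [], []
    for s in range(n_sentences):
        sid = f"s{s:03d}"
        for w in range(n_words):
            corpus_rows.append(
                dict(sentence_id=sid, word_index=w, word="a" * int(rng.integers(2, 9)),
                     frequency_per_million=float(10 ** rng.normal(2, 1)),
                     predictability=float(rng.uniform(0, 1)))
            )
    corpus = pd.DataFrame(corpus_rows)
    props = corpus.set_index(["sentence_id", "word_index"])
    for t in range(n_trials):
        sid = f"s{t % n_sentences:03d}"
        for w in range(1, n_words - 1):
            lf = math.log10(props.loc[(sid, w)]["frequency_per_million"])
            evs = float(rng.normal(16.0, 5.0))
            log_sfd = 5.6 + beta_freq * lf + beta_evs * evs + rng.normal(0, 0.2)
            word_rows.append(
                dict(subject_id=f"p{t % 4}", trial_id=f"t{t:03d}", sentence_id=sid,
                     word_index=w, sfd=math.exp(log_sfd), excluded=False,
                     launch_site_letters=float(rng.normal(5, 2)),
                     landing_site_letters=float(rng.uniform(1, 5)),
                     outgoing_saccade_letters=float(rng.normal(6, 2)),
                     onset_evs=evs, delta_evs=float(rng.normal(3, 1)))
            )
    return pd.DataFrame(word_rows), corpus


class TestSfdFrame:
    def test_log_sfd_is_natural_log(self):
        rng = np.random.default_rng(6)
        wf, corpus = _sim_word_frame(rng, n_trials=3)
        wf.loc[0, "sfd"] = 273.0
        frame = build_sfd_frame(wf, corpus)
        row = frame[(frame.trial_id == wf.loc[0, "trial_id"])
                    & (frame.word_index == wf.loc[0, "word_index"])]
        assert row["log_sfd"].iloc[0] == pytest.approx(math.log(273.0), abs=1e-12)
        assert math.log(273.0) == pytest.approx(5.609, abs=5e-4)

    def test_sentence_edge_words_never_appear(self):
        rng = np.random.default_rng(7)
        wf, corpus = _sim_word_frame(rng, n_trials=4, n_words=6)
        edge = wf.copy()
        edge.loc[len(edge)] = {**wf.iloc[0].to_dict(), "word_index": 0}
        frame = build_sfd_frame(edge, corpus)
        assert frame["word_index"].min() >= 1
        assert frame["word_index"].max() <= 4

    def test_frame_matches_hand_assembly(self):
        """Covariate columns equal an independently assembled frame."""
        rng = np.random.default_rng(8)
        wf, corpus = _sim_word_frame(rng, n_trials=10)
        frame = build_sfd_frame(wf, corpus, center=False)
        props = corpus.set_index(["sentence_id", "word_index"])
        for _, row in frame.sample(10, random_state=1).iterrows():
            sid, w = row["sentence_id"], int(row["word_index"])
            assert row["length_n"] == len(props.loc[(sid, w)]["word"])
            assert row["log_freq_prev"] == pytest.approx(
                math.log10(props.loc[(sid, w - 1)]["frequency_per_million"])
            )
            assert row["pred_next"] == pytest.approx(
                props.loc[(sid, w + 1)]["predictability"]
            )

    def test_centering(self):
        rng = np.random.default_rng(9)
        wf, corpus = _sim_word_frame(rng, n_trials=10)
        frame = build_sfd_frame(wf, corpus, center=True)
        assert abs(frame["length_n"].mean()) < 1e-10
        assert abs(frame["onset_evs"].mean()) < 1e-10


class TestFitLoglinearSfd:
    def test_pure_noise_small_t_values(self):
        rng = np.random.default_rng(10)
        rejections = 0
        n_terms = 0
        for _ in range(30):
            wf, corpus = _sim_word_frame(rng, n_trials=25)
            frame = build_sfd_frame(wf, corpus)
            fit = fit_loglinear_sfd(
                frame,
                terms=[PolyTerm("log_freq_n", 2), PolyTerm("length_n", 2)],
                interactions_with=None,
            )
            tvals = fit.z_values[1:]  # drop intercept
            rejections += int(np.sum(np.abs(tvals) > 1.96))
            n_terms += len(tvals)
        assert 0.01 < rejections / n_terms < 0.12  # ~5% type-I

    def test_frequency_effect_recovered(self):
        rng = np.random.default_rng(11)
        wf, corpus = _sim_word_frame(rng, n_trials=200, beta_freq=-0.08)
        frame = build_sfd_frame(wf, corpus, center=False)
        fit = fit_loglinear_sfd(
            frame,
            terms=[PolyTerm("log_freq_n", 1, raw=True)],
            interactions_with=None,
        )
        b, se = fit.estimates[1], fit.standard_errors[1]
        assert b - 2.5 * se <= -0.08 <= b + 2.5 * se

    def test_evs_effect_yields_positive_main_effect(self):
        rng = np.random.default_rng(12)
        wf, corpus = _sim_word_frame(rng, n_trials=200, beta_evs=0.01)
        frame = build_sfd_frame(wf, corpus, center=False)
        fit = fit_loglinear_sfd(
            frame,
            terms=[PolyTerm("onset_evs", 1, raw=True)],
            interactions_with=None,
        )
        assert fit.estimates[1] > 0
        assert fit.z_values[1] > 2.0

    def test_rank_deficiency_names_aliased_columns(self):
        rng = np.random.default_rng(13)
        wf, corpus = _sim_word_frame(rng, n_trials=10)
        frame = build_sfd_frame(wf, corpus)
        frame["dup"] = frame["onset_evs"]
        with pytest.raises(ValueError, match="aliased"):
            fit_loglinear_sfd(
                frame,
                terms=[PolyTerm("onset_evs", 1, raw=True),
                       PolyTerm("dup", 1, raw=True)],
                interactions_with=None,
            )

    def test_supports_evs_interactions(self):
        rng = np.random.default_rng(14)
        wf, corpus = _sim_word_frame(rng, n_trials=80, n_sentences=40)
        frame = build_sfd_frame(wf, corpus)
        fit = fit_loglinear_sfd(frame)
        assert any(name.startswith("onset_evs:") for name in fit.names)
        assert fit.converged


class TestCouplingRecovery:
    """Recovery of the simulator's EVS-coupling from fitted logistic models."""

    @staticmethod
    def _simulate(n_trials, coupled, seed, n_sentences=30):
        from evspan import (
            ArticulationConfig,
            CorpusConfig,
            OculomotorConfig,
            generate_corpus,
            layouts_from_corpus,
            simulate_trial,
        )
        from evspan.synthetic_data import (
            calibrate_skip_intercept,
            ground_truth_exits,
            make_length_pmf,
        )

        corpus = generate_corpus(CorpusConfig(n_sentences=n_sentences), seed=seed)
        lays = list(layouts_from_corpus(corpus).values())
        oculo = OculomotorConfig(coupling_enabled=coupled, blink_trial_prob=0.0)
        artic = ArticulationConfig()
        skip_c = calibrate_skip_intercept(oculo, make_length_pmf())
        rng = np.random.default_rng(seed + 1)
        gts = []
        for i in range(n_trials):
            st = simulate_trial(lays[i % len(lays)], oculo, artic, rng,
                                skip_intercept=skip_c)
            gts.append(st.ground_truth)
        return ground_truth_exits(pd.concat(gts, ignore_index=True))

    def test_coupled_regression_slope_significant_across_replicates(self):
        """A positive offset-EVS slope on regressions is detected in
        every replicate when coupling is on (scaled-down power check)."""
        hits = 0
        for rep in range(10):
            g = self._simulate(150, coupled=True, seed=300 + rep)
            g = g[g["regression_possible"] & g["offset_evs"].notna()]
            fit = fit_logistic(g, "regression",
                               terms=[PolyTerm("offset_evs", 1, raw=True)])
            if fit.estimates[1] > 0 and fit.z_values[1] > 1.96:
                hits += 1
        assert hits >= 9

    def test_offset_evs_more_predictive_than_onset_for_regressions(self):
        """Regressions are triggered on end-of-fixation EVS in the
        coupled generator, so the offset-EVS model fits better."""
        g = self._simulate(400, coupled=True, seed=500)
        g = g[g["regression_possible"] & g["offset_evs"].notna()
              & g["onset_evs"].notna()]
        f_off = fit_logistic(g, "regression",
                             terms=[PolyTerm("offset_evs", 1, raw=True)])
        f_on = fit_logistic(g, "regression",
                            terms=[PolyTerm("onset_evs", 1, raw=True)])
        assert f_off.deviance < f_on.deviance
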