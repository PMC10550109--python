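"""HMM core: emission factorisation, forward-backward, Viterbi, Baum-Welch."""

import numpy as np
import pandas as pd
import pytest

from modalhmm import (
    FitError,
    HMMParams,
    ObservationPanel,
    ParameterError,
    baum_welch,
    emission_prob,
    forward_backward,
    posterior_decode,
    sequence_loglik,
    viterbi,
)
from modalhmm.panel_io import SOURCES
from modalhmm.synthetic import default_paper_spec, paper_params, simulate_observations, simulate_truth

from conftest import enumerate_paths, path_joint_logp, random_params, random_sequence


def _one_district_panel(obs_weeks, week0="2020-W37"):
    """Panel with a single district from a (L, 4) observation array."""
    from modalhmm.panel_io import date_to_week, week_to_date
    from datetime import timedelta

    obs = np.asarray(obs_weeks, dtype=np.int8)[None, :, :]
    d0 = week_to_date(week0)
    weeks = [date_to_week(d0 + timedelta(weeks=k)) for k in range(obs.shape[1])]
    districts = pd.DataFrame({"district_id": ["d1"], "district_name": ["D1"], "state": ["OH"]})
    return ObservationPanel(districts, weeks, obs, window=np.array([[0, obs.shape[1]]]))


class TestEmissionProb:
    def test_all_sources_missing_marginalises_to_one(self, rng):
        params = random_params(rng)
        assert emission_prob(params, 2, [0, 0, 0, 0]) == 1.0

    def test_single_source_reads_published_cell(self):
        # true in-person, only Burbio present reporting in-person
        params = paper_params()
        got = emission_prob(params, 3, [3, 0, 0, 0])
        assert got == pytest.approx(0.823, abs=1e-6)

    def test_present_sources_multiply(self):
        # true hybrid, R2LT and SD both report hybrid
        params = paper_params()
        got = emission_prob(params, 2, [0, 0, 2, 2])
        assert got == pytest.approx(0.997 * 0.863, abs=1e-3)


class TestSequenceLoglik:
    def test_all_missing_sequence_has_zero_loglik(self, rng):
        params = random_params(rng)
        assert sequence_loglik(params, np.zeros((1, 4), dtype=int)) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_pi_identity_emissions_single_obs(self):
        eye = np.eye(3)
        params = HMMParams(pi=np.full(3, 1 / 3), T=eye, emissions={s: eye for s in SOURCES})
        seq = np.array([[0, 0, 2, 0]])
        assert sequence_loglik(params, seq) == pytest.approx(np.log(1 / 3))

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(10):
            params = random_params(rng)
            seq = random_sequence(rng, int(rng.integers(1, 7)))
            ll_oracle, *_ = enumerate_paths(params, seq)
            assert sequence_loglik(params, seq) == pytest.approx(ll_oracle, abs=1e-9)

    def test_long_sequence_does_not_underflow(self, rng):
        params = random_params(rng)
        seq = random_sequence(rng, 150)
        ll = sequence_loglik(params, seq)
        assert np.isfinite(ll) and ll < 0


class TestForwardBackward:
    def test_all_missing_uniform_model_gives_uniform_posteriors(self):
        uni = np.full((3, 3), 1 / 3)
        params = HMMParams(pi=np.full(3, 1 / 3), T=uni, emissions={s: np.eye(3) for s in SOURCES})
        gamma, xi, ll = forward_backward(params, np.zeros((6, 4), dtype=int))
        assert np.allclose(gamma, 1 / 3)
        assert ll == pytest.approx(0.0, abs=1e-12)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(10):
            params = random_params(rng)
            seq = random_sequence(rng, 5)
            _, gamma_oracle, *_ = enumerate_paths(params, seq)
            gamma, xi, ll = forward_backward(params, seq)
            assert np.allclose(gamma, gamma_oracle, atol=1e-9)

    def test_xi_marginalises_to_gamma(self, rng):
        params = random_params(rng)
        seq = random_sequence(rng, 8)
        gamma, xi, _ = forward_backward(params, seq)
        assert np.allclose(gamma.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(xi.sum(axis=(1, 2)), 1.0, atol=1e-9)
        assert np.allclose(xi.sum(axis=2), gamma[:-1], atol=1e-9)

    def test_noiseless_consistent_sequence_gives_point_mass(self):
        eye = np.eye(3)
        params = HMMParams(
            pi=np.full(3, 1 / 3), T=np.full((3, 3), 1 / 3), emissions={s: eye for s in SOURCES}
        )
        seq = np.tile([2, 2, 2, 2], (5, 1))
        gamma, _, _ = forward_backward(params, seq)
        assert np.allclose(gamma[:, 1], 1.0, atol=1e-12)


class TestViterbi:
    def test_identity_emissions_path_equals_observations(self):
        eye = np.eye(3)
        params = HMMParams(
            pi=np.full(3, 1 / 3), T=np.full((3, 3), 1 / 3), emissions={s: eye for s in SOURCES}
        )
        states = np.array([1, 3, 2, 2, 1])
        seq = np.zeros((5, 4), dtype=int)
        seq[:, 2] = states
        assert (viterbi(params, seq) == states).all()

    def test_matches_enumeration_argmax(self, rng):
        for _ in range(10):
            params = random_params(rng)
            seq = random_sequence(rng, 6)
            *_, best_path, best_logp = enumerate_paths(params, seq)
            got = viterbi(params, seq)
            assert path_joint_logp(params, seq, got) == pytest.approx(best_logp, abs=1e-9)

    def test_all_missing_sticky_chain_stays_in_person(self):
        # persistent dynamics + concentrated start: self-transition dominates
        params = paper_params(pi=np.array([0.0, 0.0, 1.0]))
        path = viterbi(params, np.zeros((20, 4), dtype=int))
        assert (path == 3).all()


class TestBaumWelch:
    def _small_panel(self, seed=0, n_districts=60, n_weeks=12):
        spec = default_paper_spec(n_districts=n_districts, n_weeks=n_weeks, seed=seed)
        return simulate_observations(simulate_truth(spec), spec)

    def test_loglik_trace_monotone(self):
        fit = baum_welch(self._small_panel(), seed=0, restarts=2, tol=1e-7, max_iter=100)
        assert (np.diff(fit.loglik_trace) >= -1e-8).all()

    def test_infinite_tol_runs_exactly_one_iteration(self):
        fit = baum_welch(self._small_panel(), seed=0, restarts=1, tol=np.inf, max_iter=50)
        assert len(fit.loglik_trace) == 2
        assert fit.n_iter == 1

    def test_empty_panel_raises_fit_error(self):
        spec = default_paper_spec(n_districts=5, n_weeks=5, seed=0)
        for s in SOURCES:
            spec.presence[s][:] = 0.0
        panel = simulate_observations(simulate_truth(spec), spec)
        with pytest.raises(FitError):
            baum_welch(panel, seed=0)

    def test_perfect_single_source_recovers_identity_emissions(self):
        # one district fully observed by a perfect source over a
        # persistent modality path: its emission matrix approaches
        # identity on the visited states
        states = np.array([1] * 14 + [2] * 13 + [3] * 13)
        obs = np.zeros((40, 4), dtype=int)
        obs[:, 2] = states
        panel = _one_district_panel(obs)
        fit = baum_welch(panel, seed=1, restarts=3, tol=1e-9, max_iter=200)
        E = fit.params.emissions["R2LT"]
        # visited hidden states should emit nearly deterministically
        assert (E.max(axis=1) > 0.99).all()

    def test_absent_source_contributes_nothing_to_its_emission_update(self):
        spec = default_paper_spec(n_districts=80, n_weeks=12, seed=2)
        spec.presence["MCH"][:] = 0.0
        panel = simulate_observations(simulate_truth(spec), spec)
        fit = baum_welch(panel, seed=0, restarts=1, tol=1e-6, max_iter=50)
        # with zero MCH observations its rows fall back to uninformative uniform
        assert np.allclose(fit.params.emissions["MCH"], 1 / 3, atol=1e-9)

    def test_invalid_init_rejected(self):
        panel = self._small_panel()
        params = paper_params()
        with pytest.raises(ParameterError):
            bad = HMMParams(
                pi=params.pi, T=np.full((3, 3), np.nan), emissions=params.emissions
            )


class TestPosteriorDecode:
    def test_noiseless_panel_point_masses_match_truth(self):
        eye = np.eye(3)
        params = HMMParams(
            pi=np.full(3, 1 / 3), T=np.full((3, 3), 1 / 3), emissions={s: eye for s in SOURCES}
        )
        spec = default_paper_spec(n_districts=20, n_weeks=10, seed=6)
        truth = simulate_truth(spec)
        obs = np.repeat(truth.paths[:, :, None], 4, axis=2)
        districts = pd.DataFrame(
            {
                "district_id": truth.district_ids,
                "district_name": truth.district_ids,
                "state": "OH",
            }
        )
        panel = ObservationPanel(districts, truth.week_ids, obs)
        decoded = posterior_decode(params, panel)
        assert (decoded.map_state[decoded.valid] == truth.paths[decoded.valid]).all()
        assert (decoded.viterbi_state[decoded.valid] == truth.paths[decoded.valid]).all()
        assert np.allclose(decoded.confidence[decoded.valid], 1.0, atol=1e-9)

    def test_all_missing_district_gets_prior_marginals(self):
        params = paper_params()
        panel = _one_district_panel(np.zeros((5, 4), dtype=int))
        decoded = posterior_decode(params, panel)
        # smoothing without data: marginals are the pi/T-propagated prior
        expected = params.pi.copy()
        for t in range(5):
            assert np.allclose(decoded.posterior[0, t], expected, atol=1e-12)
            expected = expected @ params.T

    def test_posteriors_match_enumeration(self, rng):
        params = random_params(rng)
        seq = random_sequence(rng, 5)
        panel = _one_district_panel(seq)
        decoded = posterior_decode(params, panel)
        _, gamma_oracle, *_ = enumerate_paths(params, seq)
        assert np.allclose(decoded.posterior[0, :5], gamma_oracle, atol=1e-9)


class TestPermutationCovariance:
    def test_decode_commutes_with_state_relabeling(self, rng):
        params = random_params(rng)
        perm = np.array([2, 0, 1])
        permuted = params.permute(perm)
        seq = random_sequence(rng, 7)
        panel = _one_district_panel(seq)
        a = posterior_decode(params, panel)
        b = posterior_decode(permuted, panel)
        assert np.allclose(b.posterior[0, :, perm], a.posterior[0].T, atol=1e-12)
        assert (perm[a.viterbi_state[0] - 1] + 1 == b.viterbi_state[0]).all()


class TestParamsSerialisation:
    def test_json_round_trip(self, rng, tmp_path):
        params = random_params(rng)
        path = tmp_path / "params.json"
        params.to_json(path)
        back = HMMParams.from_json(path)
        assert np.allclose(back.pi, params.pi)
        assert np.allclose(back.T, params.T)
        for s in SOURCES:
            assert np.allclose(back.emissions[s], params.emissions[s])

    def test_row_sum_validation(self):
        with pytest.raises(ParameterError):
            HMMParams(pi=[0.5, 0.5, 0.5], T=np.eye(3), emissions={s: np.eye(3) for s in SOURCES})


class TestHmmlearnCrossCheck:
    """Independent oracle: a single fully-observed source reduces to a
    plain categorical HMM, which hmmlearn implements."""

    def test_loglik_and_viterbi_agree(self, rng):
        from hmmlearn.hmm import CategoricalHMM

        params = random_params(rng)
        model = CategoricalHMM(n_components=3)
        model.startprob_ = params.pi
        model.transmat_ = params.T
        model.emissionprob_ = params.emissions["R2LT"]
        states = rng.integers(1, 4, size=25)
        seq = np.zeros((25, 4), dtype=int)
        seq[:, 2] = states
        obs = (states - 1).reshape(-1, 1)
        assert sequence_loglik(params, seq) == pytest.approx(model.score(obs), abs=1e-9)
        assert (viterbi(params, seq) == model.predict(obs) + 1).all()
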