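import numpy as np
import pandas as pd
import pytest

from dynaprl import task


def _block_table(trials):
    v = trials[trials["valid"]]
    g = v.groupby(["session_id", "block_ordinal"])
    return pd.DataFrame({
        "contrast": g["contrast_label"].first(),
        "better": g["better_side"].first(),
        "length": g.size(),
    }).reset_index()


class TestSessionStructure:
    def test_same_seed_same_table(self):
        cfg = task.TaskConfig(n_trials=400)
        a, _ = task.simulate_session("standard", {"alpha": .4, "beta": 3.},
                                     cfg, seed=9)
        b, _ = task.simulate_session("standard", {"alpha": .4, "beta": 3.},
                                     cfg, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_block_lengths_without_deferral(self):
        # the oracle policy never accumulates incorrect streaks, so every
        # completed block runs its planned 15-30 trials
        trials, _ = task.simulate_session("oracle", None,
                                          task.TaskConfig(n_trials=3000),
                                          seed=2)
        blocks = _block_table(trials)
        completed = blocks.iloc[:-1]
        assert completed["length"].between(15, 30).all()

    def test_overlong_blocks_only_in_contrast_blocks(self):
        # a random agent can defer transitions via 4+ incorrect streaks, but
        # only where an incorrect lever exists (HC/LC)
        trials, _ = task.simulate_session("random", None,
                                          task.TaskConfig(n_trials=5000),
                                          seed=3)
        blocks = _block_table(trials).iloc[:-1]
        over = blocks[blocks["length"] > 30]
        assert (over["contrast"] != "NC").all()
        assert blocks[blocks["contrast"] == "NC"]["length"].between(15, 30).all()

    def test_transition_rules(self):
        trials, _ = task.simulate_session("random", None,
                                          task.TaskConfig(n_trials=6000),
                                          seed=4)
        blocks = _block_table(trials)
        prev = blocks.shift(1)
        both = blocks.iloc[1:]
        prev = prev.iloc[1:]
        # NC blocks never repeat back-to-back
        assert not ((both["contrast"] == "NC")
                    & (prev["contrast"] == "NC")).any()
        # the better side alternates between consecutive contrast blocks
        contrast_blocks = blocks[blocks["contrast"] != "NC"]
        sides = contrast_blocks["better"].tolist()
        assert all(a != b for a, b in zip(sides, sides[1:]))

    def test_magnitude_manipulation_scope(self):
        trials, _ = task.simulate_session("oracle", None,
                                          task.TaskConfig(n_trials=20000),
                                          seed=5)
        v = trials[trials["valid"]]
        manip = v[~v["reward_volume"].isin([0.0, 33.0])]
        assert set(manip["reward_volume"]) <= {16.5, 66.0}
        assert (manip["contrast_label"] != "NC").all()
        assert (manip["block_trial"] > 12).all()
        assert (manip["reward"] == 1).all()

    def test_magnitude_manipulation_can_be_disabled(self):
        trials, _ = task.simulate_session(
            "oracle", None,
            task.TaskConfig(n_trials=5000, magnitude_manipulation=False),
            seed=5)
        assert set(trials["reward_volume"].unique()) <= {0.0, 33.0}

    def test_random_agent_reward_rate_is_045_everywhere(self):
        # (0.8+0.1)/2 = (0.6+0.3)/2 = 0.45 for a coin-flipping agent
        trials, _ = task.simulate_session("random", None,
                                          task.TaskConfig(n_trials=30000),
                                          seed=6)
        v = trials[trials["valid"]]
        for _, grp in v.groupby("contrast_label"):
            se = np.sqrt(0.45 * 0.55 / len(grp))
            assert abs(grp["reward"].mean() - 0.45) < 3 * se

    def test_invalid_trials_injected_and_rate(self):
        trials, _ = task.simulate_session(
            "standard", {"alpha": .4, "beta": 3.},
            task.TaskConfig(n_trials=5000, invalid_rate=0.05), seed=7)
        rate = 1 - trials["valid"].mean()
        assert 0.03 < rate < 0.07
        assert (trials.loc[~trials["valid"], "reward"] == 0).all()

    def test_latent_trace_covers_valid_trials(self):
        trials, trace = task.simulate_session(
            "avg_rpe", {"alpha": .4, "beta": 3., "hw": .5},
            task.TaskConfig(n_trials=300), seed=8)
        assert trace is not None and len(trace) == int(trials["valid"].sum())

    def test_unknown_agent_and_bad_params(self):
        with pytest.raises(ValueError):
            task.simulate_session("qlearn", {}, task.TaskConfig(50), seed=0)
        with pytest.raises(ValueError):
            task.simulate_session("standard", {"alpha": 2.0, "beta": 1.0},
                                  task.TaskConfig(50), seed=0)


class TestBlockSpec:
    def test_probability_pair_must_match_label(self):
        with pytest.raises(ValueError):
            task.BlockSpec("HC", 0.6, 0.3, 20, "left")
        spec = task.BlockSpec("HC", 0.1, 0.8, 20, "right")
        assert spec.planned_length == 20

    def test_nc_has_no_better_side(self):
        with pytest.raises(ValueError):
            task.BlockSpec("NC", 0.45, 0.45, 20, "left")
        with pytest.raises(ValueError):
            task.BlockSpec("LC", 0.6, 0.3, 20, None)


class TestCohort:
    def _cfg(self, **kw):
        base = dict(
            group_labels=("a", "b"), n_rats_per_group=5, sessions_per_rat=10,
            trials_per_session=20, generating_model="standard",
            group_param_distributions={
                "a": {"alpha": (0.4, 0.1), "beta": (3.0, 0.5)},
                "b": {"alpha": (0.6, 0.1), "beta": (3.0, 0.5)}},
            seed=0)
        base.update(kw)
        return task.CohortConfig(**base)

    def test_session_counting(self):
        trials, params = task.generate_cohort(self._cfg())
        assert trials.groupby(["rat_id", "session_id"]).ngroups == 100
        assert len(params) == 10

    def test_seed_reproducibility(self):
        t1, p1 = task.generate_cohort(self._cfg())
        t2, p2 = task.generate_cohort(self._cfg())
        pd.testing.assert_frame_equal(t1, t2)
        pd.testing.assert_frame_equal(p1, p2)

    def test_planted_group_difference_in_true_params(self):
        cfg = self._cfg(n_rats_per_group=60, sessions_per_rat=1,
                        trials_per_session=5,
                        group_param_distributions={
                            "a": {"alpha": (0.6, 0.05), "beta": (3.0, 0.3)},
                            "b": {"alpha": (0.4, 0.05), "beta": (3.0, 0.3)}})
        _, params = task.generate_cohort(cfg)
        diff = (params[params["group"] == "a"]["alpha"].mean()
                - params[params["group"] == "b"]["alpha"].mean())
        assert diff == pytest.approx(0.2, abs=0.03)

    def test_identical_distributions_differ_only_by_noise(self):
        d = {"alpha": (0.5, 0.1), "beta": (3.0, 0.5)}
        cfg = self._cfg(n_rats_per_group=50, sessions_per_rat=1,
                        trials_per_session=5,
                        group_param_distributions={"a": d, "b": d})
        _, params = task.generate_cohort(cfg)
        diff = (params[params["group"] == "a"]["alpha"].mean()
                - params[params["group"] == "b"]["alpha"].mean())
        assert abs(diff) < 3 * 0.1 * np.sqrt(2 / 50)

    def test_degenerate_distribution_out_of_bounds(self):
        with pytest.raises(ValueError, match="degenerate"):
            task.generate_cohort(self._cfg(group_param_distributions={
                "a": {"alpha": (1.5, 0.0), "beta": (3.0, 0.5)},
                "b": {"alpha": (0.5, 0.1), "beta": (3.0, 0.5)}}))

    def test_parameters_respect_bounds(self, reference_cohort):
        _, params = reference_cohort
        for col in ("alpha_pos", "alpha_neg", "gamma_pos", "gamma_neg"):
            assert params[col].between(0, 1).all()
        assert (params["beta"] >= 0).all()


class TestTrialIO:
    def test_roundtrip(self, tmp_path, reference_cohort):
        trials, _ = reference_cohort
        path = tmp_path / "trials.csv"
        task.write_trials(trials, path)
        back = task.read_trials(path)
        canonical = list(task.TRIAL_COLUMNS)
        pd.testing.assert_frame_equal(
            trials[canonical].reset_index(drop=True), back[canonical])

    def test_empty_roundtrip(self, tmp_path):
        path = tmp_path / "empty.csv"
        task.write_trials(pd.DataFrame(columns=task.TRIAL_COLUMNS), path)
        back = task.read_trials(path)
        assert len(back) == 0 and list(back.columns) == list(task.TRIAL_COLUMNS)

    def test_domain_error_names_rows(self, tmp_path, reference_cohort):
        trials, _ = reference_cohort
        bad = trials.head(20).copy()
        bad.loc[7, "reward"] = 2
        bad.loc[7, "reward_volume"] = 33.0
        path = tmp_path / "bad.csv"
        bad[list(task.TRIAL_COLUMNS)].to_csv(path, index=False)
        with pytest.raises(ValueError, match=r"reward.*\[7\]"):
            task.read_trials(path)

    def test_missing_column(self, tmp_path, reference_cohort):
        trials, _ = reference_cohort
        path = tmp_path / "m.csv"
        trials.drop(columns=["choice"]).to_csv(path, index=False)
        with pytest.raises(ValueError, match="missing columns"):
            task.read_trials(path)

    def test_non_monotone_trial_index(self, reference_cohort):
        trials, _ = reference_cohort
        bad = trials.head(10).copy()
        bad.loc[3, "trial_index"] = 2
        with pytest.raises(ValueError, match="non-monotone"):
            task.validate_trials(bad)

    def test_volume_consistency_checked(self, reference_cohort):
        trials, _ = reference_cohort
        bad = trials.head(10).copy()
        idx = bad.index[bad["reward"] == 1][0]
        bad.loc[idx, "reward_volume"] = 0.0
        with pytest.raises(ValueError, match="reward_volume"):
            task.validate_trials(bad)
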