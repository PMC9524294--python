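"""Trial execution: gating, tagging, accumulation, determinism."""

import dataclasses
import math

import numpy as np
import pytest

from cogsync import SimulationConfig
from cogsync.engine import gate, make_tags, run_trial
from cogsync.oscillator import OscillatorParams, PhaseState, step_phase
from cogsync.paradigms import TrialRecord, gen_extensive, gen_stroop, gen_wcst


def make_trial(active, target=0, labels=None):
    return TrialRecord(0, 0, "T", tuple(active), target, labels or {})


def quiet_config(**kw):
    """Engine config without phase noise or rate noise unless overridden."""
    base = dict(phase_noise_sd=0.0, rate_noise_sd=0.0, kappa=0.0)
    base.update(kw)
    return SimulationConfig(**base)


class TestGate:
    def test_truth_table(self):
        assert gate(0.8, 0.6) == 1
        assert gate(0.8, -0.6) == 0
        assert gate(-0.8, 0.6) == 0
        assert gate(0.0, 0.6) == 0

    def test_in_phase_beats_anti_phase_over_a_full_cycle(self):
        # Oracle: integrate the gate over one exact rotation period.
        params = OscillatorParams(C=2 * math.pi / 100)
        sender = PhaseState(1.0, 0.0)
        inphase = PhaseState(1.0, 0.0)
        antiphase = PhaseState(-1.0, 0.0)
        total_in = total_anti = 0
        for _ in range(100):
            sender = step_phase(sender, params)
            inphase = step_phase(inphase, params)
            antiphase = step_phase(antiphase, params)
            total_in += gate(sender.E, inphase.E)
            total_anti += gate(sender.E, antiphase.E)
        assert total_anti == 0
        assert total_in > 40  # ~half the cycle


class TestMakeTags:
    def test_extensive_tags_are_the_block_stimulus_set(self):
        trial = make_trial([13], labels={"block_units": (12, 13, 14, 15)})
        tags = make_tags("extensive", trial, True, 36)
        assert tags.sum() == 4
        assert list(np.flatnonzero(tags)) == [12, 13, 14, 15]

    def test_stroop_tags_follow_the_relevant_dimension(self):
        trial = make_trial([2, 5, 9], labels={"relevant_dimension": "color"})
        tags = make_tags("stroop", trial, True, 10)
        assert list(np.flatnonzero(tags)) == [4, 5, 6, 7]
        trial = make_trial([2, 5, 8], labels={"relevant_dimension": "word"})
        assert list(np.flatnonzero(make_tags("stroop", trial, True, 10))) == [0, 1, 2, 3]

    def test_wcst_tags_follow_the_relevant_dimension(self):
        trial = make_trial([0, 5, 10], labels={"relevant_dimension": "shape"})
        assert list(np.flatnonzero(make_tags("wcst", trial, True, 12))) == [8, 9, 10, 11]

    def test_sync_off_means_no_tags(self):
        trial = make_trial([2, 5, 9], labels={"relevant_dimension": "color"})
        assert make_tags("stroop", trial, False, 10).sum() == 0

    def test_unknown_paradigm_rejected(self):
        with pytest.raises(ValueError):
            make_tags("flanker", make_trial([0]), True, 4)


class TestRunTrial:
    def test_zero_weights_time_out(self, config):
        cfg = quiet_config().engine_config()
        ctrl = SimulationConfig().control_state(False)
        W = np.zeros((4, 2))
        res = run_trial(W, make_trial([0]), np.zeros(4, np.uint8), ctrl, cfg,
                        np.random.default_rng(0))
        assert res.omission and res.rt == 500
        assert res.response == 0  # argmax tie resolves to the lowest index

    def test_strong_weight_drives_its_output_no_earlier_than_ungated_bound(self):
        # Oracle: scalar leaky accumulation with the gate always open is an
        # upper bound on accumulation speed, hence a lower bound on RT.
        sim = quiet_config()
        cfg = sim.engine_config()
        ctrl = sim.control_state(False)
        W = np.zeros((3, 2))
        W[1, 1] = 1.0
        res = run_trial(W, make_trial([1], target=1), np.zeros(3, np.uint8), ctrl,
                        cfg, np.random.default_rng(1))
        assert not res.omission and res.response == 1 and res.correct
        x = acc = 0.0
        bound_rt = None
        for t in range(1, 501):
            x = (1 - cfg.leak) * x + W[1, 1] * cfg.input_drive
            acc += x
            if acc >= cfg.threshold:
                bound_rt = t
                break
        assert bound_rt is not None
        assert res.rt >= bound_rt

    def test_untrained_two_output_responses_split_evenly(self, config):
        cfg = config.engine_config()
        ctrl = config.control_state(True)
        responses = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            W = rng.uniform(0, 0.1, size=(4, 2))
            res = run_trial(W, make_trial([0], labels={}), np.ones(4, np.uint8),
                            ctrl, cfg, rng)
            responses.append(res.response)
        rate = np.mean(responses)
        assert 0.4 <= rate <= 0.6

    def test_nonfinite_weights_rejected(self, config):
        cfg = config.engine_config()
        ctrl = config.control_state(False)
        W = np.full((2, 2), np.nan)
        with pytest.raises(ValueError):
            run_trial(W, make_trial([0]), np.zeros(2, np.uint8), ctrl, cfg,
                      np.random.default_rng(0))

    def test_active_inputs_validated_against_weight_shape(self, config):
        cfg = config.engine_config()
        ctrl = config.control_state(False)
        with pytest.raises(ValueError):
            run_trial(np.zeros((2, 2)), make_trial([5]), np.zeros(2, np.uint8),
                      ctrl, cfg, np.random.default_rng(0))

    def test_seed_reproducibility(self, config):
        cfg = config.engine_config()
        ctrl = config.control_state(True)
        W = np.random.default_rng(0).uniform(0, 0.1, (4, 2))
        trial = make_trial([1])
        tags = np.array([1, 1, 0, 0], np.uint8)
        r1 = run_trial(W, trial, tags, ctrl, cfg, np.random.default_rng(7))
        r2 = run_trial(W, trial, tags, ctrl, cfg, np.random.default_rng(7))
        assert r1.rt == r2.rt and r1.response == r2.response
        assert r1.theta_power == r2.theta_power
        assert np.array_equal(r1.accumulators, r2.accumulators)

    def test_python_and_numba_backends_are_bit_identical(self, config):
        ctrl = config.control_state(True)
        design = gen_extensive(5)
        cfg_nb = config.engine_config()
        cfg_py = dataclasses.replace(cfg_nb, backend="python")
        for seed, trial in enumerate(design.trials[:4]):
            tags = make_tags("extensive", trial, True, design.n_inputs)
            r1 = run_trial(design.initial_weights, trial, tags, ctrl, cfg_nb,
                           np.random.default_rng(seed))
            r2 = run_trial(design.initial_weights, trial, tags, ctrl, cfg_py,
                           np.random.default_rng(seed))
            assert (r1.rt, r1.response, r1.omission) == (r2.rt, r2.response, r2.omission)
            assert r1.theta_power == r2.theta_power
            assert np.array_equal(r1.accumulators, r2.accumulators)

    def test_theta_power_at_baseline_when_sync_disabled(self, config):
        cfg = config.engine_config()
        ctrl = config.control_state(False)
        res = run_trial(np.zeros((2, 2)), make_trial([0]), np.zeros(2, np.uint8),
                        ctrl, cfg, np.random.default_rng(3))
        assert res.theta_power == pytest.approx(config.baseline_radius**2, rel=0.1)

    def test_theta_power_is_nondecreasing_in_rt(self, config):
        # The MFC amplitude grows deterministically until the response, so a
        # longer pre-response window can only raise mean squared amplitude.
        cfg = config.engine_config()
        ctrl = config.control_state(True)
        results = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            W = rng.uniform(0.1, 0.5, size=(2, 2))
            results.append(
                run_trial(W, make_trial([0]), np.ones(2, np.uint8), ctrl, cfg, rng)
            )
        results.sort(key=lambda r: r.rt)
        powers = [r.theta_power for r in results]
        assert all(a <= b + 1e-12 for a, b in zip(powers, powers[1:]))

    def test_tagged_input_transmits_more_than_untagged(self, config):
        # Equal weights on two active inputs driving separate outputs; the
        # tagged pathway should win the accumulator race on average.
        cfg = config.engine_config()
        ctrl = config.control_state(True)
        W = np.array([[0.2, 0.0], [0.0, 0.2]])
        tags = np.array([1, 0], np.uint8)
        wins = 0
        n = 120
        for seed in range(n):
            res = run_trial(W, make_trial([0, 1]), tags, ctrl, cfg,
                            np.random.default_rng(seed))
            wins += res.accumulators[0] > res.accumulators[1]
        assert wins / n > 0.6

    def test_zero_burst_gain_makes_sync_and_nosync_identical(self):
        sim = SimulationConfig(burst_gain=0.0)
        cfg = sim.engine_config()
        design = gen_extensive(5)
        for seed, trial in enumerate(design.trials[:4]):
            tags_on = make_tags("extensive", trial, True, design.n_inputs)
            tags_off = make_tags("extensive", trial, False, design.n_inputs)
            r1 = run_trial(design.initial_weights, trial, tags_on,
                           sim.control_state(True), cfg, np.random.default_rng(seed))
            r2 = run_trial(design.initial_weights, trial, tags_off,
                           sim.control_state(False), cfg, np.random.default_rng(seed))
            assert (r1.rt, r1.response, r1.omission) == (r2.rt, r2.response, r2.omission)
            assert np.array_equal(r1.accumulators, r2.accumulators)
            assert np.array_equal(r1.x_out_max, r2.x_out_max)

    @pytest.mark.parametrize("paradigm,gen,n_in", [
        ("stroop", gen_stroop, 10), ("wcst", gen_wcst, 12),
    ])
    def test_untrained_inseparable_tasks_time_out_or_follow_bias(self, paradigm, gen, n_in, config):
        cfg = config.engine_config()
        ctrl = config.control_state(True)
        design = gen(2)
        rng = np.random.default_rng(0)
        omit = []
        for trial in design.trials[:32]:
            tags = make_tags(paradigm, trial, True, n_in)
            res = run_trial(design.initial_weights, trial, tags, ctrl, cfg, rng)
            omit.append(res.omission)
        if paradigm == "wcst":
            assert all(omit)  # near-zero weights never reach threshold
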