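"""Secure training protocol, orchestration, accounting, and obliviousness."""

import numpy as np
import pytest

from securelr import (
    Channel,
    DepletionError,
    FixedPointFormat,
    ProtocolContext,
    RunConfig,
    TrainingJob,
    TrustedInitializer,
    count_secure_multiplications,
    randomness_plan,
    run_end_to_end,
    share_table,
    train_secure,
)
from securelr.fixedpoint import to_signed
from securelr.synthetic import (
    SyntheticSpec,
    accuracy,
    generate,
    make_shards,
    train_clear_fixed,
    train_clear_float,
)

from conftest import make_ctx


def job_df(n=64, m=16, seed=7, **kw):
    df, wtrue = generate(SyntheticSpec(n_samples=n, n_features=m, sparsity=0.25, seed=seed, **kw))
    return df, wtrue


class TestTrainSecure:
    def test_zero_iterations_gives_zero_weights(self, fmt64, rng):
        df, _ = job_df(8, 3)
        X, t, _ = share_table(df, fmt64, seed=0)
        ctx = make_ctx(fmt64)
        w = train_secure(TrainingJob(X, t, 0.1, 0, fmt64), ctx)
        assert np.all(w.open() == 0)
        assert ctx.channel.rounds == 0

    def test_secure_weights_match_fixed_point_simulator(self, fmt64):
        """Synthetic job (n=64, m=16, η=0.125, 20 iters): secure weights are
        within n_iter*3 LSB per coordinate of the clear ring simulator."""
        df, _ = job_df(64, 16, seed=7)
        X = df.drop(columns="label").to_numpy()
        t = df["label"].to_numpy()
        cfg = RunConfig(learning_rate=0.125, iterations=20, seed=7)
        res = run_end_to_end(df, cfg)
        w_fix = train_clear_fixed(X, t, 0.125, 20, fmt64, trunc_model="random", seed=3)
        dev = np.abs(to_signed(res["weights_ring"] - w_fix, fmt64))
        assert dev.max() <= 20 * 3

    def test_secure_run_replayed_by_strong_oracle_exactly(self, fmt64):
        """Feeding the recorded truncation share splits to the clear simulator
        reproduces the secure weights bit for bit."""
        df, _ = job_df(32, 8, seed=5)
        X = df.drop(columns="label").to_numpy()
        t = df["label"].to_numpy()
        cfg = RunConfig(learning_rate=0.125, iterations=10, seed=5)
        trace = []
        res = run_end_to_end(df, cfg, trunc_trace=trace)
        w_replay = train_clear_fixed(
            X, t, 0.125, 10, fmt64, trunc_model="replay", trunc_trace=trace
        )
        assert np.array_equal(res["weights_ring"], w_replay)

    def test_no_accuracy_loss_vs_float_training(self, fmt64):
        """Held-out accuracy of the secure model matches the float clear
        clipped-ReLU model within one percentage point."""
        df, _ = job_df(200, 16, seed=11)
        train, test = df.iloc[:100], df.iloc[100:]
        cfg = RunConfig(learning_rate=0.02, iterations=30, seed=11)
        res = run_end_to_end(train, cfg)
        w_float = train_clear_float(
            train.drop(columns="label").to_numpy(), train["label"].to_numpy(), 0.02, 30
        )
        Xte, tte = test.drop(columns="label").to_numpy(), test["label"].to_numpy()
        assert abs(accuracy(Xte, tte, res["weights"]) - accuracy(Xte, tte, w_float)) <= 0.01

    def test_parameter_recovery_on_separable_data(self, fmt64):
        df, wtrue = generate(
            SyntheticSpec(n_samples=200, n_features=20, sparsity=0.3, margin=0.5, seed=3)
        )
        cfg = RunConfig(learning_rate=0.02, iterations=100, seed=3)
        w = run_end_to_end(df, cfg)["weights"]
        cos = float(w @ wtrue / (np.linalg.norm(w) * np.linalg.norm(wtrue)))
        assert cos > 0.8

    def test_weights_stay_on_activation_scale(self, fmt64):
        """Decoded weights remain finite and inside the fixed-point window."""
        df, _ = job_df(64, 16, seed=7)
        res = run_end_to_end(df, RunConfig(learning_rate=0.125, iterations=20, seed=7))
        assert np.all(np.isfinite(res["weights"]))
        assert np.all(np.abs(res["weights"]) < 2**15)

    def test_undersized_tape_depletes_loudly(self, fmt64):
        df, _ = job_df(8, 3)
        X, t, _ = share_table(df, fmt64, seed=0)
        plan = randomness_plan(8, 3, 1, fmt64)
        tape = TrustedInitializer(0).generate(plan)  # sized for 1 iteration
        ctx = ProtocolContext(fmt64, tape, Channel())
        with pytest.raises(DepletionError):
            train_secure(TrainingJob(X, t, 0.1, 2, fmt64), ctx)


class TestEndToEnd:
    def test_partition_modes_yield_bit_identical_weights(self):
        """Sharing is per-value: horizontal vs vertical vs arbitrary partition
        of the same table produces identical revealed weights."""
        df, _ = job_df(24, 6, seed=9)
        cfg = RunConfig(learning_rate=0.1, iterations=5, seed=9)
        results = []
        for mode in ("horizontal", "vertical", "arbitrary"):
            shards = make_shards(df, mode, 3, seed=1)
            results.append(run_end_to_end(df, cfg, shards=shards)["weights_ring"])
        assert np.array_equal(results[0], results[1])
        assert np.array_equal(results[0], results[2])

    def test_single_owner_equals_multi_owner(self):
        df, _ = job_df(24, 6, seed=9)
        cfg = RunConfig(learning_rate=0.1, iterations=5, seed=9)
        solo = run_end_to_end(df, cfg)["weights_ring"]
        multi = run_end_to_end(df, cfg, shards=make_shards(df, "arbitrary", 3, seed=2))[
            "weights_ring"
        ]
        assert np.array_equal(solo, multi)

    def test_incomplete_shards_rejected(self, fmt64):
        df, _ = job_df(8, 3)
        shards = make_shards(df, "horizontal", 2, seed=0)[:1]  # drop an owner
        from securelr import ProtocolError

        with pytest.raises(ProtocolError):
            share_table(df, fmt64, seed=0, shards=shards)

    def test_obliviousness_transcripts_identical_across_datasets(self):
        """Message sizes depend only on (n, m, n_iter, fmt), never on values."""
        cfg = RunConfig(learning_rate=0.05, iterations=4, seed=1)
        t1 = run_end_to_end(job_df(20, 5, seed=1)[0], cfg)["transcript"]
        t2 = run_end_to_end(job_df(20, 5, seed=77, label_noise=0.2)[0], cfg)["transcript"]
        assert t1 == t2


class TestAccounting:
    def test_hand_counted_single_iteration_trace(self, fmt64):
        """n=1, m=1, one iteration, lookahead carries: tally from first principles.

        k = 28 decomposed positions: generate layer 27 ANDs; Kogge–Stone
        levels d=1,2,4,8,16 contribute 2*(27-d) ANDs; the OR over b=15
        integer bits costs 14 ANDs; conversion uses 2 masked bits; the two
        final products cost 2 ring mults; each matmul costs n*(m+1) = 2.
        """
        tally = count_secure_multiplications(1, 1, 1, fmt64, variant="lookahead")
        assert tally["inner_product"]["ring_mults"] == 2
        assert tally["gradient"]["ring_mults"] == 2
        lookahead = sum(2 * (27 - d) for d in (1, 2, 4, 8, 16))
        assert tally["activation"]["bit_ands"] == 27 + lookahead + 14
        assert tally["activation"]["masked_bits"] == 2
        assert tally["activation"]["ring_mults"] == 2
        assert tally["total"]["ring_mults"] == 6

    def test_tally_linear_in_iterations(self, fmt64):
        one = count_secure_multiplications(32, 8, 1, fmt64)["total"]
        five = count_secure_multiplications(32, 8, 5, fmt64)["total"]
        assert all(five[k] == 5 * one[k] for k in one)

    def test_tally_matches_live_consumption_counters(self, fmt64):
        """Closed form equals the instrumented counters of a real run."""
        df, _ = job_df(32, 8, seed=2)
        for variant in ("ripple", "lookahead"):
            cfg = RunConfig(learning_rate=0.1, iterations=5, seed=2, variant=variant)
            stats = run_end_to_end(df, cfg)["stats"]
            tally = count_secure_multiplications(32, 8, 5, fmt64, variant=variant)["total"]
            assert stats["ring_mults"] == tally["ring_mults"]
            assert stats["bit_ands"] == tally["bit_ands"]
            assert stats["masked_bits"] == tally["masked_bits"]


class TestRunConfig:
    def test_defaults_are_reference_operating_point(self):
        cfg = RunConfig()
        assert (cfg.frac_bits, cfg.int_bits, cfg.ring_bits) == (12, 15, 64)
        assert cfg.learning_rate == 0.001
        assert cfg.fmt == FixedPointFormat(12, 15, 64)

    def test_unknown_keys_rejected(self):
        with pytest.raises(ValueError):
            RunConfig.from_mapping({"learning_rat": 0.1})
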