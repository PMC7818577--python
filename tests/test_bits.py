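"""Secure Z_2 gates, bit decomposition, and bit-to-ring conversion."""

import numpy as np
import pytest

from securelr import (
    ProtocolError,
    SharedTensor,
    and_gate,
    bit_to_ring,
    decompose,
    not_gate,
    or_tree,
    share,
    xor_gate,
)
from securelr.sharing import bit_payload_bytes

from conftest import make_ctx


class TestGates:
    def test_and_truth_table_over_many_splits(self, fmt8, rng):
        """All four input combinations, 200 fresh share splits each."""
        reps = 200
        a = np.tile(np.array([0, 0, 1, 1], dtype=np.uint8), reps)
        b = np.tile(np.array([0, 1, 0, 1], dtype=np.uint8), reps)
        ctx = make_ctx(fmt8)
        z = and_gate(share(a, 1, rng), share(b, 1, rng), ctx)
        assert np.array_equal(z.open(), a & b)

    def test_and_with_public_zero(self, fmt8, rng):
        ctx = make_ctx(fmt8)
        zero = SharedTensor(np.zeros(64, dtype=np.uint8), np.zeros(64, dtype=np.uint8), 1)
        y = share(rng.integers(0, 2, 64, dtype=np.uint8), 1, rng)
        assert np.all(and_gate(zero, y, ctx).open() == 0)

    def test_xor_not_truth_tables_local(self, fmt8, rng):
        a = np.array([0, 0, 1, 1], dtype=np.uint8)
        b = np.array([0, 1, 0, 1], dtype=np.uint8)
        pa, pb = share(a, 1, rng), share(b, 1, rng)
        assert np.array_equal(xor_gate(pa, pb).open(), a ^ b)
        q = not_gate(pa)
        assert np.array_equal(q.open(), 1 - a)
        assert np.array_equal(q.bob, pa.bob)  # NOT flips exactly one party's share

    def test_batched_and_traffic_is_bitsliced(self, fmt64, rng):
        """A 1024-instance AND sends packed words: 2*ceil(1024/8) bytes/direction."""
        ctx = make_ctx(fmt64)
        x = share(rng.integers(0, 2, 1024, dtype=np.uint8), 1, rng)
        y = share(rng.integers(0, 2, 1024, dtype=np.uint8), 1, rng)
        and_gate(x, y, ctx)
        per_direction = 2 * bit_payload_bytes(1024)  # opening both D and E
        assert ctx.channel.bytes_a_to_b == per_direction
        assert ctx.channel.bytes_b_to_a == per_direction
        assert ctx.channel.rounds == 1

    def test_or_tree_matches_any(self, fmt8, rng):
        ctx = make_ctx(fmt8)
        bits = rng.integers(0, 2, (15, 500), dtype=np.uint8)
        z = or_tree(share(bits, 1, rng), ctx)
        assert np.array_equal(z.open(), bits.any(axis=0).astype(np.uint8))


class TestDecompose:
    def test_exhaustive_z256_all_values_many_splits(self, fmt8, rng):
        """Recomposed bits equal binary(x) for all x in Z_256, 20 splits each."""
        xs = np.tile(np.arange(256, dtype=np.uint8), 20)
        for variant in ("ripple", "lookahead"):
            ctx = make_ctx(fmt8)
            bv = decompose(share(xs, 8, rng), 8, ctx, variant=variant)
            assert np.array_equal(bv.recompose().astype(np.uint8), xs)

    def test_zero_bob_share_passthrough(self, fmt8, rng):
        """Shares (x, 0): no carries fire; output bits are the bits of x."""
        xs = np.arange(256, dtype=np.uint8)
        p = SharedTensor(xs, np.zeros_like(xs), 8)
        ctx = make_ctx(fmt8)
        bv = decompose(p, 8, ctx, variant="ripple")
        for i in range(8):
            assert np.array_equal(bv.position(i + 1).open(), (xs >> i) & 1)

    def test_variants_agree_on_random_lambda64(self, fmt64, rng):
        xs = rng.integers(0, 2**64, 2000, dtype=np.uint64)
        outs = []
        for variant in ("ripple", "lookahead"):
            ctx = make_ctx(fmt64)
            outs.append(decompose(share(xs, 64, rng), 64, ctx, variant=variant).recompose())
        assert np.array_equal(outs[0], outs[1])
        assert np.array_equal(outs[0], xs)

    def test_partial_agrees_with_full_low_positions(self, fmt64, rng):
        xs = rng.integers(0, 2**64, 300, dtype=np.uint64)
        k = fmt64.a + fmt64.b + 1
        p = share(xs, 64, rng)
        full = decompose(p, 64, make_ctx(fmt64), variant="lookahead")
        part = decompose(p, k, make_ctx(fmt64), variant="lookahead")
        assert np.array_equal(part.tensor.open(), full.tensor.open()[:k])

    @pytest.mark.parametrize("k", [4, 8, 16, 32])
    def test_round_complexity_by_variant(self, fmt64, rng, k):
        """Ripple rounds are linear in k; lookahead rounds logarithmic."""
        xs = rng.integers(0, 2**64, 10, dtype=np.uint64)
        ctx_r, ctx_l = make_ctx(fmt64), make_ctx(fmt64)
        decompose(share(xs, 64, rng), k, ctx_r, variant="ripple")
        decompose(share(xs, 64, rng), k, ctx_l, variant="lookahead")
        assert ctx_r.channel.rounds == k - 1  # 1 generate layer + (k-2) carry steps
        assert ctx_l.channel.rounds == 1 + int(np.ceil(np.log2(k - 1)))

    def test_rounds_invariant_in_batch_size(self, fmt64, rng):
        rounds = []
        for batch in (1, 64, 4096):
            ctx = make_ctx(fmt64)
            xs = rng.integers(0, 2**64, batch, dtype=np.uint64)
            decompose(share(xs, 64, rng), 28, ctx, variant="lookahead")
            rounds.append(ctx.channel.rounds)
        assert rounds[0] == rounds[1] == rounds[2]

    def test_k_out_of_range_rejected(self, fmt64, rng):
        p = share(np.zeros(4, dtype=np.uint64), 64, rng)
        with pytest.raises(ProtocolError):
            decompose(p, 65, make_ctx(fmt64))


class TestBitToRing:
    def test_all_four_mask_cases(self, fmt64):
        """b ∈ {0,1} × r ∈ {0,1}: c + (1-2c)·r always reconstructs b."""
        from securelr.randomness import MaskedBitRecord, MaskedBitRequest, RandomnessTape
        from securelr import Channel, ProtocolContext

        rng = np.random.default_rng(0)
        for b in (0, 1):
            for r in (0, 1):
                rec = MaskedBitRecord(
                    MaskedBitRequest((1,), 64),
                    share(np.array([r], dtype=np.uint8), 1, rng),
                    share(np.array([r], dtype=np.uint64), 64, rng),
                )
                ctx = ProtocolContext(fmt64, RandomnessTape([rec]), Channel())
                p = share(np.array([b], dtype=np.uint8), 1, rng)
                out = bit_to_ring(p, ctx)
                assert int(out.open()[0]) == b

    def test_random_instances_match_z2_reconstruction(self, fmt64, rng):
        ctx = make_ctx(fmt64)
        bits = rng.integers(0, 2, 100_000, dtype=np.uint8)
        p = share(bits, 1, rng)
        out = bit_to_ring(p, ctx).open()
        assert set(np.unique(out)) <= {0, 1}
        assert np.array_equal(out.astype(np.uint8), bits)

    def test_batch_costs_one_round(self, fmt64, rng):
        ctx = make_ctx(fmt64)
        p = share(rng.integers(0, 2, 1024, dtype=np.uint8), 1, rng)
        bit_to_ring(p, ctx)
        assert ctx.channel.rounds == 1

    def test_ring_input_rejected(self, fmt64, rng):
        p = share(np.zeros(4, dtype=np.uint64), 64, rng)
        with pytest.raises(ProtocolError):
            bit_to_ring(p, make_ctx(fmt64))
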