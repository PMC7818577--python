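"""Bit decomposition, secure Z_2 gates, and bit-to-ring share conversion.

Bit decomposition turns an arithmetic sharing x = x_A + x_B (mod 2^λ) into
per-position Z_2 sharings of the binary representation of x.  Each party
enters the bits of its own additive share as a trivial Z_2 sharing and the
parties jointly evaluate a binary-addition circuit with secure ANDs: the
carry recurrence c_{i+1} = (y_i ∧ z_i) ⊕ (c_i ∧ (y_i ⊕ z_i)) of a ripple-carry
adder.  Two interchangeable carry circuits are provided: a literal ripple
chain (Θ(k) rounds, the correctness reference) and a Kogge–Stone style
carry-lookahead prefix network (Θ(log k) rounds).  Decomposition may be
partial (k < λ positions) and is batched: all gate layers operate on the whole
instance batch at once, so round count is independent of batch size.

Bit-to-ring conversion of a Z_2 sharing of b uses a TI masked-bit pair (the
same random bit r shared in Z_2 and in Z_{2^λ}): the parties open c = b ⊕ r
(one batchable round) and locally output c + (1 − 2c)·⟦r⟧_{2^λ}.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from .beaver import ProtocolContext, secure_mul, secure_mul_batch
from .sharing import ProtocolError, SharedTensor, bit_payload_bytes

__all__ = [
    "BitVectorShare",
    "and_gate",
    "and_gate_batch",
    "xor_gate",
    "not_gate",
    "or_tree",
    "decompose",
    "bit_to_ring",
]


# -- gates ------------------------------------------------------------------

def and_gate(p: SharedTensor, s: SharedTensor, ctx: ProtocolContext) -> SharedTensor:
    """Elementwise secure AND of two Z_2 sharings (1 round, batch-wide)."""
    if p.bits != 1 or s.bits != 1:
        raise ProtocolError("AND is defined on Z_2 sharings")
    return secure_mul(p, s, ctx)


def and_gate_batch(pairs, ctx: ProtocolContext) -> List[SharedTensor]:
    """Independent ANDs issued together; they share one round."""
    for p, s in pairs:
        if p.bits != 1 or s.bits != 1:
            raise ProtocolError("AND is defined on Z_2 sharings")
    return secure_mul_batch(pairs, ctx)


def xor_gate(p: SharedTensor, s: SharedTensor) -> SharedTensor:
    """Local XOR: each party XORs its halves; zero traffic."""
    if p.bits != 1 or s.bits != 1:
        raise ProtocolError("XOR is defined on Z_2 sharings")
    return p + s


def not_gate(p: SharedTensor) -> SharedTensor:
    """Local NOT: Alice flips her share, Bob's is untouched."""
    if p.bits != 1:
        raise ProtocolError("NOT is defined on Z_2 sharings")
    return p.add_const(np.uint8(1))


def _and_tree(t: SharedTensor, ctx: ProtocolContext) -> SharedTensor:
    """AND-reduce along axis 0 with a balanced tree: ceil(log2 r) rounds."""
    while t.shape[0] > 1:
        r = t.shape[0]
        half = r // 2
        left = t[0 : 2 * half : 2]
        right = t[1 : 2 * half : 2]
        reduced = and_gate(left, right, ctx)
        if r % 2:
            reduced = SharedTensor(
                np.concatenate([reduced.alice, t.alice[-1:]]),
                np.concatenate([reduced.bob, t.bob[-1:]]),
                1,
            )
        t = reduced
    return t[0]


def or_tree(t: SharedTensor, ctx: ProtocolContext) -> SharedTensor:
    """OR-reduce along axis 0 via De Morgan: NOT(AND of NOTs)."""
    return not_gate(_and_tree(not_gate(t), ctx))


# -- bit decomposition ------------------------------------------------------

@dataclass
class BitVectorShare:
    """Z_2 sharings of bit positions 1..k (LSB first) for a batch of values.

    ``tensor`` has shape (k, *instance_shape); index i along axis 0 is bit
    position i+1 of the decomposed value.
    """

    tensor: SharedTensor

    @property
    def k(self) -> int:
        return self.tensor.shape[0]

    def position(self, i: int) -> SharedTensor:
        """1-based bit position, position 1 = least significant."""
        if not 1 <= i <= self.k:
            raise IndexError(f"bit position {i} outside 1..{self.k}")
        return self.tensor[i - 1]

    def recompose(self) -> np.ndarray:
        """Open all positions and reassemble the plaintext low-k bits."""
        bits = self.tensor.open().astype(np.uint64)
        weights = (np.uint64(1) << np.arange(self.k, dtype=np.uint64)).reshape(
            (self.k,) + (1,) * (bits.ndim - 1)
        )
        return (bits * weights).sum(axis=0, dtype=np.uint64)


def _share_bits(arr: np.ndarray, k: int) -> np.ndarray:
    """Low-k bits of each element, shape (k, *arr.shape), LSB first."""
    dt = arr.dtype
    shifts = np.arange(k, dtype=dt).reshape((k,) + (1,) * arr.ndim)
    return ((arr[None, ...] >> shifts) & dt.type(1)).astype(np.uint8)


def _ripple_carries(g: SharedTensor, p: SharedTensor, ctx) -> SharedTensor:
    """Sequential carry chain; k-2 rounds after the generate layer."""
    n = g.shape[0]
    cur = g[0]
    out_a = [cur.alice]
    out_b = [cur.bob]
    for i in range(1, n):
        t = and_gate(p[i], cur, ctx)
        cur = xor_gate(g[i], t)
        out_a.append(cur.alice)
        out_b.append(cur.bob)
    return SharedTensor(np.stack(out_a), np.stack(out_b), 1)


def _lookahead_carries(g: SharedTensor, p: SharedTensor, ctx) -> SharedTensor:
    """Kogge–Stone prefix network; ceil(log2 n) rounds after the generate layer."""
    n = g.shape[0]
    G, P = g, p
    d = 1
    while d < n:
        t_g, t_p = and_gate_batch([(P[d:], G[: n - d]), (P[d:], P[: n - d])], ctx)
        G = SharedTensor(
            np.concatenate([G.alice[:d], G.alice[d:] ^ t_g.alice]),
            np.concatenate([G.bob[:d], G.bob[d:] ^ t_g.bob]),
            1,
        )
        P = SharedTensor(
            np.concatenate([P.alice[:d], t_p.alice]),
            np.concatenate([P.bob[:d], t_p.bob]),
            1,
        )
        d *= 2
    return G


def decompose(
    x: SharedTensor, k: int, ctx: ProtocolContext, variant: str = "lookahead"
) -> BitVectorShare:
    """Secure (partial) bit decomposition of a ring sharing to k positions.

    Reconstructing the output positions 1..k yields the low-k bits of
    x_A + x_B mod 2^λ.  ``variant`` selects the carry circuit: "ripple"
    (linear rounds) or "lookahead" (logarithmic rounds).
    """
    if x.bits == 1:
        raise ProtocolError("input must be a ring sharing")
    if not 1 <= k <= x.bits:
        raise ProtocolError(f"cannot decompose {k} positions of a {x.bits}-bit ring")
    if variant not in ("ripple", "lookahead"):
        raise ProtocolError(f"unknown decomposition variant {variant!r}")

    inst_shape = x.shape
    flat = x.reshape(-1)
    zeros = np.zeros((k, flat.size), dtype=np.uint8)
    y = SharedTensor(_share_bits(flat.alice, k), zeros, 1)  # Alice's share bits
    z = SharedTensor(zeros.copy(), _share_bits(flat.bob, k), 1)  # Bob's share bits
    p = xor_gate(y, z)
    if k == 1:
        return BitVectorShare(p.reshape((1,) + inst_shape))

    g = and_gate(y[: k - 1], z[: k - 1], ctx)  # generate layer, 1 round
    carries = (
        _ripple_carries(g, p[: k - 1], ctx)
        if variant == "ripple"
        else _lookahead_carries(g, p[: k - 1], ctx)
    )
    out = SharedTensor(
        np.concatenate([p.alice[:1], p.alice[1:] ^ carries.alice]),
        np.concatenate([p.bob[:1], p.bob[1:] ^ carries.bob]),
        1,
    )
    return BitVectorShare(out.reshape((k,) + inst_shape))


# -- share conversion -------------------------------------------------------

def bit_to_ring(p: SharedTensor, ctx: ProtocolContext) -> SharedTensor:
    """Convert Z_2 sharings of bits into Z_{2^λ} sharings of the same bits.

    Opens c = b ⊕ r against a TI masked-bit pair (one round for the whole
    batch) and locally outputs c + (1 − 2c)·⟦r⟧_{2^λ}.
    """
    if p.bits != 1:
        raise ProtocolError("input must be a Z_2 sharing")
    lam = ctx.fmt.lam
    rec = ctx.randomness.take_masked_bits(p.shape, lam)
    c_sh = xor_gate(p, rec.r_bit)
    nbytes = bit_payload_bytes(c_sh.size)
    ctx.channel.exchange(nbytes, nbytes)
    c = c_sh.open()

    dt = ctx.fmt.dtype
    one = dt.type(1)
    neg_one = dt.type((1 << lam) - 1)
    sgn = np.where(c.astype(bool), neg_one, one)  # (1 - 2c) mod 2^λ
    out_a = c.astype(dt) + sgn * rec.r_ring.alice
    out_b = sgn * rec.r_ring.bob
    return SharedTensor(out_a, out_b, lam)
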