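"""Comparison-free secure evaluation of the clipped-ReLU activation ρ.

ρ(z) = 0 for z < −1/2, z + 1/2 for −1/2 ≤ z < 1/2, and 1 for z ≥ 1/2 — the
MPC-friendly piecewise-linear stand-in for the logistic sigmoid.  The secure
protocol avoids any general comparison: with z′ = z + 1/2 it only needs
(i) the sign of z′, read off bit a+b+1 of a *partial* bit decomposition
(legitimate because |z′| < 2^b forces every bit above position a+b to equal
the sign bit), and (ii) whether z′ ≥ 1, which holds iff any of the b integer
bits is set (an OR tree).  Both indicator bits are converted to ring sharings
P and G and the output is assembled with two sequential secure
multiplications:

    o = P · (z′ + G · (2^a − z′))

Because P and G are unscaled 0/1 ring integers, no truncation occurs anywhere
and the protocol is *exact*: the opened output equals encode(ρ(z)) bit for
bit.  All stages are batched, so the round count does not depend on how many
activations are evaluated together.
"""

from __future__ import annotations

import numpy as np

from .beaver import ProtocolContext, secure_mul
from .bits import bit_to_ring, decompose, not_gate, or_tree
from .sharing import ProtocolError, SharedTensor

__all__ = ["rho_clear", "rho_secure"]


def rho_clear(z):
    """Clipped ReLU on plaintext reals: min(1, max(0, z + 1/2))."""
    out = np.clip(np.asarray(z, dtype=np.float64) + 0.5, 0.0, 1.0)
    return out if out.shape else float(out)


def rho_secure(z: SharedTensor, ctx: ProtocolContext, variant: str = "lookahead") -> SharedTensor:
    """Secure batched clipped ReLU on a fixed-point sharing (scale 2^a).

    Precondition (caller's responsibility, cannot be checked obliviously):
    the plaintext satisfies |z + 1/2| < 2^b.  The result opens to exactly
    2^a, Q(z + 1/2), or 0 for the three branches of ρ.
    """
    fmt = ctx.fmt
    if z.bits != fmt.lam:
        raise ProtocolError("activation input must be shared over the session ring")
    a, b = fmt.a, fmt.b
    k = a + b + 1

    zp = z.add_const(fmt.dtype.type(1 << (a - 1)))  # z' = z + 1/2 at scale 2^a
    bv = decompose(zp, k, ctx, variant=variant)

    pos = not_gate(bv.position(k))         # sign bit of z' (negated)
    geq1 = or_tree(bv.tensor[a : a + b], ctx)  # any integer bit set <=> z' >= 1

    flags = SharedTensor(
        np.stack([pos.alice, geq1.alice]),
        np.stack([pos.bob, geq1.bob]),
        1,
    )
    ring_flags = bit_to_ring(flags, ctx)  # one conversion round for both flags
    P, G = ring_flags[0], ring_flags[1]

    # u = z' + G * (2^a - z'); o = P * u — two sequential multiplications,
    # no truncation: P and G are plain 0/1 integers.
    two_a = fmt.dtype.type(1 << a)
    t = secure_mul(G, zp.neg().add_const(two_a), ctx)
    u = zp + t
    return secure_mul(P, u, ctx)
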