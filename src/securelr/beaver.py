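"""Interactive arithmetic on shares: Beaver multiplication and local truncation.

Secure multiplication of sharings X, Y consumes one pre-distributed Beaver
triple (U, V, W = U·V): the parties open D = X−U and E = Y−V in a single
simultaneous exchange and locally assemble Z = W + D·V + U·E + D·E, with the
public D·E term added by Alice.  The same protocol covers scalar, elementwise,
inner-product and matrix products — always exactly one round — and Z_2
multiplication (AND) when the sharing modulus is 2.

Truncation of fixed-point products is purely local: Alice floor-divides her
share by 2^d, Bob negates, floor-divides, and negates again.  The result
equals the two's-complement floor division up to ±1 in the last place, except
with probability 2^{a+1−λ} (for values of magnitude below 2^a), in which case
it is arbitrary; see docs/methods.md for the error model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .fixedpoint import FixedPointFormat
from .randomness import _SourceBase
from .sharing import Channel, ProtocolError, SharedTensor, bit_payload_bytes

__all__ = ["ProtocolContext", "secure_mul", "secure_mul_batch", "truncate"]


@dataclass
class ProtocolContext:
    """One protocol session: format, randomness stream handle, channel."""

    fmt: FixedPointFormat
    randomness: _SourceBase
    channel: Channel


def _payload_bytes(x: SharedTensor, y_size: int) -> int:
    if x.bits == 1:
        return bit_payload_bytes(x.size) + bit_payload_bytes(y_size)
    return (x.size + y_size) * (x.bits // 8)


def _mask(x: SharedTensor, y: SharedTensor, ctx: ProtocolContext):
    """Draw the matching triple and form the D, E opening payloads."""
    if x.bits != y.bits:
        raise ProtocolError("operand modulus mismatch")
    kind = "elem" if x.shape == y.shape else "matmul"
    rec = ctx.randomness.take_triple(kind, x.bits, x.shape, y.shape)
    d_sh = x - rec.u
    e_sh = y - rec.v
    return kind, rec, d_sh, e_sh


def _combine(kind, rec, d_sh: SharedTensor, e_sh: SharedTensor) -> SharedTensor:
    d = d_sh.open()
    e = e_sh.open()
    u, v, w = rec.u, rec.v, rec.w
    if d_sh.bits == 1:
        za = w.alice ^ (d & v.alice) ^ (u.alice & e) ^ (d & e)
        zb = w.bob ^ (d & v.bob) ^ (u.bob & e)
        return SharedTensor(za, zb, 1)
    with np.errstate(over="ignore"):
        if kind == "elem":
            za = w.alice + d * v.alice + u.alice * e + d * e
            zb = w.bob + d * v.bob + u.bob * e
        else:
            za = w.alice + np.matmul(d, v.alice) + np.matmul(u.alice, e) + np.matmul(d, e)
            zb = w.bob + np.matmul(d, v.bob) + np.matmul(u.bob, e)
    return SharedTensor(za, zb, d_sh.bits)


def secure_mul_batch(
    pairs: Sequence[Tuple[SharedTensor, SharedTensor]], ctx: ProtocolContext
) -> List[SharedTensor]:
    """Multiply several independent pairs with a single shared round.

    All D/E openings are coalesced into one simultaneous exchange, so k
    independent multiplications issued together cost exactly 1 round.
    """
    staged = [_mask(x, y, ctx) for x, y in pairs]
    nbytes = sum(_payload_bytes(d, e.size) for _, _, d, e in staged)
    ctx.channel.exchange(nbytes, nbytes)
    return [_combine(kind, rec, d, e) for kind, rec, d, e in staged]


def secure_mul(x: SharedTensor, y: SharedTensor, ctx: ProtocolContext) -> SharedTensor:
    """Secure product of two sharings (elementwise if shapes match, else matmul).

    Exactly one communication round regardless of dimensions.
    """
    return secure_mul_batch([(x, y)], ctx)[0]


def truncate(x: SharedTensor, d: int, fmt: FixedPointFormat) -> SharedTensor:
    """Local two-party truncation by 2^d of a shared fixed-point value.

    Communication-free.  Alice keeps floor(x_A / 2^d); Bob keeps
    −floor(−x_B / 2^d) with all arithmetic wrapping mod 2^λ.
    """
    if x.bits == 1:
        raise ProtocolError("truncation is defined on ring sharings only")
    if not 0 <= d < x.bits:
        raise ProtocolError(f"shift amount {d} out of range for {x.bits}-bit ring")
    dt = x.dtype
    with np.errstate(over="ignore"):
        za = x.alice >> dt.type(d)
        zb = dt.type(0) - ((dt.type(0) - x.bob) >> dt.type(d))
    return SharedTensor(za, zb, x.bits)
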