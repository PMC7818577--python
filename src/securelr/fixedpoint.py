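"""Fixed-point encoding and exact arithmetic in the ring Z_{2^λ}.

Real values are mapped to ring elements with ``a`` fractional bits, ``b``
integer bits and a two's-complement sign: Q(x) = floor(2^a * x) for x >= 0 and
2^λ - floor(2^a * |x|) for x < 0.  All protocol arithmetic is exact modular
arithmetic on unsigned machine words; overflow silently wraps, by design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FixedPointFormat",
    "ring_dtype",
    "encode",
    "decode",
    "ring_add",
    "ring_sub",
    "ring_mul",
    "ring_scale",
    "ring_neg",
    "to_signed",
]

_DTYPES = {8: np.uint8, 16: np.uint16, 32: np.uint32, 64: np.uint64}


def ring_dtype(lam: int) -> np.dtype:
    """Unsigned machine-word dtype backing Z_{2^lam}."""
    try:
        return np.dtype(_DTYPES[lam])
    except KeyError:
        raise ValueError(f"ring bit width must be one of {sorted(_DTYPES)}, got {lam}")


@dataclass(frozen=True)
class FixedPointFormat:
    """Register map (a, b, λ) for fixed-point values shared over Z_{2^λ}.

    Parameters
    ----------
    a : int
        Number of fractional bits; one unit in the last place is 2**-a.
    b : int
        Number of integer bits; representable magnitudes are below 2**b.
    lam : int
        Total ring bits; the ring modulus is q = 2**lam.  Must be at least
        2*(a + b) so that a product of two in-range values still fits before
        truncation, and must be a machine word width (8, 16, 32 or 64).
    """

    a: int = 12
    b: int = 15
    lam: int = 64

    def __post_init__(self) -> None:
        if self.a < 1 or self.b < 1:
            raise ValueError("need at least one fractional and one integer bit")
        ring_dtype(self.lam)
        if self.lam < 2 * (self.a + self.b):
            raise ValueError(
                f"ring bits lam={self.lam} must be at least 2*(a+b)={2 * (self.a + self.b)}"
            )

    @property
    def q(self) -> int:
        return 1 << self.lam

    @property
    def dtype(self) -> np.dtype:
        return ring_dtype(self.lam)

    @property
    def scale(self) -> int:
        """Integer scale factor 2**a of the encoding."""
        return 1 << self.a

    @property
    def max_magnitude(self) -> float:
        return float(1 << self.b)


def encode(x, fmt: FixedPointFormat) -> np.ndarray:
    """Encode real value(s) into Z_{2^λ} fixed-point representation.

    Truncates the scaled magnitude toward zero (floor of 2^a*|x|), then applies
    the two's-complement sign.  Raises for |x| >= 2^b.
    """
    arr = np.asarray(x, dtype=np.float64)
    if np.any(~np.isfinite(arr)) or np.any(np.abs(arr) >= fmt.max_magnitude):
        raise ValueError(f"value magnitude must be below 2^b = {fmt.max_magnitude}")
    flat = np.atleast_1d(arr)
    mag = np.floor(np.abs(flat) * fmt.scale).astype(fmt.dtype)
    out = np.where(flat < 0, fmt.dtype.type(0) - mag, mag).astype(fmt.dtype)
    return out.reshape(arr.shape) if arr.ndim else out[0]


def to_signed(v, fmt: FixedPointFormat) -> np.ndarray:
    """Two's-complement reinterpretation of ring element(s) as signed integers."""
    arr = np.asarray(v, dtype=fmt.dtype)
    half = fmt.dtype.type(1) << fmt.dtype.type(fmt.lam - 1)
    # int64 is wide enough for every supported lam; lam=64 uses a direct view.
    if fmt.lam == 64:
        return arr.view(np.int64)
    signed = arr.astype(np.int64)
    signed = np.where(arr >= half, signed - (1 << fmt.lam), signed)
    return signed if signed.shape else signed[()]


def decode(v, fmt: FixedPointFormat) -> np.ndarray:
    """Decode ring element(s) back to real value(s).

    Inverse of :func:`encode` up to the 2**-a quantization.  Elements outside
    the representable window (bits above position a+b not replicating the sign
    bit) raise a range error.
    """
    signed = np.asarray(to_signed(v, fmt), dtype=np.float64)
    limit = float(1 << (fmt.a + fmt.b))
    if np.any(np.abs(signed) >= limit):
        raise ValueError("ring element outside the representable fixed-point window")
    out = signed / fmt.scale
    return out if out.shape else out[()]


def _pair(u, v, lam: int):
    dt = ring_dtype(lam)
    return np.asarray(u, dtype=dt), np.asarray(v, dtype=dt)


def ring_add(u, v, lam: int) -> np.ndarray:
    u, v = _pair(u, v, lam)
    return u + v


def ring_sub(u, v, lam: int) -> np.ndarray:
    u, v = _pair(u, v, lam)
    return u - v


def ring_mul(u, v, lam: int) -> np.ndarray:
    u, v = _pair(u, v, lam)
    return u * v


def ring_scale(u, c: int, lam: int) -> np.ndarray:
    """Multiply ring element(s) by a public integer constant."""
    dt = ring_dtype(lam)
    return np.asarray(u, dtype=dt) * dt.type(c % (1 << lam))


def ring_neg(u, lam: int) -> np.ndarray:
    dt = ring_dtype(lam)
    return dt.type(0) - np.asarray(u, dtype=dt)
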