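"""Additive secret sharing over Z_{2^λ} and Z_2, local share algebra, and the
instrumented two-party channel.

A value x is split into uniformly random shares x_A + x_B = x (mod 2^λ) held by
the two data processors, Alice and Bob.  Addition, subtraction, scaling by a
public constant and adding a public constant are communication-free; anything
else goes through a protocol that talks over the :class:`Channel`, whose
round/message/byte counters and size transcript back every complexity and
obliviousness claim made by the test-suite.

Z_2 (bit) sharings use the same container with ``bits=1``; reconstruction is
XOR.  In memory bit shares are unpacked 0/1 bytes; they are packed 8-per-byte
at the channel boundary, so counted traffic for B parallel bit instances is
proportional to ceil(B/8).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np

from .fixedpoint import ring_dtype

__all__ = [
    "ProtocolError",
    "SharedTensor",
    "Channel",
    "share",
    "open_shares",
    "bit_payload_bytes",
]


class ProtocolError(RuntimeError):
    """A protocol contract was violated (mismatched moduli, shapes, ...)."""


def _mod2(arr: np.ndarray) -> np.ndarray:
    return (arr & np.uint8(1)).astype(np.uint8)


@dataclass
class SharedTensor:
    """Additive sharing of a tensor: elementwise x = alice + bob (mod 2^bits).

    ``bits`` is the modulus bit width: the ring width λ for arithmetic
    sharings, or 1 for Z_2 (bit) sharings.  Scalars are 0-d tensors.
    """

    alice: np.ndarray
    bob: np.ndarray
    bits: int

    def __post_init__(self) -> None:
        dt = np.uint8 if self.bits == 1 else ring_dtype(self.bits)
        self.alice = np.asarray(self.alice, dtype=dt)
        self.bob = np.asarray(self.bob, dtype=dt)
        if self.alice.shape != self.bob.shape:
            raise ProtocolError("share halves must have identical shapes")

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self) -> Tuple[int, ...]:
        return self.alice.shape

    @property
    def size(self) -> int:
        return self.alice.size

    @property
    def dtype(self) -> np.dtype:
        return self.alice.dtype

    def reshape(self, *shape) -> "SharedTensor":
        return SharedTensor(self.alice.reshape(*shape), self.bob.reshape(*shape), self.bits)

    def __getitem__(self, idx) -> "SharedTensor":
        return SharedTensor(self.alice[idx], self.bob[idx], self.bits)

    def transpose(self) -> "SharedTensor":
        return SharedTensor(self.alice.T, self.bob.T, self.bits)

    # -- local (communication-free) operations -------------------------------
    def _check(self, other: "SharedTensor") -> None:
        if self.bits != other.bits:
            raise ProtocolError(f"modulus mismatch: {self.bits} vs {other.bits}")

    def __add__(self, other: "SharedTensor") -> "SharedTensor":
        self._check(other)
        if self.bits == 1:
            return SharedTensor(self.alice ^ other.alice, self.bob ^ other.bob, 1)
        with np.errstate(over="ignore"):
            return SharedTensor(self.alice + other.alice, self.bob + other.bob, self.bits)

    def __sub__(self, other: "SharedTensor") -> "SharedTensor":
        self._check(other)
        if self.bits == 1:
            return self + other  # subtraction is XOR in Z_2
        with np.errstate(over="ignore"):
            return SharedTensor(self.alice - other.alice, self.bob - other.bob, self.bits)

    def scale(self, c: int) -> "SharedTensor":
        """Multiply by a public constant: both parties scale locally."""
        if self.bits == 1:
            c = int(c) & 1
            z = np.zeros_like(self.alice)
            return SharedTensor(self.alice if c else z, self.bob if c else z.copy(), 1)
        cc = self.dtype.type(int(c) % (1 << self.bits))
        with np.errstate(over="ignore"):
            return SharedTensor(self.alice * cc, self.bob * cc, self.bits)

    def add_const(self, c) -> "SharedTensor":
        """Add a public constant: Alice adjusts her share, Bob is unchanged."""
        if self.bits == 1:
            ca = np.asarray(c, dtype=np.uint8) & np.uint8(1)
            return SharedTensor(self.alice ^ ca, self.bob, 1)
        ca = np.asarray(c, dtype=self.dtype)
        with np.errstate(over="ignore"):
            return SharedTensor(self.alice + ca, self.bob, self.bits)

    def neg(self) -> "SharedTensor":
        if self.bits == 1:
            return self
        with np.errstate(over="ignore"):
            return SharedTensor(
                self.dtype.type(0) - self.alice, self.dtype.type(0) - self.bob, self.bits
            )

    # -- reconstruction ------------------------------------------------------
    def open(self) -> np.ndarray:
        """Reconstruct the plaintext by combining both shares."""
        if self.bits == 1:
            return self.alice ^ self.bob
        with np.errstate(over="ignore"):
            return self.alice + self.bob


def share(x, bits: int, rng: np.random.Generator) -> SharedTensor:
    """Split plaintext tensor ``x`` into fresh uniform additive shares."""
    if bits == 1:
        arr = _mod2(np.asarray(x, dtype=np.uint8))
        a = rng.integers(0, 2, size=arr.shape, dtype=np.uint8)
        return SharedTensor(a, arr ^ a, 1)
    dt = ring_dtype(bits)
    arr = np.asarray(x, dtype=dt)
    a = rng.integers(0, 1 << bits, size=arr.shape, dtype=dt)
    with np.errstate(over="ignore"):
        return SharedTensor(a, arr - a, bits)


def open_shares(p: SharedTensor, s: SharedTensor | None = None) -> np.ndarray:
    """Open one sharing, or check-and-open two sharings of equal modulus."""
    if s is not None:
        p._check(s)
    return p.open()


def bit_payload_bytes(n_bits: int) -> int:
    """Bytes on the wire for ``n_bits`` packed Z_2 elements."""
    return (int(n_bits) + 7) // 8


@dataclass
class Channel:
    """Instrumented message link between the two data processors.

    One *round* is a simultaneous bidirectional exchange; independent openings
    issued together share a round.  The transcript records the (bytes A→B,
    bytes B→A) of every exchange, which depends only on public dimensions for
    an oblivious protocol.
    """

    rounds: int = 0
    messages: int = 0
    bytes_a_to_b: int = 0
    bytes_b_to_a: int = 0
    transcript: List[Tuple[int, int]] = field(default_factory=list)

    def exchange(self, nbytes_ab: int, nbytes_ba: int) -> None:
        if nbytes_ab < 0 or nbytes_ba < 0:
            raise ProtocolError("negative payload size")
        self.rounds += 1
        self.messages += 2
        self.bytes_a_to_b += nbytes_ab
        self.bytes_b_to_a += nbytes_ba
        self.transcript.append((nbytes_ab, nbytes_ba))

    @property
    def total_bytes(self) -> int:
        return self.bytes_a_to_b + self.bytes_b_to_a

    def snapshot(self) -> Tuple[int, int, int]:
        return (self.rounds, self.messages, self.total_bytes)
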