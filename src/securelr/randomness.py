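"""Trusted-initializer correlated randomness: Beaver triples and masked bits.

The trusted initializer (TI) is a third endpoint that pre-distributes
correlated randomness to the two data processors and then leaves: Beaver
multiplication triples (u, v, w) with w = u·v in Z_{2^λ} or Z_2 (elementwise
or matrix product), and masked-bit pairs — the same random bit r shared both
in Z_2 and in Z_{2^λ} — used for bit-to-ring share conversion.

Two delivery modes exist.  The canonical mode pre-generates a
:class:`RandomnessTape` from an explicit request plan (obtained by recording a
dry run, since the protocols' control flow is data-independent) and can
serialize it to one binary stream file per party.  A :class:`LiveSource`
generates records on demand from the same seeded generator — convenient in
tests, and it doubles as the plan recorder.  Every record is single-use:
reuse or depletion raises, never silently recycles.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from typing import Iterable, List, Sequence, Tuple, Union

import numpy as np

from .fixedpoint import ring_dtype
from .sharing import ProtocolError, SharedTensor, share

__all__ = [
    "DepletionError",
    "TripleRequest",
    "MaskedBitRequest",
    "TrustedInitializer",
    "RandomnessTape",
    "LiveSource",
    "write_tape_files",
    "load_tape_files",
]


class DepletionError(ProtocolError):
    """The correlated-randomness stream ran out (or a record was reused)."""


@dataclass(frozen=True)
class TripleRequest:
    """Request for one Beaver triple: ``kind`` is 'elem' or 'matmul'."""

    kind: str
    bits: int
    shape_x: Tuple[int, ...]
    shape_y: Tuple[int, ...]

    def mult_count(self) -> int:
        """Scalar-multiplication equivalents this triple pays for."""
        if self.kind == "elem":
            return int(np.prod(self.shape_x, dtype=np.int64))
        return _matmul_mults(self.shape_x, self.shape_y)


@dataclass(frozen=True)
class MaskedBitRequest:
    shape: Tuple[int, ...]
    lam: int

    def count(self) -> int:
        return int(np.prod(self.shape, dtype=np.int64))


Request = Union[TripleRequest, MaskedBitRequest]


def _matmul_mults(sx: Tuple[int, ...], sy: Tuple[int, ...]) -> int:
    if len(sx) == 2 and len(sy) == 2:
        return sx[0] * sx[1] * sy[1]
    if len(sx) == 2 and len(sy) == 1:
        return sx[0] * sx[1]
    if len(sx) == 1 and len(sy) == 2:
        return sy[0] * sy[1]
    raise ProtocolError(f"unsupported matmul shapes {sx} x {sy}")


def _matmul_out_shape(sx, sy):
    if len(sx) == 2 and len(sy) == 2 and sx[1] == sy[0]:
        return (sx[0], sy[1])
    if len(sx) == 2 and len(sy) == 1 and sx[1] == sy[0]:
        return (sx[0],)
    if len(sx) == 1 and len(sy) == 2 and sx[0] == sy[0]:
        return (sy[1],)
    raise ProtocolError(f"non-conformable matmul shapes {sx} x {sy}")


@dataclass
class TripleRecord:
    req: TripleRequest
    u: SharedTensor
    v: SharedTensor
    w: SharedTensor
    consumed: bool = False


@dataclass
class MaskedBitRecord:
    req: MaskedBitRequest
    r_bit: SharedTensor
    r_ring: SharedTensor
    consumed: bool = False


@dataclass
class ConsumptionCounters:
    """Running totals of randomness consumed, by protocol currency."""

    ring_mults: int = 0
    bit_ands: int = 0
    masked_bits: int = 0
    triples: int = 0


class TrustedInitializer:
    """Seeded generator of correlated randomness; deterministic per seed."""

    def __init__(self, seed: int):
        self.seed = int(seed)
        self._rng = np.random.default_rng(self.seed)

    # -- record construction -------------------------------------------------
    def _make_triple(self, req: TripleRequest) -> TripleRecord:
        rng = self._rng
        if req.kind == "elem":
            if req.shape_x != req.shape_y:
                raise ProtocolError(f"elementwise triple shape mismatch: {req.shape_x} vs {req.shape_y}")
        else:
            _matmul_out_shape(req.shape_x, req.shape_y)  # raises if not conformable
        if req.bits == 1:
            if req.kind != "elem":
                raise ProtocolError("Z_2 triples are elementwise only")
            u = rng.integers(0, 2, size=req.shape_x, dtype=np.uint8)
            v = rng.integers(0, 2, size=req.shape_y, dtype=np.uint8)
            w = u & v
            return TripleRecord(req, share(u, 1, rng), share(v, 1, rng), share(w, 1, rng))
        dt = ring_dtype(req.bits)
        hi = 1 << req.bits
        u = rng.integers(0, hi, size=req.shape_x, dtype=dt)
        v = rng.integers(0, hi, size=req.shape_y, dtype=dt)
        w = u * v if req.kind == "elem" else np.matmul(u, v)
        return TripleRecord(
            req,
            share(u, req.bits, rng),
            share(v, req.bits, rng),
            share(w, req.bits, rng),
        )

    def _make_masked_bits(self, req: MaskedBitRequest) -> MaskedBitRecord:
        rng = self._rng
        r = rng.integers(0, 2, size=req.shape, dtype=np.uint8)
        return MaskedBitRecord(req, share(r, 1, rng), share(r, req.lam, rng))

    def make(self, req: Request):
        if isinstance(req, TripleRequest):
            return self._make_triple(req)
        return self._make_masked_bits(req)

    def generate(self, plan: Sequence[Request]) -> "RandomnessTape":
        """Emit the whole correlated-randomness stream for ``plan`` up front."""
        return RandomnessTape([self.make(r) for r in plan])


class _SourceBase:
    def __init__(self) -> None:
        self.counters = ConsumptionCounters()

    def _account(self, rec) -> None:
        if isinstance(rec, TripleRecord):
            self.counters.triples += 1
            if rec.req.bits == 1:
                self.counters.bit_ands += rec.req.mult_count()
            else:
                self.counters.ring_mults += rec.req.mult_count()
        else:
            self.counters.masked_bits += rec.req.count()

    def take_triple(self, kind, bits, shape_x, shape_y) -> TripleRecord:
        raise NotImplementedError

    def take_masked_bits(self, shape, lam) -> MaskedBitRecord:
        raise NotImplementedError


class RandomnessTape(_SourceBase):
    """Pre-delivered stream of typed records, consumed strictly in order."""

    def __init__(self, records: List[Union[TripleRecord, MaskedBitRecord]]):
        super().__init__()
        self.records = records
        self.cursor = 0

    def _next(self):
        if self.cursor >= len(self.records):
            raise DepletionError("correlated-randomness stream exhausted")
        rec = self.records[self.cursor]
        self.cursor += 1
        if rec.consumed:
            raise DepletionError("correlated-randomness record already consumed")
        rec.consumed = True
        self._account(rec)
        return rec

    def take_triple(self, kind, bits, shape_x, shape_y) -> TripleRecord:
        rec = self._next()
        want = TripleRequest(kind, bits, tuple(shape_x), tuple(shape_y))
        if not isinstance(rec, TripleRecord) or rec.req != want:
            raise ProtocolError(f"stream record mismatch: wanted {want}, found {rec.req}")
        return rec

    def take_masked_bits(self, shape, lam) -> MaskedBitRecord:
        rec = self._next()
        want = MaskedBitRequest(tuple(shape), lam)
        if not isinstance(rec, MaskedBitRecord) or rec.req != want:
            raise ProtocolError(f"stream record mismatch: wanted {want}, found {rec.req}")
        return rec


class LiveSource(_SourceBase):
    """On-demand TI: generates records as requested and records the plan.

    Request order is determined by the (data-independent) protocol control
    flow, so a fixed seed reproduces the identical stream; the recorded
    ``plan`` can be replayed through :meth:`TrustedInitializer.generate` to
    produce the canonical pre-delivered tape.
    """

    def __init__(self, seed: int):
        super().__init__()
        self.ti = TrustedInitializer(seed)
        self.plan: List[Request] = []

    def take_triple(self, kind, bits, shape_x, shape_y) -> TripleRecord:
        req = TripleRequest(kind, bits, tuple(shape_x), tuple(shape_y))
        self.plan.append(req)
        rec = self.ti._make_triple(req)
        rec.consumed = True
        self._account(rec)
        return rec

    def take_masked_bits(self, shape, lam) -> MaskedBitRecord:
        req = MaskedBitRequest(tuple(shape), lam)
        self.plan.append(req)
        rec = self.ti._make_masked_bits(req)
        rec.consumed = True
        self._account(rec)
        return rec


# ---------------------------------------------------------------------------
# Stream files: one binary file per party, typed records in consumption order.
# Record layout: tag byte; then a shape header; then this party's payload
# arrays as little-endian words (Z_2 payloads packed 8 bits per byte).
# ---------------------------------------------------------------------------

_MAGIC = b"MPCTIS"
_TAG_ELEM, _TAG_MATMUL, _TAG_BITS, _TAG_MASK = 1, 2, 3, 4


def _pack_bits(arr: np.ndarray) -> bytes:
    return np.packbits(arr.reshape(-1).astype(np.uint8)).tobytes()


def _unpack_bits(buf: bytes, shape) -> np.ndarray:
    n = int(np.prod(shape, dtype=np.int64))
    return np.unpackbits(np.frombuffer(buf, dtype=np.uint8), count=n).reshape(shape)


def _ring_bytes(arr: np.ndarray, bits: int) -> bytes:
    return arr.astype(np.dtype(f"<u{bits // 8}")).tobytes()


def _ring_from(buf: bytes, bits: int, shape) -> np.ndarray:
    return np.frombuffer(buf, dtype=np.dtype(f"<u{bits // 8}")).reshape(shape).astype(ring_dtype(bits))


def _shape_hdr(shape) -> bytes:
    return struct.pack("<B", len(shape)) + b"".join(struct.pack("<I", d) for d in shape)


def _read_shape(f) -> Tuple[int, ...]:
    (nd,) = struct.unpack("<B", f.read(1))
    return tuple(struct.unpack("<I", f.read(4))[0] for _ in range(nd))


def write_tape_files(tape: RandomnessTape, path_alice: str, path_bob: str) -> None:
    """Serialize an (unconsumed) tape into one stream file per party."""
    for party, path in ((0, path_alice), (1, path_bob)):
        with open(path, "wb") as f:
            f.write(_MAGIC + struct.pack("<B", 1))
            for rec in tape.records:
                if isinstance(rec, TripleRecord):
                    tag = (
                        _TAG_BITS
                        if rec.req.bits == 1
                        else (_TAG_ELEM if rec.req.kind == "elem" else _TAG_MATMUL)
                    )
                    f.write(struct.pack("<BB", tag, rec.req.bits))
                    f.write(_shape_hdr(rec.req.shape_x) + _shape_hdr(rec.req.shape_y))
                    for t in (rec.u, rec.v, rec.w):
                        h = t.alice if party == 0 else t.bob
                        f.write(_pack_bits(h) if rec.req.bits == 1 else _ring_bytes(h, rec.req.bits))
                else:
                    f.write(struct.pack("<BB", _TAG_MASK, rec.req.lam))
                    f.write(_shape_hdr(rec.req.shape))
                    hb = rec.r_bit.alice if party == 0 else rec.r_bit.bob
                    hr = rec.r_ring.alice if party == 0 else rec.r_ring.bob
                    f.write(_pack_bits(hb) + _ring_bytes(hr, rec.req.lam))


def _read_records(path: str):
    out = []
    with open(path, "rb") as f:
        if f.read(6) != _MAGIC:
            raise ProtocolError(f"{path}: not a TI stream file")
        f.read(1)  # version
        while True:
            head = f.read(2)
            if not head:
                break
            tag, bits = struct.unpack("<BB", head)
            if tag == _TAG_MASK:
                shape = _read_shape(f)
                n = int(np.prod(shape, dtype=np.int64))
                rb = _unpack_bits(f.read((n + 7) // 8), shape)
                rr = _ring_from(f.read(n * bits // 8), bits, shape)
                out.append(("mask", MaskedBitRequest(shape, bits), rb, rr))
            else:
                kind = "matmul" if tag == _TAG_MATMUL else "elem"
                sx, sy = _read_shape(f), _read_shape(f)
                sw = sx if kind == "elem" else _matmul_out_shape(sx, sy)
                halves = []
                for s in (sx, sy, sw):
                    n = int(np.prod(s, dtype=np.int64))
                    if bits == 1:
                        halves.append(_unpack_bits(f.read((n + 7) // 8), s))
                    else:
                        halves.append(_ring_from(f.read(n * bits // 8), bits, s))
                out.append(("triple", TripleRequest(kind, bits, sx, sy), *halves))
    return out


def load_tape_files(path_alice: str, path_bob: str) -> RandomnessTape:
    """Combine the two per-party stream files back into a joint tape."""
    ra, rb = _read_records(path_alice), _read_records(path_bob)
    if len(ra) != len(rb):
        raise ProtocolError("party stream files disagree in record count")
    records: List[Union[TripleRecord, MaskedBitRecord]] = []
    for a, b in zip(ra, rb):
        if a[0] != b[0] or a[1] != b[1]:
            raise ProtocolError("party stream files disagree in record headers")
        if a[0] == "mask":
            req = a[1]
            records.append(
                MaskedBitRecord(
                    req,
                    SharedTensor(a[2], b[2], 1),
                    SharedTensor(a[3], b[3], req.lam),
                )
            )
        else:
            req = a[1]
            records.append(
                TripleRecord(
                    req,
                    SharedTensor(a[2], b[2], req.bits),
                    SharedTensor(a[3], b[3], req.bits),
                    SharedTensor(a[4], b[4], req.bits),
                )
            )
    return RandomnessTape(records)
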