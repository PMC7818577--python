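"""Secure logistic-regression training over additive shares, end to end.

One training iteration performs, on shares only:

1. ⟦s⟧ = X·w via one-round secure matrix multiplication, truncated by a;
2. ⟦o⟧ = ρ(⟦s⟧) with the batched comparison-free activation protocol;
3. ⟦e⟧ = t − o locally (labels are shared pre-scaled as t_d·2^a);
4. ⟦g⟧ = Xᵀ·e via one more secure multiplication, truncated by a;
5. w ← w + trunc(Q(η)·⟦g⟧): a local constant scaling and a local truncation.

Weights start at the all-zeros sharing, the iteration count is fixed and
public (no early stopping — a data-dependent stop would leak), the gradient
is the plain sum over the batch (fold any 1/n into η), and truncation is
deferred to one application per interactive product.  The message schedule
depends only on (n, m, n_iter, format), never on data values.

The module also carries the five-step orchestration — TI randomness, owner
encode-and-share, processor assembly, secure training, reveal — plus the
share-file format and the closed-form randomness/multiplication accounting.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .activation import rho_secure
from .beaver import ProtocolContext, secure_mul, truncate
from .fixedpoint import FixedPointFormat, decode, encode, ring_dtype
from .randomness import LiveSource, Request, TrustedInitializer
from .sharing import Channel, ProtocolError, SharedTensor

__all__ = [
    "TrainingJob",
    "RunConfig",
    "train_secure",
    "randomness_plan",
    "share_table",
    "run_end_to_end",
    "count_secure_multiplications",
    "read_dataset",
    "write_weights",
    "write_share_file",
    "read_share_file",
]


@dataclass
class TrainingJob:
    """Shared design matrix, shared labels, and public hyperparameters.

    ``X`` is (n, m+1) fixed-point with column 0 the encoded all-ones dummy
    feature; ``t`` is (n,) holding t_d·2^a.  η and the iteration count are
    public to both processors.
    """

    X: SharedTensor
    t: SharedTensor
    eta: float
    n_iter: int
    fmt: FixedPointFormat

    def __post_init__(self) -> None:
        if self.X.bits != self.fmt.lam or self.t.bits != self.fmt.lam:
            raise ProtocolError("job tensors must be shared over the session ring")
        if len(self.X.shape) != 2 or self.t.shape != (self.X.shape[0],):
            raise ProtocolError(
                f"shape mismatch: X {self.X.shape} vs t {self.t.shape}"
            )
        if self.n_iter < 0:
            raise ProtocolError("iteration count must be non-negative")


def train_secure(
    job: TrainingJob,
    ctx: ProtocolContext,
    variant: str = "lookahead",
    trunc_trace: Optional[List[Tuple[np.ndarray, np.ndarray]]] = None,
) -> SharedTensor:
    """Run the secure training protocol; returns the shared weight vector.

    If ``trunc_trace`` is a list, the pre-truncation share pairs are appended
    to it in execution order (three per iteration) so the in-the-clear
    fixed-point simulator can replay the identical truncation randomness.
    """
    fmt = job.fmt
    a = fmt.a
    n, mp1 = job.X.shape
    dt = fmt.dtype
    w = SharedTensor(np.zeros(mp1, dtype=dt), np.zeros(mp1, dtype=dt), fmt.lam)
    eta_enc = int(encode(float(job.eta), fmt))
    Xt = job.X.transpose()

    def _trunc(x: SharedTensor) -> SharedTensor:
        if trunc_trace is not None:
            trunc_trace.append((x.alice.copy(), x.bob.copy()))
        return truncate(x, a, fmt)

    for _ in range(job.n_iter):
        s = _trunc(secure_mul(job.X, w, ctx))
        o = rho_secure(s, ctx, variant=variant)
        e = job.t - o
        g = _trunc(secure_mul(Xt, e, ctx))
        w = w + _trunc(g.scale(eta_enc))
    return w


# -- run configuration -------------------------------------------------------

@dataclass
class RunConfig:
    """Public run configuration; defaults follow the reference operating point
    (a=12 fractional bits, b=15 integer bits, λ=64, η=0.001)."""

    frac_bits: int = 12
    int_bits: int = 15
    ring_bits: int = 64
    learning_rate: float = 0.001
    iterations: int = 10
    seed: int = 0
    variant: str = "lookahead"
    partition: str = "horizontal"

    @property
    def fmt(self) -> FixedPointFormat:
        return FixedPointFormat(self.frac_bits, self.int_bits, self.ring_bits)

    @classmethod
    def from_mapping(cls, mapping: Dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)


# -- five-step orchestration -------------------------------------------------

def randomness_plan(
    n: int, m: int, n_iter: int, fmt: FixedPointFormat, variant: str = "lookahead"
) -> List[Request]:
    """Exact TI request sequence for a training run of the given public size.

    Obtained by a dry run on an all-zeros job: the protocol's control flow
    (and hence its randomness consumption) depends only on public dimensions.
    """
    src = LiveSource(0)
    ctx = ProtocolContext(fmt, src, Channel())
    dt = fmt.dtype
    X = SharedTensor(np.zeros((n, m + 1), dtype=dt), np.zeros((n, m + 1), dtype=dt), fmt.lam)
    t = SharedTensor(np.zeros(n, dtype=dt), np.zeros(n, dtype=dt), fmt.lam)
    train_secure(TrainingJob(X, t, 0.0, n_iter, fmt), ctx, variant=variant)
    return src.plan


def share_table(
    df: pd.DataFrame,
    fmt: FixedPointFormat,
    seed: int,
    shards: Optional[Sequence[np.ndarray]] = None,
) -> Tuple[SharedTensor, SharedTensor, List[str]]:
    """Owner-side step: encode every value per the fixed-point map and split it.

    The uniform masks are drawn per table cell from the seed, so the
    assembled sharing is bit-identical however the table is partitioned
    between owners.  ``shards`` (one boolean cell mask per owner) only drives
    the assembly bookkeeping; omitted means a single owner holds everything.
    Returns shared X (with the public encoded bias column prepended), shared
    labels at scale 2^a, and the feature names.
    """
    if "label" not in df.columns:
        raise ProtocolError('dataset must contain a binary "label" column')
    feature_names = [c for c in df.columns if c != "label"]
    values = df[feature_names + ["label"]].to_numpy(dtype=np.float64)
    n, c = values.shape
    labels = values[:, -1]
    if not np.isin(labels, (0.0, 1.0)).all():
        raise ProtocolError("labels must be 0/1")

    enc = encode(values, fmt)
    rng = np.random.default_rng(seed)
    masks = rng.integers(0, 1 << fmt.lam, size=(n, c), dtype=fmt.dtype)

    if shards is None:
        shards = [np.ones((n, c), dtype=bool)]
    cover = np.zeros((n, c), dtype=np.int64)
    alice = np.zeros((n, c), dtype=fmt.dtype)
    bob = np.zeros((n, c), dtype=fmt.dtype)
    for owner_mask in shards:
        owner_mask = np.asarray(owner_mask, dtype=bool)
        if owner_mask.shape != (n, c):
            raise ProtocolError("inconsistent shard dimensions")
        cover += owner_mask
        alice[owner_mask] = masks[owner_mask]
        bob[owner_mask] = (enc - masks)[owner_mask]
    if not (cover == 1).all():
        raise ProtocolError("owner shards must tile the table exactly once")

    ones = np.full((n, 1), fmt.dtype.type(1 << fmt.a), dtype=fmt.dtype)
    zeros = np.zeros((n, 1), dtype=fmt.dtype)
    X = SharedTensor(
        np.hstack([ones, alice[:, :-1]]), np.hstack([zeros, bob[:, :-1]]), fmt.lam
    )
    t = SharedTensor(alice[:, -1], bob[:, -1], fmt.lam)
    return X, t, feature_names


def run_end_to_end(
    df: pd.DataFrame,
    config: RunConfig,
    shards: Optional[Sequence[np.ndarray]] = None,
    trunc_trace: Optional[List] = None,
):
    """All five protocol steps in one process; returns results and statistics.

    1. the TI emits the full correlated-randomness stream up front;
    2. owners encode (fixed-point map) and split every value they hold;
    3. the processors assemble ⟦X⟧ and ⟦t⟧ from the received shares;
    4. both processors run the secure training protocol;
    5. the weight shares go back to every owner, who opens them.
    """
    fmt = config.fmt
    X, t, names = share_table(df, fmt, config.seed, shards)
    n, mp1 = X.shape

    plan = randomness_plan(n, mp1 - 1, config.iterations, fmt, config.variant)
    tape = TrustedInitializer(config.seed + 1).generate(plan)
    ctx = ProtocolContext(fmt, tape, Channel())

    job = TrainingJob(X, t, config.learning_rate, config.iterations, fmt)
    w_shared = train_secure(job, ctx, variant=config.variant, trunc_trace=trunc_trace)

    opened = w_shared.open()
    weights = decode(opened, fmt)
    return {
        "weights": np.atleast_1d(weights),
        "weights_ring": opened,
        "weight_shares": w_shared,
        "feature_names": names,
        "stats": {
            "rounds": ctx.channel.rounds,
            "messages": ctx.channel.messages,
            "bytes": ctx.channel.total_bytes,
            "triples": tape.counters.triples,
            "ring_mults": tape.counters.ring_mults,
            "bit_ands": tape.counters.bit_ands,
            "masked_bits": tape.counters.masked_bits,
        },
        "transcript": list(ctx.channel.transcript),
    }


# -- structural accounting ---------------------------------------------------

def count_secure_multiplications(
    n: int, m: int, n_iter: int, fmt: FixedPointFormat, variant: str = "lookahead"
) -> Dict[str, Dict[str, int]]:
    """Closed-form tally of randomness consumed per phase of one training run.

    Counts scalar ring multiplications, Z_2 AND gates and masked-bit pairs,
    matching the instrumented consumption counters of a live run exactly.
    """
    k = fmt.a + fmt.b + 1
    B = n

    gen_ands = (k - 1) * B
    if variant == "ripple":
        carry_ands = (k - 2) * B
    elif variant == "lookahead":
        carry_ands = 0
        d = 1
        while d < k - 1:
            carry_ands += 2 * (k - 1 - d) * B
            d *= 2
    else:
        raise ProtocolError(f"unknown decomposition variant {variant!r}")
    or_ands = (fmt.b - 1) * B

    phases = {
        "inner_product": {"ring_mults": n * (m + 1)},
        "activation": {
            "bit_ands": gen_ands + carry_ands + or_ands,
            "masked_bits": 2 * B,
            "ring_mults": 2 * B,
        },
        "gradient": {"ring_mults": (m + 1) * n},
        "weight_update": {},  # local constant scaling + local truncation only
    }
    totals = {"ring_mults": 0, "bit_ands": 0, "masked_bits": 0}
    for ops in phases.values():
        for key, val in ops.items():
            totals[key] += val * n_iter
    out = {name: {k2: v2 * n_iter for k2, v2 in ops.items()} for name, ops in phases.items()}
    out["total"] = totals
    return out


# -- external formats --------------------------------------------------------

def read_dataset(path: str) -> pd.DataFrame:
    """Read a delimited (comma or tab) table with a header and a label column."""
    df = pd.read_csv(path, sep=None, engine="python")
    if "label" not in df.columns:
        raise ProtocolError(f'{path}: expected a "label" column')
    return df


def write_weights(path: str, names: Sequence[str], weights: np.ndarray) -> None:
    """Write revealed weights as tab-separated (feature, decoded weight)."""
    rows = ["feature\tweight", f"bias\t{float(weights[0])!r}"]
    rows += [f"{nm}\t{float(wt)!r}" for nm, wt in zip(names, weights[1:])]
    with open(path, "w") as f:
        f.write("\n".join(rows) + "\n")


_SHARE_MAGIC = b"MPCSHR"


def write_share_file(path: str, shares: np.ndarray, fmt: FixedPointFormat) -> None:
    """One party's share of one tensor: binary, little-endian λ-bit words."""
    arr = np.atleast_2d(np.asarray(shares, dtype=fmt.dtype))
    rows, cols = arr.shape
    with open(path, "wb") as f:
        f.write(_SHARE_MAGIC)
        f.write(struct.pack("<BBBBII", 1, fmt.lam, fmt.a, fmt.b, rows, cols))
        f.write(arr.astype(np.dtype(f"<u{fmt.lam // 8}")).tobytes())


def read_share_file(path: str) -> Tuple[np.ndarray, FixedPointFormat]:
    with open(path, "rb") as f:
        if f.read(6) != _SHARE_MAGIC:
            raise ProtocolError(f"{path}: not a share file")
        _, lam, a, b, rows, cols = struct.unpack("<BBBBII", f.read(12))
        fmt = FixedPointFormat(a, b, lam)
        body = f.read(rows * cols * lam // 8)
    arr = (
        np.frombuffer(body, dtype=np.dtype(f"<u{lam // 8}"))
        .reshape(rows, cols)
        .astype(ring_dtype(lam))
    )
    return arr, fmt
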