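"""Synthetic gene-expression-like data and in-the-clear training oracles.

The generator emulates the *shape* of high-dimensional binary-labelled
expression matrices (hundreds of samples, up to 10^4-scale features, bounded
real values, sparse informative signal): features are truncated standard
normals, a sparse true weight vector defines a linear score, and labels are
Bernoulli draws from the sigmoid of that score, optionally flipped with a
label-noise rate.  Setting ``margin > 0`` instead produces deterministic
labels with a guaranteed score margin — the separable regime used by the
parameter-recovery tests.  It does not model real expression covariance or
pathway structure; what passing tests certify is protocol fidelity, not
biological realism.

Two reference trainers mirror the secure pipeline at different fidelity:
``train_clear_float`` is plain full-batch gradient descent with the clipped
ReLU on float64, and ``train_clear_fixed`` is a single-machine simulation of
the exact ring pipeline — fixed-point encoding, modular sums, and the local
truncation rule applied to a configurable share-split model — serving as the
oracle for secure/clear equivalence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .fixedpoint import FixedPointFormat, encode, to_signed

__all__ = [
    "SyntheticSpec",
    "generate",
    "make_shards",
    "add_bias",
    "train_clear_float",
    "train_clear_fixed",
    "rho_ring",
    "predict_labels",
    "accuracy",
    "kfold_indices",
    "cross_val_accuracy",
]

# Standardized scores are rescaled to this standard deviation before the
# sigmoid draw; chosen once so that noise-free synthetic classes are fairly
# separated, as expression signatures with real predictive signal are.
_SCORE_STD = 4.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic dataset; deterministic per seed.

    Defaults mirror the larger study condition this package targets:
    470 samples with 17,814 bounded numeric features and binary labels.
    """

    n_samples: int = 470
    n_features: int = 17_814
    sparsity: float = 0.05
    feature_bound: float = 4.0
    label_noise: float = 0.0
    class_balance: float = 0.5
    margin: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.class_balance < 1:
            raise ValueError("class balance must be strictly between 0 and 1")
        if not 0 <= self.label_noise < 0.5:
            raise ValueError("label-noise rate must lie in [0, 0.5)")
        if self.feature_bound <= 0:
            raise ValueError("feature bound must be positive")
        if not 0 < self.sparsity <= 1:
            raise ValueError("true-weight sparsity fraction must lie in (0, 1]")


def generate(spec: SyntheticSpec) -> Tuple[pd.DataFrame, np.ndarray]:
    """Draw one dataset; returns (table, true weights incl. intercept).

    The table has feature columns f000001.. and a binary ``label`` column.
    The returned weight vector has the intercept first and is the ground
    truth for parameter-recovery checks.
    """
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_samples, spec.n_features

    w = np.zeros(m)
    k = max(1, int(round(spec.sparsity * m)))
    support = rng.choice(m, size=k, replace=False)
    w[support] = rng.normal(size=k)

    X = np.clip(rng.normal(size=(n, m)), -spec.feature_bound, spec.feature_bound)
    raw = X @ w
    sd = raw.std()
    if sd == 0:
        raise ValueError("degenerate spec: zero score variance")
    w *= _SCORE_STD / sd
    score = X @ w
    intercept = -np.quantile(score, 1.0 - spec.class_balance)
    score = score + intercept

    if spec.margin > 0:
        for _ in range(200):
            bad = np.abs(score) < spec.margin
            if not bad.any():
                break
            X[bad] = np.clip(
                rng.normal(size=(int(bad.sum()), m)),
                -spec.feature_bound,
                spec.feature_bound,
            )
            score = X @ w + intercept
        else:
            raise ValueError("infeasible margin: could not separate samples")
        t = (score > 0).astype(np.int64)
    else:
        p = 1.0 / (1.0 + np.exp(-score))
        t = (rng.random(n) < p).astype(np.int64)

    if spec.label_noise > 0:
        t ^= (rng.random(n) < spec.label_noise).astype(np.int64)

    cols = {f"f{i + 1:06d}": X[:, i] for i in range(m)}
    cols["label"] = t
    df = pd.DataFrame(cols)
    return df, np.concatenate([[intercept], w])


def make_shards(
    df: pd.DataFrame, mode: str, n_owners: int, seed: int = 0
) -> List[np.ndarray]:
    """Owner-assignment masks over the table cells for a partition mode.

    Returns one boolean (n_samples, n_columns) mask per owner; masks tile the
    table exactly.  ``horizontal`` splits records, ``vertical`` splits
    columns, ``arbitrary`` assigns every cell independently.
    """
    n, c = df.shape
    rng = np.random.default_rng(seed)
    masks = [np.zeros((n, c), dtype=bool) for _ in range(n_owners)]
    if mode == "horizontal":
        owner_of_row = np.repeat(np.arange(n_owners), -(-n // n_owners))[:n]
        for o in range(n_owners):
            masks[o][owner_of_row == o, :] = True
    elif mode == "vertical":
        owner_of_col = np.repeat(np.arange(n_owners), -(-c // n_owners))[:c]
        for o in range(n_owners):
            masks[o][:, owner_of_col == o] = True
    elif mode == "arbitrary":
        owner_of_cell = rng.integers(0, n_owners, size=(n, c))
        for o in range(n_owners):
            masks[o] = owner_of_cell == o
    else:
        raise ValueError(f"unknown partition mode {mode!r}")
    return masks


# -- in-the-clear trainers ---------------------------------------------------

def add_bias(X: np.ndarray) -> np.ndarray:
    """Prepend the all-ones dummy feature column x_{d,0} = 1."""
    X = np.asarray(X, dtype=np.float64)
    return np.hstack([np.ones((X.shape[0], 1)), X])


def train_clear_float(X: np.ndarray, t: np.ndarray, eta: float, n_iter: int) -> np.ndarray:
    """Full-batch clipped-ReLU gradient descent on float64, zero-initialized.

    Update per iteration: w += eta * sum_d (t_d - rho(w . x_d)) x_d, with the
    sum over the whole training set (no gradient averaging, no regularizer).
    """
    Xb = add_bias(X)
    t = np.asarray(t, dtype=np.float64)
    w = np.zeros(Xb.shape[1])
    for _ in range(n_iter):
        o = np.clip(Xb @ w + 0.5, 0.0, 1.0)
        w = w + eta * (Xb.T @ (t - o))
    return w


def rho_ring(s: np.ndarray, fmt: FixedPointFormat) -> np.ndarray:
    """Clipped ReLU directly on plaintext ring values at scale 2^a (exact)."""
    zp = np.asarray(s, dtype=fmt.dtype) + fmt.dtype.type(1 << (fmt.a - 1))
    signed = to_signed(zp, fmt)
    return np.clip(signed, 0, 1 << fmt.a).astype(fmt.dtype)


class _TruncModel:
    """Share-split model for the local truncation rule in the clear simulator."""

    def __init__(self, mode: str = "exact", seed: int = 0, trace: Sequence | None = None):
        if mode not in ("exact", "zero", "random", "replay"):
            raise ValueError(f"unknown truncation model {mode!r}")
        self.mode = mode
        self.rng = np.random.default_rng(seed)
        self.trace = list(trace) if trace is not None else []
        self.cursor = 0

    def apply(self, v: np.ndarray, d: int, fmt: FixedPointFormat) -> np.ndarray:
        dt = fmt.dtype
        v = np.asarray(v, dtype=dt)
        if self.mode == "exact":
            # idealized floor division toward -inf in two's complement
            return (to_signed(v, fmt) >> np.int64(d)).astype(np.int64).astype(dt)
        if self.mode == "zero":
            xa, xb = v, np.zeros_like(v)
        elif self.mode == "random":
            xa = self.rng.integers(0, 1 << fmt.lam, size=v.shape, dtype=dt)
            xb = v - xa
        else:
            xa, xb = self.trace[self.cursor]
            self.cursor += 1
            xa = np.asarray(xa, dtype=dt)
            xb = np.asarray(xb, dtype=dt)
            if np.any(xa + xb != v):
                raise ValueError("replayed share split does not reconstruct the value")
        za = xa >> dt.type(d)
        zb = dt.type(0) - ((dt.type(0) - xb) >> dt.type(d))
        return za + zb


def train_clear_fixed(
    X: np.ndarray,
    t: np.ndarray,
    eta: float,
    n_iter: int,
    fmt: FixedPointFormat,
    trunc_model: str | _TruncModel = "exact",
    seed: int = 0,
    trunc_trace: Sequence | None = None,
) -> np.ndarray:
    """Single-machine simulation of the exact ring training pipeline.

    Encodes inputs per the fixed-point map, runs modular inner products, the
    exact ring clipped ReLU, and the local truncation rule under the chosen
    share-split model ('exact', 'zero', 'random', or 'replay' with a recorded
    trace).  Returns the ring-encoded weight vector (intercept first).
    """
    tm = trunc_model if isinstance(trunc_model, _TruncModel) else _TruncModel(
        trunc_model, seed=seed, trace=trunc_trace
    )
    Xb = encode(add_bias(X), fmt)
    t_enc = encode(np.asarray(t, dtype=np.float64), fmt)
    eta_enc = fmt.dtype.type(int(encode(float(eta), fmt)))
    w = np.zeros(Xb.shape[1], dtype=fmt.dtype)
    for _ in range(n_iter):
        s = tm.apply(np.matmul(Xb, w), fmt.a, fmt)
        o = rho_ring(s, fmt)
        e = t_enc - o
        g = tm.apply(np.matmul(Xb.T, e), fmt.a, fmt)
        w = w + tm.apply(eta_enc * g, fmt.a, fmt)
    return w


# -- evaluation utilities ----------------------------------------------------

def predict_labels(X: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Hard labels from a clipped-ReLU model: rho(score) >= 1/2 <=> score >= 0."""
    return (add_bias(X) @ np.asarray(w, dtype=np.float64) >= 0).astype(np.int64)


def accuracy(X: np.ndarray, t: np.ndarray, w: np.ndarray) -> float:
    return float(np.mean(predict_labels(X, w) == np.asarray(t)))


def kfold_indices(n: int, k: int = 5, seed: int = 0) -> List[np.ndarray]:
    """Seeded shuffled k-fold test-index assignment."""
    perm = np.random.default_rng(seed).permutation(n)
    return [fold for fold in np.array_split(perm, k)]


def cross_val_accuracy(
    X: np.ndarray,
    t: np.ndarray,
    train_fn: Callable[[np.ndarray, np.ndarray], np.ndarray],
    k: int = 5,
    seed: int = 0,
) -> float:
    """Mean k-fold accuracy of ``train_fn(X_train, t_train) -> float weights``."""
    t = np.asarray(t)
    accs = []
    for test_idx in kfold_indices(len(t), k, seed):
        mask = np.ones(len(t), dtype=bool)
        mask[test_idx] = False
        w = train_fn(X[mask], t[mask])
        accs.append(accuracy(X[test_idx], t[test_idx], w))
    return float(np.mean(accs))
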