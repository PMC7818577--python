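# securelr

Secure two-party training of logistic-regression-like classifiers on
high-dimensional data — such as gene-expression matrices — that is split
between data owners who cannot pool it in the clear.

## The problem and the approach

Several owners (hospitals, labs) each hold part of a training table: some
rows, some columns, or an arbitrary scatter of cells.  They want a joint
binary classifier without revealing a single value to anyone.  `securelr`
implements the standard outsourced-MPC answer: every owner splits each value
into two additive secret shares over the ring **Z**<sub>2<sup>λ</sup></sub>
and hands one share to each of two non-colluding *data processors* (Alice and
Bob).  The processors train entirely on shares — every message either party
sees is uniformly random — and at the end return the weight shares to the
owners, who combine them to reveal only the trained model.  A *trusted
initializer* (TI) pre-distributes correlated randomness (Beaver
multiplication triples and masked bits) and is never involved again.

Reals are carried in fixed point: `Q(x) = ⌊2^a·x⌋` for `x ≥ 0` and
`2^λ − ⌊2^a·|x|⌋` for `x < 0`, with `a` fractional bits, `b` integer bits and
a two's-complement sign (defaults `a=12, b=15, λ=64`).  The model is a single
neuron trained by full-batch gradient descent,

    w ← w + η · Σ_d (t_d − ρ(w·x_d)) x_d ,

with the sigmoid replaced by its MPC-friendly clipped-ReLU surrogate
`ρ(z) = min(1, max(0, z + 1/2))`.  The protocol stack:

- **Beaver multiplication** — scalar, inner-product and matrix products on
  shares in exactly one communication round, whatever the dimensions;
- **local truncation** — rescaling after fixed-point products with zero
  communication, exact to ±1 ulp except with probability `2^(a+1−λ)`
  (≈ 2<sup>−51</sup> at the default operating point);
- **bit decomposition** — a secure binary-adder circuit turning ring shares
  into per-bit XOR shares, with a ripple-carry reference (Θ(k) rounds) and a
  carry-lookahead variant (Θ(log k) rounds), batched over all instances;
- **a comparison-free clipped-ReLU protocol** — reads the sign of
  `z' = z + 1/2` off one bit of a partial decomposition, checks `z' ≥ 1` with
  an OR over the b integer bits, and assembles `P·(z' + G·(2^a − z'))` with
  two multiplications and *no truncation*, so the activation is bit-exact.

Everything is verified against in-the-clear oracles (a float trainer and an
exact fixed-point ring simulator) on synthetic expression-shaped data, so the
test-suite runs with no external data.

## Worked example

Generate a small synthetic dataset and train end to end (all roles in one
process):

```python
from securelr.synthetic import SyntheticSpec, generate
df, w_true = generate(SyntheticSpec(n_samples=64, n_features=8,
                                    sparsity=0.4, margin=0.3, seed=5))
df.to_csv("demo.csv", index=False)
```

```sh
$ cat config.yaml
learning_rate: 0.05
iterations: 40
seed: 5
$ securelr simulate --data demo.csv --config config.yaml --out weights.tsv
{"rounds": 600, "messages": 1200, "bytes": 1267840, "triples": 760,
 "ring_mults": 51200, "bit_ands": 637440, "masked_bits": 5120}
```

The JSON line is the instrumented protocol cost: 40 iterations cost 600
communication rounds (15 per iteration: 1 inner product + 13 activation
layers + 1 gradient product; weight updates are local), ~1.2 MB of traffic
and 51,200 secure ring multiplications.  The revealed model:

```
feature  weight
bias     -0.291015625
f000001  0.04248046875
...
f000005  1.802001953125
f000006  0.611572265625
```

The generator's true nonzero weights sat on features 5 and 6 (3.66 and 1.35);
the trained weights recover that support with cosine similarity ≈ 0.99.  All
decoded weights are multiples of 2⁻¹² — the model really lives in fixed
point.  The same run decomposes into separate roles:

```sh
securelr ti -n 64 -m 8 --config config.yaml --out-dir ti/     # randomness
securelr share --data demo.csv --config config.yaml --out-dir shares/
securelr train --config config.yaml --shares-dir shares/ --ti-dir ti/ --out-dir out/
securelr reconstruct --alice out/w_alice.mpcshr --bob out/w_bob.mpcshr \
    --features shares/features.txt --out weights.tsv
```

and `securelr bench-activation --sizes 256,1024` shows the batched activation
at work — the round count stays at 13 regardless of batch size, so the cost
per evaluation falls as batches grow:

```
{"evaluations": 256,  "rounds": 13, "bytes": 48384,  "runtime_per_activation_ms": 0.01345}
{"evaluations": 1024, "rounds": 13, "bytes": 193536, "runtime_per_activation_ms": 0.00677}
```

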