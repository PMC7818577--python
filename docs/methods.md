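# Methods

This note records the model, the protocol semantics, the numerical choices
and the limitations of `securelr`, in the order a maintainer meets them.

## Setting and trust model

Two data processors (Alice, Bob) compute on additive secret shares over
**Z**<sub>q</sub>, q = 2^λ; a trusted initializer (TI) pre-distributes
correlated randomness and then leaves.  Adversaries are honest-but-curious:
they follow the protocol but try to infer extra information from their view.
The library targets *protocol fidelity*, not production hardening: the RNG is
a seedable PCG64, not a CSPRNG; the transport is an instrumented in-process
channel, not an authenticated socket; and both endpoint roles execute in one
process.  What the channel instrumentation preserves from a real deployment
is exactly what the correctness and complexity claims need: the number of
rounds (one per simultaneous bidirectional exchange), the bytes per message,
and the full size transcript.

## Fixed-point representation

A real x with |x| < 2^b maps to `Q(x) = ⌊2^a·|x|⌋·sign` in two's complement
(truncation toward zero on the magnitude, not rounding to nearest — chosen
for bit-exact reproducibility of the encoding rule).  Defaults a = 12,
b = 15, λ = 64.  λ must be at least 2(a+b) so one product fits before
rescaling, and must be a machine-word width (8/16/32/64) so modular
arithmetic is native unsigned overflow; the 8- and 16-bit rings exist for
exhaustive testing.  Class labels are encoded as t·2^a so that t − o is on
the activation's output scale.

## Truncation and its error model

After a product of two scale-2^a values, each party rescales locally:
Alice keeps ⌊x_A/2^d⌋, Bob keeps −⌊(−x_B)/2^d⌋ (everything mod q).  For
values of magnitude below 2^a the reconstruction equals the two's-complement
floor division up to ±1 ulp, except with probability 2^(a+1−λ) where the
result is arbitrary (the share split straddles the wrap-around boundary).
At the default operating point that is ≈ 2^−51 per truncation.  Two
consequences shape the implementation:

- truncation is deferred — one application per inner product / gradient
  product / η-scaling, never per term;
- the learning-rate update multiplies by the public constant Q(η) and
  truncates locally, keeping the weight update communication-free.

Edge cases worth knowing: with Bob's share zero the rule degenerates to a
plain unsigned shift, which is exact integer division for non-negative
values but a guaranteed failure event for negative ones — the probabilistic
guarantee is over *random* splits, and the x_B = 0 convention here keeps the
non-negative case exact.  The failure exponent is parameterized by the
magnitude bound of the truncated value; the Monte-Carlo tests draw values
with |v| < 2^a, the regime the stated law describes.

## Secure multiplication

Beaver triples (U, V, W = U·V) pre-shared by the TI; the parties open
D = X − U and E = Y − V in one simultaneous exchange and assemble
Z = W + D·V + U·E + D·E locally, with the public D·E term added by Alice
(any single-party assignment is correct; fixing it makes runs reproducible).
One round regardless of dimensions; independent calls issued together are
coalesced into one exchange.  The same machinery with modulus 2 is the
secure AND gate; XOR and NOT are local.

## Bit decomposition and share conversion

Each party enters the bits of its own additive share as trivial Z₂ sharings;
the binary-adder carry recurrence c₁ = 0,
c_{i+1} = (y_i ∧ z_i) ⊕ (c_i ∧ (y_i ⊕ z_i)) is evaluated with secure ANDs
and output bit i is y_i ⊕ z_i ⊕ c_i.  Two carry circuits are provided and
cross-checked for identical openings: a literal ripple chain (k−1 rounds,
the correctness reference) and a Kogge–Stone prefix network
(1 + ⌈log₂(k−1)⌉ rounds; generate/propagate pairs combined per level with
two batched ANDs).  Decomposition may stop at k < λ positions; when the
decomposed value is known to have magnitude below 2^(a+b), every bit above
position a+b replicates the sign bit, so k = a+b+1 positions suffice to read
the sign.  Z₂ shares are held as unpacked 0/1 bytes and packed 8-per-byte at
the channel boundary, so bit traffic is proportional to ⌈batch/8⌉.

Bit-to-ring conversion consumes a TI masked-bit pair (one random bit r
shared in both Z₂ and Z_{2^λ}): open c = b ⊕ r (one batchable round), output
c + (1 − 2c)·⟦r⟧ locally.

## The activation protocol

ρ(z) = min(1, max(0, z + 1/2)).  On shares: z' = z + Q(1/2) locally; partial
decomposition to a+b+1 positions; `pos` = ¬(bit a+b+1); `geq1` = OR of the b
integer bits, computed by De Morgan as a balanced AND tree (⌈log₂ b⌉
rounds) on negated bits; both flags converted to ring sharings P, G in one
round; output o = P·(z' + G·(2^a − z')) with two sequential multiplications.
Case analysis: pos∧geq1 → 2^a; pos∧¬geq1 → z'; ¬pos → 0 (geq1 is computed
regardless and masked by P — no data-dependent control flow).  P and G are
unscaled 0/1 integers, so no truncation occurs and the protocol is *exact*:
the opened output equals Q(ρ(z)) everywhere, including the branch
boundaries z = ±1/2.  Precondition |z + 1/2| < 2^b is the caller's
responsibility; it cannot be checked obliviously.

## Training protocol

Weights start at the all-zeros sharing (the initialization is
data-independent and makes a zero-iteration run decode to the zero vector).
Per iteration: s = trunc(X·w); o = ρ(s) over the whole batch (all n
activations share every gate layer); e = t − o locally; g = trunc(Xᵀ·e);
w += trunc(Q(η)·g).  The iteration count is fixed and public — early
stopping would leak data through the stop time.  The gradient is the plain
sum over the batch; any 1/n normalization is the caller's to fold into η.
No regularization is implemented; a ridge penalty would only add a local
linear term to the update and is left as an extension.  The message schedule
(sizes, order, rounds) depends only on (n, m, n_iter, format) — verified by
transcript comparison across datasets of equal shape.

Owner orchestration: masks for sharing are drawn per table cell from the
seed, so horizontal, vertical and arbitrary partitions of the same table
produce bit-identical sharings and therefore bit-identical revealed weights.
The TI stream is pre-generated from a request plan recorded on an all-zeros
dry run of the same public dimensions (legitimate because the control flow
is data-independent); every record is single-use and depletion raises rather
than recycling.

## Oracles

Three reference implementations pin the secure path:

- `train_clear_float` — float64 clipped-ReLU gradient descent;
- `train_clear_fixed` — the exact ring pipeline on one machine, with the
  truncation rule applied under a configurable share-split model: `exact`
  (idealized floor division), `zero`, `random` (seeded splits), or `replay`;
- replaying the secure run's recorded truncation splits through
  `train_clear_fixed` reproduces the secure weights *bit for bit* (strong
  oracle); under independent random splits the weights agree within the
  truncation budget of ±1 ulp per truncation event, three events per
  iteration path (weak oracle).

## Synthetic data

The generator emulates the shape of the motivating datasets — hundreds of
samples, up to ~18k bounded numeric features, binary labels — with truncated
standard-normal features, a sparse true weight vector rescaled so the linear
score has standard deviation 4 (one fixed choice producing fairly separated
classes), an intercept set by the class-balance quantile, Bernoulli labels
through the sigmoid of the score, and optional flip noise.  `margin > 0`
switches to deterministic labels with score-margin resampling, the separable
regime used for parameter recovery.  Not modeled: feature covariance,
batch/pathway structure, heavy tails.  Passing tests therefore certify
protocol fidelity and secure/clear equivalence, not clinical performance.

## Problem sizes and numerical choices

The test-suite and acceptance script use scaled-down study shapes chosen as
representative: exhaustive checks on the 8-bit ring (all 65,536 operand
pairs), the full activation grid [−4, 4] in steps of 2^−12 (32,769 points),
10^6 Monte-Carlo truncation draws at λ=16, and training jobs up to n = 200,
m = 50, 100 iterations.  Ties and degenerate inputs: encoding truncates
magnitudes toward zero, −0 encodes as 0; the OR/AND trees pass odd leftover
elements through unchanged; a batch of one behaves identically to any other
batch size.  η is encoded like any other constant, so the effective learning
rate is ⌊2^a·η⌋/2^a (η = 0.001 at a = 12 acts as ≈ 0.000977).

## Known limitations

Two-party passive security only; no malicious-adversary protections, no
authenticated transport, no cryptographic offline phase (the TI could be
replaced by one without changing the online protocols).  λ is limited to
machine words; no arbitrary-precision rings.  The in-process channel cannot
measure wall-clock network latency — round and byte counts are the
transferable complexity measures.
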