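# Methods

This note documents the models and procedures implemented in `uimd`, the
assumptions behind them, the parameters that matter, and what the desk-scale
test bed does and does not establish.

## The robust string grammar

Molecules are represented primarily as strings in a derivation grammar
(`uimd.grammar`) designed so that *every* symbol sequence decodes to a
chemically valid structure.  Atom symbols (`[C]`, `[=C]`, `[#N]`, …) carry
the bond order to the preceding atom; the decoder clamps each requested bond
to the valence still available (C 4, N 3, O 2, F 1), so no sequence can
over-bond an atom.  `[Branch1]` and `[Ring1]`/`[=Ring1]` control symbols read
the following symbol as an index (branch length or ring reach, up to 12) via
a fixed index table.  Inapplicable control symbols and their index are simply
skipped; an exhausted chain ends the derivation.  The consequences:

- decoding is total — the only sequences without a molecule are those whose
  derivation consumes every atom symbol as an index;
- greedy decoding of any VAE latent yields a valid molecule (a latent whose
  decoded string derives no atoms falls back to the single-carbon string, so
  the decoder is total as well);
- the alphabet is the neutral organic subset C/N/O/F with implicit
  hydrogens, matching small-molecule design corpora.  Charged species,
  radicals, stereochemistry and exotic elements are out of scope: encoding
  such a molecule raises, and stereo annotations are dropped on round trip.

The encoder (molecule → string) does a recursive DFS over the kekulized
heavy-atom graph, emitting side chains as branches (smallest subtree first)
and ring closures as back-edge references; molecules whose branch length or
ring reach exceeds the index table are rejected at load time.

## Molecule views, conformers, and "stability"

Each molecule record carries three linked views: the grammar string, a
fixed-length token sequence (PAD-padded, vocabulary built from the training
corpus), and optionally a 3D heavy-atom graph from seeded distance-geometry
embedding (ETKDGv3) followed by MMFF relaxation (`maxIters=200`).  Embedding
failure is a first-class outcome with a reason code, never an exception.

A design is **stable** when it can be interpreted as a molecule, its
conformer embedding and force-field relaxation converge, and the oracle
returns finite values.  Two refinements make this a faithful desk-scale
mirror of a forward process that "does not always converge":

- **Geometry re-interpretation.**  A raw 3D graph (e.g. after a coordinate
  or atom-type perturbation) is re-perceived from interatomic distances; if
  the perceived connectivity matches the original topology the original bond
  orders are kept, otherwise single bonds are assumed and sanitization must
  pass.  Valence violations (a swapped atom type that cannot carry its
  bonds) surface here.
- **Strain gate.**  A conformation supplied to the oracle must be
  geometrically self-consistent: its heavy-atom strain energy — the MMFF
  energy of the supplied geometry (hydrogens added and relaxed with heavy
  atoms fixed) minus the energy of its fully relaxed minimum — must be below
  2 kcal/mol, about 3 kT at room temperature.  Relaxed conformers score ~0;
  a single atom displaced by N(0, 0.1 Å) noise typically scores several
  kcal/mol.  This mirrors single-point quantum calculations degrading or
  diverging on strained geometries; it is what gives the coordinate- and
  atom-type-perturbation modes a realistic failure channel at desk scale.

## Oracles (the native forward process)

All oracles satisfy one contract — callable → `OracleResult` with status
`ok`/`unstable` — so the expensive reference process, the desk-scale
descriptor oracle, an analytic test oracle and a user-supplied external
command are interchangeable:

- `DescriptorOracle` returns molecular weight (Da), Crippen logP and TPSA
  (Å²): three descriptors mirroring the dimensionality and multi-objective
  structure of the reference HOMO/LUMO/dipole setting without any quantum
  chemistry.  Deterministic; instability is defined above.
- `AnalyticOracle` returns p = A·z + b exactly, for closed-loop harnesses in
  which the "molecule" is its latent.
- `ExternalCommandOracle` writes an SDF and parses JSON from a user command;
  program failures become `unstable` results with the captured reason.

Oracles always report natural units; standardization (z-scoring) happens in
consumers, and the surrogate and optimizer share the statistics stored on
the reacquired dataset.

## SGP-VAE

The VAE (`uimd.vae`) encodes the concatenation of the one-hot token sequence
and the masked padded graph features (atom one-hot + raw coordinates + a
presence flag, so molecules whose embedding failed still encode) through one
hidden layer to a diagonal Gaussian posterior.  The decoder maps z through
one hidden layer to per-position token logits, atom-type scores and
coordinates; a separate head predicts standardized properties from the
*sampled* z.  Graph reconstruction is deliberately non-equivariant —
coordinates are regressed in the input frame against the record's own
conformer.  The loss is the unweighted sum of property L1, masked graph
squared error, token cross-entropy, and the closed-form diagonal-Gaussian
KL; weights are configurable but default to 1.

Training uses AdamW with a cosine-annealed learning rate, 50 epochs, batch
size 32.  Defaults that are free choices here: latent dimension 64 for the
library default (32 in the desk-scale studies — small corpora need less
capacity), hidden width 512, learning rate 3e-3.  All training is seeded and
bitwise reproducible; non-finite loss components abort with the component
named.

The neural stack is NumPy + autograd throughout (reverse-mode
differentiation over numpy arrays), with a hand-written AdamW and cosine
schedule; there is no GPU path and none is needed at these problem sizes.

## Reacquisition

`reacquire` samples z ~ N(0,1), decodes (greedy), embeds, and labels through
the oracle; unstable outcomes are dropped and counted, and every stored pair
is bitwise recomputable for deterministic oracles.  Duplicate decoded
molecules are kept as distinct pairs (their latents differ; duplicates carry
the decoder's many-to-one structure).  The dataset stores its own
standardization statistics.  The production default is ~10,000 pairs; the
closed-loop studies use 1,000–2,000 (see below).  `legacy_encode_dataset`
implements the encoded-pairs baseline, flagged `legacy` in provenance, kept
for the ablation.

## Ensemble surrogate and uncertainty

The surrogate is n = 5 MLPs (latent → properties, hidden 64–64) with the
activation cycle relu/tanh/gelu/silu/elu — identical layer counts, different
nonlinearities, independent seeded initializations.  Training is L1 loss in
standardized property space, 300 epochs, batch 32, with stochastic gating:
at each mini-batch iteration each member independently takes an AdamW step
with probability q = 0.3 (seeded Bernoulli draws, realized counts recorded
per epoch), so 300 epochs correspond to ~90 effective epochs per member.

Epistemic uncertainty is the population variance of member predictions per
property, computed one-pass as mean-of-squares minus squared-mean in
standardized space, clipped at zero against floating-point negatives
(pre-clip values are asserted ≥ −1e-8), and aggregated across properties by
summation — the simplest extension of the scalar definition to the
multi-property case.

## Latent design

`optimize_latent` runs plain gradient descent with a cosine-annealed step
size on `Σ|Φ_avg(z) − p| + λ·U(z)` from a seeded N(0,1) initialization,
tracking the best iterate (descent on a nonconvex surrogate is not
monotone).  λ defaults to 1 (the unweighted sum); targets may be any subset
of the trained properties, standardized with the ensemble's statistics and
aggregated as an unweighted sum of absolute errors.  A design request runs
k = 10 independent tries; all tries (and, in grid runs, all targets) are
optimized as one batched latent matrix since the objective is row-separable.

Try selection: when an oracle is available the retained try has the lowest
total absolute oracle error (the evaluation protocol's rule); without one,
the lowest surrogate error.  The trustworthiness study below deliberately
uses surrogate-error selection, because the offline setting assumes no
forward-process access during design.  Extra penalties plug in as named
callables; the shipped example is a decode-and-score molecular-mass
preference, which contributes to candidate selection rather than to the
gradient (the decode step is discrete).

## Evaluation

Metrics: per-property MAE between oracle values of stable designs and their
targets (unstable designs counted, excluded from the mean); novelty (% of
designs whose canonical structure is absent from a reference set);
uniqueness (% distinct); misalignment |MAE_nfp − MAE_surrogate| per property.
All metrics are recomputable from the persisted per-design CSV.

The perturbation study applies one minimal perturbation per molecule in four
modes — N(0, 0.1) noise on one atom's coordinates, one atom-type
substitution, one grammar-symbol substitution, N(0, 0.1) noise on one
component of the encoded posterior mean (decoded greedily) — and reports the
stable percentage per mode plus the property MAE between original and
perturbed over molecules stable in both.  On the 200-molecule corpus the
latent mode is the most robust and the two geometric modes the least, the
ordering the latent-space design argument predicts; the reference setting's
absolute percentages are not reproducible without its quantum-chemistry
oracle, and are not claimed.

## Closed-loop harnesses

Two analytic harnesses make the design loop verifiable against linear
algebra, with no molecular decoding in the loop:

- **Bounded-region harness** (`closed_loop_harness`): oracle p = A·z with
  unit-norm random rows, training latents truncated-normal inside the box
  |z_j| ≤ 1, d = 16, N = 2,000 pairs.  In-range targets are images of points
  inside the box (achievability verified by bounded least squares);
  out-of-range targets scale each property 1.05–1.4× beyond the
  box-achievable extreme r·‖a_j‖₁.  This is the test bed for design
  recovery (median standardized oracle error on in-range targets) and for
  the uncertainty term's effect: with λ=0 the optimizer leaves the training
  region chasing unreachable targets, the surrogate claims near-zero error
  while the true error is large (misalignment); with λ=1 designs stay near
  the data and both the oracle error and the misalignment drop.
- **Lossy-autoencoder harness** (`lossy_autoencoder_harness`): the decoder
  is the identity but the encoder is e(m) = R·m + c with R = I + 0.5·G/√d,
  so legacy encoded pairs live in coordinates inconsistent with what the
  decoder implies.  Surrogates trained on legacy pairs inherit that
  inconsistency and design ~30× worse than surrogates trained on reacquired
  pairs under identical budgets.

## Problem sizes and determinism

The test suite and the acceptance script run the full method at desk scale:
200-molecule corpora (max 16 tokens), VAE 50 epochs, ensembles 300 epochs on
1,000–2,000 pairs, 20-target design grids with k = 3–5 tries, chosen so the
whole suite completes in minutes on a single CPU while keeping the training
recipes (epochs, batch size, gating probability) at their reference values.
Every stage is seeded: corpus generation, conformer embedding, VAE and
ensemble training, gating draws, latent initializations.  Two runs with the
same seeds agree bitwise.

## What the synthetic data does not show

The random-grammar corpus matches real small-molecule corpora in element
set, size range and multi-objective property structure, but not in chemical
plausibility (it is rich in strained rings and cumulated multiple bonds) or
property distributions; the descriptor oracle is smooth and cheap where a
quantum-chemistry oracle is rugged and expensive.  Passing tests therefore
establish the *mechanisms* — latent organization, reacquisition consistency,
uncertainty-guided trust regions, robustness ordering of representations —
not quantitative performance on any real design task.

## Known limitations

- The grammar covers neutral, radical-free C/N/O/F molecules without
  stereochemistry; branch/ring indices are bounded by the 12-entry table.
- The mass penalty is selection-level, not gradient-level; a differentiable
  property surrogate would be needed for gradient guidance.
- The latent-vs-string robustness margin in the perturbation study is small
  at this corpus size (one or two molecules out of ~180) and can flip for
  individual seeds, while the geometric modes trail by a wide margin.
- Active-learning reacquisition (iterating sample → label → retrain) is out
  of scope.
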