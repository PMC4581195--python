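# Methods

## Model

The package implements a weighted deep convolutional neural field (DeepCNF)
for per-residue binary sequence labeling, applied to protein order/disorder
prediction. Given per-residue input features `X = (X_1, …, X_L)` and labels
`Y ∈ {0 = order, 1 = disorder}^L`, the conditional distribution is the
linear-chain CRF

    P(Y | X) = exp( Σ_i [ Ψ′(Y, X, i) + Φ′(Y, X, i) ] ) / Z(X)

with weighted potentials

    Ψ′(Y, X, i) = Σ_{a,b} T_{a,b} · w_a · δ(Y_i = a) δ(Y_{i+1} = b)
    Φ′(Y, X, i) = Σ_{a,j} U_{a,j} · H_j(X, i, W) · w_a · δ(Y_i = a)

where `w_a` is a fixed per-label weight and `H(X, i, W)` is the top layer of
a stack of position-shared convolutional layers:

    A^1 = X,   A^{k+1}_i(j) = h( Σ_{l=-N_k}^{N_k} Σ_{j'} A^k_{i+l}(j') W^k_l(j, j') )

`h` is the sigmoid (default) or tanh. With one hidden layer the model is a
plain conditional neural field; with `w ≡ 1` the potentials reduce to the
unweighted form. The large weight on the rare disorder label (default ratio
0.7 : 9.3 order : disorder, the inverse of the ≈93 : 7 prevalence scaled by
ten) raises the cost of disorder errors both in the training objective and —
by using the same weighted potentials at inference — in the predicted
marginals.

Modeling conventions, chosen where the formulation leaves room:

* **Zero padding.** Window positions `i + l` outside `[1, L]` contribute
  zero, so every layer keeps `L` positions and convolution weights remain
  position-shared.
* **No bias terms by default.** The recursion above has none; a per-layer
  bias can be enabled (`ArchitectureSpec(use_bias=True)`) but is off so the
  default model matches the equations exactly.
* **Transition at the chain end.** The pair potential needs `Y_{i+1}`, so its
  contribution is defined as zero at `i = L` (the usual linear-chain
  convention).
* **Weighting by the first label only.** `Ψ′` multiplies by `w_a` (not
  `w_b`), exactly as written above.
* **Log-space chain arithmetic.** Partition function, forward–backward and
  path sampling all work in log space; the stack is stable for parameter
  magnitudes up to ~50 on chains of thousands of residues (tested at
  L = 2000).

## Inference and decision rule

`posterior_marginals` runs forward–backward and returns `P(Y_i = a | X)`;
`classify` calls disorder when `P(disorder) ≥ t` with default `t = 0.2`, the
operating point of the released disorder predictor (chosen there by best MCC
on training data; `best_mcc_threshold` reimplements that selection, breaking
ties toward the lowest threshold).

## Training

The objective (to maximize) is

    Σ_seq log P_w(Y | X)  −  (λ_eff / 2) ‖θ‖²,   θ = (W, U, T)

The fixed label weights `w` are hyperparameters and are never penalized or
trained. The gradient is exact: transition gradients come from empirical
minus expected pairwise marginals, emission gradients from node marginals
against top-layer activations, and convolution gradients by backpropagating
the CRF error signal through the stack; cost per sequence is O(L·K·N·M² +
L·M·D + L·D²). Optimization is L-BFGS (scipy's L-BFGS-B, history 10,
relative-objective tolerance 1e-6, gradient ∞-norm tolerance 1e-5, default
cap 200 iterations). Parameters initialize uniformly in [-0.1, 0.1] from a
seeded generator; a fit is bit-reproducible given its seed.

**Regularization factor.** The default factor is 200, interpreted as a
per-residue multiplier: `λ_eff = l2_factor / (total residues in the
corpus)`. The raw interpretation (`λ_eff = l2_factor`) is selectable via
`TrainingConfig(l2_mode="raw")`. The scaled reading keeps the penalty from
swamping the likelihood on small corpora while behaving like a fixed factor
at fixed corpus size; since only the product with the data size is
identifiable from the description "factor fixed at 200", the choice is a
documented convention, not a fitted value.

**Inverse-prevalence weights.** `reciprocal_frequency_weights` returns
weights proportional to the swapped label frequencies, normalized to sum to
one (93 % / 7 % order/disorder → (0.07, 0.93)). Because the potentials are
linear in `w`, only the ratio and joint scale matter; ratios such as 0.7:9.3
are used exactly as given.

## Features (width 129)

Per residue, three classes assembled in fixed column order:

* **Amino-acid related, 78 columns** — one-hot identity (20), 7
  physico-chemical descriptors, 11 secondary-structure-segment endpoint
  propensities, 40 correlated contact-potential values. The physico-chemical
  table ships with literature values; the 11- and 40-column tables ship as
  clearly labelled synthetic stand-ins with the correct shape and lookup
  semantics (their published sources are not redistributable here) and can be
  replaced via `AminoAcidTables.from_files`. Unknown residues (X, and
  B/Z/U/O/J folded to X) get a zero indicator and per-table column means.
* **Evolution related, 40 columns** — 20 PSI-BLAST PSSM log-odds scores
  (first score block of the ASCII matrix) squashed elementwise through a
  sigmoid so inputs stay bounded, plus 20 profile-HMM match-emission
  probabilities from an HH-suite HHM file (stored as −1000·log2 p, `*`
  meaning probability zero). Column order is normalized to the package's
  canonical residue alphabet using the header letters of each file.
* **Structure related, 11 columns** — 8-state secondary-structure and
  3-state solvent-accessibility probabilities from an upstream predictor,
  read from TSV and passed through unchanged after validating that each row
  sums to one within 1e-3 (tolerant of printed rounding).

Ablation modes (`ami_only`, `evo_only`, `struct_only`, pairwise
combinations) drop whole classes; a required class that is missing raises —
nothing is silently zero-filled. Every feature matrix carries a manifest
string recording mode and transforms; models store it and refuse
incompatible inputs at prediction time.

## Labels

Annotations use one character per residue: `O` observed, `D` coordinates
missing, `N` not available, `X` explicit disorder mark. `N` residues are
removed (masked) first; maximal runs of coordinate-lacking residues (`D` or
`X`) longer than three are disordered, shorter runs ordered; `X` positions
are then forced disordered regardless of run length. The boundary is strict:
a run of four is disordered, a run of three is not. The mask and the
old-to-new index map are preserved so predictions can be projected back onto
the full chain. `disorder_segment_stats` bins non-terminal disorder segments
(not touching either chain end) into lengths 1–5, 6–15, 16–25, >25 and
reports residue and fragment totals.

## Metrics

Precision TP/(TP+FP), balanced accuracy 0.5·(TP/(TP+FN) + TN/(TN+FP)), and
MCC in the standard product/√ form, with disorder as the positive class; a
metric whose defining ratio is 0/0 is reported as NaN, never as 0. The ROC
sweeps thresholds over the distinct scores with the ≥ convention and
integrates trapezoidally, which equals the tie-corrected Mann–Whitney
statistic (ties count ½) — verified against scikit-learn in the tests.
Residues are pooled across sequences by default; a per-sequence table is
available.

## Synthetic data

The generator emulates the study conditions so the pipeline can be trained
and validated without external datasets or predictors: ~7 % disordered
residues (realized pooled fraction within ±2 points at n ≥ 50 sequences)
arranged in segments drawn from the empirical fragment-length mixture of
curated disorder corpora (bins 1–5 : 6–15 : 16–25 : >25 at
0.629 : 0.289 : 0.058 : 0.024), placed uniformly without adjacency; terminal
segments can be allowed, forbidden or forced. Feature signal is planted the
way real disorder signal manifests: disorder-promoting residues (P, E, S, Q,
K) enriched in disordered segments, order-promoting residues (C, W, I, Y, F,
L, M, H) in ordered ones, profile scores tilted the same way, secondary
structure leaning to coil and accessibility to exposed inside disorder.
`signal_strength` scales all enrichments (0 = label-independent features;
default 2 gives a learnable but imperfect problem). Emitted files use
exactly the dialects the parsers consume and round-trip through them.

What the generator does **not** emulate: real evolutionary correlation
structure, position-dependent conservation, predictor-specific error modes
of secondary-structure/accessibility tools, or sequence-length/composition
biases of curated datasets. Passing the planted-signal checks therefore
demonstrates that the model, gradient and pipeline are correct and can
recover label signal of the kind described — not that the package, trained
on synthetic data, predicts real proteins at published accuracy; that
requires real profiles and training corpora supplied through the file
interfaces.

## Validation scenarios and problem sizes

`deepcnf.validation` fixes the desk-scale study conditions used by the test
suite and the reproduction script (sizes chosen once as a single-CPU
workload):

* enumeration checks: 20 random models, chains of length ≤ 8, tolerance
  1e-8 against exhaustive path enumeration;
* gradient checks: 3-sequence corpora (L ≤ 10) for 1-, 2- and 3-layer
  stacks against central differences with step 1e-5; component error is
  measured as |g_a − g_n| / max(|g_n|, 1e-4);
* the unweighted identity: w = (1,1) likelihood and gradients against an
  independently coded loop-and-enumeration CNF, tolerance 1e-10;
* planted-signal learning: 80 training / 20 held-out chains of length 200 at
  signal strength 3, default two-layer (and one-layer) architecture, 80
  L-BFGS iterations;
* the weighting comparison: 60/30 chains of length 150 at signal strength
  1.5, one hidden layer of 25 neurons, identical data and seed for the
  0.7:9.3 and 5:5 ratios, balanced accuracy at threshold 0.5, raw
  regularization factor 200. Two conditions matter here. First, because the
  per-label weights multiply trainable potentials, they are absorbable into
  U and T at an unpenalized optimum — the weighting mechanism acts through
  the L2 geometry (a potential carried by weight w costs 1/w² as much
  squared norm), so the penalty must bind for the comparison to measure
  anything; the raw factor provides that, matching the regime of the
  original weight-ratio experiment. Second, moderate signal keeps the
  classifier imperfect: at high signal both ratios saturate near-perfect
  accuracy and the comparison is uninformative.

## Known limitations

* Training is full-batch L-BFGS; no stochastic or Hessian-free modes.
* Two labels only are exercised, though the chain code is written for
  general D.
* The shipped 11- and 40-column amino-acid tables are synthetic stand-ins
  (see above); supply literature tables for real use.
* No bundled profile or structure predictors: PSSM/HHM/SS8/ACC3 inputs are a
  file contract.
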