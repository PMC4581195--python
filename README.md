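# deepcnf-disorder

Weighted deep convolutional neural fields (DeepCNF) for predicting
intrinsically disordered regions in proteins from sequence, evolutionary
profiles and predicted local structure.

Intrinsically disordered regions — segments with no stable tertiary
structure, operationally defined by missing atomic coordinates in crystal
structures — make up a small minority (~7 %) of residues, so per-residue
disorder prediction is a strongly imbalanced sequence-labeling problem. This
package implements the DeepCNF answer to it: a stack of position-shared
convolutional layers reads a window of per-residue features and feeds a
linear-chain conditional random field

    P(Y | X) = exp( Σ_i [ Ψ′(Y,X,i) + Φ′(Y,X,i) ] ) / Z(X)

whose transition potential Ψ′ = T_{a,b}·w_a and emission potential
Φ′ = Σ_j U_{a,j}·H_j(X,i,W)·w_a carry fixed per-label weights `w` (default
0.7 : 9.3 order : disorder, the inverse of the class prevalence) so the rare
disorder label is not drowned out during training or prediction. Training
maximizes the L2-penalized weighted conditional log-likelihood with exact
forward–backward gradients and L-BFGS.

The library covers the full workflow: the 129-dimensional feature
construction (78 amino-acid + 40 evolution + 11 structure columns, with
parsers for FASTA, PSI-BLAST ASCII PSSM, HH-suite HHM and SS8/ACC3 TSV
files), CASP-convention labeling from missing-coordinate annotations,
imbalance-aware evaluation (precision, balanced accuracy, MCC, ROC/AUC), a
seeded synthetic-corpus generator, and a CLI. See `docs/methods.md` for the
model and all numerical conventions.

## Worked example

Generate synthetic training and held-out corpora, train a small model,
predict and evaluate — no external data needed:

```sh
deepcnf-disorder generate --out corpus --n-sequences 20 --min-length 60 \
    --max-length 90 --signal-strength 1.5 --folds 2 --seed 5
deepcnf-disorder generate --out heldout --n-sequences 10 --min-length 60 \
    --max-length 90 --signal-strength 1.5 --seed 6
deepcnf-disorder train --manifest corpus/manifest.tsv --out model.json \
    --layers 2 --neurons 8 --window 7 --max-iter 40 --seed 3
deepcnf-disorder predict --model model.json --fasta heldout/sequences.fasta \
    --pssm-dir heldout/pssm --hhm-dir heldout/hhm --ss8-dir heldout/ss8 \
    --acc3-dir heldout/acc3 --out pred.tsv
deepcnf-disorder eval --pred pred.tsv --labels heldout/labels.tsv --out report.tsv
```

which prints:

```
wrote 20 sequences under corpus (manifest: corpus/manifest.tsv)
wrote 10 sequences under heldout (manifest: heldout/manifest.tsv)
model written to model.json (objective -6.6719, 40 iterations)
predictions for 10 sequences written to pred.tsv
 n_residues      auc  precision     bacc      mcc  threshold
        771 0.995244   0.938776 0.931873 0.895818        0.2
```

`auc` is the area under the ROC curve over all pooled residues (1.0 =
perfect ranking, 0.5 = random); `bacc` averages sensitivity and specificity,
and `mcc` is the Matthews correlation of the binary calls at the decision
threshold (default 0.2, the released predictor's operating point). The
prediction file holds one row per residue: position, residue, disorder
probability, binary call.

The same workflow runs from Python:

```python
from deepcnf import (GeneratorConfig, generate_corpus, ArchitectureSpec,
                     TrainingConfig, fit, posterior_marginals)

corpus = generate_corpus(GeneratorConfig(n_sequences=20, seed=5)).training_corpus()
arch = ArchitectureSpec.create(input_dim=corpus.input_dim, layers=2)
result = fit(corpus, arch, TrainingConfig(max_iterations=60))
marginals = posterior_marginals(result.params, corpus.items[0][0])
```

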