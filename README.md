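# cppscreen

Screening peptides for cell-penetrating potential with a Pearson VII
universal kernel (PUK) support vector machine over primary biochemical
descriptors.

Cell-penetrating peptides (CPPs) are short sequences — arginine-rich Tat
fragments, penetratin, transportan analogs and many others — that cross
cell membranes and can ferry cargo into cells. Experimentally confirming
penetration is slow, so a classifier that screens candidate sequences
before synthesis is useful to anyone designing delivery peptides. The
catch is the data: many confirmed positives exist, but very few peptides
have been experimentally shown *not* to penetrate, and most of those are
close analogs of known CPPs. `cppscreen` is built for exactly this
setting, for computational biologists and peptide designers who want a
transparent, descriptor-level model rather than a black box.

## What it implements

- **Descriptors.** Each peptide maps to 61 primary biochemical features:
  length, net/positive/negative charge, isoelectric point, molecular
  weight, grand-average hydropathy, the 20 residue counts and 20 residue
  percentages, residue-group percentages, hydrophobicity /
  lipophilicity / amphiphilicity / water–octanol partition / steric and
  side-chain bulk scale means, net donated side-chain hydrogen bonds,
  and helix/sheet/coil propensity fractions. Features are min-max
  normalized to [0, 1].
- **Classifier.** A soft-margin SVM with the PUK kernel
  K(x, y) = 1/[1 + (2‖x−y‖√(2^{1/ω}−1)/σ)²]^ω (defaults ω = σ = C = 1),
  trained by sequential minimal optimization. `PukSvm(X, y).fit()`
  returns a `PukSvmResults` object carrying support vectors, dual
  coefficients αᵢyᵢ, bias, diagnostics and `summary()`, in the familiar
  model/results style.
- **Imbalance-aware training sets.** Five constructions over the bundled
  111 positives / 34 negatives: unbalanced; balanced with random
  peptides; balanced with pool-drawn biological peptides; balanced by
  oversampling the known negatives; ten sets balanced by subsampling the
  positives.
- **Wrapper feature selection.** Scatter search over feature subsets
  scored by cross-validated accuracy of the same PUK-SVM.
- **Generator + screening workflow.** A seeded 0th-order Markov peptide
  generator (lengths uniform 12–26) and an end-to-end screen:
  generate → featurize → classify → rank → shortlist for synthesis.
- **Bundled data.** The compiled tables of 111 known CPPs, 34 known
  non-penetrating analogs, and the 13 wet-lab validation peptides ship
  as plain-text package resources; no network access is needed.

## Worked example

```python
import cppscreen as cs

pos = cs.load_bundled("cpp111")          # 111 known CPPs
neg = cs.load_bundled("noncpp34")        # 34 known non-penetrating analogs

# balance by oversampling the known negatives to 111, then 10-fold CV
ds = cs.build_dataset(cs.Strategy.OVERSAMPLE_NEG, pos, neg, seed=1)
print(cs.cross_validate(ds, k=10, seed=1).summary())
```

```
Classifier evaluation
========================================
Total examples:           222
Confusion (tn fp fn tp):  98 13 8 103
Accuracy:                 90.54%
True positive rate:       0.905
False positive rate:      0.095
ROC area:                 0.931
CPP accuracy:             92.79%
Non-CPP accuracy:         88.29%
========================================
```

The pooled 10-fold confusion matrix shows the balanced design working:
both classes are recovered at ~90%, far above the 76.55% majority
baseline of the raw unbalanced data (`cs.majority_baseline(111, 34)`).
A model fitted on this dataset ranks the validation peptides sensibly by
decision value:

```python
res = cs.train_svm(ds)
labels, scores = res.predict_peptides(list(cs.load_bundled("validation13")))
```

The three positive controls score highest (HIV-TAT 1.000, Pep-1 1.000,
Antennapedia 0.805) while the known non-penetrating transportan analog
TP13 scores lowest of the named controls (0.186) — although, true to the
known hardness of near-analog negatives, its decision value still falls
on the CPP side of zero.

Feature selection and screening:

```python
cand = cs.scatter_search(ds, cs.ScatterSearchConfig(seed=1))   # wrapper search
screen = cs.screen_candidates(res, cs.default_frequency_model(),
                              n=250, seed=42, shortlist=(4, 2))
```

`screen.table` ranks all 250 generated candidates by decision value and
`screen.shortlist_positive` / `shortlist_negative` give the 4 + 2
synthesis picks. The same steps are scriptable via the `cppscreen` CLI
(`cppscreen data|features|generate|build|select|train|predict|evaluate|screen --help`).

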