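# Methods

`cppscreen` classifies short peptides as cell-penetrating (CPP) or
non-penetrating from primary biochemical descriptors, using a support
vector machine with the Pearson VII universal kernel (PUK). This note
records the model, the descriptor definitions, the dataset-construction
strategies, the search and evaluation procedures, the numerical choices,
and what the packaged synthetic data can and cannot show.

## The classification model

The classifier is a soft-margin binary SVM over min-max-normalized
descriptors. The kernel is the Pearson VII function

    K(x, y) = 1 / [1 + (2 ||x − y||₂ √(2^{1/ω} − 1) / σ)²]^ω

with tailing exponent ω (Lorentzian at ω = 1, approaching a Gaussian as
ω → ∞) and half-width σ. Defaults are ω = 1, σ = 1, C = 1, the
conventional defaults of the kernel's reference implementation; all three
are exposed (`KernelParams`, `SVMConfig`). The dual quadratic program is
solved by sequential minimal optimization — delegated to libsvm through
scikit-learn on a precomputed PUK Gram matrix — and the fitted solution
(support rows, dual coefficients αᵢyᵢ, bias) is stored in
`PukSvmResults`, which predicts and serializes independently of the
solver. The solution is checked in the test suite against a dense
SLSQP quadratic-programming oracle on small problems and against the KKT
conditions directly. A decision value f(x) > 0 classifies a peptide as
CPP; ties (exactly 0) go to non-CPP.

## Descriptors (61 features)

For each peptide: length; net/positive/negative side-chain charge counts
(positive counts K, R and H — histidine is treated as positively
charged; negative counts D and E; termini excluded from the integer
counts); isoelectric point; average molecular weight (Da, free termini,
one water); grand-average hydropathy (Kyte–Doolittle); the 20 residue
counts and 20 residue percentages; four exclusive residue-group
percentages (positive {K,R,H}, negative {D,E}, polar uncharged
{S,T,N,Q,Y,C}, hydrophobic {A,V,L,I,M,F,W,P,G} — a partition of the
alphabet so the group percentages are well defined); five
mean-per-residue property scales (Eisenberg consensus hydrophobicity,
Fauchère–Pliska π for both lipophilicity and the water–octanol partition
coefficient — kept as two named features even though the default scales
coincide — Mitaku amphiphilicity, Charton steric parameter, Zimmerman
bulkiness); net donated side-chain hydrogen bonds (a packaged
donor-minus-acceptor table: R +5, K +3, W +1, C +1, M −1, D −4, E −4,
others 0; backbone excluded); and the three secondary-structure
fractions.

All scales live in `data/scales.json` with citations and are swappable;
the choice of specific published scales behind the generic property
names is a design decision of this package, so the registry confines
that ambiguity to data rather than code.

Secondary structure uses per-residue Chou–Fasman propensity argmax
(helix/sheet/coil, coil taken from the turn parameter), with ties broken
in the fixed order helix > sheet > coil. A statistical predictor such as
GOR would need an external training database; the propensity assignment
is self-contained and deterministic, at the cost of being a cruder
estimate — acceptable because the fractions act as three coarse
compositional features, not as structure predictions.

The isoelectric point solves the Henderson–Hasselbalch net-charge
equation (N- and C-terminus plus side chains C, D, E, H, K, R, Y, EMBOSS
pKa set) by bisection on pH ∈ [0, 14] to 0.001 pH; the charge is
strictly decreasing in pH so the root is unique. The test suite checks
bisection against an independent dense grid scan.

Normalization is per-feature min-max to [0, 1], fit on training rows
only; constant features map to 0 and held-out values outside the
training range are clamped. The quoted unit interval forces min-max
semantics; clamping keeps the kernel's distance geometry bounded for
screening candidates far from the training range.

## Training-set construction

Five strategies address the 111-positive / 34-negative imbalance of the
compiled tables (see `datasets.Strategy`): unbalanced (145 rows);
balanced with 111 generated random peptides as assumed negatives;
balanced with 111 biological peptides drawn without replacement from a
pool; balanced by oversampling the 34 known negatives with replacement
to 111; and ten balanced 34+34 datasets subsampling the positives with
replacement. Sampling weights are uniform over source rows. Rows are
shuffled once under the dataset seed — the shuffle belongs to the
dataset, not the fold splitter, so downstream folds are reproducible.
The ten subsampled datasets use seed + index.

The biological pool bundled for tests is *synthetic*
(`synthetic_biological_pool`): peptides sampled from the background
frequency model under a fixed seed, because the original
proteome-derived pool is not redistributable. Any real FASTA pool can be
supplied instead. Consequence: in tests, the biological-negatives
strategy behaves like the random-negatives strategy; results for that
strategy on real biological pools are not established by the test suite.

## Random-peptide generator

A 0th-order Markov model: i.i.d. residues from a frequency vector,
lengths uniform on an inclusive range (default 12–26). The packaged
default frequency table is the UniProtKB/Swiss-Prot release-average
amino-acid composition, a proteome-scale vertebrate-like background
standing in for any specific proteome; `estimate_frequencies` computes
the table from a user FASTA. The generator is driven by an explicit
seeded `numpy` generator, no global state. It emulates compositional
background only — no codon structure, no domain structure, no
higher-order correlations — so classifiers separating CPPs from these
candidates are using composition-level signal, which is also what the
descriptor set encodes.

## Wrapper feature selection (scatter search)

Subsets of the 61 descriptors are scored by stratified k-fold CV
accuracy of the same PUK-SVM used for final classification. Scatter
search keeps a reference set of b subsets (default b = 10), split half
quality (top scores, ties toward smaller subsets then lexicographic
name order) and half diversity (greedy maximization of the minimum
Hamming distance, over indicator vectors, to the members already
chosen). All refset pairs are recombined — features in both parents are
kept, features in exactly one are kept with probability ½ — and children
are improved by a first-improvement single-feature add/remove hill
climb with a capped neighbour budget. The refset update is elitist, so
the best score is non-decreasing; search stops when the refset is
unchanged for a generation or the generation budget (default 20) is
spent. Scores are memoized by subset. The inner wrapper CV uses 5 folds
by default to bound cost; reported accuracies always come from a fresh
10-fold CV.

Selected-subset *identity* is not a stable quantity — the wrapper score
surface has many near-ties — so the package treats recovered subsets
qualitatively (charge and hydrogen-bonding features recur) and tests
selection on synthetic data with planted informative features instead.

## Evaluation

Stratified k-fold cross-validation (default k = 10) pools out-of-fold
predictions into one confusion matrix (positive class = CPP). Stratified
because with 34 negatives among 145 rows an unstratified split can
produce folds without negatives. The panel reports accuracy,
class-weighted true-positive rate (algebraically equal to accuracy/100),
class-weighted false-positive rate, and class-weighted ROC area from
decision values (for two classes the per-class areas coincide with the
ordinary AUC of the CPP scores). Each fold refits normalization and the
SVM on its training split only. Note one deliberate asymmetry: wrapper
selection sees the whole dataset before the final CV — that is the
screening design this package reproduces — so reported CV accuracies
carry that selection optimism, most visibly on the small 68-row
subsampled datasets.

## Replication runs and problem sizes

`cppscreen.replication` rebuilds each strategy from the packaged
fixtures, runs scatter search, and reports 10-fold CV accuracy averaged
over 5 resampling seeds (the ten-dataset mean for the subsampled
strategy). These drivers use a compact search budget — refset 6, 3
generations, 3-fold inner CV, hill-climb cap 15 for the 222-row
datasets; 4 generations, 5-fold inner CV, cap 25 for the cheap 68-row
datasets, where selection has to work harder relative to the noise.
These budgets are the package's screening-scale defaults; the full
`ScatterSearchConfig` defaults remain available for deeper searches.
`scripts/acceptance.py` runs exactly these drivers.

## Numerical choices and degenerate inputs

- Solver tolerance: the SMO solver runs at 1/100 of the configured KKT
  tolerance (default 1e-3) so the stored solution satisfies the KKT
  conditions comfortably at the configured tolerance.
- Constant features normalize to 0 rather than NaN; empty matrices,
  empty subsets, single-class training sets and undersized pools raise
  typed errors rather than propagating degenerate numerics.
- Decision-value ties rank stably (stable argsort) and classify as
  non-CPP.
- Seeds: every stochastic component takes an explicit integer seed;
  derived child seeds come from `numpy.random.SeedSequence` and stay
  below 2³¹.

## Known limitations

- The compiled positive and negative tables mix detection methods and
  cell lines; a classifier trained on them inherits that heterogeneity.
- The negative class is small (34) and partly analogs of positives;
  oversampling repeats information rather than adding it, and CV folds
  can share duplicated rows, inflating accuracy relative to truly
  unseen analogs.
- Descriptors are composition-level; positional effects (e.g., where
  charge or aromatics sit in the sequence) are outside the feature set.
- The secondary-structure fractions are propensity heuristics, not
  structure predictions.
- Exact published per-strategy accuracies depend on unstated toolkit
  settings, fold assignments and search budgets; this package reproduces
  them within stochastic tolerance bands, not digit-for-digit.
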