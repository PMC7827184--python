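# Methods

## The prediction task

The quantity modelled is the folding free-energy change of a single
amino-acid substitution, ΔΔG = ΔG(mutant) − ΔG(wild-type) in kcal/mol,
with positive values destabilizing. The package treats this convention as
configuration rather than fact — thermodynamic databases disagree on sign —
so dataset loaders carry an explicit `target_kind` flag and the
deep-mutational-scan path (`stability_score`) negates predictions before
correlating, because stability scores run the opposite way (≈1 wild-type-
like, <1 unstable, >1 stabilized). The applied orientation is recorded in
every evaluation report.

Only sequence-derived inputs are used: the residue string and a PSSM from an
iterative profile search. The package parses PSI-BLAST's `-out_ascii_pssm`
dialect (first 20 numeric columns per residue row; header and lambda/kappa
footer ignored) and keeps the file's native column order
(`ARNDCQEGHILKMFPSTWYV`) on the object, so no encoder ever assumes
alphabetical order. Running the search itself, and binary checkpoint
formats, are out of scope.

## Features

All positions are 1-based, matching WposM mutation notation.

**PSSM normalization.** The pseudo-PSSM literature squashes log-odds scores
elementwise with the logistic function 1/(1+e⁻ˣ) before averaging; the exact
transform is a genuinely open choice, so it is configurable
(`logistic` | `identity` | `zscore`) with logistic as the documented default.
Logistic output is strictly in (0,1) and monotone, which the tests assert.

**Pseudo-PSSM** (group `psepssm`, 20 + 20·lag_max entries). Column means
capture per-amino-acid conservation averaged over the chain; the lag-g terms
mean((Pᵢⱼ − Pᵢ₊g,ⱼ)²) capture how quickly column-j scores decorrelate along
the sequence. `lag_max` defaults to 7 and must be smaller than the sequence
length (the denominator L−g would otherwise be non-positive; violating
inputs raise). The vectorized implementation is tested entrywise (1e−12)
against a literal double-loop oracle.

**Neighbor conservation scores** (group `neighbor_cs`,
20·(2·window_flank+1) entries, default flank 3 → 140). The PSSM rows of the
site and its flanks, flattened row-major. Termini are zero-padded to keep
dimensionality fixed — padding with the background (all 0.5 after logistic)
was the alternative; zeros were chosen so padded rows are distinguishable
from genuinely uninformative ones. This block depends on the position only,
not on the mutant residue.

**Sequence neighbors** (group `seq_neighbor`, 2·neighbor_span entries,
default span 5 → 10). Ordinal labels were preferred over one-hot: the
block's natural description is "ten labels with 20 possibilities each", and
gradient-boosted trees split ordinals natively, keeping the descriptor at
319 rather than 509 entries. One-hot encoding remains available via
`FeatureConfig(one_hot_neighbors=True)` for models that need it. Pad label
20 marks positions beyond the termini (and unknown residues).

**Physicochemical properties** (group `physchem`, 9 entries, fixed order:
net volume, net hydrophobicity, mutation type, net flexibility, chemical
property, size, polarity, hydrogen bond, label hydrophobicity). Net terms
are mutant-minus-wild-type differences of shipped scales — residue volumes
(Å³), Kyte–Doolittle hydropathy, an average chain-flexibility index — and
are antisymmetric under mutation reversal by construction. The categorical
entries are integer class codes of the mutant residue; `mutation_type` is
the transition code 7·class(wt)+class(mut) over the seven chemical classes.
The scales and class assignments are data on a versioned table
(`PhyschemTable`, version 2024.1), swappable without code change, because
published descriptor sets differ in exactly these details.

## Regression model and evaluation protocol

An XGBoost regression ensemble with squared-error loss. Defaults: 500 trees,
depth 5, learning rate 0.05, subsample 0.8, column subsample 0.8, L2 = 1.
The tuning grid (trees {200, 500} × depth {3, 5, 7} × learning rate
{0.05, 0.1} × subsample {0.8, 1.0}) is a replaceable default; selection is
exhaustive, scored by mean cross-validated PCC with ties broken by lower MSE
then grid order, and grid points that fail to fit are recorded and skipped.
Training runs single-threaded with a fixed random state by default, so the
whole pipeline — including every shuffle in cross-validation — is
reproducible bit-for-bit from (data, config, seed); parallel training is
available but must not change a selection, which is why the deterministic
mode is the default.

The benchmark protocol is repeated k-fold cross-validation: each repeat
reshuffles the records with a seed derived from (base seed + repeat index),
splits into folds differing in size by at most one, and scores each held-out
fold by PCC, MSE and MAE; aggregates are means and standard deviations over
all repeat × fold entries. Records are assigned to test folds exactly once
per repeat (asserted at run time). Defaults are 5 folds × 100 repeats.

Group importance sums per-feature *total gain* (gain × number of splits)
within each schema group and normalizes over groups to 1. Features the
ensemble never splits on contribute zero; a model with no splits at all
(constant target) reports uniform importances rather than dividing by zero.

**Homology-aware splitting.** Evaluation on mutations of proteins homologous
to training proteins overstates performance. `homology_partition` splits by
protein and requires every test protein to have global-alignment identity
below a threshold (default 30%) against every training protein. The
alignment scheme is Needleman–Wunsch with match +1 / mismatch 0 / gap −1 and
identity = identical positions / alignment length — no community standard
exists for this screen, so the scheme is declared rather than inferred, and
the pair is canonicalized (lexicographic order) before aligning because
co-optimal alignments could otherwise make the measure asymmetric. The
partition is greedy — shuffle proteins by seed, grow the test pool while the
identity constraint holds and the test record count stays at or below the
requested fraction — which is deterministic and adequate at the package's
scale; it makes no optimality claim about the achieved fraction.

**Comparing correlations.** Fisher's z-test,
z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3)), two-sided normal p-value.
The independent-samples form is implemented; when two methods are evaluated
on the *same* mutations a dependent-correlation test would be stricter, a
known limitation.

## Synthetic benchmark

The generator emulates the statistical shape of the real inputs, not their
biophysics. Sequences are i.i.d. draws from a background composition
(default uniform 1/20). Each PSSM row is a Dirichlet draw whose mean mixes
the background with a point mass on the true residue (`conservation`
controls the mix, `concentration` the tightness); scores are half-bit
log-odds against the background rounded to integers, as PSI-BLAST prints
them, so emitted ascii files re-parse to the in-memory matrices exactly.
Targets are y = w·x + σ·ε with ε ~ N(0,1): weights over named schema
features (default on the physicochemical block: net volume 0.02 /Å³, net
hydrophobicity 0.35, net flexibility 3.0 — chosen to give a signal spread of
roughly ±1.5 kcal/mol, the scale of real ΔΔG data), plus optional product
terms for a nonlinear ground truth used in the hyperparameter-search tests.
The noise draw is independent of the data draw, so changing σ changes
targets but not sequences, mutations or signal.

Linearity makes the best achievable held-out correlation closed-form,
ceiling = sd(signal)/√(var(signal)+σ²), which the Monte-Carlo test confirms
at n = 10000 within 0.02. Setting `target_ceiling` derives σ from the
realized signal so experiments can be specified by ceiling directly.

What passing these tests shows: the encoders, protocol and learner recover a
known ground truth at its noise limit. What it does not show: performance on
real thermodynamic data, whose targets are not linear in these features,
whose mutation spectrum is biased toward destabilizing substitutions, and
whose PSSMs carry real phylogenetic structure rather than independent
Dirichlet noise. Published headline correlations on curated ΔΔG sets are
therefore not reproducible here and are not claimed.

## Problem sizes

The parameter-recovery experiments use 2000 mutations (20 proteins × 100),
a size at which the cross-validated PCC sits within ±0.05 of a 0.9 ceiling
and the noiseless control exceeds 0.95; the acceptance script uses the same
conditions with 3 CV repeats, and the full 100-repeat protocol is exercised
on a 100-record set where the fold bookkeeping, not the learner, is under
test. These are the package's chosen desk-scale study conditions.

## Known limitations

- Predictions for stabilizing mutations inherit the destabilizing bias of
  any real training set; the generator does not emulate that bias.
- Multi-chain proteins and ProTherm scraping are out of scope; datasets are
  single-chain by assumption.
- The optional shell-out to a local `psiblast` binary is not implemented;
  PSSMs must be supplied as files.
- Classification (stabilizing/destabilizing) and reverse-mutation
  augmentation are deliberately excluded: reverse ΔΔG entries mirror the
  forward information and inflate apparent dataset size.
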