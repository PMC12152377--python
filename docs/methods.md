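# Methods

## Problem and data model

The package predicts relative inhibition — a percent-like measure of growth
reduction, positive for growth reduction and negative for growth increase,
bounded to [−200, 200] by quality filtering — for a cancer cell line
treated with one or two drugs at explicit micromolar concentrations.  A
screen entry is the tuple `(cell_line, drug_row, drug_col, conc_row,
conc_col, inhibition)`; monotherapies carry an absent second drug and a
zero second concentration.

### Preprocessing

`preprocess_screen` applies, in a fixed order: the inhibition quality
filter (|inhibition| ≤ 200); removal of entries whose every concentration
is zero; removal of cell lines lacking expression data; merging of
same-drug "pairs" into monotherapies with summed concentration; rewriting
of two-drug entries with exactly one positive concentration as
monotherapies; replicate averaging over the canonical key; log1p scaling of
concentrations; and finally a per-drug minimum-entry filter.  The canonical
replicate key orders the drug pair lexicographically with concentrations
following their drugs, so the same treatment written in either orientation
averages together.  The per-drug filter runs once after all other steps and
is not iterated to a fixed point; the entry threshold (10,000 for a
full-size public corpus) is a parameter so small synthetic screens can use
1.  The order is observable: an out-of-range inhibition is removed before
any merging, so merged monotherapies can never carry an out-of-range value.
Replicate averaging uses the unweighted arithmetic mean.

## Featurization

Cell lines enter the model as principal-component scores of their
expression profiles.  The PCA is centered (no per-gene scaling — source
expression matrices are assumed pre-normalized) and fitted **only on
training cells**, including inside every cross-validation fold; the default
of 300 components suits genome-wide expression, while synthetic worlds use
10–20.

Four drug encodings are provided.  `onehot` gives each known drug a slot
holding its log1p concentration; `onehottar` appends per-target-molecule
counts (0/1/2), with molecules kept only if targeted by at least 5 drugs;
`maccs` and `physchem` concatenate two per-drug feature blocks (binary
substructure fingerprints or numeric physico-chemical descriptors), each
followed by its drug's concentration.  Feature columns constant across the
configured drugs are dropped at config-build time, so block widths are
data-dependent rather than hard-coded.  The layout for the block encodings
is `[cell PCs | drug1 block | conc1 | drug2 block | conc2]`, and in
`onehottar` the target block follows the concentration slots; both are
frozen conventions, since any fixed layout is equivalent for the models
used here.

Because the block encodings are order-sensitive, every combination entry is
(by default) included twice, once per drug order, with the same target —
this teaches the model that both representations denote one treatment.
Test sets always contain both orders, so order-robustness can be measured.

## Splitting, model selection, models

The primary split is cell-blind: 20% of *cell lines* (not entries) form the
test set, and all of their entries go with them.  Hyperparameters are
selected by 5-fold CV whose folds partition the training cell lines; within
each fold the PCA is refit on that fold's training cells.  The winner
minimizes mean MAE across folds, ties broken by grid order.  An entry-level
random split is available for the known-cell-line contrast; it co-assigns
the AB/BA duplicates of an entry to one side.

Backends: scikit-learn random forest, elastic net and MLP behind one
fit/predict contract, plus two baselines — the global training mean, and
the per-treatment mean (per drug for monotherapies, per unordered pair for
combinations, global mean for unseen treatments).  Default grids are
deliberately compact (forest: 500 trees, sqrt features, leaf size 1/5;
elastic net: mixing {0.1, 0.5, 0.9} × penalty {0.01, 0.1, 1}; network: one
or two hidden layers with early stopping) and fully overridable; they are
this package's choices, not a claim about any particular published model.
All randomness (split, folds, model seeds) keys off explicit integer seeds.

## Dose-response measures

Inhibitions convert to viabilities by `v = clamp((100 − inh)/100, 0, 1)`.
Monotherapy curves use the three-parameter logistic in natural-log
concentration with constraints `c ∈ [0, 1]`, `b > 0`, `e > 0`, fitted by
bounded least squares from three starts (`c₀ ∈ {min v, 0}` with `b₀ = 1`,
plus a steep-slope start; `e₀` = geometric mean of the doses).  Fits need
at least 5 points and are rejected above RMSE 0.3 — the conventional
quality gate for public dose-response curves.  Data with essentially no
response range fit as `c ≈ 1` and are flagged degenerate-flat.  IC-levels
invert the curve in closed form, `x = e·((1−c)/(v*−c) − 1)^{1/b}`, and are
undefined when the asymptote `c` lies above the target viability; a
numeric root-finder serves only as a test oracle.

Dose-response matrices take the observed concentration set of each drug
plus a zero margin; monotherapy entries fill the margins, (0, 0) is
viability 1, unobserved cells are flagged missing.  Interpolation operates
on the viability scale (after clamping).  The combination CMax viability
divides `[0, CMax]` of each drug into 100 equally spaced concentrations
(inclusive of both endpoints — including 0 is harmless because
viability(0,0)=1 cannot be a nontrivial minimum), bilinearly interpolates
the matrix at all 10,000 dose pairs, and returns the minimum.  Matrix-based
measures never extrapolate: a CMax beyond the screened range is clamped to
it (flagged), or raises when clamping is disabled; curve-based measures may
evaluate the fitted function beyond the screened range and carry an
extrapolation flag instead.  The returned minimum is a lattice
approximation: it matches a dense-grid oracle within one grid cell's
viability step, and the "enlarging the box never raises the minimum"
property holds exactly for the true minimum but only up to lattice
resolution for the approximation.

## Evaluation and statistics

Pooled correlations over a multi-treatment test set are inflated by
between-treatment mean differences, so per-drug and per-combination PCCs
are first-class outputs: groups with constant actual values report an
*undefined* (NaN) PCC — deliberately not zero-filled — and macro averages
report the mean over defined groups together with the count of undefined
ones.  Interval stratification uses half-open bins `(lo, hi]` with default
edges {−25, 0, 25, 50, 75, 100}.

Approach comparisons are paired two-sided Wilcoxon signed-rank tests on
per-sample absolute errors from key-aligned test sets, with zero
differences dropped before ranking (the classic signed-rank convention),
Bonferroni adjustment by the number of pairwise tests capped at 1, and a
signed effect size `r = Z/√n_nonzero`, negative when the first approach has
the smaller errors.  Identical error vectors report p = NaN and r = 0.

Rankings sort treatments by ascending viability with lexicographic
tie-breaks; scores use Spearman correlation with average ranks for ties,
strict top-k cutoffs after tie-breaking, and the viability gap (actual
viability of the predicted best minus the actual minimum, ≥ 0 by
construction).  Treatments lacking a defined measure are excluded from
both rankings symmetrically.

## Synthetic worlds

The generator emulates the structure of a public combination-screen corpus
at desk scale.  Cells carry latent vectors `z` read out linearly into
expression (plus gene noise, sd 0.1); drugs carry random binary
fingerprints whose fixed linear projection yields a unit effect vector `w`;
monotherapy response is a 3PL curve whose log-inflection shifts by
`−(z·w)` (coupling 1.0), making cell-blind generalization learnable from
expression and drug behaviour learnable from fingerprints.  Combinations
follow Bliss independence (product of monotherapy viabilities), with a
fraction of pairs (default 0.3) given a localized Gaussian dip on the
log-concentration plane (amplitude 0.2–0.5, width half a log10 unit) —
a synergy window below the maximal doses, which is exactly the situation
the box-minimum definition of the combination CMax viability exists for.
Dose ladders are half-log-spaced around each drug's prior inflection
(6 points by default, the minimum 5 needed for curve fitting plus one);
CMax sits at quantile 0.8 of the screened log-range, so part of the
clinically relevant box is comfortably inside the screened grid.
Measured inhibition is `100·(1 − v)` plus Gaussian replicate noise
(default sd 7 inhibition units, the replicate scatter reported for large
public screens), clipped to [−200, 200] *after* noise addition so the
quality filter is exercised at extreme settings.

Default problem sizes (30 cells, 10 drugs, 15 pairs, 200 genes) were
chosen as the smallest world in which cell-blind training is meaningfully
harder than memorization while the full benchmark — two forest fits plus
baselines and all reconstructions — completes in seconds; the acceptance
script and the test suite both use these sizes.

What the generator does **not** emulate: multi-source batch effects,
heteroscedastic or inhibition-dependent noise, missing cells in dose
matrices, antagonistic interactions, or realistic marginal distributions of
inhibition beyond the replicate-noise scale.  Passing tests on these worlds
therefore demonstrate correctness of the pipeline's mechanics and the
qualitative phenomena (baseline improvements, order-robustness gains from
duplication, correlation inflation), not performance on real screens.

## Known limitations

* The 3PL model assumes monotone decreasing monotherapy response; rising
  curves (growth stimulation) are fit poorly and typically rejected by the
  RMSE gate.
* Per-treatment baselines ignore concentration entirely; they are floors,
  not competitive models.
* The neural-network backend is a small CPU MLP intended for contract
  completeness, not a tuned architecture.
* Matrix assembly assumes replicate-averaged input; conflicting duplicate
  measurements raise a consistency error.
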