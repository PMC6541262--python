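# Methods

This note documents the statistical procedures implemented in `cultshare`,
the choices made where the design was genuinely open, and what the synthetic
data do and do not establish about behaviour on real data.

## Data model

A *society* carries a name, optional decimal-degree coordinates, a non-empty
set of basic food-sharing practices drawn from a fixed 14-code vocabulary
(MM, TT, CC, WD, OD, RM, KS, GS, NS, PR, SD, DS, RA, NN), and values for 21
socio-ecological covariates (11 environmental proxies, 10 economic ones,
including the five subsistence percentages that sum to 100). The embedded
inventory covers 22 small-scale societies and ships with practice sets only;
coordinates and covariates are joined from a user table or the synthetic
generator. Practice profiles are encoded as binary 14-vectors in fixed
vocabulary order; the order in which practices occur within a society's
sharing sequence is deliberately discarded, so the encoding is injective on
practice *sets*, not sequences.

## Dissimilarity and the pairwise design

Dissimilarity between two practice profiles is the Hamming distance d_H
(count of differing positions, 0–14). Geographic separation is the
great-circle distance by the haversine formula on a sphere of radius
6371.0088 km (the IUGG mean radius; the choice of radius moves distances by
well under 0.5%, far below any effect of interest). Covariate separation is
the absolute pairwise difference |x_i − x_j|: unordered pairs force a
symmetric definition and the analysis asks "how different", not "in which
direction". For n societies the design table has n(n−1)/2 rows — 231 for the
22-society inventory — with columns `hamming`, `geo_km`, and 21 `delta_*`
covariate differences. The shared-practice network weight w_ij = |S_i ∩ S_j|
relates to the Hamming distance exactly via 2 w_ij = |S_i| + |S_j| − d_H(i,j);
the test suite asserts this identity across modules.

## Exploratory two-sample battery

For each (practice, variable) combination the 22 covariate values are split
by practice presence (14 × 21 = 294 combinations). Which test runs is decided
by assumption checks that the battery's sources leave open; we use
Shapiro–Wilk per group and Brown–Forsythe (median-centred Levene), both at
α = 0.05, as standard small-sample choices:

* both normality and homogeneity pass → Student t (pooled variance — the
  route only reaches it when homogeneity passed);
* normality fails, homogeneity passes → Wilcoxon–Mann–Whitney;
* homogeneity fails → Fligner–Policello, Brunner–Munzel and WMW are all
  reported (three p-values for that cell).

All tests are two-sided; no directional hypotheses exist. Groups below 3 are
skipped with an explicit marker (no test in the battery is meaningful there);
Brunner–Munzel additionally requires 4 per group for its variance estimate.
WMW uses exact enumeration when n1+n2 ≤ 12 without ties, otherwise the normal
approximation with mid-ranks, tie-corrected variance and continuity
correction. Fligner–Policello is placement-based (P_i = #{y < x_i}, ties
counting ½) with the standardized statistic
(ΣP − ΣQ) / (2·sqrt(V_P + V_Q + P̄·Q̄)) referred to N(0,1). Seven corrections
(Bonferroni, Šidák, Holm, Hochberg, Hommel, Benjamini–Hochberg,
Benjamini–Yekutieli) are applied across all reported p-values of the sweep;
since heterogeneous-variance cells contribute three p-values, the family is
the full set of reported values rather than the 294 cells — a conservative
reading of an underdetermined convention.

## Dependence screen (MIC, dCor, HHG)

The screen tests the Hamming vector against geographic distance, each of the
21 covariate-difference columns, and itself (a positive-control row that is
kept in the correction families), 23 comparisons in total.

**MIC** is implemented from first principles: for every grid shape (k
columns × l rows) with k·l < n^α, the y-axis is equipartitioned into l rows
(tie groups atomic, greedy target-size rule), the x-axis partition into ≤ k
bins is optimized exactly by dynamic programming over clumps (maximal
x-ordered runs sharing a row, equal-x points atomic), clump count capped at
c·k by mass equipartition; both orientations are scanned and the normalized
maximum I/log2 min(k,l) is reported. Defaults α = 0.6, c = 15. Entropy terms
use log base 2 throughout; the base cancels in the normalization. On the
231-pair Hamming self-comparison this implementation yields 0.9924: the tie
structure of the integer-valued vector prevents a perfectly balanced split,
capping the normalized value just below 1 (the maximizing grid is 5×5). The
acceptance script recomputes this value as the screen's fixed reference
point.

**Distance correlation** uses the V-statistic form: double-centred
absolute-difference matrices, dCor = dCov/sqrt(dVar_x dVar_y), clipped to
[0,1]; constant input is degenerate (dVar = 0) and returns 0. A literal
double-centring oracle checks it to 1e-12.

**HHG** builds, for every ordered pair (i, j), the 2×2 table classifying the
remaining n−2 points by d(i,k) ≤ d(i,j) in each space, and aggregates Pearson
χ² and likelihood-ratio G over tables (sum statistics) while tracking maxima
(max statistics); zero-margin tables contribute 0. Scalar inputs use
|x_i − x_j| distances. Inference permutes y with B = 999 permutations and the
add-one estimator p = (1 + #{S_perm ≥ S_obs})/(1 + B), giving the attainable
floor 1/1000 = 0.0010. The permutation kernel recomputes only the joint cell
(margins are permutation-invariant up to relabeling) and is JIT-compiled;
a quadruple-loop oracle verifies all four statistics exactly for n ≤ 12.
Bonferroni, Holm and Hochberg are applied across the 23 rows separately per
p-value family (four corrected tables).

## Predictive-null comparison

Four learners — random forest, gradient boosting, rotation forest, RBF-SVR —
and a mean-prediction baseline are compared by ten-fold nested
cross-validation on the pairwise design (response `hamming`, 22 regressors).
Inner 5-fold grid search (3-fold in the scaled-down test configuration)
minimizes MSE on each outer-train split; all methods share identical outer
folds. Default grids: RF 500 trees, max_features ∈ {p/3, √p, p}; gradient
boosting (the "boosting" variant chosen here; the ensemble family is
pluggable) 500 stages, depth {1,2,3}, learning rate {0.05, 0.1}; rotation
forest 10 trees, feature subsets {2,3}, 75% instance subsample per
principal-axis rotation; SVR C ∈ {0.1,1,10,100}, γ ∈ {0.1/p, 1/p, 10/p},
ε = 0.1, with z-scoring (fit on outer-train) for the SVR only — tree
ensembles see raw features. Rotation forest is implemented in-package
(per-tree random feature partition, PCA rotation per subset fitted on an
instance subsample, full tree on rotated features, ensemble mean) since no
established Python implementation exists.

The fold × method MSE table feeds a one-way fixed-effects ANOVA with method
as the factor: df = (4, 45) for 5 methods × 10 folds. Fold MSEs are treated
as independent observations even though folds are paired across methods;
this matches the conventional layout of such comparisons and is reproduced
deliberately — the pairing makes the test conservative in the direction that
matters (it ignores positive correlation between methods within a fold).
The verdict is "no detectable pattern" when the ANOVA p ≥ 0.05, i.e. no
learner distinguishes itself from predicting the mean.

The headline F and p of a given real-data run are not bit-reproducible (they
depend on covariate values, grid contents and CV randomness); what is
reproducible, and what the suite checks, is the df structure and the
operating characteristics: on null-regime synthetic problems the ANOVA
rejects rarely, on strong-signal problems (population R² = 0.8) it rejects
nearly always.

## Synthetic data: what it emulates and what it does not

The generator draws coordinates uniformly in a lat/lon box, Gaussian
covariates with field-realistic locations and scales, log-normal population
size, Dirichlet subsistence shares renormalized to 100, and Bernoulli
practices with base frequencies equal to the inventory's empirical marginals.
Three regimes realize the competing hypotheses: `null` (no structure),
`covariate_effect` (logistic bump β per SD of one driving covariate,
local-adaptation analogue), `diffusion` (logistic bump driven by a Gaussian
spatial field with exponential covariance and a correlation length in km,
cultural-diffusion analogue; default 2000 km, of the order of the
inter-neighbour distances in the study region). A society drawn with an
empty practice set is redrawn from the practice stream only, preserving
covariate independence under the null. The generator does not emulate
phylogenetic relatedness (common descent), coding error in ethnographic
sources, or spatial covariate autocorrelation; passing tests therefore show
correctness and calibration of the machinery, not that real cross-cultural
data satisfy the tests' independence assumptions (the classic
non-independence problem of cultural units remains the user's burden).

Simulation problem sizes used by the test suite — 140-row regression
problems, 10 CV folds with light grids, 5 replicates for the
calibration/power checks, 60-sample HHG null replicates with 99
permutations — were chosen as the smallest designs for which the quantities
under test are stable; the full-scale defaults (999 permutations, full
grids) remain the package defaults.

## Numerical choices and degenerate inputs

* Permutation p-values use the add-one estimator and can never be 0.
* Zero variance in both groups with equal values → p = 1 with a degenerate
  flag; a zero Fligner–Policello denominator is flagged likewise.
* MIC rejects constant input ("zero-variation"); dCor returns 0 for it.
* All seeds derive from a single master seed via named `SeedSequence`
  spawns; every simulation, permutation test and CV run is reproducible.
* Ties: WMW uses mid-ranks with tie-corrected variance; Fligner–Policello
  counts ties as ½ placements; MIC keeps tie groups atomic in both axes;
  HHG uses ≤ comparisons, so ties enlarge ball counts symmetrically.

## Known limitations

* The exploratory router reconstructs, not replicates, any particular
  historical routing: with 22 observations the assumption checks have
  limited power and route choices near α = 0.05 are unstable by nature.
* Permuting rows of a pairwise-difference table treats pairs as exchangeable
  although pairs sharing a society are dependent; the screen inherits this
  from its design. The self-comparison row and the null-regime calibration
  use i.i.d. structures where the permutation null is exact.
* Rotation forest follows the published algorithm but regression variants
  differ across implementations (class-subset sampling has no regression
  analogue); ours uses a plain instance subsample per rotation.
* The HHG max-χ² family is conservative on continuous data: its permutation
  distribution has a large atom at the attainable cap χ² = n−2, reached
  whenever any perfectly concordant 2×2 table exists — which happens with
  high probability in observed and permuted samples alike. Null rejection at
  α = 0.05 sits near 0.02 rather than 0.05 (the max-G family is less
  affected, ≈ 0.04). The sum families are the calibrated workhorses; the max
  families remain valid (never anti-conservative) but lose power to the atom.
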