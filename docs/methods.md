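# Methods

## Model and assumptions

`mutprop` treats a mutant series as N observations (wild residue, position,
mutant residue, response Y) sharing one receptor context. The working model
is linear: Y is assumed to respond additively to a small number of
amino-acid property changes, with any deviation absorbed as homoscedastic
noise. Nothing in the pipeline models dose–response curves, ligand
chemistry, or receptor structure prediction; EC50-type values enter as given
scalars, and "increase" always means the signed response change is positive
(users must supply a consistent sign convention — the package never infers
direction from a response label's text, since EC50 and potency run in
opposite directions).

## Property scales and normalization

A property table is any set of scales over the 20 standard residues. Each
scale is min–max normalized to [0, 1] before analysis; normalization is the
default everywhere because it puts scales with wildly different units on a
common footing before they are summed (windows, neighbourhoods) or combined
(regression). A `scale="raw"` switch exists for diagnostics. Constant
scales are rejected outright (their normalization is undefined), as are
non-standard residue codes ('B', 'Z', 'X'): the min/max are defined over the
20-letter alphabet only.

The packaged table is **synthetic**: 49 deterministic pseudo-scales (seeded
uniform draws per residue over random intervals) whose ids name the property
family they emulate. It makes the package runnable and testable without any
download; it carries no chemical meaning, and real analyses should supply a
real table (the TSV layout is one header line, then one row per property).

## Feature encodings

Per property, three per-mutant features:

* **ΔP = P(mut) − P(wild)** — antisymmetric, zero for identity substitutions.
* **Sequence window** — the sum of wild-type property values over the
  (2k+1)-residue window centred on the site, minus P(mut). The window is the
  *wild-type* segment (the mutated position contributes its wild value
  inside the sum; the mutant value is subtracted once). Windows truncate at
  the termini rather than dropping terminal mutants, so every mutant is
  usable at every k; with k = 0 the feature reduces exactly to −ΔP.
  "Window length 3/5/7" corresponds to k = 1/2/3.
* **Structural neighbourhood** — the property sum over all residues whose
  representative point lies within a cutoff of the site's, minus P(mut).
  The representative point is the Cα atom and the default cutoff 8.0 Å, the
  convention of the surrounding-hydrophobicity literature; the residue
  itself is excluded, sequence-adjacent residues are included, and radius /
  self-inclusion are configurable. Heavy-atom contact definitions are out
  of scope. PDB numbering maps to sequence positions via an explicit offset
  (default 0); insertion codes and multi-chain reads are unsupported by
  design (mutant series are per-receptor).

A mutant lacking the context an encoding needs is an error, never a NaN:
silent row dropping would change N mid-analysis.

## Regression and the exhaustive search

R is defined as corr(observed, fitted) of the OLS fit with intercept,
reported in [0, 1]; for a single column it equals |r|, and single-property
screening additionally reports signed r (direction matters there). The
subset search enumerates every combination of the requested sizes — no
stepwise heuristics, no pruning that can affect the winner — by solving the
normal equations of each subset from one precomputed (p+1)×(p+1) Gram
matrix in vectorized chunks (default 100 000 subsets per batch; a singular
batch falls back to per-subset solves and ranks singular subsets last).
Ties in R break toward the smaller subset, then lexicographic column order;
the top-m list is assembled from a per-chunk candidate pool of
max(top_m, 64) entries, which always contains the exact global best
(ranks far down the list could in principle lose an exact tie beyond that
pool depth). A configurable ceiling (default 5×10⁶ models) refuses
runaway searches with the computed size.

Two honesty guards are defaults, not afterthoughts: fits with N < p + 2 are
refused unless `allow_saturated=True` (the small-sample regime of real
mutant series — N as low as 6 with up to 5 properties — is reproducible,
but only deliberately), and every report records N, p and the enumerated
model count. No multiple-testing correction is applied across the enumerated
models, matching the original protocol; the recorded search-space size is
the user's instrument for judging selection effects.

## Classification

Feature vector per mutant and property: [P(wild), P(mut), ΔP, window sum].
The bundled classifier set is fixed and small — logistic discriminant,
Gaussian naive Bayes, 1-NN, 3-NN, decision tree (scikit-learn
implementations; scaling-sensitive methods get a standardizer fitted inside
the training fold) — and *all* are evaluated and reported, with the maximum
available but never silently substituted: the original protocol reports a
single best method without naming it, and reporting everything is the
reproducible counterpart. The jack-knife runs N folds of sizes (N−1, 1);
each mutant is predicted exactly once by a model that never saw it. A fold
whose training set collapses to one class predicts the training majority
(with a warning). By default the property/encoding choice is fixed once on
the full data (matching the apparent original protocol); a strict mode
(`jackknife_strict`) re-selects the top properties by training-fold |r|
inside every fold, and reports label which mode produced them.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, at
the sample sizes real series have (defaults: N = 28; strata of 6–28 are the
realistic range): responses linear in a planted property subset's features,
plus Gaussian noise whose SD is a stated fraction of the noiseless response
SD (scale-free difficulty; additive Gaussian is the minimal noise model for
a correlation analysis). Sequences are uniform random over the 20 residues
(length 60), positions uniform, mutant residues uniform over the 19
alternatives; structures are ideal α-helix Cα traces (rise 1.5 Å, 100°
twist, radius 2.3 Å — 8 Å neighbourhoods then hold ~4–6 residues) or
random packings with 3.8 Å minimum separation. Classification sets keep the
top-15/bottom-13 scorers of a candidate pool, doubling the pool until the
two classes are `class_margin` score-SDs apart (7 doublings maximum, then a
warning); responses are centred on the class boundary and pushed apart by
the margin, so margins control separability in feature space and all
magnitudes exceed the margin. All-zero coefficients produce a null dataset
whose labels are independent of the features. Ground truth (subset,
coefficients, noise draws) is always returned beside the data.

What passing on such data does **not** show: robustness to the features of
real mutant series the generator omits — correlated real property scales
(scales within a family are strongly correlated, synthetic ones are nearly
orthogonal, so subset recovery is easier here than on AAindex-like tables),
non-uniform mutation spectra, heteroscedastic measurement error, and any
nonlinearity in the property–response relation.

## Numerical choices and degenerate inputs

Normalization endpoints are exact (min → 0, max → 1); round-trips hold to
1e-10. Constant feature columns are excluded from correlation and search
and *reported* as skipped. A constant response is an error (R undefined).
Batched subset R is computed as √(1 − SSE/SST) clipped to [0, 1]; the
reported winners are refit by least squares, and agreement with an
independent brute-force enumerator is held to 1e-10. Zero responses cannot
be labelled increase/decrease and raise rather than defaulting. All
randomness flows through explicit integer seeds; feature matrices and
reports are bit-for-bit reproducible on identical inputs.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` use: 5 datasets (N = 20, 10
columns, sizes 1–3) for oracle agreement; 100 replicates (N = 30, 49
properties, |subset| = 3, noise 5 %) for recovery, plus 10 noiseless
replicates for exactness; 10 seeds for monotonicity over sizes 1–4; one
separable 15/13 set (margin 5 score-SDs) and 50 null seeds for the
classification loop; and one full sizes-3–5 search (≈ 2.1 M models) for
scale. These sizes mirror the strata of real series while keeping the whole
acceptance run under a minute of CPU.

## Known limitations

* The exhaustive search's tie handling below the per-chunk pool depth is
  approximate (the best model is always exact).
* Near-singular (but not exactly singular) subsets are solved as-is; their
  clipped R can be optimistic in pathological collinear designs.
* No ROC analysis or probability calibration; no regularized or
  cross-validated model selection for the regression stage — out of scope
  by design.
* The strict jack-knife nests property selection but not the choice of k or
  encoding.
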