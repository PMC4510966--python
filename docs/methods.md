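# Methods

## The analysis in brief

`handevol` reconstructs how hand proportions evolved across anthropoid
primates.  The pipeline turns specimen-level bone measurements into
size-free shape ratios, summarizes them in a covariance-PCA
morphospace, asks which adaptive-regime structure best explains the
species means on a time-calibrated phylogeny (multi-regime
Ornstein–Uhlenbeck models compared by AICc), reconstructs ancestral
positions in that morphospace with confidence intervals, and measures
phylogenetic signal with Blomberg's K.

## Shape ratios

Two ratio families are used, both computed per specimen and then
averaged per taxon (mean of ratios — the order matters and is asserted
by a test):

* **Intrinsic hand proportions (IHP)** — thumb length over fourth-ray
  length, `(MC1+PP1+DP1)/(MC4+PP4+IP4)`, the fourth-ray distal phalanx
  excluded because it is rarely preserved.  Dimensionless; a proxy for
  thumb opposability.
* **Extrinsic hand proportions (EHP)** — each of the six element
  lengths divided by the cube root of body mass (mm · kg^-1/3).  Mass
  is approximately volume, so its cube root is the nominal linear body
  size; the ratios are therefore size-standardized shape variables.

Body mass, when not recorded, is predicted from femoral head diameter
by group-specific least-squares regressions fitted in log10–log10
space.  The log–log form is the allometric convention and guarantees
positive predictions; when two reference samples are defensible (e.g.
a quadrupedal and a bipedal training set for an early hominin) the two
predictions are averaged, and both values can be carried through the
pipeline as a sensitivity pair.

## Trees

Trees are rooted, time-calibrated (branch lengths in Myr), and may be
non-ultrametric: fossil tips sit at their published ages.  Ages run
backward from the present.  Fossils are grafted onto a stem lineage
through a ghost lineage of 1 Myr — the fossil at age `a` hangs from a
new node at age `a + 1` on the host branch.  When a placement
hypothesis puts a fossil on a stem that is much older than the fossil
(the stem-great-ape placement of the 9.6-Myr late Miocene ape), a
1-Myr ghost cannot reach the host branch; that variant attaches at the
midpoint of the host branch instead, with a correspondingly longer
ghost lineage.  Polytomies (e.g. star trees) are supported exactly by
all covariance machinery; unifurcations are rejected.

The packaged anthropoid tree has 15 extant terminals (hominoids to
species, monkeys to genus, hylobatids pooled) plus graft points for
four fossils (4.4, ~2, 18 and 9.6 Myr).  Extant node ages are rounded
literature-standard dates; they are fixture constants, not scientific
claims, and are documented in `synthetic.py`.

## Evolutionary models

Brownian motion: dX = σ dB(t); tip covariance σ²·C with C the shared
path-length matrix.  The BM fit uses the GLS phylogenetic mean and the
ML rate (residual quadratic form / n), p = 2.

Multi-regime OU (Hansen): dX = α(θ − X)dt + σ dB(t), with the optimum
θ set per branch by a regime painting.  Conventions:

* the root state is fixed at the root regime's optimum (ouch-style;
  removes the unidentifiable extra parameter on ultrametric trees);
* tip means are W·θ, where W sums exponentially discounted exposure
  per regime along each root-to-tip path; rows of W sum to 1;
* tip covariance is the fixed-root OU form
  V_ij = σ²/(2α)·e^(−α(T_i+T_j−2s_ij))·(1−e^(−2αs_ij)), valid on
  non-ultrametric trees;
* σ² is profiled analytically and θ by GLS at each α (whitened
  least squares, so the profile stays finite when weight columns go
  collinear in the BM limit), reducing the fit to a bounded 1-D search
  on log α over [1e-8/h, 1e3/h] for tree height h, relative tolerance
  1e-8 (ties resolve toward smaller α, which is flagged as BM-like);
* the covariance is evaluated through `expm1`, so α → 0 degrades
  continuously to σ²·C with no separate series branch;
* p = 2 + (number of regimes) per trait.

Multivariate data are handled as traits independent given a shared
painting: per-trait fits are summed (log-likelihood and parameter
count), and the joint AICc uses n = tips × traits.  Absolute AICc
values are convention-dependent; all comparisons are within one
convention, which is all AICc differences require.  Model sets are
compared by ΔAICc and Akaike weights exp(−Δ/2), normalized.

## Regime search (forward/backward stepwise)

The forward phase starts from a single-regime OU model and repeatedly
evaluates placing a new shift on every branch (a shift paints its
branch and all descendants not claimed by a downstream shift),
re-optimizing every candidate's α and σ² in full, and accepts the best
placement if the joint AICc improves by more than `min_improvement`.
The backward phase then tries merging every pair of non-root regimes
and accepts any AICc-improving merge; accepted merges are the
signature of convergence, and merged labels keep their member names
(`s1+s2`).

The default forward threshold is 2·ln(m) AICc units, m being the
number of candidate branches.  Stepwise selection over every branch is
a large multiple comparison: simulation under a single-regime null on
a 64-tip tree shows the best spurious one-shift AICc gain has an 80th
percentile near 8, so accepting any improvement (threshold 0) plants a
spurious shift in essentially every null dataset.  The 2·ln(m) penalty
calibrates the null acceptance rate to roughly the 80–90% no-shift
range while leaving strong planted shifts (gains an order of magnitude
larger) untouched.  Backward merges face no such selection problem
(they remove parameters) and accept any improvement.  The search is
fully deterministic; ties between equal-AICc candidates go to the
branch with the older parent node, then to the lexicographically
smallest subtended tip set.

## Ancestral states and phylomorphospace

Ancestral states are ML estimates under BM, computed by GLS; for BM
these coincide with branch-length-weighted squared-change parsimony
(each internal node is the 1/branch-length weighted average of its
neighbours), and a test asserts the equivalence against an independent
sparse-system solver.  The variance of the estimate at node a is

    var_a = σ̂²·[C_aa − c_a'C⁻¹c_a + (1 − 1'C⁻¹c_a)²/(1'C⁻¹1)]

with c_a the node-to-tip shared path lengths; the last term propagates
the uncertainty of the estimated phylogenetic mean.  The ML rate σ̂² is
plugged in, which makes the intervals self-contained but slightly
anti-conservative: measured coverage of the 95% root CI over 1000 BM
simulations on a 64-tip tree is ~94%, inside the expected 93–97%
band.  CIs are estimate ± 1.96·√variance.

Ancestral states are computed directly on PC scores (linear maps
commute with linear reconstruction), giving internal-node coordinates
for the phylomorphospace; the last common ancestor of any tip pair —
notably chimpanzee–human — is queryable with its CIs.  Fossil tips
enter as ordinary non-contemporaneous tips and genuinely constrain the
reconstruction: in the strong-regime synthetic scenario, dropping the
hominin fossils moves the chimp–human LCA by less than its CI
half-width on the dominant PC axis and by about the half-width on the
secondary axis.

## Blomberg's K

K = (MSE0/MSE) / E[MSE0/MSE | BM], where MSE0 is the mean squared tip
deviation from the GLS mean, MSE the same through C⁻¹, and the
expectation [tr(C) − n/(1'C⁻¹1)]/(n−1) depends only on tree size and
shape.  K is affine- and branch-scale-invariant; on an equal-branch
star tree K ≡ 1.  Significance uses 1,000 tip permutations by default
with the add-one estimator p = (1 + #{K_perm ≥ K_obs})/(1 + n_perm)
(never returns 0; the smallest attainable p is 1/1001).  The
permutation null is exchangeability, against which any phylogenetic
signal raises K — so the test is always against the upper tail of the
permutation distribution, and significance can coexist with K < 1:
K locates the variance partitioning relative to Brownian motion, the
p-value asks whether there is signal at all.  A direction-adaptive
tail (testing K < 1 against the lower tail) would return p ≈ 1 on
strongly convergent data and was rejected for that reason.  Under
exchangeable data on a structured 64-tip tree the measured type-I
error at nominal 0.05 is ~0.05.

## Synthetic data

The generator replaces museum measurements that are not distributable.
It emulates: (1) the study's taxon panel and per-taxon sample sizes
(e.g. humans n=40, common chimpanzees n=34, baboons n=50; fossils 1–3
associated specimens); (2) taxon-mean log shape ratios evolving under
a painted OU process with exact per-branch transition sampling;
(3) specimen-level multiplicative noise — lognormal body mass
(CV 0.15) and lognormal element scatter (CV 0.05) — with lengths
rebuilt as exp(log-ratio)·BM^(1/3), so recomputing EHP from the table
recovers the simulated means; femoral head diameters consistent with a
known allometric law are emitted so the mass-regression workflow can
be exercised.

Default regime structure plants the convergent suspensory regime
(chimpanzee + orangutan clades sharing one optimum, digits elongated,
thumb shortened) and a distinct human/hominin regime.  Defaults are
α = 0.5/Myr (phenotypic half-life 1.4 Myr — strong stabilizing
selection, so tips essentially reach their optima), σ² = 4×10⁻⁴
log²/Myr (stationary SD 0.02, i.e. ±2% between-species scatter within
a regime), and optimum shifts of 0.35–0.65 log units (40–90% length
changes).  These represent a decisively supported adaptive signal —
the regime structure is many stationary SDs wide — which is the
scenario the method is designed to detect; weaker pulls leave clades
partway to their optima, a regime structure that Brownian drift can
mimic and that no AICc-based search can reliably distinguish at ~19
taxa.  What passing tests show, therefore, is that the pipeline
recovers strong, clade-structured convergence from specimen-level
data; they do not show that weak or incompletely realized regimes are
detectable at this tree size.  Real data additionally contain
measurement covariance between elements, sexual dimorphism and
structured missingness that the generator does not emulate (a uniform
missing-at-random mask is available).

## Problem sizes and numerical choices

Simulation-based validations use 64-tip trees (recovery, calibration)
and a 128-tip tree (OU parameter recovery, 200 replicates); the
stepwise-search recovery runs 50–100 replicates per scenario.  The
packaged anthropoid analyses use the full 18/19-tip study tree.  These
sizes keep every experiment comfortably reproducible on a single CPU.
Other choices: covariance solves go through Cholesky factorizations
with `expm1` for small-α stability; PCA eigenvectors are
sign-normalized (largest-magnitude loading positive) for backend
determinism; all generators take explicit seeds and are
bit-reproducible.

## Known limitations

* Traits are independent given the painting (diagonal trait
  covariance); full multivariate OU with trait correlations is out of
  scope.
* No measurement-error variance at the tips; species means are treated
  as exact.
* OU-based ancestral reconstruction is not offered (BM only), matching
  the standard phylomorphospace workflow.
* AICc parameter-count conventions differ between implementations;
  only differences within this package's convention are meaningful.
* The forward threshold 2·ln(m) is calibrated for moderate tree sizes
  (tens of branches); extremely large trees may warrant the explicit
  `min_improvement` override.
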