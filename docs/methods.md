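# Methods

`stripevol` implements the comparative-phylogenetics toolkit behind an
analysis of white-stripe evolution in clownfishes (*Amphiprion*): how adult
stripe number (0–3 vertical white bars) evolved on a time-calibrated
phylogeny, whether transitions follow a stepwise caudo-rostral sequence,
whether stripe patterns covary with morphology, and whether sympatric
species avoid sharing stripe morphs.  This note records the models, the
defaults, and the design decisions, in the package's own terms.

## Trees

Trees are rooted, binary after load, with branch lengths in Myr.  A missing
branch length is an error rather than a silent default of 1: every
downstream likelihood is time-calibrated and would be corrupted.  Polytomies
are resolved to zero-length branches at load, with a warning; all
likelihoods in the package are invariant to the resolution order because a
zero-length branch contributes an identity transition matrix.  Ultrametricity
is checked as agreement of all root-to-tip distances within a relative
tolerance of their mean (default 1e-6; the diversification likelihood uses
1e-4 to tolerate accumulated I/O rounding).

## Mk models of the stripe character

The stripe character has four states A–D (0–3 stripes); the ontogenetic
character (whether juveniles lose extra stripes before adulthood) uses the
same machinery with two states.  The likelihood is computed by Felsenstein
pruning with per-branch transition matrices `exp(Q t)`; the matrix
exponential uses a single eigendecomposition with batched reconstruction,
validated per call against SciPy's Padé scaling-and-squaring `expm` (and
falling back to it when the decomposition is inaccurate).

Four constraint structures parameterize Q:

* **i** — all k(k−1) rates free;
* **ii** — symmetric, q_ij = q_ji;
* **iii** — jumps of two or more stripes forbidden (only adjacent
  transitions allowed among the ordered states);
* **iv** — ii and iii combined: three free rates, one per adjacent pair.

Defaults and numerical choices:

* Root prior: uniform over states.  A stationary-distribution prior and
  custom vectors are available; the choice is logged because ancestral
  posteriors depend on it.
* ML fitting is multi-start (default 10 seeded starts) box-constrained
  quasi-Newton on the log-rate scale, rates bounded in [1e-9, 1e3] /Myr.
  Each start is preceded by a one-dimensional search over a common rate
  scale; without it, the first quasi-Newton step can jump onto the flat
  likelihood plateau at saturating rates (where the process mixes to
  stationarity on every branch and the gradient vanishes) and stall at the
  upper bound.
* AICc uses n = number of tips.  Model tables report both AIC and AICc.
* Polymorphic species (two observed morphs) are handled by enumerating all
  fully-resolved coding combinations (2^3 = 8 at the study's scale) and
  repeating every analysis per combination; an ambiguity mode (partial
  likelihood 1 on each member state) exists but is not the default.

Marginal ancestral states use the standard two-pass algorithm (post-order
partials, pre-order outside vectors); the tests pin it to exhaustive joint
enumeration on small trees at 1e-10.

## Stochastic character mapping

Complete character histories conditional on tip data and the MLE Q are
drawn in two steps: node states jointly (root from its posterior, each
child conditional on its parent and the subtree partials), then each branch
interior from the endpoint-conditioned CTMC bridge by uniformization — the
number of candidate jumps from its exact conditional distribution given the
endpoints, jump times as uniform order statistics, the jump chain by a
backward pass through powers of R = I + Q/Ω, and self-jumps collapsed.  A
naive forward rejection sampler serves as the cross-validation oracle in
tests.  Q is fixed at its MLE (empirical approach); joint sampling of Q and
histories is out of scope.  The ensemble default is 10,000 maps.

The "number of major transitions" of a binary character is made explicit:
a branch counts when parent and child both have a majority state (ensemble
frequency ≥ threshold, default 0.5) and they differ.  The count is
monotone: raising the threshold can only shrink the set.

## MuSSE diversification likelihood

The state-dependent speciation–extinction likelihood integrates extinction
(E) and data (D) ODEs tipward-to-rootward with tip conditions D_i(0) = f·1[i
= observed], E_i(0) = 1 − f, node operation D ← D_left·D_right·λ, and a
weighted root combination.  Throughout this package λ and μ are shared
across character states — the four stripe models differ only in the
constraint structure of Q — so the parameter counts are 14, 8, 8, 5 for
models i–iv.

Two evaluation paths coexist.  The reference path integrates the general
coupled ODEs per branch (adaptive RK45, rtol = atol = 1e-8).  Under shared
λ/μ the extinction system collapses to one scalar Riccati equation with a
closed form, and D factorizes into `exp(Q t)` times a scalar growth factor;
the closed-form path evaluates this exact solution and is what `fit` uses
(it is two orders of magnitude faster and agrees with the ODE path to
better than 1e-6 in the tests).  Two limits pin the implementation: the
single-state pure-birth (Yule) likelihood (n−1)·ln λ − λ·(total length),
and the factorization identity that ΔlnL between two Q matrices equals the
Mk ΔlnL when the root prior is fixed, because the tree term cancels.

Defaults, all logged because absolute likelihoods depend on them:
likelihood-weighted ("obs") root combination; survival conditioning on;
sampling fraction f = n_tips/30 (30 described clownfish species, missing
species assumed randomly placed).

## PGLS

Phylogenetic regressions use the Brownian-motion variance–covariance matrix
C (shared root-path lengths).  The fit whitens by the Cholesky factor of C
and solves ordinary least squares in the whitened space; the slope test is
F = (RSS₀ − RSS₁)/(RSS₁/(n−2)) in the C⁻¹ metric against F(1, n−2), with
RSS₀ from the intercept-only GLS fit.  With C = I this is exactly OLS, and
estimates are invariant to scaling C.  Stripe number is treated as a
numeric 0–3 response; regressions are simple (one predictor at a time:
host count, maximum size, elongation, anterior and posterior lobe index),
species missing a measurement are dropped per-regression with the count
recorded, and no multiple-testing correction is applied — p-values should
be read accordingly.  Morphometric indexes: anterior lobe (l1−l2)/L,
posterior lobe (lr−l2)/L, elongation = body height / standard length; all
dimensionless and scale-invariant.

## Community species-recognition test

The statistic is the identical-pairs count Σ_s n_s(n_s−1)/2 over stripe
morphs, maximized over all assignments of polymorphic members to their
possible morphs — the same rule for natural and randomized communities, so
the statistic is exchangeable under the null.  The null model draws
richness-preserving communities uniformly without replacement from the
regional pool (9999 draws by default), and the result reports the
proportions of random communities with fewer / equally many / more
identical pairs than observed.

Two significance measures are attached, because they answer different
questions.  The sign (binomial) test — successes = #greater, trials =
#greater + #less, ties dropped, one-sided — asks whether random communities
exceed the observed value more often than they fall below it.  It is a
direction indicator, not a calibrated test: whenever the observed value
sits off the null median the trials are far from fair-coin flips, so under
a true null its p-values pile up near 0 and 1 (a calibration run in the
test suite measures ~40% rejection at the 5% level).  The calibrated
quantity is the ordinary Monte-Carlo tail probability
P(random ≤ observed) = (#less + #equal + 1)/(n_random + 1), which is
(super-)uniform under the null; uniformity checks apply to it.  For small
pools an exact-enumeration mode computes the proportions over all
C(pool, richness) communities and anchors the Monte-Carlo mode in tests.

## Synthetic data

Every analysis stage is exercised without external data.  Trees come from
a forward birth–death simulation started at a crown split and stopped the
first time the extant count reaches the target (the present is placed a
uniform fraction of the next inter-event wait later so terminal branches
are positive); replicates whose crown dies are rejected and redrawn.
Characters evolve forward along every branch with the full latent history
retained.  Brownian traits are drawn from the Cholesky factor of σ²C, with
a response built as intercept + slope·x + BM noise.  Pools and communities
are drawn with configurable morph frequencies, polymorphic fraction, and an
optional dissimilarity bias (selection strength in an exponential weight on
added identical pairs) for power studies.

The packaged default fixture mirrors the study's scale: a 27-tip tree
(birth 0.25, death 0.05 /Myr, depth ≈ 15 Myr), a 4-state stripe character
generated under model iv with rates (0.123, 0.103, 0.052) /Myr from a
three-striped root (the stepwise caudo-rostral regime, slowest at the
peduncle), three polymorphic species (adjacent second morph, giving 8
coding combinations), a binary ontogeny character at rate 0.04, traits in
which only the anterior lobe index truly tracks stripe number, a 10-species
pool and eight communities of richness 3–6 assembled with a dissimilarity
bias.  What the generators do **not** emulate: state-dependent
diversification (λ, μ are state-independent, matching the models in scope),
measurement error in morphometrics, spatial structure or abundance in
communities, and phylogenetic uncertainty (a single fixed tree).  Passing
tests therefore validate the estimators under their own assumptions, not
the biological conclusions on real data.

## Problem sizes in the shipped tests

The test suite and the acceptance script regenerate everything they
measure: exact-likelihood checks on ≤5-tip trees (50 replicates),
stochastic-mapping consistency at 10,000 maps on the 27-tip fixture,
model-selection recovery on 200-tip trees (10 replicates, 2 optimizer
starts), PGLS calibration on a 100-tip tree (100 coverage + 1000 type-I
replicates), and community calibration against exact enumeration on an
8-species pool.  These sizes were chosen so a full desk run finishes in
minutes while keeping every Monte-Carlo bound meaningful.

## Known limitations

* Hidden-state, covarion and rate-heterogeneity models are out of scope, as
  are state-specific λ/μ (GeoSSE/HiSSE-style variants) and MCMC over Q.
* The reported stochastic-mapping summaries condition on the MLE Q;
  uncertainty in Q itself is not propagated.
* PGLS assumes pure Brownian residuals (no Pagel's λ or OU transform).
* The sign-test p-value reproduces the directional construction of the
  original community analysis but must not be read as a calibrated tail
  probability; use the Monte-Carlo p for that.
* Reproducing the original study's published tables requires its inputs —
  the time-calibrated clownfish phylogeny, the species coding supplement,
  and the community composition data — which are not redistributable here;
  the pipeline accepts them as files when available.
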