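# Methods

## Scope and model

`lindiv` quantifies where on a time-calibrated phylogeny lineage
diversity accumulated, per discrete biogeographic region.  It consists of
(i) an optional discrete-state ancestral reconstruction stage, (ii) a
deterministic richness/diversity computation, and (iii) a generative
simulator used for validation.  All ages are in My measured backward from
the tips (tips at age 0); trees must be rooted and ultrametric within a
tolerance (default `1e-4 ×` root age) — beyond it the package refuses
rather than repairs, because silently stretching tips would shift every
richness breakpoint.

### Dispersal model (stage i)

Lineage movement among K regions is a homogeneous continuous-time Markov
chain with rate matrix Q.  Three parameterizations are exposed:

* `equal_rates` (default): one symmetric rate q for every ordered pair —
  the K-state Mk model.  Transition probabilities use the closed form
  `P_ij(t) = 1/K + (δ_ij − 1/K) e^{−Kqt}`.
* `sym`: free symmetric rates (K(K−1)/2 parameters).
* `ard`: all rates differ (K(K−1) parameters).

Symmetric Q uses a symmetric eigendecomposition for `exp(Qt)`; general Q
uses an eigendecomposition guarded by a condition-number check with
scipy's scaling-and-squaring `expm` as fallback.  Every transition matrix
is required to be row-stochastic to 1e-9 (tiny negatives clipped, rows
renormalized); violations raise instead of propagating.

The tree likelihood is computed by Felsenstein's pruning algorithm with
per-node rescaling (no underflow at hundreds of tips and small rates);
node marginals add a pre-order outside pass and normalize
inside × outside per node.  Ambiguous tips (`?`, `-`, `NA`) carry
all-ones vectors, the standard missing-data treatment; in outputs a tip
returns its own (normalized) observation vector rather than a smoothed
marginal.  An O(K^internal) exhaustive-enumeration implementation
(`enumeration_log_likelihood` / `enumeration_marginals`) is shipped as a
validation reference; it shares only the transition-matrix code, which is
itself checked against the 2-state closed form.

The root prior defaults to the stationary distribution of Q (uniform for
symmetric structures); a fixed user prior is accepted.

Rate estimation (`AncestralStateModel.fit`) maximizes the pruning
likelihood: deterministic bounded 1-D search for `equal_rates`
(tolerance 1e-8 on q, bounds `[1e-8, q_max]` with
`q_max = 100 / (K · mean branch length)` so the likelihood has reached
its ergodic plateau at the boundary; an optimum at the boundary clears
the `converged` flag), and L-BFGS-B on log-rates with five fixed-seed
restarts for the free structures.  Monomorphic tip data leave q
unidentifiable: the fit warns (`RuntimeWarning`), returns the lower
bound, and sets `identifiable=False` — flagged, never silent.

This stage produces empirical-Bayes marginals on a *fixed* tree.  It does
not integrate over topologies or divergence times the way a joint
Bayesian tree-plus-state analysis does, and makes no claim of equivalence
to such machinery; for exact reproduction of an existing analysis, feed
the externally produced node probabilities (annotated tree or sidecar
TSV) directly into stage ii.

### Richness and node diversity (stage ii)

With node ages `t_v`, probability vectors `p_v`, and out-degrees `c_v`:

```
R_r(t) = [include_origin] · p_root,r + Σ_{v internal, t_v ≻ t} (c_v − 1) p_v,r
D_f    = Σ_r p_f,r · R_r(t_f)
```

where `≻` is `>` (strict) or `≥` (inclusive).  Conventions, all recorded
as `# key=value` metadata in every output file:

* **Origin lineage** (`include_origin`, default on): the stem lineage
  above the root counts once, attributed by the root's own vector.  This
  is the unique choice under which `Σ_r R_r(t)` equals the
  branch-counting lineage-through-time value at every age (1 at and
  above the root age, `n_tips` at 0) — the conservation law the tests
  enforce to 1e-9.  The published analyses this method descends from do
  not state the convention; the switch exists because reproducing a
  given table may require the alternative.
* **Strictly older** (`strict_older`, default on): the focal node's own
  divergence is excluded from its richness; the richness step function
  is then right-continuous in age.  Ties in age arise only in contrived
  input and follow the same rule.
* **Processing threshold** (default 0.70, boundary inclusive): a node
  whose *maximum single-region* probability is `< 0.70` is reported
  without a diversity value, but its probabilities still enter every
  richness sum — the estimates exist regardless of whether the node is
  worth reporting, and dropping them would undercount lineages.
* Multifurcations contribute `c_v − 1` simultaneous divergences at one
  age, keeping totals exact.  Tips never contribute to richness — the
  method counts divergence events.
* Ages are the point estimates carried on the input tree (mean or median
  heights, whichever the producer annotated — recorded, not chosen);
  credible-interval columns are passthrough only.

`diversity_from_node_table` runs stage ii directly from a node table
(ages + probabilities, each row one binary divergence, the oldest row
doubling as origin) for the situation where only a published node table
is available, with the caveat that the table must contain *all* internal
nodes — richness sums are over the complete set of older divergences, so
a curated subset of printed rows cannot reproduce the full analysis's
values.

Evaluation is vectorized: nodes are age-sorted once and richness at
arbitrary ages is a suffix cumulative sum plus binary search.

### Simulator (stage iii)

The synthetic generator defines the study conditions used throughout the
tests:

* **Tree**: Yule pure-birth, n = 200 tips by default (the target study
  system sampled ~205 individuals), birth rate λ = 1.0 /My giving root
  ages around 5 My, matching the few-My timescale over which such
  island/continent faunas assemble.  Grown forward with Exponential(kλ)
  waiting times; after the n-th lineage one further Exponential(nλ)
  interval sets the present, so a 2-tip tree's depth is exactly
  Exponential(2λ) (mean 1/(2λ), Monte-Carlo checked).
* **Dispersal**: equal-rates CTMC, default q = 0.1 /My over K = 4
  regions with a region-I (continental) root — a slow process producing
  a handful of region shifts per tree, the regime in which
  ancestral-state methods are typically applied.  Full jump chains are
  recorded, not just node states.
* **Probability noise**: per-node Dirichlet centred on the one-hot truth
  with concentration κ on the true region (mean mass κ/(κ+K−1); default
  κ = 50 ≈ 0.94, posterior-like; κ = ∞ gives exact one-hot).  Tips keep
  exact one-hot vectors — tip regions are observations, not estimates.
* **Streams**: topology, dispersal and noise consume independent
  generators spawned from one master seed, so fixtures are stable if one
  stage's draw count changes.  Identical config ⇒ byte-identical files.

Two oracles accompany the simulator.  `brute_force_region_counts`
attributes each lineage to the region of the divergence that founded it
(origin lineage to the root's region) using plain integer arithmetic and
the *same* `Conventions` object as the estimator — by design it validates
the estimator's arithmetic, not the attribution convention itself.
`occupancy_region_counts` instead reads each crossing branch's simulated
state at the query age from the jump record: the difference between the
two is exactly the dispersal that happened after founding, i.e. the
method's approximation error, available for study but not part of the
identity tests.

What passing these tests shows: the arithmetic of steps 2–3 is exact
(one-hot identity, conservation), the ASR machinery matches enumeration
and closed forms, and the rate is recoverable at realistic sizes.  What
they do not show: robustness to non-ultrametric input, model
misspecification (rate heterogeneity in time or among lineages,
range-inheritance dynamics), or topology/age uncertainty — real
posterior trees vary where the simulator's fixed trees do not.

## Numerical choices

* Probability vectors must sum to 1: construction tolerance 1e-9 for
  internally computed posteriors; externally loaded tables are
  renormalized when off by ≤ 0.05 and rejected beyond that.
* Parent/child age identity holds to machine precision by construction
  (ages derived from one depth pass); ultrametricity tolerance as above.
* Table output renders values at three significant figures (trailing
  zeros kept, e.g. `0.000300`), support values at two decimals.
* Degenerate inputs: single-tip trees parse (age = branch length);
  all-zero branch lengths give age 0 everywhere; zero dispersal rate is
  valid for simulation (everything inherits the root state) but the ML
  fit bounds q away from 0 at 1e-8.

## Validation-band calibration

Under posterior-like noise (κ = 200, 200 tips) the estimated diversity
stays within 5% of the oracle-count diversity computed with the same
focal weights for ≥ 90% of processed nodes (the end-to-end noise test).
Contrasting against the one-hot-truth weighting instead also folds the
focal node's own weight noise into the comparison and fails the 5% band
more often at small counts; that contrast measures the method's
approximation error (see the two oracles above) rather than the
implementation, so the test pins the former definition.

## Known limitations

* Marginals are conditional on one fixed tree; no topology or age
  uncertainty propagates into richness or diversity, and no credible
  intervals on diversity are produced (they would require a posterior
  tree set).
* The CTMC has no explicit geography (no distance- or
  adjacency-informed rates) and no range inheritance at divergences.
* The diversity statistic counts divergences, so a region colonized by a
  single unbranched lineage contributes nothing until that lineage
  divides.
* `sym`/`ard` fits are practical but lightly exercised compared to
  `equal_rates`; with K = 4 and ~200 tips, `ard`'s 12 rates are often
  weakly identified.
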