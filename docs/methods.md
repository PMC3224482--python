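# Methods

## The inference problem

A signed causal network asserts edges `source —(±1)→ target` between
functionalized biological entities.  Restricting to causal edges whose
target is an mRNA (`r(...)` term) gives every node a *downstream
signature*: the set of transcripts it controls, each carrying the sign its
abundance takes when the node's activity increases.  A transcript reached
by edges of both signs is kept with sign 0 (ambiguous — evidence of
connectivity without directional information), and a node's own transcript
is excluded from its signature so a hypothesis cannot count itself as
evidence.

Reverse causal reasoning treats every node with at least
`min_downstream_measured` (default 4) measured signature transcripts as a
candidate explanation for an observed set of State Changes and scores it in
both activity directions.

## Scoring

With N measured genes of which K are State Changes, and a hypothesis with n
measured downstream transcripts of which k overlap the SC set:

* **richness** = P(X ≥ k), X ~ Hypergeometric(N, K, n).  Direction-blind,
  identical for both hypothesis directions; k = 0 returns 1 by convention.
* **concordance** = P(X ≥ c), X ~ Binomial(c + contra, p) with p = 0.5 (a
  direction coin-flip null).  c counts overlaps whose observed direction
  matches the implied one, `contra` those that oppose it; ambiguous
  (sign-0) overlaps count toward k but are excluded from the trials because
  they carry no directional information.  c = 0 returns 1.

Both tails come from `scipy.stats`; the test suite cross-checks them
against exhaustive subset enumeration (all K-subsets of populations up to
N = 12) and exact-fraction binomial tail sums (t ≤ 30), to 1e-12.

A hypothesis is **significant** iff richness < 0.1, concordance < 0.1
(strict inequalities) and c ≥ `min_correct` (default 4).  The two cutoffs
are raw probabilities — no multiple-testing correction is applied across
hypotheses, by design; the consistency minimum c ≥ 4 is a separate
condition from the eligibility minimum n ≥ 4.  Both directions are always
scored; `best_directions` keeps the smaller concordance per term, ties
breaking toward increase.

The hypergeometric population N defaults to all measured genes after probe
mapping (`population_mode="all-measured-genes"`); the alternative
`"all-network-downstream-measured"` restricts the universe to measured
genes downstream of at least one eligible node.  Neither convention is
canonical; the default is the larger, more conservative universe.

## State Changes

The expression pipeline is: quantile normalization (each sample is mapped
rank-wise onto the mean of the column-sorted data, ties sharing the average
reference value) → per-probe pooled-variance two-group t-test on log2
intensities → Benjamini–Hochberg step-up adjustment → filter chain.  A
probe passes iff adjusted p < 0.05 AND linear |FC| > 1.3 AND (when the
intensity floor is enabled; it is off by default, documented value 250)
mean linear intensity above the floor — all strict inequalities.  A gene
changes if at least one of its probes passes; a gene whose passing probes
disagree in direction is dropped from the change list but retained in the
measured population, which is threshold-independent by construction.

The variance model is a plain pooled two-sample t, not a moderated
(shrunken) statistic: the downstream logic consumes only the ranked filter
decisions, and the filter chain — not the variance estimator — is the
behavior under test.  Probes with zero pooled variance get p = 1; a matrix
where *every* probe is constant within groups raises with advice to add
replicates or jitter.

A known interaction worth stating: quantile normalization compresses
differential signal for genes at the extreme top of the intensity
distribution (their treatment ranks map onto a reference pooled with
unshifted control columns).  Planted log2 shifts of 2 on baselines near the
top of the 7–12 baseline range can lose ~half the apparent fold change;
with a 0.05 FDR this occasionally costs one or two of the most extreme
planted genes.  This mirrors how the normalization behaves on real arrays
with few, very large effects.

## Synthetic experiments

The generator emulates the statistical structure the scoring assumes and
nothing more: a bipartite regulator→transcript graph (one hop, because the
reasoning is one hop; cascades would add no testable behavior), planted
active regulators, and direction agreement degraded by two independent
dials.

* Out-degree ~ 1 + Poisson(mean − 1), clamped to the gene count; mean 8 by
  default.  Edge signs are i.i.d. positive with probability 0.5.
* Active regulators are drawn uniformly among regulators with at least
  `max(min_downstream, min_correct)` targets (`choose_active`): a regulator
  below the eligibility threshold cannot be recovered by construction, so
  planting it would measure the sampler, not the method.
* Each target of an active regulator becomes an SC in the implied direction
  with probability q (`concordance_prob`), in the opposite direction with
  probability (1 − q) · `flip_prob` (default 0.5), else stays unchanged;
  every other gene becomes an SC with probability b
  (`background_sc_rate`), direction uniform.  A gene claimed by two active
  regulators with conflicting implied signs follows a fair coin — with
  default sizes (~40 targets over 2000 genes) such collisions arise in
  roughly a third of realizations and very occasionally cost a
  minimum-degree regulator its fourth consistent change.
* Expression: per-gene baseline log2 intensity ~ Uniform(7, 12) (linear
  intensities ≈ 130–4000, microarray-like), Gaussian noise (sd 0.1 default)
  in log2 space, treatment samples shifted ±`effect_size` (default 2) for
  planted SC genes, 5 samples per group, exported on linear scale with an
  identity probe map.

All randomness flows from one `numpy.random.SeedSequence(seed)` that spawns
an independent child stream per stage (network / state changes /
expression), so regenerating any stage is deterministic and independent of
the others.

Under q = 1, b = 0 with the default sizes, recovery is exact up to the
collision caveat above: every planted regulator is significant in the
planted direction and no unplanted regulator reaches c ≥ 4.  Under q = 0.8
the per-regulator detection probability has a closed form (multinomial over
(c, contra) against the c ≥ 4 and binomial-tail conditions) of ≈ 0.72 with
the Poisson degree profile: a degree-6 regulator with one contradicting
target already has a concordance tail of 7/64 ≈ 0.109 > 0.1.  Measured mean
recall over 20 seeds (~0.70) sits within one standard error of that
expectation.  Passing recovery tests therefore show the chain is faithful
to its own model; they do not show the model captures real microarray noise
(no probe effects, saturation, correlated genes or batch structure — all
out of scope).

## The stand-in reference network

`standin_stress_network` deterministically constructs a network carrying a
published cellular-stress model's *summary-level* counts — 730 nodes in the
standard categories (84 mRNAs, 235 proteins, 43 phosphoproteins, 180
activities, 57 complexes, 18 families, 48 processes, 65 chemicals), 1280
edges of which 778 are causal (545 human / 175 mouse / 58 rat), 428 unique
PMIDs, and a ~⅔ lung + cardiovascular tissue fraction — with invented
entities and random wiring.  It is synthetic: it exercises the TSV
round-trip and counting machinery against known totals and stands in for a
supplementary data file that ships only in spreadsheet form.

## Numerical and format choices

* Edge identity is (source, target, sign, causal_flag); duplicate
  assertions merge PMID lists and block labels, first-seen species/tissue
  kept.  Opposite-sign edge pairs are both retained and later surface as
  ambiguous signature entries.
* Non-causal edges carry sign +1 and never enter signatures, statistics
  that count causal edges, or coverage.
* Building-block labels are serialized per edge row; node membership is the
  union over incident edges (a node may belong to several blocks).  This
  keeps `parse ∘ export` an exact identity on the edge-TSV dialect.
* Coverage requires sign consistency by default (`require_sign_match`);
  the permissive variant, which inflates coverage, is an explicit flag.
* Cluster rules are applied in order A, B, C, D, E, first match wins:
  A = (±1, 0, ∓1), B = (±1, same, ∓1), C = (±1, same, 0), D = (±1, 0, 0),
  E = (0, ±1, 0); anything else — including a significant third comparison
  with a silent first — is unclustered.  Each rule matches exactly two of
  the 27 patterns.
* Hypothesis tables sort ascending by (concordance, richness, term,
  direction) — fully deterministic.

## Problem sizes

Recovery suites use 50 regulators × 2000 genes (scoring) and 20 regulators
× 1000 genes × 5v5 samples (expression pipeline), 20 seeds for regulator
recovery and 3 for pipeline recovery; the exhaustive scoring oracle runs
the complete N ≤ 12 grid.  The full test suite and the acceptance script
each run in well under a minute on one core.

## Limitations

One-hop reasoning only (no transitive signatures); no score aggregation
across data sets; no ortholog mapping between species naming conventions
(entities are opaque symbols); no moderated variance estimator; no raw
probe-level (CEL) processing, array QC or batch correction; the term
grammar is a minimal `tag(entity)` form, not a full causal-statement
language (no namespaces, nested functions or translocations).
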