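# Methods

This note documents the models and procedures implemented in
`rootquartet`, the conventions adopted where the methodology is
genuinely underdetermined, and what the synthetic-data experiments do
and do not establish.

## The root-quartet problem

Four taxon groups — by default XEN (Xenarthra), AFR (Afrotheria), BOR
(Boreoeutheria) and OUT (non-placental outgroups) — admit three
resolutions of the root quartet: Atlantogenata {XEN,AFR}|{BOR,OUT},
Afrotheria-sister {AFR,OUT}|{XEN,BOR} and Xenarthra-sister
{XEN,OUT}|{AFR,BOR}. Under the multispecies coalescent with one sampled
lineage per group, a gene genealogy displays the species-tree pairing
with probability p = 1 − (2/3)e^(−t), where t is the internal branch
length in coalescent units (2N generations); the two discordant
pairings each occur with probability (1/3)e^(−t). Inverting this law,
t = −ln(3/2(1−p)), turns an observed support fraction into a branch
length; p = 1/3 maps to t = 0 (hard polytomy) and p < 1/3 to a negative
length, which is reported with a warning since no bifurcating history
predicts it.

## Concordance classification

Gene trees are handled as unrooted split systems. Classification of a
collapsed tree proceeds on the nontrivial bipartitions over its mapped
leaves:

1. a group G is **rejected** if some retained split places members of G
   on both sides together with non-members on both sides (the four-way
   intersection test for split conflict); any rejected group — the
   outgroup included — means the tree conflicts with every hypothesis,
   since group coherence is common to all three constraint trees;
2. otherwise the tree **supports** the unique hypothesis whose pairing
   appears among the retained splits (two distinct pairings of the same
   leaf set are incompatible, so at most one can appear);
3. otherwise it is **indecisive**.

This is equivalent to the split-compatibility definition (compatible
with exactly one constraint tree vs. all three vs. none), which the test
suite verifies by exhaustive enumeration of every binary topology on six
and seven leaves.

Conventions, chosen where the source methodology is silent and exposed
as flags:

- **Collapse rule.** An internal edge survives when its support is ≥ the
  threshold ("support above the threshold" retained; strictly-below
  collapsed). Collapsing is idempotent and monotone in the threshold.
- **Missing supports are not zero.** An edge with no support label is
  collapsed whenever the threshold is positive (it carries no evidence);
  `keep_unlabelled` reverses this.
- **Unmapped taxa** are pruned with a warning rather than failing, since
  per-gene taxon sets vary.
- **Weights.** A supergene tree standing for a bin of genes is counted
  with weight equal to the bin size, so weighted outcome counts remain
  comparable to per-gene counts.

## Likelihood engine

Felsenstein pruning with per-node scaling (log accumulators, so exact
log-likelihoods are returned, never rescaled scores). Models are
time-reversible with the rate matrix scaled to one expected substitution
per unit branch length:

- **GTR+Γ**: free exchangeabilities and stationary frequencies;
  among-site rate variation by a discrete gamma with `n_cat` = 4
  equal-probability categories, each category assigned the **mean** of
  its quantile band (the most common convention). Shape α defaults to
  0.5 where a fixed value is needed.
- **Mk / Mkv**: k-state symmetric model; Mkv conditions each site's
  likelihood on variability, lnL_site − ln(1 − Σ_s L(constant_s)),
  the ascertainment correction for character matrices that exclude
  invariant characters. On data restricted to variable characters, Mk
  inflates branch lengths and Mkv removes most of that bias (checked by
  a sign test over 50 simulated replicates).

Branch lengths are optimized coordinate-wise: each edge by bounded
scalar search on [1e−8, 20], using inside/outside conditional
likelihoods so the one-dimensional objective is cheap; sweeps repeat
until a full sweep improves lnL by < 1e−6 (default cap 20 sweeps, with a
warning on hitting it). Optional flags optimize α (bounded search on log
scale), set frequencies to empirical counts, or optimize
exchangeabilities (L-BFGS-B on log scale). The optimizer is
deterministic given its inputs. Equal parameter counts across candidate
topologies (same model, same number of free branches) make ΔAIC =
2·ΔlnL in the screen below.

## Topology tests

- **Tally**: per gene, the topology with maximum total lnL; exact ties
  go to an explicit `tied` bin.
- **AIC screen**: a gene significantly supports its best topology when
  the AIC margin over the best rival is ≥ 2.0 — the conventional
  "substantial support" cut, used because the original decision rule is
  not recoverable; the threshold is a flag and is recorded in output
  metadata.
- **AU test**: multiscale RELL bootstrap. For each scale r in
  {0.5, …, 1.4}, B replicates of ⌈r·n⌉ sites are drawn with replacement
  from the per-site log-likelihood rows (implemented as multinomial
  counts over the *unique* rows with multiplicity weights —
  distributionally identical and much faster); bootstrap proportions are
  mapped through z_r = Φ⁻¹(1 − BP_r) and fitted by weighted least
  squares (binomial delta-method weights) to z_r = d√r + c/√r; the
  p-value is 1 − Φ(d − c). A tree with BP 0 (or 1) at every scale gets
  p = 0 (or 1) directly. B defaults to 10,000; all randomness flows
  through one seeded generator, so results are exactly reproducible.

## Predictive adequacy (diversity statistic)

The statistic is the mean number of distinct resolved states per
alignment column (columns with no resolved state are excluded — the
statistic is about the sites that carry data). Replicate alignments are
simulated on the fitted tree and model with the observed missing-data
mask re-applied, so per-column effective sample sizes match. The
p-value is the lower tail, P(D_rep ≤ D_obs): a model that over-predicts
diversity (typical of compositionally homogeneous models on constrained
real data) yields p near 0, an under-predicting model yields p near 1;
`upper_tail` gives the complement. This is a **parametric** predictive
check at the fitted parameter point — a deliberate approximation that
plays the role of a full posterior-predictive analysis without Bayesian
machinery; its replicate spread omits parameter uncertainty, so it is
mildly anticonservative.

## Synthetic-data generator

The generator emulates the statistical regime of a root-quartet study:

- **Species tree** (((XEN,AFR),BOR),OUT), ultrametric in coalescent
  units: stem depth 1.0 from the tips to the first join, the contested
  internal branch t (default 0.26, the regime of interest: short but
  nonzero), and 1.0 above the {XEN,AFR,BOR} ancestor. One lineage per
  group by default (the quartet mathematics); multi-lineage sampling is
  available for dilution/stress experiments.
- **Genealogies**: within each species-tree branch, j lineages coalesce
  with Exp(C(j,2)) waiting times; the root branch runs to completion.
- **Sequences**: root states from the stationary frequencies, one
  discrete-gamma category per site, states propagated through the
  transition matrices. The default sequence model is GTR with
  transition-biased exchangeabilities (AG = CT = 4× transversions),
  mildly AT-rich frequencies (0.3/0.2/0.2/0.3) and α = 0.5 — a generic
  mammalian nuclear-gene caricature. Coalescent units convert to
  substitutions via a multiplier of 0.01 substitutions per coalescent
  unit, giving the weak per-gene signal of short genes (~300 sites, a
  handful of informative sites each).
- **Gene-tree estimation error**: neighbor joining (scikit-bio) on
  k-state Jukes-Cantor-corrected distances (saturated pairs capped at 5
  substitutions/site with a warning), supports from 100 site-resampled
  bootstrap replicates. This stands in for per-gene ML search: what
  matters for the pipeline is that short noisy genes yield low supports
  on the short internal edge, which it reproduces.

What passing the synthetic experiments shows: the classification,
transform and testing layers are internally correct and calibrated
under the multispecies coalescent with finite-length, model-generated
sequences. What they do not show: robustness to alignment error, model
violation (compositional heterogeneity, among-lineage rate variation),
recombination within genes, or gene flow — none of which the generator
produces.

## Experiment sizes and analysis choices in the test suite

- MSC recovery uses 10,000 genealogies per t value and 3-binomial-SE
  bands propagated through the transform (delta method:
  SE_t = SE_p/(1−p)).
- The threshold-monotonicity experiment uses 2,000 estimated gene trees
  (300 sites, NJ + 100 bootstraps) at t = 0.26 and compares 50% vs 75%
  thresholds.
- The AIC null-calibration experiment simulates 3,000 genes on **star**
  gene trees (no internal structure, tips at 0.02 substitutions) over
  six taxa sampling each ingroup clade twice, with the fitting model
  also generating the data. Sampling clades more than once is essential
  to the null's meaning: with one taxon per group, any single parallel
  change between two tips is root-informative and the screen correctly
  flags it (ΔAIC ≈ 4–8 from one homoplastic site), whereas with
  duplicated clades a root-informative pattern requires group-coherent
  homoplasy, which is quadratically rarer — the signal-dilution regime
  of real many-taxon gene alignments, and the regime in which a
  "mostly indecisive" null expectation is actually derivable. Under the
  single-exemplar reading the indecisive fraction is ~25% (MSC t = 0;
  the genes genuinely carry genealogy signal) or ~83% (star gene
  trees); both are reported here for transparency, and the multi-lineage
  design is the package's definition of its null-calibration experiment.
- PPA calibration runs 40 trials of fit-then-check at n_rep = 100 and
  requires ≥ 85% of p-values in [0.05, 0.95].

## Known limitations

- The likelihood engine targets desk-scale problems (≲ 15 taxa,
  ≲ 10 kb); it favors exactness and determinism over speed and offers
  no tree search.
- The AU implementation follows the standard multiscale formulation but
  is not a byte-level reimplementation of any particular program;
  p-values agree in behaviour (degenerate cases, symmetry,
  monotonicity), not necessarily to the fourth decimal.
- `estimate_gene_tree` requires ≥ 4 taxa and is distance-based; very
  short alignments with saturated pairs produce capped distances and a
  warning rather than an error.
- Negative coalescent lengths (p < 1/3) are mathematically valid outputs
  of the transform and are returned with a warning, not an error.
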