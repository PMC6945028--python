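# Methods

## The inheritance model

polymap models a bi-parental full-sib cross in an autopolyploid with
`m` homologous chromosomes per parent (`m` ∈ {2, 4, 6, 8}; the package
was developed with the hexaploid case `m = 6` as the reference).  At a
locus, each parent transmits a *gamete*: a subset of `k = m/2` of its
homolog labels.  An offspring's hidden state is the ordered pair
(maternal gamete, paternal gamete), giving `C(m,k)²` states — 400 for
a hexaploid.  What is observed is never the state itself but the
*allele dosage* (0..m copies of the alternative allele), possibly with
a caller-supplied probability distribution over dosage classes.

### Gamete transition kernel

Between two loci with recombination fraction `r`, homologs pair into
`k` bivalents (a perfect matching ψ, uniform over the
`m!/(k!·2^k)` configurations under polysomic inheritance) and each
bivalent transmits one recombinant chromatid that switches partners
with probability `r`.  Marginalizing ψ gives the transition
probability between gametes `a` and `b` with `l = |a \ b|` exchanged
homologs:

    T(a, b) = r^l (1 − r)^(k − l) / C(m − k, l)

This is exact for the bivalent process: the number of configurations
consistent with both `a` and `b` is `l!(k−l)!` of the `k!` consistent
with `a`, and `l!(k−l)!/k! = 1/C(k,l) = 1/C(m−k,l)`.  The kernel is
symmetric, doubly stochastic, the identity at `r = 0`, and row sums
are exactly 1.  Fixing ψ along a whole chromosome makes the true
process non-Markov across intervals; the HMM uses the per-interval
marginal, the standard approximation in multilocus polyploid mapping.
Double reduction is not modeled in the kernel (it requires multivalent
formation and is rare where bivalents dominate); the simulator can
produce it as an optional stressor to probe robustness.

### Segregation

A parent of dosage `d` transmits `a` alternative copies with
hypergeometric probability `C(d,a)·C(m−d,k−a)/C(m,k)`; offspring
dosage is the convolution over both parents.  For a triplex × triplex
hexaploid marker this is the 1:18:99:164:99:18:1 ratio used by the
segregation-distortion filter.

## Pipeline stages

**Two-point screen.**  For each marker pair and each admissible phase
class `(sP, sQ)` (homologs carrying the alternative allele at both
loci, per parent) the joint offspring dosage distribution is a
polynomial in `r` with coefficient tensors precomputed per dosage/phase
combination, so the per-pair profile likelihood is maximized by
bounded Brent in milliseconds.  Phase ties break to the smallest
`(sP, sQ)`.  Missing dosages are dropped pairwise.  Unlinked pairs
have nearly flat likelihoods in `r` (the kernel at `r = 0.5` keeps
same-bivalent correlation and is not full independence), so their
rf estimates scatter below 0.5 while the linkage LOD stays ≈ 0 —
grouping should use the LOD, not the rf, as the strong signal.

**Grouping and ordering.**  UPGMA on the rf matrix cut at a
user-chosen number of groups (no automatic chromosome-number
inference).  Within groups, distances are Haldane-transformed
(capped at r = 0.49) and a 2-D weighted SMACOF (weights = LOD²)
configuration is projected onto a principal curve (moving-average
smoothing of the coordinates against the current arc-length order,
iterated); the arc-length parameter gives the order up to global
reversal, with 1-D classical scaling as the degenerate-fit fallback.

**Phasing.**  Markers are inserted serially in map order.  Candidate
homolog assignments are pruned by two-point evidence against placed
markers (classes more than 10 LOD worse than the pair's best class are
eliminated) and survivors compared by windowed multipoint likelihood
with the new interval's rf profiled out.  The first marker fixes the
within-parent label gauge.  Two whole-map repair passes follow,
both driven by cached forward/backward messages that give the *exact*
full-map likelihood change of a local edit in one contraction:

* *re-phasing sweeps* — every admissible assignment of every marker is
  re-scored against the complete map at fixed interval rfs (fixed so a
  wrong phase cannot buy back likelihood through inflated local
  recombination); improvements above 0.5 nat are applied;
* *gauge healing* — serial insertion can switch to a different (equally
  valid) homolog permutation partway along the map, leaving two
  internally consistent blocks stitched through a spuriously inflated
  interval.  Since relabeling a whole downstream block leaves its
  internal likelihood unchanged, every within-parent permutation of
  the block after a suspect interval (rf above ~2.5× the map median,
  floor 0.03) is scored exactly, with the boundary rf profiled;
  gains above 1 nat are accepted.

**Map estimation.**  Interval recombination fractions are re-estimated
by EM (Baum–Welch): the expected number of homolog exchanges per
interval across both parental meioses, divided by the `2k`
transmission slots.  The forward pass exploits the transition
factorization — the state distribution is an `(n_gametes ×
n_gametes)` matrix updated with two small matrix products — so a
30-marker, 300-offspring hexaploid EM iteration takes ~0.2 s.  The
likelihood is monotone across iterations; per-position scaling keeps
it finite at any length.

**Emissions.**  Dosage mode: `P(obs | state) = (1−ε)` when the
observed dosage equals the state dosage, `ε/m` otherwise; missing
observations emit uniformly.  Posterior mode uses the caller's
probability vector over dosage classes directly (a uniform floor can
be mixed in with `ε > 0`).  Fitting with ε = 0 on noisy calls inflates
the map — each miscall must be explained by recombination — which is
why the error-modeled (or posterior) fit is always shorter; the
package reproduces this direction on simulated data.

**Order comparison, pruning, anchored insertion.**  Candidate orders
are each phased and re-estimated under identical settings and compared
by final likelihood (ties keep the first candidate).  The
inflating-marker screen re-fits a ±5-marker window with and without
each marker and removes the worst offender above the expansion
threshold (default 2.0 cM), iterating to a fixed point with a
minimum-marker floor; note that at low density or small samples the
leave-one-out length difference has sampling noise of a few cM, so the
screen is meant for dense maps.  Anchored (reference-constrained)
markers are scored at every slot of their interval on one shared
marker window — a shared window is required for slot likelihoods to be
comparable — and inserted at the maximum-likelihood slot.

## Haplotype reconstruction and diagnostics

Genotype posteriors come from the scaled forward–backward pass;
summing the posterior over states containing a homolog gives its
inheritance probability curve, which sums to `k` per parent at every
position.  Genotypic information content per homolog and position is
`GIC = 1 − (4/n)·Σᵢ pᵢ(1−pᵢ)`: 1 when every individual's inheritance
is certain, 0 when all probabilities sit at 1/2.  Two homologs with
identical allele content over a segment depress each other's GIC to
≈ 0.3, not 0 — individuals inheriting both or neither copy remain
certain; only the exactly-one case (probability `2·C(m−2,k−1)/C(m,k)`,
0.6 for m = 6) is ambiguous.

**Crossover heuristic.**  The five default steps: binarize the profile
at 0.8; remove SNPs in runs shorter than 10 cM; require ≥ 20% marker
retention (else the profile is inconclusive), with one posterior
re-estimation pass on the cleaned markers followed by re-cleaning;
read exchanges off transitions between markers where exactly `k`
homologs are confident; exchanges closer than 0.5 cM are inconclusive.
Three additional conservatism guards are applied before a call is
labeled conclusive, because dosage data cannot always attribute the
partners of clustered exchanges: both homologs must have ≥ 10 cM of
support on their sides of the breakpoint; the attributed homologs must
be locally distinguishable in the parental phase from the alternative
attributions; and a second exchange signal within the 10 cM span
demotes both calls.  Call positions interpolate the last/first
confident observation of the outgoing/incoming homolog.

Recombination chains link the homologs of an individual's conclusive
calls; the largest connected component bounds the meiotic valency from
below (2 = bivalent signature, ≥ 3 = multivalent).  The detector is
deliberately conservative: detection rates are a lower bound on the
simulated multivalent rate and its efficiency declines when
multivalents are frequent enough to cluster crossovers, so the
monotone operating range is the low-multivalent regime typical of
established autopolyploids.

**Preferential pairing.**  A gamete is consistent with exactly `k!` of
the pairing configurations, each carrying weight `1/k!`; averaging the
posterior-weighted consistency over individuals gives the per-position
configuration profile (uniform = 1/15 each) and, summing
configurations containing a pair, the homolog-pair profile (uniform =
1/(m−1) = 0.2).  Soft counts (`n ×` profile) are tested χ² against the
uniform null (df 14 for configurations, df 1 per pair) with
significance declared at P < 10⁻⁴.  Because posterior uncertainty
pulls the soft counts toward uniform, the test is conservative when
information is limited; with a fully forced pair the profile ceiling
is 1/3 (the pair appears in 2 of the 6 configurations consistent with
each gamete), well separated from 0.2 at mapping sample sizes.

A simplex-repulsion screen (experimental) corroborates pairing: for
simplex marker pairs phased to distinct homologs, the fraction of
offspring carrying both alleles is compared with the random
expectation `k(k−1)/(m(m−1))`.

## The simulator

`simulate` draws phased parents (marker dosage classes from a
spectrum defaulting to 49.4% simplex / 11.3% double-simplex / 39.3%
multiplex, the composition of a dense hexaploid SNP panel), then
meioses: a uniform (or preferential) bivalent configuration per
meiosis, Poisson crossovers at 1 per Morgan per bivalent with no
interference (Haldane), one transmitted chromatid per bivalent.  With
probability `p_multi` two bivalents fuse into a quadrivalent with one
uniformly placed partner-exchange point; its two transmitted
chromatids can then traverse ≥ 3 homologs, producing the multivalent
signatures the diagnostics detect (walks are resampled in the rare
case the two chromatids would collide on one source, which would
otherwise be double reduction — available separately as an off-by-default
stressor that overwrites a chromatid tail).  Preferential pairing
forces a designated pair with exactly probability π.  Observations
perturb calls to a neighboring dosage class with probability ε,
attach geometric posterior vectors (decay `exp(−sharpness)`; sharpness
5 ≈ 0.99 top mass, 3 ≈ 0.90), mark top-posterior < 0.8 calls missing,
and blank a `missing_rate` fraction outright (with uninformative
posteriors).

What the simulator does *not* emulate: read-level noise and depth
variation (depth filters are pass-through unless a depth column is
supplied), linked-marker LD in the parents beyond their phased
haplotypes, crossover interference, segregation-distorting selection,
and locus-specific error rates.  Passing tests therefore demonstrate
correctness of the inference machinery under the stated meiotic model,
not robustness to every artifact of a real sequencing pipeline.

## Reference study conditions and numerical choices

The validation suite runs at: 30 markers / ~2 cM spacing / 300
offspring / 5% dosage error for parameter recovery (phases exact up to
within-parent permutation; interval-rf MAE ≤ 0.015; length within
20%); 200 markers / 0.5 cM / 200 offspring for crossover recovery
(≥ 80% of isolated crossovers within ±2 cM; zero multivalent chains
under pure bivalent pairing) — dense, but still ~5× sparser than the
ultra-dense maps the method targets; 100 replicate groups of 20
markers / 150 offspring for pairing-test calibration.  rf values are
clipped to [1e−6, 0.4999]; EM stops at |Δloglik| < 1e−3 (default
1e−4 in the API) or 50–100 iterations; likelihood differences above
1e−8 are meaningful (per-position scaling); phase-swap acceptance
thresholds are 0.5 nat (sweeps) and 1 nat (block relabeling).
Individuals whose observation sequence has zero probability under a
candidate map are skipped with a warning rather than poisoning the
fit; individuals with genome-wide crossover counts more than 5 MAD
above the median can be flagged as outliers.
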