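# Methods

This note records the models implemented in `egdelim`, the conventions chosen
where the published descriptions leave room, the scope of the synthetic-data
generator, and the limitations those choices imply. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Substitution models and distances

A GTR-family model is parameterised by stationary frequencies π, six
exchangeabilities (AC, AG, AT, CG, CT, GT; GT = 1 by convention), an
invariant-site fraction p_inv and a discrete-gamma shape α (4 categories,
mean-of-quantile-slice discretisation). The rate matrix is normalised so that
one unit of branch length equals one expected substitution per site averaged
over all sites, `(1 − p_inv)·Σ πᵢ(−Qᵢᵢ) = 1` with mean gamma rate 1; this
makes corrected distances directly comparable with uncorrected proportions at
low divergence. Published frequency sets rounded to two decimals (sums of
0.99) are renormalised on load. Two presets ship with the package: `coi_paper`
(TrN+I+G values for a darwinulid COI fragment: freqs 0.34/0.26/0.11/0.28, AG
4.30, CT 10.87, p_inv 0.58, α 1.57) and `its2_paper` (TPM2uf+G: freqs
0.13/0.30/0.33/0.23, rates 2.36/4.61/2.36/1/4.61/1, α 0.45) — both expressed
through the general GTR parameterisation, of which they are special cases.
Step-3 corrections of the K/θ procedure default to GTR+I+G for COI-like data
and GTR+G for ITS2-like data.

Uncorrected distances use pairwise deletion of gaps and N (the published
procedure does not state pairwise vs complete deletion; pairwise is the
standard choice for pairwise d and wastes no sites). Corrected distances
maximise the two-sequence likelihood over t ∈ [0, 10] substitutions/site
(bounded scalar search, tolerance 1e-8); a maximum at the bound is returned
with a saturation warning rather than an error, since 10 subs/site is beyond
any biologically meaningful divergence for these loci.

## Trees

Neighbor-joining and UPGMA are deterministic: ties on the selection criterion
break toward the lowest (row, column) index, and negative NJ branch estimates
are clamped to zero (logged), keeping downstream ages and distances
non-negative. Bootstrap supports come from resampling alignment columns with
replacement (seeded NumPy generator, bit-reproducible), rebuilding NJ per
replicate and counting bipartitions; by default replicate trees are built on
uncorrected distances, which is orders of magnitude faster than per-replicate
ML distances and an excellent approximation at within-study divergences.
Trees are midpoint-rooted before clade extraction (the study rooted with an
outgroup; midpoint rooting is the outgroup-free analogue and places the root
on the deepest split). Ultrametricity is enforced within a relative tolerance
of 1e-6 of tree height, absorbing decimal rounding in Newick files;
percentage supports (values > 1) are rescaled to proportions on parse. The
clock-constrained ML tree searches used in the original analyses are out of
scope: the GMYC front end accepts any user-supplied ultrametric Newick, with
UPGMA on model-corrected distances as the built-in fallback.

## The K/θ procedure

Step 2 computes, per clade, d (mean pairwise uncorrected difference),
π = d·n/(n−1) and θ = π/(1 − 4π/3); an invariant clade takes the floor
d = 2/(L·n) ("as if one sequence differed at one site"). Note π here follows
the published convention with the n/(n−1) factor; the plain mean pairwise
difference is the usual unbiased θ estimator, so this convention runs ~10%
high at n ≈ 10, partly cancelling the downward finite-site bias (measured
net bias at L = 385: about −11% at θ = 0.002 and −15% at θ = 0.01, well
inside the ±25% the acceptance checks allow).

Pair selection descends the supported-clade hierarchy: within each scope
(first the whole tree, then each maximal supported clade in turn) the maximal
clades are paired with their sisters when the sister is itself supported or a
single tip, otherwise with the lowest-K non-nested supported partner in the
scope. This reproduces the nested sister-pair structure of the original
analysis (pairs at several depths within one morphospecies) while testing
each boundary exactly once.

θ selection for the ratio: by default the larger of the two clades' θ
(conservative); the `smaller_on_n2` rule reproduces the published exception
of using the smaller value when the larger comes from an n = 2 clade, where
θ = 2d is likely an over-correction. When one clade is a singleton the other
clade's θ is used.

**Time convention for the monophyly probability.** The package enters the
two-population model at τ = K/θ in units of Ne generations with pairwise
coalescence rate 1/Ne — the only convention consistent with the K = 2μt,
θ = 2·Ne·μ algebra that motivates the 4× rule (t/Ne = K/θ). The lookup table
used in the original study is unpublished and its printed probabilities are
not exactly reproducible under any simple convention; this implementation
therefore documents its convention and does not claim agreement with the
published probability column. `reciprocal_monophyly_prob` computes the
probability that samples of n₁ and n₂ lineages, isolated for τ·Ne
generations, are reciprocally monophyletic: the isolation phase is simulated
(surviving-lineage counts from sums of exponentials), and the ancestral phase
is integrated exactly by a first-join recursion
`P(a,b) = [C(a,2)P(a−1,b) + C(b,2)P(a,b−1)] / C(a+b,2)`, P(1,1)=1 — a
Rao-Blackwellised Monte Carlo whose standard error is far below 1/√reps.
Closed forms are available for n₁, n₂ ≤ 2 (e.g. P(2,1) = 1 − (2/3)e^(−τ)).

Decision rule: "species" requires K/θ ≥ 4 **and** p ≥ 0.95. The ratio
criterion is hard (K/θ = 3.9 is never a species, whatever p); a narrow miss
of the probability criterion (within 5%) is reported as "flagged" rather than
silently rejected, mirroring the original study's treatment of its one
borderline pair.

## The GMYC model

Intervals are read root-to-present; interval i of duration x_i, ending at an
internal node, carries hazard `b_i = λ₁·kᵢ^{p₁} + λ₂·Σⱼ (m_ij(m_ij−1))^{p₂}`
and contributes `ln b_i − b_i·x_i` (zero-length intervals from duplicate
haplotypes contribute the event term only). The null model is a single
process on `n(n−1)`. These functional forms, and the 3 degrees of freedom for
the GMYC-vs-null test (extra rate, exponent and threshold), are fixed here so
the implementation is self-contained. Parameters are maximised by bounded
Nelder-Mead on (log₁₀λ, p) with p ∈ [0.01, 10], tolerance 1e-8, three
deterministic restarts. Threshold candidates sit at midpoints between
consecutive distinct node ages (the classification, hence the profile
likelihood as implemented, is piecewise constant between node ages), plus a
just-above-tips candidate (every tip its own species) and an at-root
candidate (everything one coalescent cluster — the one-species solution,
which is how a "single species" outcome arises on shallow trees). Ties
prefer fewer species. The confidence set collects the species counts of all
candidates within 2 log-likelihood units of the optimum. The
multiple-threshold fit refines the single-threshold optimum greedily, moving
one local transition a node rootward or tipward per step while the
log-likelihood improves by more than 1e-6, ties toward fewer clusters; an
exhaustive single-threshold enumeration for trees of ≤ 7 tips serves as the
test oracle. The public `gmyc_loglik` takes a single global threshold age;
lineage-specific classifications are passed explicitly, since a bare list of
ages cannot identify which lineage each age applies to.

Duplicate haplotypes place nodes at age zero; the fitted threshold then tends
to hug the haplotype level and the likelihood rewards arbitrarily large
coalescent hazards on the zero-length intervals. This is the known pathology
of GMYC on datasets with repeated sequences; the haplotype-pruned analysis
(unique sequences only) is the published remedy and `run_gmyc` always reports
both, mirroring the 2×2 complete/pruned × single/multiple grid.

## Synthetic data

Genealogies follow the multispecies Kingman coalescent via msprime with
ploidy 1, i.e. pairwise coalescence rate 1/Ne per generation, so E[T₂] = Ne
and θ = 2·Ne·μ exactly as in the motivating algebra — the haploid convention
appropriate for an asexual mitochondrial-like locus. Ancestral populations
take the mean Ne of the populations they merge unless overridden. No
recombination, migration, selection or demography: the generator realises
precisely the drift-only null the K/θ gap argument assumes, which is what
makes the calibration tests meaningful — and means passing them says nothing
about gene flow, selection or rate variation among lineages in real data.
Sequences evolve by drawing the root from the stationary frequencies and
applying per-category transition matrices P(μ·branch·rate) along each edge,
with invariant sites fixed at the root state.

The `coi_like` fixture emulates the structure of the motivating study's
mitochondrial dataset: 5 morphospecies containing 16 species, 58 specimens
carrying 29 distinct 385-bp haplotypes, within-species θ between 0.003 and
0.01 and between-species divergences chosen so realised K spans ~0.02–0.15,
with species-tree depths 0.45–3.5 million generations at μ = 2×10⁻⁸
(species/morphospecies splits at ≥ 3–10 Ne of the smaller daughter). At
these diversities identical haplotypes are common (θ·L ≈ 1–4), exactly as in
the real sample; to pin the distinct-haplotype count the generator oversamples
each species and keeps its most frequent distinct haplotypes as carriers,
emitting repeatedly-sampled haplotypes as exact duplicates grafted onto the
genealogy at zero branch length. A rare cross-species sequence collision
triggers a deterministic reseeded retry. `its2_like` is the slower nuclear
analogue (5 species, 22 specimens, 14 haplotypes, μ = 5×10⁻⁹).

## Calibration scope and known limitations

All simulation-based checks run at deliberately desk-scale sizes — tens of
replicates of tens of sequences at 385 bp — chosen to exercise every code
path with meaningful statistics rather than to map error surfaces.

* **GMYC count recovery.** With 5 species × 6 tips and divergences of 20–40
  Ne, the single-threshold point estimate equals the true count in roughly
  80–85% of replicates; the flexible scaling exponents make neighbouring
  counts sit within ~2 log-likelihood units, so the ±2 LL confidence set
  covers the truth almost always (~98% in the same runs). Exact-count
  recovery below nominal expectations on flat likelihood surfaces is a known
  property of this model class, not an optimisation failure (dense multistart
  checks find no higher optima).
* **GMYC test size.** The LR test at α = 0.05 with df = 3 rejected 10% of
  drift-only 20-tip genealogies in the shipped calibration — inflated
  relative to nominal, as expected when the threshold is profiled out.
* **False-positive behaviour of the 4× rule.** On drift-only
  single-population samples (16 sequences, θ = 0.01, 385 bp) the pipeline
  declares at least one species-positive pair in roughly a third of
  replicates. A small part is the rule's own advertised ~5% tail (basal
  splits deeper than 4 Ne); most comes from the d = 2/(L·n) floor: a large
  clade of identical sequences gets θ of order 2/(L·n), so a sister lineage
  only 3–6 substitutions away yields K/θ far above 4 with monophyly
  probability ≈ 1. Users should treat species calls whose θ comes from an
  invariant clade with corresponding caution; the report's θ-provenance
  column makes them easy to spot. Detection power, by contrast, is excellent:
  two populations separated 10 Ne generations are detected essentially
  always in the same setting.
* The molecular-clock tree searches, Bayesian inference and model selection
  of the original workflow are not reimplemented; user-supplied chronograms
  are accepted wherever an ultrametric tree is needed.
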