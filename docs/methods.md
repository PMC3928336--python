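# Methods

This note documents the models, estimators and numerical choices behind
`pomdiv`, and what the synthetic data do and do not establish about real
germplasm panels.

## Scope and data model

The package analyses a diploid, biallelic genotype panel — accessions
(rows) by SNP loci (columns), calls in {AA, AB, BB, NN} — together with
two upstream marker-discovery inputs: assembled contig sequences (for
microsatellite scanning) and per-position, per-accession allele-coverage
tables (for coverage-based SNP calling).  Genotypes are abstract A/B at
the panel layer; nucleotide identity only exists where sequence context
does (marker discovery, VCF export).

## Synthetic data generator

`generate_panel` draws panels from the Balding–Nichols model, which is
also the generative model assumed by the admixture analysis — so
parameter-recovery experiments are well posed end to end:

* ancestral allele frequency per locus: Uniform(0.1, 0.9).  The floor
  keeps simulated panels away from the low-MAF regime that the QC stage
  deliberately removes; it is configurable.
* population frequencies: Beta(p(1−F)/F, (1−p)(1−F)/F) around the
  ancestral p, so Var(p_s) = F·p(1−p).  F = 0 short-circuits to the
  ancestral frequencies; F = 1 is rejected as degenerate.
* genotypes: each of a sample's two allele copies independently draws a
  population of origin from the sample's admixture proportions (one-hot
  for unadmixed designs, Dirichlet(α) otherwise), then an allele from
  that population's frequency — the admixture model's per-gamete
  assumption.
* no-calls: independent Bernoulli dropout per genotype.

`generate_contigs` plants perfect microsatellites into random background
of controlled GC content and rejection-checks each contig with the SSR
scanner itself, regenerating until the scan reports exactly the planted
loci — this guarantees no accidental background repeats and no chance
extension of a planted repeat into its flanks.  `generate_coverage`
draws Poisson read depth per called genotype, reads uniformly from the
two genotype alleles, and corrupts each read with a uniform substitution
error (the error model is intentionally minimal: no quality stratification,
no strand bias).

What the generator does **not** emulate: linkage disequilibrium between
loci (loci are exchangeable and independent), genotyping error beyond
no-call dropout, allele-specific expression or paralog collapse in
coverage tables, and mutation within microsatellites (planted repeats
are perfect).  Tests passing on these panels therefore establish
correctness of the estimators under the stated model, not robustness to
those real-data artifacts.

## Marker discovery

**SSR scanner.**  Maximal perfect tandem repeats of primitive 1–6 nt
units, with per-unit-length copy minima following the MISA convention
(mono 10, di 6, tri–hexa 5) unless overridden.  Motifs are reported as
the lexicographically minimal rotation over the observed unit and its
reverse complement; the strand class records which of the pair was
observed.  Overlapping calls resolve to the longest repeat, ties to the
smaller unit, then leftmost.  Coordinates are 0-based half-open in
memory and 1-based in report tables (stated in column names).  Dual-
scanner confirmation is emulated by crossing two scans on the
(contig, canonical motif, start) key.  Spectrum tables carry exact
percentages plus a half-up-rounded integer column for report parity.

**SNP calling.**  A within-accession SNP requires two distinct alleles
each at ≥ 3× quality-filtered coverage; more than two qualifying alleles
sets a multi-allelic flag rather than dropping the site.  A
between-accession SNP requires each accession to carry exactly one
allele at ≥ 3× and the alleles to differ; an optional `max_minor_cov`
(e.g. 0) tightens this to zero tolerance for stray reads.  Transitions
are A↔G and C↔T; `tv_ratio` reports transitions/transversions with an
infinity flag when no transversions exist.  The ORF mutual-coverage
index is CI = 2·HSP/(QL+HL), capped at 1 because gapped alignments can
exceed either sequence length.

## Panel QC and diversity

Cleaning removes samples with **more than** 10% no-calls first, then
assays with more than 30% no-calls among the surviving samples (strict
inequalities; the order matters and is fixed).  Informativeness
filtering removes loci with MAF < 0.05 and loci heterozygous in every
called sample.  All filters log their removals and are idempotent.

Per-locus statistics use called alleles only.  PIC for a biallelic
locus is 1 − (p² + q²) − 2p²q², maximal at 0.375 when p = q = ½; the
multi-allelic form 1 − Σp_i² − Σ_{i<j} 2p_i²p_j² is also provided.

## Kinship

The genetic distance is D = 1 − PSA, where PS at one locus is the
multiset-shared allele count between the two diploid genotypes divided
by 2 (so PS ∈ {0, ½, 1}) and PSA averages PS over pairwise-complete
loci — each pair has its own effective locus count under missingness; a
pair with no co-called loci is an error, not a silent maximum.

Ward clustering uses the Lance–Williams recurrence.  The default
variant squares distances before the recurrence and reports heights on
the original scale (the square root of the merge criterion), which is
the convention under which the recurrence minimizes the Ward variance
objective; the unsquared recurrence is available via `variant="d"`
because older "ward" implementations used it.  Ties break on the
smallest pair of cluster indices, making trees reproducible.  An
exhaustive implementation that recomputes the variance objective from
cluster members at every step serves as the test oracle.

Branch confidence: loci are resampled with replacement (L-out-of-L),
each replicate re-distanced and re-clustered, and each internal
bipartition of the original tree scored by the percentage of replicate
trees containing it.  Support maps onto the original topology; only
non-root internal nodes are scored.  Newick export writes supports as
internal node labels and height differences as branch lengths.

## Admixture model and K selection

The model is the standard admixture model with uncorrelated
frequencies: P[k, l] ~ Beta(1, 1), Q_i ~ Dirichlet(α·1_K) (α = 1 by
default, fixed), and each allele copy draws an origin from Q_i then an
allele from P.  The Gibbs sampler alternates latent origins, conjugate
Beta updates for P, and conjugate Dirichlet updates for Q.  No-calls
contribute nothing.  Label switching is left unresolved within a run;
everything consumed downstream (the evidence) is permutation-invariant.

Implementation notes that matter for reproducibility and speed: the
sampler core is numba-compiled and uses a self-contained counter-based
splitmix64 uniform stream with Marsaglia polar normals and
Marsaglia–Tsang gamma draws, so a chain is a pure function of its seed
on any platform.  The two origin draws of a genotype are collapsed into
a single uniform via the joint outcome distribution (a K(K+1)/2
triangle for homozygotes, a K×K grid for heterozygotes) with
branch-free inverse-CDF selection — an exact draw from the same
conditional, roughly halving the per-sweep cost.  K = 1 short-circuits
the origin updates entirely.

Per-run model evidence is estimated from the post-burn-in
log-likelihood trace as mean − variance/2.  The trace is thinned (every
10th sweep) and the estimate is computed **from the thinned trace**:
500 near-independent points at the default desk-scale settings estimate
both moments amply, and evaluating the likelihood every sweep would
dominate total runtime for no measurable gain in the ΔK decision.

Evanno ΔK: L'(K) = mean(K) − mean(K−1), |L''(K)| = |L'(K+1) − L'(K)|,
ΔK = |L''(K)|/sd(K), selected K = argmax over interior K.  K values
with zero run-to-run sd are excluded with a warning.

**Ambiguity flag.**  The mean − var/2 estimator exhibits a small
overfitting bump at K = 2 even on panels simulated with no structure
(mean evidence rises by a few tens of log units, with run-to-run sd of
only a few), which manufactures spurious ΔK maxima — a documented
failure mode of this estimator.  A selection K* is therefore flagged
ambiguous when ΔK(K*) < 3 (curvature within run noise), when the
evidence at K* does not improve on K−1, or when the gain L'(K*) is less
than 3× the subsequent drift |L'(K*+1)|.  The last test is scale-free;
on single-population simulations the gain/drift ratio measures 1–2,
while genuine two-population structure gives 14 and far more, so the
threshold of 3 sits between the regimes the way a critical value is set
under a null.  The flag annotates the selection; it never changes it.

Default chain lengths follow the study-scale convention (5,000 burn-in,
50,000 repetitions); the analysis scripts and acceptance experiment use
the desk-scale 1,000/5,000, at which the selection experiment below is
already decisively resolved.

## Fixation indices

Per locus and group: F_S = 1 − H_obs/H_exp with H_exp = 2p(1−p) from
the group's allele frequencies; loci monomorphic within the group are
excluded from the group median.  Across groups: F_ST = (H_T − H_S)/H_T
with H_S the called-sample-count weighted average of group expected
heterozygosities and H_T from the pooled frequency; H_S ≤ H_T by
concavity, so per-locus F_ST ≥ 0.  Loci with H_T = 0 are excluded.  No
small-sample correction is applied by default, matching the classical
definitions; summaries report the median and the fraction of loci below
a configurable deviation bound (default 0.05).

A property worth knowing when interpreting medians: with two groups,
the expectation of per-locus (H_T − H_S)/H_T under Balding–Nichols
drift F is ≈ (F/2)/(1 − F/2) — the classic (K−1)/K deme factor — and
the median sits lower still because (p₁ − p₂)² is chi-square
distributed with one degree of freedom (median ≈ 0.455 × mean).  The
median per-locus F_ST of a two-group panel is therefore a conservative
summary of differentiation, roughly a quarter of the generative F, not
an estimator of it.  Estimators that do target F (Weir–Cockerham θ and
kin) are intentionally out of scope.

## Problem sizes

The analysis scripts operate on a 120-accession × 300-locus panel
(two ancestral populations, F = 0.15, 2% no-calls), 60 contigs with 60
planted SSRs, and a 6-accession coverage table at 30× depth — sizes at
which every stage, including 300 bootstrap replicates and a K = 1..5
scan with 5 chains per K, completes in a few minutes on one core.  The
acceptance experiment replicates the K-selection study (10 chains per
K, K = 1..5, 1,000/5,000 sweeps) over three independently generated
panels and reports the modal selected K; selection at this signal
strength is near-deterministic, and the replication guards the mode
against a single unlucky chain set.

## Known limitations

* Independent loci only; bootstrap support and ΔK behavior under strong
  LD are untested.
* The admixture sampler uses fixed α; no correlated-frequencies model,
  no linkage model, no prior population information, no cross-run label
  alignment (CLUMPP-style) — Q matrices from different runs are
  comparable only up to label permutation.
* Between-accession SNP calling assumes the two accessions' coverage
  tables were produced against the same contig coordinates.
* Perfect repeats only; compound or interrupted SSRs are not reported.
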