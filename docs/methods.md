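# Methods

This note records the models implemented in `gbcpipe`, the defaults
and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical choices a maintainer would need
to know. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinate model and consequences

Mutations live in CDS coordinates on the coding strand, 1-based and
closed: codon *i* covers positions 3*i*−2..3*i*. This removes any
dependence on a reference genome or transcript annotation while
preserving every downstream computation; genome-coordinate liftover
and isoform choice are explicitly out of scope. Insertions are
anchored after their position (VCF-style left anchoring); deletions
are inclusive ranges. Multi-nucleotide substitutions are rejected
with a clear error rather than silently mishandled.

Consequences are determined by applying the edit and retranslating
from the start codon with the standard genetic code: SNVs yield
synonymous / missense / nonsense / stop-lost / start-lost by codon
comparison; indels are frameshift when their length is not a multiple
of three, in-frame otherwise; any edit that destroys codon 1's ATG is
start-lost (empty mutant protein, flagged, never an exception).
Frameshift translation continues in the shifted frame to the first
stop codon. Two deliberate boundary rules:

* translation never reads past the CDS end into invented 3′ sequence —
  a frameshift without a stop before the CDS end sets
  `no_stop_reached` instead;
* stop-lost proteins extend only through an explicitly provided 3′
  flank, else they are flagged the same way.

Essential splice-site events cannot be represented in a CDS-only
model; the mutation table accepts an optional consequence-override
column so such events still count as truncating in the statistics
that need them.

## Trinucleotide contexts and the spectrum

SNVs are collapsed to the pyrimidine strand (purine references are
reverse-complemented together with their flanks), giving the standard
96 classes ordered C>A, C>G, C>T, T>A, T>C, T>G × 4×4 flanks. Flanks
at the CDS edges come from per-gene `flank5`/`flank3` strings; an
edge SNV without a flank is excluded from the spectrum and reported,
never silently dropped. The spectrum here is CDS+flank based; it is
an approximation to genome-wide context counting, declared rather
than claimed equivalent.

## Signature extraction

`nmf_extract` implements multiplicative-update NMF under the
generalized Kullback–Leibler divergence — the objective used
throughout the mutational-signature literature — on the 96 × samples
count matrix. Choices:

* stopping at 2000 iterations or a relative objective change below
  1e-8, whichever first;
* 10 random restarts by default, keeping the best final objective,
  ties going to the lowest restart index (deterministic given the
  seed, which fans out to one child stream per restart);
* denominators guarded at 1e-12; the per-iteration objective trace is
  retained and is non-increasing up to that guard;
* **W** columns normalized to sum 1 after fitting, the scale absorbed
  into **H**.

The signature count *k* is a user parameter; no automatic rank
selection is attempted. The test suite cross-checks the factorization
against scikit-learn's `NMF(solver="mu",
beta_loss="kullback-leibler")` as an independent route; the
implementation itself never calls it.

## Exact and rank statistics

The two-sided Fisher p-value (via `scipy.stats.fisher_exact`) sums
hypergeometric point probabilities not exceeding the observed one,
with the conventional 1 + 1e-7 relative tolerance; the test suite
verifies equality against full enumeration for every table with all
margins ≤ 15. The odds ratio is ad/bc, switching to the
Haldane–Anscombe correction (0.5 added to every cell, flagged) only
when a cell is zero. BH correction comes from statsmodels; the
Mann–Whitney test uses the exact distribution for combined n ≤ 20
without ties and the tie-corrected normal approximation otherwise;
Shannon entropy is computed in nats with zero-count clones ignored.

## Hotspots and gene significance

A hotspot is a codon carrying protein-altering mutations in at least
two *distinct* samples — the smallest recurrence worth reporting —
with the first affected codon used for indels (for an insertion, the
codon of the base after the anchor). Meta-hotspots match cohort
mutations against a (gene, codon) catalog exactly. An optional flag
restricts hotspot calling to mutations with RNA expression support.

Gene significance deliberately substitutes a simple Poisson
background for convolution-based exome tools: the background rate is
protein-altering mutations per CDS base per sample, hypermutated MSI
samples excluded (their outlier burden would swamp the estimate);
per-gene expectation is rate × CDS length × samples; the p-value is
the Poisson upper tail, corrected by BH; q-score = −log₁₀(q) with
q-score ≥ 1 selecting SMGs. The resulting q-scores are comparable in
spirit, not numerically, to convolution-test q-scores. One
panel-scale consideration: on a small gene panel a strong driver can
contribute a non-trivial share of all mutations and inflate the
background; `exclude_from_background` lets callers estimate the rate
from the remaining genes (excluded genes are still tested). Exome-
scale inputs do not need it.

The randomization test asks whether a gene's *truncating fraction*
(frameshift + nonsense + splice-override, over all its mutations)
exceeds what random placement produces: each null draw re-places the
same mutation set at uniform CDS positions, keeping indel types and
lengths and redrawing SNV substitution types from the cohort's
six-type frequencies conditioned on the drawn site's reference base,
then re-classifies and recomputes the fraction. The empirical p is
(1 + #{null ≥ observed}) / (1 + iterations), never exactly zero. Note
the statistic is intentionally conservative for indel-rich genes:
preserved indel types truncate under the null too, so the test probes
positional effects (e.g. nonsense placement), not indel counts.

## Neoantigens and immune editing

Candidate peptides are every 8–11mer window of the mutant protein
overlapping at least one novel residue; exact duplicates are merged
and peptides occurring verbatim in the same gene's wild-type protein
are discarded (they are not neoantigens). Proteome-wide self-peptide
filtering is *not* performed — only the same gene's wild type — a
declared limitation. Binding goes through a predictor contract
`(peptide, allele) → IC50 nM in [0.1, 50000]`; the binder rule is
inclusive, IC50 ≤ 500 nM, everywhere (a strict-vs-inclusive
discrepancy exists in the literature this mirrors; the inclusive
reading is adopted and used consistently). A scored-peptide TSV
adapter lets an external MHC-I tool be wired in; the pipeline never
shells out.

The bundled surrogate predictor derives, for each (allele, length k),
a k × 20 position-weight matrix from a seeded SHA-256-keyed random
stream with standard-normal entries; a peptide's score is the summed
per-position weights divided by √k (standard normal for random
peptides) and IC50 = 50000 × 10^(−a·z) clipped to [0.1, 50000] with
sharpness a = 1. That places roughly 2 % of random 9-mers at or below
500 nM. Because a mutation is represented by its *best* peptide over
~40–150 windows, the per-draw binder probability in the Monte Carlo
is far higher (~0.4 at defaults), which is the regime where the
Fisher comparison of binder counts is well powered and its discrete
p-values are nearly continuous.

The immune-editing Monte Carlo draws, per iteration and per pool, one
mutation and one allele copy uniformly (pool multiplicities preserved
exactly as observed), takes the best-affinity peptide, and records a
binder; after `n_sim` (default 5000) draws per pool it reports the
2×2 Fisher result and the odds ratio of the two binder proportions.
Mutation and allele draws are independent; per-(mutation, allele)
best affinities are memoized, so the cost is bounded by distinct
pairs, not draws.

## Expression programs

The activation-score formula for the NRF2 program is not uniquely
defined in the literature this follows; the sum of per-gene z-scores
(ddof = 1 across samples) over the 27-gene target signature is
adopted. Under a null of independent genes the score has standard
deviation √27 ≈ 5.2, so the activation threshold of 15 sits near 3
SD — a sensible operating point for the strict `score > 15` rule. The
27 bundled gene symbols are canonical NFE2L2 targets and are fully
configurable; zero-variance genes contribute 0 and are flagged;
missing signature genes are reported. The score is invariant to
affine rescaling of any gene's expression row, so any monotone
normalized unit (log-TPM, FPKM, counts-per-million) works.

Enrichment scans candidate genes with per-gene 2×2 Fisher tests of
mutation status against NRF2 class, BH-corrected over the candidate
list; never-mutated genes keep a p = 1 row so the correction
denominator is honest.

Threshold rules are applied with their stated comparison sense and
boundary behaviour is tested: MSI at score > 0.35 (strict), splice
variants kept iff some tumor sample has FPKM > 2 *and* non-missing
PSI > 0.1, the normal panel is zero-FPKM in > 99.8 % of samples, and
the event is not an alternative start/end or retained intron; PSI
with denominator < 10 is set missing before anything else.

## The synthetic cohort

The generator produces the statistical structure every stage assumes,
plus ground truth sufficient to score recovery without re-derivation.
Default study conditions (chosen once):

* two populations of 60 and 91 samples — the sizes of the
  two-population comparison the pipeline mirrors;
* random stop-free CDSs for a 20-gene panel (~10 kb of coding
  sequence); per-sample mutation burden negative binomial (mean 8,
  size 3) — a *panel-scaled* burden, not an exome's; genes receive
  mutations in proportion to length × rate, with one driver planted
  at 10× and the three NRF2 pathway genes scaled down so ~10 % of
  samples carry a pathway mutation;
* SNV classes drawn from a planted two-signature mixture (an
  ageing-like C>T-at-NpCpG signature and a flat C>A signature,
  near-orthogonal) with per-sample Dirichlet(2, 2) exposures.
  Placement is **class-first**: the class is drawn from the mixture
  restricted to contexts present in the gene, then a uniform site
  with that context. The alternative (site-first, class conditional
  on the site's trinucleotide) renormalizes within each context and
  provably biases the realized class marginal away from the planted
  mixture for context-concentrated signatures; class-first placement
  makes the realized marginal converge to the mixture, which is what
  recovery tests need;
* an ELF3-analog gene receiving 1-nt frameshift deletions at
  population-specific carrier rates 4/60 vs 28/91, half of them at a
  planted hotspot codon (default 320);
* expression: per-gene standard-normal baselines, with +1.5 SD added
  to the 27 signature genes of samples carrying a pathway-gene
  mutation (the ground-truth NRF2 class);
* HLA: 20 allele names with geometrically decaying population
  frequency vectors (prevalence order shifted between populations),
  6 i.i.d. draws per sample;
* clonotypes: symmetric Dirichlet-multinomial over 150 clones, 5000
  reads, concentration 0.5 for non-carriers vs 0.05 for frameshift
  carriers (the planted diversity effect);
* 3 MSI-like outliers with 1200 mutations and instability scores in
  (0.45, 0.7); everyone else below 0.2.

All draws flow from one root seed through named child streams, so the
generator is byte-reproducible. What it does **not** emulate —
sequencing noise, copy number, subclonality, germline contamination,
transcript isoforms, realistic codon usage or HLA linkage — bounds
what passing recovery tests show: they demonstrate that each stage
recovers its own planted structure at realistic effect sizes, not
that the pipeline is robust to every artifact of real data.

## Problem sizes in the test and acceptance suites

Unit tests run on reduced cohorts (tens of samples, 5-gene panels);
the calibration suites use the sizes their questions need: the
immune-editing null check runs 200 seeds at 500 draws per pool over a
shared memoized affinity table; the gene-significance calibration
uses 100 null genes of 300 codons at burden 30 (per-gene expectation
≈ 40, where the Poisson p-value distribution is close enough to
continuous for a KS check); the population-rate power check generates
200 minimal two-gene cohorts at the full n = (60, 91). Both KS-based
checks compare inherently discrete p-value distributions against the
continuous uniform, so their KS p-values are structurally depressed
even under perfect calibration; the chosen problem sizes keep the
discreteness small rather than the check lenient.

## Known limitations

* Gene significance is a background-rate test only: no covariates,
  no per-sample rates, no silent/non-silent contrast.
* The surrogate predictor is a calibration device with no biophysical
  content; absolute neoantigen counts from it are not comparable to
  counts from a real MHC predictor, only the pipeline mechanics are.
* The randomization test has no power against indel-count excess by
  construction (types are preserved under the null).
* CDS-only coordinates cannot express UTR, intronic or regulatory
  variation; splice events enter only via the override column.
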