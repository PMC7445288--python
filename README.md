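# gbcpipe

Somatic-mutation analysis for multi-population tumor cohorts:
consequence annotation and mutant-protein modelling, frameshift-aware
MHC class I neoantigen enumeration, an immune-editing Monte Carlo
comparing population HLA pools, recurrence and gene-significance
statistics, 96-context mutational signatures by NMF, NRF2
pathway-activation scoring, splice-variant and MSI threshold rules,
and TCR-repertoire diversity comparisons — all exercised end-to-end on
a seeded synthetic cohort with ground truth.

The package was built around the analysis patterns of gallbladder
cancer cohort studies, where an ETS-family gene (ELF3) accumulates
truncating frameshift mutations at very different rates between
patient populations, raising questions about neoantigen load and
immune selection. Raw patient data from such studies is controlled
access; `gbcpipe` therefore works in CDS coordinates on user-supplied
or simulated cohorts, with every external tool dependency (MHC
binding prediction, MSI scoring, splice quantification) replaced by a
clean interface plus a deterministic surrogate.

## The statistics at its core

* **Consequence model.** A mutation in CDS coordinates (1-based; codon
  *i* ↔ positions 3*i*−2..3*i*) is applied to the coding sequence and
  retranslated. Indels with length ≢ 0 (mod 3) shift the frame and
  translate a novel C-terminal tail until the first stop codon.
* **Trinucleotide spectrum.** Each SNV is assigned one of 96 classes
  `X[R>A]Y` (pyrimidine-strand convention, 6 substitution types × 16
  flank pairs). The cohort spectrum **V** (96 × samples) is factorized
  as **V ≈ W H** by multiplicative updates minimizing the generalized
  Kullback–Leibler divergence, with signature columns of **W**
  normalized to probability vectors and matched to a reference catalog
  by cosine similarity.
* **Neoantigens.** All 8–11mer windows of a mutant protein overlapping
  a novel residue, minus wild-type substrings, are scored against a
  pluggable predictor `(peptide, allele) → IC50 (nM)`; a peptide is a
  binder iff IC50 ≤ 500 nM. Per mutation the best-affinity peptide is
  the representative.
* **Immune editing.** For one gene's mutations and two population HLA
  pools (one entry per observed allele copy), 5000 Monte Carlo draws
  per pool pick a mutation and an allele uniformly and record whether
  the best peptide binds; binder counts are compared by a two-sided
  Fisher exact test, and binder proportions by the odds ratio
  (p₁/(1−p₁))/(p₂/(1−p₂)).
* **Recurrence and significance.** Hotspots are codons altered in ≥ 2
  distinct samples; meta-hotspots match a (gene, codon) catalog. Gene
  significance uses a Poisson background (mutations per CDS base per
  sample, MSI outliers excluded), BH-corrected, with
  q-score = −log₁₀(q) and q-score ≥ 1 flagging significantly mutated
  genes.
* **Expression programs.** The NRF2 activation score is the sum of
  per-gene expression z-scores over a 27-gene NFE2L2-target signature;
  samples with score > 15 are NRF2⁺. MSI is called at score > 0.35;
  splice variants must pass FPKM > 2, PSI > 0.1 (PSI with denominator
  < 10 is missing) and > 99.8 % zero-FPKM in a normal panel. TCR
  diversity is the Shannon index −Σ pᵢ ln pᵢ, compared between groups
  by a two-sided Mann–Whitney test.

## Worked example

The exact 2×2 machinery reproduces the headline comparisons of a
two-population cohort directly from the printed counts — 4 of 60
carriers in one population versus 30 of 100 in the other, and
pathway-mutation enrichment of 6/14 activated versus 2/87 quiescent
patients:

```python
from gbcpipe import fisher_exact_2x2, odds_ratio_from_props

r = fisher_exact_2x2(4, 56, 30, 70)
print(f"regional test: OR={r.odds_ratio:.2f}, p={r.p_two_sided:.2g}")
r = fisher_exact_2x2(6, 8, 2, 85)
print(f"pathway enrichment: p={r.p_two_sided:.2g}")
print(f"binder-rate OR: {odds_ratio_from_props(0.43, 0.41):.3f}")
```

```
regional test: OR=0.17, p=0.00031
pathway enrichment: p=5.7e-05
binder-rate OR: 1.086
```

The first p-value says carrier status and population are strongly
associated (an odds ratio of 0.17 for the low-rate population); the
second that pathway mutations concentrate overwhelmingly among
activated samples; the third that binder rates of 43 % versus 41 %
correspond to an odds ratio of 1.1.

A full pipeline run on a simulated 50-sample cohort, scored against
its own ground truth:

```python
from gbcpipe import run_pipeline

run_pipeline({
    "analysis": {"seed": 7, "n_sim": 1000},
    "simulate": {"n_samples": {"India": 20, "Korea": 30}, "burden_mean": 6.0,
                 "frameshift_hotspot_codon": 60},
    "signatures": {"k": 2},
    "randomization_iters": 200,
}, "demo_run")
```

which writes one TSV per stage plus `truth_scorecard.tsv`:

```
           check                  value                                   threshold status
signature_cosine                 0.9534                      >= 0.9 mean best-match   pass
    smg_recovery                    2/2                 all planted drivers flagged   pass
 enrichment_rank      CUL3 (q=0.000529) a planted pathway gene ranks first, q < 0.2   pass
  nrf2_agreement                    1.0                    balanced accuracy >= 0.9   pass
       entropy_p 1.1073568305181664e-07                  < 0.05 with planted effect   pass
```

The same stages are available from the shell (`gbcpipe run`,
`gbcpipe simulate`, `gbcpipe spectrum`, `gbcpipe signatures`,
`gbcpipe hotspots`, `gbcpipe smg`, `gbcpipe neoantigen`,
`gbcpipe immune-edit`, `gbcpipe nrf2`, `gbcpipe splice-filter`,
`gbcpipe msi`, `gbcpipe tcr-entropy`).

## Layout

```
src/gbcpipe/
  model.py        domain types, config, validation
  io.py           FASTA / TSV / minimal-VCF dialects
  consequence.py  translation, consequences, mutant proteins, 96-context spectra
  signatures.py   KL-NMF extraction and catalog matching
  stats.py        Fisher/BH/Mann-Whitney/Shannon, hotspots, gene significance,
                  randomization test
  neoantigen.py   peptide enumeration, predictor contract + surrogate,
                  allele pools, immune-editing Monte Carlo
  programs.py     NRF2 scoring/enrichment, splice filter, MSI, TCR diversity
  simulate.py     seeded synthetic-cohort generator with ground truth
  pipeline.py     stage orchestration and manifests
  cli.py          console script
docs/methods.md   model assumptions, defaults, numerical choices, limitations
```
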