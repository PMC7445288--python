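"""Seeded synthetic-cohort generator with ground truth.

The generator emulates the statistical structure the analysis stages
assume: a two-population cohort (sized like a 60-sample Indian and a
91-sample Korean series), negative-binomial per-sample mutation
burden allocated over a gene panel, SNV contexts drawn from a planted
two-signature mixture, an ELF3-like gene with a population-dependent
frameshift rate concentrated at a hotspot codon, planted driver genes
at a multiple of the background rate, an NRF2 27-gene expression
program switched on by planted pathway mutations, population-specific
HLA allele frequencies, Dirichlet-multinomial clonotype tables whose
evenness drops in frameshift carriers, and a few MSI-like hypermutated
outliers. Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .consequence import CONTEXT_CLASSES, reverse_complement
from .model import Cohort, GeneModel, SomaticMutation, STOP_CODONS

# 27 canonical NRF2 (NFE2L2) downstream targets used as the default
# activation signature; the gene list is configurable.
NRF2_TARGET_GENES = [
    "NQO1", "GCLC", "GCLM", "TXNRD1", "GPX2", "ABCC2", "AKR1C1", "AKR1B10",
    "G6PD", "PGD", "ME1", "IDH1", "SRXN1", "PRDX1", "TXN", "GSR", "FTL",
    "FTH1", "HMOX1", "SLC7A11", "ABCB6", "CBR1", "AKR1C2", "UGT1A6",
    "EPHX1", "CES1", "PTGR1",
]

_NON_STOP_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in STOP_CODONS and a + b + c != "ATG"
]


def planted_signature_pair() -> np.ndarray:
    """Two well-separated 96-vectors: an ageing-like C>T signature
    concentrated at NpCpG sites and a C>A signature (cosine ~ 0)."""
    sig1 = np.zeros(96)
    sig2 = np.zeros(96)
    for i, label in enumerate(CONTEXT_CLASSES):
        sub = label[2:5]
        if sub == "C>T":
            sig1[i] = 3.0 if label[6] == "G" else 0.3
        if sub == "C>A":
            sig2[i] = 1.0
    return np.column_stack([sig1 / sig1.sum(), sig2 / sig2.sum()])


@dataclass
class GeneSpec:
    symbol: str
    n_codons: int
    rate: dict[str, float] = field(default_factory=dict)  # per-population relative weight


@dataclass
class SimulationConfig:
    """Study conditions for the generator; the defaults mirror the
    two-population cohort structure described in the module docstring."""

    n_samples: dict[str, int] = field(
        default_factory=lambda: {"India": 60, "Korea": 91})
    genes: list[GeneSpec] = field(default_factory=list)
    burden_mean: float = 8.0           # panel SNVs per sample (a 20-gene panel, not an exome)
    burden_size: float = 3.0           # negative-binomial dispersion (size)
    signatures: Optional[np.ndarray] = None   # 96 x k planted signatures
    exposure_alpha: tuple[float, ...] = (2.0, 2.0)  # Dirichlet over signatures
    frameshift_gene: str = "ELF3"
    frameshift_rate: dict[str, float] = field(
        default_factory=lambda: {"India": 4 / 60, "Korea": 28 / 91})
    frameshift_hotspot_codon: int = 320
    frameshift_hotspot_weight: float = 0.5
    driver_genes: dict[str, float] = field(
        default_factory=lambda: {"TP53": 10.0})  # SNV-rate multipliers
    # per-gene relative SNV-rate overrides: the pathway genes stay rare
    # (~10% of samples carry one, as in a 160-sample series with 17
    # pathway-mutated patients)
    rate_overrides: dict[str, float] = field(
        default_factory=lambda: {"NFE2L2": 0.15, "KEAP1": 0.15, "CUL3": 0.15})
    nrf2_signature_genes: list[str] = field(default_factory=lambda: list(NRF2_TARGET_GENES))
    nrf2_pathway_genes: list[str] = field(
        default_factory=lambda: ["NFE2L2", "KEAP1", "CUL3"])
    nrf2_delta: float = 1.5            # activation shift, expression SD units
    n_filler_expression_genes: int = 40
    hla_alleles: list[str] = field(default_factory=list)
    hla_freqs: dict[str, np.ndarray] = field(default_factory=dict)
    alleles_per_sample: int = 6
    n_clonotypes: int = 150
    clonotype_reads: int = 5000
    clonotype_alpha: dict[str, float] = field(
        default_factory=lambda: {"diverse": 0.5, "concentrated": 0.05})
    n_msi_samples: int = 3
    msi_burden: int = 1200
    expression_read_mean: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.genes:
            panel = [
                ("TP53", 393), ("ELF3", 371), ("CTNNB1", 781), ("ERBB2", 500),
                ("KRAS", 189), ("ARID1A", 600), ("SMAD4", 552), ("PIK3CA", 500),
                ("NFE2L2", 605), ("KEAP1", 624), ("CUL3", 500), ("EHF", 300),
                ("STK11", 433), ("CDKN2A", 156), ("ACVR2A", 513), ("APC", 700),
                ("BRAF", 500), ("ARID2", 600), ("NF1", 700), ("MAP2K4", 399),
            ]
            self.genes = [GeneSpec(s, n) for s, n in panel]
        if self.signatures is None:
            self.signatures = planted_signature_pair()
        if not self.hla_alleles:
            self.hla_alleles = [f"HLA-A*{i:02d}:01" for i in range(1, 9)] + \
                               [f"HLA-B*{i:02d}:01" for i in range(1, 9)] + \
                               [f"HLA-C*{i:02d}:01" for i in range(1, 5)]
        if not self.hla_freqs:
            n = len(self.hla_alleles)
            base = np.exp(-0.25 * np.arange(n))
            pops = sorted(self.n_samples)
            for j, pop in enumerate(pops):
                w = np.roll(base, 3 * j)  # shifted prevalence ranking per population
                self.hla_freqs[pop] = w / w.sum()
        for pop, f in self.hla_freqs.items():
            f = np.asarray(f, dtype=float)
            if f.shape != (len(self.hla_alleles),) or abs(f.sum() - 1) > 1e-9 or (f < 0).any():
                raise ValueError(f"hla_freqs[{pop!r}] is not a frequency vector "
                                 f"over {len(self.hla_alleles)} alleles")
        sigs = np.asarray(self.signatures, dtype=float)
        if sigs.shape[0] != 96 or (sigs < 0).any():
            raise ValueError("planted signatures must be a non-negative 96 x k matrix")
        fs_genes = {sp.symbol: sp.n_codons for sp in self.genes}
        if self.frameshift_gene not in fs_genes:
            raise ValueError(f"frameshift gene {self.frameshift_gene!r} not in the gene panel")
        if not 2 <= self.frameshift_hotspot_codon < fs_genes[self.frameshift_gene]:
            raise ValueError(
                f"frameshift hotspot codon {self.frameshift_hotspot_codon} outside the "
                f"coding body of {self.frameshift_gene} ({fs_genes[self.frameshift_gene]} codons)")
        if len(self.exposure_alpha) != sigs.shape[1]:
            raise ValueError("exposure_alpha length must match the signature count")
        for spec in self.genes:
            if not spec.rate:
                base = self.rate_overrides.get(spec.symbol, 1.0)
                spec.rate = {pop: base for pop in self.n_samples}


@dataclass
class GroundTruth:
    """Everything a recovery test needs, recorded at generation time."""

    signatures: np.ndarray                 # 96 x k planted signatures
    exposures: dict[str, np.ndarray]       # per-sample mixture weights
    smg_genes: list[str]                   # planted driver genes
    enrichment_genes: list[str]            # planted NRF2 pathway genes
    nrf2_class: dict[str, bool]            # per-sample activation truth
    hla_freqs: dict[str, np.ndarray]
    frameshift_carriers: dict[str, bool]   # planted low-evenness group
    msi_samples: list[str]


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    body = "".join(rng.choice(_NON_STOP_CODONS, size=n_codons - 2))
    return "ATG" + body + "TAA"


def _flank(rng: np.random.Generator, n: int = 2) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def _context_at(cds: str, flank5: str, flank3: str, pos: int) -> tuple[str, str, str]:
    five = cds[pos - 2] if pos >= 2 else flank5[-1]
    three = cds[pos] if pos < len(cds) else flank3[0]
    return five, cds[pos - 1], three


_CLASS_INDEX = {c: i for i, c in enumerate(CONTEXT_CLASSES)}


class _GeneContextIndex:
    """Positions of each pyrimidine-collapsed trinucleotide in a CDS,
    so SNV classes drawn from the planted mixture can be placed at a
    compatible site (class first, then a uniform position with that
    context — the realized class marginal then matches the mixture)."""

    def __init__(self, g: GeneModel):
        self.gene = g
        self.by_context: dict[str, list[int]] = {}
        for pos in range(1, len(g.cds_sequence) + 1):
            five, ref, three = _context_at(g.cds_sequence, g.flank5, g.flank3, pos)
            tri = five + ref + three
            if ref in "AG":
                tri = reverse_complement(tri)
            self.by_context.setdefault(tri, []).append(pos)
        # availability mask over the 96 classes
        self.available = np.array([
            1.0 if f"{c[0]}{c[2]}{c[6]}" in self.by_context else 0.0
            for c in CONTEXT_CLASSES
        ])

    def draw(self, rng: np.random.Generator, mixture: np.ndarray) -> tuple[int, str, str]:
        w = mixture * self.available
        total = w.sum()
        w = w / total if total > 0 else self.available / self.available.sum()
        ci = int(rng.choice(96, p=w))
        label = CONTEXT_CLASSES[ci]
        tri, alt_pyr = label[0] + label[2] + label[6], label[4]
        positions = self.by_context[tri]
        pos = positions[int(rng.integers(0, len(positions)))]
        ref = self.gene.cds_sequence[pos - 1]
        alt = alt_pyr if ref in "CT" else reverse_complement(alt_pyr)
        return pos, ref, alt


def generate_cohort(config: Optional[SimulationConfig] = None
                    ) -> tuple[Cohort, GroundTruth]:
    """Generate a cohort plus its ground truth; fully deterministic
    given ``config.seed``."""
    cfg = config or SimulationConfig()
    root = np.random.SeedSequence(cfg.seed)
    r_genes, r_mut, r_expr, r_hla, r_clono, r_msi = (
        np.random.default_rng(s) for s in root.spawn(6))

    genes: dict[str, GeneModel] = {}
    for spec in cfg.genes:
        genes[spec.symbol] = GeneModel(
            spec.symbol, _random_cds(r_genes, spec.n_codons),
            flank5=_flank(r_genes), flank3=_flank(r_genes))
    context_index = {s: _GeneContextIndex(g) for s, g in genes.items()}

    samples: list[tuple[str, str]] = []
    for pop in sorted(cfg.n_samples):
        samples += [(f"{pop[:2].upper()}{i:03d}", pop) for i in range(cfg.n_samples[pop])]
    sample_ids = [s for s, _ in samples]

    # MSI outliers: hypermutated samples with high instability scores
    msi_samples = list(r_msi.choice(sample_ids, size=min(cfg.n_msi_samples, len(sample_ids)),
                                    replace=False)) if cfg.n_msi_samples else []
    msi_scores = {
        sid: (float(r_msi.uniform(0.45, 0.7)) if sid in msi_samples
              else float(r_msi.uniform(0.0, 0.2)))
        for sid in sample_ids
    }

    sigs = np.asarray(cfg.signatures, dtype=float)
    sigs = sigs / sigs.sum(axis=0)
    exposures: dict[str, np.ndarray] = {}
    mutations: list[SomaticMutation] = []
    frameshift_carriers: dict[str, bool] = {}
    mut_counter = 0

    gene_syms = [sp.symbol for sp in cfg.genes]
    gene_weights_by_pop = {}
    for pop in cfg.n_samples:
        w = np.array([
            sp.rate.get(pop, 1.0) * sp.n_codons * 3 * cfg.driver_genes.get(sp.symbol, 1.0)
            for sp in cfg.genes
        ], dtype=float)
        gene_weights_by_pop[pop] = w / w.sum()

    def new_id() -> str:
        nonlocal mut_counter
        mut_counter += 1
        return f"M{mut_counter:06d}"

    def impact_triple(rng, truncating: bool):
        if truncating:
            return ("deleterious", "deleterious", "deleterious")
        opts = np.array(["deleterious", "benign", "missing"])
        return tuple(rng.choice(opts, size=3, p=[0.4, 0.5, 0.1]))

    for sid, pop in samples:
        expo = r_mut.dirichlet(cfg.exposure_alpha)
        exposures[sid] = expo
        mixture = sigs @ expo
        n_mut = cfg.msi_burden if sid in msi_samples else int(
            r_mut.negative_binomial(
                cfg.burden_size, cfg.burden_size / (cfg.burden_size + cfg.burden_mean)))
        gene_idx = r_mut.choice(len(gene_syms), size=n_mut, p=gene_weights_by_pop[pop])
        for gi in gene_idx:
            g = genes[gene_syms[gi]]
            pos, ref, alt = context_index[g.gene_symbol].draw(r_mut, mixture)
            mutations.append(SomaticMutation(
                new_id(), sid, g.gene_symbol, pos, "SNV", pop,
                ref_base=ref, alt_base=alt,
                expressed_read_count=int(r_mut.poisson(cfg.expression_read_mean)),
                impact_labels=impact_triple(r_mut, False),
            ))
        # population-differential frameshift gene (1-nt deletions)
        carrier = bool(r_mut.random() < cfg.frameshift_rate.get(pop, 0.0))
        frameshift_carriers[sid] = carrier
        if carrier:
            g = genes[cfg.frameshift_gene]
            if r_mut.random() < cfg.frameshift_hotspot_weight:
                codon = cfg.frameshift_hotspot_codon
            else:
                codon = int(r_mut.integers(2, g.n_codons))
            pos = 3 * (codon - 1) + 1 + int(r_mut.integers(0, 3))
            mutations.append(SomaticMutation(
                new_id(), sid, g.gene_symbol, pos, "DEL", pop, del_length=1,
                expressed_read_count=int(r_mut.poisson(cfg.expression_read_mean)),
                impact_labels=impact_triple(r_mut, True),
            ))

    # expression with the planted NRF2 activation program
    expr_genes = (list(cfg.nrf2_signature_genes) + gene_syms
                  + [f"FILLER{i:03d}" for i in range(cfg.n_filler_expression_genes)])
    expr_genes = list(dict.fromkeys(expr_genes))
    expr = pd.DataFrame(
        r_expr.standard_normal((len(expr_genes), len(sample_ids))),
        index=pd.Index(expr_genes, name="gene"), columns=sample_ids,
    )
    pathway_mutated = {
        m.sample_id for m in mutations if m.gene_symbol in cfg.nrf2_pathway_genes}
    nrf2_class = {sid: sid in pathway_mutated for sid in sample_ids}
    for sid, active in nrf2_class.items():
        if active:
            expr.loc[cfg.nrf2_signature_genes, sid] += cfg.nrf2_delta

    # HLA genotypes: i.i.d. draws from the population frequency vector
    hla: dict[str, list[str]] = {}
    for sid, pop in samples:
        idx = r_hla.choice(len(cfg.hla_alleles), size=cfg.alleles_per_sample,
                           p=cfg.hla_freqs[pop])
        hla[sid] = [cfg.hla_alleles[i] for i in idx]

    # clonotype tables: lower Dirichlet concentration (less even) for carriers
    clonotypes: dict[str, dict[str, int]] = {}
    for sid, pop in samples:
        alpha = (cfg.clonotype_alpha["concentrated"] if frameshift_carriers[sid]
                 else cfg.clonotype_alpha["diverse"])
        p = r_clono.dirichlet(np.full(cfg.n_clonotypes, alpha))
        counts = r_clono.multinomial(cfg.clonotype_reads, p)
        clonotypes[sid] = {
            f"CL{j:04d}": int(c) for j, c in enumerate(counts) if c > 0}

    cohort = Cohort(
        samples=samples, mutations=mutations, gene_models=genes,
        expression=expr, hla=hla, clonotypes=clonotypes, msi_scores=msi_scores,
    )
    truth = GroundTruth(
        signatures=sigs,
        exposures=exposures,
        smg_genes=sorted(set(cfg.driver_genes) | {cfg.frameshift_gene}),
        enrichment_genes=list(cfg.nrf2_pathway_genes),
        nrf2_class=nrf2_class,
        hla_freqs=dict(cfg.hla_freqs),
        frameshift_carriers=frameshift_carriers,
        msi_samples=sorted(msi_samples),
    )
    return cohort, truth


def truth_report(truth: GroundTruth, outputs: dict) -> pd.DataFrame:
    """Score analysis outputs against the planted ground truth.

    ``outputs`` may provide: 'signature_W' (96 x k DataFrame),
    'smg' (list of GeneSignificance), 'enrichment' (DataFrame from
    nrf2_enrichment), 'nrf2_classes' (bool Series), 'entropy_p'
    (float). Missing stages are reported as not-run.
    """
    from .signatures import pair_signatures

    rows = []

    def add(check: str, value, threshold: str, ok: Optional[bool]):
        rows.append({"check": check, "value": value, "threshold": threshold,
                     "status": "not-run" if ok is None else ("pass" if ok else "fail")})

    W = outputs.get("signature_W")
    if W is None:
        add("signature_cosine", None, ">= 0.9 mean best-match", None)
    else:
        pairs = pair_signatures(W, truth.signatures)
        mean_cos = float(np.mean([c for _, _, c in pairs]))
        add("signature_cosine", round(mean_cos, 4), ">= 0.9 mean best-match", mean_cos >= 0.9)

    smg = outputs.get("smg")
    if smg is None:
        add("smg_recovery", None, "all planted drivers flagged", None)
    else:
        flagged = {r.gene_symbol for r in smg if r.is_smg()}
        hit = all(g in flagged for g in truth.smg_genes)
        add("smg_recovery", f"{len(set(truth.smg_genes) & flagged)}/{len(truth.smg_genes)}",
            "all planted drivers flagged", hit)

    enr = outputs.get("enrichment")
    if enr is None:
        add("enrichment_rank", None, "a planted pathway gene ranks first, q < 0.2", None)
    else:
        top = enr.iloc[0]
        ok = top["gene"] in truth.enrichment_genes and top["q"] < 0.2
        add("enrichment_rank", f"{top['gene']} (q={top['q']:.3g})",
            "a planted pathway gene ranks first, q < 0.2", bool(ok))

    cls = outputs.get("nrf2_classes")
    if cls is None:
        add("nrf2_agreement", None, "balanced accuracy >= 0.9", None)
    else:
        y_true = np.array([truth.nrf2_class[s] for s in cls.index])
        y_pred = cls.to_numpy(dtype=bool)
        sens = (y_pred & y_true).sum() / max(y_true.sum(), 1)
        spec = (~y_pred & ~y_true).sum() / max((~y_true).sum(), 1)
        bal = (sens + spec) / 2
        add("nrf2_agreement", round(float(bal), 4), "balanced accuracy >= 0.9", bal >= 0.9)

    p = outputs.get("entropy_p")
    if p is None:
        add("entropy_p", None, "< 0.05 with planted effect", None)
    else:
        add("entropy_p", float(p), "< 0.05 with planted effect", p < 0.05)

    return pd.DataFrame(rows, columns=["check", "value", "threshold", "status"])
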