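"""End-to-end orchestration: run every analysis stage on a cohort
(loaded from files or simulated), writing one TSV per stage plus a
run manifest.

Randomness is fanned out from the single config seed to per-stage
child seeds keyed by stage name, so skipping one stage never shifts
another stage's draws.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from pathlib import Path
import pandas as pd
import yaml

from . import io as cio
from .consequence import build_spectrum, classify_consequence
from .model import AnalysisConfig, Cohort
from .neoantigen import (
    SurrogatePredictor,
    build_allele_pool,
    immune_editing_mc,
    summarize_neoantigens,
)
from .programs import (
    classify_msi,
    compare_entropy_groups,
    filter_splice_variants,
    nrf2_enrichment,
    nrf2_score,
    read_splice_tsv,
)
from .signatures import cosine_match, nmf_extract, read_catalog_tsv
from .simulate import NRF2_TARGET_GENES, SimulationConfig, generate_cohort, truth_report
from .stats import (
    cooccurrence,
    detect_hotspots,
    gene_significance,
    match_meta_hotspots,
    randomization_test_truncating,
    read_hotspot_catalog,
)

log = logging.getLogger("gbcpipe")

STAGES = [
    "annotate", "spectrum", "signatures", "hotspots", "meta_hotspots", "smg",
    "cooccurrence", "randomization", "neoantigen", "immune_edit", "nrf2",
    "splice_filter", "msi", "tcr_entropy",
]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


def stage_seed(seed: int, stage: str) -> int:
    """Stable per-stage child seed (stage-name keyed, below 2**31)."""
    return (seed * 2654435761 + zlib.crc32(stage.encode())) % (2**31)


def load_pipeline_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} did not parse to a mapping")
    return cfg


def _get_cohort(cfg: dict, analysis: AnalysisConfig) -> Cohort:
    inputs = cfg.get("inputs")
    if inputs:
        missing = [p for p in inputs.values() if p and not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"input file(s) not found: {missing}")
        return cio.load_cohort(
            inputs["genes"], inputs["mutations"],
            samples_tsv=inputs.get("samples"),
            expression_tsv=inputs.get("expression"),
            hla_tsv=inputs.get("hla"),
            clonotypes_tsv=inputs.get("clonotypes"),
            msi_tsv=inputs.get("msi"),
            config=analysis,
        )
    sim_cfg = SimulationConfig(seed=stage_seed(analysis.seed, "simulate"),
                               **cfg.get("simulate", {}))
    cohort, truth = generate_cohort(sim_cfg)
    cohort.truth = truth  # type: ignore[attr-defined]
    return cohort


def run_pipeline(config: dict | str | Path, out_dir) -> dict:
    """Execute every enabled stage in order; returns the run manifest.

    ``config`` is a hierarchical mapping (or path to a YAML file) with
    optional sections ``analysis``, ``simulate`` or ``inputs``,
    ``stages`` (name -> bool) and stage parameters.
    """
    if not isinstance(config, dict):
        config = load_pipeline_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(message)s")
    fh = logging.FileHandler(out / "run.log")
    log.addHandler(fh)

    analysis = AnalysisConfig.from_dict(config.get("analysis", {}))
    with open(out / "config_snapshot.yaml", "w") as f:
        yaml.safe_dump(config, f, sort_keys=True)

    enabled = {s: bool(config.get("stages", {}).get(s, True)) for s in STAGES}
    manifest: dict = {"stages": {}, "seed": analysis.seed}

    cohort = _get_cohort(config, analysis)
    cio.write_tables(cohort, out / "cohort")
    predictor = SurrogatePredictor(seed=stage_seed(analysis.seed, "predictor"),
                                   kmin=analysis.peptide_kmin, kmax=analysis.peptide_kmax)
    spectrum = None
    nrf2 = None
    outputs: dict = {}

    def run_stage(name, fn):
        if not enabled[name]:
            manifest["stages"][name] = {"status": "skipped"}
            return
        t0 = time.time()
        try:
            files = fn() or []
        except Exception as exc:  # noqa: BLE001 - rewrapped with stage context
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            with open(out / "manifest.json", "w") as f:
                json.dump(manifest, f, indent=2, default=str)
            raise StageError(name, exc) from exc
        manifest["stages"][name] = {
            "status": "ok", "outputs": files, "seconds": round(time.time() - t0, 3)}
        log.info("stage %s done (%.2fs, seed %d)", name, time.time() - t0,
                 stage_seed(analysis.seed, name))

    def st_annotate():
        rows = [{
            "mutation_id": m.mutation_id, "sample_id": m.sample_id,
            "gene": m.gene_symbol, "cds_pos": m.cds_pos, "type": m.mutation_type,
            "consequence": classify_consequence(m, cohort.gene_models[m.gene_symbol]).value,
        } for m in cohort.mutations]
        p = out / "consequences.tsv"
        pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
        return [str(p)]

    def st_spectrum():
        nonlocal spectrum
        spectrum = build_spectrum(cohort)
        p = out / "spectrum.tsv"
        spectrum.to_tsv(p)
        return [str(p)]

    def st_signatures():
        sp = spectrum if spectrum is not None else build_spectrum(cohort)
        k = int(config.get("signatures", {}).get("k", 2))
        sigset = nmf_extract(sp, k=k, seed=stage_seed(analysis.seed, "signatures"))
        outputs["signature_W"] = sigset.W
        pw, ph = out / "signatures_W.tsv", out / "signatures_H.tsv"
        sigset.W.to_csv(pw, sep="\t", index_label="context")
        sigset.H.to_csv(ph, sep="\t", index_label="signature")
        files = [str(pw), str(ph)]
        catalog_path = config.get("signatures", {}).get("catalog")
        if catalog_path:
            best, _ = cosine_match(sigset, read_catalog_tsv(catalog_path))
            pc = out / "signature_matches.tsv"
            best.to_csv(pc, sep="\t", index=False)
            files.append(str(pc))
        return files

    def st_hotspots():
        calls = detect_hotspots(cohort, analysis.hotspot_min_samples)
        p = out / "hotspots.tsv"
        pd.DataFrame([{
            "gene": h.gene_symbol, "codon": h.protein_pos, "n_samples": h.n_samples,
            "consequences": ",".join(h.consequences)} for h in calls]
        ).to_csv(p, sep="\t", index=False)
        return [str(p)]

    def st_meta_hotspots():
        path = config.get("hotspot_catalog")
        if not path:
            manifest["stages"]["meta_hotspots"] = {"status": "skipped", "reason": "no catalog"}
            return []
        df = match_meta_hotspots(cohort, read_hotspot_catalog(path))
        p = out / "meta_hotspots.tsv"
        df.to_csv(p, sep="\t", index=False)
        return [str(p)]

    def st_smg():
        res = gene_significance(cohort, exclude_msi=True,
                                msi_threshold=analysis.msi_threshold,
                                qscore_min=analysis.qscore_min)
        outputs["smg"] = res
        p = out / "gene_significance.tsv"
        pd.DataFrame([{
            "gene": r.gene_symbol, "observed": r.observed,
            "expected": round(r.expected, 3), "p": r.p, "q": r.q,
            "q_score": round(r.q_score, 4), "smg": r.is_smg(analysis.qscore_min)}
            for r in res]).to_csv(p, sep="\t", index=False)
        return [str(p)]

    def st_cooccurrence():
        pairs = config.get("cooccurrence_pairs") or [["ELF3", "TP53"]]
        rows = []
        for ga, gb in pairs:
            if ga in cohort.gene_models and gb in cohort.gene_models:
                r = cooccurrence(cohort, ga, gb)
                rows.append({"gene_a": ga, "gene_b": gb, "odds_ratio": r.odds_ratio,
                             "p": r.p_two_sided})
        p = out / "cooccurrence.tsv"
        pd.DataFrame(rows, columns=["gene_a", "gene_b", "odds_ratio", "p"]).to_csv(
            p, sep="\t", index=False)
        return [str(p)]

    def st_randomization():
        gene = config.get("randomization_gene", "ELF3")
        if gene not in cohort.gene_models or not cohort.mutations_of_gene(gene):
            return []
        res = randomization_test_truncating(
            gene, cohort, n_iter=int(config.get("randomization_iters", 1000)),
            seed=stage_seed(analysis.seed, "randomization"))
        p = out / "randomization.tsv"
        pd.DataFrame([{"gene": gene, "observed_truncating_fraction": res.observed_statistic,
                       "empirical_p": res.empirical_p, "n_iter": res.n_iter}]).to_csv(
            p, sep="\t", index=False)
        return [str(p)]

    def st_neoantigen():
        if not cohort.hla:
            return []
        summary = summarize_neoantigens(cohort, predictor, analysis)
        p = out / "neoantigens.tsv"
        pd.DataFrame(sorted(summary.per_sample.items()),
                     columns=["sample_id", "n_neoantigens"]).to_csv(p, sep="\t", index=False)
        log.info("neoantigens per patient: mean %.2f range %s", summary.mean, summary.range)
        return [str(p)]

    def st_immune_edit():
        if not cohort.hla:
            return []
        gene = config.get("immune_edit", {}).get("gene", "ELF3")
        pops = sorted(set(dict(cohort.samples).values()))
        if gene not in cohort.gene_models or len(pops) < 2:
            return []
        muts = cohort.mutations_of_gene(gene)
        if not muts:
            return []
        pool_a = build_allele_pool(cohort, pops[0])
        pool_b = build_allele_pool(cohort, pops[1])
        res = immune_editing_mc(
            muts, cohort.gene_models[gene], pool_a, pool_b, predictor,
            n_sim=int(config.get("immune_edit", {}).get("n_sim", analysis.n_sim)),
            seed=stage_seed(analysis.seed, "immune_edit"),
            threshold_nM=analysis.binder_threshold_nM,
            kmin=analysis.peptide_kmin, kmax=analysis.peptide_kmax)
        p = out / "immune_editing.tsv"
        pd.DataFrame([{
            "pool_a": res.pool_a, "pool_b": res.pool_b, "n_sim": res.n_sim,
            "binders_a": res.binders_a, "binders_b": res.binders_b,
            "fisher_p": res.contingency.p_two_sided,
            "odds_ratio_props": res.or_from_proportions}]).to_csv(p, sep="\t", index=False)
        return [str(p)]

    def st_nrf2():
        nonlocal nrf2
        if cohort.expression is None:
            return []
        sig_genes = config.get("nrf2_signature_genes", NRF2_TARGET_GENES)
        nrf2 = nrf2_score(cohort.expression, sig_genes, analysis.nrf2_threshold)
        outputs["nrf2_classes"] = nrf2.classes
        p = out / "nrf2_scores.tsv"
        pd.DataFrame({"score": nrf2.scores, "nrf2_positive": nrf2.classes}).to_csv(
            p, sep="\t", index_label="sample_id")
        files = [str(p)]
        candidates = config.get("nrf2_candidate_genes") or sorted(cohort.gene_models)
        try:
            enr = nrf2_enrichment(nrf2.classes, cohort, candidates)
            outputs["enrichment"] = enr
            pe = out / "nrf2_enrichment.tsv"
            enr.to_csv(pe, sep="\t", index=False)
            files.append(str(pe))
        except ValueError as exc:
            log.warning("nrf2 enrichment skipped: %s", exc)
        return files

    def st_splice_filter():
        path = config.get("splice_records")
        if not path:
            return []
        kept = filter_splice_variants(read_splice_tsv(path), analysis)
        p = out / "splice_kept.tsv"
        pd.DataFrame([{"variant_id": r.variant_id, "gene": r.gene} for r in kept]).to_csv(
            p, sep="\t", index=False)
        return [str(p)]

    def st_msi():
        if not cohort.msi_scores:
            return []
        recs = classify_msi(cohort.msi_scores, analysis.msi_threshold)
        p = out / "msi.tsv"
        pd.DataFrame([{"sample_id": r.sample_id, "score": r.mantis_score,
                       "msi": r.msi} for r in recs]).to_csv(p, sep="\t", index=False)
        return [str(p)]

    def st_tcr_entropy():
        if not cohort.clonotypes:
            return []
        fs_samples = {m.sample_id for m in cohort.mutations
                      if m.mutation_type in ("INS", "DEL")
                      and (len(m.inserted_seq) if m.mutation_type == "INS"
                           else m.del_length) % 3}
        groups = {sid: ("frameshift" if sid in fs_samples else "none")
                  for sid in cohort.sample_ids if sid in cohort.clonotypes}
        if min(sum(1 for v in groups.values() if v == g)
               for g in ("frameshift", "none")) < 2:
            return []
        ent, pval = compare_entropy_groups(cohort.clonotypes, groups)
        outputs["entropy_p"] = pval
        p = out / "tcr_entropy.tsv"
        df = ent.to_frame()
        df["group"] = [groups[s] for s in df.index]
        df.to_csv(p, sep="\t", index_label="sample_id")
        with open(out / "tcr_entropy_p.txt", "w") as f:
            f.write(f"{pval}\n")
        return [str(p)]

    for name, fn in [
        ("annotate", st_annotate), ("spectrum", st_spectrum),
        ("signatures", st_signatures), ("hotspots", st_hotspots),
        ("meta_hotspots", st_meta_hotspots), ("smg", st_smg),
        ("cooccurrence", st_cooccurrence), ("randomization", st_randomization),
        ("neoantigen", st_neoantigen), ("immune_edit", st_immune_edit),
        ("nrf2", st_nrf2), ("splice_filter", st_splice_filter),
        ("msi", st_msi), ("tcr_entropy", st_tcr_entropy),
    ]:
        run_stage(name, fn)

    truth = getattr(cohort, "truth", None)
    if truth is not None:
        report = truth_report(truth, outputs)
        report.to_csv(out / "truth_scorecard.tsv", sep="\t", index=False)
        manifest["truth_scorecard"] = str(out / "truth_scorecard.tsv")

    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2, default=str)
    log.removeHandler(fh)
    fh.close()
    return manifest
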