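"""Readers and writers for the plain-text cohort dialects.

Gene models travel as FASTA (record id = gene symbol, optional
``flank5=``/``flank3=`` key=value pairs in the description). Mutations
travel as a MAF-like TSV with explicit alleles: SNV rows carry
single-base ref/alt, insertions carry ref="-" and the inserted
sequence as alt, deletions carry the deleted sequence as ref and
alt="-". A minimal VCF-subset reader (CHROM as gene symbol, POS as
CDS position) is provided for convenience.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    AnalysisConfig,
    Cohort,
    GeneModel,
    SomaticMutation,
    validate_cohort,
)

MUTATION_COLUMNS = [
    "mutation_id", "sample_id", "gene", "cds_pos", "type", "ref", "alt",
    "population", "expressed_reads",
]
OPTIONAL_MUTATION_COLUMNS = ["impact1", "impact2", "impact3", "consequence_override"]


class CohortFormatError(ValueError):
    """Raised for malformed rows, naming file, line and field."""


def read_gene_fasta(path) -> dict[str, GeneModel]:
    genes: dict[str, GeneModel] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        kv = {}
        for token in rec.description.split()[1:]:
            if "=" in token:
                k, _, v = token.partition("=")
                kv[k] = v
        genes[rec.id] = GeneModel(
            gene_symbol=rec.id,
            cds_sequence=str(rec.seq).upper(),
            flank5=kv.get("flank5", "").upper(),
            flank3=kv.get("flank3", "").upper(),
        )
    return genes


def write_gene_fasta(genes: dict[str, GeneModel], path) -> None:
    records = []
    for symbol in sorted(genes):
        g = genes[symbol]
        desc = []
        if g.flank5:
            desc.append(f"flank5={g.flank5}")
        if g.flank3:
            desc.append(f"flank3={g.flank3}")
        records.append(SeqRecord(Seq(g.cds_sequence), id=symbol, description=" ".join(desc)))
    SeqIO.write(records, str(path), "fasta")


def _parse_mutation_row(row: dict, path, line_no: int) -> SomaticMutation:
    def need(fieldname: str) -> str:
        v = row.get(fieldname)
        if v is None or (isinstance(v, float) and v != v) or v == "":
            raise CohortFormatError(f"{path}, line {line_no}: missing field '{fieldname}'")
        return str(v)

    mtype = need("type").upper()
    ref = need("ref").upper()
    alt = need("alt").upper()
    try:
        cds_pos = int(need("cds_pos"))
        reads = int(need("expressed_reads"))
    except ValueError as exc:
        raise CohortFormatError(f"{path}, line {line_no}: non-integer field ({exc})") from None
    kwargs: dict = {}
    if mtype == "SNV":
        if len(ref) != 1 or len(alt) != 1:
            raise CohortFormatError(
                f"{path}, line {line_no}: field 'ref'/'alt' — multi-nucleotide "
                "substitutions are not supported"
            )
        kwargs.update(ref_base=ref, alt_base=alt)
    elif mtype == "INS":
        if ref != "-" or not alt or alt == "-":
            raise CohortFormatError(
                f"{path}, line {line_no}: insertion rows need ref='-' and alt=inserted sequence"
            )
        kwargs.update(inserted_seq=alt)
    elif mtype == "DEL":
        if alt != "-" or not ref or ref == "-":
            raise CohortFormatError(
                f"{path}, line {line_no}: deletion rows need alt='-' and ref=deleted sequence"
            )
        kwargs.update(del_length=len(ref))
    else:
        raise CohortFormatError(f"{path}, line {line_no}: field 'type' has unknown value {mtype!r}")
    impacts = tuple(str(row.get(c, "")) for c in ("impact1", "impact2", "impact3"))
    if any(x not in ("", "nan") for x in impacts):
        kwargs["impact_labels"] = tuple(x if x not in ("", "nan") else "missing" for x in impacts)
    override = str(row.get("consequence_override", "") or "")
    if override and override != "nan":
        kwargs["consequence_override"] = override
    return SomaticMutation(
        mutation_id=need("mutation_id"),
        sample_id=need("sample_id"),
        gene_symbol=need("gene"),
        cds_pos=cds_pos,
        mutation_type=mtype,
        population=need("population"),
        expressed_read_count=reads,
        **kwargs,
    )


def read_mutations_tsv(path) -> list[SomaticMutation]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in MUTATION_COLUMNS if c not in df.columns]
    if missing:
        raise CohortFormatError(f"{path}: missing required columns {missing}")
    return [
        _parse_mutation_row(row, path, i + 2)  # +2: header is line 1
        for i, row in enumerate(df.to_dict("records"))
    ]


def read_mutations_vcf(path) -> list[SomaticMutation]:
    """Minimal VCF-subset reader: CHROM is the gene symbol, POS the CDS position.

    Per-record metadata rides in INFO as SAMPLE=, POP=, READS= keys.
    """
    muts: list[SomaticMutation] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 8:
                raise CohortFormatError(f"{path}, line {line_no}: expected >= 8 VCF columns")
            chrom, pos, vid, ref, alt, _qual, _filt, info = parts[:8]
            kv = dict(p.partition("=")[::2] for p in info.split(";") if "=" in p)
            common = dict(
                mutation_id=vid,
                sample_id=kv.get("SAMPLE", ""),
                gene_symbol=chrom,
                population=kv.get("POP", ""),
                expressed_read_count=int(kv.get("READS", 0)),
            )
            pos = int(pos)
            if len(ref) == 1 and len(alt) == 1:
                muts.append(SomaticMutation(
                    cds_pos=pos, mutation_type="SNV", ref_base=ref.upper(),
                    alt_base=alt.upper(), **common))
            elif len(ref) == 1 and len(alt) > 1 and alt[0] == ref[0]:
                muts.append(SomaticMutation(
                    cds_pos=pos, mutation_type="INS", inserted_seq=alt[1:].upper(), **common))
            elif len(alt) == 1 and len(ref) > 1 and ref[0] == alt[0]:
                muts.append(SomaticMutation(
                    cds_pos=pos + 1, mutation_type="DEL", del_length=len(ref) - 1, **common))
            else:
                raise CohortFormatError(
                    f"{path}, line {line_no}: REF/ALT pair {ref}/{alt} is neither an SNV "
                    "nor a left-anchored indel"
                )
    return muts


def read_expression_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene"
    return df


def read_hla_tsv(path) -> dict[str, list[str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        out.setdefault(row["sample_id"], []).append(row["allele"])
    return out


def read_clonotypes_tsv(path) -> dict[str, dict[str, int]]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "clonotype_id": str, "count": int})
    out: dict[str, dict[str, int]] = {}
    for _, row in df.iterrows():
        out.setdefault(row["sample_id"], {})[row["clonotype_id"]] = int(row["count"])
    return out


def read_msi_tsv(path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "score": float})
    return dict(zip(df["sample_id"], df["score"]))


def read_samples_tsv(path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return list(zip(df["sample_id"], df["population"]))


def load_cohort(
    gene_fasta,
    mutations_tsv,
    samples_tsv=None,
    expression_tsv=None,
    hla_tsv=None,
    clonotypes_tsv=None,
    msi_tsv=None,
    config: Optional[AnalysisConfig] = None,
    strict: bool = True,
) -> Cohort:
    """Load and cross-validate a cohort from the plain-text dialects.

    When ``samples_tsv`` is omitted the sample list is inferred from the
    mutation table (sorted by sample id). With ``strict`` (default) any
    invariant violation raises; otherwise violations are attached to the
    returned cohort as ``cohort.violations``.
    """
    genes = read_gene_fasta(gene_fasta)
    mutations = read_mutations_tsv(mutations_tsv)
    if samples_tsv is not None:
        samples = read_samples_tsv(samples_tsv)
    else:
        seen: dict[str, str] = {}
        for m in mutations:
            seen.setdefault(m.sample_id, m.population)
        samples = sorted(seen.items())
    cohort = Cohort(
        samples=samples,
        mutations=mutations,
        gene_models=genes,
        expression=read_expression_tsv(expression_tsv) if expression_tsv else None,
        hla=read_hla_tsv(hla_tsv) if hla_tsv else None,
        clonotypes=read_clonotypes_tsv(clonotypes_tsv) if clonotypes_tsv else None,
        msi_scores=read_msi_tsv(msi_tsv) if msi_tsv else None,
    )
    violations = validate_cohort(cohort)
    if violations and strict:
        head = "; ".join(str(v) for v in violations[:5])
        raise CohortFormatError(
            f"cohort failed validation with {len(violations)} violation(s): {head}"
        )
    cohort.violations = violations  # type: ignore[attr-defined]
    return cohort


def _mutation_row(m: SomaticMutation, genes: dict[str, GeneModel]) -> dict:
    if m.mutation_type == "SNV":
        ref, alt = m.ref_base, m.alt_base
    elif m.mutation_type == "INS":
        ref, alt = "-", m.inserted_seq
    else:
        g = genes.get(m.gene_symbol)
        deleted = (
            g.cds_sequence[m.cds_pos - 1 : m.cds_pos - 1 + m.del_length]
            if g is not None else "N" * m.del_length
        )
        ref, alt = deleted, "-"
    row = {
        "mutation_id": m.mutation_id, "sample_id": m.sample_id, "gene": m.gene_symbol,
        "cds_pos": m.cds_pos, "type": m.mutation_type, "ref": ref, "alt": alt,
        "population": m.population, "expressed_reads": m.expressed_read_count,
    }
    labels = m.impact_labels or ("", "", "")
    row.update(impact1=labels[0], impact2=labels[1], impact3=labels[2])
    row["consequence_override"] = m.consequence_override or ""
    return row


def write_tables(cohort: Cohort, out_dir) -> dict[str, str]:
    """Write the cohort in the dialects accepted by :func:`load_cohort`.

    Row order is deterministic (sample id then mutation id) so two
    writes of the same cohort are byte-identical. Returns a manifest
    mapping logical names to paths.
    """
    out_dir = Path(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    manifest: dict[str, str] = {}

    genes_path = out_dir / "genes.fasta"
    write_gene_fasta(cohort.gene_models, genes_path)
    manifest["genes"] = str(genes_path)

    rows = sorted(
        (_mutation_row(m, cohort.gene_models) for m in cohort.mutations),
        key=lambda r: (r["sample_id"], r["mutation_id"]),
    )
    mut_path = out_dir / "mutations.tsv"
    pd.DataFrame(rows, columns=MUTATION_COLUMNS + OPTIONAL_MUTATION_COLUMNS).to_csv(
        mut_path, sep="\t", index=False)
    manifest["mutations"] = str(mut_path)

    samples_path = out_dir / "samples.tsv"
    pd.DataFrame(cohort.samples, columns=["sample_id", "population"]).to_csv(
        samples_path, sep="\t", index=False)
    manifest["samples"] = str(samples_path)

    if cohort.expression is not None:
        p = out_dir / "expression.tsv"
        cohort.expression.to_csv(p, sep="\t")
        manifest["expression"] = str(p)
    if cohort.hla is not None:
        p = out_dir / "hla.tsv"
        pd.DataFrame(
            [(s, a) for s in sorted(cohort.hla) for a in cohort.hla[s]],
            columns=["sample_id", "allele"],
        ).to_csv(p, sep="\t", index=False)
        manifest["hla"] = str(p)
    if cohort.clonotypes is not None:
        p = out_dir / "clonotypes.tsv"
        pd.DataFrame(
            [(s, c, n) for s in sorted(cohort.clonotypes)
             for c, n in sorted(cohort.clonotypes[s].items())],
            columns=["sample_id", "clonotype_id", "count"],
        ).to_csv(p, sep="\t", index=False)
        manifest["clonotypes"] = str(p)
    if cohort.msi_scores is not None:
        p = out_dir / "msi.tsv"
        pd.DataFrame(
            sorted(cohort.msi_scores.items()), columns=["sample_id", "score"]
        ).to_csv(p, sep="\t", index=False)
        manifest["msi"] = str(p)
    return manifest


def load_cohort_from_manifest(manifest: dict[str, str], **kwargs) -> Cohort:
    return load_cohort(
        manifest["genes"], manifest["mutations"],
        samples_tsv=manifest.get("samples"),
        expression_tsv=manifest.get("expression"),
        hla_tsv=manifest.get("hla"),
        clonotypes_tsv=manifest.get("clonotypes"),
        msi_tsv=manifest.get("msi"),
        **kwargs,
    )
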