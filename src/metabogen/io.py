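"""Readers and writers for the pipeline's on-disk formats.

VCF carries genotypes with DP/GQ/AB FORMAT fields (parsed back with pysam);
traits, covariates, annotations and summary statistics travel as TSV with
GWAS-SSF-compatible column names; gene sets as GMT; truth tables as JSON.
Regions are written as BED (0-based half-open on disk, 1-based inclusive in
memory).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .simulate import MISSING, GenotypeData

SSF_COLUMNS = [
    "variant_id",
    "chromosome",
    "base_pair_location",
    "effect_allele",
    "other_allele",
    "trait",
    "stratum",
    "beta",
    "standard_error",
    "p_value",
    "effect_allele_frequency",
    "n",
]


def write_vcf(
    path: str | Path,
    genotypes: np.ndarray,
    variants: pd.DataFrame,
    sample_ids: list[str] | None = None,
    dp: np.ndarray | None = None,
    gq: np.ndarray | None = None,
    ab: np.ndarray | None = None,
) -> None:
    """Write an uncompressed VCF with GT (and optional DP/GQ/AB) FORMAT fields."""
    n, m = genotypes.shape
    if sample_ids is None:
        sample_ids = [f"sample{i:05d}" for i in range(n)]
    fmt_fields = ["GT"]
    if dp is not None:
        fmt_fields.append("DP")
    if gq is not None:
        fmt_fields.append("GQ")
    if ab is not None:
        fmt_fields.append("AB")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in sorted(variants["chrom"].unique()):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if dp is not None:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        if gq is not None:
            fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        if ab is not None:
            fh.write('##FORMAT=<ID=AB,Number=1,Type=Float,Description="Allele balance">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids) + "\n")
        gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for j, row in enumerate(variants.itertuples()):
            fields = [
                str(row.chrom),
                str(int(row.pos)),
                str(row.variant_id),
                str(row.ref),
                str(row.alt),
                ".",
                "PASS",
                ".",
                ":".join(fmt_fields),
            ]
            for i in range(n):
                call = [gt_strings[int(genotypes[i, j])]]
                if dp is not None:
                    call.append(str(int(dp[i, j])))
                if gq is not None:
                    call.append(str(int(gq[i, j])))
                if ab is not None:
                    call.append(f"{float(ab[i, j]):.3f}")
                fields.append(":".join(call))
            fh.write("\t".join(fields) + "\n")


def read_vcf_qc(path: str | Path):
    """Read a VCF with DP/GQ/AB FORMAT fields back into arrays.

    Returns (genotypes, dp, gq, ab, variants) with the same conventions as
    the generators: genotypes in {0,1,2,MISSING}, variants carrying an
    ``is_indel`` column inferred from allele lengths.
    """
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    gts, dps, gqs, abs_, rows = [], [], [], [], []
    for rec in vf:
        g_row, d_row, q_row, a_row = [], [], [], []
        for s in samples:
            call = rec.samples[s]
            alleles = call["GT"]
            if alleles is None or any(a is None for a in alleles):
                g_row.append(MISSING)
            else:
                g_row.append(sum(alleles))
            d_row.append(call.get("DP", 0) or 0)
            q_row.append(call.get("GQ", 0) or 0)
            a_row.append(call.get("AB", 0.0) or 0.0)
        gts.append(g_row)
        dps.append(d_row)
        gqs.append(q_row)
        abs_.append(a_row)
        alt = rec.alts[0] if rec.alts else rec.ref
        rows.append(
            {
                "variant_id": rec.id,
                "chrom": rec.chrom,
                "pos": rec.pos,
                "ref": rec.ref,
                "alt": alt,
                "is_indel": len(rec.ref) != len(alt),
            }
        )
    variants = pd.DataFrame(rows)
    gt = np.array(gts, dtype=np.int8).T  # samples x variants
    return gt, np.array(dps).T, np.array(gqs).T, np.array(abs_, dtype=float).T, variants


def write_summary_stats(path: str | Path, records: pd.DataFrame) -> None:
    """Write scan/meta output with GWAS-SSF-compatible column names."""
    df = records.rename(
        columns={
            "chrom": "chromosome",
            "pos": "base_pair_location",
            "alt": "effect_allele",
            "ref": "other_allele",
            "trait_id": "trait",
            "se": "standard_error",
            "p": "p_value",
            "af": "effect_allele_frequency",
        }
    )
    cols = [c for c in SSF_COLUMNS if c in df.columns] + [
        c for c in df.columns if c not in SSF_COLUMNS
    ]
    df[cols].to_csv(path, sep="\t", index=False)


def read_summary_stats(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df.rename(
        columns={
            "chromosome": "chrom",
            "base_pair_location": "pos",
            "effect_allele": "alt",
            "other_allele": "ref",
            "trait": "trait_id",
            "standard_error": "se",
            "p_value": "p",
            "effect_allele_frequency": "af",
        }
    )


def write_regions_bed(path: str | Path, regions) -> None:
    """Regions to BED: 0-based half-open intervals on disk."""
    with open(path, "w") as fh:
        for r in regions:
            name = "MHC" if r.is_mhc else ",".join(r.sentinels) or "."
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{name}\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT gene sets: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = set(parts[2:])
    return sets


def write_gmt(path: str | Path, gene_sets: dict[str, set[str]]) -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, name] + sorted(genes)) + "\n")


def write_truth(path: str | Path, truth) -> None:
    """Truth tables (DataFrame or dict) to JSON."""
    if isinstance(truth, pd.DataFrame):
        truth = truth.to_dict(orient="records")
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, default=lambda o: o.tolist() if hasattr(o, "tolist") else o)


def write_cohort(out_dir: str | Path, gt: GenotypeData, panel=None, med=None, ann=None) -> None:
    """Dump a simulated cohort: VCF, trait/covariate TSVs, truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    kwargs = {}
    if ann is not None:
        kwargs = {"dp": ann.dp, "gq": ann.gq, "ab": ann.ab}
    write_vcf(out / "genotypes.vcf", gt.genotypes, gt.variants, **kwargs)
    gt.variants.to_csv(out / "variants.tsv", sep="\t", index=False)
    pd.DataFrame({"sample_id": [f"sample{i:05d}" for i in range(gt.n)], "stratum": gt.strata}).to_csv(
        out / "covariates.tsv", sep="\t", index=False
    )
    if panel is not None:
        panel.traits.to_csv(out / "traits.tsv", sep="\t", index=False)
        write_truth(out / "truth_effects.json", panel.truth)
    if med is not None:
        med.baseline.assign(treated=med.treated).to_csv(out / "traits_baseline.tsv", sep="\t", index=False)
    if ann is not None:
        ann.annotations.to_csv(out / "annotations.tsv", sep="\t", index=False)
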