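"""Readers and writers for the plain-text interchange formats of the
pipeline: MAF-like variant TSV, minimal single-sample VCF v4.2 with AD,
SEG-like copy-number TSV, counts TSV/MTX, GMT gene sets and JSON truth
files.  All genomic coordinates in these files are 1-based inclusive."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

VCF_HEADER = """##fileformat=VCFv4.2
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence">
"""


def write_variants_tsv(variants: pd.DataFrame, path) -> None:
    variants.to_csv(path, sep="\t", index=False)


def read_variants_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_variants_vcf(variants: pd.DataFrame, path) -> None:
    """Minimal single-sample-per-record VCF v4.2 with an AD sample field."""
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE\n")
        for row in variants.itertuples(index=False):
            ref = int(row.total_reads) - int(row.alt_reads)
            info = f"GENE={row.gene};CSQ={row.consequence}"
            fh.write(f"{row.chrom}\t{int(row.pos)}\t{row.sample}\tN\tA\t.\tPASS\t"
                     f"{info}\tAD\t{ref},{int(row.alt_reads)}\n")


def read_variants_vcf(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            chrom, pos, vid, _, _, _, _, info, fmt, sample = line.rstrip("\n").split("\t")
            fields = dict(kv.split("=", 1) for kv in info.split(";") if "=" in kv)
            keys = fmt.split(":")
            vals = sample.split(":")
            ad = vals[keys.index("AD")].split(",")
            ref, alt = int(ad[0]), int(ad[1])
            rows.append({"sample": vid, "chrom": chrom, "pos": int(pos),
                         "gene": fields.get("GENE", ""),
                         "consequence": fields.get("CSQ", "other"),
                         "alt_reads": alt, "total_reads": ref + alt})
    return pd.DataFrame(rows)


def write_segments(segments: pd.DataFrame, path) -> None:
    segments.to_csv(path, sep="\t", index=False)


def read_segments(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_gene_models_bed(path) -> pd.DataFrame:
    """BED-like gene models (0-based half-open on disk), returned 1-based
    inclusive to match every other interface."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "gene"])
    df["start"] = df["start"] + 1
    return df


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


def read_counts(path) -> pd.DataFrame:
    """Genes x samples counts from TSV (gene column or index) or MatrixMarket
    ``.mtx`` (with ``<stem>.genes.txt`` / ``<stem>.samples.txt`` sidecars)."""
    path = Path(path)
    if path.suffix == ".mtx":
        from scipy.io import mmread
        mat = np.asarray(mmread(path).todense())
        genes = Path(str(path)[:-4] + ".genes.txt").read_text().split()
        samples = Path(str(path)[:-4] + ".samples.txt").read_text().split()
        return pd.DataFrame(mat, index=genes, columns=samples)
    return pd.read_csv(path, sep="\t", index_col=0)


def read_gmt(path) -> dict:
    """GMT gene sets: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(gene_sets: dict, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonify(truth), fh, indent=1, sort_keys=True)


def read_truth(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
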