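"""Readers and writers for the pipeline's on-disk formats.

Diagnostic sites travel as VCF (N allele as REF, S allele as ALT,
1-based positions) or TSV; pool pileups as TSV (scaffold, pos, depth,
s_count) or VCF with per-pool AD-style allele depths; haplotypes as
FASTA; window statistics as BED; dose-response tables and cohort counts
as CSV.
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VCF_HEADER = """##fileformat=VCFv4.2
##source=symbiostrain
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene id overlapping the site">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_sites_vcf(sites: pd.DataFrame, path: str | os.PathLike) -> None:
    """Diagnostic sites as a minimal VCF (REF = N allele, ALT = S allele)."""
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        for row in sites.itertuples():
            gene = getattr(row, "gene_id", "") or ""
            info = f"GENE={gene}" if gene else "."
            fh.write(
                f"{row.scaffold}\t{row.pos}\t.\t{row.n_allele}\t{row.s_allele}"
                f"\t.\tPASS\t{info}\n"
            )


def read_sites_vcf(path: str | os.PathLike) -> pd.DataFrame:
    """Diagnostic-site table from a biallelic-SNP VCF (via cyvcf2)."""
    from cyvcf2 import VCF

    rows = []
    for v in VCF(str(path)):
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            continue
        gene = v.INFO.get("GENE") or ""
        rows.append((v.CHROM, v.POS, v.REF, v.ALT[0], gene))
    return pd.DataFrame(rows, columns=["scaffold", "pos", "n_allele", "s_allele", "gene_id"])


def write_sites_tsv(sites: pd.DataFrame, path: str | os.PathLike) -> None:
    sites.to_csv(path, sep="\t", index=False)


def read_sites_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"scaffold": str})


def write_pileup_tsv(pileup: pd.DataFrame, path: str | os.PathLike) -> None:
    pileup.to_csv(path, sep="\t", index=False)


def read_pileup_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"scaffold": str})


def write_fasta(sequences: dict[str, str], path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_windows_bed(windows: pd.DataFrame, path: str | os.PathLike, value_col: str) -> None:
    """Window statistics as BED: chrom, start (0-based), end, value, n."""
    count_col = "n_sites" if "n_sites" in windows else "n_pairs"
    windows[["scaffold", "start", "end", value_col, count_col]].to_csv(
        path, sep="\t", index=False, header=False
    )


def read_peaks_tsv(path: str | os.PathLike) -> pd.DataFrame:
    """Chromatogram peak-height table (individual, fragment, scaffold,
    pos, height_n, height_s)."""
    return pd.read_csv(path, sep="\t", dtype={"scaffold": str, "individual": str})


def read_dose_response_csv(path: str | os.PathLike) -> pd.DataFrame:
    """Bioassay table with columns concentration, n, dead (replicate
    optional)."""
    df = pd.read_csv(path)
    required = {"concentration", "n", "dead"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"dose-response table missing columns: {sorted(missing)}")
    return df


def read_gene_models_gff(path: str | os.PathLike) -> list:
    """CDS features of a GFF3 file as GeneModel objects (via gffutils)."""
    import gffutils

    from .effects import GeneModel

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for feat in db.features_of_type("CDS"):
        gene_id = (
            feat.attributes.get("ID", [feat.id])[0]
            if feat.attributes
            else feat.id
        )
        genes.append(
            GeneModel(
                gene_id=gene_id,
                scaffold=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
            )
        )
    return genes


def read_term_memberships_tsv(path: str | os.PathLike) -> pd.DataFrame:
    """Flat gene-to-category table with columns (gene, term)."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene", "term"} <= set(df.columns):
        raise ValueError("membership table needs columns 'gene' and 'term'")
    return df


def ensure_dir(path: str | os.PathLike) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
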