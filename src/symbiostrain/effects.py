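"""Coding consequences of strain-diagnostic SNPs and category enrichment.

Classifies each fixed difference between the two symbiont haplotypes by
its effect on the annotated protein — synonymous, missense, start lost,
stop lost, or stop gained (a premature termination codon, PTC, when the
new stop falls strictly before the annotated final codon) — using the
bacterial genetic code (translation table 11, with GTG/TTG accepted as
alternative start codons translated as M). Gene categories carrying an
excess of affected genes are detected by two-sided Fisher exact tests
with Benjamini–Hochberg adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

BACTERIAL_TABLE = unambiguous_dna_by_id[11]
START_CODONS = ("ATG", "GTG", "TTG")

CATEGORIES = (
    "synonymous",
    "missense",
    "start_lost",
    "stop_lost",
    "stop_gained",
    "intergenic",
)


@dataclass(frozen=True)
class GeneModel:
    """A single-CDS bacterial gene model (1-based inclusive coordinates)."""

    gene_id: str
    scaffold: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        if self.end < self.start:
            raise ValueError("end < start")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, scaffold: str, pos: int) -> bool:
        return scaffold == self.scaffold and self.start <= pos <= self.end

    def cds_sequence(self, reference: dict[str, str]) -> str:
        seq = reference[self.scaffold][self.start - 1 : self.end]
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq


@dataclass
class SnpEffect:
    """Consequence of one substitution on one gene (or intergenic)."""

    scaffold: str
    pos: int
    ref_allele: str
    alt_allele: str
    category: str
    gene_id: str | None = None
    codon_change: str | None = None
    protein_pos: int | None = None
    aa_change: str | None = None


def translate_codon(codon: str, is_first: bool = False) -> str:
    """One codon to one amino acid under table 11; '*' for stop.

    The first codon of a CDS translates to M when it is any accepted
    bacterial start codon.
    """
    codon = codon.upper()
    if is_first and codon in START_CODONS:
        return "M"
    if codon in BACTERIAL_TABLE.stop_codons:
        return "*"
    return BACTERIAL_TABLE.forward_table[codon]


def classify_snp_effect(
    scaffold: str,
    pos: int,
    ref_allele: str,
    alt_allele: str,
    genes: list[GeneModel],
    reference: dict[str, str],
) -> SnpEffect:
    """Assign a coding-consequence category to one substitution.

    The affected codon is translated before and after the substitution
    on the coding strand (reverse-complementing for minus-strand genes).
    Category logic: codon 1 losing its start-codon status is
    ``start_lost``; the annotated final (stop) codon becoming non-stop is
    ``stop_lost``; an internal codon becoming a stop is ``stop_gained``
    (a premature termination codon); otherwise missense or synonymous by
    the amino-acid diff. Sites outside every CDS are ``intergenic``.
    """
    if reference[scaffold][pos - 1].upper() != ref_allele.upper():
        raise ValueError(
            f"reference mismatch at {scaffold}:{pos}: "
            f"sequence has {reference[scaffold][pos - 1]}, site table says {ref_allele}"
        )
    hit = next((g for g in genes if g.contains(scaffold, pos)), None)
    if hit is None:
        return SnpEffect(scaffold, pos, ref_allele, alt_allele, "intergenic")
    if hit.length % 3 != 0:
        raise ValueError(f"CDS of {hit.gene_id} is not a multiple of 3")
    cds = hit.cds_sequence(reference).upper()
    if hit.strand == "+":
        offset = pos - hit.start
        ref_base, alt_base = ref_allele.upper(), alt_allele.upper()
    else:
        offset = hit.end - pos
        ref_base = str(Seq(ref_allele).reverse_complement())
        alt_base = str(Seq(alt_allele).reverse_complement())
    if cds[offset] != ref_base:
        raise ValueError(f"CDS/reference inconsistency in {hit.gene_id}")
    codon_idx = offset // 3
    within = offset % 3
    codon_ref = cds[3 * codon_idx : 3 * codon_idx + 3]
    codon_alt = codon_ref[:within] + alt_base + codon_ref[within + 1 :]
    n_codons = hit.length // 3
    is_first = codon_idx == 0
    is_last = codon_idx == n_codons - 1

    if is_first and codon_ref in START_CODONS:
        category = "synonymous" if codon_alt in START_CODONS else "start_lost"
        aa_ref, aa_alt = "M", ("M" if codon_alt in START_CODONS else translate_codon(codon_alt))
    else:
        aa_ref = translate_codon(codon_ref)
        aa_alt = translate_codon(codon_alt)
        if aa_ref == "*" and aa_alt != "*":
            category = "stop_lost"
        elif aa_ref != "*" and aa_alt == "*":
            # a stop at the annotated final codon is not premature
            category = "stop_gained" if not is_last else "synonymous"
        elif aa_ref == aa_alt:
            category = "synonymous"
        else:
            category = "missense"
    return SnpEffect(
        scaffold=scaffold,
        pos=pos,
        ref_allele=ref_allele,
        alt_allele=alt_allele,
        category=category,
        gene_id=hit.gene_id,
        codon_change=f"{codon_ref}>{codon_alt}",
        protein_pos=codon_idx + 1,
        aa_change=f"{aa_ref}{codon_idx + 1}{aa_alt}",
    )


def classify_sites(
    sites: pd.DataFrame, genes: list[GeneModel], reference: dict[str, str]
) -> list[SnpEffect]:
    """Classify every row of a diagnostic-site table."""
    return [
        classify_snp_effect(
            row.scaffold, int(row.pos), row.n_allele, row.s_allele, genes, reference
        )
        for row in sites.itertuples()
    ]


def effect_summary(effects: list[SnpEffect]) -> dict[str, int]:
    """Counts per consequence category plus derived totals.

    ``exon_snps`` counts substitutions inside any CDS; ``ptc_snps`` the
    stop-gained substitutions and ``ptc_genes`` the genes carrying at
    least one of them (both are reported because either can be meant by
    a "premature termination codon" tally).
    """
    counts = {c: 0 for c in CATEGORIES}
    ptc_genes = set()
    for e in effects:
        counts[e.category] += 1
        if e.category == "stop_gained":
            ptc_genes.add(e.gene_id)
    summary = {
        "total_snps": len(effects),
        "exon_snps": len(effects) - counts["intergenic"],
        "synonymous": counts["synonymous"],
        "missense": counts["missense"],
        "start_lost": counts["start_lost"],
        "stop_lost": counts["stop_lost"],
        "ptc_snps": counts["stop_gained"],
        "ptc_genes": len(ptc_genes),
        "intergenic": counts["intergenic"],
    }
    return summary


def fisher_bh_enrichment(
    hits: set[str] | list[str],
    background: set[str] | list[str],
    memberships: pd.DataFrame,
) -> pd.DataFrame:
    """Per-term two-sided Fisher exact enrichment with BH adjustment.

    ``memberships`` has columns (gene, term); ``hits`` must be a subset
    of ``background``. For each term the 2x2 table is
    (hits in term, hits not in term, non-hits in term, non-hits not in
    term); P values are adjusted across all tested terms and the result
    is sorted by adjusted P.
    """
    hits = set(hits)
    background = set(background)
    if not background:
        raise ValueError("empty background gene set")
    if not hits <= background:
        raise ValueError("hits must be a subset of the background")
    non_hits = background - hits
    rows = []
    for term, grp in memberships.groupby("term", sort=True):
        members = set(grp["gene"]) & background
        a = len(hits & members)
        b = len(hits - members)
        c = len(non_hits & members)
        d = len(non_hits - members)
        _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append((term, a, b, c, d, float(p)))
    out = pd.DataFrame(
        rows,
        columns=["term", "hits_in", "hits_out", "nonhits_in", "nonhits_out", "p_value"],
    )
    if len(out) == 0:
        raise ValueError("no terms to test")
    out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out.sort_values("p_adjusted", kind="mergesort").reset_index(drop=True)
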