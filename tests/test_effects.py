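"""SNP consequence classification against a whole-protein-diff oracle,
Table-style summaries, and Fisher/BH enrichment against enumeration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy.stats import hypergeom

import symbiostrain as st
from symbiostrain.effects import (
    BACTERIAL_TABLE,
    START_CODONS,
    classify_sites,
    translate_codon,
)

AA = {"A": 0}  # placeholder to keep imports tidy


def make_gene(codons, scaffold="s1", start=1, strand="+", gene_id="g1", pad=("", "")):
    """Reference dict + GeneModel from a list of codons (coding strand)."""
    cds = "".join(codons)
    if strand == "-":
        from Bio.Seq import Seq

        genomic = str(Seq(cds).reverse_complement())
    else:
        genomic = cds
    seq = pad[0] + genomic + pad[1]
    gene = st.GeneModel(
        gene_id=gene_id,
        scaffold=scaffold,
        start=start + len(pad[0]),
        end=start + len(pad[0]) + len(cds) - 1,
        strand=strand,
    )
    return {scaffold: seq}, gene


def translate_cds(cds):
    """Independent oracle: translate a whole CDS codon by codon,
    table 11, first codon forced to M when it is a start codon."""
    aas = []
    for i in range(0, len(cds), 3):
        aas.append(translate_codon(cds[i : i + 3], is_first=(i == 0)))
    return "".join(aas)


def oracle_category(cds_ref, cds_alt):
    """Classify by diffing the full translated proteins."""
    p_ref, p_alt = translate_cds(cds_ref), translate_cds(cds_alt)
    if p_ref == p_alt:
        return "synonymous"
    n = len(p_ref)
    diffs = [i for i in range(n) if p_ref[i] != p_alt[i]]
    (i,) = diffs
    if i == 0 and p_ref[0] == "M" and cds_ref[:3] in START_CODONS:
        return "start_lost" if cds_alt[:3] not in START_CODONS else "missense"
    if p_ref[i] == "*" and p_alt[i] != "*":
        return "stop_lost"
    if p_alt[i] == "*" and i < n - 1:
        return "stop_gained"
    if p_alt[i] == "*":
        return "stop_gained_terminal"  # never produced: stop at final codon
    return "missense"


class TestClassifySnpEffect:
    def test_internal_stop_gain_is_ptc(self):
        ref, gene = make_gene(["ATG", "CAG", "TAA"])
        eff = st.classify_snp_effect("s1", 4, "C", "T", [gene], ref)
        assert eff.category == "stop_gained"
        assert eff.codon_change == "CAG>TAG"
        assert eff.protein_pos == 2

    def test_start_codon_lost(self):
        ref, gene = make_gene(["ATG", "AAA", "TAA"])
        eff = st.classify_snp_effect("s1", 2, "T", "C", [gene], ref)
        assert eff.category == "start_lost"

    def test_alternative_start_retained_is_synonymous(self):
        ref, gene = make_gene(["ATG", "AAA", "TAA"])
        eff = st.classify_snp_effect("s1", 1, "A", "G", [gene], ref)  # ATG->GTG
        assert eff.category == "synonymous"

    def test_stop_lost_at_final_codon(self):
        ref, gene = make_gene(["ATG", "AAA", "TAA"])
        eff = st.classify_snp_effect("s1", 9, "A", "C", [gene], ref)  # TAA->TAC
        assert eff.category == "stop_lost"

    def test_intergenic_site(self):
        ref, gene = make_gene(["ATG", "AAA", "TAA"], pad=("", "GGGG"))
        eff = st.classify_snp_effect("s1", 11, "G", "A", [gene], ref)
        assert eff.category == "intergenic" and eff.gene_id is None

    def test_minus_strand_gene(self):
        ref, gene = make_gene(["ATG", "CAG", "TAA"], strand="-")
        # genomic is revcomp of ATGCAGTAA = TTACTGCAT; coding C of codon 2
        # (CAG, offset 3) sits at genomic position end-3 = 6 (base G)
        eff = st.classify_snp_effect("s1", 6, "G", "A", [gene], ref)  # C->T coding
        assert eff.category == "stop_gained"
        assert eff.codon_change == "CAG>TAG"

    def test_frame_violation_names_gene(self):
        ref = {"s1": "ATGAAAT"}
        gene = st.GeneModel("broken", "s1", 1, 7, "+")
        with pytest.raises(ValueError, match="broken"):
            st.classify_snp_effect("s1", 2, "T", "C", [gene], ref)

    def test_reference_mismatch_rejected(self):
        ref, gene = make_gene(["ATG", "AAA", "TAA"])
        with pytest.raises(ValueError, match="mismatch"):
            st.classify_snp_effect("s1", 4, "G", "T", [gene], ref)

    def test_agrees_with_whole_protein_diff_oracle(self):
        # 1,000 random genes x one random substitution each
        rng = np.random.default_rng(7)
        bases = np.array(list("ACGT"))
        sense = [c for c in BACTERIAL_TABLE.forward_table]
        stops = BACTERIAL_TABLE.stop_codons
        checked = 0
        for _ in range(1000):
            n_codons = rng.integers(3, 30)
            codons = ["ATG"] + [sense[rng.integers(len(sense))] for _ in range(n_codons - 2)]
            codons.append(stops[rng.integers(len(stops))])
            cds = "".join(codons)
            off = int(rng.integers(len(cds)))
            alt = str(rng.choice(bases[bases != cds[off]]))
            cds_alt = cds[:off] + alt + cds[off + 1 :]
            strand = "+" if rng.random() < 0.5 else "-"
            ref, gene = make_gene(codons, strand=strand, pad=("AC", "GT"))
            if strand == "+":
                pos = gene.start + off
                g_ref, g_alt = cds[off], alt
            else:
                from Bio.Seq import Seq

                pos = gene.end - off
                g_ref = str(Seq(cds[off]).reverse_complement())
                g_alt = str(Seq(alt).reverse_complement())
            eff = st.classify_snp_effect("s1", pos, g_ref, g_alt, [gene], ref)
            expected = oracle_category(cds, cds_alt)
            if expected == "stop_gained_terminal":
                continue
            assert eff.category == expected, (cds, off, alt, strand)
            checked += 1
        assert checked > 900

    def test_strand_symmetry(self):
        # reverse-complementing the scaffold and flipping strand keeps
        # every category
        rng = np.random.default_rng(8)
        sense = [c for c in BACTERIAL_TABLE.forward_table]
        from Bio.Seq import Seq

        for _ in range(50):
            codons = ["ATG"] + [sense[rng.integers(len(sense))] for _ in range(5)] + ["TGA"]
            ref, gene = make_gene(codons, pad=("AAC", "CCA"))
            L = len(ref["s1"])
            ref_rc = {"s1": str(Seq(ref["s1"]).reverse_complement())}
            gene_rc = st.GeneModel(
                gene.gene_id, "s1", L - gene.end + 1, L - gene.start + 1, "-"
            )
            off = int(rng.integers(len("".join(codons))))
            pos = gene.start + off
            base = ref["s1"][pos - 1]
            alt = str(rng.choice(np.array([b for b in "ACGT" if b != base])))
            eff_fwd = st.classify_snp_effect("s1", pos, base, alt, [gene], ref)
            pos_rc = L - pos + 1
            eff_rev = st.classify_snp_effect(
                "s1",
                pos_rc,
                str(Seq(base).reverse_complement()),
                str(Seq(alt).reverse_complement()),
                [gene_rc],
                ref_rc,
            )
            assert eff_fwd.category == eff_rev.category


class TestEffectSummary:
    def test_crafted_ptc_counts(self):
        # 10 SNPs, 3 PTCs in 2 genes, by construction
        effects = []
        ref1, g1 = make_gene(["ATG", "CAG", "CAA", "TAA"], gene_id="g1")
        for pos, alt in [(4, "T"), (7, "T")]:  # CAG->TAG, CAA->TAA
            effects.append(st.classify_snp_effect("s1", pos, "C", "T", [g1], ref1))
        ref2, g2 = make_gene(["ATG", "GAA", "AAA", "TAA"], gene_id="g2")
        effects.append(st.classify_snp_effect("s1", 4, "G", "T", [g2], ref2))  # GAA->TAA
        # plus some non-PTC effects
        effects.append(st.classify_snp_effect("s1", 5, "A", "T", [g2], ref2))  # missense
        ref3, g3 = make_gene(["ATG", "AAA", "TAA"], gene_id="g3", pad=("", "GG"))
        effects.append(st.classify_snp_effect("s1", 10, "G", "A", [g3], ref3))
        summary = st.effect_summary(effects)
        assert summary["ptc_snps"] == 3
        assert summary["ptc_genes"] == 2
        assert summary["missense"] == 1
        assert summary["intergenic"] == 1
        assert summary["exon_snps"] == 4

    def test_empty_input_all_zero(self):
        summary = st.effect_summary([])
        assert summary["total_snps"] == 0
        assert all(
            summary[k] == 0
            for k in ("exon_snps", "missense", "ptc_snps", "ptc_genes")
        )


def fisher_two_sided_oracle(a, b, c, d):
    """Two-sided Fisher P by hypergeometric enumeration: sum the
    probabilities of all tables as or less probable than observed."""
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    rv = hypergeom(n, row1, col1)
    p_obs = rv.pmf(a)
    total = 0.0
    for k in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        pk = rv.pmf(k)
        if pk <= p_obs * (1 + 1e-9):
            total += pk
    return min(total, 1.0)


class TestEnrichment:
    def _memberships(self, term_genes):
        rows = [(g, t) for t, genes in term_genes.items() for g in genes]
        return pd.DataFrame(rows, columns=["gene", "term"])

    def test_identical_proportions_give_p_one(self):
        background = {f"g{i}" for i in range(20)}
        hits = {"g0", "g1", "g2", "g3", "g4"}  # 25% of background
        # term contains 25% of hits and 25% of non-hits
        member = self._memberships({"T": {"g0", "g5", "g6", "g7", "g8"}})
        res = st.fisher_bh_enrichment(hits, background, member)
        assert res["p_value"].iloc[0] == pytest.approx(1.0)

    def test_matches_hypergeometric_enumeration(self):
        a, b, c, d = 8, 2, 2, 88
        hits = {f"h{i}" for i in range(a + b)}
        nonhits = {f"n{i}" for i in range(c + d)}
        in_term = {f"h{i}" for i in range(a)} | {f"n{i}" for i in range(c)}
        member = self._memberships({"T": in_term})
        res = st.fisher_bh_enrichment(hits, hits | nonhits, member)
        assert res["p_value"].iloc[0] == pytest.approx(
            fisher_two_sided_oracle(a, b, c, d), rel=1e-9
        )

    def test_single_term_bh_identity(self):
        member = self._memberships({"T": {"g0", "g1"}})
        res = st.fisher_bh_enrichment({"g0"}, {f"g{i}" for i in range(10)}, member)
        assert res["p_adjusted"].iloc[0] == res["p_value"].iloc[0]

    def test_hits_must_be_subset(self):
        with pytest.raises(ValueError):
            st.fisher_bh_enrichment({"x"}, {"a"}, self._memberships({"T": {"a"}}))

    @given(
        ps=hst.lists(hst.floats(0, 1, allow_nan=False), min_size=1, max_size=30)
    )
    @settings(deadline=None, max_examples=100)
    def test_bh_monotone_step_function(self, ps):
        from statsmodels.stats.multitest import multipletests

        adj = multipletests(ps, method="fdr_bh")[1]
        order = np.argsort(ps, kind="mergesort")
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        assert np.all(adj <= 1.0 + 1e-12)

    def test_adjusted_monotone_in_rank_on_real_call(self):
        background = {f"g{i}" for i in range(40)}
        hits = {f"g{i}" for i in range(8)}
        member = self._memberships(
            {
                "T1": {f"g{i}" for i in range(6)},
                "T2": {f"g{i}" for i in range(3, 20)},
                "T3": {f"g{i}" for i in range(20, 40)},
            }
        )
        res = st.fisher_bh_enrichment(hits, background, member)
        assert (res["p_adjusted"] >= res["p_value"] - 1e-12).all()
        assert res["p_adjusted"].is_monotonic_increasing
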