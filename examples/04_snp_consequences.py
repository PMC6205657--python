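"""Annotate strain-diagnostic SNPs by coding consequence.

Builds a toy annotated scaffold, classifies each fixed difference
(synonymous / missense / start lost / stop lost / premature stop) under
the bacterial genetic code, and tests category enrichment of the
PTC-carrying genes with Fisher/BH.
"""

import pandas as pd

import symbiostrain as st
from symbiostrain.effects import classify_sites

# three tiny genes on one scaffold
reference = {"s1": "ATGCAGAAATAA" + "CC" + "ATGGAAGGCTGA" + "AA" + "ATGTTTCCCTAA"}
genes = [
    st.GeneModel("aroA", "s1", 1, 12, "+"),
    st.GeneModel("trpB", "s1", 15, 26, "+"),
    st.GeneModel("ubiC", "s1", 29, 40, "+"),
]
sites = pd.DataFrame(
    {
        "scaffold": ["s1"] * 4,
        "pos": [4, 16, 18, 32],        # CAG>TAG, start lost, GAA>TAA, TTT>CTT
        "n_allele": ["C", "T", "G", "T"],
        "s_allele": ["T", "C", "T", "C"],
        "gene_id": [""] * 4,
    }
)
effects = classify_sites(sites, genes, reference)
for e in effects:
    print(f"{e.scaffold}:{e.pos} {e.ref_allele}>{e.alt_allele} "
          f"{e.gene_id or 'intergenic'} {e.category} ({e.codon_change})")
print("summary:", st.effect_summary(effects))

# enrichment of PTC genes among functional categories
memberships = pd.DataFrame(
    [("aroA", "stimulus_response"), ("trpB", "stimulus_response"),
     ("ubiC", "biosynthesis")],
    columns=["gene", "term"],
)
ptc_genes = {e.gene_id for e in effects if e.category == "stop_gained"}
res = st.fisher_bh_enrichment(ptc_genes, {g.gene_id for g in genes}, memberships)
print(res.to_string(index=False))
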