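"""GO term enrichment of a candidate gene set against the gene universe.

Per term: counts (k, n, K, N), a log2 enrichment odds ratio
log2((k/n)/(K/N)), a one-sided hypergeometric tail p-value and a
Benjamini-Hochberg corrected p-value. Also shows the membrane-fraction
summary used to characterize hit lists.
"""

from butolscreen import goterms
from butolscreen.goterms import GOAnnotation

# tiny hand-made universe: 40 genes, membrane/efflux terms concentrated in
# the first ten, plus a parent edge for ancestor propagation
genes = [f"g{i:02d}" for i in range(40)]
gene_terms = {g: set() for g in genes}
for g in genes[:10]:
    gene_terms[g].add("GO:efflux")
for g in genes[:14]:
    gene_terms[g].add("GO:transport")
for g in genes[20:24]:
    gene_terms[g].add("GO:ribosome")
annotation = GOAnnotation(gene_terms, term_parents={"GO:efflux": ("GO:membrane",)})

study = genes[:8] + genes[30:32]  # 8 efflux genes + 2 unannotated
results = goterms.enrich(study, genes, annotation, correction="bh", propagate=True)
print(results[["term_id", "k", "n", "K", "N", "log_odds_ratio",
               "p_value", "corrected_p"]].round(4).to_string(index=False))

frac_hits = goterms.membrane_fraction(study, annotation, {"GO:membrane"})
frac_all = goterms.membrane_fraction(genes, annotation, {"GO:membrane"})
print(f"\nmembrane-related: {frac_hits:.0%} of hits vs {frac_all:.0%} genome-wide")
print("-> the efflux/membrane terms are over-represented in the hit list, "
      "the ribosome term is not")
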