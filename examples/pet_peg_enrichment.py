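"""Tissue-specificity classification and gene-set enrichment.

A gene's principally expressed tissues (PETs) are those where it is expressed
at least fold-threshold times its mean level in the other tissues; a
principally expressed gene (PEG) for the haustorial tissues is defined the
same way over a focal tissue set.
"""

from ortholoss import enrich, pet_matrix, principal_genes, principal_tissues
from ortholoss.simulate import simulate_expression

expr, truth = simulate_expression(n_genes=500, fold=10.0, noise_cv=0.2, seed=1)
pets = pet_matrix(expr, fold_threshold=2.0)
n_with_pet = int(pets.any(axis=1).sum())
print(f"{n_with_pet}/{expr.n_genes} genes have at least one PET")

gene = expr.gene_ids[0]
print(gene, "PETs:", principal_tissues(expr, gene).pet_tissues,
      "(planted:", truth.pet_tissue[gene], ")")

# PEG calling over a focal tissue pair, e.g. prehaustoria + haustoria
expr2, truth2 = simulate_expression(
    n_genes=500, tissues=("prehaustorium", "haustorium", "stem", "flower", "seed"),
    fold=10.0, noise_cv=0.2, seed=2)
pegs = principal_genes(expr2, ["prehaustorium", "haustorium"], 2.0)
print(f"{len(pegs)} haustorial PEGs")

# enrichment: is a term over-represented among the PEGs?
universe = expr2.gene_ids
annotation = {
    "root_development": {g for g, t in truth2.pet_tissue.items()
                         if t in ("prehaustorium", "haustorium")},
    "background": set(universe[::7]),
}
for row in enrich(pegs, universe, annotation):
    print(f"{row.term}: k={row.k}/{row.K}, p={row.p_value:.3g}, q={row.q_value:.3g}")
# a small p for the planted term shows the hypergeometric test picking up the
# association between haustorial expression and the annotated gene set
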