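"""Classify genes as homologous vs species-specific from an orthogroup
table plus filtered protein alignment hits, extract one-to-one orthologs,
and test whether species-specific genes are enriched among preferential
genes."""
from heterochron import (
    AlignmentHit,
    OrthogroupTable,
    chi_square_enrichment,
    classify_genes,
    extract_one_to_one,
    filter_hits,
    rescue_with_genome_hits,
)

orthogroups = OrthogroupTable({
    "OG1": {"A": ["a1"], "B": ["b1"]},          # one-to-one
    "OG2": {"A": ["a2", "a3"], "B": ["b2"]},    # many-to-one
    "OG3": {"A": ["a4"], "B": []},              # species-A only
})

def hit(query, evalue, q_end, similarity):
    return AlignmentHit(query, "target", similarity, q_end, 0, 0, 1, q_end,
                        1, q_end, evalue, 100.0, query_length=100)

# a5 has a strong full-length hit; a6's hit fails the 80% coverage filter
hits = filter_hits([hit("a5", 1e-30, 90, 60.0), hit("a6", 1e-30, 50, 60.0)])
calls = classify_genes(["a1", "a2", "a4", "a5", "a6"], "A", "B",
                       orthogroups, hits)
# a4 is rescued by a passing protein-vs-genome hit
calls = rescue_with_genome_hits(calls, filter_hits([hit("a4", 1e-40, 85, 55.0)]))

for c in calls:
    print(f"{c.gene_id}: {c.label:16s} ({c.evidence})")

pairs = extract_one_to_one(orthogroups, "A", "B")
print(f"\none-to-one pairs: {[(p.gene_a, p.gene_b) for p in pairs]}")

# 2x2 chi-square: is the preferential set depleted of homologs?
calls_many = (
    [c for c in calls] * 20  # replicate the toy calls for a non-trivial table
)
preferential = {"a5", "a6"}
res = chi_square_enrichment(calls_many, preferential)
print(f"chi2 = {res.chi2:.2f}, df = {res.df}, p = {res.p:.3g}")
print("\nEvidence precedence: orthogroup > protein hit > genome rescue;")
print("genes with none of the three are species-specific.")
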