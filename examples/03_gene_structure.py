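"""Gene models from GFF3: intron statistics, chromosome map, family naming.

Also re-tabulates the packaged published family table of the grapevine
RING C3H2C3 family.
"""

from ringkit import assign_family_names, chromosome_distribution, intron_stats, load_gene_models
from ringkit.reference import family_gene_models
from ringkit.simulate import gen_gff

gff_text, genome, truth = gen_gff(40, seed=42)
models = assign_family_names(load_gene_models(gff_text), prefix="FAM")
st = intron_stats(models)
print(f"{len(models)} genes; {st.pct_at_most_k}% with <= {st.k} introns; "
      f"max {st.max_intron_count} introns ({st.max_intron_gene}); "
      f"{st.zero_intron_count} intronless")
print("first three family names:",
      [(m.family_name, m.chromosome, m.start) for m in models[:3]])

published = family_gene_models()
dist = chromosome_distribution(published)
busiest = max(dist, key=dist.get)
print(f"published grapevine family: {len(published)} members; "
      f"busiest chromosome {busiest} with {dist[busiest]} members")
# Family names follow chromosome order then start coordinate, the convention
# used to number members of plant gene families.
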