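"""Per-context gene-body methylation and category contrasts.

Simulates a Bismark-style cytosine report with context-specific means,
computes weighted gene-body levels in CG/CHG/CHH, and recovers a planted
methylation contrast between divergence categories.
"""

import t2tdup as T
from t2tdup.methylation import category_profiles, gene_levels, levels_frame
from t2tdup.models import merge_intervals

plan = T.GenomePlan(n_chromosomes=1, chrom_length=120_000,
                    cen_array_span=20_000, sd_specs=[], n_gene_pairs=0,
                    n_collinear_blocks=0,
                    n_background_genes_per_chrom=6, seed=6)
genome, ledger, genes, tes = T.generate_genome(plan)

# plant a CG contrast: "AED" genes hypomethylated vs "NoDiff" genes
cats = {g.gene_id: ("AED" if i % 2 == 0 else "NoDiff")
        for i, g in enumerate(genes)}
gene_means = {g: {"CG": 0.3 if c == "AED" else 0.6}
              for g, c in cats.items()}
regions = {}
for g in genes:
    regions.setdefault(g.chrom, []).append(
        (max(0, g.start - 2500), g.end + 2500))
regions = {c: merge_intervals(v) for c, v in regions.items()}

cx = T.simulate_methylation(genome, genes, plan.methylation_means,
                            depth=30, seed=1, gene_means=gene_means,
                            regions=regions)
print(f"cytosine report: {len(cx):,} rows "
      f"(contexts: {dict(cx['context'].value_counts())})")

lv = levels_frame(gene_levels(cx, genes))
print("\nper-gene weighted levels (first genes):")
print(lv.pivot(index="gene_id", columns="context",
               values="level").round(3).head(4).to_string())

summary, track = category_profiles(cx, genes, cats)
print("\nper-category means:")
print(summary.round(3).to_string(index=False))
print()
print("The planted CG contrast (0.3 vs 0.6) is recovered in the category "
      "means; CHG/CHH follow the genome-wide defaults, mirroring how "
      "duplicate-gene classes are compared for methylation divergence.")
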