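"""Simulate a linked multi-omic cohort and inspect its planted ground truth.

Builds the default 80-observation cohort (2 breeds x 2 diets x High/Low-RFI
x 10 replicates) with 2,000 genes, 60 taxa rows and 13 VFA variables, then
prints the headline structure.
"""

import rumennet as rn

design = rn.CohortDesign(n_per_group=10, seed=1)
cohort = rn.simulate_cohort(design)

phen = cohort.phenotypes
print(f"observations: {len(phen)}  (animals x diet phases)")
print(f"gene counts:  {cohort.gene_counts.shape[0]} genes x {cohort.gene_counts.shape[1]} samples")
print(f"taxa rows:    {cohort.taxa_abundance.shape[0]} (leaves + internal clade sums)")
print(f"VFA rows:     {cohort.vfa.shape[0]}")

high = phen.loc[phen.rfi_group == "High", "dmi"].mean()
low = phen.loc[phen.rfi_group == "Low", "dmi"].mean()
print(f"\nmean DMI High-RFI {high:.2f} vs Low-RFI {low:.2f} kg DM/day")
print("-> inefficient (High-RFI) animals eat more for the same growth and weight")

for p, taxa in cohort.planted.phenotype_taxa.items():
    print(f"planted {p}-linked taxa: {dict(taxa)}")
print("-> these associations are the ground truth the network must recover")
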