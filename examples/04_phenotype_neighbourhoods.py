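"""Full pipeline, then the phenotype-centred neighbourhood analyses:
first-neighbour composition, the three-way overlap, and the signed
microbe-phenotype report."""

import warnings

import rumennet as rn

warnings.filterwarnings("ignore")

cfg = rn.PipelineConfig(seed=1)
res = rn.run_pipeline(cfg)
rep = res.report

print(f"network: {rep['n_nodes']} nodes, {rep['n_edges_significant']} significant edges")
for phen in ("DMI", "RFI", "ADG"):
    s = res.summaries[phen]
    tc = s.type_counts
    print(
        f"{phen}: {len(s.neighbours)} first neighbours "
        f"({tc['gene']} genes, {tc['microbe']} microbes, {tc['vfa']} VFAs, "
        f"{tc['phenotype']} phenotypes; {s.pct_of_network_nodes}% of connected nodes)"
    )

centre = res.overlap[("ADG", "DMI", "RFI")]
print(f"\nnodes neighbouring all three phenotypes: {centre}")

shared = res.microbe_report["shared_microbes"]
print(f"microbes connected to more than one phenotype: {shared}")
print("-> signs show whether abundance rises (+) or falls (-) with the trait")
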