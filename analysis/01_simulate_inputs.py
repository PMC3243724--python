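#!/usr/bin/env python
"""Generate the synthetic study bundle every downstream analysis consumes.

Produces, under results/synthetic/: a pair of annotated genomes with 10
shared, 5 inverted, and 5 per-genome unique planted PULs plus their homology
hit tables; an expression matrix with five 50x-induced operons per glycan
condition; a plate of logistic growth curves (one no-growth group, one
biphasic group); and four one-/two-site ITC titrations.  Each dataset is
written alongside its truth record.
"""

import json
from pathlib import Path

from pulscape.expression import write_expression_tsv
from pulscape.genome import write_gene_table
from pulscape.itc import BindingSite, default_design, write_titration_tsv
from pulscape.orthology import write_blast_table
from pulscape.simulate import synth_expression, synth_genome_pair, synth_plate, synth_titration

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"
OUT.mkdir(parents=True, exist_ok=True)

ann_a, ann_b, proteins, hits_ab, hits_ba, g_truth = synth_genome_pair(
    n_puls_shared=10, n_puls_inverted=5, n_puls_unique_each=5,
    n_filler_genes=200, mutation_rate=0.0, seed=SEED,
)
write_gene_table(ann_a, OUT / "genome_a.tsv")
write_gene_table(ann_b, OUT / "genome_b.tsv")
write_blast_table(hits_ab, OUT / "hits_ab.tsv")
write_blast_table(hits_ba, OUT / "hits_ba.tsv")
g_truth.to_json(OUT / "genomes_truth.json")
print(f"genomes: {len(ann_a)} + {len(ann_b)} genes, "
      f"{len(g_truth.params['puls'])} planted PULs, "
      f"{g_truth.params['n_homolog_pairs']} homolog pairs")

profile, e_truth = synth_expression(ann_a, induced=5, effect_size=50.0, noise_cv=0.10, seed=SEED)
write_expression_tsv(profile, OUT / "expression.tsv")
e_truth.to_json(OUT / "expression_truth.json")
print(f"expression: {profile.signals.shape[0]} genes x {profile.signals.shape[1]} conditions, "
      f"{sum(len(v) for v in e_truth.params['induced_operons'].values())} planted induced operons")

plate, layout, p_truth = synth_plate(
    n_groups=4, n_replicates=3, noise_sd=0.01, no_growth_groups=1, biphasic_groups=1, seed=SEED,
)
plate.to_csv(OUT / "plate.csv", index=False)
layout.to_csv(OUT / "layout.tsv", sep="\t", index=False)
p_truth.to_json(OUT / "plate_truth.json")
print(f"plate: {plate.shape[1] - 1} wells, {plate.shape[0]} reads at "
      f"{p_truth.params['read_interval_min']:.0f}-min intervals")

titrations = {
    "one_site_tight": ([BindingSite(1.0e6, -8.0, 1.0)], default_design()),
    "one_site_moderate": ([BindingSite(4.8e4, 1.6, 0.7)], default_design()),
    "two_site_separated": (
        [BindingSite(4.8e4, 1.6, 0.7), BindingSite(5.0e3, -17.5, 1.3)],
        default_design(n_injections=35, syringe_conc=2.5e-3),
    ),
    "weak_tltf": ([BindingSite(3.0e2, -10.0, 1.0)], default_design(syringe_conc=2e-2)),
}
for name, (sites, design) in titrations.items():
    clean = synth_titration(sites, design, noise_sd=0.0, seed=SEED)[0]
    noise = 0.02 * float(abs(clean.heats).max())
    series, t_truth = synth_titration(sites, design, noise_sd=noise, seed=SEED)
    write_titration_tsv(series, OUT / f"itc_{name}.tsv")
    meta = {"cell_volume": design.cell_volume, "cell_conc": design.cell_conc,
            "syringe_conc": design.syringe_conc, "temperature": design.temperature,
            "mode": design.mode,
            "model": "two_site" if len(sites) == 2 else "one_site"}
    with open(OUT / f"itc_{name}.meta.json", "w") as fh:
        json.dump(meta, fh, indent=1)
    t_truth.to_json(OUT / f"itc_{name}_truth.json")
print(f"itc: {len(titrations)} titration series written")
print(f"all inputs under {OUT}")
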