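"""Generate a synthetic three-group methylome study with planted truth.

Builds a small genome (2 autosomes + 1 non-autosome), plants differentially
methylated regions of each class, draws replicate methylomes with
beta-binomial noise, and writes everything as plain-text files.
"""

from pathlib import Path

from dmrmem import io, simulate

out = Path("example_output/simulated")
out.mkdir(parents=True, exist_ok=True)

cfg = simulate.SimulationConfig(
    seed=42,
    n_chrom=3,
    n_autosomes=2,
    chrom_length_bp=500_000,
    n_genes=80,
    dmr_plan={"shared": (6, 0.4), "memory": (3, 0.4), "specific_hyper": (4, 0.4)},
)
annotation = simulate.simulate_annotation(cfg)
truth = simulate.plant_truth(cfg, annotation)
samples = simulate.simulate_samples(cfg, annotation, truth)

io.write_chrom_sizes(annotation, out / "chrom_sizes.tsv")
io.write_gene_table(annotation, out / "genes.tsv")
for s in samples:
    io.write_cytosine_report(s, out / f"{s.sample_id}.cytosine_report.tsv")
io.write_bed(
    truth.regions.rename(columns={"class_label": "name"}),
    out / "planted_truth.bed",
    name_col="name",
)

print(f"groups and replicates: { {g: n for g, n in cfg.replicates.items()} }")
print(f"planted regions by class:")
print(truth.regions["class_label"].value_counts().to_string())
n_calls = len(samples[0].calls)
print(f"\n{len(samples)} replicate methylomes written, ~{n_calls} cytosine calls each")
print(f"files in {out}/")
# Each planted region carries per-group true methylation levels; 'memory'
# regions keep the source (MEF) level in the reprogrammed (iISC) cells while
# the target (ISC) differs — the signature the downstream classifier hunts.
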