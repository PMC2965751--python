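# chiptile

Occupancy analysis for ChIP-chip tiling-array data on compact genomes.

Chromatin factors — histone deacetylase complexes, elongating RNA
polymerase, histone marks — are mapped genome-wide by hybridizing ChIP
material to tiling microarrays (one ~60-mer probe every ~275 bp). The
question is rarely "is this probe enriched" but "where along genes does
this factor sit, and which genes share that pattern". `chiptile`
implements the standard stack that answers it:

- **Replicate combination** — per-probe inverse-variance weighted average
  of median-centered biological replicates.
- **Z-score standardization** — z_i = (x_i − μ)/σ over an experiment's
  non-missing probes, making factors with very different
  immunoprecipitation efficiencies comparable (the Z-track is invariant
  to any positive rescaling of the input).
- **Per-gene summaries** — median Z over the ORF and over the operational
  promoter, defined as the upstream min(250 bp, ⌊IG/2⌋) abutting the 5'
  boundary (IG = intergenic gap to the nearest neighbor, strand-aware);
  genes < 500 bp excluded; probes assigned by midpoint, no interpolation.
- **SOM clustering** — 1×k Kohonen map on (promoter Z, ORF Z) features,
  complete cases only, seeded and deterministic.
- **Metagene profiles** — signal mapped onto the 5' and 3' gene
  boundaries in 50 bp bins over each half-gene plus the adjacent half-IG,
  averaged per gene then across genes, smoothed with a 300 bp sliding
  window.
- **Trend curves** — Pearson correlation and a 300-gene sliding-median
  curve of one occupancy feature against genes ranked by another.

A synthetic tiling-array generator with planted per-gene occupancy
archetypes (promoter-only, promoter+ORF, 3'-skewed ramp, unbound)
provides ground truth for every stage, so the whole pipeline is testable
end to end without any array data.

## Worked example

Simulate a 300-gene study, normalize one factor, summarize, and cluster
the genes into three occupancy classes:

```python
import numpy as np
import chiptile as ct
from chiptile.normalize import ReplicateSet, combine_replicates, zscore
from chiptile.cluster_trend import feature_matrix, som_fit, pearson

fx = ct.make_fixture(seed=1, n_genes=300)
tracks, truth = fx.factors["rpd3"]
z = zscore(combine_replicates(ReplicateSet.from_tracks("rpd3", tracks)))
summary = ct.GeneSummaryTable.build({"rpd3": z}, fx.genome.annotation)
print("genes kept (>=500 bp):", len(summary))

fm = feature_matrix(summary, ["rpd3"])
print("complete-case genes:", len(fm.gene_ids))
model, nodes = som_fit(fm, k=3, seed=1)
for node in range(3):
    prom, orf = model.codebook[node]
    print(f"node {node}: {np.sum(nodes == node):3d} genes  "
          f"promoter Z {prom:+.2f}  ORF Z {orf:+.2f}")
r = pearson(summary.column("rpd3", "promoter"), summary.column("rpd3", "orf"))
print(f"promoter-vs-ORF Pearson r = {r:.2f}")
```

Output:

```
genes kept (>=500 bp): 287
complete-case genes: 222
node 0:  68 genes  promoter Z +2.75  ORF Z +1.65
node 1:  68 genes  promoter Z +2.37  ORF Z -0.08
node 2:  86 genes  promoter Z +0.09  ORF Z -0.06
promoter-vs-ORF Pearson r = 0.36
```

The three codebook vectors read directly as occupancy classes: node 0 is
bound on promoters *and* ORFs, node 1 on promoters only, node 2 is
unbound — the planted archetypes, recovered from noisy probes. (65 of
the 287 genes lack a probe in their ≤250 bp promoter or were hit by
missing values and are excluded by the complete-case rule.)

The same run as a shell pipeline:

```sh
chiptile simulate fixture --out data/ --seed 1 --n-genes 300
chiptile normalize --manifest data/manifest.tsv --out-dir norm/
chiptile summarize --annotation data/annotation.gff3 \
    --track rpd3=norm/rpd3.zscore.bedGraph --out summary.tsv
chiptile cluster --summary summary.tsv --experiments rpd3 --k 3 \
    --seed 1 --out-dir clusters/
chiptile metagene --annotation data/annotation.gff3 \
    --track norm/rpd3.zscore.bedGraph --bin 50 --span 300 --out profile.tsv
```

or, end to end from one YAML config, `chiptile run --config pipeline.yaml`
with

```yaml
output_dir: out
seed: 1
simulate: {n_genes: 300}
cluster: {k: 3, experiments: [rpd3]}
trend: {window: 100, x: rnapii:orf, y: rco1:orf}
```

Identical config and seed reproduce byte-identical tables.

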