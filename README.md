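# econet

Co-occurrence network analysis for microbial count tables: from an OTU × sample
count matrix to thresholded signed networks, topological and modular
characterization against degree-preserving nulls, Zi/Pi keystone
classification with abundance classes, and community-stability statistics
(cohesion, N:P, vulnerability, negative-link ratio), with per-time-point /
per-stage comparisons and a synthetic-data generator with known ground truth.

## Modules

| module | contents |
|---|---|
| `econet.tables` | count/abundance tables, TSV + BIOM v1 IO, rarefaction, prevalence filter, log transform, abundance classes, alpha diversity |
| `econet.netbuild` | Spearman similarity matrix, RMT (eigenvalue spacing) threshold scan, signed network construction, power-law fit |
| `econet.topology` | connectedness, geodesic efficiency, stress centrality & centralization, betweenness, eigenvector centrality, greedy modularity modules |
| `econet.nullmodels` | Maslov–Sneppen rewiring, randomized-ensemble z/p significance |
| `econet.node_roles` | Zi/Pi, role classification (network/module hubs, connectors, peripherals), keystone tables, keystone–diversity screening |
| `econet.stability` | positive/negative cohesion with a taxa-shuffle null, N:P summaries, node-removal vulnerability, negative-link ratio |
| `econet.synthetic` | latent-factor count-table generator with planted modules, hubs, connectors, sign mix and stage schedules |
| `econet.pipeline` | per-group orchestration, trend regression vs. age, ANOVA + LSD with compact letter display, networked-OTU overlap, manifest |
| `econet.cli` | `econet` command-line interface |

## CLI

```sh
# write a 3-stage synthetic series (counts, metadata, ground truth)
econet simulate --out-dir demo --seed 0

# rarefy + prevalence-filter a count table
econet filter demo/counts_S1.tsv --out filtered.tsv --prevalence 0.2

# build the signed network (fixed threshold or RMT scan)
econet network demo/counts_S3.tsv --out-prefix s3 --st fixed:0.802
econet network demo/counts_S3.tsv --out-prefix s3 --st scan

# characterize
econet topology s3.edges.tsv --out s3.topology.json
econet null s3.edges.tsv --out s3.null.tsv --reps 100 --seed 1
econet roles s3.edges.tsv --out s3.roles.tsv
econet vulnerability s3.edges.tsv --out s3.vuln.tsv
econet cohesion demo/counts_S1.tsv --out s1.cohesion.tsv --seed 1

# full per-stage pipeline from a YAML config
econet pipeline --config config.yaml --seed 1
```

A minimal `config.yaml`:

```yaml
counts_path: demo/counts_all.tsv
metadata_path: demo/metadata_all.tsv
out_dir: out
grouping: by_stage      # or by_dph
min_replicates: 27
st_policy: fixed        # or scan
st: 0.802
prevalence: 0.2
seed: 1
```

The pipeline writes, per group: edge list + GraphML, node attributes,
topology summary, null-ensemble significance, Zi/Pi roles, keystone tables,
keystone–diversity associations and per-sample cohesion; across groups:
trend regressions, stability ANOVA/LSD letters, networked-OTU overlap
counts, and a deterministic `manifest.json` recording every seed and policy.

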