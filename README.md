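# medinet

Network-diffusion mediator detection for multi-omics tumor cohorts.

`medinet` ranks candidate *mediators* — genes that relay, via molecular
interactions, the effects of upstream aberrations (somatic mutations,
dysregulated miRNAs) to downstream molecular changes (differential mRNA,
protein and phosphosite levels) — on a directed functional interaction
network. Per sample, upstream events are diffused forward and downstream
events backward over the network's largest strongly connected component with
an insulated random-walk-with-restart kernel `F = β (I − (1−β) W)⁻¹`; the two
signals are combined per gene, ranked per sample, and aggregated across the
cohort by median rank. Significance is assessed with an event-relabeling
permutation test and Benjamini–Hochberg FDR correction.

The package also ships:

* a synthetic-cohort generator that plants mediators with full ground truth,
  so every pipeline stage is testable without external data, and
* packaged fixtures transcribing the study tables used for tally checks
  (mutation table, per-layer dysregulation counts, single-layer flags).

## Command line

```sh
# generate a seeded synthetic cohort (network, mutation table,
# per-sample layer tables, truth.json)
medinet simulate --seed 7 --out cohort/            # optionally --config sim.yaml

# rank mediators without a permutation test (top fraction only)
medinet rank --cohort cohort/ --out run/ --seed 0

# full run: ranking + permutation test + FDR filtering
medinet permute --cohort cohort/ --out run/ --n-perm 10000 --seed 0

# print the JSON summary of a finished run
medinet report --results run/

# recompute the packaged fixture tallies
medinet fixtures
```

Run outputs: `ranking.tsv` (all genes), `mediators.tsv` (selected set with
empirical p and q), `mediator_matrix.tsv` (+1/−1/0 per gene, sample and
layer), `summary.json`, `config.yaml` echo and `run.log`. Runs are
byte-reproducible from (config, seed). Validation failures exit non-zero and
write `error.json`.

Analysis parameters (`RunConfig`, YAML-overridable): restart probability
`beta` (0.4), significance threshold `alpha` (0.05), selected `fraction`
(0.05), FDR cut `q_alpha` (0.05), `n_perm` (10,000), rank `aggregation`
(median | mean | sum) and score `combine` rule (product | sum | forward_only).

## Input formats

* **Network**: TSV `source  target  directed  type`; `directed=0` rows are
  expanded into both orientations, self-edges dropped, duplicates collapsed.
* **Mutations**: TSV with columns tumor_sample, normal_sample, chrom, pos,
  ref, alt, gene, effect, depth_tumor, vaf_tumor and optional depth_normal,
  vaf_normal, pon_count. VAFs may carry a `%` suffix. Filters: tumor depth
  ≥ 10, germline depth ≥ 5, ≥ 3 supporting reads, tumor VAF ≥ 5× normal VAF,
  present in < 2 panel-of-normals samples.
* **Differential tables** (per sample and layer): TSV
  `feature  log2fc  padj  detected[  gene]`; the `gene` column is required
  for phosphosites (site-to-gene collapse keeps genes with ≥ 1 significant
  site). Downstream layers are merged by the rule: protein-or-phospho
  significant ⇒ taken; detected-but-insignificant ⇒ dropped regardless of
  RNA; not detected ⇒ fall back to a significant RNA call.

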