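# syncrc

Analysis toolkit for synchronous colorectal tumour pairs: somatic/germline
variant filtering, within-pair shared-mutation comparison, Bayesian
four-component mutational-signature deconvolution, signature-exposure
variance decomposition, immune cell score (IS) computation, and
cohort-level summaries — driven end-to-end by a synthetic-cohort generator
with known ground truth, so every stage is testable without access to
restricted patient data.

## Modules

| module | contents |
| --- | --- |
| `syncrc.synthetic` | synthetic cohort generator: paired tumours with MSS/MSI statuses, mutations drawn from a known 4-signature mixture, injected exactly-shared variants, FFPE-like low-VAF C>T artefacts, read-level evidence, immune densities |
| `syncrc.filters` | somatic filter (matched-normal subtraction, panel-of-normals SNV/indel rules, target/callability masks, depth/quality/VAF thresholds) and rare-variant germline filter (population-AF thresholds) |
| `syncrc.pairs` | exact shared mutations per pair, known-gene concordance, truncating-gene overlap, pathway overlap |
| `syncrc.contexts` / `syncrc.model` | 96-trinucleotide-context catalogs and the hierarchical Poisson model: four Dirichlet(1) signatures (patient-intrinsic, MSI, ts1, ts2), half-Cauchy(100) exposure weights, MSI weight fixed to 0 in MSS tumours; Gibbs/Metropolis MCMC, MAP extraction, reference-signature matching |
| `syncrc.variance` | REML mixed-model decomposition of exposure proportions into Individual (patient) and Tumour (residual) variance with an MMR fixed effect |
| `syncrc.immune` | IS 0–4 from CD3/CD8 densities at tumour centre and invasive margin; within-pair Spearman concordance and IS distributions |
| `syncrc.cohort` | cohort metadata table, sidedness rule, cohort summaries and mutation-burden summaries |
| `syncrc.cli` | `syncrc` command-line interface and the end-to-end pipeline |

Bundled fixtures (`syncrc/data/`): the cohort metadata table (23 patients /
47 tumours), a per-tumour immune density table (39 scored tumours across 19
patients), demo pathway gene sets, a known-gene panel, and a small
stylised reference-signature matrix. The IS cutoff values are placeholder
defaults — the originally used ROC-derived cutoffs are not published, so
any real application must supply its own via `--cutoffs`.

## CLI

```sh
syncrc simulate --seed 1 --outdir out/            # synthetic cohort
syncrc filter-somatic --tumour-vcf T.vcf --normal-vcf N.vcf \
    --panel panel.tsv --targets targets.bed --out T.filtered.vcf
syncrc filter-germline --normal-vcf N.vcf --afs afs.tsv \
    --targets targets.bed --out germline.vcf
syncrc catalog --vcfs a.vcf --vcfs b.vcf --out catalog.tsv
syncrc fit-signatures --catalog catalog.tsv --design cohort.tsv \
    --seed 7 --outdir fit/
syncrc compare-pairs --cohort cohort.tsv --vcfs a.vcf --vcfs b.vcf --out pairs.json
syncrc immune-score --densities densities.tsv --outdir is/
syncrc cohort-stats --table cohort.tsv --out summary.json
syncrc run-all --config cfg.json --outdir run/     # full pipeline + manifest
```

`run-all` takes a single JSON config with per-stage sections
(`simulate`, `filter_params`, `mcmc`, `is_cutoffs`) and a `seeds` registry;
every stochastic stage requires an explicit seed, and re-running with the
same config reproduces identical outputs.

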