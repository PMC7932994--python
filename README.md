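# tcrtrack

Clonal tracking of T-cell receptor (TCR) repertoires from UMI-based
amplicon sequencing: simulate, process and analyse longitudinal TCRβ
repertoires to find the clones that expand in response to antigen
stimulation.

## The problem

Bulk AIRR-seq of an in-vitro stimulation time course (e.g. PBMCs cultured
with a viral peptide pool, sampled in triplicate at days 0, 3, 5 and 10)
yields, per library, a table of clones — reads clustered by 100%
amino-acid CDR3 identity — with abundances measured as unique-UMI counts.
The analytical questions are the ones asked of any count experiment with
biological replicates:

* how does the clonal size distribution shift over the culture?
* which clones share an expansion trajectory?
* which clones expand *significantly* between two conditions, given
  replicate-to-replicate overdispersion?

`tcrtrack` implements that full chain for repertoire count data:

1. **Read processing** — paired-end merging with Phred-aware consensus,
   MID (sample barcode) demultiplexing, semi-global V/J assignment with
   conserved Cys/Phe anchor mapping, CDR3 extraction with a per-base
   Phred ≥ 30 filter, and UMI-collapsed clone counting.
2. **Size distribution** — repertoires downsized without replacement to a
   common UMI depth (default 25,000, at which a singleton clone sits at a
   clonal frequency of 0.004%), clones binned as rare / small
   (c.f. < 0.1%) / medium (0.1% ≤ c.f. < 0.5%) / large (c.f. ≥ 0.5%), and
   per-class repertoire fractions compared by ANOVA with Bonferroni
   post-tests.
3. **Trajectory clustering** — clones present in ≥ 2 of 3 replicates are
   replicate-averaged, autoscaled (per-clone Z-score across timepoints)
   and grouped by k-means (default k = 10, best of 25 restarts) with an
   elbow curve over k.
4. **Differential expansion** — a replicate-aware negative-binomial exact
   test on clone counts. For clone *g* with replicate counts
   *y*<sub>*gi*</sub> ~ NB(μ, φ), libraries are TMM-normalized, counts
   quantile-adjusted to a common effective library size, φ estimated by
   conditional maximum likelihood (common) plus weighted-likelihood
   shrinkage (tagwise), and the two-group contrast tested exactly:
   conditional on the total *z* = *z*<sub>A</sub> + *z*<sub>B</sub>, the
   group-sum split is beta-binomial with sizes *n*<sub>A</sub>/φ and
   *n*<sub>B</sub>/φ, and the two-sided p sums all partitions no more
   probable than the observed one. Clones are labelled **DOE / DUE / NDE**
   (differentially over- / under- / not-expanded) at |fold change| > 1.5
   and Benjamini–Hochberg adjusted p < 0.05, or **DOR / DUR / NDR** for
   the bulk vs activation-marker-sorted contrast.
5. **Simulation** — a ground-truth generator for the whole of the above:
   heavy-tailed baseline clone sizes, responder archetypes (transient,
   late-expander, decliner …), NB replicate noise, a sorted fraction
   enriched for activated clones, and optional emission of UMI/MID-tagged
   paired FASTQ so the read-processing chain is testable end to end.

## Worked example

```python
from tcrtrack import SimConfig, simulate_experiment, differential_expansion

cfg = SimConfig(n_clones=2000, depth=25_000, dispersion=0.05, seed=42)
truth, table = simulate_experiment(cfg)          # 2000 clones x 12 samples

day0 = [s.sample_id for s in table.samples if s.timepoint == 0]
day10 = [s.sample_id for s in table.samples if s.timepoint == 10]
res = differential_expansion(table, day0, day10)
print(res["label"].value_counts().to_dict())
print(res.sort_values("log2_fc", ascending=False)
         .head(3)[["clone_id", "log2_fc", "adj_p", "label"]]
         .to_string(index=False))
```

prints

```
{'NDE': 1955, 'DOE': 37, 'DUE': 7}
       clone_id  log2_fc        adj_p label
CKSKFYMRNIYIYKF 5.715535 3.787508e-59   DOE
      CGDKHMMAF 5.710409 1.078114e-29   DOE
 CPVEYNKGRYQALF 5.502663 5.517837e-35   DOE
```

With 5% of clones seeded as responders, 37 clones pass the DOE cut in the
day 0 → day 10 contrast: the strongest expanders gain ~2<sup>5.7</sup> ≈
50-fold in normalized clonal frequency, while the bulk of the repertoire
(NDE) and a handful of diluted clones (DUE) do not. `res` carries one row
per clone with exactly the columns needed for an MA plot: average log2
clonal frequency (UCPM) on x, log2 fold change on y.

The same analysis is available from the shell:

```bash
tcrtrack run --config examples/demo.yaml --outdir out --seed 42
```

which writes the simulated tables, size-class summaries, cluster
assignments, differential-expansion TSVs, cross-tables and a provenance
manifest (config hash, seeds, package version) into `out/`; reruns reuse
any stage whose inputs are unchanged.

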