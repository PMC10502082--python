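# zganet

Network modeling and regulatory-genomics classification for zebrafish
zygotic genome activation (ZGA).

At ZGA, the maternal pioneer-like transcription factors Pou5f3, Sox19b
(with the zygotic SoxB1 genes) and Nanog open chromatin on enhancers,
promote H3K27 acetylation and activate the first zygotic transcripts - but
on hundreds of "antagonistic" enhancers one of Pou5f3/Nanog instead blocks
the other's activity.  `zganet` is for computational biologists who want to
reproduce, extend or stress-test the quantitative machinery behind this
analysis on data with known ground truth.  It implements two independent
arms and their cross-validation:

**ODE arm.**  A core model of the activator network - 11 states (8 mRNA
pools, 3 proteins) and 17 reactions, Hill kinetics with coefficient h = 5
and multiplicative AND gates, switch-like maternal *sox19b* clearance,
boolean genotype flags for all single/double/triple maternal-zygotic
mutants - supplies protein inputs P(t), N(t), SOX(t) to single-ODE "mini
models" of each target gene:

    dT/dt = v · g_P(P) · g_N(N) · g_S(SOX) − d·T,    T(2 hpf) = 0

with g(x) = x^h/(K^h + x^h) for activation, K^h/(K^h + x^h) for repression,
or 1.  Requiring at least one activator leaves 19 regulatory scenarios;
each is fitted to a gene's time courses by deterministic multi-start
maximum likelihood (log10 parameters, absolute Gaussian error model with
jointly estimated scales, weak L2 prior (log10 θ / 3)², profile-likelihood
identifiability) and scored by BIC = −2 log L + k ln n.  The winning
scenarios merge into six groups by Pou5f3/Nanog action (P+N+, P+, P+N−,
P−N+, N+, SOX).

**Genomics arm.**  Accessible regions (110 bp around ATAC-seq summits) are
called down/up/same per mutant by a consensus over four differential
-accessibility normalizations (FDR < 0.05); TF-bound regions lost in the
triple mutant (TdARs) fall into four groups by the non-redundant
requirement for Pou5f3 and/or Nanog; H3K27ac log2 ratios (floor 0.1,
acetylation > 0.2, ±0.7 activator/blocker thresholds) assign per-TF
enhancer statuses; rescue-by-injection and motif-enrichment scores and GC
content complete the region annotation.

**Cross-validation.**  Regions link to every transcript whose TSS lies
within ±50 kb; region and transcript classes are cross-tabulated over the
pairs and tested by Pearson chi-square, with cells at Pearson residual > 4
reported as strong positive associations.

A first-class synthetic-data module generates core time courses, target
panels and genomic fixtures with planted truth (scenarios, groups,
statuses, couplings), so every stage is testable end to end.

## Worked example

```python
import numpy as np
from zganet import build_core_model, enumerate_scenarios, scenario_to_group
from zganet.core_model import DEFAULT_FIT_GENOTYPES
from zganet.mini_models import InputCurves
from zganet.synthetic_data import generate_target_panel
from zganet.model_selection import classify_target_panel

model = build_core_model("default")
print(f"core model: {model.n_states} states, {model.n_reactions} reactions")
scenarios = enumerate_scenarios()
print(f"{len(scenarios)} scenarios -> {len({scenario_to_group(s) for s in scenarios})} groups")

inputs = InputCurves.from_core(model, DEFAULT_FIT_GENOTYPES)
panel, truth, _ = generate_target_panel(6, noise_level=0.05, seed=42, inputs=inputs)
table, _ = classify_target_panel(panel, inputs, n_starts=8, seed=1)
for _, r in table.iterrows():
    print(f"{r['gene']}: fitted {r['group']} (true {truth.gene_truth[r['gene']]['group']})"
          f"  dBIC {r['delta_bic']:.1f}")
```

prints

```
core model: 11 states, 17 reactions
19 scenarios -> 6 groups
g0000: fitted P+N+ (true P+N+)  dBIC 3.5
g0001: fitted P+N- (true P+)  dBIC 0.2
g0002: fitted P+N- (true P+N-)  dBIC 213.8
g0003: fitted P-N+ (true P-N+)  dBIC 304.3
g0004: fitted N+ (true N+)  dBIC 5.6
g0005: fitted SOX (true SOX)  dBIC 2.0
```

Five of six genes recover their generating group; the one miss (g0001,
P+ fitted as P+N−) has a BIC margin of only 0.2 - an honest tie between a
scenario and its nested extension at 5% noise.  ΔBIC is the margin to the
runner-up scenario, so large values (g0002, g0003) mean the classification
is unambiguous.

The genomics arm on a planted fixture:

```python
from zganet.synthetic_data import generate_genomic_fixture
from zganet.enhancer_genomics import call_regulation, select_tdars, assign_four_groups
from zganet.linkage_enrichment import link_regions_to_tss, chisq_enrichment

fx, _ = generate_genomic_fixture(n_regions=400, seed=7)
ev = fx["evidence"]
calls = {c: ev[ev.contrast == c].groupby("region_id").apply(
             lambda g: call_regulation(list(zip(g.log2fc, g.fdr))), include_groups=False)
         for c in ("MZtriple", "MZp", "MZn")}
tdar = select_tdars(fx["regions"], calls["MZtriple"], fx["tf_peaks"])
groups = assign_four_groups(tdar, calls["MZp"], calls["MZn"])
pairs = link_regions_to_tss(fx["regions"], fx["tss"])
res = chisq_enrichment(pairs, groups, fx["transcript_status"].set_index("gene")["status"])
print(int(tdar.sum()), groups.value_counts().to_dict())
print(f"chi2 = {res.chi2:.1f}, dof = {res.dof}, p = {res.p_value:.3g}")
print(res.strong_positive)
```

prints

```
400 {'4.-': 100, '2.P': 100, '3.N': 100, '1.PN': 100}
chi2 = 404.0, dof = 6, p = 3.8e-84
[('1.PN', 'DOWN'), ('2.P', 'DOWN'), ('3.N', 'SAME'), ('4.-', 'UP')]
```

i.e. all 400 planted TdARs land in their planted four-group labels, and the
strong-residual cells of the chi-square table are exactly the planted
region-class/transcript-class couplings.

## Command line

```bash
zganet simulate --seed 3 --outdir sim          # synthetic inputs + truth JSON
zganet fit-core --data sim/core_timecourses.tsv --starts 16 --outdir fit
zganet fit-targets --data sim/target_panel.tsv --starts 8 --outdir fit
zganet classify-transcripts --data sim/target_panel.tsv --outdir out
zganet classify-genome --indir sim --outdir out
zganet link-enrich --regions out/region_annotation.tsv \
    --status sim/transcript_status.tsv --tss sim/tss.tsv --outdir out
zganet report --seed 5 --outdir run            # full chain + summary.json
```

All thresholds and fit settings live in a YAML config
(`zganet.io.PipelineConfig`); every output TSV carries the config hash, and
reruns with the same seed and config are byte-identical.

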