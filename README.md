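# bmtime

Benchmark-time analysis of time-course transcriptomics: when, not just
whether, do cellular stress-response pathways switch on after a chemical
exposure?

`bmtime` is for toxicologists and computational biologists working with
targeted-panel (TempO-Seq-style) bulk RNA counts collected over a time course
— typically nine time points between 1 and 24 h with three biological
replicates and matched vehicle controls.  It implements the full analysis
chain:

1. **Probe filtering & normalisation** — per-compound row-sum filter
   (default ≥ 100 counts across treated + control samples), median-of-ratios
   size factors.
2. **Per-time-point differential expression** — negative-binomial Wald tests
   of treated vs time-matched control at fixed per-probe dispersion,
   Benjamini–Hochberg adjustment; a probe is a DEG at p-adj < 0.01 and
   fold change > |2| (|log2FC| > 1).
3. **Pathway over-representation** — exact hypergeometric upper-tail test of
   the DEG gene list against GMT gene sets over the panel background, FDR
   q values; significance at overlap ≥ 5, p < 0.01, q < 0.05.
4. **Benchmark-time (BMT) modelling** — the benchmark-dose framework applied
   to the time axis.  Per probe: Williams-type trend prefilter (permutation
   p < 0.05, max |log2FC| > 1), least-squares fits of ten parametric families
   (Linear, Poly2–4, Power, Hill, Exp2–5), lowest-AIC selection, inversion of
   the fitted curve at a benchmark response (default 1.349 × baseline SD) to
   the benchmark time

   BMT = min { t > 0 : |μ(t) − μ(0)| = BMR },

   parametric-bootstrap confidence bounds BMTL/BMTU, and the retention
   filters BMT ∈ [0.1 h, 24 h], BMTU/BMTL < 40, fit p > 0.1.  Retained BMTs
   are summarised as accumulation curves, earliest-response gene rankings,
   and weighted 5-parameter-logistic predicted fold changes at the BMT.

Because raw data from such studies is rarely depositable, the package ships a
first-class synthetic-data generator (`bmtime.synth`) that emulates the assay
— negative-binomial counts on a ~3,565-probe panel, log-normal library sizes,
planted pathway-structured responders with analytic true BMTs, an inert
negative-control compound — so the entire pipeline is testable against known
ground truth.  See `docs/methods.md` for the model details and assumptions.

## Worked example

Simulate a small two-compound experiment (one active compound planting a
fast metal-stress response and a slower unfolded-protein response, one inert
control) and run the full pipeline:

```python
from bmtime import synth
from bmtime.pipeline import PipelineConfig, run_pipeline

cfg = synth.SimulationConfig(
    n_probes=300,
    pathway_sizes={"metal_stress": 25, "unfolded_protein": 25},
    compounds=[
        synth.CompoundArchetype("metalotox", concentration=10.0, responses={
            "metal_stress": synth.PathwayResponse("Hill", amplitude=3.5,
                                                  onset_h=3.0, shape=3.0),
            "unfolded_protein": synth.PathwayResponse("Exp5", amplitude=3.0,
                                                      onset_h=10.0, shape=2.0),
        }),
        synth.CompoundArchetype("inert_control", inert=True),
    ],
    seed=11)
counts, metadata, truth = synth.simulate_experiment(cfg)
report = run_pipeline(PipelineConfig(outdir="example_out", seed=11,
                                     n_perm=500, n_boot=60),
                      counts=counts, metadata=metadata,
                      collection=synth.pathway_gene_sets(truth))
```

Printed headline numbers from this exact run:

```
probes after row-sum filter: 255
significant DEGs per time: {'1': 0, '2': 4, '4': 24, '6': 28, '8': 29,
                            '12': 49, '16': 50, '20': 52, '24': 53}
peak DEG time: 24.0 h
significant ORA sets at peak: ['metal_stress', 'unfolded_protein']
                   k   m   n    N             p             q  significant
metal_stress      25  25  51  245  2.548779e-20  5.097559e-20         True
unfolded_protein  24  25  51  245  4.603851e-18  4.603851e-18         True
probes eligible for BMT: 63 | retained BMTs: 38
              gene best_model    BMT   BMTL   BMTU  fitPValue  predicted_lfc_at_BMT
G0094_10658  G0094       Exp5  0.720  0.601  0.859      0.606                 0.320
G0225_11575  G0225       Exp5  0.995  0.816  1.214      0.596                 0.640
G0057_10399  G0057       Exp5  1.284  1.019  1.881      0.573                 0.644
G0154_11079  G0154       Exp5  1.591  1.067  2.245      0.168                -0.827
G0071_10497  G0071       Hill  1.801  1.387  2.148      0.646                -0.425
inert control: total significant DEGs = 0 | retained BMTs = 1
```

Reading this: DEG counts rise from 2 h and peak at 24 h; both planted
pathways are significantly over-represented at the peak time (k of the m
pathway genes among the n DEGs out of N background genes; p hypergeometric,
q after FDR); 38 probes pass the BMT retention filters, the earliest
benchmark times (0.7–1.8 h, with their bootstrap bounds) belonging to the
fast metal-stress archetype; and the inert compound yields no DEGs and a
single spurious retained BMT, consistent with the prefilter's false-positive
allowance.

Per-stage TSVs (DEG tables per time point, ORA tables, Williams prefilter,
per-probe BMT table, accumulation curve, earliest-gene ranking) and a
`report.json` land under `example_out/<compound>/`.

The same stages are scriptable from the shell via the `bmtime` CLI
(`simulate`, `filter`, `deg`, `ora`, `bmt`, `run-all`, `report`); run
`bmtime --help`.

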