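# lcgrn

Two-condition single-cell RNA-seq analysis with **directional PIDC**
gene-regulatory-network inference, packaged with a synthetic benchmark
whose true network is known.

The pipeline reimplements the computational workflow used to study how
migration reprograms human Langerhans cells (epidermal antigen-presenting
cells) towards a tolerogenic, Treg-priming state: quality control and
pooled size-factor normalization of UMI counts, Leiden clustering,
Welch-*t* differential expression, tolerogenic-signature assembly and
per-cell scoring (mean z-score and a GSVA-style single-sample enrichment),
partial-information-decomposition network inference restricted to
TF → target edges, and AUCell-style regulon-activity enrichment.  Because
the original study's conclusions rest on unreleased per-donor processing,
the package ships a fully specified generative benchmark instead: every
stage can be scored against planted truth.

## The statistic at the core

For a gene pair (X, Y) and each context gene Z, partial information
decomposition with the Williams–Beer redundancy splits the mutual
information I(X;Y) into redundant and unique parts.  With the specific
information

I_spec(S; Y=y) = Σ_s p(s|y) log₂ [ p(s|y) / p(s) ],

the redundancy of sources X and Z about Y is
I_min = Σ_y p(y) · min( I_spec(X;y), I_spec(Z;y) ), and
Unique_X(Y|Z) = I(X;Y) − I_min.  The **proportional unique contribution**
of the pair accumulates the unique share over all contexts, in both
directions:

u_XY = Σ_Z Unique_X(Y|Z)/I(X;Y) + Σ_Z Unique_Y(X|Z)/I(X;Y).

Each gene's u-scores are mapped through a per-gene CDF (empirical by
default) and an edge's **confidence** is F_X(u_XY) + F_Y(u_XY) ∈ [0, 2].
The directional step keeps only pairs touching a transcription factor,
orients them TF → target (both directions for TF–TF pairs), and retains
edges with confidence strictly above 1.

All information quantities are maximum-likelihood plug-in estimates in
bits on uniform-width discretized expression (⌈√n⌉ bins by default).

## Worked example

```python
from lcgrn import PipelineConfig
from lcgrn.pipeline import run_benchmark
from lcgrn.simulate import default_spec

res = run_benchmark(default_spec(seed=0), PipelineConfig(seed=0))
rep = res.network_report
print(f"cells after QC: {res.norm.n_cells}, genes: {res.norm.n_genes}")
print(f"significant genes: {len(res.called_deg)} "
      f"(sensitivity {res.deg_report.sensitivity:.2f}, "
      f"FDP {res.deg_report.empirical_fdp:.2f})")
print(f"network: {res.network.n_edges} edges with weight > 1")
print(f"directed AUPR {rep.aupr:.3f} vs prevalence {rep.prevalence:.3f} "
      f"(MI baseline {res.mi_baseline_report.aupr:.3f})")
for _, row in res.regulon_z[res.regulon_z.group == "B"].iterrows():
    print(f"regulon {row.regulon}: z = {row.z:.2f} in condition B")
```

prints

```
cells after QC: 1140, genes: 100
significant genes: 19 (sensitivity 1.00, FDP 0.00)
network: 77 edges with weight > 1
directed AUPR 0.888 vs prevalence 0.241 (MI baseline 0.775)
regulon TF1: z = 0.76 in condition B
regulon TF2: z = 0.75 in condition B
```

Reading: of 1200 simulated cells (600 per condition), 1140 survive the
20% mitochondrial filter.  All 19 genes whose generative rates differ
between conditions are recovered at q < 0.01 and |log₂FC| > 1 with no
false calls.  The directional PIDC network keeps 77 TF → target edges
above the confidence-1 threshold; ranking candidate edges by PIDC
confidence yields an area under the precision-recall curve of 0.888 —
3.7× the 0.241 prevalence of true edges and above the raw
mutual-information ranking baseline (0.775).  The regulons of the two
TFs activated in condition B are enriched there (z > 0.4).

A command-line interface mirrors the stages, e.g.

```sh
lcgrn simulate --out bench/
lcgrn preprocess --in bench/condition_B --out pre/
lcgrn pidc --norm pre/normalized.csv --gmt bench/signature.gmt \
           --tfs bench/tfs.txt --out net/
lcgrn evaluate --edges net/network_edges.tsv --gold bench/gold_edges.tsv
```

## Layout

- `src/lcgrn/simulate.py` — generative benchmark + truth-scoring harness
- `src/lcgrn/preprocess.py` — QC, pooled-deconvolution normalization, HVG, Leiden
- `src/lcgrn/diffexp.py` — Welch-t DE, consensus signatures
- `src/lcgrn/scoring.py` — z-score and GSVA-style signature scoring
- `src/lcgrn/pidc.py` — discretization, MI, PID redundancy/unique, PUC,
  confidence, directional network, regulon extraction
- `src/lcgrn/regulons.py` — AUCell-style activity + enrichment
- `src/lcgrn/pipeline.py` — end-to-end benchmark run
- `docs/methods.md` — model details, parameter choices, limitations
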