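# targetmet

Targeted LC-MS metabolomics processing for library-anchored, polarity-switching
HILIC workflows: peak extraction from centroided mzML runs, blank-control
detection thresholds, differential metabolite abundance, and ¹³C
natural-abundance correction for stable-isotope tracing — plus a
ground-truthed synthetic-data generator so every stage can be verified
end to end without instrument data.

## Who this is for

Labs running *targeted* metabolite panels (an in-house library of formulas,
adducts and reference retention times) on high-resolution instruments, who
quantify by peak height and call detection against instrument blanks rather
than by untargeted feature finding. The package reimplements that processing
chain as a tested, scriptable library with a CLI.

## The method

**Extraction.** For a library compound with neutral formula *M*, adduct ion
(e.g. [M+H]⁺) and reference retention time *t₀*, an extracted ion
chromatogram is built from the matching-polarity MS1 scans inside
*t₀* ± 0.5 min, summing centroid intensity within a ±5 ppm window around the
theoretical m/z

&nbsp;&nbsp;&nbsp;&nbsp;m/z = (M + Δ_ion + k·Δ¹³C) / |z|,&nbsp;&nbsp;Δ¹³C = 1.0033548 Da,

where *k* is the number of heavy-carbon substitutions (k = 0 for ordinary
quantification). The XIC apex is the reported height; a measurement is kept
only if the apex lies within ±7.5 s of a reference apex — by default the
median apex across study samples (a two-pass consensus).

**Detection.** Per metabolite, the detection threshold is
max(3 × mean(blank heights), 10 000 a.u.). A study cell at or above the
threshold is detected; non-detected cells are imputed with the threshold for
group statistics (fold changes on such cells are flagged as bounds), or with
zero for count-model downstream analyses.

**Differential abundance.** Two-sided pooled-variance t-tests per metabolite
on the imputed matrix (Welch optional); p < 0.05 flags significance, with
Benjamini–Hochberg q-values reported alongside. Row z-scores and
Euclidean/complete-linkage hierarchical clustering provide heatmap ordering;
a volcano table gives (log₂FC, −log₁₀ p) coordinates.

**Tracing.** For a metabolite with *n* carbons measured at m+0…m+n, natural
¹³C abundance (a = 0.0107) is removed by the m+0-anchored rule

&nbsp;&nbsp;&nbsp;&nbsp;corrected[k] = max(0, raw[k] − C(n,k)·(a/(1−a))ᵏ · raw[0]),

and fractional enrichment is corrected[k] / Σ corrected. A full
binomial-matrix inversion mode is available for comparison.

## Worked example

Simulate a two-group study (6 vs 6 plus 3 blanks, glucose doubled and
lactate halved in the treated group) and run the full pipeline:

```python
import pandas as pd
from targetmet import PipelineConfig, run_pipeline, SimulationConfig

config = PipelineConfig(
    outdir="demo",
    simulate=SimulationConfig(seed=42, n_metabolites=12, n_samples_per_group=6,
                              n_blanks=3, true_log2fc={"glucose": 1.0, "lactate": -1.0}),
)
run_pipeline(config)
stats = pd.read_csv("demo/stats.tsv", sep="\t")
print(stats.sort_values("p")[["metabolite", "log2fc", "p", "q", "significant"]]
      .head(5).to_string(index=False, float_format=lambda v: f"{v:.4g}"))
```

prints

```
metabolite  log2fc         p        q  significant
   lactate -0.8879 0.0002021 0.002425         True
   glucose  0.7269  0.002668  0.01601         True
  pyruvate -0.2995   0.02022  0.08087         True
  creatine -0.2392   0.06037   0.1811        False
    malate -0.2115    0.1618   0.3883        False
```

The two spiked metabolites top the list with fold-change estimates near
their true effects (−1 and +1 on the log₂ scale, attenuated slightly by
20 % between-sample noise at n = 6); pyruvate is a chance positive at
p < 0.05, which the q column already discounts. `demo/` also holds the raw
matrix, detection flags, thresholds, imputed matrices, volcano coordinates,
cluster ordering and a manifest with input/output hashes.

The same stages are available from the shell:

```
targetmet simulate --seed 42 --out demo_sim
targetmet extract --mzml-dir demo_sim/mzml --library demo_sim/library.tsv \
    --samples demo_sim/samples.tsv --out matrix.tsv
targetmet blankcorrect --matrix matrix.tsv --samples demo_sim/samples.tsv --outdir out
targetmet stats --matrix out/blank_corrected.tsv --samples demo_sim/samples.tsv \
    --group-a control --group-b treated --outdir out
```

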