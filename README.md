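# chromfate

Chromatin-level analysis of cell-fate transitions, built around the
computational questions of pioneer transcription-factor biology in the
Arabidopsis stomatal lineage: how differentiation potential falls as cells
commit (per-cell transcriptional entropy), where lineage bHLH factors bind
relative to each other and to nucleosomes (peak overlap, motif occurrence,
nucleosomal vs non-nucleosomal binding), which genes they regulate (a
single-cell target rule), how induced factor binding remodels nucleosome
occupancy (size-factor-normalised differential occupancy), and whether a
factor and its chromatin-remodeler partners bind with constrained spacing
(PWM-localised distance distributions against a triangular independence
null).

Everything runs at desk scale on synthetic data with planted ground
truth, so every step is checkable against the truth tables the generator
emits. The package is for computational biologists who want these
analyses as tested, reusable functions rather than one-off scripts.

## The statistics at the core

* **Transcriptional entropy** per cell: S = −Σᵢ pᵢ ln pᵢ with
  pᵢ = cᵢ/Σc, summarised per cluster; the two-tier concentration model
  (top 10% of genes holding a share s of transcripts) gives the analytic
  reference S = −[s ln(s/k₁) + (1−s) ln((1−s)/k₂)].
* **Peak overlap significance** by uniform re-placement permutation,
  p = (1 + #{perm ≥ obs})/(1 + n_perm).
* **Target rule**: a gene is a factor target iff detected in ≥ 25% of
  factor-expressing cells, log2FC ≥ 0.223 (CP10k means, pseudocount
  10⁻⁴), and ≥ 1 binding site within the gene body or 3 kb upstream of
  the TSS.
* **Nucleosome calling** from smoothed occupancy with a Poisson tail
  score; peaks are nucleosomal iff summit ± 73 bp overlaps a call.
* **Differential occupancy** with median-of-ratios size factors and
  log2FC = log2((treat/sf_t + 1)/(mock/sf_m + 1)).
* **Co-binding spacing**: signed distances between PWM-localised sites at
  shared peaks, classified constrained / relaxed / random against the
  triangular independence null f(d) = (2W − |d|)/(2W)² via KS at α = 0.01.

See `docs/methods.md` for assumptions, parameter defaults, and numerical
choices.

## Worked example

The numbered scripts under `analysis/` run the full study on the default
synthetic design (workspace under `scratch/`, headline tables copied to
`results/`):

```sh
cd analysis
python 01_simulate.py
python 02_entropy.py
python 03_peak_integration.py
python 04_nucleosomes.py
python 05_spacing.py
```

`02_entropy.py` prints the per-cluster entropy summary:

```
    cluster  n_cells  entropy_median  ...  n_expressed_median
meristemoid      120        7.220212  ...                1743
        GMC      120        7.062567  ...                1662
         GC      120        6.866268  ...                1560
   pavement      120        6.867602  ...                1558
concentration ordering holds: True
```

— entropy and expressed-gene counts fall along the differentiation axis
because the planted top-decile transcript share rises (0.30 → 0.40 →
0.50). `03_peak_integration.py` shows the planted co-binding and the
target rule at work:

```
overlap: observed 150 vs null 65.7+-5.7 (z=14.7, p=0.001)
motif within 100 bp of summit: 100.0% of 225 peaks
targets: 29 of 2000 genes pass the rule
```

(150 shared peaks against a null of ~66 chance overlaps; every A peak
carries its planted G-box; the 29 targets are the planted markers above
both thresholds plus genes the factor-cluster's expression tier genuinely
lifts past them.) `04_nucleosomes.py` recovers the chromatin truth:

```
nucleosome calls: 900 (planted 900)
peak classification vs planted truth: 100.0% agreement
shared/unique signal ratio: 2.00 (150 shared, 75 unique)
induced occupancy change: targets -0.97, others 0.01 (log2FC)
```

— all planted nucleosomes called, the planted 2× ChIP signal at shared
peaks and the 2-fold induced depletion (log2FC ≈ −1 at targets, ≈ 0
elsewhere) both read out. `05_spacing.py` closes with the spacing
analysis:

```
spacing: mean 9.97 bp, sd 1.90 bp
KS vs independence null: D=0.558, p=5.07e-41
classification: constrained (mode 10.5 bp, half-width 2.5 bp)
```

recovering the planted Δ = 10 ± 2 bp constrained geometry. The same
pipeline is available as a CLI (`chromfate run --out DIR --seed 1`, plus
per-stage subcommands `simulate`, `entropy`, `overlap`, `targets`,
`nuccall`, `classify`, `profile`, `diffocc`, `spacing`; see
`chromfate --help`).

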