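# Methods

This note documents the models and procedures implemented in `chromfate`,
the assumptions behind them, and the choices made where the design was
genuinely open. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Transcriptional entropy

For a cell with raw counts c_i over genes, we compute the Shannon entropy
of its transcript proportions,

    S = − Σ_i p_i log p_i,   p_i = c_i / Σ_j c_j,

with zero-count genes contributing exactly 0. Entropy is a proxy for
differentiation potential: progenitors spread transcription over many
genes (high S), differentiated cells concentrate it (low S).

Choices:

* **Log base.** Natural log (nats) by default; a base-2 option is exposed
  (`base=2`). Base only rescales every comparison.
* **"Expressed" gene.** Raw count ≥ 1 by default (`min_count` exposed).
* **No depth correction.** Entropy is computed on raw counts exactly as
  defined above. The plug-in estimator is biased low by roughly
  (k − 1)/(2N) for k expressed genes at depth N, so at the demo depth of
  5,000 transcripts a ~2,000-gene cell reads ~0.2 nats below the asymptotic
  value. Cluster *orderings* are unaffected; quantitative convergence
  checks therefore sample at depth 10^5–10^6, where the bias is < 0.1%.

**Two-tier model.** Expression concentration is parameterised by
(n_genes, top_fraction f, top_share s): k₁ = max(1, round(f·n)) high-tier
genes share s of all transcripts uniformly, the remaining k₂ genes share
1 − s. Its entropy has the closed form

    S = −[ s ln(s/k₁) + (1−s) ln((1−s)/k₂) ],

which reduces to ln n when s = f, increases in n at fixed (f, s), and
decreases in s past the uniform point. Simulated cells are multinomial
draws of fixed depth from the tier probabilities.

## Peak overlap permutation test

Significance of the overlap between two peak sets is assessed by
re-placing every subject peak uniformly at random within its own
chromosome (lengths preserved, no inter-chromosome moves), n_perm times;
the statistic is the number of query peaks overlapping ≥ 1 subject peak,
and

    p = (1 + #{perm ≥ observed}) / (1 + n_perm),

so p is never 0 and is valid (super-uniform) under the null. An optional
circular-shift mode preserves inter-peak spacing instead. Because the
statistic is integer-valued, p-values are discrete and slightly
conservative; calibration checks use peak densities at which the null
distribution of the statistic is wide enough for the discreteness to be
negligible. For a single re-placed subject of length l_s against a single
query of length l_q on a chromosome of length L, the per-permutation
overlap probability has the closed form (l_q + l_s − 1)/(L − l_s + 1)
(all start positions that touch the query), which the tests verify by
enumeration.

## PWM scanning and hit thresholds

PWMs store per-position base probabilities built from aligned sites with a
pseudocount ((count + 0.25)/(n + 1) per column by default); scanning uses
natural-log odds against the background composition, on both strands. A
site's position is the integer midpoint (start + L//2) of the matched
window.

The hit threshold is calibrated against the PWM's **null score
distribution** under the background model: for motif lengths ≤ 10 the
distribution is computed exactly by enumerating the per-position score
convolution (4^L outcomes); longer motifs fall back to Monte-Carlo. The
threshold is the smallest score whose null tail probability does not
exceed the requested rate (default 0.1%); because scores are discrete the
*realised* tail can be smaller, and it is returned alongside the threshold
so false-positive expectations use the achievable rate.

`best_site` scans every start whose midpoint lies within ±window
(default 50 bp) of the peak center and breaks score ties by smaller
|offset|, then plus strand, then leftmost — a total order, so results are
deterministic.

## Peak-to-gene annotation and the target rule

A peak is annotated to a gene when its **summit** lies inside the gene
body or within 3 kb upstream of the TSS (strand-aware); among eligible
genes the smallest |summit − TSS| wins, ties going to the
lexicographically smaller gene id. This is a deterministic, oracle-
checkable distillation of promoter-priority annotation; full annotation-
tool priority cascades (exon/intron/UTR classes) are intentionally not
reproduced.

Targets of a factor are genes that (i) are detected (count ≥ 1) in at
least 25% of factor-expressing cells (factor count ≥ 1), (ii) have
log2FC ≥ 0.223 versus non-expressing cells, and (iii) carry ≥ 1 annotated
binding site. Both thresholds are inclusive. The fold change is computed
on depth-normalised means (counts per 10k) with pseudocount ε = 10⁻⁴ on
both sides:

    log2FC = log2( (mean_in + ε) / (mean_out + ε) ).

The normalisation and ε are package choices (0.223 ≈ log2(1.168), a
common single-cell DE default); both are parameters.

## Nucleosome occupancy

**Calling.** Occupancy tracks (bin ≤ 20 bp) are smoothed with a 30-bp
Gaussian; local maxima with prominence ≥ 5 (track units) whose raw signal
clears the per-chromosome mean under a Poisson tail test
(q = −log10 P(X ≥ x), default q ≥ 2; a stringent q ≥ 50 preset matches
heavyweight callers) become 147-bp calls centred on the maximum,
resolved greedily by descending score so calls never overlap. The caller
trades the sophistication of production nucleosome callers for complete
auditability: every planted nucleosome in a clean track is recovered
exactly, which is what the recovery oracles require.

**Classification.** A ChIP peak is *nucleosomal* iff summit ± 73 bp (half
a nucleosome) overlaps any call; the window is a parameter.

**Metaprofiles.** Reference-point profiles average per-bp signal over
[anchor − flank, anchor + flank) in equal bins, flipping minus-strand
anchors; windows crossing chromosome ends are zero-padded and counted in
the profile metadata. Scaled gene-body profiles rescale each body to a
fixed number of bins using exact fractional-bin means of the cumulative
signal (genes shorter than the bin count are interpolated and flagged) and
bin flanks natively, orienting TSS-left. The profile mean is by
construction the column mean of the per-site matrix.

**Shared vs unique signal.** A's peaks are split by any-bp overlap with
B's peaks; summary means are taken over the central ±250 bp of each
profile so that neighbouring peaks inside the flanks do not dilute the
contrast (parameter `summary_halfwidth`).

**Differential occupancy.** Per-region summed signal acts as a
pseudo-count. Size factors follow the median-of-ratios scheme restricted
to its two-condition core: each condition's factor is the median over
regions of count / geometric-mean-across-conditions, computed over regions
non-empty in both conditions. Fold changes are

    log2FC = log2( (treat/sf_t + 1) / (mock/sf_m + 1) ),

with regions empty in both conditions set to 0 and flagged. Dispersion
shrinkage and per-region significance testing are out of scope. Two
numerical facts worth knowing: with two conditions the normalised
cross-condition median ratio equals 1 *exactly* only for an odd number of
usable regions (even counts interpolate the median); and a planted
depletion is diluted toward 0 by whatever background signal falls in the
region, so recovery checks use regions (± 150 bp) and background rates at
which the planted 2-fold depletion reads within 0.1 of −1.

## Co-binding spacing

Each factor's site is localised by `best_site` at its own peaks; shared
peaks (any-bp overlap, matched one-to-one by nearest summit) yield signed
distances d = pos_B − pos_A. Pairs where either factor lacks a scoring
site are dropped and counted, never imputed. Under independent binding
within ±W of a common center, d follows the triangular density
f(d) = (2W − |d|)/(2W)² on [−2W, 2W].

Classification: *random* when a one-sample KS test against the triangular
null is not rejected at α = 0.01; otherwise *constrained* when the
Gaussian-KDE density peak's half-width at half-maximum is ≤ 10 bp, else
*relaxed*. The 10-bp boundary is an operational definition of
"narrow"; distances are integers, and the lattice discreteness adds at
most ~1/(2W) to the KS statistic, which the calibration suite shows keeps
the type-I rate within the α = 0.01 band.

## Synthetic data

The generators are pure functions of (design, seed) — byte-identical
reruns — and every planted element is emitted in a truth table, so
downstream checks read ground truth from the data rather than from
constants in test code.

* **Genome and peaks.** I.i.d. uniform ACGT chromosomes; fixed-width peak
  slots with gaps; exact consensus motifs planted at declared offsets
  (PWM-sampled planting exists but consensus is the default, separating
  scanner correctness from planting noise). Before planting, chance
  occurrences of either consensus (and reverse complements) inside scanned
  windows are scrubbed; after planting, occurrences created at
  plant/background junctions are destroyed without touching planted bases.
  Constrained pairs place B at A + Δ + round(Normal(0, σ)); independent
  mode places both uniformly in ±W. Two motifs may only coexist where
  their overlapping bases agree (e.g. both factors reading one G-box), so
  a single physical genome cannot realise |d| < motif length for distinct
  motifs — *steric exclusion*. Genome-level independent-mode distances are
  therefore triangular-conditioned on non-overlap; exact triangular-null
  checks run through the spacing pathway with independently placed site
  coordinates instead.
* **Occupancy.** Nucleosomes on a regular grid (200 bp, i.e. 53-bp
  linkers) with every 10th slot left nucleosome-free (planted open
  regions, which also host the non-nucleosomal demo peaks — with 53-bp
  linkers every position between two nucleosomes is within 73 bp of one,
  so open slots are the only way to plant true negatives). Each nucleosome
  is a Gaussian bump (σ = 20 bp fuzziness, amplitude 40) on a uniform
  background of 0.1 per 10-bp bin; per-bin Poisson noise approximates read
  sampling (fragment-level simulation is out of scope). Induction
  multiplies bump amplitude by the depletion factor (default 0.5) at
  ~10% of planted nucleosomes. Both conditions share one noise substream,
  so a depletion factor of 1 gives identical tracks and the contrast is
  paired.
* **ChIP signal.** Noise-free Gaussian bumps (σ = 50 bp) at A's summits,
  amplitude doubled at peaks shared with B.
* **Single-cell counts.** Four epidermal-like clusters of 120 cells at
  depth 5,000, gene probabilities from per-cluster two-tier models
  (top 10% of genes holding 30/40/50/50% of transcripts — entropy falls
  with differentiation). The factor gene is detected (~100%) only in its
  cluster. Markers are moment-matched so declared detection rates and fold
  changes hold in expectation:

      p_in  = 1 − (1 − pct)^(1/depth)          (detection match)
      m_out = (m_in + ε)/2^log2FC − ε,  m = 10⁴·p   (fold-change match)

  with the remaining genes renormalised around the pinned ones.

**What the generator does not emulate** — real genome base composition
and repeats, fragment-length effects, per-cell depth variation,
overdispersion beyond multinomial/Poisson, ambient RNA and doublets, and
correlated gene programs. Passing recovery tests therefore demonstrates
correctness of the *methods* under their stated models, not performance
on real libraries.

## Pipeline

Stages (simulate → entropy → overlap → targets → nucleosome → diffocc →
spacing → report) communicate through files, so each stage is equally
reachable from the CLI on external inputs. Every table carries a header
comment with the package version, a hash of the analysis parameters
(output location excluded), and the seed; reruns with the same seed and
config are byte-identical, which the test suite asserts file-by-file.
`--resume` re-executes a stage only when one of its outputs is missing or
an upstream stage ran. The default design (260-kb peak genome, 300 peaks,
1,000 nucleosome slots, 480 cells) finishes in a few seconds on one CPU;
problem sizes in the validation functions (500-nucleosome recovery
tracks, 200-replicate calibration, 100-seed classifier calibration) were
chosen as the smallest sizes at which the measured quantities are stable
against their tolerance bands.

## Known limitations

* The annotation rule is a single-priority summit rule; peaks equidistant
  from two TSSs resolve lexicographically, not by expression.
* The nucleosome caller assumes mono-modal, roughly symmetric footprints;
  it does not model fuzziness scores, phasing, or overlapping particles.
* KS p-values are asymptotic; for spacing samples under ~50 pairs an
  exact two-sample option should be preferred.
* Entropy depends on sequencing depth through the plug-in bias; cross-
  dataset comparisons require matched depths (no correction is applied).
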