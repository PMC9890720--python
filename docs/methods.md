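# Methods

This note documents the models, parameter choices and known limitations of
`immunotopo`, in the order the pipeline runs.

## Stain separation

RGB is converted to optical density per channel, `OD_c = −log10((I_c + ε) /
I0_c)` with ε = 1e−8 guarding saturated pixels and negative OD clamped to 0
(over-bright pixels relative to the background estimate carry no stain
information). Stains mix additively in OD space, so per-pixel stain
amplitudes solve a 3×3 linear system whose rows are unit stain vectors;
negative solutions are clamped to 0. The default haematoxylin
(0.650, 0.704, 0.286) and DAB (0.269, 0.568, 0.778) vectors are the widely
used published H-DAB pair; the residual axis is their normalized cross
product. Per-image estimation projects tissue pixels (total OD > 0.15) onto
the principal plane of the un-centred OD cloud and takes the 1st/99th
percentile angular extremes as the stain directions — the standard
robust-extreme (SVD) heuristic. Estimation assumes the image contains
near-pure pixels of both stains; on images where every DAB-positive cell
also carries counterstain the DAB estimate is biased toward the mixture, so
the pipeline default is the published vector pair with estimation opt-in
(`stains.estimate_per_image`). Fewer than 200 tissue pixels triggers a
fallback to the defaults with a warning.

## Tissue detection and cell detection

Tissue is thresholded on the channel-OD sum (default 0.1 OD — above the
noise floor of blank glass, below the lightest stroma wash), closed with a
2 px disk, holes under 2 500 µm² filled and specks under 400 µm² removed. An
empty mask raises an unusable-core signal, and such cases drop out of the
per-case tallies exactly as degraded TMA cores do.

Cells are detected on the H+DAB OD sum so a strongly DAB-positive cell with
weak counterstain cannot be missed: Gaussian smoothing (σ = 1.5 µm), then
rolling-ball background subtraction implemented as grey-opening with a disk
footprint (radius 8 µm), threshold at 0.1 OD, connected components, and an
optional watershed split seeded from peaks of the *smoothed* distance
transform (smoothing σ = 1 µm suppresses plateau artefacts in fused clumps;
minimum peak separation 3 µm). Components outside [10, 400] µm² or with
centroids outside tissue are discarded; detections are sorted by (y, x) so
output order is deterministic. Per-cell stain means are measured over the
1-px-eroded component — the segmentation boundary sits on the smoothing
skirt of each nucleus, and including it systematically dilutes the DAB
signal of true positives (tiny components fall back to the full region). A
cell is positive when its mean DAB OD exceeds 0.2. All detection parameters
are exposed per staining type in the config, since optimal values differ
between markers; the defaults above suit lymphocyte-sized nuclei at
1–2 µm/px.

## Tumour/stroma pixel classification

Features per pixel: Gaussian-smoothed intensity, gradient magnitude and
local standard deviation of each deconvolved OD channel at scales
{1, 2, 4, 8} px (36 features), reflection borders. A random forest
(100 trees, depth ≤ 16, √p feature subsampling — standard settings for a
texture classifier of this size) is trained on up to 10 000 pixels per class
sampled from annotation polygons, with a 20 % held-out split reported as a
self-audit. One shared classifier per stain type serves the whole cohort.
Prediction assigns argmax class inside the tissue mask, background outside;
post-processing applies a majority filter (radius 2 px) and reassigns
connected tumour/stroma islands below 1 000 µm² to the opposite tissue class
(with only two tissue classes, the surrounding majority). Training is
deterministic for a fixed seed, and a persisted model reloads to
bit-identical predictions.

## Densities, phenotypes, scores

Compartment membership of a detection is the mask label at its centroid
pixel; background centroids stay unassigned and count in neither
compartment. Densities are positive cells per mm² of tumour, stroma, and
overall ((tumour + stroma counts) / (tumour + stroma area)); a case with
zero classified tumour or stroma area is unusable for topography. Cases
with two cores are averaged per (case, marker) before thresholding.

The per-marker cutoff defaults to the cohort median of per-case overall
densities (`cohort_median_overall`); the median of pooled per-compartment
densities (`pooled_compartment_median`) is implemented as an alternative
because both derivations appear in practice — even n uses the mean of the
middle pair. The phenotype rule is ordered: hot when tumour density ≥
cutoff, else excluded when stromal density ≥ cutoff, else cold. Boundary
conventions are deliberate and config-locked: phenotype compartment-high
uses ≥, while low/high dichotomization uses strict > (a case exactly at the
median is low, matching "≤ cutoff" row labelling). Combined-marker calls
default to the AND rule — a compartment is high only if every constituent
marker is high there — reflecting that lineage pairs such as CD3/CD8 mark
largely the same cells; with strongly correlated constituents the rule
choice moves few cases, and OR and mean-of-normalized-densities variants are
available. CPS is `min(100, 100 × positives / viable tumour cells)`, high
at ≥ 10; zero viable tumour cells is an undefined-CPS signal.
Semiquantitative TILs scores map density to {0, +, ++, +++} by fixed bin
edges (default 10 / 100 / 500 cells/mm²; zero density is always "0").

## Statistics

Pearson chi-square carries no continuity correction — the convention that
reproduces classical statistics-suite output, and the one under which every
published p-value bundled in `datasets` recomputes to its printed precision.
Expected counts below 5 raise a warning, not an error: the test is still
applied, as is common in published tables. Fisher's exact test is
hypergeometric for 2×2 and Freeman–Halton enumeration for r×c, with a
guard (~2×10⁶ tables) beyond which chi-square is suggested. Mann–Whitney
uses the exact null for small tie-free samples and the tie-corrected normal
approximation otherwise; Kruskal–Wallis is tie-corrected; Dunn's post hoc
test runs on pooled midranks with Holm adjustment by default (raw p is
reported alongside, since published work often leaves the adjustment
unstated). All tests are two-sided with α = 0.05.

Survival uses the Kaplan–Meier product-limit estimator and the log-rank
test. "Mean OS" is implemented as the restricted mean survival time — the
area under the KM curve up to τ (default: the largest observed time), which
is the mean that standard statistics suites print — with the classical
standard error `√(Σ A_i² d_i / (n_i(n_i − d_i)))`.

## Synthetic cohort generator

The generator produces the statistical structure the analysis assumes, not
photorealistic histology. One core: a circular tissue disk whose tumour
nests are a thresholded low-frequency Gaussian field (irregular interfaces,
≈4 nests by default, tumour fraction 0.4); immune cells are Poisson point
processes with separate intensities per compartment; every cell renders as
an anti-aliased haematoxylin disc (radius 3.5 ± 0.4 µm) and positive cells
add a DAB disc (amplitude 0.65 ± 0.10 OD); compartment-specific
haematoxylin washes (tumour 0.30, stroma 0.10 OD) plus counterstain-only
nuclei (900/350 per mm²) give the classifier a realistic texture cue;
Gaussian OD noise (sd 0.02) is added after Beer–Lambert mixing. Each marker
yields its own image of the shared geometry, matching serial-slide TMA
practice. All draws flow from a single seed; identical (spec, seed) is
bit-identical.

Cohorts plan each case as hot / cold / excluded (default equal thirds) with
class-conditional log-normal densities — medians (tumour, stroma) of
(700, 350), (50, 700) and (50, 70) cells/mm², log-sd 0.3. These medians are
free parameters chosen to give the clear class separation of a cohort in
which phenotyping is meaningful; published work reports only overall
medians, so no claim of cohort calibration is made. CD3 and CD8 share a
Gaussian copula at ρ = 0.9 (the strong lymphocyte co-expression reported in
this setting). PD-L1 CPS-high status follows a logistic model (baseline
0.10, odds ratio 6 for hot cases); an FGFR3 mutation (prevalence 0.10, the
order reported for sq-BLCA) multiplies CD8 / perforin / CD79A densities by
0.4; survival is exponential (baseline hazard 0.02/month, hazard ratio 0.4
for perforin-high cases — the simplest proportional-hazards model), with
uniform censoring of 30 % of cases over a 120-month follow-up. Default
cohort size is 114 cases.

What the generator does *not* emulate: nucleus shape and chromatin texture,
staining artefacts and folds, necrosis, core drop-out, spatial clustering
of immune cells beyond compartment membership, and multiplexed markers on
one section. Passing recovery tests therefore certifies the pipeline's
logic and numerics on data satisfying its model assumptions; they are not
evidence about antibody or scanner behaviour on real slides.

## Problem sizes and tolerances

Tests and the acceptance script use 0.4–0.6 mm cores at 1–2 µm/px,
cohort plans of 114 cases, 50 cohorts for effect-direction recovery, and
100k-draw Monte-Carlo oracles; these sizes make every recovery criterion
statistically decidable while keeping a full run in minutes on one CPU.
Oracle-equivalence checks compare against independent routes (enumeration,
permutation, hand-rolled estimators): chi-square is compared with the
fixed-margin permutation *mid*-p — the correct correspondence on a discrete
lattice — on tables inside the approximation's validity regime, since with
expected counts below 5 the chi-square tail genuinely differs from the
exact conditional null (that regime is flagged by the implementation's
small-expected-count warning instead).

## Known limitations

- No TMA de-arraying: inputs are pre-cut core images.
- One marker per stained image; no membrane/cytoplasm sub-segmentation, so
  PD-L1 scoring is count-based (CPS), not pattern-based.
- Two tissue classes only (no necrosis/artefact class).
- The pixel classifier is texture-based; on real slides with stain
  variation, per-cohort retraining (the intended workflow) is required.
- Freeman–Halton is exact but enumerative: tables much larger than the
  published 3×2s should fall back to chi-square.
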