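# immunotopo

Tumour-immune topography analysis of IHC-stained tissue-microarray (TMA)
cores, built for pathology groups quantifying immune infiltrates on
brightfield slides. The pipeline re-implements, as a reusable and tested
library, the now-standard digital workflow for characterising tumour-immune
phenotypes in squamous-differentiated bladder cancer (sq-BLCA): stain
separation, positive-cell detection, tumour/stroma pixel classification,
per-compartment cell densities, hot / cold / excluded phenotyping, PD-L1
scoring, and the association and survival statistics such studies report.

Because no public image cohort exists for this setting, the package ships a
seeded synthetic TMA-cohort generator with full ground truth (cell
coordinates, compartment masks, clinical table), so every stage is testable
end to end — plus the published cross-tabulations of a 114-case sq-BLCA
cohort as ready-made inputs for the statistics battery.

## The model

**Stain separation.** Brightfield stains follow Beer–Lambert optics: with
background intensity `I0_c` per channel, the optical density is
`OD_c = −log10(I_c / I0_c)`, and a pixel's OD is a non-negative mixture
`OD = a_H · s_H + a_DAB · s_DAB` of unit stain vectors. Deconvolution
inverts the 3×3 system per pixel (haematoxylin, DAB, residual); vectors can
be re-estimated per image from the extreme directions of the OD point cloud.

**Cell detection.** Nuclei are detected on the smoothed,
background-subtracted H+DAB OD sum (threshold → connected components →
distance-transform watershed → area filter); a cell is marker-positive when
its mean DAB OD exceeds a per-staining threshold.

**Compartments and densities.** A random-forest pixel classifier trained on
annotated representative areas labels tissue pixels tumour or stroma;
densities are positive cells per mm² of each compartment, averaged over
cores when a patient contributes two.

**Tumour-immune phenotype.** Per marker, the cohort median density is the
cutoff `c`; a case is **hot** if its intratumoural density ≥ c, else
**excluded** if its stromal density ≥ c, else **cold**. Marker combinations
(e.g. CD3/CD8) require every constituent high in a compartment (AND rule,
configurable). Densities dichotomize low/high at the cohort median
(ties → low).

**PD-L1 CPS.** `CPS = min(100, 100 × n_PD-L1-positive / n_viable tumour
cells)`, high when CPS ≥ 10.

**Statistics.** Pearson chi-square (no continuity correction), Fisher's
exact test (Freeman–Halton for r×c), Spearman's rho, Mann–Whitney U,
Kruskal–Wallis with Dunn's post hoc, Kaplan–Meier with log-rank, and the
restricted-mean survival time ("mean OS") with its standard error.

## Worked example

```python
import numpy as np
from immunotopo import datasets, statlab, synthcore, topography

# association from a published cross-tabulation
table, _ = datasets.crosstab("cd8_density_vs_subtype")
res = statlab.pearson_chi_square(table)
print(f"CD8 density (low/high) vs tumour subtype: "
      f"chi2={res.statistic:.2f}, df={res.df:.0f}, p={res.p_value:.3f}, n={res.n}")

# synthetic cohort: phenotype calls and survival effect
plan, clinical = synthcore.draw_cohort_plan(synthcore.CohortSpec(seed=1))
thresholds = topography.cohort_median_threshold(plan)
calls = topography.phenotype_table(plan, thresholds)
cd8 = calls[calls["marker"] == "CD8"]["phenotype"].value_counts(normalize=True)
print("CD8 phenotype mix:", {k: round(v, 2) for k, v in cd8.items()})

perf = plan[plan["marker"] == "perforin"].merge(clinical, on="case_id")
cutoff = thresholds.set_index("marker").loc["perforin", "cutoff"]
group = np.where(perf["overall_density"] > cutoff, "high", "low")
lr = statlab.logrank(perf["os_months"], perf["event"], group)
print(f"log-rank, OS by perforin density: chi2={lr.statistic:.2f}, p={lr.p_value:.4f}")
```

prints

```
CD8 density (low/high) vs tumour subtype: chi2=4.81, df=1, p=0.028, n=106
CD8 phenotype mix: {'cold': 0.35, 'excluded': 0.33, 'hot': 0.32}
log-rank, OS by perforin density: chi2=35.20, p=0.0000
```

Higher CD8 density is over-represented among mixed-histology tumours
(p = 0.028 from the published counts); the synthetic cohort splits CD8
phenotypes roughly in thirds, as planned; and perforin-high cases show the
built-in protective survival effect.

The image pipeline runs end to end from the shell:

```bash
immunotopo run-all --seed 7 --out-dir out
```

which simulates a cohort of stained cores, detects cells, trains and applies
the tumour/stroma classifier, derives densities/phenotypes and writes
`densities.csv`, `thresholds.csv`, `phenotypes.csv`, `results.csv` and
Kaplan–Meier step functions, all stamped with the config hash and seed.

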