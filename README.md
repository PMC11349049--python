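# trialomics

Translational and statistical analytics for CD8-stratified basket
trials of immune-checkpoint combinations, built for biostatisticians and
computational biologists who need the full chain — clinical endpoint
statistics through multi-omic biomarker comparison — as tested, reusable
code rather than one-off scripts.

The setting is a trial that enrols patients with advanced solid tumors
into a CD8-high and a CD8-low group by the baseline percentage of
intratumoral CD8 T cells (cutoff 15%), and asks whether treatment
converts "cold" (CD8-low) tumors into "hot" ones while tracking response
across tumor RNA/WES, serum proteomics, cytometry, multiplex
immunofluorescence (mIF), CITE-seq, TCR repertoires and ctDNA.

## What it computes

**Clinical endpoints** (`trialomics.endpoints`). Best-overall-response
classification (objective response = CR/PR; disease control = CR/PR or
SD ≥ 24 weeks; CD8 conversion = any on-treatment biopsy ≥ 15%), and
Bayesian credible intervals for the rate endpoints. With *s* successes
in *n* patients and a Beta(α₀, β₀) prior, the posterior is

    p | s, n ~ Beta(α₀ + s, β₀ + n − s)

and the reported interval is the equal-tailed 95% posterior interval.
DCR/ORR use the informative Beta(0.4, 1.6) prior; the conversion rate is
computed "without a prior", implemented both as the improper Beta(0, 0)
(posterior Beta(s, n − s), the default) and the uniform Beta(1, 1).
Logistic regression with Wald tests links endpoints to CD8 measures;
Fisher's exact test handles TMB/MSI-type 2×2 tables.

**Layer-aware differential comparison** (`trialomics.compare`). A
two-sample Student t per feature plus a per-assay effect gate:
RNA (p < 0.05, |log₂FC| > 1), Olink NPX (p < 0.05, |log₂FC| > 0.75),
CyTOF percent-of-parent (p < 0.01), 28-color flow (p < 0.05,
|Δmean| > 20 pp), mIF (p < 0.05, |Δmean| > 5 pp) — with quantile
normalization, baseline (pretreatment) subtraction, mean-of-z signature
scores and hypergeometric gene-set over-representation.

**mIF phenotyping** (`trialomics.mif`). Per image and marker, the pixel
intensities of all segmented cells are clustered by an *exact* 1-D
3-means (dynamic programming, deterministic — no Lloyd seed); the
positivity threshold is the mean of the two largest centers; a cell is
positive when >50% of its pixels exceed the threshold; hierarchical
phenotypes are aggregated as percent-of-parent per ROI and averaged,
unweighted, across the ROIs of an image.

**Trajectory inference** (`trialomics.trajectory`). Hastie–Stuetzle
principal curves (cubic smoothing-spline smoother with GCV penalty,
arc-length pseudotime scaled to [0, 1], no start cell required), and
per-gene Gaussian GLMs of z-scored expression on pseudotime with vendor
as batch covariate; group/timepoint dependence is tested via a
pseudotime × group interaction under a Bonferroni-adjusted p ≤ 0.10 gate
combined with a coefficient-magnitude gate (±1 trajectory, ±0.25
group/timepoint).

**TCR repertoires** (`trialomics.tcr`). Chao1 richness
(S_obs + f₁²/2f₂, with the bias-corrected fallback when f₂ = 0),
cross-patient clone sharing by exact CDR3 amino-acid identity, and
blood–tumor repertoire overlap.

**ctDNA** (`trialomics.ctdna`). Positivity (≥ 2 of 16 tracked SNVs),
molecular response (≥ 50% decrease from baseline MTM/ml), and
baseline-adjusted log₁₀ comparisons between responders and progressors.

**Synthetic data** (`trialomics.simulate`). Seeded generators for every
input layer with planted, recorded ground truth — patient-level trial
data are not publicly shareable, so recovery and calibration are
demonstrated against simulations.

## Worked example

```python
from trialomics.endpoints import beta_binomial_interval, conversion_interval_both

dcr = beta_binomial_interval(18, 72, prior=(0.4, 1.6), level=0.95)
print(dcr.point_estimate_pct, dcr.lower_pct, dcr.upper_pct)
# 25.0 15.8 35.2

conv = conversion_interval_both(14, 39)["IMPROPER_ZERO"]
print(conv.point_estimate_pct, conv.lower_pct, conv.upper_pct)
# 35.9 21.8 51.4
```

A disease-control rate of 18/72 under the Beta(0.4, 1.6) prior gives a
point estimate of 25.0% with 95% credible interval 15.8–35.2%; the
conversion rate of 14/39 evaluable CD8-low patients is 35.9%
(21.8–51.4% under the improper-prior reading).

A full synthetic round trip from the shell:

```bash
trialomics simulate --kind cohort --seed 1 --out sim/
trialomics endpoints --patients sim/patients.tsv --out out/
```

which writes `out/endpoints.json` with per-group DCR/ORR intervals and
the conversion analysis.

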