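# nirsbci

Offline analysis of a binary functional near-infrared spectroscopy (fNIRS)
brain–computer interface: mental arithmetic (MA) versus a low-load baseline
task (BL), recorded over the anterior prefrontal cortex in eyes-open (EO)
and eyes-closed (EC) variants. The package is aimed at BCI researchers who
want a tested, reproducible reference implementation of this classic
pipeline — from raw dual-wavelength light intensities to group-level
statistics — together with a paradigm-faithful synthetic-data generator
that provides ground truth for every stage.

## The method

1. **Optics.** Raw intensities are converted to optical-density changes,
   ΔOD(λ, t) = −log₁₀ I(λ, t)/I₀(λ), and then to hemoglobin concentration
   changes via the modified Beer–Lambert law: ΔOD(λ) = Σ_c ε(λ, c) Δc · d ·
   DPF(λ), solved per channel and sample as a 2×2 system for (Δ[HbO],
   Δ[HbR]) in mmol/L (wavelengths 760/850 nm, source–detector distance
   d = 30 mm, forehead-typical differential pathlength factors).
2. **Preprocessing.** 6th-order Chebyshev type-II band-pass, passband
   0.01–0.2 Hz, applied forward–backward (zero phase); epochs −8…25 s
   around task onsets; baseline correction by the mean over −2…0 s.
3. **Separability maps.** The point-biserial statistic
   r = √(N₁N₂)/(N₁+N₂) · (E[x₁]−E[x₂])/σ (σ = pooled population SD) per
   channel × time, p-values via t = r√((n−2)/(1−r²)), Bonferroni
   correction, rendered as sign(r)·(−log₁₀ p).
4. **Features.** Mean and OLS slope of Δ[HbO]/Δ[HbR] in 3 s windows
   stepped by 1 s, window right-ends at −5…25 s (31 bins); z-scored with
   training-fold statistics only.
5. **Classification.** Shrinkage LDA, w = Σ̃⁻¹(μ_MA−μ_BL) with
   Σ̃ = (1−γ)Σ̂ + γνI and the Ledoit–Wolf analytic γ, and a linear SVM;
   HbR+HbO fusion by a second-stage linear meta-classifier on the base
   models' decision values, re-estimated inside each CV fold. Protocol:
   10 repeats of stratified 5-fold CV with splits shared across all
   classifiers and chromophore sets.
6. **Evaluation.** Accuracy curves over window anchors, per-subject maxima
   in 5–25 s, paired t / Wilcoxon signed-rank tests, LDA-vs-SVM
   comparison, and mutual information between the two classifiers'
   predictions regressed against accuracy.

The synthetic generator reproduces the block design (3 runs per paradigm,
10 MA + 10 BL trials per run, 15 s tasks, 20–25 s randomized rests) with
double-gamma hemodynamic responses, 1/f drift, ~0.1 Hz Mayer waves,
respiratory and cardiac oscillations, and white optical-density noise,
then maps the ground truth through the forward Beer–Lambert model so the
full inversion chain is exercised.

## Worked example

```bash
python analysis/01_simulate_cohort.py --seed 0 --subjects 2 --out results/analysis
python analysis/02_hemodynamics.py    --out results/analysis
python analysis/03_separability_maps.py --out results/analysis
python analysis/04_classification.py  --out results/analysis
python analysis/05_group_evaluation.py --out results/analysis
```

Script 01 reports the design arithmetic (`S01 EO: 3 runs, 30 MA + 30 BL
trials, 10 channels`). Script 02 prints the grand-average responses that
drive classification, e.g.

```
S01 EC hbr: grand-average 5-15 s response MA +0.559 vs BL -0.174 (1e-3 mmol/L)
```

— Δ[HbR] rises under mental arithmetic and dips slightly under baseline,
the contrast the separability maps then localize (script 03):

```
S01 EC hbr: max |r| at ch4 (|r| = 0.70)
S02 EC hbr: max |r| at ch7 (|r| = 0.72)
```

ch4 and ch7 are the Fp1/Fp2 channels where the simulated effect is
strongest. Script 04 prints each subject's maximum cross-validated
accuracy per classifier and chromophore set (e.g. `S02 EC lda both: max
94.2% at 12 s`), and script 05 closes with the group comparisons:

```
EO vs EC (LDA, HbR+HbO): mean 95.5 vs 91.5%, paired t p = 0.5704
accuracy vs classifier-agreement MI: slope 13.6 %/bit, intercept 82.1%
```

i.e. the eyes-closed paradigm performs comparably to eyes-open on this
cohort, and subjects whose two classifiers agree more (higher mutual
information) are classified more accurately.

The same pipeline is available as a console script
(`nirsbci run --out results/pipeline --seed 0`) and as a library
(`nirsbci.run_pipeline(PipelineConfig(...))`).

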