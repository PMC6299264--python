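# cortimat — cortical microstructure maturation from diffusion MRI

`cortimat` is a desk-scale re-implementation of a cortical-maturation
analysis pipeline for multi-shell neonatal diffusion MRI: multi-compartment
tissue-model fitting with neonatal-specific adaptations, lower-shell
diffusion-tensor scalars, free-water-masked regional aggregation, and
biphasic developmental-trajectory statistics. It is aimed at researchers who
want every stage of such a pipeline as tested, importable Python — together
with synthetic-data generators that make the whole chain verifiable without
any scanner data.

## The model

Each voxel's normalised diffusion signal is modelled as three compartments:

```
A = (1 − f_iso) · (v_in · A_in + (1 − v_in) · A_en) + f_iso · A_iso
```

* **A_in** — intra-neurite space: zero-radius "sticks" whose orientations
  follow a Watson distribution `f(n) ∝ exp(κ (μᵀn)²)`. Dispersion is
  summarised by the orientation dispersion index
  `ODI = (2/π)·arctan(1/κ) ∈ (0, 1]`.
* **A_en** — extra-neurite space: an axially symmetric Gaussian tensor whose
  perpendicular diffusivity follows the tortuosity rule
  `d_⊥ = d_∥ (1 − v_in)`, orientation-averaged under the same Watson
  distribution.
* **A_iso** — free water, `exp(−b·d_iso)`.

`v_in` is the neurite density index (NDI). Compartment diffusivities are
fixed (`d_∥ = 1.7×10⁻³`, `d_iso = 3.0×10⁻³ mm²/s`, configurable). All Watson
orientation averages are evaluated exactly via a 1-D reduction of the sphere
integral of `exp(nᵀBn)` (Gauss–Legendre with a Bessel-`I₀` azimuthal factor,
overflow-free at any κ).

Around the model sit the pipeline stages:

* **Fitting** (`noddi_fit`) — per-shell b0 normalisation (the two shells are
  acquired at different echo times), grid-search initialisation with the
  intra-neurite start range restricted to [0, 0.3] (appropriate for the
  premyelinated cortex; the optimiser keeps the full [0, 1] bound), bounded
  nonlinear least squares, and a linearised-dictionary (NNLS) fallback for
  voxels whose first pass does not converge.
* **DTI** (`dti`) — weighted linear least-squares tensor fit on the b=750
  shell only, yielding FA/MD/AD/RD.
* **Regional aggregation** (`regional`) — per-region medians over cortical
  grey matter, excluding free-water-dominated voxels (f_iso ≥ 0.5).
* **Developmental statistics** (`devstats`) — Spearman partial correlations
  with covariates regressed out by a linear mixed model (random intercept
  per subject for repeated scans); independent windows below/above 38 weeks
  post-menstrual age; continuous two-segment ("biphasic") breakpoint
  regression searched between the PMA quartiles and compared with a single
  line by small-sample-corrected AIC (AICc); Benjamini–Hochberg FDR at 5%
  per contrast.
* **Synthetic data** (`dwi_synth`) — voxel/phantom signals from the forward
  model with per-shell baselines and Rician noise, and cohort tables
  (99 subjects, 8 rescanned, term-skewed scan ages) whose trajectories
  encode a breakpoint at 38 weeks with known slopes, covariate effects and
  subject random intercepts.

## Worked example

`examples/05_cohort_statistics.py` simulates a cohort with the maturational
pattern built in and runs the full statistical layer:

```
cohort: 107 acquisitions from 99 subjects

whole-cortex metric-vs-age correlations (covariate-adjusted):
         FA  pre38: rho -0.49  p 0.00031 *
        ODI  pre38: rho +0.78  p 1.6e-11 *
        NDI post38: rho +0.35  p 0.007 *
        ODI post38: rho -0.03  p 0.81
         MD   full: rho -0.64  p 1.4e-13 *
  ...

ODI breakpoint estimate: 37.1 weeks (true 38.0), preferred model: biphasic
```

Dispersion (ODI) rises steeply before 38 weeks and is flat afterwards,
neurite density (NDI) rises after 38 weeks, and diffusivity falls across the
whole range — the biphasic signature of cortical maturation, detected with
the breakpoint localised near its true week. The other examples walk through
the forward model (`01`), a noisy single-voxel fit (`02`), the
FA–dispersion coupling (`03`), and phantom-to-region aggregation (`04`).

The command-line surface mirrors the library:

```bash
cortimat simulate-cohort --config cohort.yaml --out cohort.tsv
cortimat cohort-stats --table cohort.tsv --config stats.yaml --out results/
cortimat fit-noddi --dwi dwi.nii.gz --bval dwi.bval --bvec dwi.bvec \
    --mask gm.nii.gz --out maps/
```

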