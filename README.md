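# idrfret

Quantitative analysis pipeline for intrinsically-disordered-protein
(IDP) FRET biosensors of osmotic stress and macromolecular crowding —
the kind built from a LEA-family disordered domain sandwiched between a
cyan donor and a yellow acceptor.  Hyperosmotic shock crowds the
cytoplasm, compacts the disordered chain, and raises FRET; the package
turns the raw readouts of that experiment into numbers:

* **plate-reader ratiometrics** — DxAm/DxDm ratios normalized to the
  untreated control mean, emission-spectrum normalization, in-vitro
  acceptor/donor band ratios (500–600 / 460–499 nm), donor-bleedthrough
  correction, dose–response sensitivity slopes, loess-style time-course
  smoothing with confidence bands;
* **FLIM-FRET** — Poisson maximum-likelihood mono-exponential lifetime
  fits of TCSPC histograms (40 MHz pulsing, period-wrapped model,
  optional Gaussian IRF), FRET efficiency E = 1 − τ_DA/τ_D, phasor
  coordinates g = Σc·cos ωt/Σc, s = Σc·sin ωt/Σc, and the per-cell
  shock statistic Δlifetime = (τ_final − τ_initial)/τ_initial;
* **single-cell imaging** — the blur/mask/divide ratiometric-image
  recipe, automatic cell segmentation and vacuole detection, and the
  vacuolar ratio (vacuole area / cell area) statistics that explain
  cell-to-cell FRET heterogeneity;
* **sequence design** — charge-patterning κ (blob-level asymmetry δ
  normalized by the maximally segregated δ_max), helix and disorder
  proxies, and selection of composition-preserving scrambles with less
  charge mixing and lower helix propensity than the reference;
* **coarse-grained solution scanning** — bead-per-residue Metropolis
  Monte Carlo ensembles under E = W_solv + U_lj + W_el, ensemble-mean
  radii of gyration normalized to the most expanding condition, and a
  per-sequence compaction sensitivity.

Every stage runs on synthetic data with planted ground truth generated
in-package (`idrfret.synth`), so the whole pipeline is testable without
any microscope.  It is aimed at people building or analysing
genetically encoded crowding sensors who want a reference
implementation of the downstream math.

## Layout

The computation lives in the library (`src/idrfret/`): `synth`
(generators), `fretspec` (plate/spectra), `flim` (lifetimes/phasors),
`cellquant` (images/cells), `seqtools` (κ/scrambles), `chainscan`
(chain ensembles), `io` (TIFF/CSV/FASTA/XYZ adapters).  The numbered
scripts under `analysis/` are thin narrative drivers that run each
study stage and write tables under `results/`.

## Worked example

```bash
python analysis/02_flim_lifetimes.py --seed 1
```

simulates 500k-photon TCSPC acquisitions at the three study lifetimes,
fits them, and prints:

```
 condition  tau_true_ns  tau_fit_ns  tau_stderr_ns  reduced_chi2  phasor_g  phasor_s  fret_efficiency_pct
donor_only         3.62      3.6227         0.0053        1.0416    0.5470    0.4976               0.0000
     basal         3.04      3.0386         0.0045        1.0994    0.6315    0.4822              16.1215
  shock_1M         2.32      2.3246         0.0034        1.1272    0.7453    0.4357              35.8303

delta-lifetime basal -> 1 M shock: -0.2350 (-23.5% of the initial lifetime)
```

The fitted lifetimes recover the planted values within their standard
errors and reduced χ² ≈ 1 confirms the mono-exponential model; the
phasor points sit on the universal semicircle and march right (toward
shorter lifetimes) as FRET rises; efficiencies here use the fitted
donor-only lifetime as the unquenched reference, and the shock shortens
the donor lifetime by 23.5%.

The single-cell stage ties FRET heterogeneity to vacuoles:

```bash
python analysis/03_single_cell_vacuoles.py --seed 1
```

```
segmented 100 cells (100 planted)
                               pair       r  p_value   n  planted_r
vacuolar_ratio vs baseline_lifetime  0.3252   0.0010 100       0.44
   vacuolar_ratio vs delta_lifetime -0.3793   0.0001 100      -0.47
```

Cells with larger vacuoles start at longer donor lifetimes (less
crowded cytoplasm) and lose less lifetime on shock (the vacuole buffers
water loss): both planted correlations come back with the right sign,
comfortably significant at n = 100.

The remaining drivers cover the plate dose response and bleedthrough
(`01`), κ-constrained scramble design (`04`), and the coarse-grained
λ scan of chain compaction (`05`).

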