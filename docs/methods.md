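# Methods

`idrfret` re-implements, as a tested pipeline over synthetic data with
planted ground truth, the quantitative analyses behind an
intrinsically-disordered-protein (IDP) FRET biosensor for osmotic stress
and macromolecular crowding: a LEA-family disordered sensory domain
sandwiched between a cyan donor (mCerulean3-like) and a yellow acceptor
(Citrine-like).  Crowding compacts the disordered chain, shortening the
donor–acceptor distance, raising FRET.  The pipeline covers five
analysis layers; this note records the models, the parameters that
matter, and the choices made where the design was open.

## 1. Plate-reader ratiometrics (`fretspec`)

The readout is the sensitized-emission ratio R = DxAm/DxDm per well,
normalized to the mean raw ratio of the in-run zero-treatment control
group, so the control mean is exactly 1 by construction.  Grouped
normalization (per plate, per experiment) is available through the
`group_by` argument; the default is one reference per table.

* **Dose–response sensitivity** is the OLS slope of normalized ratio
  versus concentration (per molar), with a dead-band of |slope| < 0.01
  mapped to "none"; positive slopes are called *compaction* (ratio rises
  as the chain compacts), negative *expansion*.  The slope is a plain
  linear summary of a near-linear response; no Hill or saturation model
  is fitted at analysis time.
* **Spectra** are normalized at the 515 nm sample (nearest sampled
  wavelength; ties resolve to the lower wavelength).  The in-vitro band
  ratio sums sampled intensities in the inclusive 500–600 nm acceptor
  band over the inclusive 460–499 nm donor band.
* **Bleedthrough**: donor leakage into the DxAm channel is the
  least-squares slope β of DxAm against DxDm on an acceptor-photobleached
  dataset (where all DxAm signal is leakage).  The regression fits an
  intercept (background) but only the slope is applied
  (DxAm − β·DxDm, floored at 0); background belongs to ROI subtraction
  upstream.
* **Time-course smoothing** is loess-style local linear regression with
  tricube weights over the `ceil(span·n)` nearest neighbours
  (default span 0.3), evaluated at the input times, with a pointwise 95%
  band from the local weighted residual variance and the
  equivalent-kernel norm.  Local linear fits reproduce constant and
  exactly linear series to machine precision; the band is approximate
  (no bias term).  It is hand-rolled because the confidence band and the
  local variance are part of the contract; the statsmodels `lowess`
  smoother serves as an independent cross-check in the tests.

## 2. FLIM-FRET (`flim`)

TCSPC histograms are modelled as a mono-exponential under pulsed
excitation at a 25 ns repetition period (40 MHz):

    m_k = A · exp(−t_k/τ) / (1 − exp(−T/τ)) + B,

the geometric previous-pulse sum making the shape exact for any τ/T
(and removing the truncation bias that matters once T < 8τ); an optional
Gaussian instrument response of width σ_IRF enters analytically through
the exponentially-modified-Gaussian form, computed with `erfcx` for
stability.  τ, A and B are estimated by **Poisson maximum likelihood**
— the correct counting-noise model at any photon count, unlike least
squares — initialised from a log-linear regression on
background-subtracted counts, optimised by L-BFGS-B and polished with a
simplex step (the L-BFGS relative stopping rule is loose against the
~10⁶-magnitude likelihood).  The standard error comes from the observed
information (numerical Hessian); goodness of fit is the Pearson χ²
over n_bins − 3 degrees of freedom, which flags multi-exponential
decays against a parametric-bootstrap mono-exponential null.  Fits
require ≥ 100 photons.

FRET efficiency uses the lifetime route E = 1 − τ_DA/τ_D.  Out-of-range
efficiencies are returned with a warning flag, never clamped: negative E
is a diagnostic of fitting problems or a mismatched unquenched-donor
reference, and clamping would hide it.  The unquenched donor lifetime
is an explicit argument, so per-image or per-experiment references are
both possible; the analysis scripts use the per-experiment donor-only
fit.  Published population-mean lifetime/efficiency pairs from vendor
FLIM software are generally *not* reproducible by applying
E = 1 − τ_DA/τ_D to the printed means, because vendor pipelines use
per-image unquenched references that are not reported; the pipeline
therefore treats such pairs as non-recomputable and only ever computes E
from its own fitted lifetimes.

The **phasor transform** uses the first harmonic of the repetition rate,
ω = 2π/T: g = Σc·cos(ωt)/Σc, s = Σc·sin(ωt)/Σc.  For a wrapped
mono-exponential the continuous-time coordinates are exactly
g = 1/(1+(ωτ)²), s = ωτ·g, so noiseless histograms land on the
universal semicircle s² + (g−½)² = ¼ to the bin-discretisation error
(< 10⁻⁴ at 256 bins).  The fractional lifetime change of a shock is
Δlifetime = (τ_final − τ_initial)/τ_initial.

## 3. Single-cell imaging (`cellquant`)

The ratiometric-image recipe mirrors the standard Fiji workflow:
z-stacks are summed, a scalar background per channel (ROI mean, or the
5th percentile when no ROI is given) is subtracted with negatives
floored, all channels are Gaussian-blurred (σ = 1 px), a binary mask is
taken from the AxAm channel (Otsu by default; manual threshold
accepted), and the ratio of blurred DxAm to blurred DxDm is reported
inside the mask, zero outside.  The mask is stored as {0,1}; the 8-bit
{0,255}-then-÷255 convention is mathematically identical.  Pixels are
row-major with origin top-left; areas are px², with `pixel_size` only
for µm² reporting.

Where the original workflow selected cells and outlined vacuoles by
hand, the pipeline substitutes documented automatic rules with exposed
thresholds:

* **Cells**: Otsu on AxAm, hole filling (the sensor-free vacuole is a
  hole), removal of objects < 50 px², then distance-transform watershed
  to split touching cells (marker peaks ≥ 8 px apart).
* **Vacuole**: per cell, the largest connected region with
  AxAm < θ·(cell median), θ = 0.5, required not to touch the cell
  boundary (so off-cell darkness is never counted).  The median-based
  reference assumes the vacuole occupies *less than half* the cell
  area — when it does not, the median itself samples the vacuole and the
  rule degenerates; this is a stated limitation, and the synthetic
  population respects it (see §6).  Vacuolar ratio = vacuole area /
  cell area, zero when no region qualifies; vacuole ⊆ cell and
  ratio ∈ [0,1] always.
* **Per-cell statistics**: mean lifetime and mean per-pixel ratio over
  cytoplasm (cell minus vacuole).  Pearson correlations report the
  two-sided p from t = r·√((n−2)/(1−r²)) on n−2 df.

The adherent-cell (U-2 OS-style) ROI analysis takes five circular ROIs
per cell — one background, four cytoplasmic — subtracts the background
ROI means per channel, applies the bleedthrough slope, and averages the
four cytoplasmic DxAm/DxDm values.

## 4. Sequence descriptors and scramble design (`seqtools`)

Charge patterning is summarised by κ = mean over blob sizes g ∈ {5,6}
of δ_g/δ_max,g, where δ_g is the mean squared deviation of the windowed
charge asymmetry σ = NCPR²/FCR from its global value.  Conventions:
K,R = +1; D,E = −1; histidine and termini neutral; windows without
charged residues contribute σ = 0; compositions whose δ_max is zero
(e.g. uniformly charged sequences) get κ = 0.

δ_max is exact by **exhaustive enumeration over all distinct charge
arrangements for lengths ≤ 12**.  For longer sequences it is the
maximum over a structured candidate family: charged blocks separated
and flanked by neutral runs (`0^a +^p 0^m −^q 0^c`), plus arrangements
that split one charge species into two terminal runs around the other
(`s^a 0^b t^q 0^c s^d`).  Published κ implementations differ in this
search; simpler pure-block orderings demonstrably miss the maximum
(e.g. for 2+/4−/2n at g = 6 the maximizer is `+0----0+`), whereas this
family reproduces the exhaustive δ_max for **all** 730 composition ×
blob-size cases up to length 12.  Beyond length 12 it remains a
structured search, so a pathological arrangement could in principle
exceed it; for scramble ranking this is immaterial because δ_max is
constant within a composition.

Helix propensity is a ranking proxy: the negated Pace–Scholtz
helix-breaking free energies averaged over sliding windows (default 6).
Disorder is the composition-only charge–hydropathy classification:
disordered when mean absolute net charge exceeds 2.785·⟨H⟩ − 1.151 with
⟨H⟩ the normalized Kyte–Doolittle hydropathy.  Both stand in for
full predictors (helix-coil theory servers, disorder predictors) and
are used **only** to rank or filter sequences, never compared
numerically to any predictor output.

Scramble selection: from a pool of uniform (Fisher–Yates) permutations
of the reference — identical composition and length by construction —
keep candidates with strictly larger κ, strictly lower mean helix
score, and the same disorder classification; rank by κ descending.

## 5. Coarse-grained solution scanning (`chainscan`)

A deliberately minimal bead-per-residue stand-in for all-atom solution
space scanning.  Fixed 3.8 Å bonds, bead diameter 3.8 Å, kT = 1.  The
energy decomposes as E_total = W_solv + U_lj + W_el:

* **U_lj** — a hydropathy-independent WCA repulsive core (strength
  `repulsion_eps`, default 1 kT; 0 switches excluded volume off and
  recovers the ideal freely jointed chain) plus an attractive
  Lennard-Jones tail of depth `attraction_eps`·(mean normalized
  Kyte–Doolittle hydropathy of the pair) (default 0.3 kT at hydropathy
  1), truncated at 2.5 diameters.  The split into an always-on core and
  a hydropathy-scaled well is what makes the zero-hydropathy chain a
  self-avoiding (not ideal) walk.
* **W_el** — Debye–Hückel screening, q_i·q_j·l_B·exp(−r/κ_D)/r, with
  Bjerrum length 7.1 Å (water, 298 K) and Debye length 10 Å by default
  (≈ 150 mM monovalent salt).
* **W_solv = −λ·n_contacts** over non-bonded pairs within 1.5
  diameters: λ ≥ 0 is the unitless solution-repulsion parameter, larger
  λ rewarding intrachain contacts and driving compaction.  λ = 0 is the
  reference, most-expanding condition.

Sampling is Metropolis Monte Carlo with pivot (rotate the shorter side
of a random bead about a random axis) and crankshaft (rotate an
interior segment about its end-to-end axis) moves, both exactly
bond-preserving.  Energy changes are computed incrementally from the
cross pairs between the rigidly moved segment and the rest, and audited
against a full recomputation every 10³ steps (worst observed drift is
reported; the tests require < 10⁻⁸ kT).  Each condition runs five
independent repeats from distinct seeded random-walk starts; the
condition SD is taken across the five repeat means.  The default
protocol is scaled down to 10⁵ steps (2×10⁴ equilibration, snapshot
every 125 steps); full-scale counts (5×10⁷/10⁷/12 500) are plain
configuration values for cluster runs.  Problem sizes in the shipped
analyses (40–64 residues, 10⁵ steps, 5 repeats) were chosen so a scan
completes in about a minute on one core while the repeat SDs stay a few
percent of the mean.

The scan normalizes the per-condition ensemble-mean Rg by the grid
maximum (1 at the most expanding condition) and reports sensitivity
= 1 − min normalized Rg.  The default λ grid (0, 0.2, 0.4, 0.6, 0.8)
spans the model's coil–globule crossover for chains of this size —
mapped once by scanning a wider range — because a grid confined to the
collapsed branch would only compare noise.  λ is not calibrated to any
physical osmolyte; only orderings and trends are meaningful.  Whether
the coarse-grained model reproduces all-atom native-vs-scramble
sensitivity orderings is left as an exploratory comparison
(`analysis/05_solution_scan.py`), deliberately not asserted by any test.

## 6. Synthetic data with planted truth (`synth`)

Every generator plants a known effect and flows all randomness from one
integer seed, so downstream estimates can be checked against ground
truth rather than against other code.

* **Plate wells**: expected raw ratio
  baseline·(1 + slope·min(c, c_sat)); the noisy ratio multiplies a
  unit-mean lognormal factor with CV `noise_cv`, and DxDm/DxAm split a
  constant total intensity consistently with that ratio, so channel
  arithmetic and ratio noise agree exactly and zero-concentration
  controls are always present.  Defaults (baseline 1.0, slope 0.5/M,
  5% CV, 9 replicates, 0–1 M doses) mirror a strong osmolarity
  responder read in vivo.
* **Decays**: multinomial draws of `total_photons` over bin
  probabilities of the wrapped, optionally IRF-convolved exponential
  mixture (oversampled 16× per bin), plus an optional uniform
  background fraction — photon count conserved exactly, bit-identical
  under a fixed seed.  Defaults: τ = 3.62 ns (the unquenched donor),
  25 ns period, 256 bins.
* **Cell populations**: non-overlapping disk cells (radius 8–14 px at
  0.24 µm/px) with concentric dark disk vacuoles (the sensor is
  cytosolic); vacuolar ratios uniform on (0.05, 0.45) — a realistic
  yeast vacuole/cell area range that also respects the θ·median
  vacuole rule's minority assumption.  Baseline lifetime
  τ₀ = 2.70 + 0.90·VR + ε ns; post-shock fractional change
  Δ = −(0.20 − b·VR) + ε′ with b = −0.25, so larger vacuoles start
  longer-lived and lose less lifetime.  The
  `with_target_correlations` constructor inverts
  r = |slope|·sd(VR)/√(slope²·sd(VR)² + σ²) to choose the noise SDs
  that plant requested population correlations (the shipped analyses
  plant +0.44 and −0.47).  Channel intensities follow the lifetime
  through E = 1 − τ/τ_D with a constant donor-excitation total split
  between DxDm and DxAm, so the ratio is monotone in E and consistent
  with the lifetime image.
* **Scramble pools**: uniform permutations preserving the residue
  multiset.  The shipped reference is a designed synthetic LEA-like
  64-mer (hydrophilic, FCR 0.45, well-mixed charges κ ≈ 0.06,
  disordered by the charge–hydropathy proxy, with a helix-prone
  stretch) — *not* a natural sequence; real-sequence runs take a FASTA.

What the generators deliberately do **not** emulate: optics (PSF,
photobleaching, anisotropy, 3-D sectioning), cell shape beyond disks,
granule formation, lifetime heterogeneity within a cell, or
osmolyte-specific chemistry.  Passing tests therefore demonstrate that
the estimators recover what they claim from data obeying the stated
models — not that the models exhaust real microscopy data.

## Numerical notes and degenerate inputs

* Zero DxDm inside a ratio mask → pixel set to 0 and counted in a
  warning; zero DxDm in a well table → an error naming the wells.
* Spectrum anchors snap to the nearest sample, ties to the lower
  wavelength; a zero anchor intensity is an error.
* Fits: all-zero or < 100-photon histograms are rejected; non-positive
  lifetimes/denominators raise domain errors rather than returning NaN.
* Pivot/crankshaft proposals preserve bonds exactly; a degenerate
  crankshaft axis (coincident endpoints) counts as a rejected move.
* Cell placement is rejection sampling with a 3 px margin and a bounded
  retry budget; exhausting it raises a placement error rather than
  silently returning fewer cells.
* Kappa: FCR = 0 → undefined (error); δ_max = 0 → κ = 0 by convention;
  sequences shorter than the largest blob are rejected.

## Known limitations

* The vacuole rule fails by construction for vacuoles ≥ half the cell
  area; the automatic θ = 0.5 criterion is validated only on synthetic
  disks, not on real manual outlines.
* The loess confidence band ignores smoothing bias near sharp steps.
* δ_max beyond length 12 is a structured search, not a proof.
* The coarse-grained chain model preserves the solution-repulsion →
  compaction axis and sequence dependence through charges/hydropathy,
  nothing atomistic; torsional corrections and explicit osmolytes are
  out of scope.
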