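# Methods

This note documents the models, estimators, numerical choices and
limitations behind `specbind`. Units are molar for concentrations, ppm for
chemical shifts, nm for wavelengths and deg·cm²·dmol⁻¹·residue⁻¹ for mean
residue ellipticity (MRE) throughout.

## 1:1 binding equilibrium and fast-exchange observable

The model is a single-site association H + G ⇌ HG with
K_a = [HG]/([H][G]) and K_d = 1/K_a. Mass action on the analytical
concentrations [H]₀ and [G]₀ gives the familiar quadratic whose physical
root is

    [HG] = ½ (S − √(S² − 4[H]₀[G]₀)),   S = [G]₀ + [H]₀ + 1/K_a.

As printed, this subtracts two nearly equal numbers when binding is tight
(S² ≫ 4[H]₀[G]₀ fails to hold in the dangerous direction: the root
approaches S). `complex_concentration` therefore evaluates the
algebraically identical form

    [HG] = 2[H]₀[G]₀ / (S + √(S² − 4[H]₀[G]₀)),

which only ever adds positive quantities. `equilibrium_oracle` is a fully
independent check: bisection on the free-guest concentration g, using
[HG] = K_a[H]₀g/(1 + K_a g) and the monotone guest balance
g + [HG] − [G]₀. Its stopping rule is relative to the current bracket, not
to [G]₀, because under tight binding with limiting guest the root g sits
many orders of magnitude below [G]₀. The two routes agree to better than
1e−10 relative over 10⁴ random triples spanning 12 decades in K_a (tested).

Under fast exchange a probe's observed shift change is the
population-weighted average Δδ = δ_HG · [HG]/[H]₀, pinned to 0 at
[G]₀ = 0: shifts are differences from the free state, and the free point
carries no adjustable offset. (The alternative — floating an offset at zero
DNA — would absorb referencing errors between spectra at the cost of one
degree of freedom; with the short schedules used here it is not
identifiable and is deliberately not offered.)

### Titration fitting

`fit_titration` estimates log₁₀ K_d (positivity structural, near-symmetric
error surface) plus one δ_HG per probe by least squares
(lmfit/`least_squares`), with K_d shared across probes by default when
several are supplied. Reported K_d standard errors are the delta-method
transform of the log-scale Jacobian-covariance error:
se(K_d) = ln 10 · K_d · se(log₁₀K_d). Defaults: K_d bounds 10⁻⁹–10⁻¹ M,
initial K_d at the log-midpoint of the bounds, initial δ_HG from the
largest observed shift. Degenerate data (all shifts below 10⁻⁶ ppm) or
optimiser failure yield a flagged, never-raising result; a fit that ends on
a K_d bound is reported non-converged.

Small-sample caveat: with a handful of titration points the 95% interval
should use the t quantile at (n − p) degrees of freedom, not 1.96; the
coverage test does, and achieves nominal coverage (≥90/100 seeds) at
0.005 ppm noise. Note that with [H]₀ ≈ K_d and schedules stopping at
1.3:1, a single titration with 0.005 ppm noise determines K_d to only
~10–20% (this package's fit reaches the Cramér–Rao bound for the design;
the limitation is informational, not numerical).

## CSP analysis

Combined CSP weight: the standard amide weighting α = 0.14 compresses the
~5× wider ¹⁵N range onto the ¹H scale; it is exposed as a parameter
everywhere it enters (combined CSP, tracking metric). Arginine sidechain
εNH peaks are first-class probes with their own atom tag — at low pH they
are the direct reporters of protein–phosphate contacts.

Peak tracking across a titration is nearest-neighbour in the weighted
metric √(ΔH² + (αΔN)²) from the previous matched position, with a 0.5 ppm
reject radius; a rejected point is treated as lost (intermediate-exchange
broadening), and more than one consecutive loss truncates the series with
a warning. Manual overrides (ratio → assignment) take precedence. This is
a greedy tracker: it assumes steps between consecutive titration points
are small against peak spacing, which holds for fast-exchange data but not
for slow-exchange cross-peak hopping (out of scope).

Structure mapping writes log₁₀(max(CSP, floor)/floor) into the B-factor
column of every atom of each mapped residue (Biopython PDB I/O), floor
0.01 ppm, so the floor maps to 0 and each decade adds 1. Residue numbering
follows the full engrailed sequence (456–510); a configurable offset
reconciles differently numbered structures. Raw per-residue values are
mapped, with no smoothing along the sequence.

## CD analysis

MRE conversion: MRE = mdeg/(10 · c · l · N) with c in molar, pathlength l
in cm, N residues; exactly invertible given the metadata.

SVD: the wavelength × condition matrix (spectra linearly resampled onto
their common 1 nm grid) is decomposed exactly; shapes are unit-ℓ₂ columns
oriented to correlate positively with the family mean, amplitudes absorb
the singular values, so the full-rank reconstruction is exact and the
rank-k error equals the ℓ₂ tail of discarded singular values.

Debye–Hückel trend: the fitted law A(I) = s₀ + c₁√I/(1 + c₂√I) is the
extended (screening-saturated) form — proportional to √I at low I as in
the limiting law, bounded by s₀ + c₁/c₂ as I → ∞, monotone for c₂ ≥ 0
(enforced). A pure limiting-law fit (c₂ pinned to 0) is selectable.

**Which amplitude carries the salt response?** The second SVD component's
loadings are an affine image of the underlying helix fraction, so fitting
them recovers the screening coefficient c₂ — the *shape* of the salt
response — exactly, but s₀ and c₁ only up to the arbitrary scale/offset of
a unit-norm singular vector. This indeterminacy is mathematical, not
numerical. The salt-series runner therefore fits the law twice: once to
the second-component SVD loadings (shape) and once to the per-spectrum
222 nm helix fractions, which are calibrated in absolute units by the
estimator's anchors and recover (s₀, c₁, c₂) completely. Both fits appear
in the report.

Helix content uses the single-wavelength 222 nm estimator
f = (θ₂₂₂ − θ_coil)/(θ_helix − θ_coil) with θ_coil = +640 and the
chain-length-corrected θ_helix = −40000·(1 − 2.5/N); values outside [0, 1]
are clipped with a warning. This is a documented convention — adequate for
tracking relative helicity changes, cruder than basis-set deconvolution
(deliberately out of scope).

Protein/DNA separation projects the mixture onto the two basis spectra by
SVD pseudo-inverse (singular values below 10⁻¹² of the largest are
truncated; the basis condition number is reported and > 10⁶ flags
collinearity). The protein-attributed spectrum is mixture − fitted DNA
contribution — not the fitted protein component — so bound-state features
absent from a free-protein basis stay attributed to the protein rather
than being projected away.

Ionic strength: I = ½Σcᵢzᵢ², with 1:1 salts (NaCl, KF — both treated as
fully dissociated monovalent pairs) expandable from a single entry, and
named weak buffers (phosphate pK_a2 = 7.21 carrying the −1/−2 pair,
acetate 4.76, MES 6.27, Tris 8.07) speciated by Henderson–Hasselbalch at
the stated pH. Electroneutrality is completed with Na⁺ for acid-type
buffers and Cl⁻ for base-type (Tris), reflecting how such buffers are
titrated in practice. Worked check: 25 mM sodium phosphate pH 6.8 +
50 mM NaCl → 0.089 M, i.e. ~100 mM at nearest-100 reporting.

## Synthetic data

The generator's defaults are the study conditions: 200 µM protein, 54
residues, guest:host schedule {0, 0.2, 0.4, 0.6, 0.8, 1.0, 1.3} (a second
schedule {0, 0.5, 1, 2, 3} serves the 3:1-excess experiment), K_d 95 µM
(moderate salt; 170 µM for the high-salt condition), helix fraction 0.30
free → 0.50 bound, and a 600 MHz ¹H spectrometer frequency. Salt-response
coefficients (s₀, c₁, c₂) = (0.30, 0.35, 3.0) give a gradual 30% → ~38%
helix rise over 0–0.7 M ionic strength — a moderate, saturating response
consistent with counterion screening being weaker than DNA binding.

CD spectra are helix/coil two-shape mixtures built from Gaussian bands
(helix: +193 nm, −208, −222 nm; coil: −198 nm with a small positive
baseline; B-DNA: +275, −245 nm). Each protein shape is scaled so its
222 nm value hits the corresponding estimator anchor, making the 222 nm
estimator exact on noise-free generated spectra by construction — the
round-trip then tests the pipeline's bookkeeping (MRE, resampling,
separation), not the estimator's absolute accuracy on real CD data. The
band parameters are phenomenological stand-ins, not fits to measured
spectra; real spectra contain aromatic/disulfide contributions and
instrument baselines the generator does not emulate.

HSQC titrations move each probe by δ·[HG]/[H]₀ from fixed, well-separated
reference coordinates (free list exactly at reference: positional noise
applies only at ratios > 0, since shifts are reported relative to the free
state). The intermediate-exchange regime attenuates heights by the
fast-exchange-limit two-site broadening R_ex = p_free·p_bound·Δω²/k_ex
(Δω from the ¹H limiting shift at the spectrometer frequency; heights =
base/(1 + R_ex/R₂₀), R₂₀ = 20 s⁻¹, k_ex = 2000 s⁻¹ default). This is a
regime caricature sufficient to reproduce mid-transition intensity dips —
it is not Bloch–McConnell, and generated positions still follow the
fast-exchange average even in the "intermediate" regime.

Determinism: every generator draws from `SeedSequence((seed, stream))`
with a fixed stream per generator, so identical truth + seed gives
bit-identical output and the three generators are independent of one
another.

Peak lists are written with 4 decimal places in both dimensions: 3-decimal
quantisation alone perturbs a noise-free recovered K_d by ~2%, which would
mask the round-trip contract.

## Problem sizes

Default test and acceptance workloads are small by design: titrations of
5–7 points × 1–7 probes, CD families of 8 spectra × 61–111 wavelengths,
oracle cross-checks over 10⁴ random parameter triples, and a 100-seed
Monte-Carlo coverage experiment. The full suite runs in a few seconds.

## Known limitations

- Single-site 1:1 binding only; no cooperative, multi-site or
  slow-exchange models, and no lineshape fitting.
- The greedy peak tracker can mis-assign when titration steps exceed peak
  spacing; the match-distance diagnostic and manual overrides are the
  escape hatches.
- Helix content is a single-wavelength convention, not a deconvolution;
  absolute helicities on real spectra carry the convention's bias.
- Ionic-strength speciation is ideal-dilute (activity coefficients of
  unity) and single-step for each buffer.
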