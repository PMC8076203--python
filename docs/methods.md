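# Methods

## Problem setting

A Cartesian multi-coil acquisition samples complex k-space lines along the
phase-encode axis (ky); acceleration removes whole lines. Auto-calibrated
k-space methods (GRAPPA and its nonlinear variant) re-synthesize each
missing line from acquired neighbours using weights fitted on a fully
sampled central block of ACS (auto-calibration signal) lines. This package
implements those reconstructions together with three families of line
masks, and quantifies how redistributing a fixed line budget across the
phase-encode axis changes reconstruction quality.

Conventions used throughout: 0-based line indexing with the DC line at
`floor(n_ky/2)`; the ACS block spans `[center − floor(acs/2),
center + ceil(acs/2))`; centred, orthonormal 2-D FFTs (so Parseval holds
exactly and image/k-space energies agree — metrics are scale-free only in
the sense that no renormalization is ever applied); unsampled lines are
exactly zero in every k-space container.

## Sampling schemes

**Traditional (uniform)** masks keep the ACS block plus every line on the
single congruence grid `{i ≡ center (mod R)}` outside it. One global grid
(rather than independent per-side placement) keeps the ACS and outer
samples phase-aligned — the standard GRAPPA acquisition geometry — and
yields the budget `acs + ceil((n_ky − acs)/R)` for centred blocks
(e.g. 16 + 60 = 76 of 256 lines at R = 4; 24 + 39 = 63 at R = 6).

**VDS** shrinks the ACS block and spends the freed lines on a band at a
lower ORF (typically 2) flanking it; the outermost region stays on the
*same* global R-grid as the traditional mask it derives from, since VDS
modifies only the centre of the pattern.

**MVDS** keeps the ACS count unchanged and tiles the outer k-space with
bands of strictly increasing ORF, innermost first. Each band is split half
per side (odd remainder to the high-index side) and placed at its exact
stride, anchored on the previous band's outermost line, so consecutive
acquired lines within band k are exactly `orf_k` apart. When the symmetric
split would run past one matrix edge while the other side has room, single
lines are moved across deterministically (smallest-ORF band first); band
combinations whose total stride span exceeds the space outside the ACS are
rejected as geometrically infeasible. A small number of published band
combinations fall in that category (their span exceeds the available lines
by a few strides); the mask constructor refuses to fabricate them, while
their *accounting* (totals, R_net) remains reproducible arithmetically.

`R_net = N_full / N_sampled` uses the realized mask count, never a
closed-form fraction, and is reported rounded half-up to two decimals.

## GRAPPA

For a region with reduction factor R, the missing sample at offset
`r ∈ {1..R−1}` above an acquired line is modeled per target coil j as a
linear combination of sources `S_l(ky + bRΔky, kx + hΔkx)` over all coils
l, blocks `b ∈ {0, 1}` by default (the acquired line below the target and
the next above) and columns `h ∈ [−7, 7]` (the "15 × 2" kernel; both
ranges configurable but always contiguous).

Calibration slides this source/target pattern over the ACS block in steps
of R along ky — mirroring the acquired-line spacing the weights will be
applied to — and one sample along kx, keeping only instances whose source
lines, target line and principal columns lie fully inside the ACS block
and matrix (no zero-padded calibration rows). If no instance fits, the
reconstruction fails with an "ACS too small" error: this is precisely the
few-ACS failure mode that makes ACS-starved VDS masks underperform.

The fit solves `b = A x` per (region ORF, offset, target coil) by SVD
pseudo-inverse with relative cutoff 1e-10 when unregularized (reproducible
minimum-norm behaviour on rank-deficient systems; effective rank is
reported, never raised as an error), or Tikhonov damping `λ = ridge·s_max`
otherwise. The default ridge is 0 for GRAPPA and 1e-6 for NL-GRAPPA.

Synthesis fills each band's missing lines independently, innermost band
first, reading sources from the zero-filled input only (acquired lines of
the band, adjacent bands, or the ACS; zeros beyond the matrix edge), so
acquired samples are returned bit-identical. Missing lines beyond a
band's outermost acquired line are synthesized with the same band weights
from whatever sources exist; a missing line that falls *on* the band's
stride grid (possible only when a band stops short of the matrix edge) has
no valid offset and is left zero.

## NL-GRAPPA

The nonlinear variant lifts every neighborhood into the explicit
second-order polynomial feature space before the same linear fit: the
feature vector is `[1 | S_l(b,h) | S_l(b,h)² | S_l(b,h)·S_l(b,h+1) |
S_l(b,h)·S_l(b,h+2)]` in fixed C-order over (coil, block, column), with
length `N_k = 1 + 4·L·N_b·N_h`. The `h+1` / `h+2` partners beyond the last
kernel column are read from the same acquired line along the fully sampled
kx axis (zero outside the matrix), so all four second-order blocks keep
the same size. Features are complex products without conjugation; weights
are complex. Only the degree-2 expansion is implemented — the polynomial
kernel's full feature space is larger, and the kernel view is treated as
motivation only. Cross-coil and cross-block second-order products are
deliberately absent: exactly the printed expansion is computed.

Because squares and products are not homogeneous in the data scale, the
k-space is normalized by its maximum modulus before calibration and
synthesis and the synthesized values are rescaled afterwards; this
restores scale-equivariance to 1e-8 and keeps first- and second-order
features on comparable scales. Since the linear features are a coordinate
subspace of the lifted space, the nonlinear training residual can never
exceed the linear one on the same system (up to solver noise of order
1e-13 of the target norm when both residuals are numerically zero). Fits
with `M < N_k` (few ACS lines) are expected, produce a warning, and fall
back on the minimum-norm / ridge solution.

## Simulator and the exactness fixture

Acquisitions are modeled as `FFT(sens_l ⊙ image) + noise`, with i.i.d.
circular complex Gaussian noise of standard deviation σ per real and
imaginary component per sample (no coil correlation), generator state
passed explicitly everywhere. Three phantoms: the analytic modified
Shepp-Logan ellipse set; a smooth sum of Gaussian blobs whose centres and
widths keep border truncation (hence spectral leakage) below ~1e-9 of the
peak; and "speckle", the real part of white complex k-space noise under a
Gaussian spectral envelope (edge of k-space suppressed below ~1e-10).

Coil models: "smooth-gaussian" places Gaussian-magnitude bumps with
smooth random phase at equal angles around the FOV (SoS well away from
zero everywhere); "harmonic" gives unit-modulus pure harmonics
`exp(i 2π l (y − ny/2)/ny)` — phase measured from the centre pixel so that
under the centred FFT coil l's spectrum is exactly coil 0's rolled by l
lines. With at least R harmonic coils every missing line is an exact
linear combination of acquired coil lines (the SMASH construction), so
GRAPPA-type reconstructions must be exact; this is the package's primary
correctness oracle.

Two numerical subtleties make the oracle tight. First, a smooth *generic*
phantom is required: separable or few-component images (a handful of
isotropic Gaussians) make the calibration columns nearly dependent, the
minimum-norm weights then differ from the exact interpolating ones, and
the reconstruction error floor rises to ~1e-4 — hence the speckle phantom
for exactness tests. Second, the ACS must be large enough that the fit is
overdetermined (`M ≥ N_k`), particularly for the lifted NL feature space;
the shipped fixtures use 128×128 matrices with ACS 24–32, for which both
GRAPPA and NL-GRAPPA reach relative k-space errors below 1e-9 on uniform,
VDS and MVDS masks.

## Metrics

SoS combination, artifact power and SNR follow the formulas quoted above;
magnitudes enter AP, the complex difference enters SNR, and AP(ref, ref) =
0, AP(0, ref) = 1, SNR(2·ref, ref) = 6.0206 dB serve as closed-form
anchors. AP is scale-sensitive by design, so reconstructions are always
compared at their native (orthonormal-FFT) scale. The ROI defaults to the
full matrix; rectangular ROIs are supported. AP is stored as a fraction
and rendered as percent with two decimals, SNR and R_net with two
decimals, matching the comparison-table conventions.

## Study conditions for the stochastic comparisons

The scheme-ordering and trend experiments run at 128×128 with 8
smooth-Gaussian coils, noise σ = 0.02 (a few percent of the image scale,
giving reference SNRs in the tens of dB), ACS 8, a matched total budget of
38 lines, GRAPPA with the default 15×2 kernel, and means over 10 seeds:

* ordering — traditional (ACS 8 + 30 at R4), VDS (ACS 6 + 3 at R2 + 29 at
  R4), MVDS (ACS 8 + 10/10/10 at R2/R4/R6): mean AP ranks MVDS < uniform <
  VDS;
* trend — seven matched-budget MVDS configurations with the low-ORF band
  growing from 0 to 12 lines (mirrored by the R6 band): mean AP is
  non-increasing by Spearman rank (it drops steeply at first, then
  plateaus once the three bands hold similar line counts).

These sizes keep the full suite fast while preserving the regime that
drives the effect — an ACS block small enough that calibration quality,
not raw line count, limits the reconstruction. GRAPPA rather than
NL-GRAPPA is used for these comparisons: at ACS 8 the lifted fits are
severely underdetermined (M ≈ 342 vs N_k = 961) and their
regularization-dependent behaviour would confound the sampling-scheme
effect being measured.

## What the synthetic data does and does not show

The simulator reproduces the geometry (line-based Cartesian undersampling,
shared central ACS, multi-coil SoS reference) and the noise mechanism that
drive the scheme comparisons, so orderings and trends transfer. It does
not emulate anatomy, coil coupling, sequence contrast, off-resonance or
motion, and phantom spectra are smoother than in-vivo data; absolute AP
and SNR values therefore do not — and are not meant to — match numbers
measured on any particular in-vivo acquisition.

## Known limitations

* Only 1-D line undersampling along ky; no 2-D, non-Cartesian,
  Poisson-disc or partial-Fourier patterns.
* Band placement is stride-exact; band combinations that cannot tile the
  matrix at their strides are rejected rather than approximated.
* Grid-aligned missing lines beyond a band's outermost acquired line stay
  zero (they only arise in non-tiling configurations).
* NL-GRAPPA implements the degree-2 expansion only; other kernels,
  virtual-conjugate coils and random-projection acceleration are out of
  scope, as are iterative (SPIRiT), calibrationless (SAKE) and
  image-domain (SENSE-family) reconstructions.
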