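# Methods

## Physical model

The simulator works in the static dephasing regime: water diffusion is
neglected because the field gradients of millimetre-scale vessels vary over
distances far larger than the diffusion length at body temperature, and
arterial inflow is likewise ignored at TR 2.2 s. Blood susceptibility
relative to grey matter is χ = Δχ·Hct·(Y_tissue − Y) with
Δχ = 4π·0.27×10⁻⁶ (SI, fully deoxygenated blood), so veins (Y = 0.6 <
Y_tissue = 0.85) are paramagnetic relative to tissue and arteries
(Y = 0.98) weakly diamagnetic. All field offsets are carried internally as
the dimensionless ratio ΔB_z/B0; phase enters only as γ·B0·(ΔB_z/B0)·TE,
which keeps the analytic and numerical routes on one convention.

Two forward models produce ΔB_z/B0:

* **k-space dipole kernel** (`fieldmap.field_offset_volume`): multiply the
  FFT of χ by 1/3 − k_z²/k² and invert. The k = 0 coefficient is set to 0,
  pinning the spatial mean of the field (a periodic uniform χ then yields
  an identically zero field). The grid is zero-padded by one full field of
  view per side by default to suppress cyclic-convolution wraparound;
  padding is configurable because the dipole tail falls as (a/r)² and
  half-FOV padding is often sufficient. B0 is fixed to the grid +z axis;
  oblique geometry is handled by rotating the vessels, not the kernel.
* **closed-form infinite cylinder** (`fieldmap.cylinder_field_offset`):
  the cos 2φ·(a/r)² extravascular pattern and the uniform
  (3cos²θ − 1)/3 intravascular offset. The extravascular term vanishes for
  a vessel parallel to B0; the intravascular term vanishes at the magic
  angle arccos(1/√3).

Both are verified against each other: a cylinder voxelized at ≥ 4 voxels
per diameter reproduces the analytic exterior field within 5 % of the
surface offset at r > 2a, and a voxelized sphere reproduces the
point-dipole exterior (and near-zero interior) within 5 %.

## Signal formation

A voxel's dephasing factor is the unweighted complex mean over its
subvoxels, S_T2′ = |μ(exp(iγB0(ΔB_z/B0)TE))|, and R2′ = −ln(S_T2′)/TE.
The observed signal additionally weights each subvoxel by its
compartment's steady-state gradient-echo amplitude
sin α·(1 − E1)/(1 − cos α·E1·E2), with E1 = exp(−TR/T1),
E2 = exp(−TE/T2); intravascular subvoxels use (T1_blood, T2_blood(Y)) and
extravascular ones (T1_tissue, T2_tissue = 66 ms at 3 T). Keeping S_T2′
unweighted and applying compartment weights only at the signal step is a
deliberate separation: the dephasing factor stays a pure field statistic
while the weighting captures the blood/tissue relaxation contrast. Note
the E2 factor sits inside the steady-state denominator in the default
form; a `spgr` switch selects the textbook spoiled-GRE form with a
multiplicative exp(−TE/T2). At the default 90° flip the two coincide.

Blood T2 follows a quadratic relaxometry law 1/T2 = A + B(1 − Y) +
C(1 − Y)², with 3 T defaults A = 4 s⁻¹, B = 35 s⁻¹, C = 300 s⁻¹; the
coefficients are exposed in `SimulationParams` so alternative relaxometry
calibrations can be swapped in without code changes.

## Resting-state dynamics

Vascular dynamics are sinusoids at 0.1 Hz. Veins oscillate oxygenation
Y_v, arteries oscillate blood volume; "±10 % peak-to-peak" is interpreted
as a total swing of 10 % of baseline (amplitude 5 %). In the single-voxel
cylinder models the fBV swing is realized by continuously rescaling the
cylinder radius (a ∝ √fBV) rather than re-quantizing masks — the 1 µm/40 µm
grids resolve 5 % radius changes smoothly. In the whole-network model the
arterial driver rescales each vessel radius by √(fBV(t)/fBV₀) before
voxelization at 0.2 mm; its default peak-to-peak is 30 % so that the
quantized masks actually move (a 0.8 mm vessel occupies a 13-cell 2D
footprint at 0.2 mm, and ±5 % of radius would vanish under quantization).

Sampling a 0.1 Hz sinusoid at TR 2.2 s revisits only 50 distinct phases
(0.22 cycles/frame = 11/50), so per-frame voxel states are memoized: a
30-minute, 818-frame run costs at most 50 field evaluations. When a scene
contains only veins, the susceptibility support is static and the field is
linear in (Y_tissue − Y_v(t)); the FFT is then computed once and rescaled
per frame.

## Geometry processing

Centreline volumes encode, per voxel, a diameter and an artery/vein label
(0/1/2 = none/artery/vein). Merging multiple acquisitions takes the union
of centrelines, the highest diameter estimate on overlap, and resolves
label conflicts to vein (venous susceptibility dominates the BOLD effect);
conflicts are warned about. Local orientation at a centreline voxel is the
line through the two most-separated centreline voxels that are
26-connected to it within a 9³ window, falling back to the principal axis
of the window's second-moment tensor near branch points; the zenith is
measured against scanner z after applying the volume's direction cosines
and folded to [0, π/2] so it is invariant to the direction of travel.
Vessels are rasterized as tubes by stamping, per centreline voxel, a
cylindrical segment along the local orientation (boundary inclusive), with
segments long enough (√3/2 of a centreline voxel per side) to tile curved
paths without gaps. fBV maps count occupied high-resolution subvoxels per
fMRI voxel; each fMRI voxel also inherits the orientation of the
largest-diameter centreline voxel it contains. Perivascular shells are
successive 26-connected one-voxel dilations minus their predecessors
(6-connectivity available), so shells are pairwise disjoint, disjoint from
the mask, and telescope back to the k-fold dilation.

## Metrics and evaluation

RSFA is the standard deviation of the mean-normalized series after
removing frames beyond 1.5 IQR outside the quartiles (Tukey fences — the
standard reading of "beyond 1.5 quartiles"); for a pure sinusoid of
relative amplitude A the fences remove nothing and RSFA = A/√2. FC between
two series is the signed extremum of the normalized cross-correlation over
lags within ±5 frames (11 s, covering a full 0.1 Hz period): the maximum
if the largest-magnitude extremum is positive, the minimum if negative,
ties resolved to the positive extremum. Simulated FC values are multiplied
by the target voxel's σ (RSFA) as an SNR surrogate before comparison with
noisy measurements; a geometric-mean √(σ_i σ_j) variant is available.
Predicted and measured values are compared by sorting pairs on the
predicted value, averaging in consecutive fixed-count bins (remainder
dropped), and fitting ordinary least squares through the bin means; R² of
that fit is the accuracy measure. Binning on the predicted axis follows
the convention that the prediction is the independent variable.

## Synthetic data

`synthdata` generates what the angiogram-processing pipeline would
deliver: tubular vessels of 0.8–3.0 mm diameter (0.8 mm is the
detectability floor of the time-of-flight acquisitions being emulated)
traced across a cubic FOV on an 0.8 mm centreline grid, with optional
curvature and fixed or uniformly random orientations; all randomness flows
from an explicit seed and repeated runs are bitwise identical.
Pseudo-experimental runs degrade a simulated run with a smooth
multiplicative gain map (emulating receive-coil sensitivity), an optional
sinusoidal nuisance at 0.03 Hz shared across voxels (a stand-in for
systemic low-frequency oscillations), and frame-wise Gaussian noise with
standard deviation a stated fraction of each voxel's mean (AR(1)
correlation optional; white by default, the simplest model sufficient for
recovery testing).

What the generator does **not** emulate: neural signal, hemodynamic
response shapes, realistic sLFO propagation delays, vessel pulsatility,
motion, or partial-volume behaviour of real angiographic segmentation.
Passing recovery tests therefore demonstrates the internal consistency of
the simulation–metric–regression chain under known ground truth, not
predictive accuracy on real data.

The recovery experiment simulates a vein-only network once (12 mm FOV →
a 60³ working grid and 3³ fMRI voxels, 818 frames — sizes chosen so the
full loop runs in seconds on one CPU), computes σ-weighted FC tables for
the clean run and for pseudo-experimental copies across noise levels and
seeds, and reports the binned-regression R² per (noise, seed). At zero
noise the pseudo-experimental run differs only by the multiplicative gain,
which mean-normalization removes, so R² = 1 exactly; R̄² then falls
monotonically through noise levels 0.01–0.2. The experiment's default
nuisance amplitude is 0 so that the zero-noise limit is exact
self-consistency; the nuisance path is exercised separately.

## Numerical choices and edge cases

* Tube rasterization and footprint counts treat the boundary as inclusive
  (distance ≤ radius, with a relative ε guarding float rounding); this is
  what makes a 0.8 mm vessel on a 0.2 mm grid occupy exactly 13 cells.
  The quantized footprint overshoots the analytic cross-section by 3.4 %
  at that resolution and converges as the grid refines.
* The 2D voxel clips cross-sections larger than the voxel (fBV > π/4) at
  the voxel boundary and records the realized fBV; requested fBV must lie
  in (0, 1).
* The 3D voxel emulates an infinite cylinder on an extended grid (3× the
  voxel per axis) and lets the FFT's periodicity supply distant repeats of
  the vessel; at that spacing the image contribution is below 1 %. Its
  default resolution is 100³ subvoxels of 40 µm; tests use coarser grids,
  where results agree with the 4000² (default) and 1000² 2D grids to well
  under 3 % at θ = π/2.
* The 2D grid is configurable down to 1000² (results within 0.5 % of
  4000²), which is the size used in the sweep-based checks.
* Whole-volume simulation estimates the padded-FFT memory up front and
  refuses scenes above a configurable cap with a size report instead of
  attempting them.
* Degenerate binned regressions (zero spread of bin abscissae) fall back
  to a flat fit with R² = 1 only when the fit is exact.

## Known limitations

Single-voxel models place the vessel exactly at the voxel centre; the
position of a vessel within a voxel measurably modulates the signal and is
not modelled. Multi-vessel interactions appear only in the whole-network
model. The θ ≈ 3π/4 minimum of the oscillation amplitude reflects the
interplay of intravascular and extravascular terms; the intravascular
offset itself vanishes at the magic angle arccos(1/√3) ≈ 0.304π (and its
supplement), which the implementation follows. Arterial baseline diameters
from angiography are intrinsically uncertain (vessels pulsate during
acquisition), so arterial predictions should be treated as qualitative.
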