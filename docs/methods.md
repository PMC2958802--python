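# Methods

This note records the models behind each estimator, the numerical
choices, the design decisions that were genuinely open, and what the
synthetic validation does and does not demonstrate.

## Data model

The unit of data is an *ensemble of independent trajectories*: each
trajectory is a frames × waters × 3-sites × 3 array of Å coordinates
with a shared frame interval (ps), box (Å) and water topology (site
order O, H1, H2; per-site charges summing to zero; rigid O–H length and
H–O–H angle, TIP3P values by default: −0.834/+0.417/+0.417 e, 0.9572 Å,
104.52°). Independence across trajectories is what makes
trajectory-level blocking and bootstrapping statistically honest;
nothing in the estimators assumes independence across frames.

All estimators pool (water, frame) observations, bin them on a regular
grid with half-open cells `[lo, lo+h)` (boundary points go up; a
deterministic partition without overlap), and mask any cell with fewer
than `min_samples` observations (default 100). Masking, not zeroing,
is deliberate: an empty cell would otherwise produce a spurious +∞ PMF
or a spurious zero entropy. Out-of-grid observations are counted and
excluded, never clamped, so edge-cell densities stay unbiased.

## Potential of mean force

`W(r) = −ln(N(r)/N_bulk)` in k_BT, with `N_bulk` the mean per-cell
count over an axis-aligned bulk slab. Working in k_BT (and k_B for
entropy) keeps temperature out of the arithmetic entirely. The slab
average is restricted to cells meeting the same `min_samples` floor
that the PMF itself applies; otherwise undersampled slab cells drag the
normalization down and the bulk PMF acquires a systematic offset (this
was observed, and fixed, during development of the toy-cavity pipeline).
The plug-in estimator `−ln(N̂)` carries a Jensen bias of order `1/2N`
per cell; the block-average comparison test measures it directly and
confirms it shrinks like `1/N`.

## Rotational entropy

Orientational states are unordered pairs of lab-frame sign-octants of
the two H−O displacement vectors: C(8,2) = 28 states, canonically
indexed by lexicographic rank of the pair {i<j}, with octant
`4·[x≥0] + 2·[y≥0] + [z≥0]` and components exactly at zero tying to the
non-negative side. The lab frame is the only frame in which
*position-dependent* orientational order is meaningful, which is why
octants are not molecule-fixed. A 29th overflow label is reserved for
both hydrogens in one octant; for rigid geometries with H–O–H > 90°
this is geometrically impossible (two vectors in a sign-octant subtend
at most 90°), and a Monte-Carlo test confirms zero overflow at 10⁵
uniform orientations. Entropy is the plug-in Shannon estimator over
the 28 regular states with `0·ln 0 := 0`, so `S ∈ [0, ln 28 ≈ 3.33]`.
No pooling of hydrogen-bond-equivalent states is performed.

Two properties anchor the classification thresholds: uniform occupancy
of 2 states gives `ln 2 ≈ 0.69 k_B` (under the 0.7 k_B "bound" cutoff)
and of 20 states gives `ln 20 ≈ 3.0 k_B` (the "bulk-like" cutoff). The
plug-in estimator is biased downward by ≈ `(k−1)/2N` per cell, which is
why even bulk cells in a modest synthetic run sit visibly below the
ideal value; classification cutoffs should be read with that in mind.
An entropy deficit ΔS maps to a fractional loss of effective accessible
states, `100·(1 − e^(−ΔS))` percent, via the effective state count
`e^S`.

## Dipole fluctuation tensor

`C_αβ(r) = ⟨μ_α μ_β⟩ − ⟨μ_α⟩⟨μ_β⟩` in Debye², accumulated per cell in
one pass (sums of μ and of μμᵀ). The molecular dipole is
`Σ q·(r_site − r_O)` converted at 4.803204 D per e·Å; origin
independence requires zero net molecular charge, which the topology
enforces. The tensor is symmetric and positive semi-definite up to
rounding. Closed forms used as oracles: frozen orientation → zero
tensor; isotropic orientations with |μ| = μ₀ → `diag(μ₀²/3)`;
deterministic 180° flips along x → `C_xx = μ₀²`, all else zero.

The "sum of the off-diagonal elements" is reported as the sum of all
six off-diagonal entries, i.e. `2(C_xy + C_xz + C_yz)`, with sign.
Whether each symmetric pair should count once or twice is a convention
with no physical content; the six-entry sum is used and documented, and
per-component maps are always exported so either convention can be
reconstructed.

## Translational and rotational mobility

Translational diffusion uses the Einstein relation at a single fixed
lag (default τ = 50 ps, which must be an integer multiple of the frame
interval): every frame is a start, each (molecule, start-frame) pair is
attributed to the cell occupied *at the start* of the lag window, and
`D(r) = ⟨|Δr|²⟩/6τ`, `D_α(r) = ⟨Δα²⟩/2τ`. Start-cell attribution is
the simplest consistent reading of "assign to a grid position, measure
the displacement τ later"; molecules that leave the cell during the lag
still contribute to it, so maps are smoothed over a diffusion length
`√(2Dτ)` — a known, documented resolution limit, not corrected for (no
survival-probability correction; out of scope). Overlapping starts are
used; their correlation inflates no mean but does reduce the effective
sample count, which is why errors come from trajectory-level resampling
rather than per-observation formulas. Unwrapped coordinates are
required (a squared displacement across a periodic wrap is meaningless);
unwrapping applies the minimum-image convention to consecutive oxygen
positions and shifts whole molecules so rigidity is preserved.

Rotational decorrelation `Q(r) = ⟨cos²θ(τ)⟩` is model-free and always
exported. The derived map inverts the isotropic rotational-diffusion
relation `⟨P₂⟩ = (3Q−1)/2 = e^(−6 D_rot τ)`; cells with `(3Q−1)/2 ≤ 0`
are masked as decorrelated beyond the model's range. The inversion is
a model choice (the underlying decay law is not observable from a
single lag), which is exactly why Q is kept alongside.

## Uncertainty

Blocks are contiguous runs of trajectory indices (any partition of
independent trajectories is valid); the reported block-averaged field
is the per-cell mean over blocks, by default over the blocks in which
the cell is unmasked. The bootstrap resamples whole trajectories with
replacement (frame-level resampling would ignore within-trajectory
correlation), evaluates the estimator per resample, and reports the
per-cell standard deviation; resamples in which the estimator fails are
skipped with a warning, and more than 10% failures abort. All
resampling is seeded and the seed is recorded in the output metadata;
a fixed seed reproduces the resample indices bit for bit. Calibration:
for a mean of i.i.d. per-trajectory values the bootstrap error agrees
with the closed-form `σ/√m` within 20% at 100 resamples.

## Synthetic ground truth

The generator produces exactly the statistical structure the estimators
assume, nothing more: non-interacting rigid waters, overdamped-Langevin
translation `Δr = −D_t ∇U Δt + √(2 D_t Δt)·ξ` (per-axis `D_t`
honored), and orientation either propagated as a composition of
small-angle random rotations with per-axis variance `2 D_rot Δt`, or
overridden by a restricted mode. Initial positions are drawn from the
exact Boltzmann distribution of the imposed potential by rejection
sampling (uniform envelope scaled by `e^(−U_min)`; aborts below 10⁻³
acceptance), so trajectories are stationary from frame zero.

Numerical caveats, measured by the tests rather than assumed: the
Euler–Maruyama stationary variance in a harmonic well is
`2 D Δt / (1 − (1 − kDΔt)²)`, exceeding the exact `1/k` by ≈ `kDΔt/2`,
so equilibrium-distribution tests use steps with `kDΔt ≲ 0.03`; the
small-angle rotational propagation is refused when `D_rot·Δt > 0.1`,
keeping the `P₂`-exponential inversion accurate to a few percent or
better.

Restricted orientation modes give closed-form targets: `frozen` (zero
tensor, Q = 1), `two_state_flip` (deterministic 180° dipole flip each
frame: `C_xx = μ₀²`), and `uniform_states(k)`, which cycles each
particle deterministically through representative orientations of k
designated octant-pair states in a balanced round-robin, so occupancy
is exactly uniform and the target entropy exactly `ln k`. The
representative orientation for each state is found once by seeded
rejection over uniform rotations (uniform random quaternions), cached
per geometry.

The toy cavity — a soft-walled cylinder of radius 7.5 Å along z in a
30 × 30 × 60 Å box, wall stiffness 2 k_BT/Å², mouth at z = 40 Å with an
open bulk region beyond, soft harmonic walls (5 k_BT/Å²) at the box
faces — is a desk-scale analogue of a solvated macromolecular channel
opening into bulk. Its rotational rate default (0.005 rad²/ps) is
chosen so the dipole is still partially correlated at the 50 ps lag
(`6 D_rot τ = 1.5`), keeping the rotational-diffusion inversion in
range over most of the map.

What passing synthetic tests shows: the estimators are unbiased and
correctly calibrated for the statistical model they implement, at the
sample sizes used. What it does not show: anything about interacting
water — hydrogen-bond networks, electrostriction, collective dipole
fluctuations, non-Markovian dynamics. On real trajectories those
physics enter through the data; the estimators remain the same.

## Problem sizes and determinism

Validation runs are deliberately desk-scale: recovery tests use
ensembles of 100 trajectories of 10²–10³ frames (10⁴–10⁵ pooled
observations per quantity), the Boltzmann-inversion test 10⁵ draws, and
the end-to-end cavity run 40 × 120-frame trajectories of 15 waters on a
3 Å grid with a 50-observation floor. Statistical assertions use fixed
seeds; the "every cell within 3 standard errors" PMF check is a
simultaneous statement over ~50 cells and is therefore seeded rather
than run on fresh randomness, since even a perfectly calibrated
estimator exceeds 3σ somewhere in a few percent of replications. All
generator and resampling randomness flows from explicit seeds; a
pipeline rerun with the same config reproduces its summary byte for
byte.

## Known limitations

* Orthorhombic boxes only; no triclinic support.
* Single-lag kinetics: no MSD-vs-lag curves, memory kernels, or
  cell-escape corrections.
* The PMF and entropy maps inherit plug-in estimator bias in sparsely
  sampled cells; the masks bound but do not remove it.
* The dipole tensor is a susceptibility proxy; no spatially varying
  dielectric constant is computed.
* The entropy-vs-internal-energy view of solvent populations is not
  implemented: a per-water internal energy is not defined without a
  force field, which this package deliberately does not evaluate.
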