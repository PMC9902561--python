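# Methods

## Physical model

**Force clamp.** A bead of buoyancy-corrected mass m_eff spun at angular
velocity ω = 2π·RPM/60 at rotor radius r experiences F = m_eff ω²r. With the
default m_eff = 6.9×10⁻¹⁵ kg (Dynabeads M-270) and r = 0.133 m, the spin
rates 1410/1221/997/705 RPM map to 20/15/10/5 pN (296/222/148/74 g).
Spin-up and spin-down ramps are not modelled: analysis time zero is the
first frame at final RPM and only the constant-force segment is analysed.

**Dissociation kinetics.** Each tether is a one-shot first-order process,
so the fraction of tethers remaining decays as y(t) = y₀ + A·e^(−kt). The
offset y₀ ∈ [0, 1] absorbs beads that never dissociate (anomalous
"stuck" tethers); A ∈ (0, 1.5] is the dissociating fraction. Censored
tethers (still attached at the recording end) count as remaining at every
time and are never discarded — they are exactly what identifies y₀.

**Bell-Evans force dependence.** k(F) = k_thermal·e^(F/f) with force scale
f = k_BT/x‡. Fitting ln k against force over ≥3 forces gives the zero-force
off-rate (intercept) and the transition-state distance
x‡ = k_BT·slope. The relation x‡·f = k_BT is an identity of the
parameterisation and holds to machine precision by construction.

**Stacking free energy.** Two constructs identical up to one terminal base
stack are assumed to share on-rates and transition state, so the stack
shifts only the activation energy and

ΔG_stack = RT·ln(k_stack/k_control)

at any common force (negative = stabilising). The error is first-order
(delta-method) propagation of the two relative off-rate uncertainties:
RT·√((sd_s/k_s)² + (sd_c/k_c)²). The implementation computes the
difference of logarithms rather than the log of the ratio so that swapping
the pair flips the sign *exactly*, and a per-force consistency table flags
any pair of forces whose ΔG ± error intervals fail to overlap (a shared
force scale predicts force-independent ΔG).

Default temperature is 294.15 K (21 °C room temperature), giving
RT = 0.5845 kcal/mol and k_BT = 4.061 pN·nm. The temperature is
configurable; between 294 and 298 K the derived transition distances move
by ~1%, within typical experimental rounding.

## Synthetic data: what it emulates and what it does not

The generator draws tether populations with: exponential lifetimes at the
configured off-rate; a stuck fraction (default 2%) censored at the
experiment end; a slow multi-tether fraction (default 1%) drawn at a
reduced rate (default off_rate/10, clamped below the arm's rate); and
right-censoring of any lifetime beyond the recording. Paired experiments
set k_stack = k_control·e^(ΔG/RT) exactly, so the ground-truth energy is
known by construction. Default study conditions: control off-rate
0.05 s⁻¹ at 15 pN (runs complete in tens of minutes), 7200 s recording,
5 s between saved frames (1 fps acquisition, every fifth frame kept),
200 tethers per replicate, three replicates. Replicate seeds derive from
the master seed via `SeedSequence(master, spawn_key=(arm, replicate))`, so
whole studies are reproducible from one integer.

Movies render each bead as a bright-centred disc with a dark annulus —
a high-local-variance pattern matching the variance-based caller — that
vanishes instantaneously between the two saved frames straddling its
dissociation time. Per-frame i.i.d. Gaussian pixel noise is added. Not
modelled: Brownian bead motion, drift, gradual defocus during dissociation,
tether elasticity, optical PSF physics, illumination gradients. Passing
tests on these movies therefore demonstrate the correctness of the
detection/calling logic under the assay's intended contrast regime, not
robustness to every imaging pathology of real data.

## Tracking: numerical choices

* **Detection**: Canny edges (σ = 2.0) into a circle-Hough accumulator over
  radii 4–10 px; normalized peaks above 0.5 (fraction of a complete
  perimeter) become beads. On generator frames at contrast/noise = 5 this
  localises 100/100 beads within 2 px with no false peaks on pure noise.
* **ROI**: fixed square of half-width ceil(1.5 × detected radius) at the
  frame-0 centre; no re-centring (tethered beads are laterally confined).
* **Exclusions**: pairs closer than 10 px → both `clustered`; ROI clipping
  the frame → `edge` (kept distinct in the log since it is a geometric,
  not biophysical, exclusion); focus screened by Laplacian energy in the
  frame-0 ROI with band median ± max(3×scaled MAD, 50% of median). The
  relative floor matters: sharp and defocused beads differ by orders of
  magnitude in this metric while pixel noise alone moves it by ~5%, and a
  pure MAD band over near-identical beads would shrink to the noise scale
  and exclude good beads.
* **Calling**: baseline = max(median of the first 5 saved frames,
  trace[0]). Anchoring on frame 0 — where the bead is known to exist,
  having been detected there — keeps dissociations *inside* the baseline
  window callable instead of silently censored. Dissociation is the first
  frame with variance < 0.5 × baseline sustained for ≥3 consecutive saved
  frames; recovery above threshold afterwards excludes the bead as
  `multiple_drops` (possible multiple tethers). Thresholds are exposed on
  the CLI; the defaults leave ≥2× margin at contrast/noise ≥ 5, where the
  present/absent variance levels differ ~6-fold.

Lowering the drop threshold can only delay a call (the below-threshold set
shrinks), a monotonicity the tests assert as a property.

## Fitting: numerical choices

The fit target is the full empirical survival function on the saved-frame
grid, not the event histogram — this avoids bin-width sensitivity; the
span-scaled histogram (bin width = span/20 rounded to whole frames, ≥1) is
retained for QC only. `curve_fit` runs with bounds y₀ ∈ [0,1],
A ∈ (0, 1.5], k > 0; initial values y₀ = censored fraction,
A = 1 − censored fraction, k from the empirical 1/e crossing; up to five
perturbed restarts on non-convergence, after which the fit is returned
flagged `converged=False` (never silent defaults). Time is normalised by
the final grid point internally, which makes the fitted k exactly
equivariant under common rescaling of all times (bit-exact for power-of-two
factors). R² is 1 − SS_res/SS_tot against the empirical curve. On clean
simulated data the fit agrees with the closed-form censored-exponential MLE
k̂ = d/(Σtᵢ + Σc_j) within a few percent (the MLE is kept in the package as
an independent QC cross-check). Bell-Evans fits use inverse-variance
weights on the log scale, 1/(k_sd/k_mean)², falling back to unit weights
when any replicate sd is zero.

## Problem sizes

Test and acceptance runs use 3 replicates × 500 tethers per arm for
stacking-energy recovery (recovered ΔG unbiased with seed-to-seed sd
≈ 0.024 kcal/mol at both −2.3 and −0.5 kcal/mol), 200 tethers × 3
replicates × 4 forces for Bell-Evans recovery, a 120-frame 512² movie with
100 beads for tracking benchmarks, and a 240-frame 256² 16-bead movie for
the end-to-end demonstration. The demonstration and the acceptance script's
recoveries run in seconds on one core; the sizes were chosen to match the
"tens to hundreds of tethers per run, at least triplicate" scale of real
CFM studies. The bundled demo uses clean conditions (no stuck or slow
beads) so every rendered bead produces an event, making the ground-truth
comparison exact.

## Known limitations

* The slow multi-tether phase is treated as a small contaminant, not a
  model term: no double-exponential or mixture fitting. Large slow
  fractions will bias k upward.
* Beads dissociating before the second saved frame cannot exist by
  construction (frame 0 defines the detected population), and beads lost
  during spin-up are invisible to the analysis — both mirror the physical
  assay's selection.
* The focus screen is a reproducible proxy (Laplacian energy band) for what
  is a visual judgement in practice; it detects strong defocus, not subtle
  multi-tether geometry.
* ΔG extraction assumes equal on-rates and an unchanged transition state
  between paired constructs; violations shift ΔG systematically and are
  not detectable from a single force. The per-force consistency table is
  the built-in diagnostic.
* No extrapolation of ΔG across temperature (no enthalpy/entropy split),
  and no models beyond single-barrier Bell-Evans.
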