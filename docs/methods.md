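# Methods

This note records the models implemented, the choices made where the
underlying methodology left the design open, and what the synthetic-data
generators do and do not emulate.

## Observation volume and the FCS model family

All fluctuation analysis assumes a 3D Gaussian detection profile with 1/e²
radii ω_xy (radial) and ω_z (axial), structure factor K = ω_z/ω_xy and
effective volume V_eff = π^(3/2) ω_xy² ω_z. Calibration fits the
one-component 3D triplet model to a reference-dye curve with K free, then
sets ω_xy = √(4 D_ref τ_d) from the dye's known diffusion coefficient
(default 400 µm²/s, Atto 488 at room temperature). A fitted K outside
[3, 10] triggers a warning — typical confocal volumes fall in that range.
During sample fits K is held fixed at the calibrated value; leaving it
free trades diffusion-time accuracy for an unidentifiable shape parameter.

The model family is exactly four members — {3D, 2D} × {1, 2 components},
each times a triplet factor and a baseline offset G_∞. The triplet factor
multiplies the whole diffusive part (both components share one blinking
term), and G_∞ is left free in fits; under the raw-correlation
normalization used here (uncorrelated baseline → 1) it sits near 1 and is
bounded to [0.5, 1.5]. Other bounds: N ∈ (10⁻³, 10⁴), τ_d ∈ (1 µs, 10 s),
τ_trip ∈ (0.1 µs, 100 µs), F_trip ∈ [0, 0.8). Initialization places τ_d at
the half-amplitude lag (two-component starts bracket it by ×10 each way,
F₂ = 0.5) with five log-normally jittered restarts; the best chi-square
wins. Parameters pinned at a bound are flagged in the result rather than
silently returned. After fitting, components are relabeled so that
"fast"/"slow" refers to diffusion time, and F_slow is reported for the
slower component regardless of which slot the optimizer used.

Model selection fits every candidate and scores by BIC computed from the
weighted residuals, n·ln(χ²/n) + k·ln(n); candidates within ΔBIC < 2 are
tied and the tie breaks toward fewer parameters. This is an
information-criterion approximation to full Bayes-factor selection: on the
clean synthetic fixtures used here the two agree in the regime that
matters (nested one- vs two-component decisions), which is all this
package claims.

## Correlator

The estimator is the symmetric-normalized raw correlation
G(τ) = ⟨F(t)F(t+τ)⟩ / (⟨F(t)⟩⟨F(t+τ)⟩), with the means taken over the
overlapping window at each lag. The multi-tau grid uses 16 linear lags at
the native bin width, then cascades that rebin by pairwise summation
(doubling the bin width) and append 8 lags each, up to lags of duration/8.
Cascade factor and point counts are conventional; any hardware correlator's
exact scheme differs in detail, so correctness is defined by agreement with
the direct single-lag estimator, which the tests check to <1% across the
correlation decay on a high-count trace. Beyond a few diffusion times the
two estimators fluctuate independently around the baseline, so the
comparison is confined to the decay. Per-lag spreads come from correlating
10 equal segments independently; the across-segment SD divided by √10 is
the error of the mean and the default fit weight. Traces shorter than 100
bins per segment fall back to unweighted fitting with a logged warning.

## Photon-trace simulation

Brownian dynamics in a periodic box (side ≥ 10 ω_xy): per-axis Gaussian
steps of SD √(2 D Δt), per-bin expected counts
Σ_particles brightness·exp(−2(x²+y²)/ω_xy² − 2z²/ω_z²)·Δt plus background,
realized as Poisson draws. Triplet blinking is a two-state telegraph
process per particle with the stationary dark fraction and relaxation time
of the triplet model, independent of position — it reproduces the
correlation signature without photophysical detail. The same trajectories
(and blinking) feed every detection channel, so two-channel configurations
are perfectly co-diffusing by construction, which is what cross-correlation
tests need. Binned counts, not photon timestamps, are simulated: every
downstream estimator operates on binned intensity, and lifetime-resolved
filtering is out of scope.

Desk-scale study conditions: the reference scenario uses 60 particles in a
4 µm box (occupancy ≈ 0.4 in V_eff), 60 kHz peak brightness, 2 µs bins,
1 s duration. One-second acquisitions leave the single-run diffusion-time
scatter at ~±15%; tests therefore average ≥5 seeds, mirroring how
measurement series are averaged in practice. Real acquisitions are tens of
seconds; runtimes here are chosen so the full suite stays in minutes.

## Model-curve fixtures

The recovery experiments generate model ACFs directly: exact model values
on a 250-point log grid from 0.32 µs to 3.2 s (the span and density of a
hardware multi-tau correlator) plus lag-independent zero-mean Gaussian
noise with SD equal to 2% of the fluctuation amplitude G(τ_min) − G_∞.
A lag-independent amplitude-scaled noise model is the simplest choice that
preserves fit-weight semantics; real correlator noise is lag-dependent,
so recovery tests here validate the fitting chain, not any claim about
real-data noise. Fixture ground truths are the published in vivo
parameter sets (cell-border: D_fast 27.6, D_slow 0.6 µm²/s, F_slow 0.6;
ventricle: 54.6/4.8; secreted control: 87.5; heparinase-treated:
43.4/0.4/0.6) on the ω_xy = 0.25 µm, K = 5 calibration, with N = 10,
F_trip = 0.15, τ_trip = 10 µs, G_∞ = 1 where unpublished. The ventricle
slow-pool fraction is not published; the fixture uses F_slow = 0.3, a
ventricle dominated by the free species.

## FCCS amplitudes and K_d

The amplitude equations are implemented in their general corrected form
(per-channel brightnesses η, cross-talk terms, backgrounds β, FRET/quench
factors q); under the quasi-PIE condition (η_rG = η_gR = 0, β_G = 0,
q = 1) they reduce to closed forms used as the test oracle. Inversion runs
bounded least squares on relative residuals from the closed-form starting
point and requires residuals < 10⁻⁹ in every equation. One genuine
degeneracy is documented: the red amplitude is non-monotonic in total red
concentration below the background-equivalent occupancy
β_R/(η_rR·N_A·V_eff) ≈ 1 nM at the default 400 Hz background, where two
triples reproduce the amplitudes exactly; the inverter returns the
high-concentration branch. Default calibration constants: η_gG = 1900 Hz,
η_rR = 1400 Hz, β_R = 400 Hz, β_G = 0, q = 1, V_eff = 0.5 fL (V_eff enters
only through N_A·V_eff and is recorded in every output).

Across measurements, K_d is the slope of the zero-intercept regression of
C_g·C_r on C_gr — mass action with a shared K_d predicts exactly that
proportionality — reported with its R² and standard error; the per-point
mean is also computed for transparency. The single-fixture concentration
triple (40, 70, 25 nM) is constructed to satisfy K_d = 112 nM.

## FRAP

Double normalization: I(t) = [(ROI−BG)/(REF−BG)] normalized to its
pre-bleach mean — the reference region cancels monitoring bleach, the
background region detector offset. The recovery model is the
double exponential above; the generator splits the mobile amplitude 0.8/0.2
between fast and slow terms (the fast term dominates published recovery
curves; the split is a fixture choice, not an estimate). The mobile
fraction is F_m = (I_plateau − I₀)/(1 − I₀): the recovered share of what
the bleach removed. D_global = r²/(4τ_fast) uses the fast constant only —
the slow term tracks fluorophore production, not transport — and r is the
nominal bleach ROI radius with no effective-radius correction; the
estimate is apparent by construction. Fits whose post-bleach window is
shorter than 3× the initial fast-time guess are refused as unconstrained;
non-convergent double fits fall back to a flagged single exponential.

## Colocalization

Segmentation thresholds are found Costes-style with the intensity
correlation quotient in place of Pearson's r: candidate threshold pairs
walk down the B-on-A regression line in 1% steps (starting one step below
the maximum so the foreground is never empty) and the search stops at the
first pair whose below-threshold voxels have ICQ ≤ 0. Scoring: for
A-foreground voxels, the sign of the product of deviations from the
foreground means (ICA), weighted by a Gaussian distance weight
exp(−d²/2σ_d²) — d the anisotropic physical distance to the nearest
B-foreground voxel, σ_d the PSF width — and an intensity weight
min(A/Ā, B/B̄, 1) with below-threshold intensities set to zero. The
concrete weight formulas are this package's documented choice; published
implementations of ICA-based masking differ in detail and no equivalence
is claimed. Colocalized voxels are A-foreground with positive score; a
strictly additive 3³ morphological closing confined to the A-foreground
repairs single-voxel PDM sign flips at structure edges; components smaller
than 27 voxels are dropped. Channel-exclusive masks are voxels above
threshold in exactly one channel, so the three masks are disjoint and
channel swap exchanges the exclusive masks. For a secreted ligand (green)
against a membrane reporter of producing cells (red), the colocalized mask
is the source region and the green-only mask the target region.

The stack generator renders thin spherical shells (membrane-like), blurs
with a Gaussian PSF, and adds Poisson noise over a constant background.
Ground-truth labels live on the noiseless blurred support: a voxel belongs
to a structure when its expected signal exceeds the background by more
than the shot-noise band (background + 4√background). A one-voxel shell is
not commensurable with a PSF-widened detection mask, and voxels whose
signal drowns in shot noise are invisible to any segmenter, so the label
definition makes truth and measurement describe the same object. What
passing Jaccard ≥ 0.8 shows is that the pipeline recovers structures whose
light it can see; it says nothing about deconvolution-grade localization
or about real tissue autofluorescence, which the generator does not model.

## Reproducibility and I/O

Every generator takes an explicit seed and is bit-reproducible under it; a
run without a seed draws one and logs it. The acceptance script derives an
independent sub-stream per fixture from its `--seed` via SeedSequence.
Units are µm, s, Hz and nM throughout, recorded in every output JSON,
which validates against the pydantic schema shipped in `fcskit.io`.

## Known limitations

- No photon-timestamp simulation, lifetime filtering, or FLCS statistical
  weights; the quasi-PIE condition is represented by its consequence
  (zero cross-talk and green background), not by its mechanism.
- No anomalous diffusion, flow, or photobleaching during FCS acquisition.
- No spatial FRAP model: bleach-profile and reaction-diffusion effects are
  folded into the "apparent" D_global.
- The periodic simulation box is only ~3 axial waists wide; residual
  correlations from box re-entry are below the estimator noise at the
  sizes used but would bias very long acquisitions.
- Colocalization assumes registered channels and identical acquisition
  settings; no registration or deconvolution is performed.
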