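# Methods

`npkinetics` models the assembly of trimeric ORF1p (the major protein of
the LINE-1 retrotransposition machinery) on a single 8.1 knt ssDNA
molecule held at constant tension in an optical trap, and provides the
analysis chain that recovers the kinetic constants of the
compact/de-compact binding scheme from extension-versus-time records.
This note documents the model, its parameters, the estimators, and what
the synthetic data do and do not capture.

## Kinetic scheme

The strand is discretized into 162 independent 50-nt sites (the
footprint of one trimer); the monomeric construct m128p instead
occupies 476 independent 17-nt sites (one trimer subunit).  Each trimer
site is in one of three states:

* **E** — empty;
* **C** — compact: one trimer engages its full footprint and shortens
  those nucleotides by a fraction γ_c of their bare extension;
* **D** — de-compact (overcrowded): a second trimer has invaded, the
  two trimers share the footprint with partial engagement, and the
  shortening fraction drops to γ_d ≈ γ_c/3.

Transitions carry saturating (Michaelis-type) concentration dependence,
standing in for a two-step localize-then-act mechanism, which
reproduces the observed linear-then-plateau dependence of both binding
phase rates on concentration:

| transition | rate law | meaning |
|---|---|---|
| E → C | r_on(c) = k_b·c·k_c/(k_b·c + k_c) | bimolecular capture, then compaction |
| C → D | r_dec(c) = k_bd·c·k_dec/(k_bd·c + k_dec) | crowding by additional protein |
| D → C | k_rec(c) = k_di0·K_r/(K_r + c) | facilitated re-compaction: a departing trimer hands its nucleotides to the neighbour; free protein suppresses the net rate by rebinding |
| C → E | k_df(F) = k_df0·exp((F − 30 pN)·Δx_df/k_BT) | dissociation of the compact trimer (Bell law) |

The K_r form of the re-compaction rate makes the equilibrium de-compact
fraction θ_d(c) = r_dec/(r_dec + k_rec) follow a near-Langmuir curve in
concentration while reducing exactly to k_di0 the moment free protein
is washed out.  This reconciles the otherwise inconsistent published
rate pair (an in-binding reverse asymptote of 0.15 s⁻¹ versus a washout
initial dissociation rate of 0.11 s⁻¹ with an isotherm midpoint of
3 nM); it is a modeling choice of this package, not a published
mechanism.

**Oligomerization.** Neighbouring bound trimers slowly form inter-trimer
contacts: an occupied site with at least one occupied neighbour acquires
an oligomer flag at rate 1/τ_oligo·exp(−(F − 30 pN)·Δx_olig/k_BT),
irreversibly on experimental timescales.  The flag divides the
dissociation-type rates — C→E and D→C — *and both directions of the
C↔D reorganization* by the protection factor λ ≈ 11.  Protecting both
reorganization directions (a point the underlying experiments do not
constrain) keeps the C↔D equilibrium independent of oligomerization;
if only D→C were protected, flagged sites would equilibrate almost
entirely de-compacted and the occupancy isotherm would shift several-
fold away from its measured midpoint.  The per-site ratio
(D→C)/(C→E) = k_di0/k_df0 is flag-invariant either way.

The oligomerization-deficient variant (151p mode) sets the flag rate to
zero.  Monomer mode (m128p) has plain two-state on/off kinetics with
r_on,mono(c) = k_b,mono·c·k_c/(k_b,mono·c + k_c) and a constant off
rate.

## Polymer model

Bare ssDNA extension per nucleotide follows the freely-jointed chain,
x(F) = L_nt[coth(u) − 1/u], u = F·b/k_BT, with L_nt = 0.56 nm/nt and
b = 1.5 nm (standard ssDNA literature values; an optional enthalpic
1 + F/S term is off by default) at 294.15 K (k_BT = 4.06 pN·nm).
A site in state s removes γ_s(F) · footprint · x(F) nanometres of
extension; γ tables are given at 10/30/50 pN (γ_c = 0.8/0.6/0.3,
decreasing with force because tension resists compaction) and linearly
interpolated.  Absolute compaction amplitudes are conventions — the
published record fixes only their ratios and the rates — so all
acceptance-grade quantities are rates, time- and concentration-
dependences, and amplitude *ratios*.

## Reference parameter set

All rates are calibrated once from the published constants
(`npkinetics.lattice.REFERENCE_OBSERVABLES`, packaged in
`data/params_reference.yaml`): k_b = 0.042 nM⁻¹s⁻¹, k_c = 0.45 s⁻¹,
k_dec = 0.15 s⁻¹, k_di0 = 0.11 s⁻¹, λ = 11, τ_oligo = 100 s,
K_r = 3 nM.  Two entries are derived: k_bd = 0.0289 nM⁻¹s⁻¹ solves the
midpoint balance r_dec(3 nM) = k_rec(3 nM), and k_df0 = 0.0069 s⁻¹
makes the low-concentration off/on ratio equal 0.17 nM.  Bell lengths
Δx_df = 0.25 nm (≈10-fold rise of the final dissociation rate from 10
to 50 pN) and Δx_olig = 0.4 nm (oligomer protection vanishing at high
force) are conventions consistent with the published force trends.
Monomer rates: k_b,mono = k_b/3 (the published ≈3-fold lower on-rate);
k_off,mono = 0.024 s⁻¹, read as half the WT initial dissociation rate
*under the comparison's own conditions* (30 nM, 100 s incubation, where
the WT rate is the oligomerization-mixed ≈0.05 s⁻¹) — this also keeps
the saturated monomer's equilibrium extension equal to the de-compact
WT plateau, as observed.  Below 6 pN the de-compaction channel is
switched off (no elongation step is observed at 5 pN); this is a
config-exposed phenomenological switch, not a mechanism.

## Simulation

`simulate_trace` runs the direct Gillespie method over the
concentration schedule (fixed force per record), samples the extension
every 0.1 s and adds i.i.d. Gaussian noise of 2 nm — drift-free, since
the emulated instrument corrects drift.  Everything is reproducible
from the protocol seed; trace i of condition j in a preset uses
`seed_base + 10000·j + i` so any single record can be regenerated
alone.  `meanfield_trace` integrates the matching 5-state (or 2-state)
ODE with the neighbour condition treated as satisfied whenever
occupancy is positive; it is the testing oracle for the simulator
(ensemble mean within 3×SEM on 20-site lattices in all modes).

## Estimators

The per-record analysis follows the classic recipe: split the record
into monotonic phases (sign changes of a 2 s moving-average derivative;
schedule boundaries — in particular the washout instant — are forced
breakpoints) and fit each phase with a two-parameter exponential decay
(variable projection: plateau and amplitude solved linearly for each
trial rate; exact to machine precision on noiseless input).  At the
condition level the phase-amplitude threshold is 30 nm: a single
binding or unbinding event moves the extension of the 162-site lattice
by up to ~15 nm, and a lower threshold would segment individual events
as phases.

Per-phase exponential rates are reported in the condition tables, but
three refinements are used for parameter-level inference, because the
elementary processes overlap in time:

1. **Joint washout fit.**  After washout the dynamics are a sequential
   conversion (D→C) followed by slow dissociation (C→E), whose
   ensemble-mean extension is exactly a bi-exponential.  Fitting the
   whole washout window jointly (`fit_biexponential`) recovers both
   dissociation-phase rates without the truncation/leakage bias of
   per-phase fits, and its amplitudes yield the full-compaction
   reduction per nucleotide (the Δx_max reference) — the fast amplitude
   tends to the conversion amplitude as k_slow/k_fast → 0, so the
   result is insensitive to the assumed γ_c/γ_d ≈ 3.  The
   oligomerization-deficient mode provides the clean single-population
   control for this fit.
2. **Trajectory fit of the binding scheme.**  The two binding-phase
   rates cross near 3 nM, where no estimator can separate them from a
   single record.  The binding constants (k_b, k_c, k_bd, k_dec, K_r)
   and γ_d are therefore estimated by least-squares fitting of the
   mean-field trajectory to the ensemble-mean incubation records of
   all concentrations jointly, with the dissociation/oligomerization
   parameters fixed at their independently measured values.
3. **Initial-slope rate for the oligomerization series.**  The washout
   re-compaction after a long incubation is a fast/slow mixture
   (unprotected/protected sites), and the amplitude-weighted mean rate
   — which is exactly k_inf + (k_0 − k_inf)e^(−t/τ) — equals the
   initial slope divided by the total conversion amplitude
   Δx_max − Δx_eq.  The slope comes from a quadratic fit over a window
   of ≈0.1/rate seconds (curvature bias below ~2% of the fastest
   component while averaging over the shot noise of discrete events);
   the signed value is kept so that replicate averaging stays unbiased.

Occupancy handling: at 1 nM the equilibrium vacancy implied by the
off/on ratio (0.17 nM against a compact-state fraction near one) is
~10%, which would read as de-compaction in the isotherm conversion
θ_d = (Δx_max − Δx_f)/(Δx_max − Δx_min).  Equilibrium reductions are
therefore expressed per bound site using the fitted model's occupancy
before the conversion; the same correction (from the monomer's own
measured on/off rates) is applied to the monomer side of the
trimer/monomer compaction-ratio comparison.

## Preset problem sizes

The packaged presets reproduce each experiment family at desk scale:
binding concentration series 1–90 nM at 30 pN with 100 records per
concentration and 100 s incubation; force series 10–50 pN;
oligomerization series with incubation times 25–800 s (100 records
each; 25 s = τ/4 is the shortest time at which the lattice has reached
its binding equilibrium, the state the series is defined on); washout
controls with 600 s of protein-free buffer.  At these counts the SEM of
recovered rate constants is a few percent of the mean, and every preset
completes in a few minutes on one CPU.

## What the synthetic data do not capture

* Independent, non-overlapping sites: no McGhee–von Hippel gap
  statistics, no partial footprints, no sequence specificity.
* Oligomerization as a per-site two-state flag with a single protection
  factor; real oligomer size distributions and their reversibility are
  not modeled.
* Gaussian sampling noise without drift, bead fluctuations or force
  feedback artifacts.
* The de-compaction switch-off below 6 pN is imposed, not emergent.
* Competition with free oligonucleotides, duplex chaperone activity and
  two-substrate (tripartite) binding are out of scope.

Passing tests therefore certify that the analysis chain recovers the
generative constants under these idealized conditions, not that the
scheme is the unique explanation of any particular real record.

## Numerical choices

Stochastic simulation uses the direct method with vectorized propensity
updates; the sampler reproduces bit-identical traces from the seed.
Mean-field integration uses LSODA with rtol 1e-8 (stiffness from the
λ-divided rates is mild).  Exponential fits scan 120 log-spaced rates
across the window bandwidth, refine by bounded scalar minimization and
finish with two parabolic polish steps; non-convergence is flagged in
the fit object, never silent.  The bi-exponential fit decimates to
≤1500 points for its coarse 30×30 rate grid and polishes on the full
record (Nelder–Mead in log-rates).  Langmuir, saturating-rate and
oligomerization-time fits are ordinary nonlinear least squares with
SEM weights when replicates provide them; the Bell fit is log-linear
and closed-form for two points.  Ties and degenerate inputs raise
informative errors (constant segments, single-concentration isotherms,
non-positive rates in Bell input).
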