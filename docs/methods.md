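# Methods

## The system being modeled

Two prevalent human gut bacteria are grown in closed batch bottles of
Wilkins–Chalgren (WC) anaerobe medium, alone and together, with and without
mucin-coated gel beads: *Bacteroides thetaiotaomicron* (BT), a fast primary
fermenter, and *Roseburia intestinalis* (RI), a butyrate producer. Growth on
the medium's glucose and pyruvate acidifies the bottle; the two species
respond to starvation and acid stress in opposite ways — BT loses viability
at low pH unless mucin gives it an energy source, while RI survives by a
diauxic shift to consuming the acetate and lactate it helped produce,
exporting butyrate. The package couples a kinetic model of these dynamics to
the measurement pipeline (flow cytometry with live/dead staining and
machine-learning species assignment) and to derived analytics (interaction
strengths, pH–SCFA and attachment regressions).

## Kinetic model

State vector (densities in cells/µl of culture, concentrations in mM):

* per species, a glucose-fed **fast** state, a post-glucose **slow** state
  (mucin foraging for BT; acetate/lactate consumption for RI) and an
  **inviable** pool;
* lumped substrate pools: `G` (glucose + pyruvate), `M` (mucin-derived
  sugars), `A` (acetate + lactate), `Bu` (butyrate), and other acids
  (succinate + formate).

pH is algebraic, not a state: `pH = max(4.0, pH0 − c_pH·ΣA)` with
`ΣA = A + Bu + other`, reflecting the observed linear pH–ΣSCFA
relationship. Growth responds to pH through a steep Hill factor
`φ_s(pH) = 1/(1 + (pH_half_s/pH)^n_pH)` per species, with
`pH_half_bt > pH_half_ri` (BT is more acid-sensitive; BT growth on
glucose is essentially off at pH 4.5–5.0 while RI still grows at pH 5.3).

Growth laws (all Monod in their substrate, times the pH factor):

* BT fast on `G`; BT slow on `M`, inhibited by glucose through
  `KI_G_bt/(KI_G_bt + G)` (carbon-catabolite-style repression);
* RI fast on `G`, inhibited by mucin sugars through a **Hill-shaped**
  factor `KI^h/(KI^h + M^h)` with `h = n_MI = 4.3`. The cooperative form
  (rather than first-order inhibition) encodes the threshold-like
  repression of glucose catabolism that mucin sugars exert on RI; it is
  also what lets one parameter set reproduce both the stalled RI
  monoculture with mucin and the transiently competitive RI in the mucin
  co-culture;
* RI slow on `A`, with a small rate — net viable counts in the slow mode
  decline slowly (growth minus decay), which is how the observed drop from
  the RI peak to 2–4×10⁵ cells/µl is represented.

Switching fast→slow is smooth-thresholded: RI switches at rate
`k_switch_ri·σ(θ_G−G)·σ(θ_M−M)` — only when **both** glucose and mucin
sugars are low, matching its diauxic trigger; BT switches at
`k_switch_bt·σ(θ_G−G)` — low glucose alone, since BT's slow mode *feeds on*
mucin sugars and abundant `M` must not block the transition. σ is a
logistic with configurable width (defaults 0.1 mM on the glucose trigger).

Death moves viable cells to the inviable pool and conserves per-species
totals (the total count is unaffected by viability loss, as observed):

* BT: `d_bt·(1−φ_bt)·(1−E)` where `E = max(G/(K_G+G), M/(K_M_maint+M))` is
  an energy-availability term — acid kills BT only when it has no energy
  source. `K_M_maint` (5 µM) is far below the growth half-saturation:
  maintenance needs much less flux than growth;
* BT slow additionally pays a maintenance cost `m_bt·(1−φ_bt)`,
  representing ATP diverted to pH homeostasis at low pH. This term gives
  the model a pH set-point: BT's mucin-fueled biomass grows until the acid
  it produces pushes φ_bt down to where growth balances maintenance, which
  caps the attached BT maximum in monoculture (where the glucose phase has
  already acidified the bottle deeply) while allowing the higher co-culture
  peak (milder glucose-phase acidification leaves more headroom);
* RI fast: starvation death `d_ri·(1−G/(K_G+G))`; RI slow: constant slow
  decay `d_ri_slow`.

Mucin is inexhaustible and not a state; attached viable cells of both
species release `M` at `r_M` per cell (fixed attached fractions
`f_att_bt = 0.33`, `f_att_ri = 0.25` of total cells; planktonic = (1−f)·
total, attached = f·total at all times, giving the observed linear
attached–planktonic relationship with slope f/(1−f)).

Acid bookkeeping: BT produces `A` and other acids at ~1 mM per mM glucose
each, but only ~0.12 mM each per mM mucin sugar (foraging yields fewer
acids per substrate; without this the mucin bottles over-acidify
immediately). RI fast produces `A`, `Bu` and formate; RI slow converts `A`
to `Bu` at 0.5 mM/mM — a net **loss** of acid moles, so the pH drifts back
up late in RI cultures (5.6 → 5.8 in the calibrated WC monoculture).

### Default parameters and calibration

Defaults in `ModelParams` are the package's own calibration: a worst-case
band-margin (minimax) fit of the rate constants to fourteen printed
observables of the study (peak viable densities, peak timing, pH landmarks
and attached maxima across the six scenarios), followed by freezing. Key
values: µ_max 0.45/0.37 h⁻¹ (BT/RI on glucose), 0.30 h⁻¹ (BT on mucin
sugars); yields ~9.0/5.5 ×10⁴ cells·µl⁻¹·mM⁻¹; c_pH 0.055 pH/mM;
pH_half 5.4/4.8; initial pool G₀ = 14.6 mM (1 g/l glucose + 1 g/l sodium
pyruvate); inocula 1.2×10³ (BT) and 1.8×10³ (RI) cells/µl — equal-OD₆₀₀
inocula of species with different cell sizes give species-specific
starting densities. Any parameter can be overridden from YAML without code
changes (`mucodyn simulate --params`).

Integration uses LSODA with rtol 10⁻⁸ / atol 10⁻⁶; the steep Hill factors
and logistic switches make the system moderately stiff. Solver trial steps
may probe ~10⁻⁶-level negative states; these are clipped inside the RHS,
and the final solution is rejected if any component undershoots beyond
0.01 cells/µl (or µM) — far below one cell.

### Known limitations of the model

* The second RI peak in the WC co-culture (38 h) is not reproduced —
  the mechanism is unresolved and deliberately not encoded.
* Late mucin scenarios over-acidify relative to the reported pH (the
  calibrated co-culture with mucin reaches pH ≈ 4.5 by 120 h vs ≈ 5.1
  reported); the acceptance observables are unaffected, but long-horizon
  pH in mucin bottles should not be over-interpreted.
* The fixed-fraction attachment assumption cannot simultaneously match the
  reported RI planktonic maximum (4.5×10⁵) and attached maximum (1.1×10⁵)
  with f = 0.25 (they imply different totals); the calibration places both
  within ±30%.
* Lactate's variable consumption is not resolved (lumped into `A`);
  propionate is absent (the medium lacks vitamin B₁₂).

## Flow-cytometry pipeline

Channels: forward/side scatter and SYBR-Green (SG) / propidium-iodide (PI)
fluorescence. The "arcsin" variance-stabilizing step is implemented as the
inverse hyperbolic sine (plain arcsine is undefined above 1; an arcsine
variant rescaled by the channel maximum is available via config), followed
by per-channel standardization. Events are embedded into 3-D by UMAP
(Euclidean, 25 neighbors, 0.1 min-dist, fixed seed ⇒ single-threaded and
bit-reproducible). Gating: events overlapping the sterile-medium blank
population are removed first, then PI⁺ → inviable, SG⁺PI⁻ → live, rest →
debris. SG/PI thresholds default to the KDE valley between the two largest
modes of the pooled transformed distribution, overridable by explicit
values. Blank overlap: each blank event claims a ball whose radius is
proportional to its local blank density (k-NN estimate, k = 15;
`r_i = scale·r_med²/r_k(i)`), so dense blank regions claim wide areas while
isolated cell-carryover events in blank files claim almost nothing; the
default scale (2.0) flags ≥ 95% of events drawn from the blank
distribution itself. Species assignment reprojects live co-culture events
into a supervised UMAP trained on up to 5000 events per monoculture
replicate and votes with distance-weighted 50-NN under the Mahalanobis
metric of the training embedding. Densities: events / acquired volume
(1 min × 10 µl/min = 10 µl) × dilution (1:10 early, 1:200 later). The
study's interactive 3-D inspection step is replaced by an automated QC
dict (thresholds, category fractions, truth agreement when available).

## Synthetic data

Trajectory replicates apply mean-preserving multiplicative lognormal noise
to densities (default CV 10%, the scale of the reported replicate scatter)
and additive truncated-Gaussian noise to metabolites (0.5 mM) and pH
(0.05). Event mixtures are multivariate lognormal per population in log10
channel space (SD 0.15 decades/channel) with the five populations the
gating distinguishes; the minimum pairwise center separation is set in
pooled-SD units, so test difficulty is a single dial. The real instrument's
channel covariances are unknown without the deposited FCS files; the
defaults are order-of-magnitude choices, and passing classification tests
demonstrates pipeline correctness on controllable mixtures, not
instrument-level performance.

## Calibration machinery

The objective is a weighted sum of squared residuals over three blocks:
log10(viable + 1) densities (counts span four decades), metabolites (mM)
and pH; several scenarios are fitted jointly with one parameter set. Free
parameters are searched in log space inside positive bounds; an optional
differential-evolution stage precedes least-squares refinement; fixed
seeds make fits reproducible. Recovery tests (4 free parameters, ±30%
perturbed starts) recover noise-free data to ≪ 5% and 10%-CV, 3-replicate
data to < 20%. No Bayesian posterior or profile likelihood is attempted.

## Problem sizes used by tests and the acceptance script

Simulations run on the 19-point experimental grid (0–120 h). Flow tests
use 3000-event mixtures (+600 blanks) for gating and 5000 training events
per species with 1500–2000 co-culture events for species assignment;
module-level tests use smaller mixtures with the training-size knob
reduced. These sizes give stable accuracy estimates while keeping the full
suite in a few minutes on one CPU.
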