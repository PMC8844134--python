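# Methods

## Model

The package couples two exponential learning curves into Holling's disk
equation. Experience is the continuous cumulative number of prey consumed in
the current trial, `N` (not an integer count: the dynamics are treated as a
smooth ODE). The attack rate rises and the handling time falls with
experience,

    a(N) = a_m − (a_m − a0) e^(−l_a N),    0 < a0 ≤ a_m ≤ 1,  0 ≤ l_a ≤ 1
    h(N) = h_m + (h0 − h_m) e^(−l_h N),    0 ≤ h_m ≤ h0,      0 ≤ l_h ≤ 1

equivalently `da/dN = l_a (a_m − a)` and `dh/dN = −l_h (h − h_m)`. A learning
rate of 1 means the parameter closes most of the remaining gap to its
asymptote with each consumed prey; a rate of 0, or a zero amplitude
(`a0 = a_m`, `h0 = h_m`), disables learning and the model is the classical
type II disk equation.

Two settings:

* **Fixed density (Holling).** Prey density `D` is held constant
  (consumed prey are replaced): `dN/dt = a(N) D / (1 + a(N) h(N) D)`.
* **Depletion (Rogers).** Prey form a fixed pool `N0` removed without
  replacement. The state is the remaining prey `Na`,
  `dNa/dt = −a(N) Na / (1 + a(N) h(N) Na)` with `N = N0 − Na`. With no
  learning this integrates to the classical random-predator implicit
  equation `N = N0 (1 − e^(−a(T − hN)))`, which the package exposes as an
  analytic oracle (bracketed Brent root finding by default, Lambert-W as a
  cross-checking alternative; they agree to < 1e−10).

## Numerical integration

Classical fixed-step RK4 over an experiment of length `T = 1` time unit at
`dt = 1/1024` (both configurable; `T` must be an integer multiple of `dt` to
1e−12 relative — the last step is never fractional). The learning curves are
substituted in closed form into a single scalar ODE and re-evaluated at
every internal RK stage; a coupled formulation that integrates `(N, a, h)`
as a system is retained purely as a cross-check (the two agree to ~1e−13,
tested). Global fourth-order accuracy is verified by Richardson ratios
(~15.5–15.8 against the ideal 16). There is no randomness anywhere; results
are bit-reproducible for a fixed configuration.

In the depletion setting the remaining-prey state is clamped to zero within
a 1e−9 tolerance; any excursion below that is reported as a numerical
failure naming the step rather than silently repaired.

Response curves evaluate one independent trial per offered value (constant
density, or initial pool size under depletion) on a uniform offered grid.
All trials advance in one vectorised RK4 pass; results are identical to
evaluating trials one at a time (tested), vectorisation is purely for speed.

## Shape diagnosis

Derivatives of consumed vs offered prey are taken by second-order central
differences on the uniform grid (endpoints excluded). Curves are noiseless
ODE output, so no smoothing is applied by default; an optional
moving-average window exists for user-supplied empirical curves.

For classification the curve is affinely rescaled so offered and consumed
each span [0, 1]; thresholds on the normalized second derivative `g` are
then scale-free. The decision procedure, with defaults `eps_lin = 0.02`,
`eps_pos = 0.05`, persistence `k = 5`:

1. `max |g| < eps_lin` → **type I** (no curvature worth the name);
2. a persistent positive-to-negative zero crossing of `g` with
   `max g ≥ eps_pos` → **type III** (genuine sigmoid);
3. a persistent crossing with `0 < max g < eps_pos` → **near-type II**
   (sigmoid signature too small to see);
4. `g ≤ 0` everywhere (within `eps_lin/10`) and `min g < −eps_lin` →
   **type II**;
5. otherwise → **near-type I**.

A crossing is *persistent* when the sign holds for `k` consecutive grid
points on each side (truncated at the array edges), which suppresses
single-point floating-point flips. When several crossings exist the first
(lowest offered value) is reported as the inflection, linearly interpolated
between grid points. The raw-scale second-derivative maximum is reported
alongside the normalized one, since the two scales order curves differently
and map figures may be drawn on either.

The thresholds are calibration constants: the source taxonomy ("near-zero",
"barely noticeable") is visual and gives no numbers. They are exposed in the
API and CLI. With these defaults the type III region in the attack-learning
plane ends at a0 ≈ 0.39 when scanned at l_a = 0.2 — close to, but above,
the ~0.3 the original qualitative description suggests; the boundary is
sharp in the model (the positive-curvature region simply vanishes), so this
is a property of the dynamics, not of the threshold choice.

## Sweeps and scans

The two study designs are sweeps over (a0 × l_a) with `a_m = 1` and handling
fixed at `h = 0.1`, and over (h_m × l_h) with `h0 = 1` and attack fixed at
`a = 0.1`, each with or without depletion. Grids are endpoint-inclusive
uniform point counts; the full design is 1001 × 1001 with offered prey
1–200 at step 0.01, but classification is stable to grid refinement away
from region boundaries (tested), so sweeps default to offered step 0.5 and
any grid count. Cells are independent simulations; chunked vectorised
evaluation is exactly equivalent to sequential evaluation (tested).
`threshold_scan` operationalises boundary statements: it scans one parameter
axis and returns the smallest (or largest) value whose curve classifies as a
requested shape, or an explicit not-found.

Default problem sizes used by the test suite and the acceptance script —
101 × 101 region maps, 100-point boundary scans, offered step 0.5 — were
chosen as the scale at which every qualitative feature of the full design is
already resolved.

## What the model does and does not show

The simulator generates its own study conditions (there is no external
data): naive predators, a single prey type, deterministic smooth learning,
one-time-unit trials. Passing tests therefore demonstrate properties of the
model, not of any empirical predator: real functional-response data add
trial-to-trial stochasticity, integer prey counts, and between-individual
variation in learning, none of which are modelled here.

Two findings deserve emphasis because they differ from the narrative this
model is usually given:

* **Attack-rate learning is the only route to type III.** Reproduced
  cleanly: a low initial attack rate plus a nonzero learning rate yields a
  sigmoid, with the inflection moving toward zero as learning accelerates,
  and depletion dampens the maximum curvature (it removes chances to learn)
  while slightly extending the type III region.
* **Handling-time learning cannot express within these trial lengths.**
  With the attack rate fixed at 0.1 and `T = 1`, consumption over a trial is
  at most ~2.2 prey even at density 200, so `h(N)` barely moves; the
  response satisfies `N/(aD) + (1 − e^(−l_h N))/l_h = T`, which is concave
  in `D` everywhere and saturates at `N = −ln(1 − l_h)/l_h` for `l_h < 1`.
  A type I response or any positive-curvature region from handling learning
  is therefore impossible under this model at these settings — no matter the
  classifier thresholds, since the sign of the second derivative is
  invariant to normalization. The acceptance suite states the conventional
  expectation for this regime and records its failure rather than adjusting
  the model to manufacture it. Handling learning *would* produce
  asymptotically linear (type-I-like) responses if experience accrued with
  encounters rather than consumptions, or over much longer trials; both are
  outside the present model's definition.

## Known limitations

* No forgetting: learning is monotone within a trial and experience never
  decays.
* Single prey type: no switching, no alternative prey, no prey learning
  (and hence no type IV responses).
* Fixed-step RK4 only; the dynamics are non-stiff and smooth, so adaptive
  or stiff solvers are unnecessary, but very large `dt` is rejected rather
  than repaired.
* The classifier is designed for noiseless simulated curves; for empirical
  curves the optional smoother helps but no statistical model selection
  between response types is attempted.
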