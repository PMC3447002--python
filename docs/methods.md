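# Methods

`paracortex` is a stochastic, on-lattice agent-based simulator of T cell
motility, chemotaxis, ingress and egress in the lymph node paracortex (the
T zone). This note records the model, its assumptions, the parameters that
matter, the numerical choices, and what the synthetic scenarios do and do
not show about real tissue.

## The lattice domain ("blob")

Cells move on a cubic lattice in 15 s time steps. T cells occupy about 60%
of paracortical volume; with a 150 µm³ cell this fixes the grid spacing at
(150/0.6)^⅓ = 6.3 µm, one cell per site. The occupied region is a roughly
spherical "blob" of AVAILABLE sites whose count always equals the number
of cells: ingress opens the OUTSIDE site nearest the nominal spherical
surface, egress closes the farthest unoccupied AVAILABLE site (lexicographic
tie-breaks make both deterministic). When every boundary site is occupied a
closure is deferred to a later step and counted. The blob therefore stays
maximally spherical as it grows and contracts; its nominal radius is
R = (3N/4π)^⅓ (≈13.4 sites for 10 k cells).

Crowding is handled by the passing rule: at most two cells per site, and
double occupancy is permitted for a single step only. After the movement
pass, every cell still sharing a site redraws a jump from its distribution
renormalized over admissible destinations (no-jump excluded); a cell with
no admissible destination stays put and the event is logged. In steady-state
runs these stuck events are essentially absent (≪1% of cell-steps).

## Motility: persistent random walk

At each step a cell rests with probability `p0` or jumps to one of its 26
Moore neighbours with probability

    p(i) ∝ (1 − p0) · exp(κ cos φᵢ) / |u(i)|,

where φᵢ is the angle between the jump vector u(i) and the cell's
persistence direction and the 1/|u| factor corrects for the three jump
lengths (1, √2, √3). The persistence direction is a slowly relaxing
*heading*: an executed jump replaces it only with probability
`p_reorient` (default 0.2). The heading mechanism is this package's
design choice for the base walk: it decouples short-window straightness
from long-time diffusion, and is what allows one parameter set to
reproduce simultaneously the intravital anchors — mean speed 8–16 µm/min,
motility coefficient C_m 50–100 µm²/min — and the apparent (chemotaxis-free)
McCutcheon indices of ~0.53 (10 steps) and ~0.39 (20 steps). A
last-jump-updates-heading walk (p_reorient = 1) cannot: at speed
15 µm/min, pinning the 10-step index to 0.53 forces C_m ≈ 33 µm²/min,
below the measured range.

`calibrate_motility(target_speed, target_cm)` determines `p0` in closed
form from the speed target (the stationary mean executed-jump length
depends only on κ) and bisects κ on the simulated C_m (1000 free-space
trajectories of 2 h; C_m from the tail-half linear fit of the MSD/6).
Shipped defaults: targets 15 µm/min and 55 µm²/min → `p0 = 0.5626`,
`κ = 0.875`. Speed is total path length over time; no-jump steps
contribute nothing.

## Chemotaxis

A cell under attraction **C** mixes its base walk with a chemotaxis-only
distribution over the 26 jumps,

    p_c(i) ∝ cos²(θᵢ)/|u(i)|   for cos θᵢ ≥ 0, else 0,

with mixing weight α = min(1, |C|): p*(i) = (1−α)p(i) + αp_c(i), and
p*(0) = (1−α)p(0) plus the mass of crowding-blocked directions (a blocked
attempt is a failed move; the alternative — renormalizing over free
directions — would inflate lateral movement in crowds). At |C| ≥ 1 motion
is fully chemotactic, which fixes the ceiling of the directional
chemotaxis index at E[Δx]/E[|u|] = 1/1.361 ≈ 0.735.

Attraction from an exit portal at distance r is the bounded inverse-square
g(r) = min(1, K_E/r²), K_E being the cell's chemotactic susceptibility;
multiple portals (or any caller-supplied sources) combine by vector
addition. Contributions below 0.01 are dropped (the bias is then under 1%
and portal scans stay local); a portal at the cell's own site has no
defined direction and contributes nothing. Explicit chemokine
concentration fields are not simulated — only the distance-function
approximation — but the interface accepts arbitrary attraction vectors.

The chemotaxis index (CI) is estimated on free-space trajectories under a
spatially uniform attraction along +x: standard (McCutcheon) CI is
|net displacement|/path length; the directional variant projects the
displacement on the attraction axis so the index vanishes with |C|.
Defaults: 10 steps, 1000 trajectories, directional. Trajectories that
never jump (probability p0¹⁰ ≈ 0.3%) have no defined index and are
excluded.

## Ingress, exit portals, egress

Cells enter at Poisson rate F_in, placed uniformly at sites with
r ≤ 0.7 R and occupancy < 2 (up to 50 draws, then the arrival is deferred
one step); each arrival opens one boundary site. Egress happens only in
the 27-site Moore neighbourhoods of discrete exit portals: any cell there
departs with probability P_E = 0.02 per 15 s step, applied once per step
even where neighbourhoods overlap (portals are kept ≥ 4 sites apart, so
overlap is rare). Portal sites must have their whole Moore block inside
the blob, at least one block site with a neighbour outside, and lie
outside the cap x/R > 0.6 that represents the B cell follicle interface.
Portals are placed by dart throwing (100 tries per portal, then the
most-isolated candidate with a logged separation relaxation) and are
relocated to the nearest valid candidate whenever blob resizing
invalidates them.

The portal count follows the empirically calibrated steady-state law

    N_E = round( max(β(K_E), 0.5) · (0.02/P_E) · a · N^b / T_res ),

recomputed every step from the current population, which makes the
population self-regulating: a surplus adds portals and raises efflux.
The constants a = 0.5655, b = 0.9809 (T_res in minutes) ship with the
package and were obtained by `calibrate_exit_constants`: for each of six
population sizes between 2 k and 25 k, the integer portal count is
bisected on the sign of the population drift of a 5-day constant-influx
run (influx N/T_res, no chemotaxis, no inflammation). Because the egress
flux of a *fixed* portal count is nearly independent of the population
(the blob shrinks with it, keeping the density at one cell per site), an
imbalance drifts the population linearly, and the relative drift *rate*
is the quantity interpolated between the bracketing integer counts —
exact balance generally falls between integers at these scales. Each
endpoint rate is averaged over three independent runs, and probes abort
early once the population leaves a ±20–25% band (the rate is already
determined by then). Log–log least squares over the six fractional
counts gives (a, b); the fit residuals are ~1% and the exponent
b ≈ 0.98 is nearly linear. The mean-field estimate N·dt/(27 P_E T_res)
(a ≈ 0.46) underestimates the portal need by ~20% because portal
neighbourhoods are not held at full single occupancy.

β(K_E) = 0.0231 K_E² − 0.2159 K_E + 0.9997 (evaluated no further than its
vertex, clamped at 0.5) is the exit-count reduction needed when *all*
cells are attracted to portals: crowded neighbourhoods saturate at two
cells per site, so beyond K_E ≈ 4 extra chemotaxis changes nothing.
`calibrate_beta` regenerates the table by the same bisection.

## Inflammation → vascularity → influx

An external inflammation signal A(t) ∈ [0,1] (held at a level for 3.5
days then ramped to zero over 24 h, by default) drives growth-factor
production; relative vascularity V grows with a Hill function of the
growth-factor concentration and multiplies the baseline influx N₀/T_res:

    dM_G/dt = β_G N₀ + α_G N₀ A(t) − δ_G M_G,    C_G = M_G / N
    dV/dt   = α_V H(C_G) V − δ_V V,              F_in = V N₀ / T_res
    H(C_G)  = x² / (x² + β_V²),  x = C_G / C_G_eq,  C_G_eq = β_G/δ_G

with α_G = 4×10⁻⁷, β_G = 5×10⁻⁸ gfu cell⁻¹ min⁻¹, δ_G = 0.002 min⁻¹,
α_V = 0.001 min⁻¹, β_V = 2, n_V = 2, and δ_V = α_V H(C_G_eq) = 2×10⁻⁴
min⁻¹ so that (V = 1, A = 0) is a fixed point. Two conventions here are
this package's choices: β_G is the *baseline* production coefficient and
α_G the inflammation-driven one (full inflammation then raises production
9-fold, producing the severalfold population expansion of a reactive
node; the reverse assignment would give a biologically inert 12.5%
bump), and the Hill function is normalized by the equilibrium
concentration so that β_V = 2 is dimensionless.

The sub-model is integrated by explicit Euler at the 15 s lattice step;
all rates are ≤ 2×10⁻³ min⁻¹, and the Euler path agrees with an adaptive
LSODA integration to better than 0.5% over 10 days (tested).
`population_ode` provides the deterministic mean-field cross-check
dN/dt = F_in − N/T_res coupled to the same vascular equations; agent
runs track it to within demographic noise. With these rates a full-level
pulse peaks near 8× N₀ and the fixed point is restored with a ~3.5-day
vascular time constant: levels ≤ 0.5 re-enter the ±10% band by days
12–14, a level-1.0 pulse by about day 15.

## The step loop, determinism, and measurement

Per 15 s step: vascular/influx update → Poisson ingress → movement over
all cells in a freshly shuffled order (avoiding lattice-sweep artifacts)
→ forced resolution of shared sites (attractions recomputed at the new
positions) → egress → portal/blob bookkeeping → recording. All
randomness flows from one `numpy` Generator seeded by the config, with
compiled kernels consuming pre-drawn uniforms, so a config + seed
reproduces a run bit-identically. Cell conservation
(entries − exits = ΔN) is asserted every step and full site/occupancy
audits every 4 h of simulated time.

Transit statistics use closed entry/exit records of cells entering after
a 24 h burn-in. Because a finite run right-censors the long transits of
late entrants (naively biasing a 6-day run's mean ~10% low), the
estimator restricts entries to a window leaving a tail margin of several
residence times — entries in [24 h, 72 h] of a 6-day run for T_res = 12 h
(residual bias < 0.5%).

## Problem sizes and what the scenarios show

The published experiments run 50 k–1.1 M cells for 10 days; this package's
default checks use scaled-down versions chosen to keep the full suite at
desk scale: steady-state residence time on 10 k cells × 6 days;
scale-invariance at 5 k and 16 k × 4.5 days; the egress-probability
inverse law on 2 k cells × 2 days; β saturation on 3 k cells × 2 days
(the required reduction factor measured from the saturated per-portal
egress capacity, since a single rounded portal cannot hold an exact
steady state); the chemotactic subset experiment on 6 k cells ×
4.5 days with a 10% subset; the inflammation pulse on 6 k cells ×
10 days at level 0.25. The exit-count power law makes portal counts
(hence residence times) scale-free, so these reductions test the same
mechanisms at coarser counting statistics; portal-count granularity at
small N is the main cost (a blob of 2 k cells earns only ~2 portals, so
steady populations sit within a few percent, not arbitrarily close, of
N₀).

The synthetic scenarios emulate trafficking statistics, not tissue
anatomy: there is no fibroreticular network, no dendritic cells or
activation, no B cell follicle beyond the excluded cap, no explicit
chemokine field or S1P/CCR7 receptor dynamics, and entry/exit geometry is
idealized (interior entry sphere, boundary portals). Passing tests show
that the trafficking, chemotaxis and inflammation mechanisms interact
consistently and reproduce the published calibration anchors — not that
the paracortex is anatomically like this.

## Known limitations

- Portal counts are integers; at small populations the steady state
  dithers between adjacent counts, leaving a few-percent population
  offset that shrinks with N.
- The exit power law is calibrated over 2 k–25 k cells; extrapolation far
  beyond (≥ 10⁵) inherits the fit's uncertainty, though b ≈ 0.93 makes it
  mild.
- The β(K_E) quadratic ships from the published fit; regenerating it at
  small scale yields slightly different coefficients (crowding saturation
  depends weakly on blob curvature).
- The inflammation sub-model is phenomenological by construction; its
  absolute population trajectories depend on the decided Hill form and
  coefficient role assignment documented above.
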