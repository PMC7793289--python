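# Methods

## Models

All models are mass-action reaction networks in nM and seconds, with
binding, dissociation and catalysis treated explicitly (no quasi-steady
Michaelis–Menten reduction). The single-site cycle has species S, S*,
MS, DS*, M_free, D_free and reactions

    ∅ →(Q) S                      S + M ⇌(k+M, k−M) MS →(kcat,M) S* + M
    S* + D ⇌(k+D, k−D) DS* →(kcat,D) S + D
    S, MS →(δ1) ∅ (enzyme freed)  S*, DS* →(δ2) ∅ (enzyme freed)

Degradation of a complex removes only the substrate moiety and releases
the enzyme; by default a complex degrades at the rate of the substrate
state it carries (MS at δ1, DS* at δ2), with `complex_degradation=
"uniform"` (δ1 for both) as the documented alternative — the choice is
immaterial in the enzyme-limited regime because complexes hold a
negligible substrate fraction. Enzymes are conserved totals: no enzyme
synthesis or turnover. The GK variant sets Q = δ1 = δ2 = 0 and conserves
total substrate; the Intermediate variant sets δ2 = δ1; the Full variant
requires δ2 > δ1 > 0.

The chain models replicate this scheme over chain lengths k = 0…ℓ.
The E3 binds free substrate with k < ℓ, the DUB binds free substrate
with k > 0, and each substrate molecule is occupied by at most one
enzyme at a time (DUBs do not attack E3-bound chains). Catalysis depends
on the mechanism: a distributive E3 releases after each addition
(MS_k → S_{k+1} + M), a processive E3 stays bound (MS_k → MS_{k+1});
a distributive/sequential DUB removes one unit and releases
(DS_k → S_{k−1} + D), a processive/sequential DUB trims while bound
(DS_k → DS_{k−1}), and a base-cleaving DUB removes the whole chain
(DS_k → S_0 + D). Catalytic rates are chain-length independent. States
with k below the degradation threshold (4 by default, reflecting the
minimal chain the proteasome recognizes efficiently) degrade at δ1,
states at or above it at δ2. The modified fraction S* counts **all**
substrate molecules with k ≥ threshold — free and enzyme-bound — whereas
in the single-site models S* is the free modified species over [S]_T
(the enzyme-bound correction is below 10⁻⁴ at reference conditions, as
the test suite's symmetry checks document).

The multi-substrate model gives each of N substrates its own Full-model
species set while both enzymes are drawn from shared free pools. With
N = 1, or with a competitor synthesized at Q2 = 0, it reduces exactly to
the single-substrate Full model (tested).

## Reference parameters

`ptmcycle/data/table1.yaml`, loadable via `reference_parameters()`:
k± = 10⁻⁴ nM⁻¹s⁻¹ / 10⁻³ s⁻¹, kcat = 0.999 s⁻¹ (so K_M = 10⁴ nM),
Q = 0.02 nM/s, δ1 = 2×10⁻⁵ s⁻¹ (the average human protein half-life of
~10 h), δ2 = 2×10⁻⁴ s⁻¹ (near the fastest observed degradation rates),
[D]_T = 0.1 nM; [M]_T is set through r at scan time. The `saturated_Q`
column raises Q to 2.0 nM/s ([S]_T = 10⁵ nM); `saturated_KM` raises k+
to 10⁻² nM⁻¹s⁻¹ (K_M = 10² nM) at unchanged Q. M and D kinetics are
equal throughout, matching the closed forms' validity condition. The
supported regime is enzyme-limited ([M]_T, [D]_T ≪ [S]_T); a warning is
emitted when enzyme totals exceed 10% of steady-state substrate.

## Steady states and scans

A state is stationary when |dy_i/dt| ≤ atol + rtol·|y_i| with
rtol = 10⁻⁸, atol = 10⁻¹² nM/s (responses span five decades of
concentration). The solver integrates with LSODA over geometrically
growing windows from the empty system (synthesis fills it) and polishes
with damped root-finding in which each conserved quantity's redundant
ODE row is replaced by its conservation residual; roots with meaningful
negativity or drifted conservation totals are rejected. Along a scan the
previous steady state warm-starts the next solve (root-first). A
uniqueness spot-check re-solves scan endpoints from a substrate-loaded
initial condition; no multistability has been observed in any model
here, consistent with chain-length-independent catalytic rates.

Scan grids are log-spaced (200 points by default) with bounds expanded
decade by decade until the normalized response either comes within 0.5%
of its theoretical asymptote or has been flat (< 10⁻⁴ per decade) for
three consecutive decades. The flattening rule matters for chain models:
molecules transiting the sub-threshold states keep S* strictly below 1
even at infinite r, so a fixed-coverage criterion would never terminate.

r50/r10/r90 are located by log-linear interpolation on the grid and then
refined by bisection on fresh steady-state solves to within 10⁻⁴ of the
level — n_eff is exquisitely sensitive to r10/r90 on steep curves, so
grid interpolation alone is not trusted. Levels are absolute molar
fractions for S* and fractions of the dynamic range (the drop from Q/δ1
toward Q/δ2) for [S]_T; for these decreasing curves r10 means 10% *of
the drop*, a convention recorded in every metrics record. Levels outside
the attained range are reported as missing, never extrapolated.

## Chain truncation

`choose_truncation` doubles ℓ from the degradation threshold upward and
accepts the first ℓ whose r50 and n_eff both moved by < 1% from the
previous doubling. At reference parameters the representative
(processive E3, distributive/sequential DUB) model converges by ℓ ≤ 50.
A caveat for processive E3s with slow release (k−M ≪ kcat): a bound
substrate keeps elongating for ~kcat/(k−M + δ2) steps, so the *chain
length distribution* extends with ℓ even where the *metrics* have
converged — the truncated model is therefore validated by metric
convergence plus agreement with the truncation-free stochastic
simulator, not by the tail mass itself (which is only asserted negligible
for distributive E3s).

## Stochastic simulation

The simulator is an exact direct-method SSA over substrate counts per
(chain length, binding status) class — agents of equal state are
exchangeable, so per-class counts lose nothing while keeping propensity
updates O(active chain lengths). Chain lengths are unbounded (a 4096
buffer guards the kernel; overflow aborts loudly). Concentrations map to
copies via the volume factor ω (copies/nM): unimolecular constants
unchanged, association rates divided by ω, synthesis multiplied by ω.
The kernel is numba-compiled and seeded; identical (seed, parameters,
initial state) give bit-identical event sequences.

Steady-state averages discard a burn-in of five mean substrate lifetimes
(5/δ1) from an empty start and time-average the remainder; replicate
seeds give the standard error. The deterministic/stochastic equivalence
tests run all six mechanisms at *fast-turnover* conditions — δ1 = 2×10⁻³
s⁻¹, δ2 = 2×10⁻² s⁻¹, Q = 2 nM/s, [D]_T = 1 nM, r = 200, ω = 10 (≈10⁴
substrate copies) — which keep [S]_T and the saturation ratio at their
reference values while shrinking the relaxation time a hundredfold so
that ten replicates per mechanism fit in seconds. For processive E3s the
release rate is k−M = 0.1 s⁻¹ there (≈8 additions per binding, a
realistic processivity) with ℓ = 60, where the truncated ODE is
converged to well within the Monte-Carlo error; Table-1 release rates
would need far larger ℓ for the same comparison without changing the
conclusion.

## Synthetic data

Parameter ensembles draw the varied symbols (K_M, δ1, δ2) log-uniformly
over a configurable span (default two decades centred on the base set).
K_M moves through k+ of both enzymes jointly, preserving equal M/D
kinetics; draws with δ2 < δ1 are rejected and redrawn, and an
Intermediate-patterned base keeps δ2 = δ1.

The ligase–substrate generator emulates curated interaction databases
with a zero-inflated truncated power law: degree ∝ k^(−1.7) on 1…92,
zero-degree probability set so the overall substrate load (substrates
per annotated ligase) hits its target, 2.1 by default. At those defaults
~59% of ligases have no substrate, ~50% of the remainder have ≥2 and
~11% have >10 — close to, though not exactly, the reported database
fractions (54%/52%/11%); a single exponent cannot match all three
simultaneously and the tail fraction was prioritized. The generator
emulates degree statistics only: substrate identities are unique per
ligase, so substrate *sharing* between ligases — real in the databases —
is not represented, and passing load-statistics tests says nothing about
which proteins are coupled.

What the synthetic conditions do not emulate more broadly: cell-to-cell
parameter variability, enzyme turnover, substrate-specific kinetics in
the multi-substrate default (substrates differ only in Q), and any
transient (pre-steady-state) behaviour.

## Numerical edge cases

Modified-fraction observables report NaN ("missing") for systems whose
total substrate is below 10⁻¹² nM, which absorbs root-polish dust in
structurally empty compartments. Non-negativity is enforced by clipping
integrator output at zero (deviations are at rounding level) and by
rejecting root solutions with meaningful negativity. Metric extraction
refuses curves with any non-converged point, and scans fail loudly if
the response is non-monotone beyond 10⁻³ of its range.

## Known limitations

Closed forms assume equal M/D kinetics; the enzyme-comparable-to-
substrate regime is unsupported (warned); no branched or mixed-linkage
chains; no explicit E1/E2 machinery or proteasome binding kinetics; no
bifurcation/multistability search; figure-quality plotting is out of
scope (experiments emit CSV/JSON tables).
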