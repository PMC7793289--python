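# ptmcycle

Steady-state and stochastic models of post-translational modification
(PTM) cycles coupled to protein turnover.

## The problem

In the classic Goldbeter–Koshland (GK) picture, a substrate S is
interconverted with its modified form S* by a modifying enzyme M (e.g. a
kinase, or an E3 ubiquitin ligase) and a demodifying enzyme D (a
phosphatase or a DUB). When the enzymes are saturated ([S]_T ≫ K_M), the
steady-state modified fraction S* responds to the enzyme-activity ratio

    r = kcat_M·[M]_T / (kcat_D·[D]_T) = Vmax_M / Vmax_D

like an on–off switch ("zeroth-order ultrasensitivity"). But proteins in
cells are also synthesized (rate Q) and degraded (rate δ1; modified forms
tagged for degradation at δ2 > δ1, as with polyubiquitylation). This
package implements the model family that asks what turnover does to the
switch:

* **GK** — closed cycle, no turnover (total substrate conserved);
* **Intermediate** — synthesis at Q, uniform degradation at δ1, so that
  [S]_T = Q/δ1 at steady state;
* **Full** — modified forms degrade faster (δ2 > δ1), so total substrate
  itself switches between Q/δ1 and Q/δ2 as r rises;
* **chain models** — polyubiquitin chains of length k = 0…ℓ with
  processive/distributive E3 and three DUB mechanisms; chains of ≥ 4
  ubiquitins are degraded fast;
* **multi-substrate models** — N substrates sharing one E3/DUB pair,
  coupling their levels and sensitivities ("crosstalk").

Dose–response curves are characterized by the half-maximal input ratio
r50 and the effective Hill coefficient

    n_eff = log(81) / log(r90 / r10),

with absolute molar-fraction levels for S* and dynamic-range-normalized
levels for [S]_T. Closed forms implemented alongside the numerics (equal
M/D kinetics):

    r50(I)  = (1 + δ1/kcat_D) + Q/(2·kcat_D·[D]_T) + δ1·K_M/(kcat_D·[D]_T)
    r50(I)  → 1 + (δ1 + Q/(2[D]_T))/kcat_D          as K_M → 0
    n_eff(I) → 2                                     as Q → ∞
    n_eff(Full) → log 81 / [log 9 + log((9δ1+δ2)/(9δ2+δ1))]  as Q → ∞

An exact agent-based stochastic simulator (per-molecule chain lengths,
no truncation) validates the ℓ-truncated deterministic chain models, and
a synthetic-data module generates log-uniform parameter ensembles and
heavy-tailed ligase–substrate networks for robustness and crosstalk
statistics. See `docs/methods.md` for assumptions and numerical choices.

## Worked example

```python
from ptmcycle import (ModelVariant, analytics, as_variant, compute_metrics,
                      reference_parameters, response_family, scan_response)

p = as_variant(reference_parameters("unsaturated"), ModelVariant.INTERMEDIATE)
curve = scan_response(response_family(ModelVariant.INTERMEDIATE, p), n_points=120)
m = compute_metrics(curve)
closed = analytics.r50_intermediate_closed_form(
    p.kcat_D, p.delta1, p.Q, p.K_M_D, p.D_total)
print(f"r50 numeric {m.r50:.4f} vs closed form {closed:.4f}; n_eff {m.n_eff:.4f}")
```

prints

```
r50 numeric 3.1031 vs closed form 3.1021; n_eff 1.0232
```

i.e. at the unsaturated reference parameters (Q = 0.02 nM/s, δ1 = 2×10⁻⁵
s⁻¹, K_M = 10⁴ nM, [D]_T = 0.1 nM) the Intermediate cycle is already three
times less sensitive than the GK loop (whose r50 is exactly 1) and barely
cooperative. The same comparison from the command line:

```bash
ptm analytics                  # closed-form table
ptm run fig2_saturation --out results/   # GK/Intermediate/Full metrics
ptm validate                   # oracle self-checks
```

`ptm run fig2_saturation` writes a metrics table showing the saturation
effects: raising Q a hundredfold moves the Intermediate r50 from 3.10 to
13.0 and the Full r50 from 21.2 to 39.2, while the GK r50 stays at 1.

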