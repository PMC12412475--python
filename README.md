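# crnpde

Chemical reaction network (CRN) compilation and simulation for a molecular
neural-network PDE solver, with export to DNA strand-displacement (DSD)
reaction programs.

The package builds, under deterministic mass-action kinetics:

* **core** — CRN data model, stiff ODE integration (BDF, rtol 1e-8),
  stoichiometry, steady-state detection, dual-rail signal encoding, and a
  plain-text CRN interchange format (`A + 2 B -> C @ 0.003`).
* **signals** — oscillator CRNs emitting offset sine/cosine test inputs.
* **differentiator** — membrane-diffusion first/second-order derivative
  modules, the five-reaction subtraction operator, and a chain-rule
  integrator (e.g. the cube function of a sine input).
* **partials** — division-principle CRNs computing values and first-order /
  mixed partial derivatives of monomial sums at clamped inputs.
* **ann** — an augmented-matrix network (2 inputs, 4 square-activation
  hidden units, linear combination/readout) trained by reference-arithmetic
  gradient descent and compiled chemically per augmented input pattern;
  reversible weight-storage (adjustment) CRNs.
* **brusselator** — the Brusselator CRN, target-function verification
  module, dual-rail error comparator, reduced-PDE residual channel with the
  `Error2 = R11^2` squaring readout, and the Loss assembly; plus the fully
  wired pipeline.
* **dsd** — compilation of every ideal reaction into strand-displacement
  step cascades (slow step `q_i`, fast steps `qmax`), species classification
  into auxiliary / intermediate / inert-waste sets, rate-map feasibility
  checking, trajectory-equivalence validation, and a deterministic script
  format.

Concentrations are nM, time is seconds.

## CLI

All functionality is exposed through the `crnpde` entry point:

```bash
crnpde simulate system.crn --t-end 20000 --out traj.csv
crnpde signals --phase sine --t-end 12.56
crnpde differentiate --input sine --order 2 --kdiff 10 --t-end 25
crnpde partials --function "x^2 + 2 t^2 + 0.5 x t" --at x=0.8,t=0.5 --wrt x
crnpde ann --x 0.8 --t 0.5 --target "x^2 + 2 t^2 + 0.5 x t"
crnpde solve-pde --report errors.csv
crnpde compile --crn system.crn --cmax 1000 --qmax 1e7 --validate
crnpde reproduce-table5 --out table5.csv
crnpde fixtures --kind brusselator-demo
crnpde config > tables.yaml
```

Subcommands exit nonzero when a requested computation fails to converge.

## Notes

* Bimolecular and trimolecular rates are in /nM/s internally; rates quoted
  in /M/s convert via 1e-9 (e.g. qmax = 1e7 /M/s = 1e-2 /nM/s).
* The differentiator's nominal rate (kdiff = 4e-4 /s, tau = 2500 s) is far
  too coarse to check against closed forms; `DifferentiatorConfig.fast_regime`
  scales all module rates with kdiff so the o(tau) error analysis is visible
  (max error against cos(t) falls as ~1.1/kdiff).
* DSD compilation offers two modes: `buffered=True` (default) initializes the
  reverse coproduct of each slow reversible step at Cmax, which makes the
  printed rate maps (`q_i = k/Cmax` unimolecular, `q_i = k` bimolecular,
  `q_i = k*Cmax` trimolecular) kinetically exact in the q << qmax regime;
  `buffered=False` emits the literal printed cascades (classification of the
  displaced strands as inert waste), which are structural rather than
  kinetically faithful.
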