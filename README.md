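# fracno

Space-fractional reaction–diffusion simulation of nitric oxide (NO)
biotransport in a cylindrical vessel–tissue geometry.

NO is produced by neurons and by shear mechanotransduction at the
endothelium, diffuses radially across the vessel wall, and is removed by
hemoglobin in the blood, by reaction with extracellular superoxide, and
by saturable inactivation in the tissue. When endothelial microparticles
or disease processes trap and release NO, its spread is better described
by a Lévy flight than by Brownian motion: `fracno` models this with a
generalized Fick law built from left- and right-sided Riemann–Liouville
derivatives of order ε ∈ (0, 1],

    ∂C/∂t = −(1/r) ∂/∂r(r F) + sources − sinks,
    F(r,t) = −D [ p ∂ᵋ_{R−} − q ∂ᵋ_{L+} ] C,     p + q = 1,

discretized with Grünwald–Letnikov matrices on an equispaced radial grid
and integrated as a stiff method-of-lines system (BDF with analytic
Jacobian). ε = 1, p = q = ½ recovers the classical model exactly. The
package is aimed at computational physiologists studying how anomalous
diffusion, vascular wall mechanics and oxidative stress shape the NO
available at the vascular wall.

## Worked example

Simulate the baseline anomalous-diffusion scenario (ε = 0.85,
forward-dominant transport p = 0.75, normal wall and superoxide):

```
$ fracno simulate --epsilon 0.85 --p 0.75 --out no_run
peak 3.191735e-09 mol/m^3 at t = 0.8283 s
wrote no_run/concentration.csv, no_run/metadata.json, no_run/endothelium_profile.csv
```

The printed peak is the maximum NO concentration at the outer face of
the endothelium (r = a + h, the node at 25.53 µm on the 300-interval
grid): about 3.2 nmol/m³, reached 0.83 s after the neuronal synthesis
pulse starts. `concentration.csv` holds the full field in long format
(`r_m,t_s,c_no_mol_per_m3`), `endothelium_profile.csv` the wall time
series, and `metadata.json` the complete resolved configuration and
solver diagnostics needed to reproduce the run.

The same from Python:

```python
from fracno import RunConfig, simulate, endothelium_profile, peak_metrics

cfg = RunConfig(epsilon=0.85, p=0.75, q=0.25)
model = cfg.to_model()
result = simulate(model)
profile = endothelium_profile(result, model.geometry)
print(peak_metrics(profile))
# {'peak_value': 3.191734562066035e-09, 'peak_time': 0.8282999999999999, 'n_maxima': 1}
```

Other entry points:

* `fracno scenario fig3a` … `fig10d` — presets matching the study's
  figure panels (ε, p, wall stiffness, superoxide level);
* `fracno sweep --epsilons 1.0,0.95,0.85 --p-values 1.0` — endothelial
  peak metrics over an ε × p grid;
* `fracno oracle` — convergence table of the Grünwald–Letnikov
  discretization against the closed-form Riemann–Liouville derivative.

Configuration files are flat YAML/JSON with the same keys as the CLI
flags; unset keys take the canonical parameter-table defaults.

Note: the mechanotransduction term multiplies the local concentration,
and for strongly anomalous transport (ε ≤ 0.75 at the tabulated
oscillation amplitude) the coupled system is linearly unstable — such
runs abort with a diagnostic integration error rather than returning
unphysical values. See `docs/methods.md` for the analysis.

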