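# tmesim

A three-dimensional, multi-scale, agent-based simulator of the tumor
microenvironment (TME): avascular tumor growth, tumor-induced angiogenesis
and vascular tumor growth, fully coupled across subcellular biochemistry,
cellular phenotypes and tissue-scale fluid dynamics.

It is aimed at computational-biology researchers who want a transparent,
testable reference implementation of the classic hybrid continuous–discrete
TME modeling stack: reaction–convection–diffusion fields for oxygen,
glucose, CO2, VEGF/VEGFR-2, Ang-1/Ang-2/Tie-2, MMP and ECM; lattice agents
for tumor cells and endothelial tip cells; and a vessel graph with
lumenogenesis, shear-stress/metabolic/pressure/VEGF diameter adaptation,
elastic deformation, disruption, non-Newtonian hemorheology, hematocrit
phase separation, Starling filtration and Darcy interstitial flow.

## The model in brief

Tumor cells live on a 50 µm lattice. Cellular respiration couples the
nutrient fields to a *vitality*

    ϑ = φ · o2/(o2+o2_ch) · g/(g+g_ch) · exp(−5 (co2/co2_ch − 1)⁴ H(co2−co2_ch))

which gates an ATP budget dψ/dt = (k_a_p ϑ − k_a_c ϑ/(ϑ+1)) for active
cells (division at ψ ≥ ψ_ch) and −k_q_c for quiescent ones (necrosis at
ψ < 0). Hypoxic cells secrete VEGF; a circular primary vessel in the tumor
mid-plane sprouts tip cells wherever VEGF exceeds an activation level,
which migrate by chemotaxis/haptotaxis with movement probabilities read off
the finite-difference discretization of the cell-density equations
(the hybrid continuous–discrete method, over the full 26-neighborhood).
Anastomosed loops carry Poiseuille flow with the Pries in-vivo viscosity
law, leak plasma by Starling's law, raise the interstitial fluid pressure
(−∇²p_ins = sources at vessel walls), and remodel their diameters from
wall shear stress, transvascular pressure, hematocrit-borne metabolic
demand and VEGF. See `docs/methods.md` for the full model, parameter
rationale and numerical choices.

## Worked example

```bash
tmesim run --fixture toy21 --seed 1 --scenario normal --out out_normal
```

runs two simulated days on a 21³ lattice (1 mm cube, five tumor cells
seeded at the center, primary vessel ring of radius ≈ 0.45 mm) and prints
one line per 3 h snapshot:

```
day   1.00  total=   39 A/Q/N=35/4/0 neo=0
day   1.38  total=   66 A/Q/N=51/15/0 neo=0
day   1.50  total=   67 A/Q/N=50/17/0 neo=21
day   2.00  total=  153 A/Q/N=153/0/0 neo=116
{"t_days": 2.0, "total": 153, "active": 153, "quiescent": 0, "necrotic": 0,
 "n_neo_segments": 116, "tumor_volume_mm3": 0.019125}
```

`total` is the tumor-cell count and `A/Q/N` its split into active,
quiescent and necrotic phenotypes. By day ~1.4 the interior has quiesced
(51/15 split); the hypoxic cells' VEGF then reaches the ring, the first
sprouts appear (`neo` segments at day 1.5), and perfusion re-activates the
quiescent cells — at this small toy scale the ring is close, so
vascularization is early and the avascular slowdown brief (the 41³
`small41` fixture shows the full three-phase curve). `out_normal/`
contains the tidy metrics CSV, a JSON summary with event times (first
hypoxia, first sprout, first perfused neo-vessel …), cell and
vessel-network CSVs, a restartable `checkpoint.pkl`, and VTK exports
(`.vti` fields, `.vtp` network) for ParaView.

The same studies are scriptable from Python:

```python
from tmesim import make_fixture, run
state = run(make_fixture("small41", seed=1, t_end_days=6.0))
print(state.report.events)          # staging: hypoxia -> necrosis -> sprouting
print(state.report.final())         # censuses, morphometry, TGP, peak IFP
```

Scenario presets (`hyperglycemia`, `hypoxemia`, `hypertension`, `low_ihc`,
…) scale the perfusion constants, inlet pressure or interstitial hydraulic
conductivity; `tmesim.apply_scenario` is a pure function on the parameter
set, so baselines are never mutated.

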