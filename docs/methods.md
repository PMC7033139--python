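# Methods

`tmesim` simulates a three-dimensional tumor microenvironment (TME) on a
single regular lattice, coupling three scales:

* **subcellular** — reaction–convection–diffusion transport of nine
  biochemical agents: the cellular-respiration (CR) species oxygen, glucose
  and carbon dioxide; VEGF and its endothelial receptor VEGFR-2;
  angiopoietin-1/-2 competing for Tie-2; MMP; and ECM (fibronectin);
* **cellular** — lattice agents: tumor cells (TCs) with a
  vitality/ATP-energy phenotype machine, and tip endothelial cells leading
  angiogenic sprouts;
* **tissue** — the vessel network graph (lumenogenesis, wall-signal
  adaptation, elastic deformation, disruption), intravascular Poiseuille
  flow with plasma skimming of hematocrit, Starling transvascular
  filtration, and Darcy interstitial flow driven by a Poisson equation for
  interstitial fluid pressure (IFP).

## Model summary

**Transport.** Every soluble species obeys
`∂c/∂t + ∇·(u_ins c) = D∇²c + S(x, t)` with first-order upwind convection,
a 7-point Laplacian, forward-Euler stepping under the explicit stability
bound `dt ≤ h²/(6D)` (checked per species), Dirichlet boundaries at the
initial values, and clamping of negative concentrations (audited; the
cumulative clamped mass is reported per run). ECM has no transport — it
only decays proteolytically, `∂c_e/∂t = −ε_e c_m c_e`.

**CR metabolism and phenotypes.** TC consumption/production follows the
respiration stoichiometry `C6H12O6 + 6 O2 → 6 CO2 + …`: oxygen consumption
equals CO2 production equals six times glucose consumption, all
proportional to a *vitality*
`ϑ = φ · [o2/(o2+o2_ch)] · [g/(g+g_ch)] · exp(−5 (co2/co2_ch − 1)⁴ H(co2 − co2_ch))`.
Vitality above a threshold makes a cell active (it may divide and migrate);
at or below, quiescent (inert but still metabolizing); a quiescent cell
whose ATP budget `ψ` goes negative becomes necrotic, irreversibly. Active
cells gain `ψ` at `k_a_p ϑ − k_a_c ϑ/(ϑ+1)` and divide at `ψ ≥ ψ_ch`,
both daughters restarting at `ψ_ch/2` in a free 26-neighbor site (division
is deferred under contact inhibition); quiescent cells drain `ψ` at `k_q_c`.

**Perfusion.** At vessel-wall nodes, oxygen/CO2 exchange at
`f · (d_v/d_c) · (p/p_lum_ref)` and glucose with an extra Michaelis–Menten
factor in the local concentration; `p` is the transvascular pressure
(luminal minus interstitial). `p_lum_ref` is a *characteristic* luminal
pressure (30 mmHg), deliberately held fixed across scenarios: with the
alternative reading (`p` divided by the local luminal pressure) the ratio
is ≈ 1 regardless of blood pressure and the inlet-pressure study would have
no mechanism. VEGF washout into vessels is pressure-independent
(`f_v d_v/d_c`), as the transport model states it.

**Angiogenesis.** Hypoxic TCs (`o2 < o2_ch`) secrete VEGF at
`R_v (1 − o2/o2_ch)`. Ring nodes seeing VEGF above an activation level
spawn tip cells, spaced by NOTCH-like lateral inhibition (> `min_spacing`).
Tips migrate by hybrid continuous–discrete sampling: transition rates per
26-direction are read off the explicit finite-difference discretization of
the density equation — random walk `D/h²` plus saturating chemotaxis
`[β_c/(1+α c_v)] ∂c_v/∂e / (2(|e|h)²)` plus haptotaxis `β_h ∂c_e/∂e /(2(|e|h)²)`
— multiplied by `exp(−λ_p Δp_bias)` (solid stress as a barrier), with
`P_move = dt·rate`, negatives clipped, the remainder on *stay*, and no
immediate backtracking onto the trail. Tips reaching an existing vessel
node anastomose (loops allowed). Stalk nodes above a VEGF branching
threshold differentiate into new tips at a configurable rate, respecting
spacing. Segment diameters follow lumenogenesis
`d_v = d_c G_s/(G_s+G_0)` with
`dG_s/dt = α_p c_v/(c_v+θ_p) − ω_m [c_v/(c_v+θ_m)][(a1/a2)/((a1/a2)+ρ_m)] − (1−c_v/(c_v+θ_d))δ + k_age`
until a segment first carries flow, after which the wall-signal adaptation
law takes over:
`d(d_v)/dt = k_d (S_WSS + S_p + S_HM + S_vegf − S_Sh)` with the
log-law stimuli (wall shear stress, transvascular pressure, hematocrit
metabolic supply, VEGF-dependent susceptibility). Diameters are elastically
deformed by `d_v^d = d_v ((p − p_s + p_c)/E)^cp` (collapse at non-positive
base) and segments chronically below a WSS threshold, or chronically
VEGF-flooded inside the tumor, for longer than a survival time are removed;
fragments cut off from the ring are pruned.

**Hemodynamics.** Nodal pressures solve mass balance with Hagen–Poiseuille
conductances `(π/128) d⁴/(Lμ)` and distributed Starling leak
`π d L L_p (p − σ(π_lum − π_ins))` split between segment endpoints; the
apparent viscosity is the in-vivo diameter law
`μ_n = 3.2 + 6 e^{−0.085d} − 2.44 e^{−0.06 d^{0.645}}` with the hematocrit
correction `f(H_D) = [(1−H_D)^C − 1]/[(1−H_D_n)^C − 1]` and the near-wall
factor `(d/(d−1.1))²`. Hematocrit propagates from the inlets through the
solved flow field in descending-pressure order (a topological order of the
flow directions, so loops need no fixed-point iteration); at bifurcations
plasma skimming splits the parent hematocrit between daughters
(conserving the concentration sum; beyond the velocity-ratio threshold the
slower daughter gets none). The IFP solves `−∇²p_ins = L_p (S/V)/K_ins (p −
σΔπ)` at vessel-wall nodes with zero-Dirichlet boundaries; Darcy velocity
`u_ins = −K_ins ∇p_ins` advects all soluble species. Flow and interstitium
are coupled by fixed-point alternation to 10⁻³ mmHg.

## Time hierarchy

Transport substeps (default 60 s) are nested inside cellular steps
(10 min: phenotype → energy → division → migration → sprouting/tip
migration/branching), which nest inside remodeling steps (1 h:
lumenogenesis, deformation, flow + IFP coupling, hematocrit, adaptation,
disruption, cache refresh). Receptor kinetics are automatically
sub-stepped whenever ligand levels make their Euler step stiff. A single
seed feeds named RNG sub-streams (sprouting, tips, branching,
proliferation, migration, ordering), so runs are bit-reproducible and
individual subsystems replayable; checkpoints restore runs bit-exactly.

## Geometry and initial conditions

The domain is a cube with 50 µm node spacing (one cell diameter). Five
active TCs seed the center; nutrients start at their characteristic
values, growth factors at zero; ECM at its characteristic level. A
circular *primary vessel ring* of radius ≈ half the domain extent lies in
the tumor mid-plane; its node pressures vary smoothly from the inlet value
(30 mmHg default) to inlet − 10 mmHg on the far side, providing the
driving pressure once anastomosed loops form. Presets: `toy21` (21³,
1 mm), `small41` (41³, 2 mm), `paperlike201` (201³, 10 mm, 35 days — the
full-scale geometry; long-running, not exercised by the test suite).

## Parameter choices

Concentrations are normalized by their characteristic values (all
`c_ch = 1`); lengths in µm, time in s, pressures in mmHg, WSS in dyn/cm².
The full default set lives in `tmesim.config.ParameterSet`; every run
records its SHA-256 digest. The rate constants are *placeholder defaults*:
they were chosen by order-of-magnitude reasoning so that, at the reduced
lattice sizes above, the model traverses the full avascular → angiogenic →
vascular arc in a few simulated days:

* `γ0 = 2.2e-3 /s` — sets the depth of nutrient depletion; strong enough
  that the rim of a few-hundred-cell tumor falls below the activity
  threshold (the avascular quasi-plateau), weak enough that the initial
  five-cell cluster stays active.
* division band: `k_a_c/k_a_p = 1.15` makes ATP accumulation breakeven at
  ϑ ≈ 0.15 and fast above ϑ ≈ 0.22, so division effectively stops in the
  depleted rim (threshold `ϑ_ch = 0.20`) and resumes sharply on
  re-oxygenation; `k_q_c` gives a freshly divided quiescent cell a ≈ 1-day
  ATP reserve, so the recently quiesced rim survives until vessels arrive
  while the older core necroses first.
* VEGF: `R_v`, `ε_v` and the vessel washout `f_v` balance so the
  steady-state level is O(1) near the tumor with a decay length
  (`√(D_v/ε_v) ≈ 390 µm`) that lets the hypoxic signal reach the ring in
  1–2 simulated days.
* TC motility is small (`D_TC = 3e-4 µm²/s`, `β_h = 0.3`): at these step
  sizes larger values let cells chase intact ECM outward faster than they
  divide, dispersing the tumor into a well-fed cloud with no avascular
  plateau. Tip chemotaxis `β_c = 300` crosses the ring-to-tumor gap in
  hours once activated.
* Fluid constants (`L_p`, `K_ins`, oncotic pressures, plasma viscosity,
  `H_D_n = 0.45`) are standard microcirculation magnitudes.

## What the reduced-scale runs do and do not show

The bundled study conditions are scaled down (21³/41³ lattices, ≤ 6
simulated days) so the suite runs on a desktop. They reproduce the
*staging* (near-linear avascular rise → pre-vascular slowdown with an
emerging, persistent necrotic core → post-vascularization re-acceleration
and loss of spherical symmetry) and the *directions* of the scenario
studies (hyperoxemia/hyperglycemia accelerate, hypoxemia/hypoglycemia
inhibit, hypocarbia ≈ baseline; lower interstitial hydraulic conductivity
raises IFP and final size). They do not reproduce full-scale magnitudes
(mm³ volumes, 35-day horizons), and two couplings are qualitatively
scale-limited at 1 mm: the ring perfuses a large fraction of the toy
domain, so raising inlet pressure also suppresses hypoxia-driven VEGF and
can *delay* vascularization — at full scale the ring cannot oxygenate the
tumor center and the pressure effect acts through the vasculature alone.

## Numerical choices

* Poisson: cached 7-point operator per lattice; sparse LU below 50 k
  unknowns, warm-started conjugate gradients above; residual max-norm
  checked against the requested tolerance on every return.
* The transvascular-pressure stimulus `S_p` uses the published empirical
  fit, which is real-valued only for p ≥ 10 mmHg (the nested log10);
  lower pressures clamp to the 14 dyn/cm² plateau and the event is
  counted. The VEGF stimulus argument is floored at 0.1 before the log.
* The adaptation law sums four dimensionless log-stimuli; a single rate
  scale `k_d` (default 1 µm/h per unit stimulus) gives it units.
* Eq-level ties (Heaviside at 0) break to "off" everywhere.
* Zero-Ang-2 guard in the maturation term: the Ang-1/Ang-2 ratio is
  treated as infinite (maturation factor 1); with no ligands at all the
  factor is 0.
* Within a cell sweep, movement probabilities are computed against the
  start-of-sweep occupancy; moves apply in randomized order and conflicts
  fall back to "stay". Division and migration order is randomized per step
  to avoid lattice anisotropy.
* Hematocrit is clamped to [0, 0.99]; segments at or below the 1.1 µm
  viscosity pole are treated as collapsed (no flow, logged).
* Vessel components that lose their pressure reference (all paths
  collapsed) carry no flow and no perfusion until reconnected.

## Known limitations

* Parameter values are placeholders in normalized units, not a calibrated
  fit to any tissue; absolute magnitudes (volumes, IFP in mmHg, flows) at
  reduced scale are indicative only.
* Explicit transport stepping makes the full 201³ geometry expensive;
  no implicit integrator or multigrid is provided.
* Unbounded VEGF accumulation is possible under extreme parameter choices
  (the secretion law has no saturation); the defaults keep it O(1), and
  receptor updates sub-step automatically if levels rise.
* The avascular plateau at toy scale (21³) is shallow — the domain
  boundary feeds the rim; the 41³ lattice is the smallest geometry with a
  clear three-phase curve.
* Pulsatile flow, red-cell tracking, pericytes, immune cells,
  deformable/adhesive cell mechanics and drug pharmacokinetics are out of
  scope.
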