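# cablescale

Balance-point modelling and quantification of actin-cable length control
in budding yeast.

Polarized actin cables in *S. cerevisiae* are linear bundles polymerized
by formins at the bud neck that grow along the mother-cell cortex and
serve as tracks for secretory transport. Their steady-state length matches
the **length** of the mother cell — not its volume — so the popular
limiting-pool picture of organelle scaling (size ∝ cell volume) cannot
explain them. `cablescale` implements the alternative: a *balance-point*
model in which the net extension rate is a decreasing function of the
cable length normalized by cell length, together with the machinery needed
to test it against (synthetic) microscopy data: trajectory generators,
the quantification pipeline, allometric scaling fits, kinetic parameter
inference, and model selection against the competing *boundary-sensing*
picture (constant growth until the tip hits the rear of the cell).

## The model

Cable length evolves by the difference between assembly (k₊) and
disassembly (k₋) rates. Writing the net rate as a scale-invariant
feedback function of normalized length x = L_cable/L_cell,

    dL_cable/dt = f(L_cable / L_cell),

the steady state L\* = x\* L_cell (where f(x\*) = 0) is automatically
proportional to cell length. Taylor expansion at early times gives closed
forms

    L(t)     = L_cell (f(0)/f'(0)) (e^{f'(0) t / L_cell} − 1)
    dL/dt(t) = f(0) e^{f'(0) t / L_cell}
    d0       = f(0) f'(0) / L_cell        (initial deceleration)

with two sharp predictions: |d0| is inversely proportional to cell length
(cells enlarged 4.3 → 8.2 µm: ratio 1.9) and proportional to the initial
rate (strains with f(0) raised 0.35 → 0.42 µm/s: ratio 1.2). Near L\*, the
restoring force f'(x\*)/L_cell weakens with cell length, so steady-state
length fluctuations grow with cell size (Ornstein–Uhlenbeck variance
σ²L_cell / 2|f'(x\*)|).

Four feedback families are provided: `linear` (f = f0(1 − x/x\*), realises
the closed forms exactly), `gradient_linear` and `gradient_exp` (constant
assembly minus a disassembly gradient highest at the cell rear), and
`boundary` (constant rate, hard stop — the rejected alternative).

## Worked example

```python
import cablescale as cs

params = cs.FeedbackParams.linear(0.36, x_star=1.0)      # wt feedback
cells  = cs.generate_cell_population("haploid", n=82, seed=1)
trajs  = cs.simulate_cohort(params, cells, cs.ObservationModel(seed=1), seed=1)

res = cs.CableGrowthModel(trajs).fit(seed=0)
print(res.summary())
print(cs.select_model(trajs).chosen)
```

prints

```
Cable growth model (balance-point, early-time solution)
  method: length space, family: linear
  cables: 82   observations: 3362   SSE: 54.86

     param   estimate    std err     [0.025     0.975]
        f0     0.3492     0.0055     0.3383     0.3602
   fprime0    -0.3490     0.0057    -0.3603    -0.3377

  implied x* = -f0/f'(0) = 1.0007

balance_point
```

The fit recovers the generating initial rate f(0) = 0.36 µm/s and slope
f'(0) = −0.36 µm/s within their cable-clustered 95% confidence intervals
from 82 noisy trajectories, the implied normalized steady state x\* ≈ 1
says cables stop at the cell length, and BIC model selection correctly
identifies the balance-point generator. The analytic predictions are one
call each:

```python
cs.initial_deceleration(params, cs.CellGeometry(4.5, 3.75, 3.75))
# -0.0288  (µm/s²) — and |d0| for a 4.3 vs an 8.2 µm cell gives ratio 1.91
```

A `cablescale` console script exposes the same pipeline from the shell
(`synth | simulate | measure | fit | scale | select`); every output embeds
the seed and a config hash.

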