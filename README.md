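# textode

Executable ODE models of signaling networks from textual knowledge.

Mechanistic modeling of cell signaling — receptor activation, kinase
cascades, transcriptional feedback — usually means hand-writing systems of
differential equations, which does not scale as pathway knowledge grows.
`textode` lets you declare a network one reaction per line in a constrained
natural-language format, compiles it to a mass-action / Michaelis–Menten /
Hill ODE system, and provides the surrounding machinery a systems biologist
needs: thermodynamic consistency constraints, simulation under stimulus
conditions, ensemble parameter fitting to time-course data, local
sensitivity analysis, import of KEGG KGML pathway files, and literature
co-occurrence weighting of pathway graphs.

It is aimed at systems-biology researchers who want to go from a pathway
diagram or a written pathway description to a simulatable, fittable model
without writing equations.

## The model

Each reaction line maps to a rate law:

| line | rate law |
|---|---|
| `A binds B --> AB` | reversible mass action, v = k_f[A][B] − k_r[AB] |
| `S is phosphorylated --> pS` | reversible first-order, v = k_f[S] − k_r[pS] |
| `E phosphorylates S --> pS` | Michaelis–Menten, v = V[E][S]/(K+[S]) |
| `TF transcribes M` | Hill, v = V[TF]ⁿ/(Kⁿ+[TF]ⁿ) |
| `M is translated into P` | first-order in the template, v = k_f[M] |
| `X is degraded` / `X is synthesized` | first-order / zeroth-order |

The state evolves as **ẋ = S·v(x, θ)** with S the stoichiometric matrix
(enzymes and templates are modifiers, not consumed). Closed loops of
reversible reactions are detected as the right null space of the reversible
stoichiometric submatrix; for each independent loop, detailed balance
(the Wegscheider condition ∏ K_eq^σ = 1 around the loop) eliminates one
reverse rate constant, which becomes a derived parameter. Free parameters
are fitted in log₁₀ space by seeded differential evolution, one independent
run per parameter set, and reported trajectories are the normalized ensemble
mean ± sd. Sensitivity coefficients are metabolic-control-style log-log
finite differences, s = ln q(f·θᵢ)/q(θ) / ln f.

## Worked example

```python
import textode as tx

model = tx.ReactionNetworkModel.from_text("""
EGF binds EGFR --> EGF_EGFR
EGF_EGFR phosphorylates ERK --> pERK
pERK is dephosphorylated --> ERK
pERK is degraded
@obs pERK: pERK
@init EGFR = 1
@init ERK = 2
@sim_condition EGF_low: EGF=0.3
@sim_condition EGF_high: EGF=3
""")
print(model.report())
```

prints the compiled system:

```
5 species, 4 reactions, 7 parameters

Reactions (index, line, rate law):
  r1 (line 1): v = EGF*EGFR*kf_r1 - EGF_EGFR*kr_r1
  r2 (line 2): v = EGF_EGFR*ERK*V_r2/(ERK + K_r2)
  r3 (line 3): v = -ERK*kr_r3 + kf_r3*pERK
  r4 (line 4): v = kf_r4*pERK

Observables:
  pERK = 1*pERK

No closed loops of reversible reactions detected.
```

i.e. ligand binding is reversible mass action, the receptor complex drives
ERK phosphorylation through a saturating Michaelis–Menten rate, and pERK
reverts and degrades by first-order steps. Simulating the high-EGF
condition at the default parameters,

```python
traj = model.simulate(condition=tx.SimulationCondition("EGF_high", {"EGF": 3.0}, 10.0, 6))
print(traj.species("pERK"))   # [0.  0.4613  0.1811  0.0655  0.0228  0.0079]
```

shows the transient pERK pulse: fast activation while free EGFR lasts,
then decay as the pool degrades. `model.fit(data, FitConfig(...))` returns
a `FitResults` whose `summary()` tabulates the ensemble of fitted
parameter sets, and `model.sensitivity([...])` ranks parameters by their
log-log effect on any response metric.

The same operations are available from a shell:

```
textode compile model.txt
textode simulate model.txt --duration 10 --out sim.tsv
textode fit model.txt data.tsv --seed 1 --n-sets 10 --out ensemble.tsv
textode kgml2text pathway.xml --degrade pAKT,pERK --out model.txt
textode weigh corpus.tsv --genes EGFR,AKT1 --edges EGFR-AKT1 --query MCF-7 --out w.graphml
```

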