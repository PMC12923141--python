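# coevrisk

Tools for studying how cooperation, collective risk, and the cost of
cooperating coevolve in threshold public goods games (collective-risk social
dilemmas).

## The model

Groups of `N` players are sampled from an infinite well-mixed population.
Cooperators contribute a cost `c` toward a collective target; if at least `M`
of the `N` members cooperate, everyone keeps their endowment `b`, otherwise
all members lose it with probability `r` — the collective risk. Three
variables coevolve in continuous time:

```
ε₁ ẋ = x(1−x) [ b r C(N−1, M−1) x^(M−1) (1−x)^(N−M) − c ]
ε₂ ṙ = r(1−r) [ μ₁(1−x) − μ₂ x ]
   ċ = (α−c)(c−β) [ θ₁(1−x) − θ₂ x + θ₃ r − θ₄(1−r) ]
```

* `x` — fraction of cooperators, driven by the replicator equation; the
  bracket is the gradient of selection `f_C − f_D`.
* `r` — risk, raised by defectors (rate `μ₁`) and lowered by cooperators
  (rate `μ₂`), pinned to the faces `r ∈ {0, 1}`.
* `c` — per-capita cooperation cost, raised by defection (`θ₁`) and risk
  (`θ₃`), lowered by cooperation (`θ₂`) and safety (`θ₄`), confined to
  `[β, α]`.

The state box `[0,1] × [0,1] × [β,α]` is invariant. The "tragedy of the
commons" corner `(0, 1, α)` — full defection, maximal risk, maximal cost —
is **always** a stable attractor, but depending on the feedback coefficients
the system is bistable or tristable, with additional attractors on the edges
(`r = 1`, cost pinned) and cost faces where cooperators and defectors
coexist. Which outcome is reached depends on the initial condition; the
package measures this through basin-of-attraction fractions.

The package provides:

* the payoffs, selection gradient (both the group-sampled binomial
  expectation and its closed form), feedback functions, full vector field,
  and analytic Jacobian (`coevrisk.model`);
* a complete equilibrium atlas — 8 corners, 2×2 edge roots, 3 surface
  points, 1 interior point — with existence conditions and stability
  classified both by closed-form sign conditions and by Jacobian
  eigenvalues (`coevrisk.atlas`);
* trajectory integration with attractor assignment (`coevrisk.dynamics`);
* grid-based basin estimation, threshold-`M` sweeps, and regime labelling
  (`coevrisk.basins`);
* a deterministic CLI with YAML configs and named presets covering all
  representative regimes (`coevrisk.cli`, `coevrisk.presets`).

## Worked example

```python
>>> import coevrisk as cr
>>> p = cr.get_preset("bistable_edge_alpha")   # N=8, M=5, b=2, α=0.3, β=0.1
>>> [eq.label for eq in cr.stable_equilibria(p)]
['corner(0,1,alpha)', 'edge_alpha_upper']
>>> cr.edge_equilibria(p, "alpha")[1].x        # stable cooperator fraction
0.7697425013432277
>>> est = cr.estimate_basins(p, grid=(21, 21, 11))
>>> est.fractions
{'corner(0,1,alpha)': 0.3333333333333333, 'edge_alpha_upper': 0.6666666666666666}
```

Under these parameters the system is bistable: about two thirds of interior
starting conditions reach the coexistence state with ~77 % cooperators at
maximal cost, the other third collapse into the tragedy corner.

Sweeping the threshold `M` at the same background parameters:

```python
>>> cr.sweep_threshold(p, [2, 3, 4, 5, 6], "alpha").to_frame()
   M        x2  basin_fraction  success_rate
0  2  0.381025        0.952774      0.872343
1  3  0.514444        0.889020      0.873611
2  4  0.644152        0.773318      0.887026
3  5  0.769743        0.657615      0.911700
4  6  0.885438        0.080283      0.945945
```

A stricter threshold sustains more cooperators (`x2` rises) and a higher
collective success probability, but its basin of attraction shrinks — a
harder target is better *if* the population starts close enough to reach it.

The same computations are available from the shell:

```sh
coevrisk equilibria --preset bistable_edge_alpha --out atlas.json
coevrisk simulate   --config examples/bistable_alpha.yaml --out trajectory.csv
coevrisk basins     --preset bistable_edge_alpha --out basins.json
coevrisk sweep-m    --config examples/bistable_alpha.yaml --out sweep.csv
```

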