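# ehrgame

Evolutionary-game analysis of vertical electronic-health-record (EHR)
integration inside a medical consortium, for health-policy modellers who want
the full pipeline — payoff model, replicator dynamics, equilibrium stability,
scenario simulation and sensitivity sweeps — as tested, scriptable code
instead of a point-and-click system-dynamics model.

## The model

Three boundedly rational populations interact repeatedly: local
**governments** either push EHR integration hard or treat it negatively,
**hospitals** in the consortium participate actively or passively, and
**patients** either supervise (complain when their records are not shared) or
waive supervision.  Twelve nonnegative payoff parameters describe the
incentives — benefits (Rg, Rh, Rp), costs (Cg, Kg, Ch, Kh, Cp), subsidies and
rewards (Fh, Fp) and penalties (Fg, Mh) — with the structural orderings
Cg > Kg and Ch > Kh (negligence is cheaper than effort).

Writing x, y, z for the fractions of pushing governments, active hospitals
and supervising patients, each fraction follows replicator dynamics
u̇ = u(1 − u)·g_u, where the gain g_u is the payoff advantage of the active
strategy.  Derived from the 2×2×2 payoff matrix (the package's single source
of algebraic truth):

```
g_x = (Rg + Fg + Mh + Kg − Cg) − y (z·Fp + Fg + Fh + Mh)
g_y = (Rh + Kh − Ch) + x (Fh + Mh)
g_z = x (Fp − Rp + y·Rp) + (1 − y) Rp − Cp
```

The eight cube vertices are the pure-strategy equilibria; the Jacobian there
is diagonal, so each vertex is classified by the signs of three closed-form
eigenvalues.  Under the shipped baseline parameterization (Rg=30, Cg=6, Kg=3,
Fg=4, Rh=50, Ch=7, Kh=5, Fh=8, Mh=10, Fp=2, Cp=1, Rp=6) the unique stable
vertex is full cooperation (1, 1, 1).

Because several hand-transcribed variants of these equations circulate with
sign slips, the package also ships a symbolic audit (`derivation_audit`,
`table3_audit`) that re-derives everything from the payoff matrix and reports
the residual of every non-matching variant.

## Worked example

```
$ ehrgame stability
(0, 0, 0): eigenvalues (41.0, 48.0, 5.0) -> unstable
(0, 0, 1): eigenvalues (41.0, 48.0, -5.0) -> saddle
(0, 1, 0): eigenvalues (19.0, -48.0, -1.0) -> saddle
(0, 1, 1): eigenvalues (17.0, -48.0, 1.0) -> saddle
(1, 0, 0): eigenvalues (-41.0, 66.0, 1.0) -> saddle
(1, 0, 1): eigenvalues (-41.0, 66.0, -1.0) -> saddle
(1, 1, 0): eigenvalues (-19.0, -66.0, 1.0) -> saddle
(1, 1, 1): eigenvalues (-17.0, -66.0, -1.0) -> stable
reference det/tr table rows flagged by the audit: [(0, 1, 0), (1, 1, 1)]
```

Every eigenvalue is a replicator gain (or its negation) at a vertex: at the
origin the gains (41, 48, 5) are all positive, so universal defection repels
in every direction; at (1, 1, 1) all three are negative and full cooperation
is the evolutionarily stable outcome.  Simulation agrees:

```
$ ehrgame simulate --x0 0.45 --y0 0.35 --z0 0.4 --out trajectory.csv
final state: (1.0, 1.0, 0.9999999992174401)
converged vertex: (1, 1, 1)
```

The patients' long-run behaviour is a knife edge in the supervision reward
Fp versus its cost Cp (the z-eigenvalue at full cooperation is −(Fp − Cp)):

```
$ ehrgame patient-threshold
Fp>Cp (Fp=2, Cp=1): z limit 1.000000, z eigenvalue at (1,1,1) -1, vertex stable
Fp=Cp (Fp=1.5, Cp=1.5): z limit 0.398102, z eigenvalue at (1,1,1) -0, vertex non-hyperbolic
Fp<Cp (Fp=0, Cp=2): z limit 0.000000, z eigenvalue at (1,1,1) 2, vertex saddle
```

When the reward falls short of the cost, patients free-ride and supervision
dies out; on the knife edge the supervision fraction freezes wherever the
fast x and y transients leave it.  `ehrgame full --out-dir report/` runs the
whole pipeline (audit, stability, six labelled scenarios, three sweep
families, threshold and penalty-marginal experiments) and writes CSV tables
plus a plain-text summary; `ehrgame generate` draws seeded synthetic
parameter sets for stress-testing the analysis away from the baseline.

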