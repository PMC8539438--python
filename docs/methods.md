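# Methods

## The model

Sphingomyelin synthase (SMS) transfers the phosphocholine head group of
phosphatidylcholine (PC) onto ceramide (Cer), yielding diacylglycerol (DAG)
and sphingomyelin (SM):

    PC + Cer  <->  DAG + SM           (overall, constant K)

The enzyme works by double displacement (ping-pong): the head group is first
parked on a catalytic tyrosine, giving a covalent phosphoenzyme
intermediate, before the second substrate binds.  The network therefore has
six species — the four lipids plus free enzyme E and phosphoenzyme EP — and
two reversible elementary reactions:

    PC  + E   <->  EP + DAG           (k1, k-1)
    Cer + EP  <->  E  + SM            (k2, k-2)

All rate laws are elementary mass action; no Michaelis–Menten reduction is
applied.  The default stepwise constants are k1 = 0.1, k-1 = 0.2, k2 = 1,
k-2 = 1.43, which give an overall K = (k1/k-1)(k2/k-2) = 0.34965 ≈ 0.35.
The default initial composition is 25 % mol/mol per lipid with the enzyme
fully unphosphorylated.

Units: the lipids are mole fractions of the lipid pool (% mol/mol, the four
lipids summing to 100 at the default start); the enzyme states live on their
own scale, normalised to the configurable total pool (default 1.0), and are
excluded from the 100 % lipid budget.  Time is in arbitrary simulation
units — the bimolecular constants carry no calibrated units, so only
equilibrium values and qualitative kinetics are physically interpretable,
not the absolute time axis.

### Conservation structure

The stoichiometry matrix has rank 2, leaving four independent conserved
moieties: the DAG backbone (pc + dag), the ceramide backbone (cer + sm),
total enzyme (e + ep), and the phosphocholine head count (pc + sm + ep).
The right-hand side is written so each conserved sum's derivative cancels
exactly in floating point, and tests assert this for random states.

### The enzyme pool is not a passive catalyst

A point that matters for interpreting equilibria: at steady state both
reactions satisfy detailed balance, which fixes ep/e = k1·pc/(k1r·dag) > 0.
The phosphoenzyme therefore *stores* head groups — about 0.46 per unit of
enzyme at the default constants — and the head-count conservation law pulls
the lipid composition away from the enzyme-free equilibrium by roughly half
that amount.  The mass-action ratio [DAG][SM]/([PC][Cer]) equals K exactly
regardless of the enzyme pool, but the composition does depend on it: at
the default pool of 1.0 (1 % of the lipid scale) each lipid sits within
0.23 % mol/mol of the enzyme-free values (PC = Cer = 31.42, DAG = SM =
18.58), converging to them as the pool shrinks.  Both behaviours are
tested; claims of composition "independence from enzyme amount" hold only
in this trace-enzyme limit.

## Equilibrium oracles

Two algebraic solutions back the ODE integrator:

* **Lipid-only closed form** — with a single reaction extent ξ,
  (DAG₀+ξ)(SM₀+ξ) = K·(PC₀−ξ)(Cer₀−ξ) is a quadratic in ξ, solved with the
  cancellation-free root formula and the admissibility constraint that all
  species stay non-negative.  Exact in the trace-enzyme limit.
* **Full-network equilibrium** — two extents coupled by detailed balance of
  both reactions; eliminating the enzyme split ep/e = k1·pc/(k1r·dag)
  reduces the system to a scalar root in ξ₁, bracketed by a sign scan and
  polished by Brent's method.  Agrees with the integrated steady state to
  machine precision for any enzyme pool, and never touches the ODE path it
  is used to check.

## Numerics

* Integration: `scipy.integrate.solve_ivp` with the implicit BDF scheme
  (the network is stiff when the stepwise constants are well separated);
  rtol 1e-8, atol 1e-10.  Conservation is verified post hoc to 1e-9
  relative; violations raise rather than being clipped, so positivity and
  conservation tests stay meaningful.
* Steady state: integrate over expanding horizons (10, 100, …) until
  max|dy/dt| < 1e-10 or a time cap of 1e6 units; non-convergence is
  reported as such, never as an invented state.
* Degenerate inputs: an empty lipid pool, or zero enzyme, yields a constant
  trajectory; the closed form rejects the all-zero composition for which no
  equilibrium extent exists.

## Thermodynamic bookkeeping

Reaction profiles are scored as pair sums of binding free energies:
ΔΔG = (ΔG_DAG + ΔG_SM) − (ΔG_PC + ΔG_Cer).  For wild-type lipids in a POPC
membrane the reference sums are −21.7 (reactants) and −26.6 (products)
kcal/mol, hence ΔΔG = −4.9 kcal/mol.  The ΔΔG ↔ K link uses
K = exp(−ΔΔG/RT) at 298 K by default (configurable; some reference
simulation protocols for this system were thermostatted at 300 K).

Two caveats are deliberately surfaced rather than reconciled:

* The slowest-step heuristic kon = min{k_i}, koff = min{k_-i} gives
  kon/koff = 0.5 on the default constants, while the stepwise product gives
  K = 0.35.  Both are computed and reported side by side; neither is ever
  silently substituted for the other.
* ΔΔG = −4.9 kcal/mol implies a thermodynamic K ≫ 1, whereas the kinetic
  K = 0.35 used for the network is a literature-informed working value.
  The two are treated as independent inputs; no automatic ΔΔG → rate
  coupling is applied.

`rates_from_K` maps a target overall K onto the stepwise constants by
rescaling exactly one named constant — the minimal change, labelled as
such, because the energetics-to-rates mapping is under-determined.

## Perturbation analysis

2-hydroxylated ceramide (2R configuration) binds the phosphoenzyme in a
transfer-competent pose, modelled as an increase of k2 by a configurable
factor (default 2.0, an illustrative choice).  Scenario comparisons drive
baseline and perturbed networks to steady state (both restarted from the
same initial composition; a chained mode can start the perturbed run
elsewhere) and report per-lipid deltas with sign labels.  Doubling k2
doubles K to 0.699 and shifts the equilibrium toward products: SM rises
from 18.4 to 22.6 % mol/mol (+4.2), DAG correspondingly, while PC and Cer
fall — the activator-like signature.  Backbone conservation forces
Δpc = −Δdag and Δcer = −Δsm, which is asserted to 1e-9.

## Parameter estimation

Trajectory least squares over the four constants, log-parameterised to
enforce positivity, solved with `scipy.optimize.least_squares` (bounded
trust-region, bounds k ∈ [1e-4, 1e4]) and seeded multi-start (5 starts by
default).  The finite-difference step for the Jacobian is 1e-4 in log
space, deliberately far above the integrator's error floor.  Only the four
lipid columns enter the residual — enzyme states are treated as unobserved
and integrated internally.  Uncertainty scales are relative standard errors
from the Gauss–Newton curvature at the optimum.

Identifiability: one series from one initial composition under-determines
the stepwise constants (a near-equilibrium series pins essentially only the
mass-action ratio, so K is recovered while individual constants drift —
this is itself a tested property).  The standard benchmark fits three
initial compositions jointly: noiseless recovery is then exact to well
under 1 %, and with 1 % additive noise K is recovered within 5 %.

## Synthetic data

The generator emulates the model's own simulation outputs: deterministic
trajectories from known constants plus i.i.d. additive Gaussian noise on
each sampled value (standard deviation in % mol/mol units, optional
truncation at zero).  Additive noise is the simplest model consistent with
observations reported as mole-percent amounts; multiplicative noise was
rejected for lack of any constraint favouring it.  Binding-energy tables
carry the wild-type membrane sums above — split evenly per species, since
only the pair sums are externally constrained — plus hydroxylated-ceramide
variants whose ceramide energy is raised by a uniform draw in 0.6–0.9
kcal/mol, moving the variant ΔΔG to −5.5…−5.8 kcal/mol.  Every stochastic
entry point takes a mandatory seed; identical seeds give bit-identical
output.

What the generator does not emulate: measurement of real lipidomics data
(extraction efficiency, compositional closure of measured fractions,
correlated errors between species), enzyme-level observables, or docking /
metadynamics score distributions.  Passing recovery tests therefore show
that the estimator inverts this model correctly under its own noise
assumptions, not that it would do so on experimental lipid measurements.

## Problem sizes

Default suite sizes: 1000 random states for conservation, 60–200 random
parameter draws for steady-state cross-checks, 26-point grids over t ∈
[0, 50] for the three-series estimation benchmark, and a 3-seed noise sweep
(σ ∈ {5, 1, 0} % mol/mol) for the recovery-vs-noise property.  These sizes
keep every statistic stable across seeds while the full suite stays fast.

## SBML exchange

Export writes Level 3 Version 2: six species with initial amounts, the four
constants as global parameters, and each reversible reaction as a single
reaction whose kinetic law is the explicit two-term net expression (e.g.
`k1*pc*e - k1r*ep*dag`) — the encoding common simulators expect.  Import
reconstructs the network and rejects anything whose kinetic laws are not
recognisably of that form (e.g. saturating laws), with a diagnostic naming
the reaction.  python-libsbml is the primary backend (including consistency
checking); a self-contained XML reader/writer covering the same subset is
used when libsbml is unavailable, so round-trip fidelity does not depend on
the optional dependency.

## Known limitations

* The absolute time axis is uncalibrated; only equilibria and qualitative
  transients are meaningful.
* The k2-doubling factor is illustrative, not derived from binding-energy
  differences; the package deliberately makes no quantitative
  metadynamics-to-rate link.
* Reference free energies (pair sums, hydroxylated-variant ΔΔG values,
  metadynamics minima −9.33 / −9.52 kcal/mol) are tabulated external
  inputs, reported but never recomputed.
* The ODE model is deterministic and well mixed: no spatial or membrane-
  compartment resolution, no stochastic (Gillespie) simulation.
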