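"""ODE integration, steady-state detection and the closed-form equilibrium.

The network is stiff for strongly separated rate constants, so integration
uses an implicit BDF scheme (rtol 1e-8, atol 1e-10 by default).  Negative
concentrations are never clipped: conservation and positivity are checked
after the fact and violations raise, so the invariant tests stay meaningful.

The closed-form equilibrium solves the conservation-constrained condition
(DAG*SM)/(PC*Cer) = K exactly via a reaction-extent quadratic and serves as
an independent oracle for the integrated steady state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .network import (
    LIPIDS,
    SPECIES,
    NetworkModel,
    RateConstants,
    SpeciesState,
    ValidationError,
    rhs_array,
)

__all__ = [
    "TimeCourse",
    "EquilibriumResult",
    "IntegrationError",
    "ConservationError",
    "simulate",
    "steady_state",
    "equilibrium_closed_form",
    "equilibrium_full_network",
    "mass_action_ratio",
]


class IntegrationError(RuntimeError):
    """The ODE solver failed; carries the last accepted time."""

    def __init__(self, message: str, last_time: float):
        super().__init__(message)
        self.last_time = last_time


class ConservationError(RuntimeError):
    """A conserved-moiety sum drifted beyond tolerance; names the moiety."""


@dataclass
class TimeCourse:
    """Sampled trajectory of the six species.

    ``states`` has one row per time point, columns in SPECIES order
    (pc, cer, dag, sm, e, ep).
    """

    times: np.ndarray
    states: np.ndarray
    rc: RateConstants
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.times.ndim != 1 or self.states.shape != (self.times.size, len(SPECIES)):
            raise ValidationError("states must be (n_times, 6) matching times")
        if self.times.size and (self.times[0] != 0 or np.any(np.diff(self.times) <= 0)):
            raise ValidationError("times must start at 0 and be strictly increasing")

    def state_at(self, i: int) -> SpeciesState:
        return SpeciesState.from_array(self.states[i])

    def column(self, name: str) -> np.ndarray:
        return self.states[:, SPECIES.index(name)]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(SPECIES))
        df.insert(0, "time", self.times)
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, rc: RateConstants | None = None) -> "TimeCourse":
        """Read a time-course CSV; enzyme columns are optional (filled with 0)."""
        df = pd.read_csv(path)
        if "time" not in df.columns:
            raise ValidationError("time-course CSV must have a 'time' column")
        missing_lipids = [c for c in LIPIDS if c not in df.columns]
        if missing_lipids:
            raise ValidationError(f"time-course CSV missing lipid columns: {missing_lipids}")
        states = np.zeros((len(df), len(SPECIES)))
        for j, name in enumerate(SPECIES):
            if name in df.columns:
                states[:, j] = df[name].to_numpy(dtype=float)
        rc = rc if rc is not None else RateConstants(1.0, 1.0, 1.0, 1.0)
        return cls(times=df["time"].to_numpy(dtype=float), states=states, rc=rc,
                   meta={"source": str(path)})


@dataclass
class EquilibriumResult:
    """Steady state of the network with convergence diagnostics."""

    state: SpeciesState
    mass_action_ratio: float
    residual: float
    converged: bool
    time_reached: float = float("nan")


def mass_action_ratio(state: SpeciesState) -> float:
    """[DAG][SM] / ([PC][Cer]); equals the overall K at equilibrium."""
    denom = state.pc * state.cer
    if denom == 0:
        return float("inf") if state.dag * state.sm > 0 else float("nan")
    return (state.dag * state.sm) / denom


def _check_conservation(net: NetworkModel, states: np.ndarray, rel_tol: float) -> None:
    index = {s: i for i, s in enumerate(SPECIES)}
    for members, total in net.conserved_moieties:
        sums = states[:, [index[m] for m in members]].sum(axis=1)
        scale = max(abs(total), 1.0)
        drift = np.max(np.abs(sums - total)) / scale
        if drift > rel_tol:
            raise ConservationError(
                f"moiety {'+'.join(members)} drifted by {drift:.3e} relative "
                f"(tolerance {rel_tol:.1e})"
            )


def _integrate(
    net: NetworkModel,
    times: np.ndarray,
    rtol: float,
    atol: float,
    method: str,
    conservation_tol: float,
) -> np.ndarray:
    y0 = net.initial_state.to_array()
    sol = solve_ivp(
        lambda t, y: rhs_array(y, net.rc),
        (times[0], times[-1]),
        y0,
        method=method,
        t_eval=times,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        last = sol.t[-1] if sol.t.size else times[0]
        raise IntegrationError(f"integrator failed: {sol.message}", last_time=last)
    states = sol.y.T
    _check_conservation(net, states, conservation_tol)
    return states


def simulate(
    net: NetworkModel,
    t_end: float,
    n_samples: int = 200,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "BDF",
    times: np.ndarray | None = None,
    conservation_tol: float = 1e-9,
) -> TimeCourse:
    """Integrate the network and sample the trajectory.

    Either ``t_end``/``n_samples`` (uniform grid from 0) or an explicit
    ``times`` grid (must start at 0, strictly increasing) selects the sample
    points.  Conservation of all moieties is verified to ``conservation_tol``
    relative after integration.
    """
    if times is None:
        if t_end <= 0:
            raise ValidationError(f"t_end must be > 0, got {t_end}")
        if n_samples < 2:
            raise ValidationError(f"n_samples must be >= 2, got {n_samples}")
        times = np.linspace(0.0, float(t_end), int(n_samples))
    else:
        times = np.asarray(times, dtype=float)
    states = _integrate(net, times, rtol, atol, method, conservation_tol)
    meta = {"method": method, "rtol": rtol, "atol": atol}
    return TimeCourse(times=times, states=states, rc=net.rc, meta=meta)


def steady_state(
    net: NetworkModel,
    tol: float = 1e-10,
    time_cap: float = 1e6,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "BDF",
) -> EquilibriumResult:
    """Drive the network to steady state by integrating expanding horizons.

    Converged means max |dy/dt| < ``tol`` at the reported state.  If the cap
    is reached first, the result is returned with ``converged=False`` and the
    best state found — never an invented one.
    """
    y = net.initial_state.to_array()
    residual = float(np.max(np.abs(rhs_array(y, net.rc))))
    t_now = 0.0
    horizon = 10.0
    while residual >= tol and t_now < time_cap:
        t_next = min(t_now + horizon, time_cap)
        sol = solve_ivp(
            lambda t, v: rhs_array(v, net.rc),
            (t_now, t_next),
            y,
            method=method,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise IntegrationError(f"integrator failed: {sol.message}", last_time=t_now)
        y = sol.y[:, -1]
        t_now = t_next
        horizon *= 10.0
        residual = float(np.max(np.abs(rhs_array(y, net.rc))))
    # tiny negatives from solver tolerance are zeroed before validation
    y = np.where((y < 0) & (y > -10 * atol), 0.0, y)
    state = SpeciesState.from_array(y)
    return EquilibriumResult(
        state=state,
        mass_action_ratio=mass_action_ratio(state),
        residual=residual,
        converged=residual < tol,
        time_reached=t_now,
    )


def equilibrium_closed_form(
    initial_lipids: tuple[float, float, float, float], K: float
) -> SpeciesState:
    """Exact lipid equilibrium under the two backbone conservation laws.

    With reaction extent xi: PC = PC0 - xi, Cer = Cer0 - xi, DAG = DAG0 + xi,
    SM = SM0 + xi, and (DAG*SM)/(PC*Cer) = K.  That is a quadratic in xi;
    the unique root keeping all species >= 0 is returned.  Enzyme fields of
    the returned state are 0 (the lipid equilibrium is independent of the
    enzyme pool).  Serves as the independent oracle for :func:`steady_state`.
    """
    if K <= 0 or not np.isfinite(K):
        raise ValidationError(f"K must be finite and > 0, got {K}")
    p0, c0, d0, s0 = (float(x) for x in initial_lipids)
    if min(p0, c0, d0, s0) < 0:
        raise ValidationError("initial lipid fractions must be >= 0")
    if (p0 == 0 or c0 == 0) and (d0 == 0 or s0 == 0):
        raise ValidationError(
            "no reacting pair: need pc*cer > 0 or dag*sm > 0 to define equilibrium"
        )

    # f(xi) = (d0+xi)(s0+xi) - K (p0-xi)(c0-xi), increasing on the admissible
    # interval [-min(d0,s0), min(p0,c0)] with a sign change across it
    a = 1.0 - K
    b = d0 + s0 + K * (p0 + c0)
    c = d0 * s0 - K * p0 * c0
    lo, hi = -min(d0, s0), min(p0, c0)
    if a == 0.0:
        xi = -c / b
    else:
        # b > 0 whenever any lipid is present; use the cancellation-free form
        disc = max(b * b - 4 * a * c, 0.0)
        q = -0.5 * (b + np.sqrt(disc))
        roots = [q / a, c / q] if q != 0 else [0.0]
        eps = 1e-12 * max(1.0, hi - lo)
        candidates = [r for r in roots if lo - eps <= r <= hi + eps]
        if not candidates:
            raise ValidationError("no admissible equilibrium extent found")
        xi = float(np.clip(candidates[0], lo, hi))
    return SpeciesState(
        pc=p0 - xi, cer=c0 - xi, dag=d0 + xi, sm=s0 + xi, e=0.0, ep=0.0
    )


def equilibrium_full_network(
    net: NetworkModel, n_scan: int = 4000
) -> SpeciesState:
    """Exact equilibrium of the full six-species network, without ODEs.

    At equilibrium both reactions obey detailed balance, which couples the
    two reaction extents xi1 (phosphorylation) and xi2 (transfer):

        ep/e = k1*pc / (k1r*dag)          (reaction 1)
        k2*cer*ep = k2r*e*sm              (reaction 2)
        ep  = ep0 + xi1 - xi2,  e = E_total - ep

    Eliminating ep via reaction 1 leaves a scalar root-finding problem in
    xi1, solved by bisection on a sign-change bracket.  This is the
    independent algebraic oracle for :func:`steady_state`; unlike the
    lipid-only closed form it accounts for phosphocholine heads sequestered
    on the phosphoenzyme, so it agrees with the ODE steady state for any
    enzyme pool size.
    """
    from scipy.optimize import brentq

    rc = net.rc
    st0 = net.initial_state
    p0, c0, d0, s0 = st0.pc, st0.cer, st0.dag, st0.sm
    ep0, E = st0.ep, st0.e + st0.ep
    if E == 0:
        return SpeciesState(p0, c0, d0, s0, 0.0, 0.0)

    def residual(xi1: float) -> float:
        pc, dag = p0 - xi1, d0 + xi1
        u = (rc.k1 * pc) / (rc.k1r * dag)  # ep/e from reaction-1 balance
        ep = E * u / (1.0 + u)
        e = E - ep
        xi2 = xi1 - (ep - ep0)
        cer, sm = c0 - xi2, s0 + xi2
        return rc.k2 * cer * ep - rc.k2r * e * sm

    # admissible xi1 keeps pc, dag, cer, sm >= 0
    eps = 1e-12 * max(p0 + d0, 1.0)
    lo_limit, hi_limit = -d0 + eps, p0 - eps
    grid = np.linspace(lo_limit, hi_limit, n_scan)
    valid = []
    for x in grid:
        ep = E * ((rc.k1 * (p0 - x)) / (rc.k1r * (d0 + x)))
        ep = ep / (1.0 + ep / E) if E else 0.0
        xi2 = x - (ep - ep0)
        if -s0 <= xi2 <= c0:
            valid.append(x)
    if len(valid) < 2:
        raise ValidationError("no admissible equilibrium bracket found")
    vals = [(x, residual(x)) for x in valid]
    bracket = None
    for (x1, f1), (x2, f2) in zip(vals[:-1], vals[1:]):
        if f1 == 0:
            bracket = (x1, x1)
            break
        if f1 * f2 < 0:
            bracket = (x1, x2)
            break
    if bracket is None:
        raise ValidationError("no detailed-balance root found on the admissible range")
    xi1 = bracket[0] if bracket[0] == bracket[1] else brentq(
        residual, *bracket, xtol=1e-14, rtol=1e-15
    )
    pc, dag = p0 - xi1, d0 + xi1
    u = (rc.k1 * pc) / (rc.k1r * dag)
    ep = E * u / (1.0 + u)
    xi2 = xi1 - (ep - ep0)
    return SpeciesState(
        pc=pc, cer=c0 - xi2, dag=dag, sm=s0 + xi2, e=E - ep, ep=ep
    )
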