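"""Scenario comparisons: baseline vs rate-perturbed SMS networks.

The motivating experiment models 2R-hydroxylated ceramide, which binds the
phosphoenzyme more productively than wild-type ceramide, as an increase in
the transfer rate constant k2 (default factor 2).  Comparing the baseline
and perturbed steady states shows the activator-like effect: SM and DAG rise,
PC and Cer fall, while both backbone conservation laws pin the deltas to be
equal and opposite within each pair.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .network import LIPIDS, RateConstants, SpeciesState, ValidationError, build_sms_network
from .simulate import EquilibriumResult, TimeCourse, simulate, steady_state
from .thermo import K_from_rates

__all__ = [
    "Scenario",
    "ComparisonReport",
    "perturbed_rates",
    "compare_scenarios",
    "paired_timecourses",
    "plot_comparison",
]


@dataclass(frozen=True)
class Scenario:
    """A named (rate constants, initial state) bundle."""

    label: str
    rc: RateConstants
    initial: SpeciesState
    notes: str = ""

    def __post_init__(self) -> None:
        if not self.label:
            raise ValidationError("scenario label must be non-empty")

    def network(self):
        return build_sms_network(
            self.rc,
            (self.initial.pc, self.initial.cer, self.initial.dag, self.initial.sm),
            enzyme_total=self.initial.e + self.initial.ep,
        )


@dataclass
class ComparisonReport:
    """Steady-state comparison of two scenarios."""

    baseline: EquilibriumResult
    perturbed: EquilibriumResult
    deltas: dict[str, float] | None
    direction_summary: dict[str, str] | None
    K_baseline: float
    K_perturbed: float
    converged: bool
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def _eq(r: EquilibriumResult) -> dict:
            return {
                "state": {n: getattr(r.state, n) for n in ("pc", "cer", "dag", "sm", "e", "ep")},
                "mass_action_ratio": r.mass_action_ratio,
                "residual": r.residual,
                "converged": r.converged,
            }

        return {
            "baseline": _eq(self.baseline),
            "perturbed": _eq(self.perturbed),
            "deltas": self.deltas,
            "direction_summary": self.direction_summary,
            "K_baseline": self.K_baseline,
            "K_perturbed": self.K_perturbed,
            "converged": self.converged,
            "meta": self.meta,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def perturbed_rates(
    rc: RateConstants, target: str = "k2", factor: float = 2.0
) -> RateConstants:
    """Scale one named rate constant by ``factor`` (default: double k2)."""
    if target not in ("k1", "k1r", "k2", "k2r"):
        raise ValidationError(f"target must name one of k1/k1r/k2/k2r, got {target!r}")
    if factor <= 0:
        raise ValidationError(f"factor must be > 0, got {factor}")
    return rc.replace(**{target: getattr(rc, target) * factor})


def _sign_label(x: float, tol: float = 1e-6) -> str:
    if x > tol:
        return "increase"
    if x < -tol:
        return "decrease"
    return "unchanged"


def compare_scenarios(
    base: Scenario, alt: Scenario, tol: float = 1e-10, time_cap: float = 1e6
) -> ComparisonReport:
    """Drive both scenarios to steady state and report per-lipid shifts.

    Deltas are perturbed minus baseline in % mol/mol.  If either scenario
    fails to converge the report is flagged and deltas are withheld.
    """
    base_totals = (base.initial.pc + base.initial.dag, base.initial.cer + base.initial.sm)
    alt_totals = (alt.initial.pc + alt.initial.dag, alt.initial.cer + alt.initial.sm)
    if not np.allclose(base_totals, alt_totals):
        raise ValidationError(
            f"scenarios must share lipid backbone totals; got {base_totals} vs {alt_totals}"
        )

    eq_base = steady_state(base.network(), tol=tol, time_cap=time_cap)
    eq_alt = steady_state(alt.network(), tol=tol, time_cap=time_cap)
    converged = eq_base.converged and eq_alt.converged

    deltas = direction = None
    if converged:
        deltas = {
            n: getattr(eq_alt.state, n) - getattr(eq_base.state, n) for n in LIPIDS
        }
        direction = {n: _sign_label(d) for n, d in deltas.items()}

    return ComparisonReport(
        baseline=eq_base,
        perturbed=eq_alt,
        deltas=deltas,
        direction_summary=direction,
        K_baseline=K_from_rates(base.rc),
        K_perturbed=K_from_rates(alt.rc),
        converged=converged,
        meta={
            "baseline_label": base.label,
            "perturbed_label": alt.label,
            "line_style": {"baseline": "solid", "perturbed": "dashed"},
        },
    )


def paired_timecourses(
    base: Scenario, alt: Scenario, t_end: float = 50.0, n_samples: int = 200
) -> tuple[TimeCourse, TimeCourse]:
    """Transient trajectories of both scenarios on a shared time grid."""
    return (
        simulate(base.network(), t_end=t_end, n_samples=n_samples),
        simulate(alt.network(), t_end=t_end, n_samples=n_samples),
    )


def plot_comparison(tc_base: TimeCourse, tc_alt: TimeCourse, path) -> None:
    """Plot paired lipid time courses (baseline solid, perturbed dashed)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    colors = dict(zip(LIPIDS, ("C0", "C1", "C2", "C3")))
    for name in LIPIDS:
        ax.plot(tc_base.times, tc_base.column(name), "-", color=colors[name],
                label=f"{name.upper()} (baseline)")
        ax.plot(tc_alt.times, tc_alt.column(name), "--", color=colors[name],
                label=f"{name.upper()} (perturbed)")
    ax.set_xlabel("time (arbitrary units)")
    ax.set_ylabel("species amount (% mol/mol)")
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
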