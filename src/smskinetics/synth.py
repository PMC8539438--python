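"""Synthetic-data generation: noisy time courses and binding-energy tables.

Everything downstream (estimation benchmarks, thermodynamic profiling) can be
exercised without any external data.  Two generators:

* :func:`generate_timecourses` — integrates the SMS network from known rate
  constants and adds i.i.d. Gaussian observation noise to each sampled value
  (additive, in % mol/mol units, optionally truncated at zero).  The truth
  and seed are embedded in each series' metadata for recovery tests.
* :func:`generate_binding_table` — emits a wild-type membrane binding table
  whose pair sums reproduce the reference profile (reactants -21.7, products
  -26.6 kcal/mol, ddG -4.9), plus hydroxylated-ceramide variant rows whose
  ceramide energy is shifted so the variant ddG moves toward products by a
  uniform draw in a configurable range (default 0.6-0.9 kcal/mol).

All stochastic entry points require a seed; identical seed and parameters
give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .network import RateConstants, ValidationError, build_sms_network
from .simulate import TimeCourse, simulate
from .thermo import BindingEnergyRecord

__all__ = [
    "NoiseModel",
    "DEFAULT_WT_TABLE",
    "generate_timecourses",
    "generate_binding_table",
]


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian observation noise on sampled fractions.

    ``sigma`` is the standard deviation in % mol/mol units; ``truncate_at_zero``
    clips negative noisy observations to 0 (fractions cannot be negative).
    """

    sigma: float = 0.0
    seed: int = 0
    truncate_at_zero: bool = True

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValidationError(f"sigma must be >= 0, got {self.sigma}")


#: Synthetic wild-type membrane binding table.  Only the pair sums (-21.7 for
#: PC+Cer, -26.6 for DAG+SM, kcal/mol) are externally constrained; the
#: per-species split is an even partition of each sum, chosen here because no
#: per-species decomposition is available.
DEFAULT_WT_TABLE: tuple[BindingEnergyRecord, ...] = (
    BindingEnergyRecord("PC", "WT", "membrane", -10.85),
    BindingEnergyRecord("Cer", "WT", "membrane", -10.85),
    BindingEnergyRecord("DAG", "WT", "membrane", -13.30),
    BindingEnergyRecord("SM", "WT", "membrane", -13.30),
)


def generate_timecourses(
    truth: RateConstants,
    initial_sets: Sequence[tuple[float, float, float, float]],
    enzyme_total: float = 1.0,
    times: np.ndarray | None = None,
    noise: NoiseModel = NoiseModel(),
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> list[TimeCourse]:
    """Simulate one noisy series per initial lipid composition.

    Noise is added to every sampled species value (lipids and enzyme alike);
    with ``sigma=0`` the output is exactly the deterministic trajectory.
    """
    if not isinstance(truth, RateConstants):
        truth = RateConstants(*truth)
    if len(initial_sets) == 0:
        raise ValidationError("initial_sets must contain at least one composition")
    if times is None:
        times = np.linspace(0.0, 50.0, 26)
    times = np.asarray(times, dtype=float)

    rng = np.random.default_rng(noise.seed)
    courses: list[TimeCourse] = []
    for i, lipids in enumerate(initial_sets):
        net = build_sms_network(truth, lipids, enzyme_total)
        tc = simulate(net, t_end=times[-1], times=times, rtol=rtol, atol=atol)
        states = tc.states.copy()
        if noise.sigma > 0:
            states = states + rng.normal(0.0, noise.sigma, size=states.shape)
            if noise.truncate_at_zero:
                states = np.clip(states, 0.0, None)
        courses.append(
            TimeCourse(
                times=times,
                states=states,
                rc=truth,
                meta={
                    "truth": truth.as_tuple(),
                    "enzyme_total": enzyme_total,
                    "sigma": noise.sigma,
                    "seed": noise.seed,
                    "series_index": i,
                    "initial_lipids": tuple(float(x) for x in lipids),
                },
            )
        )
    return courses


def generate_binding_table(
    base: Sequence[BindingEnergyRecord] = DEFAULT_WT_TABLE,
    hydroxyl_shift_range: tuple[float, float] = (0.6, 0.9),
    variants: Sequence[str] = ("2R-OH", "2S-OH"),
    seed: int = 0,
) -> list[BindingEnergyRecord]:
    """Wild-type table plus hydroxylated-ceramide variant rows.

    For each variant, the ceramide binding energy is raised (made less
    negative) by a uniform draw in ``hydroxyl_shift_range`` so that the
    variant reaction ddG = (DAG+SM) - (PC+Cer_variant) moves toward products
    by exactly that amount relative to wild type.
    """
    lo, hi = hydroxyl_shift_range
    if lo > hi:
        raise ValidationError(f"shift range low {lo} exceeds high {hi}")
    by_species = {r.species_id: r for r in base if r.variant == "WT"}
    missing = {"PC", "Cer", "DAG", "SM"} - set(by_species)
    if missing:
        raise ValidationError(f"base table missing WT species: {sorted(missing)}")

    rng = np.random.default_rng(seed)
    records = list(base)
    wt_cer = by_species["Cer"]
    for variant in variants:
        shift = float(rng.uniform(lo, hi))
        records.append(
            BindingEnergyRecord(
                species_id="Cer",
                variant=variant,
                context=wt_cer.context,
                dG=wt_cer.dG + shift,
            )
        )
    return records
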