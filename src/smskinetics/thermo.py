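"""Free-energy bookkeeping for the SMS reaction cycle.

Links membrane binding free energies to equilibrium constants:

* pair-sum bookkeeping — the reaction PC + Cer -> DAG + SM is scored by the
  difference between the summed binding free energies of the product pair and
  the reactant pair, ddG = (dG_DAG + dG_SM) - (dG_PC + dG_Cer);
* the thermodynamic link K = exp(-ddG / RT);
* the overall kinetic equilibrium constant from the stepwise constants,
  K = (k1/k1r) * (k2/k2r);
* the literal min-rule heuristic kon = min{k_i}, koff = min{k_-i}, kept as a
  separately reported quantity because it does NOT equal the stepwise-product
  K in general (on the default constants it gives 0.5 vs 0.35).

Binding-energy tables are exchanged as CSV with columns
``species_id, variant, context, dG_kcal_mol``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .network import RateConstants, ValidationError

__all__ = [
    "R_KCAL_PER_MOL_K",
    "VARIANTS",
    "CONTEXTS",
    "REFERENCE_ENERGIES",
    "ThermoConfig",
    "BindingEnergyRecord",
    "ProfileResult",
    "pair_ddG",
    "K_from_rates",
    "kon_koff_min_rule",
    "rates_from_K",
    "ddG_to_K",
    "K_to_ddG",
    "read_binding_table",
    "write_binding_table",
]

#: gas constant in kcal mol^-1 K^-1
R_KCAL_PER_MOL_K = 1.98720425864e-3

#: closed vocabulary of hydroxylation variants (wild type, 2-hydroxy R/S)
VARIANTS = ("WT", "2R-OH", "2S-OH")
#: closed vocabulary of binding contexts
CONTEXTS = ("membrane", "SMS1", "SMS2", "SMS1-P", "SMS2-P")

#: Reference free energies (kcal/mol) from docking/metadynamics studies of the
#: SMS system.  These are tabulated external inputs carried for reporting;
#: nothing in this package recomputes them.
REFERENCE_ENERGIES: dict[str, float] = {
    # membrane pair sums for wild-type lipids
    "membrane_pair_sum_PC_Cer": -21.7,
    "membrane_pair_sum_DAG_SM": -26.6,
    "membrane_ddG_WT": -4.9,
    # hydroxylated-ceramide reaction ddG on the SMS1 isoform
    "SMS1_ddG_2R_OH_Cer": -4.0,
    "SMS1_ddG_2S_OH_Cer": -4.2,
    # metadynamics binding minima of the phosphoenzyme with (hydroxy)ceramide
    "SMS1P_Cer_minimum": -9.33,
    "SMS2P_2ROHCer_minimum": -9.52,
}


@dataclass(frozen=True)
class ThermoConfig:
    """Temperature and gas constant used by the ddG <-> K conversion.

    Default 298 K; kept configurable because different simulation protocols
    for this system were thermostatted at 298 K and 300 K.
    """

    temperature: float = 298.0
    gas_constant: float = R_KCAL_PER_MOL_K

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValidationError(f"temperature must be > 0 K, got {self.temperature}")

    @property
    def RT(self) -> float:
        return self.gas_constant * self.temperature


@dataclass(frozen=True)
class BindingEnergyRecord:
    """Binding free energy of one lipid species in one environment."""

    species_id: str
    variant: str
    context: str
    dG: float

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValidationError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        if self.context not in CONTEXTS:
            raise ValidationError(f"unknown context {self.context!r}; expected one of {CONTEXTS}")
        if not math.isfinite(self.dG):
            raise ValidationError(f"dG must be finite, got {self.dG!r}")


@dataclass(frozen=True)
class ProfileResult:
    """Pair-sum free-energy profile of the overall reaction."""

    reactant_sum: float
    product_sum: float
    ddG: float
    K_thermo: float
    context_mismatch: bool = False


def pair_ddG(
    reactant_records: Sequence[BindingEnergyRecord],
    product_records: Sequence[BindingEnergyRecord],
    cfg: ThermoConfig = ThermoConfig(),
) -> ProfileResult:
    """Free-energy difference between the product pair and the reactant pair.

    ddG = sum(product dG) - sum(reactant dG); negative values favour products.
    Mixing binding contexts (membrane vs enzyme) across the four records is
    flagged in the result but is not an error — comparing membrane and
    receptor-bound energies is legitimate bookkeeping for this cycle.
    """
    if len(reactant_records) != 2 or len(product_records) != 2:
        raise ValidationError("pair_ddG expects exactly two records per side")
    reactant_sum = sum(r.dG for r in reactant_records)
    product_sum = sum(r.dG for r in product_records)
    ddG = product_sum - reactant_sum
    contexts = {r.context for r in (*reactant_records, *product_records)}
    return ProfileResult(
        reactant_sum=reactant_sum,
        product_sum=product_sum,
        ddG=ddG,
        K_thermo=ddG_to_K(ddG, cfg),
        context_mismatch=len(contexts) > 1,
    )


def ddG_to_K(ddG: float, cfg: ThermoConfig = ThermoConfig()) -> float:
    """Equilibrium constant implied by a free-energy difference: exp(-ddG/RT)."""
    return math.exp(-ddG / cfg.RT)


def K_to_ddG(K: float, cfg: ThermoConfig = ThermoConfig()) -> float:
    """Inverse of :func:`ddG_to_K`: ddG = -RT ln K."""
    if K <= 0:
        raise ValidationError(f"K must be > 0, got {K}")
    return -cfg.RT * math.log(K)


def K_from_rates(rc: RateConstants) -> float:
    """Overall equilibrium constant of the two-stage cycle, (k1/k1r)*(k2/k2r).

    Full precision is retained; rounding for display is the caller's concern.
    RateConstants construction already rejects zero reverse constants.
    """
    if not isinstance(rc, RateConstants):
        rc = RateConstants(*rc)
    return rc.K


def kon_koff_min_rule(
    forward_constants: Iterable[float], reverse_constants: Iterable[float]
) -> tuple[float, float]:
    """Overall on/off constants by the slowest-step heuristic.

    Returns (min of forward constants, min of reverse constants).  This is a
    literal rate-limiting-step heuristic: in general kon/koff does NOT equal
    the stepwise-product equilibrium constant of :func:`K_from_rates` (for
    the default SMS constants the heuristic gives 0.1/0.2 = 0.5 while the
    stepwise product is 0.35), so the two are always reported separately.
    """
    forwards = list(forward_constants)
    reverses = list(reverse_constants)
    if not forwards or not reverses:
        raise ValidationError("forward and reverse constant lists must be non-empty")
    for k in (*forwards, *reverses):
        if k <= 0:
            raise ValidationError(f"rate constants must be > 0, got {k}")
    return (min(forwards), min(reverses))


def rates_from_K(
    target_K: float, template: RateConstants, adjust: str = "k2"
) -> RateConstants:
    """Rescale one stepwise constant so the overall K hits ``target_K``.

    The mapping from equilibrium energetics to four stepwise constants is
    under-determined; this implements the minimal change — a single named
    constant (``k1``, ``k1r``, ``k2`` or ``k2r``) is rescaled, the other
    three are kept — and makes no claim beyond that.
    """
    if target_K <= 0:
        raise ValidationError(f"target_K must be > 0, got {target_K}")
    if adjust not in ("k1", "k1r", "k2", "k2r"):
        raise ValidationError(f"adjust must name one of k1/k1r/k2/k2r, got {adjust!r}")
    ratio = target_K / template.K
    current = getattr(template, adjust)
    # forward constants scale with K, reverse constants against it
    new_value = current * ratio if adjust in ("k1", "k2") else current / ratio
    return template.replace(**{adjust: new_value})


_TABLE_COLUMNS = ["species_id", "variant", "context", "dG_kcal_mol"]


def write_binding_table(records: Iterable[BindingEnergyRecord], path) -> None:
    """Write binding-energy records as CSV."""
    df = pd.DataFrame(
        [(r.species_id, r.variant, r.context, r.dG) for r in records],
        columns=_TABLE_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_binding_table(path) -> list[BindingEnergyRecord]:
    """Read binding-energy records from CSV (validates vocabularies)."""
    df = pd.read_csv(path)
    missing = set(_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"binding table missing columns: {sorted(missing)}")
    return [
        BindingEnergyRecord(
            species_id=str(row.species_id),
            variant=str(row.variant),
            context=str(row.context),
            dG=float(row.dG_kcal_mol),
        )
        for row in df.itertuples()
    ]
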