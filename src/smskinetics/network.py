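"""Reaction network for the sphingomyelin synthase (SMS) cycle.

SMS transfers the phosphocholine head group of phosphatidylcholine (PC) onto
ceramide (Cer), producing diacylglycerol (DAG) and sphingomyelin (SM).  The
mechanism is ping-pong (double displacement): the head group is first parked
on a catalytic tyrosine, giving a phosphoenzyme intermediate (EP), before the
second substrate binds.  The network therefore has two reversible elementary
reactions over six species:

    PC + E   <-> EP + DAG        (k1 forward, k1r reverse)
    Cer + EP <-> E  + SM         (k2 forward, k2r reverse)

Lipids are tracked as mole fractions of the lipid pool (% mol/mol); the
enzyme states E (free) and EP (phosphorylated) live on their own scale,
normalised to the total enzyme amount, and are excluded from the 100% lipid
budget.  All rate laws are elementary mass action.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SPECIES",
    "LIPIDS",
    "RateConstants",
    "SpeciesState",
    "Reaction",
    "NetworkModel",
    "build_sms_network",
    "mass_action_rhs",
    "rhs_array",
]

#: canonical species ordering used by every array in the package
SPECIES = ("pc", "cer", "dag", "sm", "e", "ep")
#: the four lipid species (the % mol/mol pool)
LIPIDS = ("pc", "cer", "dag", "sm")


class ValidationError(ValueError):
    """Raised when a model object violates its declared invariants."""


@dataclass(frozen=True)
class RateConstants:
    """The four stepwise mass-action rate constants of the SMS cycle.

    Parameters
    ----------
    k1, k1r
        Forward / reverse constants of the phosphorylation half-reaction
        PC + E <-> EP + DAG (per-fraction per-time units).
    k2, k2r
        Forward / reverse constants of the transfer half-reaction
        Cer + EP <-> E + SM.
    """

    k1: float
    k1r: float
    k2: float
    k2r: float

    def __post_init__(self) -> None:
        for name in ("k1", "k1r", "k2", "k2r"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValidationError(
                    f"rate constant {name} must be finite and > 0, got {value!r}"
                )

    @property
    def K(self) -> float:
        """Overall equilibrium constant (k1/k1r)*(k2/k2r)."""
        return (self.k1 / self.k1r) * (self.k2 / self.k2r)

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.k1, self.k1r, self.k2, self.k2r)

    def replace(self, **changes: float) -> "RateConstants":
        return replace(self, **changes)


@dataclass
class SpeciesState:
    """Composition of the six network species at one instant.

    ``pc``/``cer``/``dag``/``sm`` are lipid mole fractions in % mol/mol;
    ``e``/``ep`` are the unphosphorylated and phosphorylated enzyme fractions
    on their own (total-enzyme) scale.
    """

    pc: float
    cer: float
    dag: float
    sm: float
    e: float
    ep: float

    def __post_init__(self) -> None:
        for name in SPECIES:
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise ValidationError(
                    f"species {name} must be finite and >= 0, got {value!r}"
                )

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in SPECIES], dtype=float)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "SpeciesState":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (len(SPECIES),):
            raise ValidationError(f"expected a length-{len(SPECIES)} vector")
        return cls(**dict(zip(SPECIES, arr)))

    @property
    def lipids(self) -> np.ndarray:
        """The (pc, cer, dag, sm) block as an array."""
        return np.array([self.pc, self.cer, self.dag, self.sm])

    def conserved_sums(self) -> dict[str, float]:
        """The four conserved-moiety totals implied by the stoichiometry."""
        return {
            "pc+dag": self.pc + self.dag,
            "cer+sm": self.cer + self.sm,
            "e+ep": self.e + self.ep,
            "pc+sm+ep": self.pc + self.sm + self.ep,
        }


@dataclass(frozen=True)
class Reaction:
    """One reversible mass-action reaction (all stoichiometries are 1)."""

    reactants: tuple[str, ...]
    products: tuple[str, ...]
    kf: float
    kr: float


@dataclass
class NetworkModel:
    """The six-species, two-reaction SMS network plus its conservation laws."""

    species: tuple[str, ...]
    reactions: list[Reaction]
    conserved_moieties: list[tuple[tuple[str, ...], float]]
    initial_state: SpeciesState
    rc: RateConstants
    meta: dict = field(default_factory=dict)

    def stoichiometry_matrix(self) -> np.ndarray:
        """Species x reactions stoichiometry matrix (net, forward direction)."""
        S = np.zeros((len(self.species), len(self.reactions)))
        index = {s: i for i, s in enumerate(self.species)}
        for j, rxn in enumerate(self.reactions):
            for s in rxn.reactants:
                S[index[s], j] -= 1
            for s in rxn.products:
                S[index[s], j] += 1
        return S


def build_sms_network(
    rc: RateConstants,
    initial_lipids: tuple[float, float, float, float] = (25.0, 25.0, 25.0, 25.0),
    enzyme_total: float = 1.0,
) -> NetworkModel:
    """Assemble the SMS ping-pong network.

    The enzyme starts fully unphosphorylated (e = ``enzyme_total``, ep = 0).
    ``initial_lipids`` is (pc, cer, dag, sm) in % mol/mol.

    Raises
    ------
    ValidationError
        If a rate constant is non-positive (the offending constant is named),
        an initial lipid fraction is negative, or ``enzyme_total`` <= 0.
    """
    if not isinstance(rc, RateConstants):
        rc = RateConstants(*rc)
    pc0, cer0, dag0, sm0 = (float(x) for x in initial_lipids)
    for name, value in zip(LIPIDS, (pc0, cer0, dag0, sm0)):
        if value < 0:
            raise ValidationError(f"initial fraction {name} must be >= 0, got {value}")
    if enzyme_total < 0:
        raise ValidationError(f"enzyme_total must be >= 0, got {enzyme_total}")

    state0 = SpeciesState(pc0, cer0, dag0, sm0, e=float(enzyme_total), ep=0.0)
    reactions = [
        Reaction(reactants=("pc", "e"), products=("ep", "dag"), kf=rc.k1, kr=rc.k1r),
        Reaction(reactants=("cer", "ep"), products=("e", "sm"), kf=rc.k2, kr=rc.k2r),
    ]
    moieties = [
        (("pc", "dag"), pc0 + dag0),
        (("cer", "sm"), cer0 + sm0),
        (("e", "ep"), float(enzyme_total)),
        (("pc", "sm", "ep"), pc0 + sm0 + 0.0),
    ]
    return NetworkModel(
        species=SPECIES,
        reactions=reactions,
        conserved_moieties=moieties,
        initial_state=state0,
        rc=rc,
    )


def rhs_array(y: np.ndarray, rc: RateConstants) -> np.ndarray:
    """Mass-action time derivative on a raw state vector (SPECIES order).

    Hot path for the ODE integrator; no validation.
    """
    pc, cer, dag, sm, e, ep = y
    v1 = rc.k1 * pc * e - rc.k1r * ep * dag
    v2 = rc.k2 * cer * ep - rc.k2r * e * sm
    return np.array([-v1, -v2, v1, v2, -(v1 - v2), v1 - v2])


def mass_action_rhs(state: SpeciesState, rc: RateConstants) -> SpeciesState:
    """Time derivative of every species under elementary mass action.

    Net fluxes: v1 = k1*pc*e - k1r*ep*dag (phosphorylation half-reaction),
    v2 = k2*cer*ep - k2r*e*sm (transfer half-reaction).  The returned object
    reuses the SpeciesState shape for its field names; derivatives may be
    negative, so invariant validation is bypassed.
    """
    dy = rhs_array(state.to_array(), rc)
    out = object.__new__(SpeciesState)
    for name, value in zip(SPECIES, dy):
        object.__setattr__(out, name, float(value))
    return out
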