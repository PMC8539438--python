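"""Run configuration with lossless YAML round-tripping."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .network import RateConstants, ValidationError

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Everything a reproducible run needs, in one flat record."""

    k1: float = 0.1
    k1r: float = 0.2
    k2: float = 1.0
    k2r: float = 1.43
    initial_lipids: tuple[float, float, float, float] = (25.0, 25.0, 25.0, 25.0)
    enzyme_total: float = 1.0
    rtol: float = 1e-8
    atol: float = 1e-10
    steady_state_tol: float = 1e-10
    t_end: float = 50.0
    n_samples: int = 200
    perturb_target: str = "k2"
    perturb_factor: float = 2.0
    temperature: float = 298.0
    outdir: str = "results"
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.initial_lipids = tuple(float(x) for x in self.initial_lipids)
        if len(self.initial_lipids) != 4:
            raise ValidationError("initial_lipids must have 4 entries (pc, cer, dag, sm)")

    @property
    def rc(self) -> RateConstants:
        return RateConstants(self.k1, self.k1r, self.k2, self.k2r)

    def to_yaml(self, path) -> None:
        payload = asdict(self)
        payload["initial_lipids"] = list(self.initial_lipids)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        unknown = set(payload) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)
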