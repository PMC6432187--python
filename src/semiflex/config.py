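"""Run configuration: TOML-backed, all defaults materialized.

A RunConfig is a flat record of everything a run needs -- model, system
size, ensemble, schedule, seeds, output prefix.  Writing a config always
materializes every field (provenance: the file accompanying an output
directory is complete), and configs round-trip through TOML losslessly.
"""

from __future__ import annotations

import tomllib
from dataclasses import asdict, dataclass, field, fields

from .models import ModelSpec, box_from_density

ENSEMBLES = ("canonical", "muca", "nve")


@dataclass
class RunConfig:
    # model
    model: str = "bead-stick"
    kappa: float = 0.0
    eps: float = 1.0
    # system
    N: int = 14
    M: int = 1
    rho: float = 0.0            # 0 -> no box; else cubic box from density
    # ensemble / schedule
    ensemble: str = "canonical"
    T: float = 1.0              # canonical production temperature
    t_min: float = 0.5          # temperature window for muca coverage
    t_max: float = 3.0
    e_total: float = 0.0        # nve ensemble: fixed total energy
    sweeps: int = 20_000
    discard: int = 2_000
    de: float = 0.5             # energy bin width
    sweeps_init: int = 5_000    # muca iteration schedule
    max_iter: int = 40
    walkers: int = 1
    seed: int = 1
    # output
    out: str = "run"

    def __post_init__(self) -> None:
        if self.ensemble not in ENSEMBLES:
            raise ValueError(f"ensemble must be one of {ENSEMBLES}")

    def model_spec(self) -> ModelSpec:
        return ModelSpec(model_kind=self.model, kappa=self.kappa,
                         eps=self.eps)

    @property
    def box(self) -> float | None:
        if self.rho <= 0:
            return None
        return box_from_density(self.N, self.M, self.rho)

    # -- TOML round trip ----------------------------------------------------

    def to_toml(self, path) -> None:
        with open(path, "w") as fh:
            for f in fields(self):
                v = getattr(self, f.name)
                if isinstance(v, str):
                    fh.write(f'{f.name} = "{v}"\n')
                elif isinstance(v, bool):
                    fh.write(f"{f.name} = {str(v).lower()}\n")
                elif isinstance(v, float):
                    fh.write(f"{f.name} = {v!r}\n")
                else:
                    fh.write(f"{f.name} = {v}\n")

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        # coerce ints given where floats are expected
        kwargs = {}
        for f in fields(cls):
            if f.name in data:
                v = data[f.name]
                if f.type in (float, "float") and isinstance(v, int):
                    v = float(v)
                kwargs[f.name] = v
        return cls(**kwargs)

    def asdict(self) -> dict:
        return asdict(self)
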