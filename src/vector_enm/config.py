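"""Run configuration: every tunable default of the pipeline in one place."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields


@dataclass
class RunConfig:
    """Resolved pipeline configuration.

    Unknown keys are rejected on load; the resolved config serialises to
    an identical object and hashes stably, so every run can be reproduced
    from its echoed configuration plus the inputs.
    """

    seed: int = 0
    min_species: int = 2              # distinct species a cell needs to qualify as well-surveyed
    background_n: int = 10000         # background cells to draw
    background_radius: float = 250.0  # map-unit buffer around qualifying cells
    grid_rm: tuple = (1, 2, 3, 4, 5)
    grid_fc: tuple = ("L", "LQ", "H", "LQH")
    n_hinge_knots: int = 32
    beta_anchors: tuple = ((10, 1.0), (30, 0.2), (100, 0.05))
    beta_hinge: float = 0.5
    beta_indicator: float = 0.25
    lambda_sd_floor: float = 0.01
    cum_threshold: float = 0.8        # cumulative-contribution cut (fraction of 100%)
    r_threshold: float = 0.7          # |Pearson r| filter
    n_null: int = 100
    n_permutations: int = 5
    boyce_windows: int = 101
    omission_rule: str = "mtp"
    k_folds: int = 4
    convergence_tol: float = 1e-7
    max_iter: int = 2000

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        for key in ("grid_rm", "grid_fc", "beta_anchors"):
            val = getattr(cfg, key)
            if isinstance(val, list):
                setattr(cfg, key, tuple(tuple(v) if isinstance(v, list) else v for v in val))
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid_rm"] = list(self.grid_rm)
        d["grid_fc"] = list(self.grid_fc)
        d["beta_anchors"] = [list(a) for a in self.beta_anchors]
        return d

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Read a YAML or JSON config file into a RunConfig."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)
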