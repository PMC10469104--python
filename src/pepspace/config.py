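"""Flat key-value run configuration shared by the CLI subcommands.

Every entry has a documented default; a config file (``key = value`` per
line, ``#`` comments) overrides the defaults and any CLI flag overrides
its config key.  ``pepspace config --dump`` prints the full table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

from .descriptors import DEFAULT_OPERATORS
from .scales import PROPERTY_SCALES


@dataclass
class RunConfig:
    # descriptors
    scales: str = ",".join(PROPERTY_SCALES)
    operators: str = ",".join(DEFAULT_OPERATORS)
    choquet_density_total: float = 0.9
    gowawa_lambda: float = 1.0
    gowawa_beta: float = 0.5
    # feature selection
    bins: int = 10
    entropy_cutoff: float = 0.3
    nmi_cutoff: float = 0.7
    # similarity / networks
    metric: str = "euclidean"
    conversion: str = "reciprocal"
    cutoff: float = 0.75
    # communities / centrality
    community_method: str = "louvain"
    centrality: str = "weighted_degree"
    # mQSSM
    fusion: str = "MAX"
    similarity_kind: str = "local_identity"
    model_threshold: float = 0.5
    # misc
    seed: int = 0

    def __post_init__(self) -> None:
        for name, value, lo, hi in [
            ("cutoff", self.cutoff, 0.0, 1.0),
            ("entropy_cutoff", self.entropy_cutoff, 0.0, 1.0),
            ("nmi_cutoff", self.nmi_cutoff, 0.0, 1.0),
            ("model_threshold", self.model_threshold, 0.0, 1.0),
            ("gowawa_beta", self.gowawa_beta, 0.0, 1.0),
        ]:
            if not lo <= value <= hi:
                raise ValueError(f"{name} must lie in [{lo}, {hi}], got {value}")

    def dump(self) -> str:
        lines = []
        for f in fields(self):
            lines.append(f"{f.name} = {getattr(self, f.name)}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        kv: dict[str, str] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected 'key = value'")
                key, _, value = line.partition("=")
                kv[key.strip()] = value.strip()
        return cls.from_mapping(kv)

    @classmethod
    def from_mapping(cls, kv: dict[str, str]) -> "RunConfig":
        typed: dict = {}
        known = {f.name: f.type for f in fields(cls)}
        casts = {"int": int, "float": float, "str": str}
        for key, value in kv.items():
            if key not in known:
                raise ValueError(f"unknown config key {key!r}")
            typed[key] = casts[known[key]](value)
        return cls(**typed)
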