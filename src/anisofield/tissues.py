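"""Tissue conductivity assignments: literature values and uncertainty ranges."""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import yaml

__all__ = ["ConductivityAssignment", "default_assignment"]


@dataclass
class ConductivityAssignment:
    """Per-tissue isotropic conductivity (S/m) plus optional [low, high] bounds.

    The bounds are the supports of the independent uniform priors used by the
    polynomial-chaos uncertainty analysis and the box constraints of the
    conductivity fit.
    """

    iso: dict  # tissue name -> sigma_iso (S/m)
    bounds: dict = field(default_factory=dict)  # tissue name -> (low, high)

    def __post_init__(self):
        for name, (lo, hi) in self.bounds.items():
            if name not in self.iso:
                raise ValueError(f"bounds given for unknown tissue {name!r}")
            if not (0 < lo <= self.iso[name] <= hi):
                raise ValueError(
                    f"tissue {name!r}: need 0 < low <= iso <= high, "
                    f"got ({lo}, {self.iso[name]}, {hi})"
                )

    def sigma(self, name: str) -> float:
        return self.iso[name]

    @classmethod
    def from_yaml(cls, path) -> "ConductivityAssignment":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            iso=dict(raw["conductivities"]),
            bounds={k: tuple(v) for k, v in raw.get("ranges", {}).items()},
        )


def default_assignment() -> ConductivityAssignment:
    """Packaged literature conductivities and uncertainty ranges."""
    ref = resources.files("anisofield").joinpath("data/tissues.yaml")
    raw = yaml.safe_load(ref.read_text())
    return ConductivityAssignment(
        iso=dict(raw["conductivities"]),
        bounds={k: tuple(v) for k, v in raw.get("ranges", {}).items()},
    )
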