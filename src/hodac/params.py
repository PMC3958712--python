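"""Model weights and solver controls.

The energy being minimised is

    E(u1, u2, phi) = ∫|∇phi|
        + ∫(alpha1|f-u1|^2 + beta1|∇u1| + gamma1|Δu1|) phi
        + ∫(alpha2|f-u2|^2 + beta2|∇u2| + gamma2|Δu2|) (1-phi)

over phi ∈ [0,1].  alpha* weight the data fidelity, beta* the total
variation of the region approximations, gamma* their Laplacian (the
higher-order diffusion term).  mu1/theta1 are the Bregman penalty weights
of the region subproblem, lam the penalty of the phi subproblem, dt the
semi-implicit step of the phi update, th the final binarisation threshold.

Defaults are engineering choices validated on the synthetic phantom suite;
they are exposed here and in the CLI config file.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace as _dc_replace
from typing import Mapping

__all__ = ["ModelParams"]

# config files may use the mathematical name "lambda"
_ALIASES = {"lambda": "lam"}

_PHI_SCHEMES = ("consistent", "literal")


@dataclass(frozen=True)
class ModelParams:
    alpha1: float = 4.0
    alpha2: float = 4.0
    beta1: float = 0.1
    beta2: float = 0.1
    gamma1: float = 0.05
    gamma2: float = 0.05
    mu1: float = 800.0
    theta1: float = 1.0
    lam: float = 0.1
    dt: float = 0.5
    th: float = 0.5
    n_outer: int = 150
    n_inner_region: int = 5
    n_inner_phi: int = 30
    tol: float = 1e-4
    phi_scheme: str = "consistent"

    def __post_init__(self):
        for name in ("alpha1", "alpha2", "mu1", "theta1", "lam", "dt"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be positive, got {v}")
        # beta/gamma may be zero: that is exactly the Chan-Vese reduction
        for name in ("beta1", "beta2", "gamma1", "gamma2", "tol"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        if not 0.0 < self.th < 1.0:
            raise ValueError(f"th must lie in (0, 1), got {self.th}")
        for name in ("n_outer", "n_inner_region", "n_inner_phi"):
            v = getattr(self, name)
            if not (isinstance(v, (int,)) and v >= 1):
                raise ValueError(f"{name} must be an integer >= 1, got {v!r}")
        if self.phi_scheme not in _PHI_SCHEMES:
            raise ValueError(f"phi_scheme must be one of {_PHI_SCHEMES}")

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "ModelParams":
        """Build from a flat key-value mapping (e.g. a parsed YAML config)."""
        kwargs = {}
        valid = set(cls.__dataclass_fields__)
        for key, value in mapping.items():
            key = _ALIASES.get(key, key)
            if key not in valid:
                raise ValueError(f"unknown parameter {key!r}")
            kwargs[key] = value
        return cls(**kwargs)

    def replace(self, **changes) -> "ModelParams":
        return _dc_replace(self, **changes)

    def to_dict(self) -> dict:
        return asdict(self)
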