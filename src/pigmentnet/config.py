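"""Residue-name sets and chain-role maps.

Ligand codes and chain labelling differ between deposits, so pigment
classification and subunit roles are driven by a small configuration
object rather than hard-coded tables.  Defaults cover the common case:
chlorophyll a is the wwPDB ligand ``CLA``; the carotenoid set starts
from beta-carotene (``BCR``) and is user-extendable (e.g. ``ZEX`` for
zeaxanthin-type codes).  Chain roles are resolved first through an
exact chain-id map, then through a prefix map — the latter is what the
synthetic generator's chain naming scheme uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .records import ISIA, OTHER

__all__ = ["NamingConfig"]

DEFAULT_CHLOROPHYLL = frozenset({"CLA"})
DEFAULT_CAROTENOID = frozenset({"BCR"})

#: prefix -> role convention emitted by the synthetic generator.
SYNTHETIC_PREFIX_ROLES = {
    "I": ISIA,
    "O": ISIA,
    "A": "PsaA",
    "B": "PsaB",
    "K": "PsaK",
    "C": "PsaC",
    "D": "PsaD",
    "E": "PsaE",
}


@dataclass
class NamingConfig:
    chlorophyll_residues: frozenset = DEFAULT_CHLOROPHYLL
    carotenoid_residues: frozenset = DEFAULT_CAROTENOID
    chain_roles: dict = field(default_factory=dict)      # exact chain id -> role
    prefix_roles: dict = field(default_factory=dict)     # chain id prefix -> role
    default_role: str = OTHER
    #: "error" (default) refuses chlorophylls missing NB/ND; "skip" drops
    #: them with a warning recorded in the parse report.
    on_missing_dipole: str = "error"
    #: chain id whose direction from the ring axis anchors ring index 1;
    #: None -> the first PsaK-role subunit (chain-id order), else first antenna.
    reference_chain: Optional[str] = None
    #: fallback sign for the membrane normal (+1/-1 along the raw principal
    #: axis) when no cytoplasmic marker subunit is present.
    cytoplasmic_sign: Optional[int] = None

    def __post_init__(self) -> None:
        self.chlorophyll_residues = frozenset(self.chlorophyll_residues)
        self.carotenoid_residues = frozenset(self.carotenoid_residues)
        overlap = self.chlorophyll_residues & self.carotenoid_residues
        if overlap:
            raise ValueError(f"residue codes in both classes: {sorted(overlap)}")
        if self.on_missing_dipole not in ("error", "skip"):
            raise ValueError("on_missing_dipole must be 'error' or 'skip'")

    @classmethod
    def synthetic(cls, **overrides) -> "NamingConfig":
        """Config matching the chain naming of the synthetic generator."""
        kw = dict(prefix_roles=dict(SYNTHETIC_PREFIX_ROLES))
        kw.update(overrides)
        return cls(**kw)

    def role_for(self, chain_id: str) -> str:
        if chain_id in self.chain_roles:
            return self.chain_roles[chain_id]
        for prefix, role in sorted(self.prefix_roles.items(),
                                   key=lambda kv: -len(kv[0])):
            if chain_id.startswith(prefix):
                return role
        return self.default_role

    def classify_residue(self, residue_name: str) -> Optional[str]:
        if residue_name in self.chlorophyll_residues:
            return "chlorophyll_a"
        if residue_name in self.carotenoid_residues:
            return "carotenoid"
        return None

    # -- serialization -------------------------------------------------
    @classmethod
    def from_yaml(cls, path) -> "NamingConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = {
            "chlorophyll_residues": sorted(self.chlorophyll_residues),
            "carotenoid_residues": sorted(self.carotenoid_residues),
            "chain_roles": dict(self.chain_roles),
            "prefix_roles": dict(self.prefix_roles),
            "default_role": self.default_role,
            "on_missing_dipole": self.on_missing_dipole,
            "reference_chain": self.reference_chain,
            "cytoplasmic_sign": self.cytoplasmic_sign,
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
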