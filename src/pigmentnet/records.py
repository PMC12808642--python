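"""Core record types shared across the pipeline.

The in-memory model of a pigment-protein complex is deliberately small:
protein chains are reduced to their C-alpha traces (enough for centroids
and rigid superposition), and each pigment cofactor is reduced to the
atoms that the downstream geometry and energy-transfer stages actually
consume — the central Mg and the NB/ND nitrogen pair that spans the
Qy transition-dipole axis of a chlorin, or a centroid for carotenoids.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "PigmentClass",
    "Ring",
    "AtomRecord",
    "PigmentRecord",
    "SubunitRecord",
    "ComplexModel",
]


class PigmentClass(str, enum.Enum):
    CHLOROPHYLL_A = "chlorophyll_a"
    CAROTENOID = "carotenoid"


class Ring(str, enum.Enum):
    INNER = "inner"
    OUTER = "outer"
    NONE = "none"


#: role string used for antenna protomers; core subunits carry their
#: canonical names ("PsaA" ... "PsaX") and everything else is "other".
ISIA = "isia"
OTHER = "other"


def is_core_role(role: str) -> bool:
    """True for PSI core subunit roles (PsaA...PsaX)."""
    return role.startswith("Psa")


@dataclass(frozen=True)
class AtomRecord:
    """A single atom kept from the deposited model (C-alpha traces)."""

    atom_name: str
    residue_name: str
    residue_number: int
    chain_id: str
    position: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(
                f"atom {self.atom_name} {self.chain_id}/{self.residue_number}: "
                "position must be a finite 3-vector"
            )
        if not self.atom_name:
            raise ValueError("atom_name must be non-empty")
        object.__setattr__(self, "position", pos)


@dataclass
class SubunitRecord:
    """One protein chain with its functional role and ring assignment.

    ``ring``/``ring_index`` are meaningful only for antenna (IsiA-type)
    subunits and are filled in by ring assignment; index numbering follows
    the anticlockwise-from-the-lumenal-side convention used for labelling
    antenna protomers (i-1..i-N on the inner ring, o-1..o-M on the outer).
    """

    chain_id: str
    role: str = OTHER
    ring: Ring = Ring.NONE
    ring_index: Optional[int] = None

    @property
    def is_antenna(self) -> bool:
        return self.role == ISIA

    @property
    def is_core(self) -> bool:
        return is_core_role(self.role)

    @property
    def label(self) -> str:
        if self.ring is Ring.INNER and self.ring_index is not None:
            return f"i-{self.ring_index}"
        if self.ring is Ring.OUTER and self.ring_index is not None:
            return f"o-{self.ring_index}"
        return self.chain_id


@dataclass
class PigmentRecord:
    """One pigment cofactor with its geometric handles.

    Chlorophylls carry ``mg``, ``nb`` and ``nd`` positions (Angstrom, as
    deposited); carotenoids carry a representative ``centroid`` instead.
    """

    pigment_id: tuple  # (chain_id, residue_number, residue_name)
    pigment_class: PigmentClass
    subunit: SubunitRecord
    mg: Optional[np.ndarray] = None
    nb: Optional[np.ndarray] = None
    nd: Optional[np.ndarray] = None
    centroid: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        for name in ("mg", "nb", "nd", "centroid"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=float))
        if self.pigment_class is PigmentClass.CHLOROPHYLL_A:
            if self.mg is None or self.nb is None or self.nd is None:
                raise ValueError(
                    f"chlorophyll {self.pigment_id}: Mg, NB and ND are all required"
                )
            if np.allclose(self.nb, self.nd):
                raise ValueError(
                    f"chlorophyll {self.pigment_id}: NB and ND coincide "
                    "(degenerate dipole axis)"
                )
        else:
            if self.centroid is None:
                raise ValueError(
                    f"carotenoid {self.pigment_id}: centroid position required"
                )

    @property
    def chain_id(self) -> str:
        return self.pigment_id[0]

    @property
    def residue_number(self) -> int:
        return self.pigment_id[1]

    @property
    def position(self) -> np.ndarray:
        """Representative position: Mg for chlorophylls, centroid otherwise."""
        return self.mg if self.mg is not None else self.centroid

    @property
    def is_chlorophyll(self) -> bool:
        return self.pigment_class is PigmentClass.CHLOROPHYLL_A

    @property
    def key(self) -> str:
        """Stable string id, e.g. ``I01/501`` — used as graph node id."""
        return f"{self.pigment_id[0]}/{self.pigment_id[1]}"


@dataclass
class ComplexModel:
    """A parsed pigment-protein complex.

    ``atoms`` holds the retained C-alpha records used for subunit
    centroids and rigid superposition; ``pigments`` reference entries of
    ``subunits`` so that ring/role annotations propagate automatically.
    """

    name: str
    subunits: list[SubunitRecord] = field(default_factory=list)
    pigments: list[PigmentRecord] = field(default_factory=list)
    atoms: list[AtomRecord] = field(default_factory=list)

    def validate(self) -> None:
        ids = [p.pigment_id for p in self.pigments]
        if len(ids) != len(set(ids)):
            raise ValueError(f"{self.name}: duplicate pigment ids")
        known = {id(s) for s in self.subunits}
        for p in self.pigments:
            if id(p.subunit) not in known:
                raise ValueError(
                    f"{self.name}: pigment {p.pigment_id} references an "
                    "unlisted subunit"
                )

    # -- lookups -------------------------------------------------------
    def subunit(self, chain_id: str) -> SubunitRecord:
        for s in self.subunits:
            if s.chain_id == chain_id:
                return s
        raise KeyError(f"{self.name}: no subunit with chain id {chain_id!r}")

    def chlorophylls(self, role: Optional[str] = None) -> list[PigmentRecord]:
        out = [p for p in self.pigments if p.is_chlorophyll]
        if role is not None:
            out = [p for p in out if p.subunit.role == role]
        return out

    def subunits_with_role(self, role: str) -> list[SubunitRecord]:
        return [s for s in self.subunits if s.role == role]

    def ca_positions(self, chain_id: str) -> np.ndarray:
        pos = [a.position for a in self.atoms
               if a.chain_id == chain_id and a.atom_name == "CA"]
        return np.array(pos, dtype=float).reshape(-1, 3)

    def subunit_centroid(self, chain_id: str) -> np.ndarray:
        """Mean C-alpha position; falls back to mean pigment position."""
        ca = self.ca_positions(chain_id)
        if len(ca) > 0:
            return ca.mean(axis=0)
        pig = [p.position for p in self.pigments if p.chain_id == chain_id]
        if not pig:
            raise ValueError(
                f"{self.name}: chain {chain_id} has neither C-alpha atoms "
                "nor pigments; cannot compute a centroid"
            )
        return np.mean(np.array(pig, dtype=float), axis=0)
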