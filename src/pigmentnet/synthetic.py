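"""Parametric pseudo-complexes with known ground truth.

The generator emulates the architecture of a double-ring antenna
supercomplex: one or three core moieties at the centre, surrounded by
two concentric rings (or arcs) of antenna protomers.  Each protomer is
a poly-alanine C-alpha trace carrying a fixed pigment complement —
chlorophylls as Mg/NB/ND pseudo-atom triplets laid out on a two-layer
(cytoplasmic/lumenal) ring-sector lattice, plus carotenoid place-holders.
An extrinsic marker pseudo-subunit (PsaC role) sits on the cytoplasmic
side so that the membrane-frame sign convention is recoverable, and a
PsaK pseudo-subunit marks the angular reference pole for ring indexing.

Everything downstream — sidedness labels, ring membership and indices,
interfacial pairs at any cutoff, dipole directions — is known by
construction and exposed as :class:`GroundTruth`, so the full pipeline
can be validated without any deposited structure.

Default counts follow the double-ring supercomplex: 18 inner + 25 outer
protomers of 17 chlorophylls each (11 cytoplasmic + 6 lumenal) and 4
carotenoids, i.e. 731 antenna chlorophylls of which 473 sit on the
cytoplasmic and 258 on the lumenal side.
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import gemmi
import numpy as np

from .records import (
    ISIA,
    AtomRecord,
    ComplexModel,
    PigmentClass,
    PigmentRecord,
    Ring,
    SubunitRecord,
)

__all__ = [
    "SyntheticComplexSpec",
    "GroundTruth",
    "generate_complex",
    "write_structure",
    "perturb_complex",
    "trimer_double_ring",
    "monomer_double_layer",
]

log = logging.getLogger(__name__)

#: total NB-ND span along the dipole axis, Angstrom (approximate span of
#: the chlorin NB-ND nitrogen pair; any positive value gives the same
#: unit dipole).
NB_ND_SPAN = 4.2

_CHL_FIRST_RESNUM = 501       # antenna chlorophylls: 501, 502, ...
_CAR_FIRST_RESNUM = 521       # carotenoids: 521...
_CORE_CHL_FIRST_RESNUM = 1101


@dataclass(frozen=True)
class SyntheticComplexSpec:
    """Full parameterization of one generated pseudo-complex."""

    name: str = "synthetic"
    inner_count: int = 18
    outer_count: int = 25
    chl_per_subunit: int = 17
    carotenoids_per_subunit: int = 4
    inner_radius: float = 110.0
    outer_radius: float = 150.0
    #: signed heights of the two chlorophyll layers along the membrane
    #: normal: (cytoplasmic, lumenal), Angstrom.
    layer_offsets: tuple = (14.0, -14.0)
    #: chlorophylls per layer, (cytoplasmic, lumenal); must sum to
    #: chl_per_subunit.
    layer_allocation: tuple = (11, 6)
    #: angular spacing between protomers, degrees; None = 360/count
    #: (closed ring).  Set explicitly for open arcs.
    inner_spacing_deg: Optional[float] = None
    outer_spacing_deg: Optional[float] = None
    #: reference pole angle (deg): protomer #1 of each ring and the PsaK
    #: marker sit here; successive indices run anticlockwise as seen
    #: from the lumenal side.
    reference_angle_deg: float = 90.0
    #: "tangential" | "radial" | "random" Qy dipole orientations.
    dipole_rule: str = "tangential"
    chl_radial_extent: float = 12.0
    chl_tangential_spacing: float = 7.0
    core_count: int = 3
    core_ring_radius: float = 60.0
    core_chl_per_core: int = 20
    coordinate_noise_sd: float = 0.0
    seed: int = 0
    #: number of planted close, optimally oriented inner<->outer pairs
    #: with strictly decreasing rate (for network ranking tests).
    plant_close_pairs: int = 0

    def validate(self) -> None:
        errors = []
        for f in ("inner_count", "outer_count", "chl_per_subunit",
                  "carotenoids_per_subunit", "core_count",
                  "core_chl_per_core", "plant_close_pairs"):
            if getattr(self, f) < 0:
                errors.append(f"{f} must be >= 0")
        if self.inner_radius >= self.outer_radius:
            errors.append("inner_radius must be < outer_radius")
        if sum(self.layer_allocation) != self.chl_per_subunit:
            errors.append(
                f"layer_allocation {self.layer_allocation} must sum to "
                f"chl_per_subunit={self.chl_per_subunit}")
        if not self.layer_offsets[0] > self.layer_offsets[1]:
            errors.append("layer_offsets must be (cytoplasmic, lumenal) "
                          "with cytoplasmic > lumenal")
        if self.dipole_rule not in ("tangential", "radial", "random"):
            errors.append(f"unknown dipole_rule {self.dipole_rule!r}")
        if self.coordinate_noise_sd < 0:
            errors.append("coordinate_noise_sd must be >= 0")
        if self.plant_close_pairs > min(self.inner_count, self.outer_count):
            errors.append("plant_close_pairs exceeds the protomer count")
        if errors:
            raise ValueError("invalid SyntheticComplexSpec: " + "; ".join(errors))


def trimer_double_ring(**overrides) -> SyntheticComplexSpec:
    """Closed double ring around a trimeric core (18 + 25 protomers)."""
    return replace(SyntheticComplexSpec(name="trimer-double-ring"), **overrides)


def monomer_double_layer(**overrides) -> SyntheticComplexSpec:
    """Open double layer on a monomeric core (6 + 7 protomers).

    Arc spacings match the closed-ring geometry so that the layer is a
    sector of the full double ring.
    """
    base = SyntheticComplexSpec(
        name="monomer-double-layer",
        inner_count=6, outer_count=7, core_count=1,
        inner_spacing_deg=20.0, outer_spacing_deg=14.4,
    )
    return replace(base, **overrides)


@dataclass
class GroundTruth:
    """What the generator knows by construction."""

    sidedness: dict = field(default_factory=dict)   # pigment_id -> side
    rings: dict = field(default_factory=dict)       # chain_id -> (ring, idx)
    normal: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    dipoles: dict = field(default_factory=dict)     # pigment_id -> unit vec
    #: planted inner<->outer pair ids, fastest first.
    planted_pairs: list = field(default_factory=list)
    _model: Optional[ComplexModel] = None

    def interfacial_pairs(self, cutoff: float) -> set:
        """Brute-force inter-subunit chlorophyll pairs within cutoff.

        Recomputed O(N^2) from the emitted coordinates, independent of
        the k-d-tree path used by the geometry stage.
        """
        chls = self._model.chlorophylls()
        out = set()
        for i in range(len(chls)):
            for j in range(i + 1, len(chls)):
                a, b = chls[i], chls[j]
                if a.subunit is b.subunit:
                    continue
                if np.linalg.norm(a.mg - b.mg) <= cutoff:
                    out.add(tuple(sorted((a.pigment_id, b.pigment_id))))
        return out


def _row_partition(n: int) -> list:
    """Split n chlorophylls over 3 radial rows, near-even, inner first."""
    base, rem = divmod(n, 3)
    return [base + (1 if i < rem else 0) for i in range(3)]


def _layer_sites(spec: SyntheticComplexSpec, n: int) -> list:
    """(radial_offset, tangential_offset) lattice for one layer."""
    rows = _row_partition(n)
    dr_values = (-spec.chl_radial_extent, 0.0, spec.chl_radial_extent)
    sites = []
    for dr, m in zip(dr_values, rows):
        for j in range(m):
            dt = (j - (m - 1) / 2.0) * spec.chl_tangential_spacing
            sites.append((dr, dt))
    return sites


def _frame_at(angle_deg: float) -> tuple[np.ndarray, np.ndarray]:
    th = math.radians(angle_deg)
    rho = np.array([math.cos(th), math.sin(th), 0.0])
    tau = np.array([-math.sin(th), math.cos(th), 0.0])
    return rho, tau


class _Builder:
    def __init__(self, spec: SyntheticComplexSpec):
        self.spec = spec
        self.model = ComplexModel(name=spec.name)
        self.truth = GroundTruth()
        self.rng = np.random.default_rng(spec.seed)
        # noise uses a stream independent of the dipole stream so that
        # zero-noise models are identical across noise settings
        self.noise_rng = np.random.default_rng((spec.seed, 1))

    def random_unit(self) -> np.ndarray:
        v = self.rng.normal(size=3)
        return v / np.linalg.norm(v)

    def noise(self) -> np.ndarray:
        if self.spec.coordinate_noise_sd == 0:
            return np.zeros(3)
        return self.noise_rng.normal(scale=self.spec.coordinate_noise_sd, size=3)

    def add_ca_trace(self, sub: SubunitRecord, center: np.ndarray,
                     n: int = 24, radius: float = 7.0,
                     z_amp: float = 3.0) -> None:
        for k in range(n):
            th = 2 * math.pi * k / n
            pos = center + np.array([
                radius * math.cos(th), radius * math.sin(th),
                z_amp * math.sin(2 * th),
            ]) + self.noise()
            self.model.atoms.append(AtomRecord(
                atom_name="CA", residue_name="ALA", residue_number=k + 1,
                chain_id=sub.chain_id, position=pos))

    def add_chlorophyll(self, sub: SubunitRecord, resnum: int,
                        mg: np.ndarray, dipole: np.ndarray,
                        side: str) -> PigmentRecord:
        u = dipole / np.linalg.norm(dipole)
        mg = mg + self.noise()
        nb = mg - u * (NB_ND_SPAN / 2) + self.noise()
        nd = mg + u * (NB_ND_SPAN / 2) + self.noise()
        pid = (sub.chain_id, resnum, "CLA")
        rec = PigmentRecord(pigment_id=pid,
                            pigment_class=PigmentClass.CHLOROPHYLL_A,
                            subunit=sub, mg=mg, nb=nb, nd=nd)
        self.model.pigments.append(rec)
        self.truth.sidedness[pid] = side
        self.truth.dipoles[pid] = u
        return rec

    def dipole_for(self, rho: np.ndarray, tau: np.ndarray) -> np.ndarray:
        rule = self.spec.dipole_rule
        if rule == "tangential":
            return tau
        if rule == "radial":
            return rho
        return self.random_unit()

    def add_antenna_subunit(self, chain_id: str, ring: Ring, index: int,
                            radius: float, angle_deg: float) -> None:
        spec = self.spec
        sub = SubunitRecord(chain_id=chain_id, role=ISIA)
        self.model.subunits.append(sub)
        self.truth.rings[chain_id] = (ring.value, index)
        rho, tau = _frame_at(angle_deg)
        center = radius * rho
        self.add_ca_trace(sub, center)
        resnum = _CHL_FIRST_RESNUM
        for layer, n_layer, side in zip(
                spec.layer_offsets, spec.layer_allocation,
                ("cytoplasmic", "lumenal")):
            for dr, dt in _layer_sites(spec, n_layer):
                mg = (radius + dr) * rho + dt * tau + np.array([0, 0, layer])
                self.add_chlorophyll(sub, resnum, mg,
                                     self.dipole_for(rho, tau), side)
                resnum += 1
        for k in range(spec.carotenoids_per_subunit):
            dr = -spec.chl_radial_extent - 2 if k % 2 == 0 else spec.chl_radial_extent + 2
            dt = 10.0 if k < 2 else -10.0
            cpos = (radius + dr) * rho + dt * tau
            pid = (chain_id, _CAR_FIRST_RESNUM + k, "BCR")
            self.model.pigments.append(PigmentRecord(
                pigment_id=pid, pigment_class=PigmentClass.CAROTENOID,
                subunit=sub, centroid=cpos + self.noise()))

    def add_core(self, core_index: int, angle_deg: float) -> None:
        spec = self.spec
        rho, _ = _frame_at(angle_deg)
        center = (spec.core_ring_radius * rho if spec.core_count > 1
                  else np.zeros(3))
        # reaction-centre subunit: a larger C-alpha blob + two chl layers
        psaa = SubunitRecord(chain_id=f"A{core_index}", role="PsaA")
        self.model.subunits.append(psaa)
        for k in range(30):
            th = 2 * math.pi * k / 30
            pos = center + np.array([
                10.0 * math.cos(th), 10.0 * math.sin(th),
                -10.0 + 20.0 * k / 29,
            ]) + self.noise()
            self.model.atoms.append(AtomRecord(
                atom_name="CA", residue_name="ALA", residue_number=k + 1,
                chain_id=psaa.chain_id, position=pos))
        n_core_chl = spec.core_chl_per_core
        per_layer = (n_core_chl + 1) // 2, n_core_chl // 2
        resnum = _CORE_CHL_FIRST_RESNUM
        for z, m, side in zip(spec.layer_offsets, per_layer,
                              ("cytoplasmic", "lumenal")):
            for k in range(m):
                th = 2 * math.pi * k / max(m, 1)
                mg = center + np.array([20.0 * math.cos(th),
                                        20.0 * math.sin(th), z])
                u = np.array([-math.sin(th), math.cos(th), 0.0])
                self.add_chlorophyll(psaa, resnum, mg, u, side)
                resnum += 1
        # pole subunit marking the angular reference for ring indexing
        psak = SubunitRecord(chain_id=f"K{core_index}", role="PsaK")
        self.model.subunits.append(psak)
        pole_rho, _ = _frame_at(angle_deg)
        pole = (spec.core_ring_radius + 25.0) * pole_rho if spec.core_count > 1 \
            else 25.0 * pole_rho
        self.add_ca_trace(psak, pole, n=8, radius=4.0, z_amp=2.0)
        # cytoplasmic extrinsic marker fixing the membrane-normal sign
        psac = SubunitRecord(chain_id=f"C{core_index}", role="PsaC")
        self.model.subunits.append(psac)
        self.add_ca_trace(psac, center + np.array([0, 0, 28.0]),
                          n=8, radius=4.0, z_amp=2.0)

    def plant_pairs(self) -> None:
        """Create optimally oriented inner<->outer pairs of known ranking.

        Pair k repositions one outer-protomer chlorophyll at a distance
        of (12 + k) Angstrom radially outward from a chosen inner-ring
        chlorophyll, with both dipoles collinear with the separation
        (kappa^2 = 4); increasing distance gives strictly decreasing
        rates, fastest first.
        """
        spec = self.spec
        for k in range(spec.plant_close_pairs):
            inner_chain = f"I{k + 1:02d}"
            outer_chain = f"O{k + 1:02d}"
            inner = [p for p in self.model.pigments
                     if p.chain_id == inner_chain and p.is_chlorophyll]
            outer = [p for p in self.model.pigments
                     if p.chain_id == outer_chain and p.is_chlorophyll]
            donor = max(inner, key=lambda p: float(np.linalg.norm(p.mg[:2])))
            accept = min(outer, key=lambda p: float(np.linalg.norm(p.mg[:2])))
            r_hat = np.array([*(donor.mg[:2] / np.linalg.norm(donor.mg[:2])), 0.0])
            accept.mg = donor.mg + (12.0 + k) * r_hat
            for p in (donor, accept):
                p.nb = p.mg - r_hat * (NB_ND_SPAN / 2)
                p.nd = p.mg + r_hat * (NB_ND_SPAN / 2)
                self.truth.dipoles[p.pigment_id] = r_hat
            self.truth.sidedness[accept.pigment_id] = \
                self.truth.sidedness[donor.pigment_id]
            self.truth.planted_pairs.append(
                (donor.pigment_id, accept.pigment_id))

    def build(self) -> tuple[ComplexModel, GroundTruth]:
        spec = self.spec
        inner_step = (spec.inner_spacing_deg if spec.inner_spacing_deg
                      is not None else 360.0 / max(spec.inner_count, 1))
        outer_step = (spec.outer_spacing_deg if spec.outer_spacing_deg
                      is not None else 360.0 / max(spec.outer_count, 1))
        for c in range(spec.core_count):
            self.add_core(c + 1, spec.reference_angle_deg + 360.0 * c / max(spec.core_count, 1))
        # index m sits at reference - (m-1)*step: decreasing plane angle
        # = increasing angle in the anticlockwise-from-lumen convention
        for m in range(1, spec.inner_count + 1):
            self.add_antenna_subunit(
                f"I{m:02d}", Ring.INNER, m, spec.inner_radius,
                spec.reference_angle_deg - (m - 1) * inner_step)
        for m in range(1, spec.outer_count + 1):
            self.add_antenna_subunit(
                f"O{m:02d}", Ring.OUTER, m, spec.outer_radius,
                spec.reference_angle_deg - (m - 1) * outer_step)
        if spec.plant_close_pairs:
            self.plant_pairs()
        self.model.validate()
        self.truth._model = self.model
        return self.model, self.truth


def generate_complex(spec: SyntheticComplexSpec) -> tuple[ComplexModel, GroundTruth]:
    """Deterministically generate a pseudo-complex and its ground truth."""
    spec.validate()
    return _Builder(spec).build()


# ---------------------------------------------------------------------------
# structure writing

_ELEMENTS = {"MG": "Mg", "NB": "N", "ND": "N", "CA": "C",
             "C1": "C", "C2": "C", "C3": "C"}


def _add_atom(res: gemmi.Residue, name: str, pos: np.ndarray) -> None:
    a = gemmi.Atom()
    a.name = name
    a.element = gemmi.Element(_ELEMENTS.get(name, "C"))
    a.occ = 1.0
    a.pos = gemmi.Position(*[float(x) for x in pos])
    res.add_atom(a)


def _new_residue(name: str, num: int, het: bool) -> gemmi.Residue:
    res = gemmi.Residue()
    res.name = name
    res.seqid = gemmi.SeqId(num, " ")
    res.het_flag = "H" if het else "A"
    return res


def write_structure(model: ComplexModel, path, fmt: str = "mmcif") -> str:
    """Write a :class:`ComplexModel` as mmCIF or PDB; returns the format used.

    PDB output is only possible for single-character chain ids and
    coordinates within the fixed-width fields; otherwise the file is
    written as mmCIF at the same path with a warning.
    """
    if fmt not in ("mmcif", "pdb"):
        raise ValueError(f"unknown format {fmt!r}; use 'mmcif' or 'pdb'")
    st = gemmi.Structure()
    st.name = model.name
    gm = gemmi.Model("1")
    for sub in model.subunits:
        chain = gemmi.Chain(sub.chain_id)
        ca = [a for a in model.atoms if a.chain_id == sub.chain_id
              and a.atom_name == "CA"]
        for a in sorted(ca, key=lambda a: a.residue_number):
            res = _new_residue(a.residue_name, a.residue_number, het=False)
            _add_atom(res, "CA", a.position)
            chain.add_residue(res)
        pigs = [p for p in model.pigments if p.chain_id == sub.chain_id]
        for p in sorted(pigs, key=lambda p: p.pigment_id[1]):
            res = _new_residue(p.pigment_id[2], p.pigment_id[1], het=True)
            if p.is_chlorophyll:
                _add_atom(res, "MG", p.mg)
                _add_atom(res, "NB", p.nb)
                _add_atom(res, "ND", p.nd)
            else:
                # three collinear pseudo-atoms whose mean is the centroid
                for k, name in enumerate(("C1", "C2", "C3")):
                    _add_atom(res, name,
                              p.centroid + np.array([0, 0, 2.0 * (k - 1)]))
            chain.add_residue(res)
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    path = Path(path)
    if fmt == "pdb":
        pdb_ok = all(len(s.chain_id) <= 1 for s in model.subunits)
        coords = [a.position for a in model.atoms] + \
                 [p.position for p in model.pigments]
        if coords:
            lo = min(float(np.min(c)) for c in coords)
            hi = max(float(np.max(c)) for c in coords)
            pdb_ok = pdb_ok and (-999.999 < lo) and (hi < 9999.999)
        if not pdb_ok:
            log.warning("model %s does not fit fixed-width PDB fields; "
                        "writing mmCIF to %s instead", model.name, path)
            fmt = "mmcif"
    if fmt == "pdb":
        st.write_pdb(str(path))
    else:
        st.make_mmcif_document().write_file(str(path))
    return fmt


# ---------------------------------------------------------------------------
# rigid perturbations

def _rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    from scipy.spatial.transform import Rotation
    return Rotation.from_rotvec(axis * math.radians(angle_deg)).as_matrix()


def perturb_complex(
    model: ComplexModel,
    rotation_deg: float = 0.0,
    axis=(0.0, 0.0, 1.0),
    translation=(0.0, 0.0, 0.0),
    center=(0.0, 0.0, 0.0),
    subunit_overrides: Optional[dict] = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ComplexModel:
    """Return a copy with exact rigid motions applied.

    ``subunit_overrides`` maps chain id -> dict with any of
    ``rotation_deg``, ``axis``, ``translation``, ``center`` (defaults:
    z axis through the origin); these per-subunit motions are applied
    first, in the model's own frame, and the global rotation (about
    ``axis`` through ``center``) plus translation is applied afterwards
    to every atom and pigment.  Optional Gaussian coordinate noise is
    seeded and deterministic.
    """
    out = copy.deepcopy(model)
    overrides = dict(subunit_overrides or {})
    known = {s.chain_id for s in out.subunits}
    unknown = set(overrides) - known
    if unknown:
        raise ValueError(f"unknown subunit names: {sorted(unknown)}")

    def make_fn(rot_deg, ax, tr, ctr):
        r = _rotation_matrix(np.asarray(ax, float), rot_deg)
        ctr = np.asarray(ctr, float)
        tr = np.asarray(tr, float)
        return lambda p: r @ (p - ctr) + ctr + tr

    global_fn = make_fn(rotation_deg, axis, translation, center)
    chain_fns = {}
    for cid, ov in overrides.items():
        chain_fns[cid] = make_fn(
            ov.get("rotation_deg", 0.0), ov.get("axis", (0.0, 0.0, 1.0)),
            ov.get("translation", (0, 0, 0)), ov.get("center", (0.0, 0.0, 0.0)))

    rng = np.random.default_rng(seed)

    def move(cid: str, p: np.ndarray) -> np.ndarray:
        q = chain_fns[cid](p) if cid in chain_fns else p
        q = global_fn(q)
        if noise_sd > 0:
            q = q + rng.normal(scale=noise_sd, size=3)
        return q

    new_atoms = []
    for a in out.atoms:
        new_atoms.append(AtomRecord(
            atom_name=a.atom_name, residue_name=a.residue_name,
            residue_number=a.residue_number, chain_id=a.chain_id,
            position=move(a.chain_id, a.position)))
    out.atoms = new_atoms
    for p in out.pigments:
        cid = p.chain_id
        if p.is_chlorophyll:
            p.mg = move(cid, p.mg)
            p.nb = move(cid, p.nb)
            p.nd = move(cid, p.nd)
        else:
            p.centroid = move(cid, p.centroid)
    return out
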