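"""Rigid superposition and per-subunit displacement analysis.

Two complexes are compared by least-squares (Kabsch) superposition of
the C-alpha traces of a shared reference core subunit (PsaA by
convention), after which matched antenna subunits yield centroid
displacements decomposed into in-membrane ("horizontal") and
along-normal ("vertical", + = toward the cytoplasm) components, a
best-fit in-plane ring rotation angle, and a vertical curvature
profile around each ring.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .geometry import MembraneFrame
from .records import ComplexModel, Ring, SubunitRecord

__all__ = [
    "RigidTransform",
    "SubunitShift",
    "superpose_on_reference",
    "subunit_shifts",
    "ring_rotation_angle",
    "curvature_profile",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RigidTransform:
    """x -> rotation @ x + translation, with the fit RMSD (Angstrom)."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float)
        if r.shape != (3, 3) or abs(np.linalg.det(r) - 1.0) > 1e-6:
            raise ValueError("rotation must be a proper 3x3 rotation matrix")
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation",
                           np.asarray(self.translation, dtype=float))
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.rotation.T + self.translation
        return out[0] if np.asarray(points).ndim == 1 else out

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(rotation=np.eye(3), translation=np.zeros(3), rmsd=0.0)


@dataclass(frozen=True)
class SubunitShift:
    """Centroid displacement of one matched subunit (b -> a frame)."""

    subunit_ref: tuple          # (ring, ring_index) or ("chain", chain_id)
    chain_a: str
    chain_b: str
    horizontal: float           # in-membrane component, Angstrom
    vertical: float             # along-normal, signed (+ = cytoplasmic)
    total: float

    def __post_init__(self) -> None:
        if abs(self.total ** 2 - (self.horizontal ** 2 + self.vertical ** 2)) > 1e-6 * max(1.0, self.total ** 2):
            raise ValueError("shift components violate the Pythagorean identity")


def _matched_ca(model_a: ComplexModel, chain_a: str,
                model_b: ComplexModel, chain_b: str) -> tuple[np.ndarray, np.ndarray]:
    """C-alpha coordinate pairs matched by residue number."""
    pa = {a.residue_number: a.position for a in model_a.atoms
          if a.chain_id == chain_a and a.atom_name == "CA"}
    pb = {a.residue_number: a.position for a in model_b.atoms
          if a.chain_id == chain_b and a.atom_name == "CA"}
    common = sorted(set(pa) & set(pb))
    xa = np.array([pa[i] for i in common]).reshape(-1, 3)
    xb = np.array([pb[i] for i in common]).reshape(-1, 3)
    return xa, xb


def _kabsch(xa: np.ndarray, xb: np.ndarray) -> RigidTransform:
    """Proper rigid transform mapping xb onto xa (least squares)."""
    ca, cb = xa.mean(axis=0), xb.mean(axis=0)
    rot, rssd = Rotation.align_vectors(xa - ca, xb - cb)
    rmat = rot.as_matrix()
    rmsd = float(rssd / math.sqrt(len(xa)))
    return RigidTransform(rotation=rmat, translation=ca - rmat @ cb, rmsd=rmsd)


def superpose_on_reference(
    model_a: ComplexModel,
    model_b: ComplexModel,
    reference_role: str = "PsaA",
    chain_a: Optional[str] = None,
    chain_b: Optional[str] = None,
) -> RigidTransform:
    """Kabsch superposition of model_b onto model_a via a core subunit.

    The matched atom set is the C-alpha pairs of the reference chains
    sharing a residue number.  When a model holds several copies of the
    reference role (a trimeric core has three PsaA chains) and no chain
    is named, every (a, b) chain combination is fitted and the
    lowest-RMSD one is returned.
    """
    cands_a = ([model_a.subunit(chain_a)] if chain_a
               else model_a.subunits_with_role(reference_role))
    cands_b = ([model_b.subunit(chain_b)] if chain_b
               else model_b.subunits_with_role(reference_role))
    if not cands_a or not cands_b:
        raise ValueError(
            f"reference role {reference_role!r} missing from "
            f"{'model_a' if not cands_a else 'model_b'}"
        )
    best: Optional[RigidTransform] = None
    best_pair = None
    for sa in cands_a:
        for sb in cands_b:
            xa, xb = _matched_ca(model_a, sa.chain_id, model_b, sb.chain_id)
            if len(xa) < 3:
                continue
            t = _kabsch(xa, xb)
            if best is None or t.rmsd < best.rmsd:
                best, best_pair = t, (sa.chain_id, sb.chain_id)
    if best is None:
        raise ValueError(
            f"fewer than 3 matched C-alpha atoms between any "
            f"{reference_role} chain pair"
        )
    log.info("superposed on %s (%s <- %s): rmsd %.3f A over reference C-alphas",
             reference_role, best_pair[0], best_pair[1], best.rmsd)
    return best


def _match_subunits(
    model_a: ComplexModel,
    model_b: ComplexModel,
    subunit_map: Optional[dict] = None,
) -> list[tuple[tuple, SubunitRecord, SubunitRecord]]:
    """Pair antenna subunits across models by (ring, ring_index).

    ``subunit_map`` (chain_a -> chain_b) overrides the ring matching.
    Unmatched subunits are skipped with a warning.
    """
    pairs = []
    if subunit_map is not None:
        for ca, cb in subunit_map.items():
            pairs.append((("chain", ca), model_a.subunit(ca), model_b.subunit(cb)))
        return pairs
    index_b = {(s.ring, s.ring_index): s for s in model_b.subunits
               if s.is_antenna and s.ring is not Ring.NONE}
    unmatched = []
    for sa in model_a.subunits:
        if not sa.is_antenna or sa.ring is Ring.NONE:
            continue
        sb = index_b.get((sa.ring, sa.ring_index))
        if sb is None:
            unmatched.append(sa.label)
            continue
        pairs.append(((sa.ring.value, sa.ring_index), sa, sb))
    if unmatched:
        log.warning("%d antenna subunits without a counterpart skipped: %s",
                    len(unmatched), ", ".join(unmatched))
    return pairs


def subunit_shifts(
    model_a: ComplexModel,
    model_b: ComplexModel,
    transform: RigidTransform,
    frame: MembraneFrame,
    subunit_map: Optional[dict] = None,
) -> list[SubunitShift]:
    """Displacements of matched subunit centroids after superposition.

    The displacement (b, transformed into a's frame, minus a) is
    decomposed along the membrane normal of ``frame`` (vertical, signed,
    + = cytoplasmic) and within the membrane plane (horizontal norm).
    """
    shifts = []
    for ref, sa, sb in _match_subunits(model_a, model_b, subunit_map):
        cb = transform.apply(model_b.subunit_centroid(sb.chain_id))
        d = cb - model_a.subunit_centroid(sa.chain_id)
        vertical = float(np.dot(d, frame.normal))
        horizontal = float(np.linalg.norm(d - vertical * frame.normal))
        shifts.append(SubunitShift(
            subunit_ref=ref, chain_a=sa.chain_id, chain_b=sb.chain_id,
            horizontal=horizontal, vertical=vertical,
            total=float(np.linalg.norm(d)),
        ))
    return shifts


def ring_rotation_angle(
    model_a: ComplexModel,
    model_b: ComplexModel,
    transform: RigidTransform,
    subunit_refs: Optional[Sequence[tuple]] = None,
    frame: Optional[MembraneFrame] = None,
    per_subunit: bool = False,
):
    """Best-fit in-plane rotation (degrees) of model_b's ring vs model_a's.

    Matched subunit centroids are projected into the membrane plane
    around the ring axis of ``frame`` (computed from model_a when not
    given); the angle is the rotation-only 2-D orthogonal Procrustes
    solution mapping b's projections onto a's.  Positive = anticlockwise
    as viewed from the lumenal side.  With ``per_subunit`` the individual
    angular offsets are returned alongside the Procrustes angle.
    """
    from .geometry import membrane_frame
    if frame is None:
        frame = membrane_frame(model_a)
    pairs = _match_subunits(model_a, model_b, None)
    if subunit_refs is not None:
        want = set(subunit_refs)
        pairs = [p for p in pairs if p[0] in want]
    if len(pairs) < 2:
        raise ValueError(
            f"need at least 2 matched subunits for a ring rotation, "
            f"got {len(pairs)}"
        )
    z = -frame.normal  # lumenal-view axis: + angle = anticlockwise from lumen
    e1 = np.zeros(3)
    e1[np.argmin(np.abs(z))] = 1.0
    e1 = e1 - np.dot(e1, z) * z
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(z, e1)

    def proj2d(p: np.ndarray) -> np.ndarray:
        v = frame.in_plane(p)
        return np.array([np.dot(v, e1), np.dot(v, e2)])

    pa = np.array([proj2d(model_a.subunit_centroid(sa.chain_id))
                   for _, sa, _ in pairs])
    pb = np.array([proj2d(transform.apply(model_b.subunit_centroid(sb.chain_id)))
                   for _, _, sb in pairs])
    # centre each projected set: a rotation about the ring axis equals a
    # rotation about the set centroid plus a translation, so centring
    # recovers the angle exactly for open arcs as well as closed rings
    pac = pa - pa.mean(axis=0)
    pbc = pb - pb.mean(axis=0)
    # rotation-only 2-D Procrustes: theta maps b onto a
    num = float(np.sum(pbc[:, 0] * pac[:, 1] - pbc[:, 1] * pac[:, 0]))
    den = float(np.sum(pbc[:, 0] * pac[:, 0] + pbc[:, 1] * pac[:, 1]))
    theta = math.degrees(math.atan2(num, den))
    if not per_subunit:
        return theta
    offsets = {}
    for (ref, _, _), a2, b2 in zip(pairs, pac, pbc):
        da = math.atan2(a2[1], a2[0]) - math.atan2(b2[1], b2[0])
        offsets[ref] = math.degrees((da + math.pi) % (2 * math.pi) - math.pi)
    return theta, offsets


def curvature_profile(model: ComplexModel, frame: MembraneFrame) -> pd.DataFrame:
    """Vertical offset of each antenna subunit vs its angular position.

    Offsets are centroid heights relative to the mean core-subunit
    centroid height (falling back to the chlorophyll-layer midplane when
    no core subunits are present).  A flat ring gives a near-zero
    peak-to-peak amplitude per ring; a tilted or curved membrane region
    shows as a systematic angular modulation.
    """
    core = [s for s in model.subunits if s.is_core]
    if core:
        ref_height = float(np.mean([
            np.dot(model.subunit_centroid(s.chain_id), frame.normal)
            for s in core]))
    else:
        ref_height = frame.midplane_offset
    z = -frame.normal
    e1 = np.zeros(3)
    e1[np.argmin(np.abs(z))] = 1.0
    e1 = e1 - np.dot(e1, z) * z
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(z, e1)
    rows = []
    for s in model.subunits:
        if not s.is_antenna or s.ring is Ring.NONE:
            continue
        c = model.subunit_centroid(s.chain_id)
        v = frame.in_plane(c)
        rows.append({
            "ring": s.ring.value,
            "ring_index": s.ring_index,
            "chain_id": s.chain_id,
            "angle_deg": math.degrees(math.atan2(np.dot(v, e2), np.dot(v, e1))) % 360.0,
            "vertical_offset": float(np.dot(c, frame.normal)) - ref_height,
        })
    return (pd.DataFrame(rows, columns=["ring", "ring_index", "chain_id",
                                        "angle_deg", "vertical_offset"])
            .sort_values(["ring", "ring_index"]).reset_index(drop=True))


def curvature_summary(profile: pd.DataFrame) -> pd.DataFrame:
    """Peak-to-peak vertical amplitude per ring."""
    if profile.empty:
        return pd.DataFrame(columns=["ring", "peak_to_peak"])
    return (profile.groupby("ring")["vertical_offset"]
            .agg(peak_to_peak=lambda s: float(s.max() - s.min()))
            .reset_index())
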