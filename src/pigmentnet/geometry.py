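"""Membrane frame, sidedness, ring assignment and interfacial pairs.

The membrane frame is estimated from the chlorophyll Mg cloud: antenna
chlorophylls lie in two thin layers parallel to the membrane, so the
direction of least spread (smallest principal component of the Mg
covariance) is the membrane normal.  The sign is fixed so that the
cytoplasmic extrinsic subunits (PsaC/PsaD/PsaE by default) project to
the positive side; the midplane is placed in the gap between the two
Mg layers found by an exact 1-D two-means split.

Ring assignment for antenna protomers uses radial distance from the
central axis with a largest-gap split into inner/outer, and indexes
protomers by angle, anticlockwise as viewed from the lumenal side,
starting from a reference subunit (the one nearest the PsaK pole by
default).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .config import NamingConfig
from .records import ComplexModel, PigmentRecord, Ring, SubunitRecord

__all__ = [
    "MembraneFrame",
    "GeometryThresholds",
    "PairCategory",
    "InterfacialPair",
    "membrane_frame",
    "classify_sidedness",
    "ring_axis_center",
    "assign_rings",
    "interfacial_pairs",
]

log = logging.getLogger(__name__)

DEFAULT_MARKER_ROLES = frozenset({"PsaC", "PsaD", "PsaE"})

CYTOPLASMIC = "cytoplasmic"
LUMENAL = "lumenal"


@dataclass(frozen=True)
class MembraneFrame:
    """Unit membrane normal + signed midplane offset along it.

    The positive side of ``normal`` is the cytoplasmic face; a point at
    position x is cytoplasmic iff ``x @ normal - midplane_offset >= 0``
    (points exactly on the midplane count as cytoplasmic).
    """

    normal: np.ndarray
    midplane_offset: float
    #: projection of the chlorophyll centroid; anchors the ring axis.
    center: np.ndarray

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float)
        if abs(np.linalg.norm(n) - 1.0) > 1e-9:
            raise ValueError("membrane normal must be a unit vector")
        object.__setattr__(self, "normal", n)
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))

    def height(self, point: np.ndarray) -> float:
        """Signed distance from the midplane (+ = cytoplasmic)."""
        return float(np.dot(point, self.normal) - self.midplane_offset)

    def in_plane(self, point: np.ndarray) -> np.ndarray:
        """Component of (point - center) perpendicular to the normal."""
        d = np.asarray(point, dtype=float) - self.center
        return d - np.dot(d, self.normal) * self.normal


@dataclass(frozen=True)
class GeometryThresholds:
    """Mg-Mg distance cutoffs (Angstrom) for interfacial pairs."""

    pair_cutoff: float = 23.0
    highlight_cutoff: float = 18.0

    def __post_init__(self) -> None:
        if not (0 < self.highlight_cutoff <= self.pair_cutoff):
            raise ValueError("require 0 < highlight_cutoff <= pair_cutoff")


class PairCategory(str, enum.Enum):
    INNER_OUTER = "inner_outer"
    CORE_INNER = "core_inner"
    OTHER = "other"


@dataclass(frozen=True)
class InterfacialPair:
    pigment_a: tuple
    pigment_b: tuple
    mg_mg_distance: float
    category: PairCategory
    highlight: bool


def _two_means_split_1d(values: np.ndarray) -> int:
    """Index k minimizing within-group SSE of sorted values split at k.

    Exact 1-D two-means: the optimal clustering of sorted data is a
    contiguous split, so scanning all n-1 splits with prefix sums is
    exact and deterministic.  Returns k with 1 <= k <= n-1 such that
    groups are values[:k] and values[k:].
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    c1 = np.cumsum(v)
    c2 = np.cumsum(v * v)
    k = np.arange(1, n)
    sse_lo = c2[k - 1] - c1[k - 1] ** 2 / k
    sse_hi = (c2[-1] - c2[k - 1]) - (c1[-1] - c1[k - 1]) ** 2 / (n - k)
    return int(k[np.argmin(sse_lo + sse_hi)])


def membrane_frame(
    model: ComplexModel,
    marker_roles: Iterable[str] = DEFAULT_MARKER_ROLES,
    cytoplasmic_sign: Optional[int] = None,
) -> MembraneFrame:
    """Estimate the membrane frame from the chlorophyll Mg cloud.

    ``cytoplasmic_sign`` (+1/-1 along the raw smallest principal axis)
    may be supplied when no marker subunit is present in the model.
    """
    mg = np.array([p.mg for p in model.chlorophylls()], dtype=float)
    if len(mg) < 3:
        raise ValueError(
            f"{model.name}: need at least 3 chlorophylls to define a "
            f"membrane frame, found {len(mg)}"
        )
    centroid = mg.mean(axis=0)
    cov = np.cov((mg - centroid).T)
    evals, evecs = np.linalg.eigh(cov)
    normal = evecs[:, np.argmin(evals)]
    normal = normal / np.linalg.norm(normal)

    markers = [s for s in model.subunits if s.role in set(marker_roles)]
    if markers:
        pts = []
        for s in markers:
            try:
                pts.append(model.subunit_centroid(s.chain_id))
            except ValueError:
                continue
        if not pts:
            raise ValueError(
                f"{model.name}: marker subunits have no atoms or pigments")
        marker_centroid = np.mean(np.array(pts), axis=0)
        if np.dot(marker_centroid - centroid, normal) < 0:
            normal = -normal
    elif cytoplasmic_sign is not None:
        normal = normal * (1 if cytoplasmic_sign >= 0 else -1)
    else:
        raise ValueError(
            f"{model.name}: no marker subunit with role in "
            f"{sorted(set(marker_roles))} and no cytoplasmic_sign configured; "
            "cannot orient the membrane normal"
        )

    proj = mg @ normal
    k = _two_means_split_1d(proj)
    v = np.sort(proj)
    midplane = 0.5 * (v[k - 1] + v[k])
    return MembraneFrame(normal=normal, midplane_offset=midplane,
                         center=centroid)


def classify_sidedness(
    pigments: Sequence[PigmentRecord],
    frame: MembraneFrame,
) -> tuple[dict, dict]:
    """Label each pigment cytoplasmic/lumenal by its midplane side.

    Returns ``(labels, counts)`` where labels maps pigment_id -> side and
    counts holds both totals.  Pigments exactly on the midplane count as
    cytoplasmic.
    """
    labels = {}
    for p in pigments:
        side = CYTOPLASMIC if frame.height(p.position) >= 0 else LUMENAL
        labels[p.pigment_id] = side
    counts = {
        CYTOPLASMIC: sum(1 for s in labels.values() if s == CYTOPLASMIC),
        LUMENAL: sum(1 for s in labels.values() if s == LUMENAL),
    }
    return labels, counts


@dataclass
class RingAssignment:
    """Summary of an inner/outer ring split of antenna protomers."""

    inner: list  # chain ids in index order
    outer: list
    single_ring: bool
    radial_gap: float


def _angles_about_axis(
    points: np.ndarray,
    frame: MembraneFrame,
    axis_center: np.ndarray,
    reference_dir: np.ndarray,
) -> np.ndarray:
    """Angles in [0, 2pi) about the ring axis, anticlockwise as seen
    from the lumenal side (i.e. about -normal), zero at reference_dir."""
    z = -frame.normal
    e1 = reference_dir - np.dot(reference_dir, z) * z
    norm = np.linalg.norm(e1)
    if norm < 1e-12:
        raise ValueError("reference direction is parallel to the membrane normal")
    e1 = e1 / norm
    e2 = np.cross(z, e1)
    d = points - axis_center
    ang = np.mod(np.arctan2(d @ e2, d @ e1), 2 * np.pi)
    # the reference subunit itself sits at angle 0; numerical jitter must
    # not wrap it to just below 2*pi and push it to the last index
    ang[ang > 2 * np.pi - 1e-9] = 0.0
    return ang


def ring_axis_center(model: ComplexModel, frame: MembraneFrame) -> np.ndarray:
    """Point the ring axis passes through.

    The reaction-centre subunits (PsaA/PsaB) anchor the axis when
    present — for an open antenna arc the chlorophyll centroid is pulled
    off-axis, while the core stays central; otherwise any core subunit,
    otherwise the chlorophyll centroid itself.
    """
    for roles in (("PsaA", "PsaB"), None):
        if roles is None:
            subs = [s for s in model.subunits if s.is_core]
        else:
            subs = [s for s in model.subunits if s.role in roles]
        pts = []
        for s in subs:
            try:
                pts.append(model.subunit_centroid(s.chain_id))
            except ValueError:
                continue
        if pts:
            return np.mean(np.array(pts), axis=0)
    return frame.center


def assign_rings(
    model: ComplexModel,
    frame: MembraneFrame,
    min_ring_gap: float = 15.0,
    reference_chain: Optional[str] = None,
    explicit: Optional[dict] = None,
    axis_center: Optional[np.ndarray] = None,
) -> RingAssignment:
    """Split antenna subunits into inner/outer rings and index them.

    Radial distances of antenna-subunit centroids from the ring axis
    (the frame normal through :func:`ring_axis_center` unless
    ``axis_center`` is given) are split at their largest sorted gap; a
    gap smaller than ``min_ring_gap`` (Angstrom) flags a single-ring
    result instead of forcing a spurious split.  ``explicit`` may map
    chain id -> "inner"/"outer" to override the radial split entirely.
    Subunit records in ``model`` are updated in place.
    """
    antenna = [s for s in model.subunits if s.is_antenna]
    if not antenna:
        raise ValueError(f"{model.name}: no antenna (isia-role) subunits")
    if axis_center is None:
        axis_center = ring_axis_center(model, frame)
    axis_center = np.asarray(axis_center, dtype=float)

    def radial(p: np.ndarray) -> float:
        d = p - axis_center
        d = d - np.dot(d, frame.normal) * frame.normal
        return float(np.linalg.norm(d))

    cents = {s.chain_id: model.subunit_centroid(s.chain_id) for s in antenna}
    radii = {c: radial(p) for c, p in cents.items()}

    if explicit is not None:
        inner_set = {c for c, r in explicit.items() if r == "inner"}
        outer_set = {c for c, r in explicit.items() if r == "outer"}
        unknown = (inner_set | outer_set) - set(cents)
        if unknown:
            raise ValueError(f"explicit ring map names unknown chains: {sorted(unknown)}")
        single = not outer_set
        gap = np.nan
    else:
        order = sorted(cents, key=lambda c: radii[c])
        rv = np.array([radii[c] for c in order])
        if len(rv) == 1:
            single, gap = True, 0.0
            inner_set, outer_set = set(order), set()
        else:
            gaps = np.diff(rv)
            kmax = int(np.argmax(gaps))
            gap = float(gaps[kmax])
            if gap < min_ring_gap:
                single = True
                inner_set, outer_set = set(order), set()
                log.info("%s: largest radial gap %.1f A < %.1f A; "
                         "treating antenna as a single ring",
                         model.name, gap, min_ring_gap)
            else:
                single = False
                inner_set = set(order[:kmax + 1])
                outer_set = set(order[kmax + 1:])

    # reference direction for angular index 1
    ref_chain = reference_chain
    if ref_chain is None:
        psak = sorted(model.subunits_with_role("PsaK"),
                      key=lambda s: s.chain_id)
        if psak:
            ref_chain = psak[0].chain_id
        else:
            ref_chain = sorted(c for c in cents)[0]
    try:
        ref_point = model.subunit_centroid(ref_chain)
    except (KeyError, ValueError) as exc:
        raise ValueError(f"{model.name}: cannot use {ref_chain!r} as ring "
                         f"reference: {exc}") from exc
    ref_dir = ref_point - axis_center

    def ordered(chains: set) -> list:
        if not chains:
            return []
        pts = np.array([cents[c] for c in sorted(chains)])
        names = sorted(chains)
        ang = _angles_about_axis(pts, frame, axis_center, ref_dir)
        return [names[i] for i in np.argsort(ang, kind="stable")]

    inner_sorted = ordered(inner_set)
    outer_sorted = ordered(outer_set)
    for s in antenna:
        if s.chain_id in inner_set:
            s.ring = Ring.INNER
            s.ring_index = inner_sorted.index(s.chain_id) + 1
        elif s.chain_id in outer_set:
            s.ring = Ring.OUTER
            s.ring_index = outer_sorted.index(s.chain_id) + 1
        else:
            s.ring = Ring.NONE
            s.ring_index = None
    return RingAssignment(inner=inner_sorted, outer=outer_sorted,
                          single_ring=single, radial_gap=gap)


def pair_category(a: SubunitRecord, b: SubunitRecord) -> PairCategory:
    rings = {a.ring, b.ring}
    if a.is_antenna and b.is_antenna and rings == {Ring.INNER, Ring.OUTER}:
        return PairCategory.INNER_OUTER
    if (a.is_core and b.ring is Ring.INNER) or (b.is_core and a.ring is Ring.INNER):
        return PairCategory.CORE_INNER
    return PairCategory.OTHER


def interfacial_pairs(
    model: ComplexModel,
    thresholds: GeometryThresholds = GeometryThresholds(),
    categories: Optional[set] = None,
) -> list[InterfacialPair]:
    """Chlorophyll pairs from different subunits within the Mg-Mg cutoff.

    Boundary semantics: a pair at exactly the cutoff is included
    (<= pair_cutoff); the highlight flag is strict (< highlight_cutoff).
    Pairs are returned sorted by distance, then by pigment ids.
    """
    chls = model.chlorophylls()
    if len(chls) < 2:
        return []
    mg = np.array([p.mg for p in chls])
    tree = cKDTree(mg)
    out = []
    for i, j in tree.query_pairs(r=thresholds.pair_cutoff):
        a, b = chls[i], chls[j]
        if a.subunit is b.subunit:
            continue
        cat = pair_category(a.subunit, b.subunit)
        if categories is not None and cat not in categories:
            continue
        d = float(np.linalg.norm(a.mg - b.mg))
        pa, pb = sorted((a.pigment_id, b.pigment_id))
        out.append(InterfacialPair(
            pigment_a=pa, pigment_b=pb, mg_mg_distance=d,
            category=cat, highlight=d < thresholds.highlight_cutoff,
        ))
    out.sort(key=lambda p: (p.mg_mg_distance, p.pigment_a, p.pigment_b))
    return out
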