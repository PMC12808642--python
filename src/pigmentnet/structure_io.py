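"""Parse atomic models and emit normalized pigment/subunit records.

mmCIF and PDB files are read through gemmi.  Each chlorophyll must carry
its central Mg plus the NB/ND nitrogen pair (the Qy transition-dipole
axis); carotenoids are reduced to the centroid of their atoms.  Protein
chains are reduced to C-alpha traces, which is all the downstream
geometry (centroids, Kabsch superposition) needs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import gemmi
import numpy as np
import pandas as pd

from .config import NamingConfig
from .records import (
    AtomRecord,
    ComplexModel,
    PigmentClass,
    PigmentRecord,
    Ring,
    SubunitRecord,
)

__all__ = [
    "StructureParseError",
    "ParseReport",
    "parse_structure",
    "pigment_census",
    "write_pigment_table",
    "read_pigment_table",
]

log = logging.getLogger(__name__)


class StructureParseError(ValueError):
    """Raised for unreadable files or malformed pigment records."""


@dataclass
class ParseReport:
    """Counts and warnings accumulated while normalizing one structure."""

    n_chains: int = 0
    n_chlorophylls: int = 0
    n_carotenoids: int = 0
    skipped_pigments: list = field(default_factory=list)
    altloc_warnings: list = field(default_factory=list)


def _first_conformer_atom(residue: gemmi.Residue, name: str) -> Optional[gemmi.Atom]:
    """First matching atom by name; altloc duplicates resolve to the first."""
    hits = [a for a in residue if a.name == name]
    if not hits:
        return None
    return hits[0]


def _pos(atom: gemmi.Atom) -> np.ndarray:
    return np.array([atom.pos.x, atom.pos.y, atom.pos.z], dtype=float)


def parse_structure(
    path,
    naming: Optional[NamingConfig] = None,
    fmt: Optional[str] = None,
    report: Optional[ParseReport] = None,
) -> ComplexModel:
    """Read an mmCIF/PDB file into a :class:`ComplexModel`.

    Parameters
    ----------
    path
        Structure file.  Format is detected from the extension unless
        ``fmt`` ("mmcif" or "pdb") is given.
    naming
        Residue-name and chain-role configuration; defaults to
        :meth:`NamingConfig.synthetic`, which understands the chain
        naming scheme of the bundled generator.
    report
        Optional report object to fill with per-class counts and the
        list of pigments skipped under ``on_missing_dipole="skip"``.
    """
    naming = naming or NamingConfig.synthetic()
    report = report if report is not None else ParseReport()
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"no such file: {path}")

    fmt_map = {"mmcif": gemmi.CoorFormat.Mmcif, "pdb": gemmi.CoorFormat.Pdb}
    try:
        if fmt is None:
            st = gemmi.read_structure(str(path))
        else:
            st = gemmi.read_structure(str(path), format=fmt_map[fmt.lower()])
    except KeyError:
        raise StructureParseError(f"unknown format {fmt!r}; use 'mmcif' or 'pdb'")
    except Exception as exc:  # gemmi raises RuntimeError with record context
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0 or sum(1 for _ in st[0]) == 0:
        raise StructureParseError(f"{path}: no atoms / no chains found")

    model = ComplexModel(name=st.name or path.stem)
    gmodel = st[0]
    for chain in gmodel:
        sub = SubunitRecord(chain_id=chain.name, role=naming.role_for(chain.name))
        model.subunits.append(sub)
        report.n_chains += 1
        for residue in chain:
            cls = naming.classify_residue(residue.name)
            if cls == "chlorophyll_a":
                if any(len([a for a in residue if a.name == nm]) > 1
                       for nm in ("MG", "NB", "ND")):
                    report.altloc_warnings.append(
                        f"{chain.name}/{residue.seqid.num}"
                    )
                    log.warning(
                        "chlorophyll %s/%s has alternate conformers; "
                        "taking the first", chain.name, residue.seqid.num,
                    )
                atoms = {nm: _first_conformer_atom(residue, nm)
                         for nm in ("MG", "NB", "ND")}
                missing = [nm for nm, a in atoms.items() if a is None]
                pid = (chain.name, residue.seqid.num, residue.name)
                if missing:
                    if naming.on_missing_dipole == "skip":
                        report.skipped_pigments.append(pid)
                        log.warning("skipping chlorophyll %s: missing %s",
                                    pid, ",".join(missing))
                        continue
                    raise StructureParseError(
                        f"chlorophyll {pid} is missing atoms "
                        f"{','.join(missing)} required for the dipole axis"
                    )
                model.pigments.append(PigmentRecord(
                    pigment_id=pid,
                    pigment_class=PigmentClass.CHLOROPHYLL_A,
                    subunit=sub,
                    mg=_pos(atoms["MG"]),
                    nb=_pos(atoms["NB"]),
                    nd=_pos(atoms["ND"]),
                ))
                report.n_chlorophylls += 1
            elif cls == "carotenoid":
                coords = np.array([_pos(a) for a in residue], dtype=float)
                model.pigments.append(PigmentRecord(
                    pigment_id=(chain.name, residue.seqid.num, residue.name),
                    pigment_class=PigmentClass.CAROTENOID,
                    subunit=sub,
                    centroid=coords.mean(axis=0),
                ))
                report.n_carotenoids += 1
            else:
                ca = _first_conformer_atom(residue, "CA")
                if ca is not None:
                    model.atoms.append(AtomRecord(
                        atom_name="CA",
                        residue_name=residue.name,
                        residue_number=residue.seqid.num,
                        chain_id=chain.name,
                        position=_pos(ca),
                    ))
    model.validate()
    log.info("parsed %s: %d chains, %d chlorophylls, %d carotenoids",
             path.name, report.n_chains, report.n_chlorophylls,
             report.n_carotenoids)
    return model


def pigment_census(
    model: ComplexModel,
    restrict_to: Optional[set] = None,
) -> pd.DataFrame:
    """Count pigments per (role, ring, pigment class).

    ``restrict_to`` is an optional set of subunit roles (e.g. ``{"isia"}``);
    an empty selection yields an empty table whose counts sum to zero.
    """
    rows = []
    for p in model.pigments:
        if restrict_to is not None and p.subunit.role not in restrict_to:
            continue
        rows.append({
            "role": p.subunit.role,
            "ring": p.subunit.ring.value,
            "pigment_class": p.pigment_class.value,
        })
    if not rows:
        return pd.DataFrame(columns=["role", "ring", "pigment_class", "count"])
    df = pd.DataFrame(rows)
    out = (df.value_counts(["role", "ring", "pigment_class"])
             .rename("count").reset_index()
             .sort_values(["role", "ring", "pigment_class"])
             .reset_index(drop=True))
    return out


_TABLE_COLUMNS = [
    "chain_id", "residue_number", "residue_name", "pigment_class",
    "role", "ring", "ring_index",
    "x", "y", "z", "nb_x", "nb_y", "nb_z", "nd_x", "nd_y", "nd_z",
]


def write_pigment_table(model: ComplexModel, path) -> None:
    """Write one row per pigment as TSV (coordinates to 0.001 A)."""
    rows = []
    for p in model.pigments:
        pos = p.position
        row = {
            "chain_id": p.pigment_id[0],
            "residue_number": p.pigment_id[1],
            "residue_name": p.pigment_id[2],
            "pigment_class": p.pigment_class.value,
            "role": p.subunit.role,
            "ring": p.subunit.ring.value,
            "ring_index": "" if p.subunit.ring_index is None else p.subunit.ring_index,
            "x": pos[0], "y": pos[1], "z": pos[2],
        }
        for name, vec in (("nb", p.nb), ("nd", p.nd)):
            for ax, val in zip("xyz", vec if vec is not None else (np.nan,) * 3):
                row[f"{name}_{ax}"] = val
        rows.append(row)
    df = pd.DataFrame(rows, columns=_TABLE_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.3f")


def read_pigment_table(path) -> pd.DataFrame:
    """Read back a pigment table written by :func:`write_pigment_table`."""
    return pd.read_csv(path, sep="\t", dtype={"chain_id": str, "ring": str})


def model_from_pigment_table(df: pd.DataFrame, name: str = "table") -> ComplexModel:
    """Rebuild a minimal :class:`ComplexModel` from a pigment table.

    Protein atoms are not stored in the table, so subunit centroids fall
    back to pigment means; sufficient for pair/network stages.
    """
    model = ComplexModel(name=name)
    subs: dict[str, SubunitRecord] = {}
    for _, r in df.iterrows():
        cid = str(r["chain_id"])
        if cid not in subs:
            ring = Ring(r["ring"]) if isinstance(r["ring"], str) else Ring.NONE
            idx = r.get("ring_index")
            subs[cid] = SubunitRecord(
                chain_id=cid, role=r["role"], ring=ring,
                ring_index=None if pd.isna(idx) or idx == "" else int(idx),
            )
            model.subunits.append(subs[cid])
        pid = (cid, int(r["residue_number"]), r["residue_name"])
        if r["pigment_class"] == PigmentClass.CHLOROPHYLL_A.value:
            model.pigments.append(PigmentRecord(
                pigment_id=pid, pigment_class=PigmentClass.CHLOROPHYLL_A,
                subunit=subs[cid],
                mg=[r["x"], r["y"], r["z"]],
                nb=[r["nb_x"], r["nb_y"], r["nb_z"]],
                nd=[r["nd_x"], r["nd_y"], r["nd_z"]],
            ))
        else:
            model.pigments.append(PigmentRecord(
                pigment_id=pid, pigment_class=PigmentClass.CAROTENOID,
                subunit=subs[cid], centroid=[r["x"], r["y"], r["z"]],
            ))
    model.validate()
    return model
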