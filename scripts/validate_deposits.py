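#!/usr/bin/env python
"""Run the pipeline checks against locally downloaded deposited models.

The bundled test suite and acceptance script run entirely on synthetic
complexes.  This helper applies the same analyses to real deposited
mmCIF files (e.g. the trimeric double-ring supercomplex 9LZJ and the
monomeric double-layer complex 9LZK) once the user has downloaded them,
reporting antenna-chain counts, ring split, modal chlorophylls per
antenna chain, sidedness counts and — when two files are given — the
outer-ring rotation after superposition on the reference core subunit.

Chain roles are read from a YAML naming config
(``pigmentnet.NamingConfig``); without one, a best-effort role map is
built from the deposit's own ``_entity`` annotations (descriptions
matching "IsiA" / "Psa<X>").

Usage:
    python scripts/validate_deposits.py 9lzj.cif [9lzk.cif] [--config roles.yaml]
"""

from __future__ import annotations

import argparse
import json
import re
import sys
from collections import Counter
from pathlib import Path

import gemmi

from pigmentnet import (
    NamingConfig,
    assign_rings,
    classify_sidedness,
    membrane_frame,
    parse_structure,
    ring_rotation_angle,
    superpose_on_reference,
)
from pigmentnet.records import ISIA


def roles_from_entity_annotations(path: Path) -> dict:
    """chain id -> role, inferred from _entity.pdbx_description."""
    doc = gemmi.cif.read(str(path))
    block = doc.sole_block()
    desc = {row.str(0): row.str(1) for row in
            block.find("_entity.", ["id", "pdbx_description"])}
    roles = {}
    for row in block.find("_entity_poly.", ["entity_id", "pdbx_strand_id"]):
        text = desc.get(row.str(0), "")
        role = None
        if re.search(r"\bIsiA\b|iron[- ]stress", text, re.IGNORECASE):
            role = ISIA
        else:
            m = re.search(r"\bPsa([A-Z])\b", text)
            if m:
                role = f"Psa{m.group(1)}"
        if role:
            for cid in re.split(r"[,\s]+", row.str(1)):
                if cid:
                    roles[cid] = role
    if not roles:
        sys.exit(f"{path}: could not infer any chain roles from _entity "
                 "annotations; supply --config with an explicit chain map")
    return roles


def analyse(path: Path, naming: NamingConfig) -> tuple:
    model = parse_structure(path, naming=naming)
    frame = membrane_frame(model, cytoplasmic_sign=naming.cytoplasmic_sign)
    rings = assign_rings(model, frame, reference_chain=naming.reference_chain)
    chls = model.chlorophylls(role=ISIA)
    _, side_counts = classify_sidedness(chls, frame)
    per_chain = Counter(p.chain_id for p in chls)
    modal = per_chain.most_common(1)[0][1] if per_chain else 0
    report = {
        "antenna_chains": sum(1 for s in model.subunits if s.is_antenna),
        "inner_ring": len(rings.inner),
        "outer_ring": len(rings.outer),
        "single_ring": rings.single_ring,
        "antenna_chlorophylls": len(chls),
        "modal_chlorophylls_per_antenna_chain": modal,
        "sidedness": side_counts,
    }
    return model, frame, report


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("structures", nargs="+", type=Path,
                    help="one or two local mmCIF files")
    ap.add_argument("--config", type=Path, default=None,
                    help="YAML naming config with the chain-role map")
    ap.add_argument("--ref-role", default="PsaA")
    args = ap.parse_args()

    reports = {}
    models = []
    for path in args.structures[:2]:
        if args.config:
            naming = NamingConfig.from_yaml(args.config)
        else:
            naming = NamingConfig(chain_roles=roles_from_entity_annotations(path))
        model, frame, report = analyse(path, naming)
        models.append((model, frame))
        reports[path.name] = report

    if len(models) == 2:
        (ma, fa), (mb, _) = models
        t = superpose_on_reference(ma, mb, reference_role=args.ref_role)
        refs = [("outer", s.ring_index) for s in mb.subunits
                if s.is_antenna and s.ring.value == "outer"]
        comparison = {"reference_rmsd": round(t.rmsd, 3)}
        try:
            comparison["outer_ring_rotation_deg"] = round(
                ring_rotation_angle(ma, mb, t, subunit_refs=refs, frame=fa), 3)
        except ValueError as exc:
            comparison["outer_ring_rotation_deg"] = f"unavailable: {exc}"
        reports["comparison"] = comparison

    print(json.dumps(reports, indent=2))


if __name__ == "__main__":
    main()
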