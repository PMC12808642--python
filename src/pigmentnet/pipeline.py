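"""End-to-end run wiring: structure -> pigments -> geometry -> network.

A run is described by a :class:`RunConfig` (typically loaded from YAML)
and produces a bundle of text outputs in one directory: the pigment
table, sidedness counts, interfacial-pair table, network exports, the
outer-to-inner transfer ranking, an optional structure comparison, and
a machine-readable JSON summary.  Re-running with unchanged inputs is
idempotent.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .config import NamingConfig
from .fret import (
    FretParameters,
    PathwayThresholds,
    build_network,
    export_graph,
    lifetime_filtered,
    outer_to_inner_table,
)
from .geometry import (
    GeometryThresholds,
    assign_rings,
    classify_sidedness,
    interfacial_pairs,
    membrane_frame,
)
from .records import ISIA, ComplexModel, Ring
from .structure_io import parse_structure, pigment_census, write_pigment_table

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    structure: str
    output_dir: str
    compare_with: Optional[str] = None       # second structure (optional)
    naming: NamingConfig = field(default_factory=NamingConfig.synthetic)
    pair_cutoff: float = 23.0
    highlight_cutoff: float = 18.0
    display_lifetime_max: float = 40.0
    fast_lifetime_max: float = 20.0
    fret_C: float = 32.26
    fret_n: float = 1.55
    min_ring_gap: float = 15.0
    reference_role: str = "PsaA"
    seed: int = 0

    def validate(self) -> None:
        errors = []
        if not Path(self.structure).exists():
            errors.append(f"structure file not found: {self.structure}")
        if self.compare_with and not Path(self.compare_with).exists():
            errors.append(f"comparison file not found: {self.compare_with}")
        for f in ("pair_cutoff", "highlight_cutoff", "display_lifetime_max",
                  "fast_lifetime_max"):
            if getattr(self, f) <= 0:
                errors.append(f"{f} must be positive")
        if errors:
            raise ValueError("invalid run config: " + "; ".join(errors))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        naming = data.pop("naming", None)
        cfg = cls(**data)
        if naming is not None:
            cfg.naming = NamingConfig(**naming)
        return cfg


def _analyse(model: ComplexModel, cfg: RunConfig) -> dict:
    """Geometry + network stages shared by the main and compare models."""
    frame = membrane_frame(model,
                           cytoplasmic_sign=cfg.naming.cytoplasmic_sign)
    rings = assign_rings(model, frame, min_ring_gap=cfg.min_ring_gap,
                         reference_chain=cfg.naming.reference_chain)
    labels, counts = classify_sidedness(model.chlorophylls(role=ISIA), frame)
    return {"frame": frame, "rings": rings, "sidedness": labels,
            "side_counts": counts}


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage and write the output bundle.

    Returns the summary dictionary (also written as ``summary.json``).
    """
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed for "
                               f"{cfg.structure}: {exc}") from exc

    model = stage("parse", parse_structure, cfg.structure, naming=cfg.naming)
    geo = stage("geometry", _analyse, model, cfg)

    write_pigment_table(model, out / "pigments.tsv")

    census = pigment_census(model)
    census.to_csv(out / "census.tsv", sep="\t", index=False)

    thresholds = GeometryThresholds(pair_cutoff=cfg.pair_cutoff,
                                    highlight_cutoff=cfg.highlight_cutoff)
    pairs = stage("pairs", interfacial_pairs, model, thresholds)
    pd.DataFrame([{
        "pigment_a": "/".join(map(str, p.pigment_a[:2])),
        "pigment_b": "/".join(map(str, p.pigment_b[:2])),
        "mg_mg_distance": round(p.mg_mg_distance, 3),
        "category": p.category.value,
        "highlight": p.highlight,
    } for p in pairs]).to_csv(out / "pairs.tsv", sep="\t", index=False)

    params = FretParameters(C=cfg.fret_C, n=cfg.fret_n)
    pathway = PathwayThresholds(display_lifetime_max=cfg.display_lifetime_max,
                                fast_lifetime_max=cfg.fast_lifetime_max)
    graph = stage("network", build_network, model, params, thresholds)
    display = lifetime_filtered(graph, pathway.display_lifetime_max)
    export_graph(display, out / "network.gexf", "gexf")
    export_graph(graph, out / "network_edges.tsv", "tsv")
    table, pair_summary = outer_to_inner_table(graph, pathway)
    table.to_csv(out / "outer_to_inner.tsv", sep="\t", index=False)
    pair_summary.to_csv(out / "outer_to_inner_summary.tsv", sep="\t",
                        index=False)

    antenna_chl = len(model.chlorophylls(role=ISIA))
    summary = {
        "pigmentnet_version": __version__,
        "structure": str(cfg.structure),
        "n_subunits": len(model.subunits),
        "n_antenna_subunits": sum(1 for s in model.subunits if s.is_antenna),
        "n_inner": len(geo["rings"].inner),
        "n_outer": len(geo["rings"].outer),
        "single_ring": geo["rings"].single_ring,
        "antenna_chlorophylls": antenna_chl,
        "total_chlorophylls": len(model.chlorophylls()),
        "sidedness_counts": geo["side_counts"],
        "n_interfacial_pairs": len(pairs),
        "n_highlight_pairs": sum(p.highlight for p in pairs),
        "n_network_edges": graph.number_of_edges(),
        "n_display_edges": display.number_of_edges(),
        "n_fast_edges": lifetime_filtered(
            graph, pathway.fast_lifetime_max).number_of_edges(),
        "thresholds": {
            "pair_cutoff_A": cfg.pair_cutoff,
            "highlight_cutoff_A": cfg.highlight_cutoff,
            "display_lifetime_ps": cfg.display_lifetime_max,
            "fast_lifetime_ps": cfg.fast_lifetime_max,
            "C": cfg.fret_C, "n": cfg.fret_n, "R_unit": "nm",
        },
        "seed": cfg.seed,
    }

    if cfg.compare_with:
        from .compare import (curvature_profile, curvature_summary,
                              ring_rotation_angle, subunit_shifts,
                              superpose_on_reference)
        model_b = stage("parse-compare", parse_structure, cfg.compare_with,
                        naming=cfg.naming)
        geo_b = stage("geometry-compare", _analyse, model_b, cfg)
        transform = stage("superpose", superpose_on_reference, model, model_b,
                          reference_role=cfg.reference_role)
        shifts = subunit_shifts(model, model_b, transform, geo["frame"])
        pd.DataFrame([{
            "subunit": "-".join(map(str, s.subunit_ref)),
            "chain_a": s.chain_a, "chain_b": s.chain_b,
            "horizontal": round(s.horizontal, 3),
            "vertical": round(s.vertical, 3),
            "total": round(s.total, 3),
        } for s in shifts]).to_csv(out / "subunit_shifts.tsv", sep="\t",
                                   index=False)
        prof = curvature_profile(model_b, geo_b["frame"])
        prof.to_csv(out / "curvature_profile.tsv", sep="\t", index=False)
        rotations = {}
        for ring in (Ring.INNER, Ring.OUTER):
            refs = [s.subunit_ref for s in shifts if s.subunit_ref[0] == ring.value]
            if len(refs) >= 2:
                rotations[ring.value] = ring_rotation_angle(
                    model, model_b, transform, subunit_refs=refs,
                    frame=geo["frame"])
        summary["comparison"] = {
            "reference_rmsd": round(transform.rmsd, 4),
            "ring_rotation_deg": {k: round(v, 3) for k, v in rotations.items()},
            "max_shift": round(max((s.total for s in shifts), default=0.0), 3),
            "mean_shift": round(float(pd.Series(
                [s.total for s in shifts]).mean()) if shifts else 0.0, 3),
            "curvature_peak_to_peak": {
                r["ring"]: round(r["peak_to_peak"], 3)
                for _, r in curvature_summary(prof).iterrows()},
        }

    (out / "summary.json").write_text(json.dumps(summary, indent=2,
                                                 sort_keys=True))
    log.info("pipeline finished: %d antenna chlorophylls, %d network edges",
             antenna_chl, summary["n_network_edges"])
    return summary
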