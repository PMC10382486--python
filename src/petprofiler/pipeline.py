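"""End-to-end orchestration: structure-comparison and assay report bundles.

A run is driven by a :class:`RunConfig`; outputs are plain TSV/JSON files in
the configured directory plus a manifest (package version, config echo, seed)
sufficient to rerun it. Identical configs produce byte-identical TSV/JSON.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from petprofiler import __version__ as _version
from petprofiler.assay_analytics import (
    DSCRecord, MeltCurve, ProductTimeCourse, TitrationTrace,
    base_to_acid_equivalents, crystallinity, depolymerization_extent, fit_tm,
)
from petprofiler.conformation_metrics import (
    RegionSet, divergence_profile, region_summary,
)
from petprofiler.geometry import backbone_torsions
from petprofiler.seq_align import global_align, percent_identity
from petprofiler.structure_io import (
    Structure, extract_sequence, read_pdb, write_annotated_pdb,
)
from petprofiler.superpose import superpose_structures

logger = logging.getLogger("petprofiler")

__all__ = ["RunConfig", "run_structure_comparison", "run_assay_report",
           "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    out_dir: str = "petprofiler-out"
    seed: int = 0
    # structure comparison
    reference: str | None = None          # path to reference PDB
    comparators: list[str] = field(default_factory=list)
    chain: str | None = None              # reference chain (default: first)
    comparator_chains: list[str] = field(default_factory=list)
    divergence_mode: str = "wrapped"
    trim_factor: float = 2.0
    max_iter: int = 5
    regions: dict[str, tuple[str, int, int]] = field(default_factory=dict)
    gap_open: float = 11.0
    gap_extend: float = 1.0
    # assay inputs (CSV paths)
    melt_curves: dict[str, str] = field(default_factory=dict)
    dsc: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    timecourses: dict[str, str] = field(default_factory=dict)
    titrations: dict[str, str] = field(default_factory=dict)
    tm_window: int = 5

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_manifest(cfg: RunConfig, out: Path, produced: list[str]) -> None:
    manifest = {
        "package": "petprofiler",
        "version": _version,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "config": asdict(cfg),
        "outputs": sorted(produced),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True, default=str) + "\n")


def run_structure_comparison(cfg: RunConfig) -> dict:
    """Compare a reference structure against each comparator.

    Per pair: global sequence alignment, trimmed Kabsch superposition,
    torsion profiles, a Ramachandran-divergence TSV, region summaries, and a
    divergence-annotated PDB for putty rendering. Returns the report dict
    that is also written to ``report.json``.
    """
    if cfg.reference is None or not cfg.comparators:
        raise PipelineError("structure comparison needs a reference and >=1 comparator")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    produced: list[str] = []
    report: dict = {"pairs": []}

    try:
        ref = read_pdb(cfg.reference)
    except Exception as exc:
        raise PipelineError(f"stage read_pdb(reference): {exc}") from exc
    ref_chain = cfg.chain or ref.first_chain_id()
    ref_seq = extract_sequence(ref, ref_chain)
    ref_torsions = backbone_torsions(ref, ref_chain)
    regions = RegionSet.from_dict(cfg.regions) if cfg.regions else None

    for k, comp_path in enumerate(cfg.comparators):
        stage = f"comparator[{k}]"
        try:
            comp = read_pdb(comp_path)
            comp_chain = (cfg.comparator_chains[k]
                          if k < len(cfg.comparator_chains) else comp.first_chain_id())
            comp_seq = extract_sequence(comp, comp_chain)
            amap = global_align(ref_seq, comp_seq,
                                gap_open=cfg.gap_open, gap_extend=cfg.gap_extend)
            sup = superpose_structures(ref, comp, amap, ref_chain, comp_chain,
                                       trim_factor=cfg.trim_factor,
                                       max_iter=cfg.max_iter)
            comp_torsions = backbone_torsions(comp, comp_chain)
            div = divergence_profile(ref_torsions, comp_torsions, amap,
                                     mode=cfg.divergence_mode)
            tag = Path(comp_path).stem
            div_tsv = out / f"divergence_{tag}.tsv"
            div.to_tsv(div_tsv)
            produced.append(div_tsv.name)
            annotated = out / f"annotated_{tag}.pdb"
            write_annotated_pdb(ref, div.as_bfactor_values(ref_chain), annotated)
            produced.append(annotated.name)
            pair: dict = {
                "comparator": comp_path,
                "identity_percent": round(percent_identity(amap), 4),
                "rmsd": round(sup.rmsd, 6),
                "n_used": sup.n_used,
                "n_initial": sup.n_initial,
                "n_aligned": len(amap.pairs),
            }
            if regions is not None:
                pair["regions"] = region_summary(div, regions)
            report["pairs"].append(pair)
        except PipelineError:
            raise
        except Exception as exc:
            for name in produced:
                (out / name).unlink(missing_ok=True)
            raise PipelineError(f"stage {stage}: {exc}") from exc

    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=str) + "\n")
    produced.append("report.json")
    _write_manifest(cfg, out, produced)
    logger.info("structure comparison written to %s", out)
    return report


def _read_two_column_csv(path: str) -> tuple[np.ndarray, np.ndarray]:
    data = np.genfromtxt(path, delimiter=",", names=True)
    names = data.dtype.names
    return np.asarray(data[names[0]], float), np.asarray(data[names[1]], float)


def run_assay_report(cfg: RunConfig) -> dict:
    """Reduce configured assay inputs to a results table + manifest."""
    if not (cfg.melt_curves or cfg.dsc or cfg.timecourses or cfg.titrations):
        raise PipelineError("no assay inputs configured")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {}

    for label, path in cfg.melt_curves.items():
        try:
            t, y = _read_two_column_csv(path)
            est = fit_tm(MeltCurve(t, y), window=cfg.tm_window)
            report.setdefault("tm", {})[label] = round(est.tm, 3)
        except Exception as exc:
            raise PipelineError(f"stage tm[{label}]: {exc}") from exc

    for label, (dhm, dhc, dhf) in cfg.dsc.items():
        try:
            report.setdefault("crystallinity_percent", {})[label] = round(
                crystallinity(DSCRecord(dhm, dhc, dhf)), 4)
        except Exception as exc:
            raise PipelineError(f"stage crystallinity[{label}]: {exc}") from exc

    for label, path in cfg.timecourses.items():
        try:
            data = np.genfromtxt(path, delimiter=",", names=True)
            tc = ProductTimeCourse(
                times=data["time"], tpa=data["tpa"], mhet=data["mhet"],
                bhet=data["bhet"], volume=float(data["volume"][0]),
                pet_load=float(data["pet_load"][0]),
            )
            ext = depolymerization_extent(tc)
            report.setdefault("depolymerization_percent", {})[label] = {
                "final": round(float(ext[-1]), 4),
                "series": [round(float(v), 4) for v in ext],
            }
        except Exception as exc:
            raise PipelineError(f"stage depolymerization[{label}]: {exc}") from exc

    for label, path in cfg.titrations.items():
        try:
            t, v = _read_two_column_csv(path)
            tt = TitrationTrace(times=t, cumulative_volume=v)
            eq = base_to_acid_equivalents(tt)
            report.setdefault("acid_equivalents_mol", {})[label] = [
                round(float(x), 8) for x in eq]
        except Exception as exc:
            raise PipelineError(f"stage titration[{label}]: {exc}") from exc

    (out / "assay_report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=str) + "\n")
    _write_manifest(cfg, out, ["assay_report.json"])
    logger.info("assay report written to %s", out)
    return report
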