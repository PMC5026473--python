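"""End-to-end orchestration: config, stage execution, consolidated report.

A single structured config (YAML or an in-memory dict) names the inputs
and the stages to run; ``run_all`` executes the requested stages in
dependency order (structure -> access; glygly -> fractions -> enrichment;
ibaq -> rank -> enrichment), collects warnings, and writes a JSON report
plus TSV tables. A failing stage halts its dependents but leaves
independent branches running; the manifest records everything.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import enrichment, glygly_quant, insolubility, probe_access, structure_io

logger = logging.getLogger(__name__)

_FLOAT_PRECISION = 6


@dataclass
class RunManifest:
    """What a run consumed and produced."""

    config: dict
    input_digests: dict[str, str] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    failures: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "input_digests": self.input_digests,
            "outputs": sorted(self.outputs),
            "warnings": self.warnings,
            "failures": self.failures,
        }


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def _round_floats(obj: Any) -> Any:
    """Fixed float precision so identical runs diff byte-identically."""
    if isinstance(obj, float):
        return round(obj, _FLOAT_PRECISION)
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    return obj


def write_report(results: dict, out_dir: str | Path) -> Path:
    """Write the consolidated JSON report (stable key order, fixed precision)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "report.json"
    payload = _round_floats(results)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


# ---------------------------------------------------------------------------
# stages


def run_access_stage(cfg: dict, out_dir: Path, manifest: RunManifest) -> dict:
    """structure -> assembly states -> site list -> accessibility counts."""
    structure_path = Path(cfg["structure"])
    manifest.input_digests[str(structure_path)] = _digest(structure_path)
    atoms, meta = structure_io.load_structure(structure_path, cfg.get("format", "auto"))
    chain_map = dict(cfg.get("chain_map", {}))
    states = []
    for state_cfg in cfg["states"]:
        states.append(
            structure_io.select_state(
                atoms,
                state_cfg["chains"],
                state_cfg["name"],
                chain_map=chain_map,
                source=str(structure_path),
            )
        )
    sites_tsv = Path(cfg["sites"])
    manifest.input_digests[str(sites_tsv)] = _digest(sites_tsv)
    site_df = pd.read_csv(sites_tsv, sep="\t")
    requested = [
        (str(r["protein"]), int(r["residue_number"])) for _, r in site_df.iterrows()
    ]
    offsets = {str(k): int(v) for k, v in cfg.get("offsets", {}).items()}
    acc_cfg = probe_access.AccessConfig(
        probe_radius=float(cfg.get("probe_radius", 25.0)),
        n_directions=int(cfg.get("n_directions", 1024)),
        clearance_slack=float(cfg.get("clearance_slack", 0.0)),
    )
    tables = []
    for st in states:
        sites = structure_io.find_lysine_sites(st, requested, offsets=offsets)
        tables.append(probe_access.classify_sites(sites, [st], acc_cfg))
    table = pd.concat(tables, ignore_index=True)
    summary = probe_access.summarize_access(table)
    table_path = out_dir / "access_sites.tsv"
    table.to_csv(table_path, sep="\t", index=False, float_format="%.6g")
    manifest.outputs.append(str(table_path))
    return {
        "per_state": {
            row["state"]: {
                "accessible": int(row["accessible"]),
                "inaccessible": int(row["inaccessible"]),
                "unobserved": int(row["unobserved"]),
                "observed": int(row["observed"]),
            }
            for _, row in summary.iterrows()
        },
        "probe_radius": acc_cfg.probe_radius,
    }


def run_glygly_stage(cfg: dict, out_dir: Path, manifest: RunManifest) -> dict:
    """site table -> summaries -> category fractions (+ optional enrichment)."""
    path = Path(cfg["sites"])
    manifest.input_digests[str(path)] = _digest(path)
    records = glygly_quant.read_site_table(path)
    protein_ratios = None
    if cfg.get("protein_ratios"):
        pr_path = Path(cfg["protein_ratios"])
        manifest.input_digests[str(pr_path)] = _digest(pr_path)
        protein_ratios = glygly_quant.read_protein_ratios(pr_path)
    summaries = glygly_quant.summarize_table(
        records, min_reps=int(cfg.get("min_reps", 2)), protein_ratios=protein_ratios
    )
    fractions = glygly_quant.report_fractions(summaries)
    sum_path = out_dir / "glygly_summaries.tsv"
    summaries.to_csv(sum_path, sep="\t", index=False, float_format="%.6g")
    frac_path = out_dir / "glygly_fractions.tsv"
    fractions.to_csv(frac_path, sep="\t", index=False, float_format="%.6g")
    manifest.outputs += [str(sum_path), str(frac_path)]

    result: dict = {
        "n_sites_quantified": int((~summaries["filtered"].astype(bool)).sum()),
        "n_sites_filtered": int(summaries["filtered"].astype(bool).sum()),
        "n_decreased_2x": int(fractions.attrs.get("n_decreased_total", 0)),
        "fractions": fractions.drop(
            columns=[c for c in fractions.columns if c.endswith("_display")]
        ).to_dict(orient="records"),
    }

    quantified = summaries[~summaries["filtered"].astype(bool)]
    if len(quantified) and cfg.get("enrich", True):
        key = quantified["protein"] + ":" + quantified["position"].astype(str)
        annotations = dict(zip(key, quantified["category"]))
        selected = key[quantified["decreased_2x"].astype(bool)]
        enr = enrichment.enrich_categories(selected, annotations, key)
        enr_path = out_dir / "glygly_enrichment.tsv"
        enr.to_csv(enr_path, sep="\t", index=False, float_format="%.6g")
        manifest.outputs.append(str(enr_path))
        result["enrichment"] = enr.to_dict(orient="records")
    return result


def run_ibaq_stage(cfg: dict, out_dir: Path, manifest: RunManifest) -> dict:
    """iBAQ table -> delta-iBAQ -> top-decile ranking (+ optional enrichment)."""
    path = Path(cfg["table"])
    manifest.input_digests[str(path)] = _digest(path)
    abundances = insolubility.read_ibaq_table(
        path,
        mutant_cols=cfg["mutant_cols"],
        wildtype_cols=cfg["wildtype_cols"],
        protein_col=cfg.get("protein_col", "protein"),
    )
    summaries = [insolubility.delta_ibaq(a) for a in abundances]
    ranked = insolubility.rank_and_select(summaries, decile=float(cfg.get("decile", 0.10)))
    ranked_out = ranked.drop(columns=["delta_per_replicate"])
    ranked_path = out_dir / "delta_ibaq_ranked.tsv"
    ranked_out.to_csv(ranked_path, sep="\t", index=False, float_format="%.6g")
    manifest.outputs.append(str(ranked_path))
    result: dict = {
        "n_proteins": int(len(ranked)),
        "n_top_decile": int(ranked["top_decile"].sum()),
        "top_decile": ranked.loc[ranked["top_decile"], "protein"].tolist(),
    }
    if cfg.get("annotations"):
        ann_path = Path(cfg["annotations"])
        manifest.input_digests[str(ann_path)] = _digest(ann_path)
        annotations = enrichment.read_annotations(ann_path)
        enr = enrichment.enrich_categories(
            result["top_decile"], annotations, ranked["protein"]
        )
        enr_path = out_dir / "ibaq_enrichment.tsv"
        enr.to_csv(enr_path, sep="\t", index=False, float_format="%.6g")
        manifest.outputs.append(str(enr_path))
        result["enrichment"] = enr.to_dict(orient="records")
    return result


_STAGES = {
    "access": run_access_stage,
    "glygly": run_glygly_stage,
    "ibaq": run_ibaq_stage,
}


def run_all(config: dict, out_dir: str | Path) -> tuple[RunManifest, dict]:
    """Execute every configured stage; failures halt dependents only.

    ``config`` maps stage names ("access", "glygly", "ibaq") to their
    stage configs; absent stages are skipped. Returns the manifest and
    the consolidated report dict (also written to ``report.json``).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config)
    results: dict = {}
    for stage, fn in _STAGES.items():
        stage_cfg = config.get(stage)
        if not stage_cfg:
            continue
        try:
            results[stage] = fn(stage_cfg, out_dir, manifest)
        except Exception as exc:  # a stage failure must not kill the run
            logger.error("stage %s failed: %s", stage, exc)
            manifest.failures[stage] = str(exc)
    report_path = write_report(results, out_dir)
    manifest.outputs.append(str(report_path))
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(
        json.dumps(_round_floats(manifest.to_dict()), indent=2, sort_keys=True) + "\n"
    )
    return manifest, results
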