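"""End-to-end pipeline: simulate or load, screen, orchestrate, network,
aggregate targets — with deterministic artefacts and a provenance manifest.

All randomness flows from one top-level seed; stages derive their own
sub-seeds from it, so rerunning the same configuration over the same
inputs produces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .disproportionality import ANALYSES, AnalysisOptions, run_analysis
from .network import (
    build_matrix,
    compare_partitions,
    compute_ppmi,
    detect_communities,
    edge_jaccard,
    fit_ising,
    select_terms,
)
from .simulate import GeneratorConfig, demo_config, generate_database, generate_target_map
from .store import (
    IcsrDatabase,
    apply_exclusion,
    read_database_dir,
    select_cases,
    write_database,
)
from .targets import aggregate_targets, read_target_map
from .workflow import dotplot_table, rank_signals, run_all

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

FLOAT_FORMAT = "%.6g"


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run."""

    outdir: str
    seed: int = 0
    stages: tuple = ("simulate", "signals", "workflow", "network", "targets")
    data_dir: str | None = None          # required when not simulating
    simulate: dict = field(default_factory=dict)  # GeneratorConfig overrides
    demo: bool = True                     # use the demo scenario as the base config
    network_classes: tuple = ("beta_blocker", "amphetamine_like")
    network_seed_offset: int = 101
    awareness_path: str | None = None
    target_map_path: str | None = None
    analysis: dict = field(default_factory=dict)  # AnalysisOptions overrides

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.outdir:
            raise ValueError("config field 'outdir' is required")
        bad = set(self.stages) - {"simulate", "signals", "workflow", "network", "targets"}
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        if "simulate" not in self.stages and not self.data_dir:
            raise ValueError("config field 'data_dir' is required when not simulating")

    def options(self) -> AnalysisOptions:
        return AnalysisOptions(**self.analysis)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, na_rep="",
                 float_format=FLOAT_FORMAT, lineterminator="\n")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the requested stages in dependency order; returns the
    manifest (also written to ``manifest.json``)."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    opts = cfg.options()
    artefacts: dict[str, Path] = {}
    inputs: dict[str, Path] = {}

    # --- data ------------------------------------------------------------
    if "simulate" in cfg.stages:
        base = demo_config(seed=cfg.seed) if cfg.demo else GeneratorConfig(seed=cfg.seed)
        gen_cfg = dataclasses.replace(base, seed=cfg.seed, **cfg.simulate)
        db, truth = generate_database(gen_cfg)
        data_dir = outdir / "data"
        for name, path in write_database(db, data_dir).items():
            artefacts[f"data/{name}"] = path
        truth_path = data_dir / "ground_truth.json"
        truth.write_json(truth_path)
        artefacts["data/ground_truth.json"] = truth_path
        tmap = generate_target_map(db.drug_dictionary, seed=cfg.seed)
        tmap_path = data_dir / "target_map.tsv"
        _write_tsv(tmap, tmap_path)
        artefacts["data/target_map.tsv"] = tmap_path
    else:
        db = read_database_dir(cfg.data_dir)
        for name in ("reports.tsv", "report_drugs.tsv", "report_events.tsv",
                     "drug_dictionary.tsv", "event_dictionary.tsv"):
            inputs[name] = Path(cfg.data_dir) / name

    # --- disproportionality ---------------------------------------------
    frames = None
    if "signals" in cfg.stages or "workflow" in cfg.stages:
        frames = {a: run_analysis(db, a, opts) for a in ANALYSES}
    if "signals" in cfg.stages:
        signals = pd.concat(frames.values(), ignore_index=True)
        path = outdir / "signals.tsv"
        _write_tsv(signals, path)
        artefacts["signals.tsv"] = path

    # --- workflow ---------------------------------------------------------
    records = None
    if "workflow" in cfg.stages:
        records = run_all(db, opts)
        awareness = None
        if cfg.awareness_path:
            awareness = pd.read_csv(cfg.awareness_path, sep="\t", dtype=str)
            inputs["awareness.tsv"] = Path(cfg.awareness_path)
        ranked = rank_signals(records, awareness, db.drug_dictionary)
        path = outdir / "consistency.tsv"
        _write_tsv(ranked, path)
        artefacts["consistency.tsv"] = path

        dots = dotplot_table(frames)
        path = outdir / "dotplot.tsv"
        _write_tsv(dots, path)
        artefacts["dotplot.tsv"] = path

        report = {
            "n_reports": int(db.n_reports),
            "n_drugs_evaluated": int(len(records)),
            "n_significant_primary": int(records["significant_primary"].sum()),
            "n_consistent_all": int(records["consistent_all"].sum()),
        }
        path = outdir / "report.json"
        path.write_text(json.dumps(report, indent=2, sort_keys=True))
        artefacts["report.json"] = path

    # --- networks ---------------------------------------------------------
    if "network" in cfg.stages:
        included = apply_exclusion(
            db, select_cases(db, opts.rp_pt_codes), opts.exclusion_atc_prefixes
        )
        edge_rows, part_rows, agree_rows = [], [], []
        for tag in cfg.network_classes:
            terms = select_terms(db, tag, included, exclude_pts=opts.rp_pt_codes, options=opts)
            if not terms:
                logger.warning("class %s: no disproportionate terms; skipped", tag)
                continue
            matrix = build_matrix(db, tag, included, terms)
            if len(matrix.pt_codes) < 2:
                logger.warning("class %s: fewer than two variable terms; skipped", tag)
                continue
            nets = {}
            try:
                nets["ising"] = fit_ising(matrix)
            except ValueError as exc:
                logger.warning("class %s: Ising fit refused (%s)", tag, exc)
            nets["ppmi"] = compute_ppmi(matrix)
            parts = {}
            for method, net in nets.items():
                part = detect_communities(net, seed=cfg.seed + cfg.network_seed_offset)
                parts[method] = part
                for a, b, w in net.edges():
                    edge_rows.append((tag, method, a, b, w))
                for node, comm in sorted(part.items()):
                    part_rows.append((tag, method, node, comm))
            if len(parts) == 2:
                agree_rows.append((
                    tag,
                    compare_partitions(parts["ising"], parts["ppmi"]),
                    edge_jaccard(nets["ising"], nets["ppmi"]),
                ))
        _write_tsv(pd.DataFrame(edge_rows, columns=["class_tag", "method", "pt_a", "pt_b", "weight"]),
                   outdir / "network_edges.tsv")
        _write_tsv(pd.DataFrame(part_rows, columns=["class_tag", "method", "pt_code", "community"]),
                   outdir / "network_partitions.tsv")
        _write_tsv(pd.DataFrame(agree_rows, columns=["class_tag", "ari", "edge_jaccard"]),
                   outdir / "network_agreement.tsv")
        for name in ("network_edges.tsv", "network_partitions.tsv", "network_agreement.tsv"):
            artefacts[name] = outdir / name

    # --- targets ----------------------------------------------------------
    if "targets" in cfg.stages:
        if cfg.target_map_path:
            tmap = read_target_map(cfg.target_map_path)
            inputs["target_map.tsv"] = Path(cfg.target_map_path)
        elif "data/target_map.tsv" in artefacts:
            tmap = read_target_map(artefacts["data/target_map.tsv"])
        else:
            raise ValueError("targets stage needs target_map_path or a simulate stage")
        if records is None:
            records = run_all(db, opts, with_summaries=False)
        signal_drugs = records[records["significant_primary"]]
        ranked_targets = aggregate_targets(signal_drugs, tmap)
        path = outdir / "targets.tsv"
        _write_tsv(ranked_targets, path)
        artefacts["targets.tsv"] = path

    # --- provenance -------------------------------------------------------
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "stages": list(cfg.stages),
        "inputs": {k: _sha256(p) for k, p in sorted(inputs.items())},
        "outputs": {k: _sha256(p) for k, p in sorted(artefacts.items())},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (outdir / "config.yaml").write_text(yaml.safe_dump(dataclasses.asdict(cfg), sort_keys=True))
    return manifest
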