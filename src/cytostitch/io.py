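"""Readers/writers, configuration, and the end-to-end pipeline driver.

On-disk schema for expression tables: one wide table with cell_id,
donor_id, panel_id then one column per marker; unmeasured entries are
empty (NA).  The measured mask is never stored — it is re-derived from
the panel design on load and validated against the NA pattern, so a file
whose values contradict its design is rejected instead of silently
trusted.  Every pipeline run writes a JSON manifest listing each artifact
with a content hash, the config hash and all seeds actually used.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import ExpressionTable, InputError, PanelDesign
from .integrate import aggregate_medians, confusion_matrix, meta_cluster, micro_cluster
from .markers import (
    cluster_level_correlation,
    ks_differential,
    nominate_minimal_panel,
    validate_recapitulation,
)
from .preprocess import (
    GateDef,
    GatePredicate,
    apply_gates,
    detect_expressed_markers,
    percentile_normalize,
)

logger = logging.getLogger("cytostitch")

__all__ = [
    "PipelineConfig",
    "load_expression_table",
    "save_expression_table",
    "load_panel_design",
    "load_gates",
    "run_pipeline",
]


def load_panel_design(path) -> PanelDesign:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return PanelDesign.from_dict(doc)


def load_gates(path) -> list[GateDef]:
    """Gate documents: list of {name, parent?, predicates: [{marker, relation, threshold}]}."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    gates = []
    for entry in doc:
        preds = [
            GatePredicate(
                p["marker"],
                p["relation"],
                tuple(p["threshold"]) if isinstance(p["threshold"], list) else p["threshold"],
            )
            for p in entry["predicates"]
        ]
        gates.append(GateDef(entry["name"], preds, parent=entry.get("parent")))
    return gates


def save_expression_table(table: ExpressionTable, path) -> None:
    path = Path(path)
    if path.suffix == ".parquet":
        table.data.reset_index().to_parquet(path, index=False)
    else:
        table.data.to_csv(path, index=True)


def load_expression_table(
    path, panel_design: PanelDesign, fmt: str | None = None
) -> ExpressionTable:
    """Load and validate a wide expression table (csv or parquet).

    Rows are canonicalized by sorting on cell_id; the NA pattern must
    match the design exactly (a value present for an off-panel screen
    marker is a schema violation, as is a missing measured value).
    """
    path = Path(path)
    fmt = fmt or ("parquet" if path.suffix == ".parquet" else "csv")
    if fmt == "parquet":
        df = pd.read_parquet(path)
        df = df.set_index("cell_id")
    elif fmt == "csv":
        df = pd.read_csv(path, index_col="cell_id")
    else:
        raise InputError(f"unknown format {fmt!r} (csv or parquet)")
    df = df.sort_index()
    return ExpressionTable(df, panel_design)  # validates


@dataclass
class PipelineConfig:
    """Configuration of a full stitch-select-gate run."""

    panel_design: PanelDesign
    table_path: str | None = None  # input table; None -> caller passes a table
    out_dir: str = "run"
    cofactor: float = 5.0
    percentile: float = 99.9
    min_fraction: float = 0.001
    positivity_thresholds: Mapping[str, float] | None = None
    k_micro: int = 400
    algorithm: str = "som"
    min_support: int = 5
    k_neighbors: int = 15
    resolution: float = 1.0
    alpha: float = 0.05
    n_subsample: int = 2000
    redundancy_cap: float = 0.8
    forced_markers: tuple[str, ...] = ()
    gates: Sequence[GateDef] | None = None
    gate_path: str | None = None
    seed: int = 0

    def stage_seeds(self) -> dict[str, int]:
        """Expand the root seed into independent per-stage seeds (< 2^31)."""
        names = ("micro", "meta", "differential", "reduced")
        state = np.random.SeedSequence(self.seed).generate_state(len(names))
        return {n: int(s % (2**31)) for n, s in zip(names, state)}

    def content_hash(self) -> str:
        doc = {
            k: (v.to_dict() if isinstance(v, PanelDesign) else v)
            for k, v in asdict(self).items()
            if k not in ("gates",)
        }
        blob = json.dumps(doc, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(
    config: PipelineConfig, table: ExpressionTable | None = None
) -> dict:
    """Run preprocess -> integrate -> differential -> select -> gate.

    Returns the manifest dict (also written to ``manifest.json`` in the
    run directory).  Reruns with an identical config and input are
    byte-identical.  A stage failure raises with the stage named; partial
    artifacts are kept on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()
    manifest: dict = {
        "version": __version__,
        "config_hash": config.content_hash(),
        "seeds": seeds,
        "stages": {},
        "artifacts": {},
    }
    stage = "load"
    try:
        if table is None:
            if config.table_path is None:
                raise InputError("config.table_path or an in-memory table required")
            table = load_expression_table(config.table_path, config.panel_design)

        stage = "preprocess"
        normalized, divisors = percentile_normalize(table, q=config.percentile)
        divisors.to_csv(out / "percentile_divisors.csv", header=True)
        logger.info("percentile normalization at q=%s", config.percentile)
        if config.positivity_thresholds is not None:
            detected, fractions = detect_expressed_markers(
                normalized, config.positivity_thresholds, config.min_fraction
            )
            fractions.to_csv(out / "positive_fractions.csv", header=True)
            marker_universe = sorted(
                detected - set(config.panel_design.conserved_markers)
            )
        else:
            detected = set(normalized.markers)
            marker_universe = list(config.panel_design.screen_markers)
        manifest["stages"]["preprocess"] = {
            "cofactor": config.cofactor,
            "percentile": config.percentile,
            "n_detected": len(detected),
        }

        stage = "integrate"
        micro = micro_cluster(
            normalized,
            config.panel_design.conserved_markers,
            k=config.k_micro,
            algorithm=config.algorithm,
            seed=seeds["micro"],
        )
        micro.assignments.to_csv(out / "micro_clusters.csv", header=True)
        profile = aggregate_medians(micro, normalized, min_support=config.min_support)
        profile.medians.to_csv(out / "cluster_medians.csv")
        profile.support.to_csv(out / "cluster_support.csv")
        meta = meta_cluster(
            profile,
            k_neighbors=config.k_neighbors,
            resolution=config.resolution,
            seed=seeds["meta"],
        )
        meta.labels.to_csv(out / "meta_clusters.csv", header=True)
        manifest["stages"]["integrate"] = {
            "k_micro": micro.k,
            "algorithm": config.algorithm,
            "n_meta": meta.n_meta,
        }

        stage = "select"
        cell_meta = meta.cell_labels(micro)
        corr = cluster_level_correlation(profile)
        corr.to_csv(out / "cluster_correlation.csv")
        metas = sorted(cell_meta.unique())
        diffs = []
        for i, a in enumerate(metas):
            for b in metas[i + 1 :]:
                # equal-subsample size limited by the thinnest measured
                # marker (screen markers are only on 1/K of each group)
                n_sub = config.n_subsample
                for g in (a, b):
                    cells = cell_meta.index[cell_meta == g]
                    counts = normalized.data.loc[cells, marker_universe].notna().sum()
                    n_sub = min(n_sub, int(counts.min()))
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    diffs.append(
                        ks_differential(
                            normalized,
                            cell_meta,
                            a,
                            b,
                            n_subsample=n_sub,
                            alpha=config.alpha,
                            seed=seeds["differential"],
                            markers=marker_universe,
                        )
                    )
        tidy = pd.concat(
            [
                d.table.assign(group_a=d.group_a, group_b=d.group_b)
                for d in diffs
            ],
            ignore_index=True,
        )
        tidy.to_csv(out / "differential.csv", index=False)
        selection = nominate_minimal_panel(
            diffs,
            corr,
            forced_markers=config.forced_markers,
            redundancy_cap=config.redundancy_cap,
        )
        (out / "selection.json").write_text(
            json.dumps(
                {"selected": selection.selected, "params": selection.params},
                indent=2,
                default=str,
            )
        )
        cm, ari, _ = validate_recapitulation(
            profile,
            selection,
            meta,
            k_neighbors=config.k_neighbors,
            resolution=config.resolution,
            seed=seeds["reduced"],
        )
        cm.to_csv(out / "recapitulation_confusion.csv")
        manifest["stages"]["select"] = {
            "n_selected": len(selection.selected),
            "recapitulation_ari": ari,
        }

        stage = "gate"
        gates = config.gates
        if gates is None and config.gate_path is not None:
            gates = load_gates(config.gate_path)
        if gates:
            calls = apply_gates(normalized, list(gates))
            calls.labels.to_csv(out / "population_calls.csv", header=True)
            gate_vs_meta, gate_ari = confusion_matrix(calls.labels, cell_meta)
            gate_vs_meta.to_csv(out / "gates_vs_meta_confusion.csv")
            manifest["stages"]["gate"] = {
                "n_gates": len(gates),
                "ari_vs_meta": gate_ari,
            }
    except Exception as exc:
        raise type(exc)(f"pipeline stage {stage!r} failed: {exc}") from exc

    for f in sorted(out.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["artifacts"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
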