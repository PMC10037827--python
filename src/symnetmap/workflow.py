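"""Configuration validation and end-to-end orchestration.

``run_all`` executes the full pipeline on an input directory in stage
order — structural constraint, functional connectivity, node selection,
graph properties, association statistics — persisting every intermediate
as CSV/JSON and recording a manifest with seeds, parameter echoes and
per-file checksums so deterministic stages can be replay-verified.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from ._errors import ConfigurationError
from .fc import build_fc_matrices
from .graph import auc_table, metric_curves, sparsity_grid
from .identify import GLMSpec, fit_symptom_glm, select_nodes
from .io import read_nodes, read_pheno, read_structural_dir, read_timeseries_dir
from .stats import group_tests, moderation_analysis, property_interaction_glm
from .structural import consensus_nodes

log = logging.getLogger("symnetmap")

__all__ = ["RunConfig", "RunManifest", "validate_config", "run_all"]

_DEFAULTS = {
    "fraction": 0.15,
    "consensus": 0.5,
    "alpha": 0.05,
    "selection_rule": "simple_slope",
    "smin": 0.15,
    "smax": 0.45,
    "step": 0.01,
    "n_null": 100,
    "n_boot": 5000,
    "seed": 0,
    "score": "avlt5",
    "group_col": "group",
    "reference": "HC",
    "moderation_x": "age",
}
_PATH_KEYS = ("phenotype", "timeseries_dir", "structural_dir", "nodes")
_REQUIRED = _PATH_KEYS + ("outdir",)


@dataclass(frozen=True)
class RunConfig:
    phenotype: Path
    timeseries_dir: Path
    structural_dir: Path
    nodes: Path
    outdir: Path
    fraction: float = 0.15
    consensus: float = 0.5
    alpha: float = 0.05
    selection_rule: str = "simple_slope"
    smin: float = 0.15
    smax: float = 0.45
    step: float = 0.01
    n_null: int = 100
    n_boot: int = 5000
    seed: int = 0
    score: str = "avlt5"
    group_col: str = "group"
    reference: str = "HC"
    moderation_x: str = "age"


@dataclass
class RunManifest:
    version: str
    config_hash: str
    seed: int
    stages: list = field(default_factory=list)
    checksums: dict = field(default_factory=dict)
    started: float = 0.0
    finished: float = 0.0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)


def validate_config(source) -> RunConfig:
    """Load and range-check a YAML/JSON/dict run configuration.

    All problems are collected and reported at once.
    """
    if isinstance(source, (str, Path)):
        raw = yaml.safe_load(Path(source).read_text())
        base = Path(source).parent
    else:
        raw = dict(source)
        base = Path(".")
    problems = []
    known = set(_DEFAULTS) | set(_REQUIRED)
    for key in raw:
        if key not in known:
            problems.append(f"unknown key {key!r}")
    for key in _REQUIRED:
        if key not in raw:
            problems.append(f"missing required key {key!r}")
    merged = {**_DEFAULTS, **{k: v for k, v in raw.items() if k in known}}
    for key in ("fraction", "consensus"):
        v = merged.get(key)
        if key in merged and not (isinstance(v, (int, float)) and 0 < v <= 1):
            problems.append(f"{key} must be in (0, 1], got {v!r}")
    if not (0 < merged["alpha"] < 1):
        problems.append(f"alpha must be in (0, 1), got {merged['alpha']!r}")
    if not (0 < merged["smin"] < merged["smax"] <= 1):
        problems.append("sparsity bounds need 0 < smin < smax <= 1")
    if merged["step"] <= 0:
        problems.append("step must be positive")
    if merged["n_null"] < 1:
        problems.append("n_null must be >= 1")
    if merged["n_boot"] < 1000:
        problems.append("n_boot must be >= 1000")
    paths = {}
    for key in _PATH_KEYS:
        if key in raw:
            p = Path(raw[key])
            if not p.is_absolute():
                p = base / p
            if not p.exists():
                problems.append(f"{key}: path does not exist: {p}")
            paths[key] = p
    if problems:
        raise ConfigurationError("; ".join(problems))
    outdir = Path(raw["outdir"])
    if not outdir.is_absolute():
        outdir = base / outdir
    cfg = RunConfig(outdir=outdir, **paths,
                    **{k: merged[k] for k in _DEFAULTS})
    log.info("validated config: %s", cfg)
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig) -> RunManifest:
    """Execute the five pipeline stages in order on one input directory.

    Stage failures abort with the stage name; every completed stage's
    outputs are already persisted under ``config.outdir``.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = hashlib.sha256(
        json.dumps(dataclasses.asdict(config), sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest = RunManifest(version=__version__, config_hash=cfg_hash,
                           seed=config.seed, started=time.time())

    pheno = read_pheno(config.phenotype)
    nodes = read_nodes(config.nodes)
    node_names = list(nodes["region"])
    seeds = list(nodes.loc[nodes.get("is_seed", False) == True, "region"])  # noqa: E712
    if not seeds:
        seeds = [n for n in node_names if n.startswith("HIP")]

    stage = "structural_constraint"
    try:
        structural = read_structural_dir(config.structural_dir)
        wm = {}
        for seed, maps in structural.items():
            table = consensus_nodes(maps, fraction=config.fraction,
                                    consensus=config.consensus)
            wm[seed] = table
            table.to_frame().to_csv(out / f"wm_connections_{seed}.csv")
        manifest.stages.append(stage)

        stage = "functional_connectivity"
        ts = read_timeseries_dir(config.timeseries_dir)
        fc = build_fc_matrices(ts, node_names)
        fc_dir = out / "fc"
        fc_dir.mkdir(exist_ok=True)
        for subject, mat in fc.items():
            mat.to_csv(fc_dir / f"{subject}.csv")
        manifest.stages.append(stage)

        stage = "network_identification"
        networks = {}
        for seed in seeds:
            hemi = seed.rsplit(".", 1)[-1]
            candidates = [r for r in wm[seed].connected_regions
                          if r.endswith(f".{hemi}") and r not in seeds]
            if not candidates:
                continue
            spec = GLMSpec(score=config.score,
                           pairs=tuple((seed, c) for c in candidates),
                           group_col=config.group_col, reference=config.reference,
                           alpha=config.alpha)
            fit = fit_symptom_glm(pheno, fc, spec)
            fit.terms.rename_axis("term").to_csv(out / f"glm_terms_{seed}.csv")
            net = select_nodes(fit, wm[seed], rule=config.selection_rule)
            networks[seed] = net
            (out / f"network_{seed}.json").write_text(json.dumps({
                "seed": net.seed, "hemisphere": net.hemisphere, "nodes": net.nodes,
                "selection_pvalues": net.selection_pvalues.to_dict(),
                "rule": net.rule, "warning": net.warning,
            }, indent=2))
        manifest.stages.append(stage)

        stage = "graph_properties"
        # graph analysis runs on the left-hemisphere network, the
        # symptom-defined network of interest
        left_seed = next((s for s in seeds if s.endswith(".L")), seeds[0])
        net_nodes = networks[left_seed].nodes if left_seed in networks else []
        grid = sparsity_grid(config.smin, config.smax, config.step)
        if len(net_nodes) >= 4:
            curves = {}
            for subject, mat in fc.items():
                sub = mat.loc[net_nodes, net_nodes]
                curves[subject] = metric_curves(sub, grid, n_null=config.n_null,
                                                rng_seed=config.seed)
            long = pd.concat(curves, names=["subject_id"]).reset_index()
            long.to_csv(out / "global_properties_curves.csv", index=False)
            aucs = auc_table(curves)
            aucs.to_csv(out / "global_properties_auc.csv")
        else:
            aucs = None
            log.warning("left network too small for graph analysis (%d nodes)",
                        len(net_nodes))
        manifest.stages.append(stage)

        stage = "association_stats"
        cont = [c for c in ("age", "ecog", config.score) if c in pheno.columns]
        cat = [c for c in ("sex",) if c in pheno.columns]
        group_tests(pheno, continuous=cont, categorical=cat,
                    group_col=config.group_col).to_csv(
            out / "group_comparisons.csv", index=False)
        if aucs is not None:
            metrics = [c for c in aucs.columns if not c.endswith("__coverage")]
            property_interaction_glm(
                pheno, aucs, config.score, group_col=config.group_col,
                reference=config.reference).to_csv(
                out / "property_glm.csv", index=False)
            moderator = "Eglobal" if "Eglobal" in metrics else metrics[0]
            mod = moderation_analysis(
                pheno[config.score], pheno[config.moderation_x],
                aucs[moderator].reindex(pheno.index),
                n_boot=config.n_boot, rng_seed=config.seed,
                names=(config.score, config.moderation_x, moderator))
            (out / "moderation.json").write_text(json.dumps({
                "dependent": mod.dependent, "independent": mod.independent,
                "moderator": mod.moderator,
                "interaction": mod.interaction,
                "interaction_std": mod.interaction_std,
                "interaction_p": mod.interaction_p,
                "ci": [mod.ci_low, mod.ci_high],
                "n_boot": mod.n_boot, "rng_seed": mod.rng_seed,
            }, indent=2))
        manifest.stages.append(stage)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    for f in sorted(out.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest.checksums[str(f.relative_to(out))] = _sha256(f)
    manifest.finished = time.time()
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
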