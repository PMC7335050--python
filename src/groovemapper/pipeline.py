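"""Config-driven orchestration of the analysis stages into one reproducible report.

Stages (all optional): ``csp`` -> ``map`` (groove enrichment), ``cluster``
(per-ensemble populations and site ranking), ``fit`` (steady-state K_D) and
``release``.  Reports are hash-stable apart from the timestamp; all
randomness derives from the single global seed by stage-indexed offsets.
"""

from __future__ import annotations

import difflib
import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Optional

import yaml

from . import __version__
from .assays import fit_steady_state, read_isotherm_csv, read_trace_csv, summarize_release
from .csp import TitrationSeries, classify_residues, profile_titration, read_peak_list
from .ensemble import (
    DEFAULT_EPSILON,
    average_linkage_cluster,
    compare_sites,
    default_mask,
    pairwise_rmsd,
    read_ensemble,
    top_population,
)
from .grooves import (
    default_grooves,
    groove_enrichment,
    grooves_from_yaml,
    load_structure,
    map_perturbations,
)

__all__ = ["RunConfig", "validate_config", "run", "report_hash"]

# stage-indexed seed offsets: deterministic, independent streams per stage
_SEED_OFFSETS = {"csp": 0, "map": 1, "cluster": 2, "fit": 3, "release": 4}

_SCHEMA: dict[str, dict[str, type | tuple]] = {
    "csp": {
        "apo": str,
        "points": dict,  # ratio -> path
        "noise_floor": (int, float),
        "tol_H": (int, float),
        "tol_N": (int, float),
    },
    "map": {
        "pdb": str,
        "chain": str,
        "grooves": str,  # optional YAML override
        "permutations": int,
    },
    "cluster": {
        "ensembles": dict,  # name -> path
        "epsilon": (int, float),
        "n_boot": int,
    },
    "fit": {
        "isotherms": dict,  # name -> path
        "with_offset": bool,
    },
    "release": {
        "traces": dict,  # condition -> list of paths
        "window": (int, float),
    },
}
_TOP_KEYS = {"seed", "outdir"} | set(_SCHEMA)
_REQUIRED: dict[str, list[str]] = {
    "csp": ["apo", "points"],
    "map": ["pdb"],
    "cluster": ["ensembles"],
    "fit": ["isotherms"],
    "release": ["traces"],
}


@dataclass
class RunConfig:
    seed: int = 0
    outdir: Path = Path("groovemapper_out")
    stages: dict[str, dict] = field(default_factory=dict)
    source: Optional[str] = None

    def stage_seed(self, stage: str) -> int:
        return int(self.seed) * 1000 + _SEED_OFFSETS[stage]


def _suggest(key: str, valid) -> str:
    close = difflib.get_close_matches(key, list(valid), n=1)
    return f" (did you mean {close[0]!r}?)" if close else ""


def validate_config(path: str | Path) -> RunConfig:
    """Parse and schema-check a YAML run config; unknown keys are errors."""
    path = Path(path)
    data = yaml.safe_load(path.read_text())
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    for key in data:
        if key not in _TOP_KEYS:
            raise ValueError(f"{path}: unknown config key {key!r}{_suggest(key, _TOP_KEYS)}")
    stages: dict[str, dict] = {}
    for stage, schema in _SCHEMA.items():
        if stage not in data:
            continue
        block = data[stage] or {}
        if not isinstance(block, dict):
            raise ValueError(f"{path}: stage {stage!r} must be a mapping")
        for key, value in block.items():
            if key not in schema:
                raise ValueError(
                    f"{path}: unknown key {key!r} in stage {stage!r}"
                    f"{_suggest(key, schema)}"
                )
            if not isinstance(value, schema[key]):
                raise ValueError(
                    f"{path}: key {key!r} in stage {stage!r} has wrong type "
                    f"({type(value).__name__})"
                )
        for req in _REQUIRED[stage]:
            if req not in block:
                raise ValueError(f"{path}: stage {stage!r} missing required key {req!r}")
        stages[stage] = dict(block)

    cfg = RunConfig(
        seed=int(data.get("seed", 0)),
        outdir=Path(data.get("outdir", "groovemapper_out")),
        stages=stages,
        source=str(path),
    )
    _check_paths(cfg)
    # defaults injected here so the report echoes effective parameters
    if "cluster" in cfg.stages:
        cfg.stages["cluster"].setdefault("epsilon", DEFAULT_EPSILON)
        cfg.stages["cluster"].setdefault("n_boot", 200)
    if "csp" in cfg.stages:
        cfg.stages["csp"].setdefault("noise_floor", 0.1)
    if "map" in cfg.stages:
        cfg.stages["map"].setdefault("permutations", 9999)
    if "fit" in cfg.stages:
        cfg.stages["fit"].setdefault("with_offset", False)
    if "release" in cfg.stages:
        cfg.stages["release"].setdefault("window", 0.1)
    return cfg


def _iter_config_paths(cfg: RunConfig):
    for stage, block in cfg.stages.items():
        for key, value in block.items():
            if key in ("apo", "pdb", "grooves"):
                yield value
            elif key in ("points", "ensembles", "isotherms"):
                yield from value.values()
            elif key == "traces":
                for paths in value.values():
                    yield from paths if isinstance(paths, list) else [paths]


def _check_paths(cfg: RunConfig) -> None:
    missing = [p for p in _iter_config_paths(cfg) if not Path(p).exists()]
    if missing:
        raise FileNotFoundError(f"config references missing files: {missing}")


def report_hash(report: dict) -> str:
    """SHA-256 of the canonical report JSON, timestamps excluded."""
    stripped = {k: v for k, v in report.items() if k != "generated_at"}
    blob = json.dumps(stripped, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def _run_csp(cfg: RunConfig, params: dict, report: dict, profile_holder: dict) -> dict:
    apo = read_peak_list(params["apo"])
    points = sorted((float(r), read_peak_list(p)) for r, p in params["points"].items())
    series = TitrationSeries(apo=apo, points=points)
    profile = classify_residues(
        profile_titration(
            series,
            noise_floor=float(params["noise_floor"]),
            tol_H=float(params.get("tol_H", 0.05)),
            tol_N=float(params.get("tol_N", 0.25)),
        )
    )
    profile.write(cfg.outdir / "csp")
    profile_holder["profile"] = profile
    return profile.summary()


def _run_map(cfg: RunConfig, params: dict, report: dict, profile_holder: dict) -> dict:
    profile = profile_holder.get("profile")
    if profile is None:
        raise RuntimeError("map stage requires the csp stage in the same run")
    structure = load_structure(params["pdb"], chain=params.get("chain"))
    grooves = (
        grooves_from_yaml(params["grooves"])
        if "grooves" in params
        else list(default_grooves())
    )
    mapping = map_perturbations(profile, structure, grooves)
    enrichment = groove_enrichment(
        mapping,
        n_permutations=int(params["permutations"]),
        seed=cfg.stage_seed("map"),
    )
    (cfg.outdir / "map").mkdir(parents=True, exist_ok=True)
    mapping.to_frame().to_csv(cfg.outdir / "map" / "groove_mapping.csv", index=False)
    enrichment.write(cfg.outdir / "map" / "enrichment.json")
    return enrichment.to_dict()


def _run_cluster(cfg: RunConfig, params: dict, report: dict, _holder: dict) -> dict:
    epsilon = float(params["epsilon"])
    summaries: dict[str, dict] = {}
    ensembles = {}
    outdir = cfg.outdir / "cluster"
    outdir.mkdir(parents=True, exist_ok=True)
    for name in sorted(params["ensembles"]):
        ens = read_ensemble(params["ensembles"][name])
        ensembles[name] = ens
        result = average_linkage_cluster(pairwise_rmsd(ens), epsilon)
        pop, medoid = top_population(result)
        summaries[name] = {**result.to_dict(), "top_population": pop, "medoid": medoid}
        with open(outdir / f"{name}_labels.csv", "w") as fh:
            fh.write("frame,cluster\n")
            for fid, lab in zip(ens.frame_ids, result.labels):
                fh.write(f"{fid},{int(lab)}\n")
    out: dict[str, Any] = {"epsilon": epsilon, "ensembles": summaries}
    if len(ensembles) >= 2:
        out["ranking"] = compare_sites(
            ensembles,
            epsilon=epsilon,
            n_boot=int(params["n_boot"]),
            seed=cfg.stage_seed("cluster"),
        )
        if out["ranking"]["warnings"]:
            report["warnings"].extend(out["ranking"]["warnings"])
    (outdir / "populations.json").write_text(
        json.dumps(out, indent=2, sort_keys=True, default=str) + "\n"
    )
    return out


def _run_fit(cfg: RunConfig, params: dict, report: dict, _holder: dict) -> dict:
    out = {}
    outdir = cfg.outdir / "fit"
    for name in sorted(params["isotherms"]):
        iso = read_isotherm_csv(params["isotherms"][name], analyte=name)
        fit = fit_steady_state(iso, with_offset=bool(params["with_offset"]))
        fit.write(outdir / f"{name}_fit.json")
        out[name] = fit.to_dict()
        if not fit.saturation_ok:
            report["warnings"].append(f"{name}: {fit.caveat}")
    return out


def _run_release(cfg: RunConfig, params: dict, report: dict, _holder: dict) -> dict:
    traces = []
    for condition, paths in params["traces"].items():
        for p in paths if isinstance(paths, list) else [paths]:
            traces.append(read_trace_csv(p, condition=condition))
    summaries = summarize_release(traces, window=float(params["window"]))
    outdir = cfg.outdir / "release"
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "release_summary.csv", "w") as fh:
        fh.write("condition,n_replicates,mean_percent,sd_percent,flagged\n")
        for s in summaries:
            sd = "" if s.sd_percent is None else f"{s.sd_percent:.6f}"
            fh.write(f"{s.condition},{s.n_replicates},{s.mean_percent:.6f},{sd},{s.flagged}\n")
    return {
        s.condition: {
            "n_replicates": s.n_replicates,
            "mean_percent": s.mean_percent,
            "sd_percent": s.sd_percent,
            "flagged": s.flagged,
        }
        for s in summaries
    }


_STAGE_RUNNERS = {
    "csp": _run_csp,
    "map": _run_map,
    "cluster": _run_cluster,
    "fit": _run_fit,
    "release": _run_release,
}
_STAGE_ORDER = ["csp", "map", "cluster", "fit", "release"]


def run(config: RunConfig) -> dict:
    """Execute configured stages in dependency order and write report.json/.md.

    A stage failure aborts the run naming the stage; outputs of completed
    stages are retained.
    """
    config.outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "package_version": __version__,
        "seed": config.seed,
        "config_source": config.source,
        "parameters": {k: _jsonable(v) for k, v in config.stages.items()},
        "stages": {},
        "warnings": [],
        "generated_at": datetime.now(timezone.utc).isoformat(),
    }
    holder: dict = {}
    for stage in _STAGE_ORDER:
        if stage not in config.stages:
            continue
        try:
            report["stages"][stage] = _STAGE_RUNNERS[stage](
                config, config.stages[stage], report, holder
            )
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    report["report_hash"] = report_hash(report)
    (config.outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=str) + "\n"
    )
    (config.outdir / "report.md").write_text(_render_markdown(report))
    return report


def _jsonable(value):
    if isinstance(value, Path):
        return str(value)
    if isinstance(value, dict):
        return {k: _jsonable(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_jsonable(v) for v in value]
    return value


def _render_markdown(report: dict) -> str:
    lines = [
        "# groovemapper run report",
        "",
        f"- package version: {report['package_version']}",
        f"- seed: {report['seed']}",
        f"- report hash: {report['report_hash']}",
        "",
    ]
    for stage, summary in report["stages"].items():
        lines.append(f"## {stage}")
        lines.append("")
        lines.append("```json")
        lines.append(json.dumps(summary, indent=2, sort_keys=True, default=str))
        lines.append("```")
        lines.append("")
    if report["warnings"]:
        lines.append("## warnings")
        lines.extend(f"- {w}" for w in report["warnings"])
        lines.append("")
    return "\n".join(lines)
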