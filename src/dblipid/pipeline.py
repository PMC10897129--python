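"""End-to-end screening pipeline: enumerate -> describe -> predict ->
simulate -> analyze, with a manifest for reproducibility.

The pipeline is deterministic given its config: every stochastic stage
takes an explicit seed from the config (there is no global default
randomness), and the manifest records package/library versions, seeds, and
SHA-256 digests of the written tables.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .building_blocks import Registry, default_registry, load_registry
from .descriptors import describe_library
from .enumerator import LibraryDesign, enumerate_library, library_to_dataframe
from .errors import ValidationError
from .rules import RuleConfig, screen_library
from .sar import analyze
from .synthetic_screen import ScreenParams, simulate


def default_config() -> dict:
    """The default study conditions: Libraries 1 and 2, default generator."""
    return {
        "seed": 0,
        "registry": None,  # None -> shipped default registry
        "designs": [
            {"amines": ["amine-1"], "epoxides": "all", "acyls": "all"},
            {"amines": "all", "epoxides": ["epoxide-10"], "acyls": ["acyl-8"]},
        ],
        "rules": {"d_max": 1.0},
        "screen": {},  # ScreenParams overrides
        "sar": {"invitro_threshold": 1e4},
    }


def _validate_config(config: dict) -> dict:
    if "seed" not in config:
        raise ValidationError("config missing required field 'seed'")
    merged = default_config()
    for key, value in config.items():
        if key not in merged:
            raise ValidationError(f"unknown config field {key!r}")
        merged[key] = value
    return merged


def _resolve_design(registry: Registry, spec: dict) -> LibraryDesign:
    def pick(field: str, blocks) -> list[str]:
        sel = spec.get(field, "all")
        return [b.id for b in blocks] if sel == "all" else list(sel)

    return LibraryDesign.of(
        pick("amines", registry.amines),
        pick("epoxides", registry.epoxides),
        pick("acyls", registry.acyl_chlorides),
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class PipelineResult:
    library: pd.DataFrame
    descriptors: pd.DataFrame
    verdicts: pd.DataFrame
    summary: dict
    records: pd.DataFrame
    report: object  # SARReport
    manifest: dict


def run_pipeline(config: dict, outdir: str | Path | None = None) -> PipelineResult:
    """Run every stage and (optionally) write the artifact bundle to disk."""
    import numpy
    import rdkit
    import scipy

    config = _validate_config(config)
    stages: list[str] = []

    # enumerate
    registry = (
        default_registry()
        if config["registry"] is None
        else load_registry(config["registry"])
    )
    designs = [_resolve_design(registry, d) for d in config["designs"]]
    seen: set[str] = set()
    lipidoids = []
    for design in designs:
        for lip in enumerate_library(registry, design):
            if lip.name not in seen:
                seen.add(lip.name)
                lipidoids.append(lip)
    library_df = library_to_dataframe(lipidoids)
    stages.append("enumerate")

    # describe
    desc_df = describe_library(lipidoids, registry)
    stages.append("describe")

    # predict
    rule_config = RuleConfig(**config["rules"])
    verdicts, summary = screen_library(registry, designs, rule_config)
    stages.append("predict")

    # simulate
    params = ScreenParams(seed=config["seed"], **config["screen"])
    candidates = verdicts[["name", "deviation", "total_carbons", "predicted_potent"]]
    records = simulate(candidates, params)
    stages.append("simulate")

    # analyze
    report = analyze(
        records, desc_df, threshold=config["sar"]["invitro_threshold"]
    )
    stages.append("analyze")

    manifest = {
        "package": "dblipid",
        "version": __version__,
        "versions": {
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "rdkit": rdkit.__version__,
        },
        "seed": config["seed"],
        "stages": stages,
        "n_candidates": summary.n_candidates,
        "summary": summary.as_dict(),
        "outputs": {},
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tables = {
            "library.csv": library_df,
            "descriptors.csv": desc_df,
            "verdicts.csv": verdicts,
            "screen_records.csv": records,
        }
        for fname, df in tables.items():
            path = outdir / fname
            df.to_csv(path, index=False)
            manifest["outputs"][fname] = _sha256(path)
        report_path = report.to_json(outdir / "sar_report.json")
        manifest["outputs"]["sar_report.json"] = _sha256(report_path)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return PipelineResult(
        library=library_df,
        descriptors=desc_df,
        verdicts=verdicts,
        summary=summary.as_dict(),
        records=records,
        report=report,
        manifest=manifest,
    )
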