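"""End-to-end analysis configuration and report bundle.

``run_report`` ties the modules together: read scores, build the ROC
curve, lay the requested isolines and success region over it, judge
compliance (with and without bootstrap), select thresholds, and write
everything as plain CSV/JSON plus a human-readable summary.  All JSON
payloads carry a ``schema_version`` and, next to the full-precision
numbers, a ``display`` block rounded to the report precision (3 decimal
places by default, round-half-to-even).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bootstrap import compliance_with_ci
from .data import LabeledScores, read_scores
from .isolines import (
    IsoLine,
    PredictiveCriteria,
    equi_npv_line,
    equi_ppv_line,
    roc_meets_criteria,
    success_region,
)
from .roc import empirical_roc, write_roc_csv
from .thresholds import (
    closest_corner_threshold,
    select_rule_in_threshold,
    select_rule_out_threshold,
    youden_threshold,
)

SCHEMA_VERSION = 1

__all__ = ["AnalysisConfig", "run_report", "load_config", "save_config"]


@dataclass
class AnalysisConfig:
    """Flat configuration for one analysis run."""

    input_path: str
    output_dir: str
    prevalence: float
    ppv_c: float | None = None
    npv_c: float | None = None
    sn_min: float | None = None
    sp_min: float | None = None
    bootstrap: int = 0  # 0 disables the bootstrap
    level: float = 0.95
    seed: int | None = None
    precision: int = 3

    def criteria(self) -> PredictiveCriteria:
        return PredictiveCriteria(
            self.prevalence,
            ppv_c=self.ppv_c,
            npv_c=self.npv_c,
            sn_min=self.sn_min,
            sp_min=self.sp_min,
        )


_CONFIG_TYPES = {
    "input_path": str,
    "output_dir": str,
    "prevalence": float,
    "ppv_c": float,
    "npv_c": float,
    "sn_min": float,
    "sp_min": float,
    "bootstrap": int,
    "level": float,
    "seed": int,
    "precision": int,
}


def save_config(config: AnalysisConfig, path: str | Path) -> None:
    """Write the config as flat ``key = value`` text (lossless round-trip)."""
    lines = []
    for f in dataclasses.fields(config):
        v = getattr(config, f.name)
        if v is not None:
            lines.append(f"{f.name} = {v!r}" if isinstance(v, str) else f"{f.name} = {v}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_config(path: str | Path) -> AnalysisConfig:
    """Read a flat key = value config file."""
    kwargs = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, value = line.partition("=")
        key = key.strip()
        value = value.strip().strip("'\"")
        if key not in _CONFIG_TYPES:
            raise ValueError(f"unknown config key {key!r}")
        kwargs[key] = _CONFIG_TYPES[key](value)
    return AnalysisConfig(**kwargs)


def _display(value, precision: int):
    if isinstance(value, dict):
        return {k: _display(v, precision) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_display(v, precision) for v in value]
    if isinstance(value, float):
        return round(value, precision)
    return value


def _json_payload(body: dict, precision: int) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "generator": f"rocpv {__version__}",
        **body,
        "display": _display(body, precision),
    }


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_json(body: dict, path: str | Path, precision: int = 3) -> None:
    Path(path).write_text(
        json.dumps(_json_payload(body, precision), indent=2, cls=_NumpyEncoder, allow_nan=True)
        + "\n"
    )


def _isoline_rows(line: IsoLine, n: int = 51) -> pd.DataFrame:
    xs = np.linspace(line.start[0], line.end[0], n)
    ys = line.y_at(xs)
    return pd.DataFrame({"kind": line.kind, "x": xs, "y": ys})


def geometry_tables(criteria: PredictiveCriteria):
    """Isoline segments and region vertices as (DataFrame, dict)."""
    frames = []
    lines = {}
    if criteria.ppv_c is not None:
        line = equi_ppv_line(criteria.ppv_c, criteria.p)
        frames.append(_isoline_rows(line))
        lines["equi_ppv"] = dataclasses.asdict(line)
    if criteria.npv_c is not None:
        line = equi_npv_line(criteria.npv_c, criteria.p)
        frames.append(_isoline_rows(line))
        lines["equi_npv"] = dataclasses.asdict(line)
    region = success_region(criteria)
    verts = [list(v) for v in region.vertices]
    if verts:
        frames.append(
            pd.DataFrame(
                {"kind": "region-vertex", "x": [v[0] for v in verts], "y": [v[1] for v in verts]}
            )
        )
    table = pd.concat(frames, ignore_index=True)
    geom = {
        "criteria": {
            "prevalence": criteria.p,
            "ppv_c": criteria.ppv_c,
            "npv_c": criteria.npv_c,
            "sn_min": criteria.sn_min,
            "sp_min": criteria.sp_min,
        },
        "isolines": lines,
        "region_vertices": verts,
        "region_empty": region.is_empty,
    }
    return table, geom


def _compliance_body(report) -> dict:
    return {
        "meets": report.meets,
        "meets_rule_in": report.meets_rule_in,
        "meets_rule_out": report.meets_rule_out,
        "best_ppv": report.best_ppv,
        "best_npv": report.best_npv,
        "crossings": [list(c) for c in report.crossings],
        "segments_inside": [[list(a), list(b)] for a, b in report.segments_inside],
    }


def run_report(config: AnalysisConfig, data: LabeledScores | None = None) -> dict:
    """Run the full analysis and write the report bundle.

    Returns a dict of output paths.  ``data`` may be passed directly to
    bypass file input (used by the CLI's simulate-and-report path).
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    if data is None:
        data = read_scores(config.input_path)
    criteria = config.criteria()
    curve = empirical_roc(data)
    paths = {}

    paths["roc"] = outdir / "roc.csv"
    write_roc_csv(curve, paths["roc"])

    table, geom = geometry_tables(criteria)
    paths["isolines"] = outdir / "isolines.csv"
    table.to_csv(paths["isolines"], index=False)
    paths["geometry"] = outdir / "geometry.json"
    write_json(geom, paths["geometry"], config.precision)

    report = roc_meets_criteria(curve, criteria)
    comp_body = {
        "point_estimate": _compliance_body(report),
        "auroc": curve.auroc,
        "n_cases": data.n_cases,
        "n_controls": data.n_controls,
        "sample_case_fraction": data.sample_case_fraction,
    }
    if config.bootstrap:
        ci = compliance_with_ci(
            data,
            criteria,
            n_boot=config.bootstrap,
            level=config.level,
            seed=config.seed,
        )
        comp_body["bootstrap"] = {
            "verdict": ci.verdict,
            "replicate_fraction": ci.replicate_fraction,
            "n_boot": ci.band.n_boot,
            "level": ci.band.level,
            "seed": ci.band.seed,
            "lower_meets": ci.lower_meets,
            "upper_meets": ci.upper_meets,
        }
        paths["band"] = outdir / "band.csv"
        pd.DataFrame(
            {
                "sp": ci.band.sp_grid,
                "sn_lo": ci.band.sn_lower,
                "sn_hat": ci.band.sn_point,
                "sn_hi": ci.band.sn_upper,
            }
        ).to_csv(paths["band"], index=False)
    paths["compliance"] = outdir / "compliance.json"
    write_json(comp_body, paths["compliance"], config.precision)

    choices = {}
    if criteria.ppv_c is not None:
        choices["rule_in"] = select_rule_in_threshold(data, criteria).as_dict()
    if criteria.npv_c is not None:
        choices["rule_out"] = select_rule_out_threshold(data, criteria).as_dict()
    choices["youden"] = youden_threshold(data, criteria.p).as_dict()
    choices["closest_corner"] = closest_corner_threshold(data, criteria.p).as_dict()
    paths["thresholds"] = outdir / "thresholds.json"
    write_json({"thresholds": choices}, paths["thresholds"], config.precision)

    prec = config.precision
    lines = [
        "rocpv report",
        f"input: {config.input_path}",
        f"n = {len(data)} ({data.n_cases} cases / {data.n_controls} controls; "
        f"sample case fraction {data.sample_case_fraction:.{prec}f} — not the prevalence)",
        f"prevalence (user-supplied): {criteria.p}",
        f"AUROC = {curve.auroc:.{prec}f}",
        f"criteria: PPV>={criteria.ppv_c} NPV>={criteria.npv_c} "
        f"Sn>={criteria.sn_min} Sp>={criteria.sp_min}",
        f"meets criteria: {report.meets}",
        f"best PPV along curve: {report.best_ppv:.{prec}f}; "
        f"best NPV: {report.best_npv:.{prec}f}",
    ]
    if config.bootstrap:
        lines.append(
            f"bootstrap verdict: {comp_body['bootstrap']['verdict']} "
            f"(replicate fraction {comp_body['bootstrap']['replicate_fraction']:.{prec}f})"
        )
    paths["summary"] = outdir / "summary.txt"
    paths["summary"].write_text("\n".join(lines) + "\n")
    return paths
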