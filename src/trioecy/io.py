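"""Readers and writers for the shared delimited table formats.

Canonical dialect is tab-separated text with a single header row;
comma-separated files are accepted on read via sniffing. Validation
errors carry the offending row number.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Dict, List, Optional, Sequence, Union

import pandas as pd
import yaml

from .crosses import CrossType
from .inference import CrossRecord, MapFitResult
from .survey import PopulationRecord

__all__ = [
    "read_cross_table",
    "write_cross_table",
    "read_survey_table",
    "write_survey_table",
    "load_config",
    "write_manifest",
    "write_map_fit",
]

PathLike = Union[str, Path]

CROSS_COLUMNS = [
    "cross_id",
    "mother_id",
    "father_id",
    "cross_type",
    "n_male",
    "n_sterile_male",
    "n_female",
    "n_hermaphrodite",
]

SURVEY_COLUMNS = [
    "population_id",
    "latitude",
    "longitude",
    "n_male",
    "n_sterile_male",
    "n_female",
    "n_hermaphrodite",
    "area",
]


def _read_table(path: PathLike, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def _id_str(value: Any) -> str:
    """Identifier cell as a string; blank cells stay empty."""
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return ""
    return str(value)


def read_cross_table(path: PathLike) -> List[CrossRecord]:
    """Read a cross progeny table (one row per cross family).

    All rows are loaded; the minimum-family-size analysis filter is
    applied downstream via :meth:`CrossRecord.eligible`.
    """
    required = [
        "cross_id", "cross_type",
        "n_male", "n_sterile_male", "n_female", "n_hermaphrodite",
    ]
    df = _read_table(path, required)
    records = []
    for pos, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(
                CrossRecord(
                    cross_id=str(row.cross_id),
                    cross_type=CrossType(row.cross_type),
                    n_male=int(row.n_male),
                    n_sterile_male=int(row.n_sterile_male),
                    n_female=int(row.n_female),
                    n_hermaphrodite=int(row.n_hermaphrodite),
                    mother_id=_id_str(getattr(row, "mother_id", "")),
                    father_id=_id_str(getattr(row, "father_id", "")),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}, row {pos}: {exc}") from exc
    return records


def write_cross_table(records: Sequence[CrossRecord], path: PathLike) -> None:
    rows = [
        {
            "cross_id": r.cross_id,
            "mother_id": r.mother_id,
            "father_id": r.father_id,
            "cross_type": r.cross_type.value,
            "n_male": r.n_male,
            "n_sterile_male": r.n_sterile_male,
            "n_female": r.n_female,
            "n_hermaphrodite": r.n_hermaphrodite,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=CROSS_COLUMNS).to_csv(path, sep="\t", index=False)


def read_survey_table(path: PathLike) -> List[PopulationRecord]:
    """Read a population survey table (one row per population)."""
    required = [
        "population_id",
        "n_male", "n_sterile_male", "n_female", "n_hermaphrodite",
    ]
    df = _read_table(path, required)

    def _opt(row: Any, name: str) -> Optional[float]:
        v = getattr(row, name, None)
        if v is None or pd.isna(v):
            return None
        return float(v)

    records = []
    for pos, row in enumerate(df.itertuples(index=False), start=2):
        try:
            region = getattr(row, "region", None)
            records.append(
                PopulationRecord(
                    population_id=str(row.population_id),
                    n_male=int(row.n_male),
                    n_sterile_male=int(row.n_sterile_male),
                    n_female=int(row.n_female),
                    n_hermaphrodite=int(row.n_hermaphrodite),
                    latitude=_opt(row, "latitude"),
                    longitude=_opt(row, "longitude"),
                    area=_opt(row, "area"),
                    region=None if region is None or pd.isna(region) else str(region),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}, row {pos}: {exc}") from exc
    return records


def write_survey_table(records: Sequence[PopulationRecord], path: PathLike) -> None:
    rows = [
        {
            "population_id": r.population_id,
            "latitude": r.latitude,
            "longitude": r.longitude,
            "n_male": r.n_male,
            "n_sterile_male": r.n_sterile_male,
            "n_female": r.n_female,
            "n_hermaphrodite": r.n_hermaphrodite,
            "area": r.area,
            "region": r.region,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=SURVEY_COLUMNS + ["region"]).to_csv(
        path, sep="\t", index=False
    )


def load_config(path: PathLike) -> Dict[str, Any]:
    """Load a YAML or JSON configuration file into a dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text) or {}


def write_manifest(
    path: PathLike,
    command: str,
    inputs: Dict[str, Any],
    parameters: Dict[str, Any],
    seed: Optional[int] = None,
) -> None:
    """Write a JSON manifest sufficient to reproduce a run."""
    from . import __version__

    manifest = {
        "tool": "trioecy",
        "version": __version__,
        "command": command,
        "inputs": inputs,
        "parameters": parameters,
        "seed": seed,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")


def write_map_fit(result: MapFitResult, outdir: PathLike) -> None:
    """Export a map fit: summary JSON, per-cross scenario table, and the
    full C_LLR grid surface as delimited text."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary = {
        "best_r12": result.best_r12,
        "best_r23": result.best_r23,
        "c_llr": result.c_llr,
        "weight_mode": result.weight_mode,
    }
    (outdir / "map_fit_summary.json").write_text(
        json.dumps(summary, indent=2) + "\n"
    )
    rows = [
        {
            "cross_id": cid,
            "scenario": fit.scenario.label,
            "p_male": fit.expected.p_male,
            "p_sterile_male": fit.expected.p_sterile_male,
            "p_female": fit.expected.p_female,
            "p_hermaphrodite": fit.expected.p_hermaphrodite,
            "llr": fit.llr,
            "p_value": fit.p_value,
        }
        for cid, fit in result.per_cross_best.items()
    ]
    pd.DataFrame(rows).to_csv(outdir / "per_cross_scenarios.tsv", sep="\t", index=False)
    surface = pd.DataFrame(
        result.c_llr_surface,
        index=pd.Index(result.r12_grid, name="r12"),
        columns=pd.Index(result.r23_grid, name="r23"),
    )
    surface.to_csv(outdir / "c_llr_surface.tsv", sep="\t")
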