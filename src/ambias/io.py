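"""Delimited-text readers/writers, schema validation and run manifests.

All tables are comma-separated UTF-8 with a header row and '.' decimal
separator.  RTs are stored in decimal milliseconds so write-then-read round
trips are exact.  A missing response (e.g. the RT of an omission) is an
empty field.  Every pipeline run writes a JSON manifest echoing the
configuration, per-stage row counts and content digests of the outputs.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from importlib import metadata
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .design import ParadigmDesign
from .simulate import CohortConfig, CohortDataset

__all__ = [
    "TableValidationError",
    "SCHEMAS",
    "load_trial_data",
    "write_table",
    "write_cohort",
    "read_cohort",
    "cohort_config_from_dict",
    "cohort_config_to_dict",
    "write_manifest",
]


class TableValidationError(ValueError):
    """Raised when a delimited table fails schema validation."""


@dataclasses.dataclass(frozen=True)
class TableSchema:
    name: str
    columns: tuple[tuple[str, str], ...]  # (column, kind); kind in str/int/float/bool/float?
    key: tuple[str, ...]


SCHEMAS: dict[str, TableSchema] = {
    "dotprobe": TableSchema(
        name="dotprobe",
        columns=(
            ("participant_id", "str"),
            ("block_index", "int"),
            ("block_type", "str"),
            ("trial_index", "int"),
            ("pair_id", "str"),
            ("pain_word_position", "str"),
            ("probe_position", "str"),
            ("congruent", "bool"),
            ("contingency", "str"),
            ("correct", "bool"),
            ("rt_ms", "float"),
        ),
        key=("participant_id", "block_index", "trial_index"),
    ),
    "rir": TableSchema(
        name="rir",
        columns=(
            ("participant_id", "str"),
            ("tone_index", "int"),
            ("onset_ms", "int"),
            ("episode_index", "int"),
            ("pain", "bool"),
            ("response_class", "str"),
            ("rt_ms", "float?"),
        ),
        key=("participant_id", "tone_index"),
    ),
    "participants": TableSchema(
        name="participants",
        columns=(
            ("participant_id", "str"),
            ("gender", "str"),
            ("age", "float"),
            ("training_order", "str"),
            ("list_order", "str"),
            ("pain_first", "bool"),
            ("pain_threshold_c", "float"),
            ("pain_tolerance_c", "float"),
        ),
        key=("participant_id",),
    ),
}


def _convert_column(raw: pd.Series, kind: str, errors: list[str], col: str) -> pd.Series:
    if kind == "str":
        return raw.astype(str)
    if kind == "bool":
        mapped = raw.map({"True": True, "False": False})
        bad = mapped.isna() & (raw != "")
        for row in raw.index[bad]:
            errors.append(f"row {row + 2}: column {col!r}: {raw[row]!r} is not a boolean")
        return mapped
    # float() is correctly rounded, so written values read back bit-exact
    parsed: list[float] = []
    for row, value in zip(raw.index, raw):
        if value == "":
            parsed.append(np.nan)
            continue
        try:
            parsed.append(float(value))
        except ValueError:
            parsed.append(np.nan)
            errors.append(f"row {row + 2}: column {col!r}: {value!r} is not numeric")
    numeric = pd.Series(parsed, index=raw.index, dtype=float)
    if kind == "float?":
        return numeric.astype(float)
    empty = raw == ""
    for row in raw.index[empty]:
        errors.append(f"row {row + 2}: column {col!r} is required but empty")
    if kind == "int":
        frac = numeric.notna() & (numeric != numeric.round())
        for row in raw.index[frac]:
            errors.append(f"row {row + 2}: column {col!r}: {raw[row]!r} is not an integer")
        return numeric.round().astype("Int64")
    return numeric.astype(float)


def load_trial_data(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate a trial table against a named schema.

    Row-level problems (unparseable values, missing required fields,
    duplicate keys) are collected and reported together; unknown or missing
    columns fail immediately.  Row numbers in messages are 1-based file
    lines (header = line 1).
    """
    if schema not in SCHEMAS:
        raise TableValidationError(f"unknown schema {schema!r}; have {sorted(SCHEMAS)}")
    spec = SCHEMAS[schema]
    path = Path(path)
    if not path.exists():
        raise TableValidationError(f"file not found: {path}")
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise TableValidationError(f"{path}: malformed CSV: {exc}") from exc
    expected = [c for c, _ in spec.columns]
    unknown = [c for c in raw.columns if c not in expected]
    absent = [c for c in expected if c not in raw.columns]
    if unknown or absent:
        raise TableValidationError(
            f"{path}: header mismatch for schema {schema!r}; "
            f"unknown columns {unknown}, missing columns {absent}"
        )
    errors: list[str] = []
    out = pd.DataFrame(index=raw.index)
    for col, kind in spec.columns:
        out[col] = _convert_column(raw[col], kind, errors, col)
    dup = out.duplicated(subset=list(spec.key), keep=False)
    if dup.any():
        keys = out.loc[dup, list(spec.key)].drop_duplicates().head(5)
        errors.append(
            f"duplicate {spec.key} keys, e.g. {keys.to_dict(orient='records')}"
        )
    if errors:
        raise TableValidationError(f"{path}: " + "; ".join(errors[:20]))
    for col, kind in spec.columns:
        if kind == "int":
            out[col] = out[col].astype(np.int64)
        elif kind == "bool":
            out[col] = out[col].astype(bool)
    return out


def write_table(df: pd.DataFrame, path: str | Path, schema: str | None = None) -> Path:
    """Write a table in the package dialect (CSV, UTF-8, header row)."""
    path = Path(path)
    if schema is not None:
        cols = [c for c, _ in SCHEMAS[schema].columns]
        df = df[cols]
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def cohort_config_to_dict(config: CohortConfig) -> dict:
    d = dataclasses.asdict(config)
    d["design"]["list_order"] = list(d["design"]["list_order"])
    d["rir_interval_values_ms"] = list(d["rir_interval_values_ms"])
    return d


def cohort_config_from_dict(d: Mapping) -> CohortConfig:
    d = dict(d)
    design = d.pop("design", None)
    kwargs = dict(d)
    if design is not None:
        design = dict(design)
        if "list_order" in design:
            design["list_order"] = tuple(design["list_order"])
        kwargs["design"] = ParadigmDesign(**design)
    if "rir_interval_values_ms" in kwargs:
        kwargs["rir_interval_values_ms"] = tuple(kwargs["rir_interval_values_ms"])
    return CohortConfig(**kwargs)


def write_cohort(dataset: CohortDataset, outdir: str | Path) -> dict[str, Path]:
    """Write a simulated cohort as delimited tables plus JSON sidecars."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["dotprobe"] = write_table(dataset.dotprobe, outdir / "dotprobe_trials.csv", "dotprobe")
    paths["participants"] = write_table(
        dataset.participants, outdir / "participants.csv", "participants"
    )
    paths["questionnaire_items"] = write_table(
        dataset.questionnaire_items, outdir / "questionnaire_items.csv"
    )
    if dataset.rir is not None:
        paths["rir"] = write_table(dataset.rir, outdir / "rir_trials.csv", "rir")
        (outdir / "rir_schedule.json").write_text(json.dumps(dataset.rir_meta, indent=2))
        paths["rir_schedule"] = outdir / "rir_schedule.json"
    truth_path = outdir / "ground_truth.json"
    truth_path.write_text(
        json.dumps(
            {
                "config": cohort_config_to_dict(dataset.config),
                "participants": dataset.truth.to_dict(orient="records"),
            },
            indent=2,
        )
    )
    paths["ground_truth"] = truth_path
    return paths


def read_cohort(outdir: str | Path) -> dict:
    """Read back a cohort directory written by :func:`write_cohort`."""
    outdir = Path(outdir)
    out: dict = {
        "dotprobe": load_trial_data(outdir / "dotprobe_trials.csv", "dotprobe"),
        "participants": load_trial_data(outdir / "participants.csv", "participants"),
        "questionnaire_items": pd.read_csv(outdir / "questionnaire_items.csv"),
    }
    rir_path = outdir / "rir_trials.csv"
    if rir_path.exists():
        out["rir"] = load_trial_data(rir_path, "rir")
        out["rir_meta"] = json.loads((outdir / "rir_schedule.json").read_text())
    truth_path = outdir / "ground_truth.json"
    if truth_path.exists():
        payload = json.loads(truth_path.read_text())
        out["truth"] = pd.DataFrame(payload["participants"])
        out["config"] = cohort_config_from_dict(payload["config"])
    return out


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(
    outdir: str | Path,
    config: Mapping,
    outputs: Mapping[str, Path],
    counts: Mapping[str, int] | None = None,
) -> Path:
    """Write the run manifest: config echo, row counts, output digests."""
    outdir = Path(outdir)
    try:
        version = metadata.version("ambias")
    except metadata.PackageNotFoundError:  # pragma: no cover
        version = "unknown"
    manifest = {
        "package_version": version,
        "config": dict(config),
        "counts": dict(counts or {}),
        "outputs": {
            name: {"path": str(Path(p).name), "sha256": _digest(Path(p))}
            for name, p in sorted(outputs.items())
        },
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
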