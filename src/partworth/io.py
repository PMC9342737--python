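"""File interchange: CSV schemas, XLSX replication input, run manifests.

All tabular artifacts are UTF-8 CSV with a header row:

* design:     profile_id + one column per attribute (level labels)
* allocation: respondent_id, position, profile_id
* responses:  respondent_id, position, profile_id, monitoring, sglt2,
              lisinopril_increase, ibuprofen_replace

Deposited spreadsheets (XLSX) are accepted read-only through a
column-mapping config that renames columns and recodes outcome values to
the canonical schema; the mapping can also name per-attribute level columns
when the file carries profile levels instead of profile ids.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from datetime import datetime, timezone
from pathlib import Path
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .attributes import (
    AttributeSpec,
    Profile,
    SpecError,
    frame_to_profiles,
    profiles_to_frame,
)
from .allocate import AllocationPlan
from .simulate import OUTCOMES, RESPONSE_COLUMNS


class SchemaError(ValueError):
    """A file does not match its documented schema."""


# ---------------------------------------------------------------------------
# design / allocation / response tables


def write_design(profiles: Sequence[Profile], attrs: Sequence[AttributeSpec], path: str | Path) -> None:
    profiles_to_frame(profiles, attrs).to_csv(path, index=False)


def read_design(path: str | Path, attrs: Sequence[AttributeSpec]) -> list[Profile]:
    return frame_to_profiles(pd.read_csv(path), attrs)


def write_allocation(plan: AllocationPlan, path: str | Path) -> None:
    plan.to_frame().to_csv(path, index=False)


def read_allocation(path: str | Path) -> AllocationPlan:
    return AllocationPlan.from_frame(pd.read_csv(path))


def write_responses(responses: pd.DataFrame, path: str | Path) -> None:
    validate_responses(responses)
    responses.to_csv(path, index=False)


def read_responses(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    validate_responses(df)
    return df


def validate_responses(df: pd.DataFrame) -> None:
    """Check the response schema; errors carry row/column context."""
    required = [c for c in RESPONSE_COLUMNS if c != "position"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"response table missing columns: {missing}")
    bad = ~df["monitoring"].isin(["increase", "maintain", "decrease"]) & df["monitoring"].notna()
    if bad.any():
        i = df.index[bad][0]
        raise SchemaError(
            f"row {i}, column 'monitoring': unknown label {df.loc[i, 'monitoring']!r}"
        )
    for col in OUTCOMES[1:]:
        bad = ~df[col].isin(["yes", "no"]) & df[col].notna()
        if bad.any():
            i = df.index[bad][0]
            raise SchemaError(
                f"row {i}, column {col!r}: unknown label {df.loc[i, col]!r}"
            )


# ---------------------------------------------------------------------------
# XLSX replication input


@dataclasses.dataclass
class ColumnMap:
    """Mapping from a deposited spreadsheet's layout to the canonical schema.

    ``columns`` maps canonical names (respondent_id, profile_id, monitoring,
    sglt2, lisinopril_increase, ibuprofen_replace) to source column names.
    ``values`` optionally recodes raw cell values per outcome column.
    ``attribute_columns`` (attribute name -> source column) is used when the
    file carries attribute levels instead of profile ids; profiles are then
    reconstructed by matching level labels.
    """

    columns: dict[str, str]
    values: dict[str, dict[str, str]] = dataclasses.field(default_factory=dict)
    attribute_columns: dict[str, str] = dataclasses.field(default_factory=dict)


def load_column_map(path: str | Path) -> ColumnMap:
    with Path(path).open() as fh:
        payload = yaml.safe_load(fh) if Path(path).suffix != ".json" else json.load(fh)
    return ColumnMap(
        columns=dict(payload.get("columns", {})),
        values={k: dict(v) for k, v in payload.get("values", {}).items()},
        attribute_columns=dict(payload.get("attribute_columns", {})),
    )


def read_responses_xlsx(
    path: str | Path,
    colmap: ColumnMap,
    attrs: Sequence[AttributeSpec],
    profiles: Sequence[Profile] | None = None,
) -> tuple[pd.DataFrame, list[Profile]]:
    """Read a deposited spreadsheet into the canonical response schema.

    Returns ``(responses, profiles)``.  If the mapping uses
    ``attribute_columns``, profiles are matched against ``profiles`` when
    given (by level assignment) or minted fresh otherwise.
    """
    raw = pd.read_excel(path)
    rename = {src: canon for canon, src in colmap.columns.items()}
    missing = [src for src in colmap.columns.values() if src not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: spreadsheet missing mapped columns {missing}")
    df = raw.rename(columns=rename)
    for col, mapping in colmap.values.items():
        if col in df.columns:
            df[col] = df[col].map(lambda v: mapping.get(v, v))
    if colmap.attribute_columns:
        missing = [src for src in colmap.attribute_columns.values() if src not in raw.columns]
        if missing:
            raise SchemaError(f"{path}: spreadsheet missing attribute columns {missing}")
        key_cols = [colmap.attribute_columns[a.name] for a in attrs if a.name in colmap.attribute_columns]
        if len(key_cols) != len(attrs):
            raise SchemaError("attribute_columns must cover every attribute")
        lookup: dict[tuple[str, ...], int] = {}
        out_profiles: list[Profile] = []
        if profiles is not None:
            for p in profiles:
                lookup[tuple(p.assignment[a.name] for a in attrs)] = p.profile_id
                out_profiles.append(p)
        pids = []
        for i, row in raw.iterrows():
            key = tuple(str(row[c]) for c in key_cols)
            if key not in lookup:
                if profiles is not None:
                    raise SchemaError(
                        f"row {i}: profile {key} not in the supplied design"
                    )
                pid = len(lookup)
                lookup[key] = pid
                out_profiles.append(
                    Profile(pid, {a.name: k for a, k in zip(attrs, key)})
                )
            pids.append(lookup[key])
        df["profile_id"] = pids
    else:
        if profiles is None:
            raise SpecError("profile-id mapped spreadsheets need a design catalog")
        out_profiles = list(profiles)
    keep = [c for c in RESPONSE_COLUMNS if c in df.columns]
    df = df[keep]
    validate_responses(df)
    return df.reset_index(drop=True), out_profiles


# ---------------------------------------------------------------------------
# manifests


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(
    outdir: str | Path,
    *,
    stage: str,
    seeds: Mapping[str, int | None] | None = None,
    inputs: Sequence[str | Path] = (),
    extra: Mapping[str, object] | None = None,
) -> Path:
    """Record versions, seeds and input digests so a stage can be re-run."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seeds": dict(seeds or {}),
        "inputs": {
            str(p): _digest(Path(p)) for p in inputs if Path(p).exists()
        },
    }
    if extra:
        manifest.update(extra)
    path = outdir / f"manifest_{stage}.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
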