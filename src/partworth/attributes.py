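"""Attribute and profile primitives for single-profile conjoint experiments.

A study is described by a list of :class:`AttributeSpec` objects, each with an
ordered set of level labels and a designated reference level used for
odds-ratio contrasts.  A :class:`Profile` is one hypothetical vignette: one
level chosen from every attribute.
"""

from __future__ import annotations

import dataclasses
import json
from collections.abc import Mapping, Sequence
from pathlib import Path

import pandas as pd
import yaml


class SpecError(ValueError):
    """An attribute specification or profile violates its invariants."""


@dataclasses.dataclass(frozen=True)
class AttributeSpec:
    """A named attribute with ordered levels.

    Parameters
    ----------
    name
        Attribute label, e.g. ``"egfr"``.
    levels
        Ordered level labels; display value plus any clinical annotation,
        e.g. ``"45 ml/min/1.73m^2 (moderately decreased)"``.
    reference_level
        Index of the level used as the contrast baseline for odds ratios.
    """

    name: str
    levels: tuple[str, ...]
    reference_level: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", tuple(self.levels))
        if not self.name:
            raise SpecError("attribute name must be non-empty")
        if len(self.levels) < 2:
            raise SpecError(
                f"attribute {self.name!r} needs >=2 levels, got {len(self.levels)}"
            )
        if len(set(self.levels)) != len(self.levels):
            raise SpecError(f"attribute {self.name!r} has duplicate level labels")
        if not 0 <= self.reference_level < len(self.levels):
            raise SpecError(
                f"attribute {self.name!r}: reference_level {self.reference_level} "
                f"out of range for {len(self.levels)} levels"
            )

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def reference(self) -> str:
        return self.levels[self.reference_level]

    def level_index(self, label: str) -> int:
        try:
            return self.levels.index(label)
        except ValueError:
            raise SpecError(
                f"attribute {self.name!r} has no level {label!r}"
            ) from None


@dataclasses.dataclass(frozen=True)
class Profile:
    """One hypothetical vignette: a chosen level for every attribute."""

    profile_id: int
    assignment: Mapping[str, str]

    def level_indices(self, attrs: Sequence[AttributeSpec]) -> tuple[int, ...]:
        """Level index per attribute, in attribute order."""
        out = []
        for a in attrs:
            if a.name not in self.assignment:
                raise SpecError(
                    f"profile {self.profile_id} missing attribute {a.name!r}"
                )
            out.append(a.level_index(self.assignment[a.name]))
        return tuple(out)


def validate_attributes(attrs: Sequence[AttributeSpec]) -> None:
    if not attrs:
        raise SpecError("attribute list must be non-empty")
    names = [a.name for a in attrs]
    if len(set(names)) != len(names):
        raise SpecError("attribute names must be unique")


def study_attributes() -> list[AttributeSpec]:
    """The six-attribute clinical vignette specification for the DKD study.

    PromarkerD (a blood-test risk score for incident diabetic kidney disease)
    has four levels including "no test"; the five clinical attributes have
    three levels each, giving a 4 x 3^5 = 972-profile full factorial.
    Reference levels are the first level of each attribute.
    """
    return [
        AttributeSpec(
            "promarkerd",
            ("No test", "Low risk", "Moderate risk", "High risk"),
        ),
        AttributeSpec(
            "albuminuria",
            (
                "15 mcg/mg (mildly increased)",
                "165 mcg/mg (moderately increased)",
                "500 mcg/mg (severely increased)",
            ),
        ),
        AttributeSpec(
            "egfr",
            (
                "110 ml/min/1.73m^2 (normal)",
                "75 ml/min/1.73m^2 (mildly decreased)",
                "45 ml/min/1.73m^2 (moderately decreased)",
            ),
        ),
        AttributeSpec(
            "blood_pressure",
            ("120/70 mmHg", "135/90 mmHg", "150/95 mmHg"),
        ),
        AttributeSpec("hba1c", ("6.3%", "7.5%", "8.4%")),
        AttributeSpec("age", ("48 years", "66 years", "83 years")),
    ]


# ---------------------------------------------------------------------------
# serialization


def save_attributes(attrs: Sequence[AttributeSpec], path: str | Path) -> None:
    """Write an attribute spec to YAML or JSON (chosen by file suffix)."""
    validate_attributes(attrs)
    payload = [
        {
            "name": a.name,
            "levels": list(a.levels),
            "reference_level": a.reference_level,
        }
        for a in attrs
    ]
    path = Path(path)
    with path.open("w") as fh:
        if path.suffix.lower() == ".json":
            json.dump(payload, fh, indent=2)
        else:
            yaml.safe_dump(payload, fh, sort_keys=False)


def load_attributes(path: str | Path) -> list[AttributeSpec]:
    """Read an attribute spec from YAML or JSON."""
    path = Path(path)
    with path.open() as fh:
        if path.suffix.lower() == ".json":
            payload = json.load(fh)
        else:
            payload = yaml.safe_load(fh)
    if not isinstance(payload, list):
        raise SpecError(f"{path}: expected a list of attribute entries")
    attrs = [
        AttributeSpec(
            name=entry["name"],
            levels=tuple(entry["levels"]),
            reference_level=int(entry.get("reference_level", 0)),
        )
        for entry in payload
    ]
    validate_attributes(attrs)
    return attrs


def profiles_to_frame(
    profiles: Sequence[Profile], attrs: Sequence[AttributeSpec]
) -> pd.DataFrame:
    """Tabulate profiles as one row each: profile_id plus one column per attribute."""
    rows = {
        "profile_id": [p.profile_id for p in profiles],
    }
    for a in attrs:
        rows[a.name] = [p.assignment[a.name] for p in profiles]
    return pd.DataFrame(rows)


def frame_to_profiles(
    df: pd.DataFrame, attrs: Sequence[AttributeSpec]
) -> list[Profile]:
    """Rebuild Profile objects from a design table, validating level labels."""
    validate_attributes(attrs)
    missing = [c for c in ["profile_id"] + [a.name for a in attrs] if c not in df.columns]
    if missing:
        raise SpecError(f"design table missing columns: {missing}")
    profiles = []
    for i, row in df.iterrows():
        assignment = {}
        for a in attrs:
            label = row[a.name]
            if label not in a.levels:
                raise SpecError(
                    f"row {i}: unknown level {label!r} for attribute {a.name!r}"
                )
            assignment[a.name] = label
        profiles.append(Profile(int(row["profile_id"]), assignment))
    ids = [p.profile_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise SpecError("duplicate profile_id in design table")
    return profiles
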