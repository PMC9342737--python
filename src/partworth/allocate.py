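"""Least-fill allocation of design profiles to respondents.

Each respondent is shown a fixed number of distinct profiles.  To keep
exposure even, every draw is made uniformly at random from the profiles that
have currently been shown the fewest times (excluding profiles the respondent
already holds), and show counts are updated after each draw.  This keeps the
spread of show counts across profiles at most one.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from collections.abc import Sequence

import numpy as np
import pandas as pd


class AllocationError(ValueError):
    """An allocation request is infeasible."""


@dataclasses.dataclass
class AllocationPlan:
    """respondent_id -> ordered list of profile_ids."""

    assignments: dict[int, list[int]]

    @property
    def show_counts(self) -> Counter[int]:
        counts: Counter[int] = Counter()
        for profs in self.assignments.values():
            counts.update(profs)
        return counts

    @property
    def n_respondents(self) -> int:
        return len(self.assignments)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (rid, pos + 1, pid)
            for rid, profs in self.assignments.items()
            for pos, pid in enumerate(profs)
        ]
        return pd.DataFrame(rows, columns=["respondent_id", "position", "profile_id"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AllocationPlan":
        missing = [
            c for c in ("respondent_id", "position", "profile_id") if c not in df.columns
        ]
        if missing:
            raise AllocationError(f"allocation table missing columns: {missing}")
        assignments: dict[int, list[int]] = {}
        ordered = df.sort_values(["respondent_id", "position"])
        for rid, grp in ordered.groupby("respondent_id", sort=True):
            assignments[int(rid)] = [int(p) for p in grp["profile_id"]]
        return cls(assignments)


def least_fill_assign(
    profile_ids: Sequence[int],
    n_respondents: int,
    per_respondent: int,
    seed: int | None = 0,
) -> AllocationPlan:
    """Allocate profiles to respondents by least fill.

    Respondents are processed in order (ids 1..n_respondents); within a
    respondent, each of the ``per_respondent`` draws picks uniformly among the
    currently least-shown profiles the respondent does not already hold.
    Final show counts satisfy max - min <= 1.
    """
    ids = np.asarray(list(profile_ids))
    if len(set(profile_ids)) != len(ids):
        raise AllocationError("profile_ids must be unique")
    if per_respondent > len(ids):
        raise AllocationError(
            f"per_respondent={per_respondent} exceeds design size {len(ids)}"
        )
    if n_respondents < 1 or per_respondent < 1:
        raise AllocationError("n_respondents and per_respondent must be >= 1")
    rng = np.random.default_rng(seed)
    counts = np.zeros(len(ids), dtype=int)
    assignments: dict[int, list[int]] = {}
    for rid in range(1, n_respondents + 1):
        taken = np.zeros(len(ids), dtype=bool)
        chosen: list[int] = []
        for _ in range(per_respondent):
            avail = ~taken
            m = counts[avail].min()
            pool = np.flatnonzero(avail & (counts == m))
            k = pool[rng.integers(len(pool))]
            taken[k] = True
            counts[k] += 1
            chosen.append(int(ids[k]))
        assignments[rid] = chosen
    return AllocationPlan(assignments)
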