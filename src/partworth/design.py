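"""Full-factorial enumeration, effects coding, D-efficiency and design search.

The design problem: from the full factorial of attribute-level combinations,
pick a small set of profiles whose effects-coded main-effects information
matrix loses as little determinant as possible relative to the full factorial.
The search is a Fedorov-style exchange: starting from a random subset, swap an
in-design profile for an out-of-design candidate whenever the swap increases
det(X'X), until no swap helps; repeat over random restarts and keep the best.

Relative D-efficiency of a candidate design ``Xc`` (Nc runs) against the full
factorial ``Xf`` (Nf runs) with p model columns is::

    D_rel = ( det(Xc'Xc / Nc) / det(Xf'Xf / Nf) ) ** (1/p)

which is 1 for the (possibly replicated) full factorial itself.
"""

from __future__ import annotations

import dataclasses
import itertools
from collections.abc import Sequence

import numpy as np

from .attributes import AttributeSpec, Profile, SpecError, validate_attributes


class DesignError(ValueError):
    """A design request is infeasible or inconsistent."""


@dataclasses.dataclass
class DesignMatrix:
    """Effects-coded numeric expansion of a profile catalog.

    ``X`` has one row per profile: an intercept column followed by L-1
    contrast columns per L-level attribute (entries in {-1, 0, 1}).
    ``column_map`` records, per column, the (attribute, level) it indicates;
    the intercept maps to (None, None).
    """

    X: np.ndarray
    columns: list[str]
    column_map: list[tuple[str | None, str | None]]
    profile_ids: list[int]

    @property
    def n_runs(self) -> int:
        return self.X.shape[0]

    @property
    def n_columns(self) -> int:
        return self.X.shape[1]


@dataclasses.dataclass
class DEfficiencyResult:
    value: float
    degenerate: bool
    log_det_candidate: float
    log_det_full: float


@dataclasses.dataclass
class BalanceReport:
    """Level-balance diagnostics for a profile set."""

    level_counts: dict[str, dict[str, int]]
    pair_counts: dict[tuple[str, str], np.ndarray]
    max_pair_deviation: float
    missing_levels: list[tuple[str, str]]


@dataclasses.dataclass
class FractionalDesign:
    """Result of the exchange search: chosen profiles plus diagnostics."""

    profiles: list[Profile]
    matrix: DesignMatrix
    d_efficiency: float
    restart_best: list[float]  # cumulative best D-efficiency after each restart
    seed: int | None
    diagnostics: BalanceReport


def enumerate_full_factorial(attrs: Sequence[AttributeSpec]) -> list[Profile]:
    """All possible profiles: the Cartesian product of attribute levels.

    Ordering is lexicographic by attribute order then level index, and
    profile ids run 0..N-1 in that order, so catalogs are reproducible.
    """
    validate_attributes(attrs)
    profiles = []
    for pid, combo in enumerate(
        itertools.product(*(range(a.n_levels) for a in attrs))
    ):
        assignment = {a.name: a.levels[idx] for a, idx in zip(attrs, combo)}
        profiles.append(Profile(pid, assignment))
    return profiles


def encode_effects(
    profiles: Sequence[Profile], attrs: Sequence[AttributeSpec]
) -> DesignMatrix:
    """Effects-code a profile catalog (zero-sum contrast per attribute).

    For an L-level attribute, levels 1..L-1 each get a unit indicator column
    and the last level is coded -1 in all of that attribute's columns, so the
    decoded per-level utilities sum to zero within each attribute.
    """
    validate_attributes(attrs)
    if not profiles:
        raise SpecError("cannot encode an empty profile list")
    columns = ["intercept"]
    column_map: list[tuple[str | None, str | None]] = [(None, None)]
    for a in attrs:
        for lvl in a.levels[:-1]:
            columns.append(f"{a.name}[{lvl}]")
            column_map.append((a.name, lvl))
    p = len(columns)
    X = np.zeros((len(profiles), p))
    X[:, 0] = 1.0
    # column offset of each attribute's first contrast column
    offsets = {}
    off = 1
    for a in attrs:
        offsets[a.name] = off
        off += a.n_levels - 1
    for i, prof in enumerate(profiles):
        for a, idx in zip(attrs, prof.level_indices(attrs)):
            o = offsets[a.name]
            if idx < a.n_levels - 1:
                X[i, o + idx] = 1.0
            else:
                X[i, o : o + a.n_levels - 1] = -1.0
    return DesignMatrix(
        X=X,
        columns=columns,
        column_map=column_map,
        profile_ids=[prof.profile_id for prof in profiles],
    )


def effects_decode_matrix(
    attrs: Sequence[AttributeSpec],
) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """Linear map from coefficient vector to per-level utilities.

    Returns ``(D, row_map)`` where ``D @ beta`` gives one utility per
    attribute level (rows ordered as attributes then levels); the last level
    of each attribute is the negative sum of the others.
    """
    validate_attributes(attrs)
    p = 1 + sum(a.n_levels - 1 for a in attrs)
    rows = []
    row_map = []
    off = 1
    for a in attrs:
        k = a.n_levels - 1
        for j, lvl in enumerate(a.levels):
            r = np.zeros(p)
            if j < k:
                r[off + j] = 1.0
            else:
                r[off : off + k] = -1.0
            rows.append(r)
            row_map.append((a.name, lvl))
        off += k
    return np.vstack(rows), row_map


def d_efficiency(
    candidate: DesignMatrix,
    full: DesignMatrix,
    *,
    cond_limit: float = 1e10,
    return_diagnostics: bool = False,
) -> float | DEfficiencyResult:
    """Relative D-efficiency of a candidate design versus the full factorial.

    Returns a value in (0, 1] for nonsingular candidates; a candidate whose
    information matrix is singular (or conditioned worse than ``cond_limit``)
    is degenerate and scores 0.
    """
    if candidate.columns != full.columns:
        raise DesignError("candidate and full designs must share columns")
    p = candidate.n_columns
    Mc = candidate.X.T @ candidate.X / candidate.n_runs
    Mf = full.X.T @ full.X / full.n_runs
    sign_f, ld_f = np.linalg.slogdet(Mf)
    if sign_f <= 0:
        raise DesignError("full-factorial information matrix is singular")
    sign_c, ld_c = np.linalg.slogdet(Mc)
    degenerate = sign_c <= 0 or np.linalg.cond(Mc) > cond_limit
    value = 0.0 if degenerate else float(np.exp((ld_c - ld_f) / p))
    if return_diagnostics:
        return DEfficiencyResult(value, degenerate, float(ld_c), float(ld_f))
    return value


def design_diagnostics(
    profiles: Sequence[Profile], attrs: Sequence[AttributeSpec]
) -> BalanceReport:
    """Level counts, pairwise joint counts and the worst deviation from balance.

    ``max_pair_deviation`` is the largest absolute difference between an
    observed attribute-pair joint count and the count a perfectly orthogonal
    design of the same size would give (n / (Li * Lj)).
    """
    if not profiles:
        raise DesignError("diagnostics require a nonempty design")
    validate_attributes(attrs)
    n = len(profiles)
    idx = np.array([p.level_indices(attrs) for p in profiles])
    level_counts: dict[str, dict[str, int]] = {}
    missing = []
    for j, a in enumerate(attrs):
        counts = np.bincount(idx[:, j], minlength=a.n_levels)
        level_counts[a.name] = {lvl: int(c) for lvl, c in zip(a.levels, counts)}
        for lvl, c in zip(a.levels, counts):
            if c == 0:
                missing.append((a.name, lvl))
    pair_counts: dict[tuple[str, str], np.ndarray] = {}
    max_dev = 0.0
    for j, k in itertools.combinations(range(len(attrs)), 2):
        a, b = attrs[j], attrs[k]
        joint = np.zeros((a.n_levels, b.n_levels), dtype=int)
        np.add.at(joint, (idx[:, j], idx[:, k]), 1)
        pair_counts[(a.name, b.name)] = joint
        expected = n / (a.n_levels * b.n_levels)
        max_dev = max(max_dev, float(np.abs(joint - expected).max()))
    return BalanceReport(level_counts, pair_counts, max_dev, missing)


def _random_nonsingular_start(
    Xall: np.ndarray, n_profiles: int, rng: np.random.Generator, tries: int = 100
) -> np.ndarray:
    for _ in range(tries):
        idx = rng.choice(Xall.shape[0], size=n_profiles, replace=False)
        sign, _ = np.linalg.slogdet(Xall[idx].T @ Xall[idx])
        if sign > 0:
            return idx
    raise DesignError("could not find a nonsingular starting design")


def _fedorov_local_search(
    Xall: np.ndarray, idx: np.ndarray, max_passes: int = 500
) -> np.ndarray:
    """Exchange profiles (without replacement) until det(X'X) stops improving.

    The determinant ratio for swapping design row x_j out and candidate x_i in
    uses the classical rank-two update
    ``det(M')/det(M) = 1 + d(xi) - d(xj) - [d(xi)d(xj) - d(xi,xj)^2]``
    with ``d(x, y) = x' M^-1 y``; ties keep the incumbent design.
    """
    idx = idx.copy()
    n_all = Xall.shape[0]
    for _ in range(max_passes):
        Xd = Xall[idx]
        M = Xd.T @ Xd
        try:
            Minv = np.linalg.inv(M)
        except np.linalg.LinAlgError:  # pragma: no cover - guarded by start
            break
        A = Xall @ Minv  # (N, p)
        d_all = np.einsum("ij,ij->i", A, Xall)  # d(x_i)
        cross = A @ Xd.T  # (N, n) d(x_i, x_j)
        d_des = d_all[idx]
        ratio = (
            1.0
            + d_all[:, None]
            - d_des[None, :]
            - (d_all[:, None] * d_des[None, :] - cross**2)
        )
        in_design = np.zeros(n_all, dtype=bool)
        in_design[idx] = True
        ratio[in_design, :] = -np.inf
        i, j = np.unravel_index(np.argmax(ratio), ratio.shape)
        if ratio[i, j] <= 1.0 + 1e-10:
            break
        idx[j] = i
    return idx


def search_fractional_design(
    catalog: Sequence[Profile],
    attrs: Sequence[AttributeSpec],
    n_profiles: int,
    *,
    restarts: int = 20,
    seed: int | None = 0,
) -> FractionalDesign:
    """Search for a D-efficient fractional design by Fedorov exchange.

    Runs ``restarts`` independent exchange searches from random nonsingular
    starting subsets (seeded, so results are reproducible) and returns the
    best design found.  ``restart_best`` records the best-so-far D-efficiency
    after each restart; it is non-decreasing, and adding restarts can only
    improve the result for the same seed.
    """
    full = encode_effects(catalog, attrs)
    p = full.n_columns
    if n_profiles < p:
        raise DesignError(
            f"n_profiles={n_profiles} infeasible: main-effects model has {p} columns"
        )
    if n_profiles >= len(catalog):
        report = design_diagnostics(list(catalog), attrs)
        return FractionalDesign(
            profiles=list(catalog),
            matrix=full,
            d_efficiency=float(d_efficiency(full, full)),
            restart_best=[1.0],
            seed=seed,
            diagnostics=report,
        )
    Xall = full.X
    children = np.random.SeedSequence(seed).spawn(restarts)
    best_idx: np.ndarray | None = None
    best_logdet = -np.inf
    restart_best: list[float] = []
    for child in children:
        rng = np.random.default_rng(child)
        idx = _random_nonsingular_start(Xall, n_profiles, rng)
        idx = _fedorov_local_search(Xall, idx)
        _, logdet = np.linalg.slogdet(Xall[idx].T @ Xall[idx])
        if logdet > best_logdet:
            best_logdet = logdet
            best_idx = np.sort(idx)
        cand = DesignMatrix(
            X=Xall[best_idx],
            columns=full.columns,
            column_map=full.column_map,
            profile_ids=[catalog[i].profile_id for i in best_idx],
        )
        restart_best.append(float(d_efficiency(cand, full)))
    assert best_idx is not None
    chosen = [catalog[i] for i in best_idx]
    matrix = encode_effects(chosen, attrs)
    return FractionalDesign(
        profiles=chosen,
        matrix=matrix,
        d_efficiency=float(d_efficiency(matrix, full)),
        restart_best=restart_best,
        seed=seed,
        diagnostics=design_diagnostics(chosen, attrs),
    )
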