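"""Synthetic survey respondents for the clinical-vignette conjoint study.

Generates response tables with the statistical structure the estimation stage
assumes: each respondent evaluates several profiles, answering three yes/no
treatment questions (prescribe an SGLT2 inhibitor, increase lisinopril dose,
replace ibuprofen) and one three-category monitoring question
(increase / maintain / decrease risk-factor monitoring frequency).

Binary answers are Bernoulli draws with
``P(yes) = logistic(intercept + sum of the profile's level utilities)``.
The monitoring answer is drawn as "increase" with its logistic probability;
otherwise it is "decrease" with probability ``decrease_rate`` and "maintain"
with the remainder, producing the sparse "decrease" category seen in
practice.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .allocate import AllocationPlan
from .attributes import AttributeSpec, Profile, SpecError, study_attributes
from .design import enumerate_full_factorial

#: The four decision outcomes, in canonical order.
OUTCOMES = ("monitoring", "sglt2", "lisinopril_increase", "ibuprofen_replace")

#: CSV schema for response tables.
RESPONSE_COLUMNS = (
    "respondent_id",
    "position",
    "profile_id",
    "monitoring",
    "sglt2",
    "lisinopril_increase",
    "ibuprofen_replace",
)

_ZERO_SUM_TOL = 1e-8


@dataclasses.dataclass
class TrueUtilityModel:
    """Generative part-worth utilities for each decision outcome.

    ``utilities[outcome][attribute]`` is one log-odds utility per level,
    zero-sum within the attribute.  ``decrease_rate`` is the conditional
    probability that a non-"increase" monitoring answer is "decrease".
    ``heterogeneity_sd`` optionally perturbs each respondent's utilities with
    zero-sum normal noise (0 = pure aggregate model, the default analysis
    assumption).
    """

    intercepts: dict[str, float]
    utilities: dict[str, dict[str, np.ndarray]]
    decrease_rate: float = 0.0
    heterogeneity_sd: float = 0.0

    def __post_init__(self) -> None:
        for outcome in self.utilities:
            if outcome not in OUTCOMES:
                raise SpecError(f"unknown outcome {outcome!r}")
            self.utilities[outcome] = {
                attr: np.asarray(u, dtype=float)
                for attr, u in self.utilities[outcome].items()
            }
            for attr, u in self.utilities[outcome].items():
                if abs(float(u.sum())) > _ZERO_SUM_TOL:
                    raise SpecError(
                        f"utilities for {outcome}/{attr} must be zero-sum "
                        f"(sum={u.sum():.3g})"
                    )
        if not 0.0 <= self.decrease_rate < 1.0:
            raise SpecError("decrease_rate must be in [0, 1)")
        if self.heterogeneity_sd < 0:
            raise SpecError("heterogeneity_sd must be >= 0")

    def linear_predictor(
        self,
        outcome: str,
        level_idx: np.ndarray,
        attrs: Sequence[AttributeSpec],
    ) -> np.ndarray:
        """Log-odds for each row of ``level_idx`` (one level index per attribute)."""
        utils = self.utilities[outcome]
        eta = np.full(level_idx.shape[0], self.intercepts.get(outcome, 0.0))
        for j, a in enumerate(attrs):
            if a.name not in utils:
                raise SpecError(
                    f"model for outcome {outcome!r} missing attribute {a.name!r}"
                )
            u = utils[a.name]
            if len(u) != a.n_levels:
                raise SpecError(
                    f"model for {outcome}/{a.name} has {len(u)} utilities, "
                    f"attribute has {a.n_levels} levels"
                )
            eta = eta + u[level_idx[:, j]]
        return eta


def _centered(*values: float) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    return v - v.mean()


def simulate_survey(
    model: TrueUtilityModel,
    plan: AllocationPlan,
    profiles: Sequence[Profile],
    attrs: Sequence[AttributeSpec],
    seed: int | None = 0,
) -> pd.DataFrame:
    """Simulate one survey wave; returns a response table.

    One row per respondent-profile evaluation, in allocation order, with the
    columns in :data:`RESPONSE_COLUMNS`.  Randomness uses one named stream
    per outcome (plus streams for heterogeneity and the monitoring
    "decrease" draw), so the draws for one outcome are unaffected by adding
    or removing other outcomes.  Bit-reproducible for a given seed.
    """
    by_id = {p.profile_id: p for p in profiles}
    rows = [
        (rid, pos + 1, pid)
        for rid, profs in plan.assignments.items()
        for pos, pid in enumerate(profs)
    ]
    missing = sorted({pid for _, _, pid in rows} - set(by_id))
    if missing:
        raise SpecError(f"allocation references unknown profile_ids: {missing[:5]}")
    rid_arr = np.array([r for r, _, _ in rows])
    level_idx = np.array(
        [by_id[pid].level_indices(attrs) for _, _, pid in rows], dtype=int
    )

    ss = np.random.SeedSequence(seed)
    het_seq, dec_seq, *outcome_seqs = ss.spawn(2 + len(OUTCOMES))
    streams = dict(zip(OUTCOMES, outcome_seqs))

    # optional respondent-level utility perturbation, zero-sum per attribute
    perturb: dict[str, np.ndarray] | None = None
    resp_ids = sorted(plan.assignments)
    if model.heterogeneity_sd > 0:
        het_rng = np.random.default_rng(het_seq)
        resp_pos = {rid: i for i, rid in enumerate(resp_ids)}
        perturb = {}
        for outcome in OUTCOMES:
            blocks = []
            for a in attrs:
                eps = het_rng.normal(
                    0.0, model.heterogeneity_sd, size=(len(resp_ids), a.n_levels)
                )
                blocks.append(eps - eps.mean(axis=1, keepdims=True))
            perturb[outcome] = np.hstack(blocks)

    data: dict[str, np.ndarray | list] = {
        "respondent_id": rid_arr,
        "position": np.array([p for _, p, _ in rows]),
        "profile_id": np.array([pid for _, _, pid in rows]),
    }

    def eta_for(outcome: str) -> np.ndarray:
        eta = model.linear_predictor(outcome, level_idx, attrs)
        if perturb is not None:
            offsets = np.cumsum([0] + [a.n_levels for a in attrs])[:-1]
            flat = level_idx + offsets[None, :]
            rows_pos = np.array([resp_pos[r] for r in rid_arr])
            eta = eta + perturb[outcome][rows_pos[:, None], flat].sum(axis=1)
        return eta

    # monitoring: three-category draw
    p_inc = expit(eta_for("monitoring"))
    u_inc = np.random.default_rng(streams["monitoring"]).random(len(rows))
    u_dec = np.random.default_rng(dec_seq).random(len(rows))
    monitoring = np.where(
        u_inc < p_inc,
        "increase",
        np.where(u_dec < model.decrease_rate, "decrease", "maintain"),
    )
    data["monitoring"] = monitoring

    for outcome in OUTCOMES[1:]:
        p_yes = expit(eta_for(outcome))
        u = np.random.default_rng(streams[outcome]).random(len(rows))
        data[outcome] = np.where(u < p_yes, "yes", "no")

    return pd.DataFrame(data, columns=list(RESPONSE_COLUMNS))


def study_template(
    decrease_share: float = 0.05,
) -> tuple[list[AttributeSpec], TrueUtilityModel]:
    """The default study configuration: six vignette attributes plus a
    plausible generative utility model.

    PromarkerD part-worths are log-odds contrasts consistent with effect
    sizes reported for this kind of biomarker-vignette survey; the clinical
    attributes are scaled so that each outcome has a realistic leading
    attribute (HbA1c for SGLT2 prescribing, blood pressure for lisinopril
    dose, eGFR for ibuprofen replacement, the biomarker for monitoring).
    ``decrease_rate`` is calibrated analytically so the marginal share of
    "decrease" monitoring answers over the full factorial equals
    ``decrease_share`` (5% by default).
    """
    attrs = study_attributes()
    utilities = {
        "monitoring": {
            "promarkerd": _centered(0.0, -0.734, 0.451, 0.940),
            "albuminuria": _centered(-0.46, 0.04, 0.42),
            "egfr": _centered(-0.25, 0.0, 0.25),
            "blood_pressure": _centered(-0.22, 0.0, 0.22),
            "hba1c": _centered(-0.22, 0.0, 0.22),
            "age": _centered(-0.08, 0.0, 0.08),
        },
        "sglt2": {
            "promarkerd": _centered(0.0, -0.357, 0.405, 0.683),
            "albuminuria": _centered(-0.25, 0.0, 0.25),
            "egfr": _centered(-0.20, 0.10, 0.10),
            "blood_pressure": _centered(-0.15, 0.0, 0.15),
            "hba1c": _centered(-0.80, 0.10, 0.70),
            "age": _centered(0.10, 0.05, -0.15),
        },
        "lisinopril_increase": {
            "promarkerd": _centered(0.0, -0.10, 0.15, 0.392),
            "albuminuria": _centered(-0.15, 0.0, 0.15),
            "egfr": _centered(-0.10, 0.0, 0.10),
            "blood_pressure": _centered(-1.05, 0.10, 0.95),
            "hba1c": _centered(-0.10, 0.0, 0.10),
            "age": _centered(-0.05, 0.0, 0.05),
        },
        "ibuprofen_replace": {
            "promarkerd": _centered(0.0, -0.288, 0.470, 0.577),
            "albuminuria": _centered(-0.20, 0.0, 0.20),
            "egfr": _centered(-0.47, -0.01, 0.48),
            "blood_pressure": _centered(-0.15, 0.0, 0.15),
            "hba1c": _centered(-0.15, 0.0, 0.15),
            "age": _centered(-0.10, 0.0, 0.10),
        },
    }
    intercepts = {
        "monitoring": 0.2,
        "sglt2": 0.0,
        "lisinopril_increase": -0.3,
        "ibuprofen_replace": -0.2,
    }
    model = TrueUtilityModel(intercepts=intercepts, utilities=utilities)
    # calibrate the conditional decrease rate so the marginal share of
    # "decrease" answers over the (uniformly shown) full factorial hits target
    catalog = enumerate_full_factorial(attrs)
    level_idx = np.array([p.level_indices(attrs) for p in catalog])
    mean_not_increase = float(
        np.mean(1.0 - expit(model.linear_predictor("monitoring", level_idx, attrs)))
    )
    model.decrease_rate = decrease_share / mean_not_increase
    if not 0.0 <= model.decrease_rate < 1.0:  # pragma: no cover - sanity guard
        raise SpecError("calibrated decrease_rate out of range")
    return attrs, model


# ---------------------------------------------------------------------------
# serialization


def save_model(model: TrueUtilityModel, path: str | Path) -> None:
    payload = {
        "intercepts": {k: float(v) for k, v in model.intercepts.items()},
        "utilities": {
            outcome: {attr: [float(x) for x in u] for attr, u in per.items()}
            for outcome, per in model.utilities.items()
        },
        "decrease_rate": float(model.decrease_rate),
        "heterogeneity_sd": float(model.heterogeneity_sd),
    }
    with Path(path).open("w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_model(path: str | Path) -> TrueUtilityModel:
    with Path(path).open() as fh:
        payload = yaml.safe_load(fh)
    return TrueUtilityModel(
        intercepts=dict(payload["intercepts"]),
        utilities={
            outcome: {attr: np.asarray(u, dtype=float) for attr, u in per.items()}
            for outcome, per in payload["utilities"].items()
        },
        decrease_rate=float(payload.get("decrease_rate", 0.0)),
        heterogeneity_sd=float(payload.get("heterogeneity_sd", 0.0)),
    )
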