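"""Relative importance and odds-ratio reporting from fitted logit models.

Two headline statistics per outcome:

* **Relative importance** of attribute *i* is its utility range (max minus
  min part-worth) divided by the sum of ranges over all attributes, as a
  percent — the shares sum to 100%.
* **Odds ratios** contrast each attribute level against the attribute's
  reference level: ``OR = exp(u_level - u_ref)`` with a delta-method Wald
  95% CI on the log scale and a two-sided Wald p-value.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .attributes import AttributeSpec, SpecError
from .design import effects_decode_matrix
from .estimate import FitError, FittedLogit, utilities_by_attribute
from .simulate import OUTCOMES


class ImportanceError(ValueError):
    """Relative importance is undefined (all attribute ranges zero)."""


@dataclasses.dataclass
class OddsRatioResult:
    attribute: str
    level: str
    reference: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    log_or: float
    se: float


@dataclasses.dataclass
class EffectsReport:
    """Per-outcome importance shares and OR table."""

    outcome: str
    importance: dict[str, float]  # attribute -> percent, sums to 100
    or_table: pd.DataFrame  # one row per non-reference level


@dataclasses.dataclass
class ReportBundle:
    reports: dict[str, EffectsReport]
    importance_panel: pd.DataFrame  # outcomes x attributes, percent
    missing_outcomes: list[str]


def relative_importance(
    utilities: Mapping[str, Sequence[float] | np.ndarray]
) -> dict[str, float]:
    """Normalized utility ranges, in percent.

    ``importance_i = range_i / sum_j range_j * 100`` where ``range_i`` is the
    max-minus-min part-worth within attribute *i*.  Invariant to shifting any
    attribute's utilities by a constant and to globally rescaling all
    utilities.
    """
    if len(utilities) < 2:
        raise ImportanceError("need >=2 attributes for relative importance")
    ranges = {}
    for attr, u in utilities.items():
        u = np.asarray(u, dtype=float)
        if u.size < 2:
            raise ImportanceError(f"attribute {attr!r} needs >=2 levels")
        ranges[attr] = float(u.max() - u.min())
    total = sum(ranges.values())
    if total <= 0:
        raise ImportanceError("all attribute utility ranges are zero")
    return {attr: 100.0 * r / total for attr, r in ranges.items()}


def _contrast_vector(
    attrs: Sequence[AttributeSpec], attribute: str, level: str, reference: str
) -> np.ndarray:
    D, row_map = effects_decode_matrix(attrs)
    rows = {(a, lvl): i for i, (a, lvl) in enumerate(row_map)}
    try:
        return D[rows[(attribute, level)]] - D[rows[(attribute, reference)]]
    except KeyError as exc:
        raise SpecError(f"unknown attribute/level {exc.args[0]!r}") from None


def odds_ratio(
    fit: FittedLogit,
    attribute: str,
    level: str,
    reference: str | None = None,
    alpha: float = 0.05,
) -> OddsRatioResult:
    """OR of ``level`` vs ``reference`` for one attribute, with Wald CI and p.

    ``reference`` defaults to the attribute's configured reference level.
    The contrast is a linear function of the coefficients, so the SE comes
    directly from the coefficient covariance (delta method on the log scale).
    """
    if not fit.converged:
        raise FitError(f"outcome {fit.outcome!r}: fit did not converge")
    spec = {a.name: a for a in fit.attrs}
    if attribute not in spec:
        raise SpecError(f"unknown attribute {attribute!r}")
    if reference is None:
        reference = spec[attribute].reference
    if level == reference:
        return OddsRatioResult(attribute, level, reference, 1.0, 1.0, 1.0, 1.0, 0.0, 0.0)
    c = _contrast_vector(fit.attrs, attribute, level, reference)
    log_or = float(c @ fit.params)
    se = float(np.sqrt(c @ fit.cov @ c))
    z = norm.ppf(1 - alpha / 2)
    p = float(2 * norm.sf(abs(log_or) / se)) if se > 0 else 0.0
    return OddsRatioResult(
        attribute=attribute,
        level=level,
        reference=reference,
        odds_ratio=float(np.exp(log_or)),
        ci_low=float(np.exp(log_or - z * se)),
        ci_high=float(np.exp(log_or + z * se)),
        p_value=p,
        log_or=log_or,
        se=se,
    )


def or_table(fit: FittedLogit, alpha: float = 0.05) -> pd.DataFrame:
    """OR of every non-reference level vs its attribute's reference."""
    rows = []
    for a in fit.attrs:
        for lvl in a.levels:
            if lvl == a.reference:
                continue
            r = odds_ratio(fit, a.name, lvl, alpha=alpha)
            rows.append(
                {
                    "attribute": r.attribute,
                    "level": r.level,
                    "reference": r.reference,
                    "odds_ratio": r.odds_ratio,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "p_value": r.p_value,
                    "significant": r.p_value < alpha,
                }
            )
    return pd.DataFrame(rows)


def build_report(
    fits: Mapping[str, FittedLogit],
    attrs: Sequence[AttributeSpec],
    alpha: float = 0.05,
    outcomes: Sequence[str] = OUTCOMES,
) -> ReportBundle:
    """Assemble the importance panel and per-outcome OR tables.

    Outcomes without a fit are reported as explicit gaps rather than
    silently dropped.
    """
    reports: dict[str, EffectsReport] = {}
    missing = [o for o in outcomes if o not in fits]
    panel_rows = {}
    for outcome in outcomes:
        if outcome not in fits:
            panel_rows[outcome] = {a.name: np.nan for a in attrs}
            continue
        fit = fits[outcome]
        imp = relative_importance(utilities_by_attribute(fit))
        reports[outcome] = EffectsReport(
            outcome=outcome, importance=imp, or_table=or_table(fit, alpha=alpha)
        )
        panel_rows[outcome] = imp
    panel = pd.DataFrame(panel_rows).T.reindex(
        index=list(outcomes), columns=[a.name for a in attrs]
    )
    panel.index.name = "outcome"
    return ReportBundle(reports=reports, importance_panel=panel, missing_outcomes=missing)


# ---------------------------------------------------------------------------
# rendering


def write_report(bundle: ReportBundle, outdir: str | Path) -> list[Path]:
    """Write the importance panel and OR tables as CSV plus a Markdown digest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    panel_path = outdir / "importance_panel.csv"
    bundle.importance_panel.to_csv(panel_path)
    written.append(panel_path)
    for outcome, rep in bundle.reports.items():
        p = outdir / f"odds_ratios_{outcome}.csv"
        rep.or_table.to_csv(p, index=False)
        written.append(p)
    md = ["# Conjoint effects report", ""]
    if bundle.missing_outcomes:
        md += ["Missing outcome fits: " + ", ".join(bundle.missing_outcomes), ""]
    md += [
        "## Relative importance (%)",
        "",
        "```",
        bundle.importance_panel.round(1).to_string(),
        "```",
        "",
    ]
    for outcome, rep in bundle.reports.items():
        md += [
            f"## Odds ratios — {outcome}",
            "",
            "```",
            rep.or_table.round(3).to_string(index=False),
            "```",
            "",
        ]
    md_path = outdir / "report.md"
    md_path.write_text("\n".join(md))
    written.append(md_path)
    return written


def plot_importance(bundle: ReportBundle, path: str | Path) -> Path:
    """Grouped bar chart of relative importance per outcome."""
    import matplotlib.pyplot as plt

    panel = bundle.importance_panel.dropna(how="all")
    fig, ax = plt.subplots(figsize=(9, 4.5))
    n_out, n_attr = panel.shape
    width = 0.8 / n_attr
    x = np.arange(n_out)
    for j, attr in enumerate(panel.columns):
        ax.bar(x + j * width, panel[attr], width, label=attr)
    ax.set_xticks(x + 0.4 - width / 2)
    ax.set_xticklabels(panel.index, rotation=15)
    ax.set_ylabel("relative importance (%)")
    ax.legend(fontsize=8, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_or_forest(bundle: ReportBundle, attribute: str, path: str | Path) -> Path:
    """Forest plot of one attribute's ORs (vs reference) across outcomes."""
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    ypos = 0
    labels = []
    for outcome, rep in bundle.reports.items():
        sub = rep.or_table[rep.or_table["attribute"] == attribute]
        for _, row in sub.iterrows():
            ax.errorbar(
                row["odds_ratio"],
                ypos,
                xerr=[
                    [row["odds_ratio"] - row["ci_low"]],
                    [row["ci_high"] - row["odds_ratio"]],
                ],
                fmt="o",
                color="tab:blue",
                capsize=3,
            )
            labels.append(f"{outcome}: {row['level']}")
            ypos += 1
    ax.axvline(1.0, color="grey", linestyle="--", linewidth=1)
    ax.set_yticks(range(len(labels)))
    ax.set_yticklabels(labels, fontsize=8)
    ax.set_xlabel("odds ratio vs reference (95% CI)")
    ax.set_xscale("log")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
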