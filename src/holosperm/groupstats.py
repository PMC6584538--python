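"""Two-group comparison of morphometric parameters.

Groups are compared with the classic equal-variance (pooled) Student
t-test, two-sided, one spermatozoon = one replicate.  Results carry the
two-tier significance annotation customary in morphometry tables:
``*``/different lower-case letters for P < 0.05 and ``**``/different
capital letters for P < 0.01; no multiple-testing correction by default
(an optional Holm step-down is available for the full report).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import ValidationError
from .morphometry3d import MorphometricRecord

__all__ = ["GroupComparison", "compare_groups", "records_to_frame", "build_report", "report_to_markdown"]

_PARAMETERS = (
    "volume_um3",
    "surface_area_um2",
    "concentration_fg_per_um3",
    "dry_mass_pg",
    "sphericity",
)


@dataclass
class GroupComparison:
    """Pooled two-sample t-test result for one parameter."""

    parameter: str
    group_labels: tuple[str, str]
    means: tuple[float, float]
    sds: tuple[float, float]
    n: tuple[int, int]
    t_statistic: float
    p_value: float
    tier: str  # "ns", "*", "**"
    letters: tuple[str, str]  # e.g. ("a", "b") or ("A", "B")


def _tier(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def _letters(p: float) -> tuple[str, str]:
    if p < 0.01:
        return ("A", "B")
    if p < 0.05:
        return ("a", "b")
    return ("a", "a")


def compare_groups(
    values_a,
    values_b,
    parameter: str = "",
    labels: tuple[str, str] = ("A", "B"),
) -> GroupComparison:
    """Two-sided pooled-variance Student t-test between two groups.

    Sample SDs use the n−1 denominator.  Identical groups give t = 0,
    p = 1.  Raises for groups with fewer than two observations.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs n ≥ 2")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    t, p = float(t), float(p)
    if not np.isfinite(t):  # zero pooled variance, equal means
        t, p = 0.0, 1.0
    return GroupComparison(
        parameter=parameter,
        group_labels=labels,
        means=(float(a.mean()), float(b.mean())),
        sds=(float(a.std(ddof=1)), float(b.std(ddof=1))),
        n=(int(a.size), int(b.size)),
        t_statistic=t,
        p_value=p,
        tier=_tier(p),
        letters=_letters(p),
    )


def records_to_frame(records: list[MorphometricRecord]) -> pd.DataFrame:
    """Tidy DataFrame of measurement records (one row per record)."""
    return pd.DataFrame([r.to_dict() for r in records])


def build_report(
    records,
    groups: tuple[str, str] | None = None,
    holm: bool = False,
) -> pd.DataFrame:
    """Comparison table over (region × band × parameter) combinations.

    ``records`` is a list of :class:`MorphometricRecord` or the equivalent
    tidy DataFrame.  Each row reports mean ± SD per group with significance
    letters; combinations undetectable in a group render as ``—``.  With
    ``holm=True`` p-values are Holm-adjusted across rows before tiering.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if df.empty:
        raise ValidationError("no records to report")
    available = sorted(df["group"].dropna().unique())
    if groups is None:
        if len(available) != 2:
            raise ValidationError(f"need exactly two groups, have {available}")
        groups = (available[0], available[1])
    for g in groups:
        if g not in available:
            raise ValidationError(f"group {g!r} missing; available groups: {available}")

    rows = []
    for (region, band), sub in df.groupby(["region", "band"], sort=False):
        for param in _PARAMETERS:
            if param not in sub.columns:
                continue
            va = sub.loc[(sub["group"] == groups[0]) & sub["detectable"], param].dropna()
            vb = sub.loc[(sub["group"] == groups[1]) & sub["detectable"], param].dropna()
            if va.empty and vb.empty:
                if param == "sphericity" and region != "head":
                    continue
                rows.append(
                    {"region": region, "band": band, "parameter": param,
                     groups[0]: "—", groups[1]: "—", "p_value": np.nan, "tier": "—"}
                )
                continue
            if len(va) < 2 or len(vb) < 2:
                rows.append(
                    {"region": region, "band": band, "parameter": param,
                     groups[0]: _fmt(va) if len(va) else "—",
                     groups[1]: _fmt(vb) if len(vb) else "—",
                     "p_value": np.nan, "tier": "—"}
                )
                continue
            cmp_ = compare_groups(va, vb, parameter=param, labels=groups)
            rows.append(
                {"region": region, "band": band, "parameter": param,
                 groups[0]: f"{_fmt(va)}^{cmp_.letters[0]}^" if cmp_.tier != "ns" else _fmt(va),
                 groups[1]: f"{_fmt(vb)}^{cmp_.letters[1]}^" if cmp_.tier != "ns" else _fmt(vb),
                 "p_value": cmp_.p_value, "tier": cmp_.tier}
            )
    out = pd.DataFrame(rows)
    if holm and not out.empty:
        mask = out["p_value"].notna()
        p = out.loc[mask, "p_value"].to_numpy()
        order = np.argsort(p)
        adj = np.minimum.accumulate((p[order] * (len(p) - np.arange(len(p))))[::-1])[::-1]
        padj = np.empty_like(p)
        padj[order] = np.clip(adj, 0, 1)
        out.loc[mask, "p_value"] = padj
        out.loc[mask, "tier"] = [_tier(v) for v in padj]
    return out


def _fmt(values) -> str:
    v = np.asarray(values, dtype=float)
    if v.size == 1:
        return f"{v[0]:.4g}"
    return f"{v.mean():.4g} ± {v.std(ddof=1):.3g}"


def report_to_markdown(report: pd.DataFrame) -> str:
    """Render the comparison table as a GitHub-style Markdown table."""
    cols = list(report.columns)
    lines = ["| " + " | ".join(cols) + " |", "| " + " | ".join("---" for _ in cols) + " |"]
    for _, row in report.iterrows():
        cells = []
        for c in cols:
            v = row[c]
            if isinstance(v, float):
                cells.append("" if np.isnan(v) else f"{v:.3g}")
            else:
                cells.append(str(v))
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines) + "\n"
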