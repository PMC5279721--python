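"""Writer/eraser class-asymmetry comparisons.

Opposing enzyme classes — kinases vs phosphatases, acetyltransferases vs
deacetylases, ubiquitin ligases vs proteases — are compared over every
annotation metric: gene counts, protein abundance, essentiality or
disease association, PPI degree, transcriptional responsiveness, protein
half-life, capacity to be phosphorylated, and negative genetic
interactions. Numeric metrics use the rank-sum test, flag metrics
Fisher's exact test, and each class can also be compared against the
genome-wide background. Only measured (non-missing) values enter any
comparison, so reported group sizes reflect data availability, not class
sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import ComparisonResult, fisher_2x2, rank_sum_test, spearman_corr

__all__ = [
    "gene_count_ratio",
    "compare_numeric_metric",
    "compare_fraction_metric",
    "compare_vs_background",
    "responsiveness_abundance_correlation",
    "filter_by_subclass",
    "run_battery",
    "BatteryReport",
    "DEFAULT_BATTERY",
]

NUMERIC_METRICS = (
    "abundance", "ppi_degree", "de_perturbation_count", "half_life",
    "conserved_sites", "ngi_count",
)
FLAG_METRICS = (
    "essential", "de_responsive", "phospho_curated", "phospho_peptide",
    "phospho_conserved",
)


def _class_rows(records: pd.DataFrame, enzyme_class: str) -> pd.DataFrame:
    sub = records[records["enzyme_class"] == enzyme_class]
    if sub.empty:
        raise ValueError(f"class {enzyme_class!r} has no records")
    return sub


def _metric_values(rows: pd.DataFrame, metric: str) -> np.ndarray:
    if metric not in rows.columns:
        raise ValueError(f"metric {metric!r} not in records")
    return rows[metric].to_numpy(dtype=float)


def gene_count_ratio(records: pd.DataFrame, class_a: str, class_b: str) -> float:
    """Ratio of gene counts, class A over class B (e.g. kinase : phosphatase)."""
    return len(_class_rows(records, class_a)) / len(_class_rows(records, class_b))


def compare_numeric_metric(
    records: pd.DataFrame,
    metric: str,
    class_a: str,
    class_b: str,
    tail: str = "two-sided",
    method: str = "auto",
) -> ComparisonResult:
    """Rank-sum comparison of a numeric metric between two classes.

    Missing values are dropped per class before testing; group sizes and
    medians in the result refer to the measured subsets.
    """
    a = _metric_values(_class_rows(records, class_a), metric)
    b = _metric_values(_class_rows(records, class_b), metric)
    return rank_sum_test(
        a, b, tail=tail, method=method, metric=metric, labels=(class_a, class_b)
    )


def compare_fraction_metric(
    records: pd.DataFrame,
    flag_metric: str,
    class_a: str,
    class_b: str,
    tail: str = "two-sided",
) -> ComparisonResult:
    """Fisher comparison of a flag metric (fraction flagged) between classes."""
    a = _metric_values(_class_rows(records, class_a), flag_metric)
    b = _metric_values(_class_rows(records, class_b), flag_metric)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError(f"no measured {flag_metric!r} flags in one of the classes")
    table = (
        int((a > 0).sum()), int((a <= 0).sum()),
        int((b > 0).sum()), int((b <= 0).sum()),
    )
    return fisher_2x2(
        *table, tail=tail, metric=flag_metric, labels=(class_a, class_b)
    )


def compare_vs_background(
    records: pd.DataFrame,
    metric: str,
    enzyme_class: str,
    background_records: pd.DataFrame,
    tail: str = "two-sided",
    method: str = "auto",
    exclude_class_from_background: bool = False,
) -> ComparisonResult:
    """Rank-sum comparison of one class against the genome-wide background.

    By default the background keeps any records of the focal class it may
    contain (genome-wide denominators); set
    ``exclude_class_from_background`` to remove them by id.
    """
    a_rows = _class_rows(records, enzyme_class)
    bg = background_records
    if exclude_class_from_background:
        bg = bg[~bg["id"].isin(set(a_rows["id"]))]
    if bg.empty:
        raise ValueError("background is empty")
    a = _metric_values(a_rows, metric)
    b = _metric_values(bg, metric)
    return rank_sum_test(
        a, b, tail=tail, method=method, metric=metric,
        labels=(enzyme_class, "all"),
    )


def responsiveness_abundance_correlation(
    records: pd.DataFrame,
    scope: str | Sequence[str] = "all",
    method: str = "auto",
) -> tuple[float, float]:
    """Spearman correlation of perturbation responsiveness vs abundance.

    Checks whether genes that are differentially expressed in many
    perturbations are simply the highly expressed ones — if the
    correlation is weak, lower phosphatase responsiveness cannot be an
    artifact of their higher abundance. ``scope`` is ``"all"`` or a list
    of enzyme classes to include.
    """
    rows = records if scope == "all" else records[
        records["enzyme_class"].isin(list(scope))
    ]
    if rows.empty:
        raise ValueError(f"scope {scope!r} selects no records")
    return spearman_corr(
        rows["de_perturbation_count"].to_numpy(dtype=float),
        rows["abundance"].to_numpy(dtype=float),
        method=method,
    )


def filter_by_subclass(
    records: pd.DataFrame,
    include_rule: Mapping[str, Sequence] | None = None,
    exclude_rule: Mapping[str, Sequence] | None = None,
) -> pd.DataFrame:
    """Set algebra on annotation columns.

    ``include_rule`` keeps rows matching *all* listed column/value
    constraints; ``exclude_rule`` then drops rows matching all of its
    constraints (e.g. keep tyrosine-annotated enzymes, drop those also
    annotated with serine/threonine activity). Unknown columns raise.
    """
    def mask(rule: Mapping[str, Sequence]) -> pd.Series:
        m = pd.Series(True, index=records.index)
        for col, values in rule.items():
            if col not in records.columns:
                raise ValueError(f"unknown rule field {col!r}")
            vals = [values] if np.isscalar(values) else list(values)
            m &= records[col].isin(vals)
        return m

    keep = mask(include_rule) if include_rule else pd.Series(True, index=records.index)
    if exclude_rule:
        keep &= ~mask(exclude_rule)
    return records[keep].copy()


@dataclass(frozen=True)
class BatteryReport:
    """All comparisons from one battery run plus any per-row failures."""

    results: tuple[ComparisonResult, ...]
    errors: tuple[tuple[str, str], ...] = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_dict() for r in self.results])


# Default comparison plan mirroring the standard asymmetry figures.
# Each row: (metric, kind, tail for class A vs class B). Tails encode the
# claimed direction of each asymmetry: erasers more abundant and with more
# NGIs, writers more essential, connected, responsive, phosphorylatable
# and shorter-lived.
DEFAULT_BATTERY: tuple[tuple[str, str, str], ...] = (
    ("abundance", "numeric", "less"),
    ("essential", "flag", "greater"),
    ("ppi_degree", "numeric", "greater"),
    ("de_responsive", "flag", "greater"),
    ("de_perturbation_count", "numeric", "greater"),
    ("half_life", "numeric", "less"),
    ("phospho_curated", "flag", "greater"),
    ("phospho_peptide", "flag", "greater"),
    ("phospho_conserved", "flag", "greater"),
    ("conserved_sites", "numeric", "greater"),
    ("ngi_count", "numeric", "less"),
)


def run_battery(
    records: pd.DataFrame,
    background_records: pd.DataFrame | None = None,
    config: Sequence[tuple[str, str, str]] = DEFAULT_BATTERY,
    class_a: str = "kinase",
    class_b: str = "phosphatase",
    method: str = "auto",
    background_metrics: Sequence[str] = ("ppi_degree",),
) -> BatteryReport:
    """Run the full asymmetry battery between two classes.

    One result per configured (metric, kind, tail) row, in configured
    order; when ``background_records`` is given, each metric listed in
    ``background_metrics`` additionally compares both classes against the
    background. Failures (e.g. a metric with no measured values) are
    recorded and the battery continues.
    """
    results: list[ComparisonResult] = []
    errors: list[tuple[str, str]] = []
    for metric, kind, tail in config:
        try:
            if kind == "numeric":
                res = compare_numeric_metric(
                    records, metric, class_a, class_b, tail=tail, method=method
                )
            elif kind == "flag":
                res = compare_fraction_metric(records, metric, class_a, class_b,
                                              tail=tail)
            else:
                raise ValueError(f"unknown comparison kind {kind!r}")
            results.append(res)
        except ValueError as exc:
            errors.append((f"{metric}:{class_a}-vs-{class_b}", str(exc)))
        if background_records is not None and metric in background_metrics:
            for cls in (class_a, class_b):
                try:
                    results.append(
                        compare_vs_background(
                            records, metric, cls, background_records,
                            tail="greater" if cls == class_a else "two-sided",
                            method=method,
                        )
                    )
                except ValueError as exc:
                    errors.append((f"{metric}:{cls}-vs-all", str(exc)))
    return BatteryReport(tuple(results), tuple(errors))
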