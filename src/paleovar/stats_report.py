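"""Statistical layer and report assembly.

Implements the nonparametric comparisons used throughout the analysis —
tie-corrected Kruskal–Wallis on mid-ranks, Benjamini–Hochberg step-up
adjustment, Pearson chi-squared on contingency tables — plus the rounding
convention for reported proportions (one decimal, half away from zero),
and the assembly of the final result bundle from the upstream tables.

The formulas are written out explicitly here so each can be unit-tested
against closed forms and permutation/brute-force oracles; significance is
declared at two-sided adjusted P < 0.01.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

#: Two-sided significance threshold applied to (adjusted) P values.
SIGNIFICANCE_THRESHOLD = 0.01

__all__ = [
    "TestResult",
    "kruskal_wallis",
    "bh_adjust",
    "chi_squared",
    "proportion",
    "build_report",
    "write_report",
    "SIGNIFICANCE_THRESHOLD",
]


@dataclass
class TestResult:
    """Outcome of one hypothesis test (optionally BH-adjusted in a family)."""

    statistic: float
    df: int
    p_value: float
    method: str
    adjusted_p: float | None = None

    @property
    def significant(self) -> bool:
        p = self.adjusted_p if self.adjusted_p is not None else self.p_value
        return p < SIGNIFICANCE_THRESHOLD

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "adjusted_p": self.adjusted_p,
            "method": self.method,
            "significant": self.significant,
        }


# ---------------------------------------------------------------------------
# Kruskal–Wallis
# ---------------------------------------------------------------------------

def kruskal_wallis(groups: dict[str, list[float]]) -> TestResult:
    """Tie-corrected Kruskal–Wallis H test over ≥2 groups of values.

    H is computed on mid-ranks and divided by the tie-correction factor
    ``1 − Σ(t³−t)/(N³−N)``; the P value comes from the chi-squared
    approximation with k−1 degrees of freedom.  A pooled sample in which
    every value is identical carries no rank information: H = 0, P = 1.

    Raises ``ValueError`` for fewer than two groups, an empty group, or
    total N < 3 (the approximation is meaningless below that).
    """
    if len(groups) < 2:
        raise ValueError(
            "Kruskal-Wallis requires at least two groups; a single group "
            "has no between-group variation to test"
        )
    sizes = {k: len(v) for k, v in groups.items()}
    if any(n == 0 for n in sizes.values()):
        empty = [k for k, n in sizes.items() if n == 0]
        raise ValueError(f"empty group(s): {empty}")
    pooled = np.concatenate([np.asarray(v, dtype=float) for v in groups.values()])
    n_total = pooled.size
    if n_total < 3:
        raise ValueError("Kruskal-Wallis requires a pooled sample of at least 3")

    ranks = sps.rankdata(pooled)  # mid-ranks for ties
    df = len(groups) - 1

    h = 0.0
    start = 0
    for vals in groups.values():
        n_i = len(vals)
        r_bar = ranks[start : start + n_i].mean()
        h += n_i * (r_bar - (n_total + 1) / 2.0) ** 2
        start += n_i
    h *= 12.0 / (n_total * (n_total + 1))

    _, tie_counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - float(np.sum(tie_counts**3 - tie_counts)) / (
        n_total**3 - n_total
    )
    if correction <= 0.0:
        # every pooled value identical: no rank variation at all
        return TestResult(0.0, df, 1.0, "kruskal-wallis")
    h /= correction
    p = float(sps.chi2.sf(h, df))
    return TestResult(float(h), df, p, "kruskal-wallis")


# ---------------------------------------------------------------------------
# Benjamini–Hochberg
# ---------------------------------------------------------------------------

def bh_adjust(p_values: list[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted P values, in input order.

    ``q_(i) = min_{j≥i} p_(j)·m/j`` on the ascending sort, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out.tolist()


# ---------------------------------------------------------------------------
# Chi-squared
# ---------------------------------------------------------------------------

def chi_squared(table, yates: bool = False) -> TestResult:
    """Pearson chi-squared test of independence on an r×c count table.

    Expected counts come from the row/column margins; df = (r−1)(c−1);
    the P value is the upper tail of the chi-squared distribution.  No
    continuity correction by default (``yates=True`` enables it for 2×2).
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("zero row or column margin: test undefined")
    expected = np.outer(row, col) / obs.sum()
    diff = np.abs(obs - expected)
    if yates and obs.shape == (2, 2):
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float(np.sum(diff**2 / expected))
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(sps.chi2.sf(stat, df))
    return TestResult(stat, df, p, "chi-squared" + ("-yates" if yates else ""))


# ---------------------------------------------------------------------------
# Proportions
# ---------------------------------------------------------------------------

def proportion(numerator: int, denominator: int) -> float:
    """``100·n/d`` rounded half-away-from-zero to one decimal place.

    This is the convention behind every reported percentage (e.g. 119 of
    121 → 98.3).  Raises on a zero denominator or a numerator outside
    [0, denominator].
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must lie in [0, denominator]")
    frac = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return float(frac.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------

#: Table families expected in a complete result bundle.
REPORT_TABLES = (
    "catalog_summary",
    "clade_sharing",
    "gene_class_comparison",
    "founder_sharing",
    "chronology",
    "geography",
)


@dataclass
class ReportBundle:
    """The assembled result tables plus the family of test results."""

    tables: dict = field(default_factory=dict)
    tests: dict = field(default_factory=dict)

    def __getitem__(self, key):
        return self.tables[key]


def build_report(
    catalog_summary,
    clade_sharing: pd.DataFrame,
    clade_test: TestResult,
    gene_class_tests: dict[str, TestResult],
    founder_sharing: pd.DataFrame,
    chronology: dict,
    geography: pd.DataFrame,
) -> ReportBundle:
    """Assemble the final result bundle from the upstream stage outputs.

    The per-gene class-comparison tests form one BH family; the clade
    comparison is adjusted as its own (singleton) family.  Missing upstream
    inputs raise ``ValueError`` naming the absent stage.
    """
    stages = {
        "catalog_summary": catalog_summary,
        "clade_sharing": clade_sharing,
        "clade_test": clade_test,
        "founder_sharing": founder_sharing,
        "chronology": chronology,
        "geography": geography,
    }
    for name, value in stages.items():
        if value is None:
            raise ValueError(f"missing upstream table: {name}")
    if not gene_class_tests:
        raise ValueError("missing upstream table: gene_class_tests")

    genes = list(gene_class_tests)
    adj = bh_adjust([gene_class_tests[g].p_value for g in genes])
    for g, q in zip(genes, adj):
        gene_class_tests[g].adjusted_p = q
    clade_test.adjusted_p = bh_adjust([clade_test.p_value])[0]

    gene_rows = [
        {
            "gene": g,
            "statistic": t.statistic,
            "df": t.df,
            "p_value": t.p_value,
            "adjusted_p": t.adjusted_p,
            "significant": t.significant,
        }
        for g, t in gene_class_tests.items()
    ]
    bundle = ReportBundle(
        tables={
            "catalog_summary": catalog_summary,
            "clade_sharing": clade_sharing,
            "gene_class_comparison": pd.DataFrame(gene_rows),
            "founder_sharing": founder_sharing,
            "chronology": chronology,
            "geography": geography,
        },
        tests={"clade": clade_test, "per_gene": gene_class_tests},
    )
    return bundle


def write_report(bundle: ReportBundle, outdir) -> None:
    """Write the bundle as TSV/JSON files plus a plain-text summary log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lines = []
    for name, table in bundle.tables.items():
        if isinstance(table, pd.DataFrame):
            table.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
        elif hasattr(table, "to_dict"):
            (outdir / f"{name}.json").write_text(
                json.dumps(table.to_dict(), indent=2, default=str) + "\n"
            )
        else:
            (outdir / f"{name}.json").write_text(
                json.dumps(table, indent=2, default=str) + "\n"
            )
        lines.append(f"table {name}: written")
    clade = bundle.tests["clade"]
    lines.append(
        f"clade comparison: H={clade.statistic:.4g} df={clade.df} "
        f"adjusted_p={clade.adjusted_p:.3g} significant={clade.significant}"
    )
    for gene, t in bundle.tests["per_gene"].items():
        lines.append(
            f"{gene} PV/BV/VUS comparison: H={t.statistic:.4g} "
            f"adjusted_p={t.adjusted_p:.3g} significant={t.significant}"
        )
    (outdir / "summary.log").write_text("\n".join(lines) + "\n")
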