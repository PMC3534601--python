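"""Chromosome-class tabulation and enrichment/depletion contrasts.

The central quantities are per-tissue counts of female- and male-biased
probes per chromosome class (autosomes A, X, Y, unmapped NA), the two-sided
Fisher's exact contrasts between them (female vs male within X; X vs A within
each direction), and the signed relative difference of the X and autosomal
biased fractions — negative values are depletions, e.g. -0.25 is a 25%
relative depletion of male-biased probes on X.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateInputError, MetadataError
from .model import FEMALE, MALE, AnnotationTable, EscapeeList
from .stats import recall_at

CLASS_ORDER = ("A", "X", "Y", "NA", "all")

COMPARISONS = ("XF_vs_XM", "XF_vs_AF", "XM_vs_AM")

#: Total count below which the exact integer enumeration is used directly.
_EXACT_N_LIMIT = 500


def tabulate(
    results_by_tissue: dict[str, pd.DataFrame],
    ann: AnnotationTable,
    alpha: float = 0.001,
) -> pd.DataFrame:
    """Tally biased probes per tissue and chromosome class at ``alpha``.

    Returns a DataFrame indexed by (tissue, chrom_class) with the class size
    ``n_class``, the biased counts ``tot``/``f``/``m`` (tot = f + m) and the
    corresponding percentages of the class size. The ``all`` row sums the
    four classes. Bias calls are re-derived from the stored p-values and
    deltas, so one screening pass serves any threshold.
    """
    rows = []
    for tissue, results in results_by_tissue.items():
        classes = ann.classes_of(results.index)
        call = recall_at(results, alpha)
        per_class = {}
        for chrom_class in CLASS_ORDER[:-1]:
            in_class = classes == chrom_class
            n_class = int(in_class.sum())
            f = int(((call == FEMALE) & in_class.to_numpy()).sum())
            m = int(((call == MALE) & in_class.to_numpy()).sum())
            per_class[chrom_class] = (n_class, f, m)
        n_all = sum(v[0] for v in per_class.values())
        f_all = sum(v[1] for v in per_class.values())
        m_all = sum(v[2] for v in per_class.values())
        per_class["all"] = (n_all, f_all, m_all)
        for chrom_class in CLASS_ORDER:
            n_class, f, m = per_class[chrom_class]
            rows.append(
                {
                    "tissue": tissue,
                    "chrom_class": chrom_class,
                    "n_class": n_class,
                    "tot": f + m,
                    "f": f,
                    "m": m,
                    "pct_tot": 100.0 * (f + m) / n_class if n_class else np.nan,
                    "pct_f": 100.0 * f / n_class if n_class else np.nan,
                    "pct_m": 100.0 * m / n_class if n_class else np.nan,
                }
            )
    return pd.DataFrame(rows).set_index(["tissue", "chrom_class"])


def counts_from_table1(
    table1: pd.DataFrame, class_totals: dict[str, int]
) -> pd.DataFrame:
    """Build a bias-count table from the printed per-tissue tallies.

    ``class_totals`` supplies the per-class probe totals the printed table
    omits (see :func:`xbias.fixtures.derive_class_totals`); percentages are
    recomputed from them rather than copied, keeping the table internally
    consistent.
    """
    rows = []
    for _, r in table1.iterrows():
        n_class = class_totals.get(r["chrom_class"], np.nan)
        rows.append(
            {
                "tissue": r["tissue"],
                "chrom_class": r["chrom_class"],
                "n_class": n_class,
                "tot": int(r["tot"]),
                "f": int(r["f"]),
                "m": int(r["m"]),
                "pct_tot": 100.0 * r["tot"] / n_class,
                "pct_f": 100.0 * r["f"] / n_class,
                "pct_m": 100.0 * r["m"] / n_class,
            }
        )
    return pd.DataFrame(rows).set_index(["tissue", "chrom_class"])


def fisher_exact_p(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 table.

    The two-sided p is the probability-mass definition: the sum of
    hypergeometric probabilities (same margins) of all tables at most as
    probable as the observed one. For small tables (N <= 500) the sum is
    evaluated in exact integer arithmetic; larger tables use the identical
    definition in floating point. The odds ratio is the sample odds ratio
    a*d / (b*c), with inf/nan at zero boundaries.
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise DegenerateInputError("fisher_exact_p expects a 2x2 table")
    if (arr < 0).any() or not np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float)
        if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
            raise DegenerateInputError("cell counts must be nonnegative integers")
        arr = np.round(arr).astype(np.int64)
    a, b = int(arr[0, 0]), int(arr[0, 1])
    c, d = int(arr[1, 0]), int(arr[1, 1])
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise DegenerateInputError("a margin of the 2x2 table is zero")
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    n = r1 + r2
    if n <= _EXACT_N_LIMIT:
        lo, hi = max(0, c1 - r2), min(r1, c1)
        weights = [math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)]
        observed = weights[a - lo]
        p = sum(w for w in weights if w <= observed) / math.comb(n, c1)
    else:
        p = float(sps.fisher_exact(arr, alternative="two-sided")[1])
    return odds, min(1.0, float(p))


@dataclass(frozen=True)
class EnrichmentResult:
    """One Fisher contrast between bias-count cells."""

    comparison: str
    tissue: str
    contingency: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p: float
    #: (X fraction - A fraction) / A fraction for cross-class contrasts;
    #: None for the within-X female-vs-male contrast.
    relative_difference: float | None


def compare_classes(
    counts: pd.DataFrame, tissue: str, comparison: str
) -> EnrichmentResult:
    """Run one of the three chromosome-class contrasts for a tissue.

    ``XF_vs_XM``: female- vs male-biased fractions within the X.
    ``XF_vs_AF`` / ``XM_vs_AM``: X vs autosomal biased fraction in one
    direction; ``relative_difference`` is the signed relative excess of the
    X fraction over the autosomal one (negative = depletion).
    """
    if comparison not in COMPARISONS:
        raise ValueError(f"unknown comparison {comparison!r}")
    try:
        x_row = counts.loc[(tissue, "X")]
        a_row = counts.loc[(tissue, "A")]
    except KeyError as exc:
        raise MetadataError(f"tissue {tissue!r} missing from count table") from exc
    n_x, n_a = int(x_row["n_class"]), int(a_row["n_class"])
    if n_x <= 0 or (comparison != "XF_vs_XM" and n_a <= 0):
        raise DegenerateInputError("zero class totals in count table")
    if comparison == "XF_vs_XM":
        f, m = int(x_row["f"]), int(x_row["m"])
        table = ((f, n_x - f), (m, n_x - m))
        rel = None
    else:
        col = "f" if comparison == "XF_vs_AF" else "m"
        x_n, a_n = int(x_row[col]), int(a_row[col])
        table = ((x_n, n_x - x_n), (a_n, n_a - a_n))
        x_frac, a_frac = x_n / n_x, a_n / n_a
        if a_frac == 0:
            raise DegenerateInputError("autosomal biased fraction is zero")
        rel = (x_frac - a_frac) / a_frac
    odds, p = fisher_exact_p(np.asarray(table))
    return EnrichmentResult(comparison, tissue, table, odds, p, rel)


def relative_depletion_percent(result: EnrichmentResult) -> int:
    """Depletion magnitude as the nearest integer percent (for reports)."""
    if result.relative_difference is None:
        raise ValueError("within-X contrast has no relative difference")
    return int(round(-100.0 * result.relative_difference))


def exclude_escapees(
    results: pd.DataFrame, ann: AnnotationTable, esc: EscapeeList
) -> pd.DataFrame:
    """Drop probes whose gene (or intron host gene) is a known XCI escapee.

    Matching is by gene symbol token, so aliased labels like
    ``2010000I03Rik (Jpx)`` are caught by either name. Unknown escapee
    symbols are ignored.
    """
    symbols = ann.df.loc[
        ann.df.index.intersection(results.index), "gene_symbol"
    ].fillna("")
    drop = {pid for pid, sym in symbols.items() if sym and esc.matches(str(sym))}
    return results.loc[[pid for pid in results.index if pid not in drop]]


def enrichment_report(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Flatten contrasts to a tab-friendly report frame."""
    rows = []
    for r in results:
        (a, b), (c, d) = r.contingency
        rows.append(
            {
                "tissue": r.tissue,
                "comparison": r.comparison,
                "a": a,
                "b": b,
                "c": c,
                "d": d,
                "odds_ratio": r.odds_ratio,
                "p": r.p,
                "relative_difference": (
                    np.nan if r.relative_difference is None else r.relative_difference
                ),
            }
        )
    return pd.DataFrame(rows)
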