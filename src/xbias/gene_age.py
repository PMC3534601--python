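"""Phylostratigraphic analysis of sex-biased X-linked genes.

Each X probe is joined to a phylogenetic branch label (0-11, the stratum at
which orthologs of its gene first appear; branches 0-5 predate the placental
mammal radiation, >100 myr). Per-branch proportions of female- and
male-biased probes are reported for branches carrying at least a minimum
number of probes (default 10), and the old-vs-young difference is tested
with a two-sided Fisher's exact test on the 2x2 of (biased, not biased) x
(branch <= 5, branch >= 6).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateInputError
from .model import FEMALE, MALE, AnnotationTable, BranchTable
from .enrichment import fisher_exact_p
from .stats import recall_at

#: Oldest branch of the "young" stratum: branches <= OLD_MAX_BRANCH are old
#: (>100 myr, predating the placental radiation).
OLD_MAX_BRANCH = 5

MIN_BRANCH_PROBES = 10


def join_branches(
    results: pd.DataFrame,
    ann: AnnotationTable,
    branches: BranchTable,
    alpha: float = 0.001,
) -> pd.DataFrame:
    """Attach branch labels to X-linked probe results.

    Matching is by ensembl_id with gene_symbol fallback. Returns the joined
    records (X probes with a branch) with columns ``branch`` and ``call``
    (re-derived at ``alpha``); unmatched probes are excluded and counted in
    ``.attrs['n_unmatched']``.
    """
    sub = ann.df.loc[ann.df.index.intersection(results.index)]
    x_probes = sub.index[sub["chrom_class"] == "X"]
    call = recall_at(results.loc[x_probes], alpha)
    rows = []
    n_unmatched = 0
    for pid in x_probes:
        ens = str(sub.loc[pid, "ensembl_id"] or "")
        sym = str(sub.loc[pid, "gene_symbol"] or "")
        branch = branches.get(ens) if ens else None
        if branch is None and sym:
            branch = branches.get(sym)
        if branch is None:
            n_unmatched += 1
            continue
        rows.append({"probe_id": pid, "branch": int(branch), "call": call.loc[pid]})
    out = (
        pd.DataFrame(rows).set_index("probe_id")
        if rows
        else pd.DataFrame(columns=["branch", "call"], index=pd.Index([], name="probe_id"))
    )
    out.attrs["n_unmatched"] = n_unmatched
    return out


def branch_proportions(
    joined: pd.DataFrame, min_probes: int = MIN_BRANCH_PROBES
) -> pd.DataFrame:
    """Per-branch sex-bias proportions with the minimum-probe filter.

    Branches represented by fewer than ``min_probes`` probes are marked
    excluded and carry NaN proportions (they would be parenthesized in a
    figure). The frame covers all branches 0-11, absent ones with n_probes 0.
    """
    rows = []
    for branch in range(12):
        grp = joined[joined["branch"] == branch]
        n = len(grp)
        included = n >= min_probes
        rows.append(
            {
                "branch": branch,
                "n_probes": n,
                "prop_female": (grp["call"] == FEMALE).mean() if included else np.nan,
                "prop_male": (grp["call"] == MALE).mean() if included else np.nan,
                "included": included,
            }
        )
    return pd.DataFrame(rows).set_index("branch")


@dataclass(frozen=True)
class AgeSplitResult:
    """Old-vs-young Fisher contrast for one bias direction."""

    direction: str
    old_biased: int
    old_total: int
    young_biased: int
    young_total: int
    odds_ratio: float
    p: float


def age_split_test(joined: pd.DataFrame, direction: str) -> AgeSplitResult:
    """Fisher's exact test of bias proportion in old vs young branches.

    Old = branches 0..5 (>100 myr), young = branches 6..11. Both strata must
    be non-empty.
    """
    if direction not in (FEMALE, MALE):
        raise ValueError(f"direction must be female or male, got {direction!r}")
    old = joined[joined["branch"] <= OLD_MAX_BRANCH]
    young = joined[joined["branch"] > OLD_MAX_BRANCH]
    if old.empty or young.empty:
        raise DegenerateInputError("old or young stratum is empty")
    ob = int((old["call"] == direction).sum())
    yb = int((young["call"] == direction).sum())
    if ob + yb == 0:
        # no biased probe in either stratum: no evidence of a difference
        return AgeSplitResult(direction, 0, len(old), 0, len(young), np.nan, 1.0)
    table = np.array(
        [[ob, len(old) - ob], [yb, len(young) - yb]], dtype=np.int64
    )
    odds, p = fisher_exact_p(table)
    return AgeSplitResult(direction, ob, len(old), yb, len(young), odds, p)
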