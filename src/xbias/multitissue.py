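"""Cross-tissue consistency, gene-level aggregation and proximity clusters.

A probe is *consistently* sex-biased when it reaches significance (default
p<0.01, the relaxed threshold) in at least two tissues with the same
direction in every significant tissue; probes significant in opposite
directions in different tissues are excluded. Probes are then aggregated to
gene-level entries (intron-marked probe rows merge into their host entry),
and female-biased entries lying within 50 kb of each other on one chromosome
are chained into clusters — the gap is measured between probe-alignment
extents, next.start - current.stop, floored at 0 for overlaps.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import MetadataError, XBiasError
from .model import FEMALE, MALE, AnnotationTable
from .stats import recall_at

#: Default proximity threshold (bp) for female-biased gene clusters.
CLUSTER_GAP = 50_000


def consistent_probes(
    results_by_tissue: dict[str, pd.DataFrame], alpha: float = 0.01
) -> pd.DataFrame:
    """Probes significant at ``alpha`` in >=2 tissues, same direction throughout.

    Returns one row per qualifying probe: ``direction``, per-tissue
    significance flags ``sig_<tissue>``, per-tissue fold-change magnitudes
    ``fc_<tissue>`` (2**|delta|, recorded for every tissue), ``n_tissues``
    and the tuple of significant ``tissues``.
    """
    if len(results_by_tissue) < 2:
        raise MetadataError("consistency analysis needs results from >=2 tissues")
    tissues = list(results_by_tissue)
    calls = {}
    for tissue, results in results_by_tissue.items():
        calls[tissue] = recall_at(results, alpha)
    probe_ids = sorted(set().union(*[set(r.index) for r in results_by_tissue.values()]))
    rows = []
    for pid in probe_ids:
        sig_dirs = []
        sig_tissues = []
        for tissue in tissues:
            call = calls[tissue].get(pid, "ns")
            if call in (FEMALE, MALE):
                sig_dirs.append(call)
                sig_tissues.append(tissue)
        if len(sig_tissues) < 2 or len(set(sig_dirs)) != 1:
            continue
        rec: dict = {"probe_id": pid, "direction": sig_dirs[0]}
        for tissue in tissues:
            rec[f"sig_{tissue}"] = tissue in sig_tissues
            res = results_by_tissue[tissue]
            if pid in res.index:
                rec[f"fc_{tissue}"] = float(2.0 ** abs(res.loc[pid, "delta"]))
            else:
                rec[f"fc_{tissue}"] = np.nan
        rec["n_tissues"] = len(sig_tissues)
        rec["tissues"] = tuple(sig_tissues)
        rows.append(rec)
    cols = (
        ["direction"]
        + [f"sig_{t}" for t in tissues]
        + [f"fc_{t}" for t in tissues]
        + ["n_tissues", "tissues"]
    )
    if not rows:
        return pd.DataFrame(columns=cols, index=pd.Index([], name="probe_id"))
    return pd.DataFrame(rows).set_index("probe_id")[cols]


def aggregate_entries(
    records: pd.DataFrame, ann: AnnotationTable
) -> pd.DataFrame:
    """Aggregate consistency records to gene-level entries.

    Probes sharing an entry_id (including intron-marked rows merged into
    their host entry) form one aggregate per direction: the significant
    tissues are unioned, coordinates span min(start)..max(stop). Entries
    whose probes are all intronic are flagged ``intronic``. The ``gene_key``
    (gene symbol, falling back to entry id for unnamed units) is the unit of
    "unique gene" counting.
    """
    missing = [pid for pid in records.index if pid not in ann.df.index]
    if missing:
        raise MetadataError(f"probes missing from annotation: {missing[:5]}")
    sig_cols = [c for c in records.columns if c.startswith("sig_")]
    tissues = [c[len("sig_"):] for c in sig_cols]
    joined = records.join(
        ann.df[["entry_id", "gene_symbol", "chrom", "start", "stop", "feature_class"]]
    )
    if joined["entry_id"].isna().any() or (joined["entry_id"] == "").any():
        bad = list(joined.index[(joined["entry_id"].isna()) | (joined["entry_id"] == "")])
        raise MetadataError(f"probes without entry_id: {bad[:5]}")
    rows = []
    for (entry_id, direction), grp in joined.groupby(["entry_id", "direction"]):
        tissue_union = [
            t for t in tissues if bool(grp[f"sig_{t}"].any())
        ]
        symbols = [s for s in grp["gene_symbol"].unique() if isinstance(s, str) and s]
        symbol = symbols[0] if symbols else ""
        rows.append(
            {
                "entry_id": entry_id,
                "gene_symbol": symbol,
                "gene_key": symbol if symbol else str(entry_id),
                "direction": direction,
                "n_probes": len(grp),
                "n_tissues": len(tissue_union),
                "tissues": tuple(tissue_union),
                "chrom": grp["chrom"].iloc[0],
                "start": float(grp["start"].min()),
                "stop": float(grp["stop"].max()),
                "intronic": bool((grp["feature_class"] == "intron").all()),
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    return out.sort_values(["chrom", "start"]).reset_index(drop=True)


def count_multibias(
    units: pd.DataFrame, min_tissues: int, level: str = "gene"
) -> int:
    """Number of genes or probe rows sex-biased in >= ``min_tissues`` tissues.

    ``level='gene'`` expects aggregates and counts unique gene keys
    (deduplicating entries that share a gene symbol); ``level='probe'``
    expects per-probe consistency records and counts rows. ``min_tissues``
    below 2 is rejected: consistency is defined from two tissues up.
    """
    if min_tissues < 2:
        raise ValueError("min_tissues must be >= 2")
    if level not in ("gene", "probe"):
        raise ValueError(f"unknown level {level!r}")
    if units.empty:
        return 0
    hits = units[units["n_tissues"] >= min_tissues]
    if level == "probe":
        return int(len(hits))
    return int(hits["gene_key"].nunique())


def find_clusters(
    aggregates: pd.DataFrame, max_gap: int = CLUSTER_GAP
) -> pd.DataFrame:
    """Chain entries on one chromosome whose adjacent gaps are < ``max_gap``.

    Single-linkage on start-sorted entries: the gap between consecutive
    entries is next.start - current.stop (0 when they overlap); a gap below
    the threshold joins them. Only clusters with >=2 members are reported,
    as BED-like rows: chrom, start, stop, cluster_id, n_members, member
    entry ids (ordered by start) and the largest internal gap.
    """
    if aggregates.empty:
        return pd.DataFrame(
            columns=["chrom", "start", "stop", "cluster_id", "n_members", "members", "max_gap"]
        )
    if aggregates[["start", "stop"]].isna().any().any():
        bad = aggregates.loc[aggregates[["start", "stop"]].isna().any(axis=1), "entry_id"]
        raise MetadataError(f"entries without coordinates: {list(bad)[:5]}")
    if aggregates["chrom"].nunique() > 1:
        raise MetadataError(
            "find_clusters expects entries from a single chromosome; "
            f"got {sorted(aggregates['chrom'].unique())}"
        )
    ordered = aggregates.sort_values(["start", "stop"]).reset_index(drop=True)
    all_rows = []
    current = [0]
    gaps: list[float] = []
    running_stop = float(ordered.loc[0, "stop"])

    def flush(members: list[int], gaps: list[float]) -> None:
        if len(members) >= 2:
            sub = ordered.loc[members]
            all_rows.append(
                {
                    "chrom": sub["chrom"].iloc[0],
                    "start": float(sub["start"].min()),
                    "stop": float(sub["stop"].max()),
                    "n_members": len(members),
                    "members": tuple(sub["entry_id"]),
                    "max_gap": max(gaps) if gaps else 0.0,
                }
            )

    for i in range(1, len(ordered)):
        start_i = float(ordered.loc[i, "start"])
        stop_i = float(ordered.loc[i, "stop"])
        gap = max(0.0, start_i - running_stop)
        if gap < max_gap:
            current.append(i)
            gaps.append(gap)
            running_stop = max(running_stop, stop_i)
        else:
            flush(current, gaps)
            current, gaps = [i], []
            running_stop = stop_i
    flush(current, gaps)
    out = pd.DataFrame(
        all_rows,
        columns=["chrom", "start", "stop", "n_members", "members", "max_gap"],
    )
    out.insert(3, "cluster_id", [f"cluster_{i + 1}" for i in range(len(out))])
    bad = out["max_gap"] >= max_gap
    if bad.any():
        raise XBiasError("internal error: emitted cluster violates gap threshold")
    return out


def table2_report(
    aggregates: pd.DataFrame, records: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Structured multi-tissue report: probe rows split by direction.

    Mirrors the printed table layout: per-probe rows carry per-tissue
    fold-change magnitude columns (NaN where not significant), the entry id
    and direction; the two directions are returned as separate frames under
    ``female`` and ``male`` keys, each sorted by entry then position.
    """
    out = {}
    fc_cols = [c for c in records.columns if c.startswith("fc_")]
    sig_cols = [c for c in records.columns if c.startswith("sig_")]
    for direction in (FEMALE, MALE):
        recs = records[records["direction"] == direction].copy()
        for fc, sig in zip(fc_cols, sig_cols):
            recs[fc] = recs[fc].where(recs[sig], np.nan)
        agg = aggregates[aggregates["direction"] == direction]
        n_entries = agg["entry_id"].nunique() if not agg.empty else 0
        recs.attrs["n_entries"] = int(n_entries)
        out[direction] = recs
    return out
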