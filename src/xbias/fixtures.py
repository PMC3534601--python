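"""Packaged transcriptions of the study's printed summary tables.

``table1`` is the per-tissue, per-chromosome-class tally of sex-biased probes
(counts and percentages at p<0.001). ``table2A``/``table2B`` are the per-probe
multi-tissue consistency tables (female- and male-biased sections): per-tissue
fold-change magnitudes with a two-level significance grade (p<0.001 printed
bold, p<0.01 italic — encoded here as ``**`` / ``*`` suffixes), probe-alignment
coordinates, gene labels, printed entry numbers (``8i`` marks intronic rows
that merge into entry 8; a bare ``i`` marks a standalone intronic row) and
proximity-cluster letters.

The array does not publish per-class probe totals; :func:`derive_class_totals`
recovers them from the printed count/percentage pairs.
"""
from __future__ import annotations

import re
from importlib import resources

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .model import FEMALE, MALE, AnnotationTable

#: Tissue column labels in printed order.
TISSUES = ("Ki", "Li", "Lu", "St", "Ey", "Hi")

#: Long tissue names (for reports).
TISSUE_NAMES = {
    "Ki": "Kidney",
    "Li": "Liver",
    "Lu": "Lung",
    "St": "Striatum",
    "Ey": "Eye",
    "Hi": "Hippocampus",
}

_FIXTURE_FILES = {
    "table1": "table1.tsv",
    "table2A": "table2a.tsv",
    "table2B": "table2b.tsv",
    "escapees": "escapees.txt",
}

_CELL_RE = re.compile(r"^(\d+(?:\.\d+)?)(\*{1,2})$")


def _fixture_text(name: str) -> str:
    try:
        fname = _FIXTURE_FILES[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown fixture {name!r}; expected one of {sorted(_FIXTURE_FILES)}"
        ) from None
    ref = resources.files("xbias") / "fixtures" / fname
    if not ref.is_file():
        raise ConfigurationError(f"fixture file missing from package: {fname}")
    return ref.read_text()


def _parse_cell(cell: str) -> tuple[float, float]:
    """A printed fold-change cell -> (magnitude, grade alpha) or (nan, nan)."""
    cell = cell.strip()
    if cell in ("ns", ""):
        return (np.nan, np.nan)
    m = _CELL_RE.match(cell)
    if not m:
        raise ConfigurationError(f"malformed fold-change cell {cell!r}")
    value = float(m.group(1))
    grade = 0.001 if m.group(2) == "**" else 0.01
    return (value, grade)


def load_table1() -> pd.DataFrame:
    """Counts/percentages of sex-biased probes per tissue and chromosome class.

    Columns: tissue, chrom_class (all/A/X/Y/NA), tot, f, m, pct_tot, pct_f,
    pct_m. ``tot`` is the number of sex-biased probes (f + m); percentages are
    relative to the number of probes in the class.
    """
    from io import StringIO

    # keep_default_na: the literal chromosome-class token "NA" must survive
    df = pd.read_csv(StringIO(_fixture_text("table1")), sep="\t", keep_default_na=False)
    for col in ("tot", "f", "m"):
        df[col] = df[col].astype(int)
    for col in ("pct_tot", "pct_f", "pct_m"):
        df[col] = df[col].astype(float)
    return df


def _load_table2(name: str, direction: str) -> pd.DataFrame:
    from io import StringIO

    raw = pd.read_csv(
        StringIO(_fixture_text(name)), sep="\t", dtype=str, keep_default_na=False
    )
    rows = []
    bare_intron = 0
    for _, r in raw.iterrows():
        rec: dict = {
            "probe_id": r["probe_id"],
            "chrom": r["chrom"],
            "start": int(r["start"]),
            "stop": int(r["stop"]),
            "label": r["gene_symbol"],
            "cluster": r.get("cluster", "") or "",
            "direction": direction,
        }
        entry_raw = r["entry"].strip()
        if entry_raw == "i":
            bare_intron += 1
            rec["entry_num"] = None
            rec["entry_id"] = f"{direction[0].upper()}i{bare_intron}_{r['probe_id']}"
            rec["intronic"] = True
        else:
            m = re.match(r"^(\d+)(i?)$", entry_raw)
            if not m:
                raise ConfigurationError(f"malformed entry label {entry_raw!r}")
            rec["entry_num"] = int(m.group(1))
            rec["entry_id"] = f"{direction[0].upper()}{int(m.group(1)):03d}"
            rec["intronic"] = bool(m.group(2))
        label = r["gene_symbol"]
        if "Intergenic" in label:
            rec["feature_class"] = "intergenic"
            rec["gene_symbol"] = ""
        elif "intron" in label:
            rec["feature_class"] = "intron"
            host = re.search(r"\(([^)]+) intron\)", label)
            rec["gene_symbol"] = host.group(1) if host else ""
        else:
            rec["feature_class"] = "gene"
            rec["gene_symbol"] = label
        for tissue in TISSUES:
            fc, grade = _parse_cell(r[tissue])
            rec[f"fc_{tissue}"] = fc
            rec[f"grade_{tissue}"] = grade
        rows.append(rec)
    df = pd.DataFrame(rows).set_index("probe_id")
    return df


def load_fixture(name: str):
    """Load a packaged fixture by name: table1, table2A, table2B or escapees."""
    if name == "table1":
        return load_table1()
    if name == "table2A":
        return _load_table2("table2A", FEMALE)
    if name == "table2B":
        return _load_table2("table2B", MALE)
    if name == "escapees":
        from .model import EscapeeList

        symbols = set()
        for line in _fixture_text("escapees").splitlines():
            line = line.split("#", 1)[0].strip()
            if line:
                symbols.add(line)
        return EscapeeList(frozenset(symbols))
    raise ConfigurationError(f"unknown fixture {name!r}")


def derive_class_totals(table1: pd.DataFrame | None = None) -> dict[str, int]:
    """Recover per-class array probe totals from printed count/percentage pairs.

    For each chromosome class the total is estimated by the pooled ratio
    sum(counts) / sum(percent/100) over every printed cell of that class with
    a nonzero percentage, then rounded to the nearest probe. The printed
    percentages carry rounding error, so the totals are accurate to a few
    tens of probes — enough for the relative enrichment/depletion contrasts.
    """
    if table1 is None:
        table1 = load_table1()
    totals: dict[str, int] = {}
    for chrom_class, grp in table1.groupby("chrom_class"):
        count_sum = 0.0
        frac_sum = 0.0
        for count_col, pct_col in (("tot", "pct_tot"), ("f", "pct_f"), ("m", "pct_m")):
            counts = grp[count_col].to_numpy(dtype=float)
            pcts = grp[pct_col].to_numpy(dtype=float)
            keep = pcts > 0
            count_sum += counts[keep].sum()
            frac_sum += (pcts[keep] / 100.0).sum()
        if frac_sum > 0:
            totals[chrom_class] = int(round(count_sum / frac_sum))
    return totals


def fixture_consistency_records(table2: pd.DataFrame) -> pd.DataFrame:
    """Convert a parsed table2 section to multi-tissue consistency records.

    One row per probe: direction, the set of tissues significant at p<0.01
    (any printed grade), and per-tissue fold-change magnitudes. Matches the
    output layout of :func:`xbias.multitissue.consistent_probes`.
    """
    recs = table2.copy()
    sig_cols = {}
    for tissue in TISSUES:
        sig_cols[f"sig_{tissue}"] = recs[f"grade_{tissue}"].notna()
    out = pd.DataFrame(sig_cols, index=recs.index)
    out["direction"] = recs["direction"]
    for tissue in TISSUES:
        out[f"fc_{tissue}"] = recs[f"fc_{tissue}"]
    out["n_tissues"] = out[[f"sig_{t}" for t in TISSUES]].sum(axis=1).astype(int)
    out["tissues"] = out.apply(
        lambda r: tuple(t for t in TISSUES if r[f"sig_{t}"]), axis=1
    )
    return out


def fixture_annotation(table2: pd.DataFrame) -> AnnotationTable:
    """Build an :class:`AnnotationTable` for the probes of a table2 section."""
    df = pd.DataFrame(
        {
            "entry_id": table2["entry_id"],
            "gene_symbol": table2["gene_symbol"],
            "chrom_class": "X",
            "chrom": table2["chrom"],
            "start": table2["start"].astype(float),
            "stop": table2["stop"].astype(float),
            "feature_class": table2["feature_class"],
            "ensembl_id": "",
        }
    )
    df.index.name = "probe_id"
    return AnnotationTable(df)
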