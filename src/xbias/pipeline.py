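"""End-to-end orchestration and the packaged-fixture reproduction suite.

``run_all`` executes the full analysis on either a simulated experiment or
real tab-delimited inputs: standardization, per-tissue screening,
chromosome-class tabulation and contrasts (with and without escapee
exclusion), cross-tissue consistency, aggregation and cluster detection,
and per-tissue gene-age analysis, writing every report plus a run log.

``fixtures_check`` recomputes every number the packaged table fixtures pin
down and compares them to their expected values.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, DegenerateInputError
from .model import FEMALE, MALE, standardize
from . import io as xio
from .enrichment import (
    COMPARISONS,
    compare_classes,
    counts_from_table1,
    enrichment_report,
    exclude_escapees,
    relative_depletion_percent,
    tabulate,
)
from .fixtures import derive_class_totals, fixture_annotation, fixture_consistency_records, load_fixture
from .gene_age import age_split_test, branch_proportions, join_branches
from .multitissue import aggregate_entries, consistent_probes, count_multibias, find_clusters
from .simulate import SimConfig, generate_experiment
from .stats import test_tissue, write_results

logger = logging.getLogger("xbias")


@dataclass
class PipelineConfig:
    """Flat pipeline configuration.

    Exactly one of ``sim`` (a :class:`SimConfig`) or ``paths`` (real input
    files) must be set. ``paths`` maps: ``expression`` (dict tissue -> file),
    ``samples``, ``annotation``, and optionally ``escapees`` / ``branches``.
    """

    sim: SimConfig | None = None
    paths: dict | None = None
    alpha_primary: float = 0.001
    alpha_consistency: float = 0.01
    cluster_gap: int = 50_000
    min_branch_probes: int = 10
    seed: int = 0
    outdir: str = "xbias_out"

    def validate(self) -> None:
        if (self.sim is None) == (self.paths is None):
            raise ConfigurationError("set exactly one of sim config or input paths")
        for alpha in (self.alpha_primary, self.alpha_consistency):
            if not 0.0 < alpha < 1.0:
                raise ConfigurationError("significance thresholds must be in (0, 1)")
        if self.cluster_gap <= 0:
            raise ConfigurationError("cluster_gap must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        sim = None
        if "sim" in doc:
            sim_doc = doc.pop("sim")
            if isinstance(sim_doc, str):
                sim = SimConfig.from_yaml(sim_doc)
            else:
                import tempfile, os

                with tempfile.NamedTemporaryFile(
                    "w", suffix=".yaml", delete=False
                ) as fh:
                    yaml.safe_dump(sim_doc, fh)
                    tmp = fh.name
                try:
                    sim = SimConfig.from_yaml(tmp)
                finally:
                    os.unlink(tmp)
        cfg = cls(sim=sim, **doc)
        cfg.validate()
        return cfg


def _load_inputs(config: PipelineConfig):
    if config.sim is not None:
        sim = config.sim
        if config.seed is not None:
            from dataclasses import replace

            sim = replace(sim, seed=config.seed)
        exp = generate_experiment(sim)
        return exp.matrices, exp.samples, exp.annotation, exp.escapees, exp.branch_table()
    paths = config.paths or {}
    matrices = {
        tissue: xio.read_expression(p) for tissue, p in paths["expression"].items()
    }
    samples = xio.read_sample_table(paths["samples"])
    ann = xio.read_annotation(paths["annotation"])
    esc = xio.read_escapees(paths["escapees"]) if paths.get("escapees") else None
    branches = xio.read_branches(paths["branches"]) if paths.get("branches") else None
    return matrices, samples, ann, esc, branches


def run_all(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle to ``config.outdir``."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run_log.txt", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("xbias %s seed=%s alpha_primary=%s alpha_consistency=%s "
                    "cluster_gap=%s min_branch_probes=%s", __version__, config.seed,
                    config.alpha_primary, config.alpha_consistency,
                    config.cluster_gap, config.min_branch_probes)
        matrices, samples, ann, esc, branches = _stage(
            "load", _load_inputs, config
        )

        std = _stage(
            "standardize",
            lambda: {t: standardize(m) for t, m in matrices.items()},
        )
        results = _stage(
            "test",
            lambda: {
                t: test_tissue(m, samples.for_tissue(t), config.alpha_primary)
                for t, m in std.items()
            },
        )
        for t, res in results.items():
            write_results(res, outdir / f"results_{t}.tsv")

        counts = _stage("tabulate", tabulate, results, ann, config.alpha_primary)
        counts.to_csv(outdir / "bias_counts.tsv", sep="\t", float_format="%.4g")
        contrasts = _stage("enrich", _contrasts, counts, list(results))
        enrichment_report(contrasts).to_csv(
            outdir / "enrichment.tsv", sep="\t", index=False, float_format="%.6g"
        )
        if esc is not None:
            filtered = {
                t: exclude_escapees(res, ann, esc) for t, res in results.items()
            }
            counts_x = tabulate(filtered, ann, config.alpha_primary)
            contrasts_x = _contrasts(counts_x, list(filtered))
            enrichment_report(contrasts_x).to_csv(
                outdir / "enrichment_excl_escapees.tsv",
                sep="\t",
                index=False,
                float_format="%.6g",
            )

        records = _stage(
            "consistency", consistent_probes, results, config.alpha_consistency
        )
        records.to_csv(outdir / "consistency.tsv", sep="\t", float_format="%.6g")
        aggregates = _stage("aggregate", aggregate_entries, records, ann)
        aggregates.to_csv(
            outdir / "aggregates.tsv", sep="\t", index=False, float_format="%.10g"
        )
        fem_x = aggregates[
            (aggregates["direction"] == FEMALE) & (aggregates["chrom"] == "X")
        ] if not aggregates.empty else aggregates
        clusters = _stage("clusters", find_clusters, fem_x, config.cluster_gap)
        _write_clusters(clusters, outdir / "clusters.tsv")

        age_rows = []
        if branches is not None:
            for t, res in results.items():
                joined = join_branches(res, ann, branches, config.alpha_primary)
                props = branch_proportions(joined, config.min_branch_probes)
                props.to_csv(
                    outdir / f"branch_proportions_{t}.tsv",
                    sep="\t",
                    float_format="%.6g",
                )
                for direction in (FEMALE, MALE):
                    try:
                        r = age_split_test(joined, direction)
                        age_rows.append(
                            {
                                "tissue": t,
                                "direction": direction,
                                "old_biased": r.old_biased,
                                "old_total": r.old_total,
                                "young_biased": r.young_biased,
                                "young_total": r.young_total,
                                "odds_ratio": r.odds_ratio,
                                "p": r.p,
                            }
                        )
                    except DegenerateInputError as exc:
                        logger.warning("age split (%s, %s) skipped: %s", t, direction, exc)
            pd.DataFrame(age_rows).to_csv(
                outdir / "age_split.tsv", sep="\t", index=False, float_format="%.6g"
            )
        logger.info("pipeline complete: %d tissues, outputs in %s", len(results), outdir)
        return {
            "results": results,
            "counts": counts,
            "contrasts": contrasts,
            "records": records,
            "aggregates": aggregates,
            "clusters": clusters,
            "age": pd.DataFrame(age_rows),
        }
    finally:
        logger.removeHandler(handler)
        handler.close()


def _stage(name, fn, *args):
    try:
        out = fn(*args)
        logger.info("stage %s ok", name)
        return out
    except Exception:
        logger.exception("stage %s failed", name)
        raise


def _contrasts(counts, tissues):
    out = []
    for t in tissues:
        for comparison in COMPARISONS:
            try:
                out.append(compare_classes(counts, t, comparison))
            except DegenerateInputError as exc:
                logger.warning("contrast %s/%s skipped: %s", t, comparison, exc)
    return out


def _write_clusters(clusters: pd.DataFrame, path: Path) -> None:
    df = clusters.copy()
    if not df.empty:
        df["members"] = df["members"].map(lambda m: ",".join(m))
        df["start"] = df["start"].astype(int)
        df["stop"] = df["stop"].astype(int)
        df["max_gap"] = df["max_gap"].astype(int)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# packaged-fixture reproduction
# ---------------------------------------------------------------------------

#: Genes found female-biased in every tissue of the multi-tissue table —
#: all previously recognised XCI escapees.
ALL_TISSUE_FEMALE_GENES = frozenset(
    {
        "Ddx3x",
        "Kdm6a",
        "Eif2s3x",
        "Xist",
        "5530601H04Rik",
        "2610029G23Rik",
        "Kdm5c",
        "D930009K15Rik",
    }
)


def fixture_numbers() -> dict:
    """Recompute every fixture-pinned quantity from the packaged tables."""
    table1 = load_fixture("table1")
    totals = derive_class_totals(table1)
    logger.info("derived class totals: %s", totals)
    counts = counts_from_table1(table1, totals)
    out: dict = {
        "class_total_X": totals["X"],
        "class_total_A": totals["A"],
    }
    for tissue, key in (("Kidney", "kidney"), ("Liver", "liver")):
        res = compare_classes(counts, tissue, "XM_vs_AM")
        out[f"{key}_male_depletion_pct"] = relative_depletion_percent(res)
        out[f"{key}_male_depletion_p"] = res.p

    t2a = load_fixture("table2A")
    t2b = load_fixture("table2B")
    out["female_entries"] = int(t2a["entry_num"].dropna().nunique())
    out["male_entries"] = int(t2b["entry_num"].dropna().nunique())
    out["female_intron_rows"] = int(t2a["intronic"].sum())
    out["male_intron_rows"] = int(t2b["intronic"].sum())

    rec_a = fixture_consistency_records(t2a)
    rec_b = fixture_consistency_records(t2b)
    agg_a = aggregate_entries(rec_a, fixture_annotation(t2a))
    out["female_genes_ge3_tissues"] = count_multibias(agg_a, 3, level="gene")
    out["male_probes_ge3_tissues"] = count_multibias(rec_b, 3, level="probe")
    out["male_probes_ge4_tissues"] = count_multibias(rec_b, 4, level="probe")

    all_six = agg_a[agg_a["n_tissues"] == 6]
    out["all_tissue_female_genes"] = frozenset(
        s for s in all_six["gene_symbol"] if s
    )

    esc = load_fixture("escapees")
    filtered = exclude_escapees(rec_a, fixture_annotation(t2a), esc)
    agg_filtered = aggregate_entries(filtered, fixture_annotation(t2a)) if not filtered.empty else filtered
    out["all_tissue_female_after_exclusion"] = (
        0
        if agg_filtered.empty
        else int((agg_filtered["n_tissues"] == 6).sum())
    )

    fem_x = agg_a[agg_a["chrom"] == "X"]
    clusters = find_clusters(fem_x, 50_000)
    kdm5c_entry = agg_a.loc[agg_a["gene_symbol"] == "Kdm5c", "entry_id"].iloc[0]
    members = None
    for _, row in clusters.iterrows():
        if kdm5c_entry in row["members"]:
            members = row["members"]
            break
    out["kdm5c_cluster_size"] = 0 if members is None else len(members)
    out["kdm5c_cluster_members"] = members
    return out


#: expected values for each fixture check (printed-table reproductions)
FIXTURE_EXPECTED = {
    "kidney_male_depletion_pct": 25,
    "liver_male_depletion_pct": 27,
    "female_entries": 94,
    "male_entries": 33,
    "female_intron_rows": 8,
    "male_intron_rows": 2,
    "female_genes_ge3_tissues": 25,
    "male_probes_ge3_tissues": 2,
    "male_probes_ge4_tissues": 0,
    "all_tissue_female_genes": ALL_TISSUE_FEMALE_GENES,
    "all_tissue_female_after_exclusion": 0,
    "kdm5c_cluster_size": 5,
}


def fixtures_check() -> tuple[bool, dict]:
    """Compare recomputed fixture numbers against their expected values."""
    actual = fixture_numbers()
    report = {}
    ok = True
    for key, expected in FIXTURE_EXPECTED.items():
        got = actual.get(key)
        passed = got == expected
        ok = ok and passed
        report[key] = {"expected": expected, "actual": got, "pass": passed}
    return ok, report
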