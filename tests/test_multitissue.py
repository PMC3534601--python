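"""Cross-tissue consistency, entry aggregation and proximity clustering."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from xbias.errors import MetadataError
from xbias.fixtures import (
    fixture_annotation,
    fixture_consistency_records,
    load_fixture,
)
from xbias.model import AnnotationTable
from xbias.multitissue import (
    aggregate_entries,
    consistent_probes,
    count_multibias,
    find_clusters,
    table2_report,
)
from xbias.stats import recall_at


def _results(probes_p: dict[str, tuple[float, float]]) -> pd.DataFrame:
    """Tiny result frame from probe -> (delta, p_wilcoxon)."""
    idx = pd.Index(sorted(probes_p), name="probe_id")
    delta = np.array([probes_p[p][0] for p in idx])
    p = np.array([probes_p[p][1] for p in idx])
    return pd.DataFrame(
        {
            "mean_f": 8 + delta / 2,
            "mean_m": 8 - delta / 2,
            "delta": delta,
            "fold_change": 2.0**delta,
            "p_wilcoxon": p,
            "p_ttest": p,
            "call": "ns",
        },
        index=idx,
    )


def _ann(rows) -> AnnotationTable:
    df = pd.DataFrame(
        rows,
        columns=["probe_id", "entry_id", "gene_symbol", "chrom", "start", "stop", "feature_class"],
    )
    df["chrom_class"] = "X"
    df["ensembl_id"] = ""
    return AnnotationTable(df.set_index("probe_id"))


class TestConsistentProbes:
    def test_two_tissue_same_direction_included(self):
        res = {
            "a": _results({"p1": (0.5, 0.001)}),
            "b": _results({"p1": (0.4, 0.005)}),
        }
        rec = consistent_probes(res, alpha=0.01)
        assert list(rec.index) == ["p1"]
        assert rec.loc["p1", "direction"] == "female"
        assert rec.loc["p1", "n_tissues"] == 2

    def test_single_tissue_excluded(self):
        res = {
            "a": _results({"p1": (0.5, 0.001)}),
            "b": _results({"p1": (0.4, 0.5)}),
        }
        assert consistent_probes(res, alpha=0.01).empty

    def test_opposite_directions_excluded(self):
        res = {
            "a": _results({"p1": (0.5, 0.001)}),
            "b": _results({"p1": (-0.5, 0.001)}),
        }
        assert consistent_probes(res, alpha=0.01).empty

    def test_threshold_nesting_from_simulation(self, small_results):
        """Every probe biased at 0.001 in >=2 tissues (same direction)
        appears in the relaxed 0.01 consistency set."""
        strict = consistent_probes(small_results, alpha=0.001)
        relaxed = consistent_probes(small_results, alpha=0.01)
        assert set(strict.index) <= set(relaxed.index)
        assert len(strict) > 0


class TestAggregation:
    def test_union_semantics_on_disjoint_tissue_pairs(self):
        res = {
            t: _results({"p1": (0.5, 0.001), "p2": (0.5, 0.001)})
            for t in ("a", "b", "c", "d")
        }
        # p1 significant in a, b only; p2 in c, d only
        res["c"].loc["p1", "p_wilcoxon"] = 0.9
        res["d"].loc["p1", "p_wilcoxon"] = 0.9
        res["a"].loc["p2", "p_wilcoxon"] = 0.9
        res["b"].loc["p2", "p_wilcoxon"] = 0.9
        rec = consistent_probes(res, alpha=0.01)
        ann = _ann(
            [
                ("p1", "E1", "GeneA", "X", 100, 200, "gene"),
                ("p2", "E1", "GeneA", "X", 300, 400, "gene"),
            ]
        )
        agg = aggregate_entries(rec, ann)
        assert len(agg) == 1
        assert agg.iloc[0]["n_tissues"] == 4
        assert agg.iloc[0]["start"] == 100 and agg.iloc[0]["stop"] == 400

    def test_eif2s3x_aggregates_to_all_six_tissues(self):
        t2a = load_fixture("table2A")
        agg = aggregate_entries(fixture_consistency_records(t2a), fixture_annotation(t2a))
        eif = agg[agg["gene_symbol"] == "Eif2s3x"]
        assert len(eif) == 1
        assert eif.iloc[0]["n_probes"] == 3
        assert eif.iloc[0]["n_tissues"] == 6

    def test_probe_without_entry_is_metadata_error(self):
        res = {
            "a": _results({"p1": (0.5, 0.001)}),
            "b": _results({"p1": (0.5, 0.001)}),
        }
        rec = consistent_probes(res, alpha=0.01)
        ann = _ann([("p1", "", "GeneA", "X", 100, 200, "gene")])
        with pytest.raises(MetadataError):
            aggregate_entries(rec, ann)


@pytest.fixture(scope="module")
def table2a_aggregates():
    t2a = load_fixture("table2A")
    return aggregate_entries(
        fixture_consistency_records(t2a), fixture_annotation(t2a)
    )


class TestCountMultibias:
    def test_female_genes_more_than_two_tissues(self, table2a_aggregates):
        assert count_multibias(table2a_aggregates, 3, level="gene") == 25

    def test_male_probe_counts(self):
        rec = fixture_consistency_records(load_fixture("table2B"))
        assert count_multibias(rec, 3, level="probe") == 2
        assert count_multibias(rec, 4, level="probe") == 0

    def test_empty_input(self):
        assert count_multibias(pd.DataFrame(columns=["n_tissues"]), 3, "probe") == 0

    def test_min_tissues_below_two_rejected(self, table2a_aggregates):
        with pytest.raises(ValueError):
            count_multibias(table2a_aggregates, 1, level="gene")


def _toy_aggregates(coords, chrom="X"):
    return pd.DataFrame(
        {
            "entry_id": [f"E{i}" for i in range(len(coords))],
            "gene_symbol": [f"G{i}" for i in range(len(coords))],
            "gene_key": [f"G{i}" for i in range(len(coords))],
            "direction": "female",
            "n_probes": 1,
            "n_tissues": 2,
            "tissues": [("a", "b")] * len(coords),
            "chrom": chrom,
            "start": [c[0] for c in coords],
            "stop": [c[1] for c in coords],
            "intronic": False,
        }
    )


class TestFindClusters:
    def test_one_gap_below_one_above_threshold(self):
        agg = _toy_aggregates([(0, 10_000), (20_000, 30_000), (200_000, 210_000)])
        calls = find_clusters(agg, max_gap=50_000)
        assert len(calls) == 1
        assert calls.iloc[0]["members"] == ("E0", "E1")

    def test_overlapping_entries_cluster(self):
        agg = _toy_aggregates([(0, 10_000), (5_000, 15_000)])
        calls = find_clusters(agg, max_gap=50_000)
        assert len(calls) == 1
        assert calls.iloc[0]["max_gap"] == 0.0

    def test_input_order_invariance(self):
        coords = [(0, 10_000), (20_000, 30_000), (35_000, 36_000), (500_000, 510_000)]
        agg = _toy_aggregates(coords)
        shuffled = agg.sample(frac=1.0, random_state=3)
        a = find_clusters(agg, 50_000)
        b = find_clusters(shuffled, 50_000)
        assert list(a["members"]) == list(b["members"])

    def test_emitted_clusters_respect_gap_bound(self):
        rng = np.random.default_rng(9)
        starts = np.sort(rng.integers(0, 5_000_000, size=60))
        agg = _toy_aggregates([(s, s + 500) for s in starts])
        calls = find_clusters(agg, 30_000)
        assert (calls["max_gap"] < 30_000).all()

    def test_mixed_chromosomes_rejected(self):
        agg = _toy_aggregates([(0, 1000), (2000, 3000)])
        agg.loc[1, "chrom"] = "7"
        with pytest.raises(MetadataError):
            find_clusters(agg)

    def test_kdm5c_cluster_from_printed_coordinates(self):
        """Entries 76-80 (Kdm5c through 2900056M20Rik) chain into a single
        5-member cluster under the 50 kb rule."""
        t2a = load_fixture("table2A")
        agg = aggregate_entries(
            fixture_consistency_records(t2a), fixture_annotation(t2a)
        )
        calls = find_clusters(agg[agg["chrom"] == "X"], 50_000)
        kdm5c = [
            row for _, row in calls.iterrows() if "F076" in row["members"]
        ]
        assert len(kdm5c) == 1
        assert kdm5c[0]["members"] == ("F076", "F077", "F078", "F079", "F080")

    def test_planted_clusters_recovered_exactly(self, small_experiment, small_results):
        """Precision and recall of planted cluster membership are 1.0 when
        every member is detected (cluster effects are planted large)."""
        exp = small_experiment
        rec = consistent_probes(small_results, alpha=0.01)
        agg = aggregate_entries(rec, exp.annotation)
        fem_x = agg[(agg["direction"] == "female") & (agg["chrom"] == "X")]
        calls = find_clusters(fem_x, 50_000)
        detected = {frozenset(m) for m in calls["members"]}
        truth = exp.truth.df
        planted = {
            frozenset(truth.loc[truth["cluster_id"] == cid, "entry_id"])
            for cid in truth["cluster_id"].unique()
            if cid
        }
        assert detected == planted


class TestTable2Report:
    def test_fixture_round_trip_counts(self):
        t2a = load_fixture("table2A")
        t2b = load_fixture("table2B")
        rec = pd.concat(
            [fixture_consistency_records(t2a), fixture_consistency_records(t2b)]
        )
        ann_df = pd.concat(
            [fixture_annotation(t2a).df, fixture_annotation(t2b).df]
        )
        agg = aggregate_entries(rec, AnnotationTable(ann_df))
        report = table2_report(agg, rec)
        assert report["female"].attrs["n_entries"] == 94 + 1  # 94 numbered + Snx12 intron
        assert report["male"].attrs["n_entries"] == 33 + 2  # 33 numbered + 2 introns
        assert len(report["female"]) == 133
        assert len(report["male"]) == 37

    def test_empty_input_gives_empty_report(self):
        rec = pd.DataFrame(
            columns=["direction", "sig_a", "sig_b", "fc_a", "fc_b", "n_tissues", "tissues"],
            index=pd.Index([], name="probe_id"),
        )
        report = table2_report(rec.iloc[:0], rec)
        assert report["female"].empty and report["male"].empty
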