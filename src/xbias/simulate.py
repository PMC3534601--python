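"""Synthetic multi-tissue two-sex expression experiments with planted truth.

The generator emulates the study design the pipeline targets: a large
oligonucleotide array (~43,000 autosomal probes, ~1,400 X probes, a handful
of Y probes and a few unmapped ones) hybridized with female and male samples
from several somatic tissues. Log2 intensities are near-normal around a
per-probe baseline (mean 8, between-probe SD ~1.94) with per-probe residual
noise (SD 0.5), so the pooled SD is ~2 and the mean-8/SD-2 standardization
is a near-no-op. Sex effects are planted as symmetric log2 shifts: females
draw from Normal(baseline + delta/2, noise_sd) and males from
Normal(baseline - delta/2, noise_sd).

Planted features mirror the salient structure of the real data:

* X effects are mostly small and female-biased (|delta| drawn from
  [0.07, 1.0], i.e. fold-changes ~1.05-2), while "dimorphic" tissues
  (kidney/liver-like) allow much larger autosomal effects;
* an Xist-like X probe is expressed in females only (delta ~7, a
  ~128-fold change);
* Y probes are expressed in males only, females sitting at a fixed low
  floor (4.0) because arrays report an intensity for every probe;
* a configurable number of escapee-like X entries are female-biased in
  every tissue;
* female-biased positional clusters are planted on X with inter-gene gaps
  drawn from [1 kb, max_gap), while all other X genes are spaced at least
  five cluster thresholds apart so no accidental cluster can arise;
* every entry carries a phylogenetic branch label 0-11, with an optional
  interaction that enriches old branches (0-5) among female-biased entries.

Every probe, its per-tissue true delta, escapee flag, cluster membership
and branch are recorded in :class:`PlantedTruth` for recovery testing.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .model import (
    AnnotationTable,
    EscapeeList,
    ExpressionMatrix,
    FEMALE,
    MALE,
    SampleTable,
)

#: 5x the default 50 kb cluster rule: minimum spacing of non-cluster X genes.
NONCLUSTER_SPACING = 250_000

_DEFAULT_BRANCH_WEIGHTS = (
    0.25, 0.10, 0.08, 0.07, 0.004, 0.15, 0.08, 0.07, 0.004, 0.004, 0.09, 0.098,
)


@dataclass(frozen=True)
class TissueEffects:
    """Per-tissue planted effect fractions and effect-size ranges.

    Fractions are the probabilities that a background probe of the class is
    female-/male-biased in this tissue; deltas are drawn uniformly from the
    given log2 ranges. The defaults scale with the detected fractions of the
    six study tissues, kidney- and liver-like tissues being strongly
    dimorphic with large autosomal effects.
    """

    name: str
    frac_female_a: float = 0.0
    frac_male_a: float = 0.0
    frac_female_x: float = 0.0
    frac_male_x: float = 0.0
    x_delta_range: tuple[float, float] = (0.07, 1.0)
    a_delta_range: tuple[float, float] = (0.07, 1.0)

    def validate(self) -> None:
        for frac in (
            self.frac_female_a,
            self.frac_male_a,
            self.frac_female_x,
            self.frac_male_x,
        ):
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError(
                    f"tissue {self.name!r}: effect fractions must be in [0, 1]"
                )
        for rng_ in (self.x_delta_range, self.a_delta_range):
            if rng_[0] <= 0 or rng_[1] < rng_[0]:
                raise ConfigurationError(
                    f"tissue {self.name!r}: delta range must be 0 < lo <= hi"
                )


def default_tissue_effects() -> tuple[TissueEffects, ...]:
    """Six tissues mirroring the detected-bias structure of the study:
    two strongly dimorphic (kidney/liver-like), four weakly dimorphic."""
    dimorphic = {"a_delta_range": (0.07, 3.0)}
    return (
        TissueEffects("kidney", 0.097, 0.085, 0.137, 0.064, **dimorphic),
        TissueEffects("liver", 0.053, 0.062, 0.078, 0.046, **dimorphic),
        TissueEffects("lung", 0.006, 0.0054, 0.029, 0.004),
        TissueEffects("striatum", 0.0116, 0.0045, 0.026, 0.001),
        TissueEffects("eye", 0.0007, 0.0005, 0.025, 0.0014),
        TissueEffects("hippocampus", 0.0001, 0.0001, 0.016, 0.0014),
    )


@dataclass(frozen=True)
class ClusterSpec:
    """A planted female-biased cluster: member count and maximum gap (bp)."""

    n_genes: int
    max_gap: int = 40_000


@dataclass(frozen=True)
class SimConfig:
    """Full description of a simulated experiment; a fixed seed makes the
    generated outputs bit-identical across runs."""

    seed: int = 0
    tissues: tuple[TissueEffects, ...] = field(default_factory=default_tissue_effects)
    samples_per_sex: int = 50
    n_probes_a: int = 43_000
    n_probes_x: int = 1_428
    n_probes_y: int = 16
    n_probes_na: int = 30
    baseline_mean: float = 8.0
    baseline_sd: float = 1.94
    noise_sd: float = 0.5
    n_escapees: int = 8
    escapee_delta: float = 0.4
    xist_like: bool = True
    xist_delta: float = 7.0
    y_male_only: bool = True
    y_floor: float = 4.0
    clusters: tuple[ClusterSpec, ...] = (ClusterSpec(5), ClusterSpec(2))
    cluster_delta: float = 0.6
    noncluster_spacing: int = NONCLUSTER_SPACING
    chrom_length_x: int | None = None
    branch_weights: tuple[float, ...] = _DEFAULT_BRANCH_WEIGHTS
    old_female_odds: float = 3.0

    def validate(self) -> None:
        if self.samples_per_sex < 2:
            raise ConfigurationError("samples_per_sex must be >= 2")
        for n in (self.n_probes_a, self.n_probes_x, self.n_probes_y, self.n_probes_na):
            if n < 0:
                raise ConfigurationError("probe counts must be nonnegative")
        if self.n_probes_x < 1:
            raise ConfigurationError("need at least one X probe")
        if not self.tissues:
            raise ConfigurationError("at least one tissue required")
        names = [t.name for t in self.tissues]
        if len(set(names)) != len(names):
            raise ConfigurationError("tissue names must be unique")
        for t in self.tissues:
            t.validate()
        if self.noise_sd <= 0 or self.baseline_sd < 0:
            raise ConfigurationError("noise_sd must be > 0, baseline_sd >= 0")
        if len(self.branch_weights) != 12 or min(self.branch_weights) < 0:
            raise ConfigurationError("branch_weights must be 12 nonnegative numbers")
        if self.old_female_odds <= 0:
            raise ConfigurationError("old_female_odds must be positive")
        n_special = (
            (1 if self.xist_like else 0)
            + self.n_escapees
            + sum(c.n_genes for c in self.clusters)
        )
        if n_special > self.n_probes_x:
            raise ConfigurationError(
                "xist + escapees + cluster members exceed the X probe count"
            )

    # -- flat key-value serialization ------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        doc: dict = {
            k: getattr(self, k)
            for k in (
                "seed", "samples_per_sex", "n_probes_a", "n_probes_x",
                "n_probes_y", "n_probes_na", "baseline_mean", "baseline_sd",
                "noise_sd", "n_escapees", "escapee_delta", "xist_like",
                "xist_delta", "y_male_only", "y_floor", "cluster_delta",
                "noncluster_spacing", "chrom_length_x", "old_female_odds",
            )
        }
        doc["branch_weights"] = list(self.branch_weights)
        doc["clusters"] = [[c.n_genes, c.max_gap] for c in self.clusters]
        doc["tissues"] = [
            {
                "name": t.name,
                "frac_female_a": t.frac_female_a,
                "frac_male_a": t.frac_male_a,
                "frac_female_x": t.frac_female_x,
                "frac_male_x": t.frac_male_x,
                "x_delta_range": list(t.x_delta_range),
                "a_delta_range": list(t.a_delta_range),
            }
            for t in self.tissues
        ]
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        doc = yaml.safe_load(Path(path).read_text())
        tissues = tuple(
            TissueEffects(
                name=t["name"],
                frac_female_a=float(t.get("frac_female_a", 0.0)),
                frac_male_a=float(t.get("frac_male_a", 0.0)),
                frac_female_x=float(t.get("frac_female_x", 0.0)),
                frac_male_x=float(t.get("frac_male_x", 0.0)),
                x_delta_range=tuple(t.get("x_delta_range", (0.07, 1.0))),
                a_delta_range=tuple(t.get("a_delta_range", (0.07, 1.0))),
            )
            for t in doc.pop("tissues", [])
        ) or default_tissue_effects()
        clusters = tuple(
            ClusterSpec(int(n), int(g)) for n, g in doc.pop("clusters", [])
        )
        weights = tuple(doc.pop("branch_weights", _DEFAULT_BRANCH_WEIGHTS))
        cfg = cls(tissues=tissues, clusters=clusters, branch_weights=weights, **doc)
        cfg.validate()
        return cfg


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth of a simulated experiment.

    ``df`` has one row per probe (exactly once): entry_id, chrom_class,
    escapee flag, cluster_id ('' if none), branch, and one ``delta_<tissue>``
    column per tissue with the true log2 sex difference.
    """

    df: pd.DataFrame

    def delta(self, probe_id: str, tissue: str) -> float:
        return float(self.df.loc[probe_id, f"delta_{tissue}"])

    def deltas(self, tissue: str) -> pd.Series:
        return self.df[f"delta_{tissue}"]

    def write(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", float_format="%.6g")


@dataclass(frozen=True)
class Experiment:
    """A generated experiment bundle."""

    config: SimConfig
    matrices: dict[str, ExpressionMatrix]
    samples: SampleTable
    annotation: AnnotationTable
    truth: PlantedTruth
    escapees: EscapeeList | None

    @property
    def tissues(self) -> list[str]:
        return list(self.matrices)

    def branch_table(self):
        """Branch assignments keyed on the simulated Ensembl-style ids."""
        from .model import BranchTable

        ann = self.annotation.df
        keyed = self.truth.df.join(ann["ensembl_id"])
        series = (
            keyed.drop_duplicates("ensembl_id").set_index("ensembl_id")["branch"]
        )
        return BranchTable(series.astype(int))


def _place_x_entries(cfg: SimConfig, rng: np.random.Generator):
    """Assign X coordinates: cluster blocks first, then isolated genes.

    Cluster members are chained with gaps drawn from [1 kb, max_gap); all
    other adjacent X genes are separated by at least ``noncluster_spacing``.
    Returns (starts, stops, cluster_ids) in probe order.
    """
    n = cfg.n_probes_x
    cluster_sizes = [c.n_genes for c in cfg.clusters]
    starts = np.zeros(n)
    stops = np.zeros(n)
    cluster_ids = np.array([""] * n, dtype=object)
    cursor = 3_000_000.0
    idx = 0
    # planted clusters occupy the first consecutive probe slots after the
    # special probes; the caller maps slots to probe indices
    for ci, spec in enumerate(cfg.clusters):
        for j in range(spec.n_genes):
            length = rng.uniform(1_000, 20_000)
            starts[idx] = cursor
            stops[idx] = cursor + length
            cluster_ids[idx] = f"clu{ci + 1}"
            gap = rng.uniform(1_000, spec.max_gap)
            cursor = stops[idx] + gap
            idx += 1
        cursor += cfg.noncluster_spacing + rng.uniform(0, cfg.noncluster_spacing)
    while idx < n:
        length = rng.uniform(1_000, 20_000)
        starts[idx] = cursor
        stops[idx] = cursor + length
        cursor = stops[idx] + cfg.noncluster_spacing + rng.uniform(
            0, cfg.noncluster_spacing
        )
        idx += 1
    if cfg.chrom_length_x is not None and cursor > cfg.chrom_length_x:
        raise ConfigurationError(
            f"X layout needs {cursor:.0f} bp but chrom_length_x is {cfg.chrom_length_x}"
        )
    return starts, stops, cluster_ids


def _simulate(cfg: SimConfig, null: bool) -> Experiment:
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    tissues = [t.name for t in cfg.tissues]

    # ---- probe bookkeeping ------------------------------------------------
    ids_a = [f"A{i + 1:06d}_at" for i in range(cfg.n_probes_a)]
    ids_x = [f"X{i + 1:05d}_at" for i in range(cfg.n_probes_x)]
    ids_y = [f"Y{i + 1:03d}_at" for i in range(cfg.n_probes_y)]
    ids_na = [f"N{i + 1:03d}_at" for i in range(cfg.n_probes_na)]
    probe_ids = ids_a + ids_x + ids_y + ids_na
    n_total = len(probe_ids)
    classes = (
        ["A"] * cfg.n_probes_a
        + ["X"] * cfg.n_probes_x
        + ["Y"] * cfg.n_probes_y
        + ["NA"] * cfg.n_probes_na
    )

    # special X probe slots (probe order within X): clusters occupy the
    # first slots so their coordinates are laid out contiguously, then the
    # Xist-like probe, then escapees, then background.
    n_cluster = sum(c.n_genes for c in cfg.clusters)
    use_xist = cfg.xist_like and not null
    xist_slot = n_cluster if use_xist else None
    esc_slots = list(
        range(n_cluster + (1 if use_xist else 0),
              n_cluster + (1 if use_xist else 0) + (0 if null else cfg.n_escapees))
    )
    cluster_slots = list(range(n_cluster))

    x_starts, x_stops, x_cluster_ids = _place_x_entries(cfg, rng)
    if null:
        x_cluster_ids = np.array([""] * cfg.n_probes_x, dtype=object)

    # ---- annotation -------------------------------------------------------
    chroms = []
    starts = np.full(n_total, np.nan)
    stops = np.full(n_total, np.nan)
    autosomes = [str(c) for c in range(1, 20)]
    cursor_a = {c: 3_000_000.0 for c in autosomes}
    for i in range(cfg.n_probes_a):
        chrom = autosomes[i % len(autosomes)]
        chroms.append(chrom)
        starts[i] = cursor_a[chrom]
        stops[i] = cursor_a[chrom] + 5_000
        cursor_a[chrom] += NONCLUSTER_SPACING
    chroms += ["X"] * cfg.n_probes_x
    starts[cfg.n_probes_a : cfg.n_probes_a + cfg.n_probes_x] = x_starts
    stops[cfg.n_probes_a : cfg.n_probes_a + cfg.n_probes_x] = x_stops
    for i in range(cfg.n_probes_y):
        chroms.append("Y")
        base = 3_000_000.0 + i * NONCLUSTER_SPACING
        starts[cfg.n_probes_a + cfg.n_probes_x + i] = base
        stops[cfg.n_probes_a + cfg.n_probes_x + i] = base + 5_000
    chroms += [""] * cfg.n_probes_na

    entry_ids = [f"ENT_{pid[:-3]}" for pid in probe_ids]
    symbols = [f"Simgene{pid[:-3]}" for pid in probe_ids]
    ensembl = [f"ENSSIMG{i + 1:08d}" for i in range(n_total)]
    if use_xist:
        symbols[cfg.n_probes_a + xist_slot] = "SimXist"
    ann = pd.DataFrame(
        {
            "entry_id": entry_ids,
            "gene_symbol": symbols,
            "chrom_class": classes,
            "chrom": chroms,
            "start": starts,
            "stop": stops,
            "feature_class": ["intergenic" if c == "NA" else "gene" for c in classes],
            "ensembl_id": ensembl,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    annotation = AnnotationTable(ann)

    # ---- planted effects --------------------------------------------------
    deltas = {t: np.zeros(n_total) for t in tissues}
    x_offset = cfg.n_probes_a
    escapee_flags = np.zeros(n_total, dtype=bool)
    cluster_col = np.array([""] * n_total, dtype=object)
    cluster_col[x_offset : x_offset + cfg.n_probes_x] = x_cluster_ids

    special_x = set(cluster_slots) | set(esc_slots)
    if xist_slot is not None:
        special_x.add(xist_slot)

    if not null:
        for slot in esc_slots:
            escapee_flags[x_offset + slot] = True
            for t in tissues:
                deltas[t][x_offset + slot] = cfg.escapee_delta
        for slot in cluster_slots:
            for t in tissues:
                deltas[t][x_offset + slot] = cfg.cluster_delta
        if xist_slot is not None:
            for t in tissues:
                deltas[t][x_offset + xist_slot] = cfg.xist_delta

        bg_x = np.array(
            [i for i in range(cfg.n_probes_x) if i not in special_x], dtype=int
        )
        bg_a = np.arange(cfg.n_probes_a)
        for te in cfg.tissues:
            t = te.name
            # autosomal background
            n_f = int(round(te.frac_female_a * len(bg_a)))
            n_m = int(round(te.frac_male_a * len(bg_a)))
            chosen = rng.choice(bg_a, size=n_f + n_m, replace=False)
            deltas[t][chosen[:n_f]] = rng.uniform(*te.a_delta_range, size=n_f)
            deltas[t][chosen[n_f:]] = -rng.uniform(*te.a_delta_range, size=n_m)
            # X background
            n_f = int(round(te.frac_female_x * len(bg_x)))
            n_m = int(round(te.frac_male_x * len(bg_x)))
            chosen = x_offset + rng.choice(bg_x, size=n_f + n_m, replace=False)
            deltas[t][chosen[:n_f]] = rng.uniform(*te.x_delta_range, size=n_f)
            deltas[t][chosen[n_f:]] = -rng.uniform(*te.x_delta_range, size=n_m)

    # ---- branches ---------------------------------------------------------
    weights = np.asarray(cfg.branch_weights, dtype=float)
    weights = weights / weights.sum()
    female_entry = np.zeros(n_total, dtype=bool)
    for t in tissues:
        female_entry |= deltas[t] > 0
    w_female = weights.copy()
    if cfg.old_female_odds != 1.0:
        w_female[: 6] *= cfg.old_female_odds
        w_female = w_female / w_female.sum()
    branches = np.where(
        female_entry,
        rng.choice(12, size=n_total, p=w_female),
        rng.choice(12, size=n_total, p=weights),
    )

    # ---- expression -------------------------------------------------------
    baselines = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=n_total)
    y_idx = np.arange(
        cfg.n_probes_a + cfg.n_probes_x,
        cfg.n_probes_a + cfg.n_probes_x + cfg.n_probes_y,
    )
    use_y = cfg.y_male_only and not null
    n_per = cfg.samples_per_sex
    matrices: dict[str, ExpressionMatrix] = {}
    sample_rows = []
    for t in tissues:
        f_ids = [f"{t}_F{i + 1:03d}" for i in range(n_per)]
        m_ids = [f"{t}_M{i + 1:03d}" for i in range(n_per)]
        for sid in f_ids:
            sample_rows.append({"sample_id": sid, "sex": FEMALE, "tissue": t})
        for sid in m_ids:
            sample_rows.append({"sample_id": sid, "sex": MALE, "tissue": t})
        d = deltas[t]
        mean_f = baselines + d / 2.0
        mean_m = baselines - d / 2.0
        if use_y:
            mean_f = mean_f.copy()
            mean_m = mean_m.copy()
            mean_f[y_idx] = cfg.y_floor
            # expressed in males: keep the male mean clear of the floor
            mean_m[y_idx] = np.maximum(baselines[y_idx], cfg.y_floor + 2.0)
        if use_xist:
            xi = x_offset + xist_slot
            mean_f[xi] = cfg.y_floor + cfg.xist_delta
            mean_m[xi] = cfg.y_floor
        fvals = rng.normal(mean_f[:, None], cfg.noise_sd, size=(n_total, n_per))
        mvals = rng.normal(mean_m[:, None], cfg.noise_sd, size=(n_total, n_per))
        data = pd.DataFrame(
            np.concatenate([fvals, mvals], axis=1),
            index=pd.Index(probe_ids, name="probe_id"),
            columns=f_ids + m_ids,
        )
        matrices[t] = ExpressionMatrix(data)

    # record the implied Y / Xist deltas in the truth
    if use_y:
        for t in tissues:
            deltas[t][y_idx] = cfg.y_floor - np.maximum(
                baselines[y_idx], cfg.y_floor + 2.0
            )
    if use_xist:
        for t in tissues:
            deltas[t][x_offset + xist_slot] = cfg.xist_delta

    samples = SampleTable(pd.DataFrame(sample_rows))

    truth_df = pd.DataFrame(
        {
            "entry_id": entry_ids,
            "chrom_class": classes,
            "escapee": escapee_flags,
            "cluster_id": cluster_col,
            "branch": branches.astype(int),
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    for t in tissues:
        truth_df[f"delta_{t}"] = deltas[t]
    truth = PlantedTruth(truth_df)

    esc_list = None
    if not null and esc_slots:
        esc_symbols = frozenset(symbols[x_offset + s] for s in esc_slots)
        esc_list = EscapeeList(esc_symbols)

    return Experiment(cfg, matrices, samples, annotation, truth, esc_list)


def generate_experiment(config: SimConfig) -> Experiment:
    """Generate a full experiment with planted effects (see module docs)."""
    return _simulate(config, null=False)


def generate_null(config: SimConfig) -> Experiment:
    """Generate a null experiment: every delta 0, Y/Xist features disabled."""
    return _simulate(config, null=True)
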