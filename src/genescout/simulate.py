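"""Seeded generator of multi-batch temporal NB count datasets.

Emulates the structure of the combined mouse-retina development study that the
pipeline targets: 12 timepoints from embryonic day 11 (E11) to postnatal day
28 (P28), >=2 replicates per timepoint, two sequencing batches, NB counts with
batch-specific means and dispersions, and planted temporal pattern modules.
One module — "rising, peaking around P10-P14", the temporal signature of
photoreceptor outer-segment development — carries known functional genes plus
planted unannotated candidates, giving every downstream stage ground truth.

Counts for gene g in sample j (timepoint t, batch b) are drawn

    c_gj ~ NB(mean = mu_g * f_pattern(g)(t) * m_b,  dispersion = alpha_g * d_b)

with variance mu + alpha*mu^2. Evidence tables and GO-style gene sets are
emitted by the simulator itself (a target term containing exactly the
functional module's known+candidate genes, plus random decoy sets), so the
discovery stage needs no external ontology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from ._nbinom import nb_rvs


class ConfigError(ValueError):
    pass


DEFAULT_TIMEPOINTS = ("E11", "E12", "E13", "E14", "E15", "E16",
                      "P0", "P2", "P6", "P10", "P14", "P28")

# Per-timepoint multiplicative factors for the default 12-timepoint design.
# "rising" climbs from embryonic baseline to a peak at P10-P14 with a mild
# dip by P28 (the outer-segment signature); "falling" mirrors it; "transient"
# peaks early postnatally (P0-P2) and falls back; "flat" is the non-DE
# background. All three shaped modules are differentially expressed between
# the embryonic and postnatal stages, so the DEG-selected profile set carries
# exactly three planted temporal patterns.
DEFAULT_PATTERNS = {
    "rising": (0.15, 0.15, 0.18, 0.20, 0.25, 0.30, 0.90, 1.50, 2.20, 3.00, 3.00, 2.60),
    "falling": (3.00, 3.00, 2.80, 2.40, 2.00, 1.60, 0.80, 0.50, 0.30, 0.20, 0.20, 0.20),
    "transient": (0.20, 0.20, 0.25, 0.30, 0.50, 0.90, 3.00, 3.00, 2.00, 1.00, 0.50, 0.30),
    "flat": (1.0,) * 12,
}


@dataclass
class FunctionalModuleSpec:
    pattern: str = "rising"
    n_known: int = 10
    n_candidates: int = 3


@dataclass
class SimulationConfig:
    n_genes: int = 500
    timepoints: tuple = DEFAULT_TIMEPOINTS
    replicates_per_timepoint: int = 2
    n_batches: int = 2
    batch_mean_factors: tuple = (1.0, 1.8)
    batch_disp_factors: tuple = (1.0, 1.5)
    pattern_library: dict = field(default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_PATTERNS.items()})
    module_spec: dict = field(default_factory=lambda: {"rising": 80, "falling": 80, "transient": 80, "flat": 260})
    functional_module: FunctionalModuleSpec = field(default_factory=FunctionalModuleSpec)
    base_mean_log_mean: float = float(np.log(80.0))  # log-normal mu of per-gene base mean
    base_mean_log_sd: float = 1.0
    dispersion: float = 0.1  # per-gene NB dispersion alpha
    dispersion_log_sd: float = 0.0  # lognormal jitter around `dispersion`
    gene_length_log_mean: float = float(np.log(2000.0))
    gene_length_log_sd: float = 0.5
    n_decoy_sets: int = 20
    decoy_size_range: tuple = (15, 50)
    seed: int = 0

    def condition_of(self, tp: str) -> str:
        return "embryonic" if tp.startswith("E") else "postnatal"

    def validate(self) -> None:
        total = sum(self.module_spec.values())
        if total != self.n_genes:
            raise ConfigError(f"module_spec gene counts sum to {total}, expected {self.n_genes}")
        for name in self.module_spec:
            if name not in self.pattern_library:
                raise ConfigError(f"module_spec pattern {name!r} not in pattern_library")
        for name, fac in self.pattern_library.items():
            if len(fac) != len(self.timepoints):
                raise ConfigError(f"pattern {name!r} has {len(fac)} factors for "
                                  f"{len(self.timepoints)} timepoints")
            if any(f <= 0 for f in fac):
                raise ConfigError(f"pattern {name!r} has non-positive factors")
        if len(self.batch_mean_factors) != self.n_batches or len(self.batch_disp_factors) != self.n_batches:
            raise ConfigError("need one batch mean/dispersion factor per batch")
        if any(f <= 0 for f in self.batch_mean_factors + self.batch_disp_factors):
            raise ConfigError("batch factors must be > 0")
        fm = self.functional_module
        if fm.pattern not in self.module_spec:
            raise ConfigError(f"functional module pattern {fm.pattern!r} has no genes")
        if fm.n_known + fm.n_candidates > self.module_spec[fm.pattern]:
            raise ConfigError("functional module known+candidates exceed module size")


@dataclass
class SimulatedTruth:
    pattern_of: dict  # gene_id -> pattern name
    is_de: dict  # gene_id -> bool (planted condition effect)
    role_of: dict  # gene_id -> known | planted_candidate | background
    batch_mean_factors: tuple
    batch_disp_factors: tuple

    def genes_with_role(self, role: str) -> list[str]:
        return [g for g, r in self.role_of.items() if r == role]

    def to_frame(self) -> pd.DataFrame:
        genes = list(self.pattern_of)
        return pd.DataFrame({
            "gene_id": genes,
            "pattern": [self.pattern_of[g] for g in genes],
            "role": [self.role_of[g] for g in genes],
            "is_de": [str(self.is_de[g]).lower() for g in genes],
        })


def _pattern_is_de(factors, timepoints, condition_of, fold: float = 2.0) -> bool:
    emb = np.mean([f for f, t in zip(factors, timepoints) if condition_of(t) == "embryonic"])
    post = np.mean([f for f, t in zip(factors, timepoints) if condition_of(t) == "postnatal"])
    return abs(np.log2(post / emb)) >= np.log2(fold)


def simulate_dataset(config: SimulationConfig):
    """Generate (CountMatrix, SampleMetadata, GeneAnnotation, KnownGeneList,
    EvidenceTable, GeneSetCollection, SimulatedTruth), deterministically under
    ``config.seed``. Independent RNG streams are spawned per output so adding
    one stream never perturbs another."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_counts, rng_lengths, rng_base, rng_decoys, rng_evidence = (
        np.random.Generator(np.random.PCG64(s)) for s in ss.spawn(5)
    )

    n_digits = max(4, len(str(config.n_genes)))
    gene_ids = [f"g{str(i + 1).zfill(n_digits)}" for i in range(config.n_genes)]

    # deterministic module assignment in id order
    pattern_of: dict[str, str] = {}
    cursor = 0
    module_genes: dict[str, list[str]] = {}
    for name in config.module_spec:
        n = config.module_spec[name]
        module_genes[name] = gene_ids[cursor:cursor + n]
        for g in module_genes[name]:
            pattern_of[g] = name
        cursor += n

    fm = config.functional_module
    fm_genes = module_genes[fm.pattern]
    known = fm_genes[:fm.n_known]
    candidates = fm_genes[fm.n_known:fm.n_known + fm.n_candidates]
    role_of = {g: "background" for g in gene_ids}
    role_of.update({g: "known" for g in known})
    role_of.update({g: "planted_candidate" for g in candidates})

    is_de = {
        g: _pattern_is_de(config.pattern_library[pattern_of[g]], config.timepoints,
                          config.condition_of)
        for g in gene_ids
    }

    # samples: replicate r of timepoint t goes to batch ((r-1) mod n_batches)
    rows = []
    for tp in config.timepoints:
        for rep in range(1, config.replicates_per_timepoint + 1):
            batch_idx = (rep - 1) % config.n_batches
            rows.append({
                "sample_id": f"{tp}_r{rep}",
                "batch": f"B{batch_idx + 1}",
                "timepoint": tp,
                "condition": config.condition_of(tp),
                "replicate": rep,
            })
    meta = gio.SampleMetadata(pd.DataFrame(rows))

    base_mean = rng_base.lognormal(config.base_mean_log_mean, config.base_mean_log_sd,
                                   size=config.n_genes)
    if config.dispersion_log_sd > 0:
        alpha = config.dispersion * rng_base.lognormal(0.0, config.dispersion_log_sd,
                                                       size=config.n_genes)
    else:
        alpha = np.full(config.n_genes, config.dispersion)

    tp_index = {tp: i for i, tp in enumerate(config.timepoints)}
    pattern_arr = np.array([config.pattern_library[pattern_of[g]] for g in gene_ids])
    counts = np.empty((config.n_genes, len(rows)), dtype=np.int64)
    for j, row in enumerate(rows):
        b = int(row["batch"][1:]) - 1
        mu_j = base_mean * pattern_arr[:, tp_index[row["timepoint"]]] * config.batch_mean_factors[b]
        a_j = alpha * config.batch_disp_factors[b]
        counts[:, j] = nb_rvs(rng_counts, mu_j, a_j)
    cm = gio.CountMatrix(gene_ids, [r["sample_id"] for r in rows], counts)

    lengths = np.maximum(
        rng_lengths.lognormal(config.gene_length_log_mean, config.gene_length_log_sd,
                              size=config.n_genes).astype(int), 200)
    ann = gio.GeneAnnotation(pd.DataFrame({
        "gene_id": gene_ids, "symbol": gene_ids, "length_bp": lengths}))

    known_list = gio.KnownGeneList(frozenset(known), provenance="simulated known functional genes")

    # evidence: known genes are documented; planted candidates have zero hits
    # but positive expression; background genes are documented except for a
    # small fraction with zero hits AND no expression evidence (these exercise
    # the conjunction rule without ever qualifying).
    ev_rows = []
    for g in gene_ids:
        if role_of[g] == "planted_candidate":
            hits, expr = 0, True
        elif role_of[g] == "known":
            hits, expr = 1 + int(rng_evidence.poisson(5)), True
        else:
            if rng_evidence.random() < 0.05:
                hits, expr = 0, False
            else:
                hits, expr = 1 + int(rng_evidence.poisson(2)), bool(rng_evidence.random() < 0.8)
        ev_rows.append({"gene_id": g, "literature_hits": hits, "expression_evidence": expr})
    evidence = gio.EvidenceTable(pd.DataFrame(ev_rows))

    # gene sets: one target term = exactly the functional module's known and
    # candidate genes; decoy terms are random background draws.
    sets = {
        "TERM:OS": gio.GeneSet("TERM:OS", "outer segment module (synthetic)", "CC",
                               frozenset(known + candidates)),
    }
    lo, hi = config.decoy_size_range
    for i in range(config.n_decoy_sets):
        size = int(rng_decoys.integers(lo, hi + 1))
        members = rng_decoys.choice(gene_ids, size=min(size, config.n_genes), replace=False)
        ns = gio.NAMESPACES[i % 3]
        tid = f"TERM:D{i + 1:02d}"
        sets[tid] = gio.GeneSet(tid, f"decoy set {i + 1} (synthetic)", ns, frozenset(members))
    collection = gio.GeneSetCollection(sets)

    truth = SimulatedTruth(pattern_of, is_de, role_of,
                           tuple(config.batch_mean_factors), tuple(config.batch_disp_factors))
    return cm, meta, ann, known_list, evidence, collection, truth


FIXTURE_FILES = ("counts.tsv", "metadata.tsv", "annotation.tsv", "known_genes.txt",
                 "evidence.tsv", "gene_sets.gmt", "truth.tsv")


def write_fixture(outputs, directory) -> list[Path]:
    """Write the 7-file fixture (counts, metadata, annotation, known genes,
    evidence, gene sets, truth) readable by the :mod:`genescout.io` readers."""
    cm, meta, ann, known, evidence, sets, truth = outputs
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    gio.write_count_matrix(cm, directory / "counts.tsv")
    gio.write_sample_metadata(meta, directory / "metadata.tsv")
    gio.write_gene_annotation(ann, directory / "annotation.tsv")
    gio.write_known_genes(known, directory / "known_genes.txt")
    gio.write_evidence(evidence, directory / "evidence.tsv")
    gio.write_gene_sets(sets, directory / "gene_sets.gmt")
    truth.to_frame().to_csv(directory / "truth.tsv", sep="\t", index=False)
    return [directory / f for f in FIXTURE_FILES]


def small_config(seed: int = 0) -> SimulationConfig:
    """Desk-scale preset: 500 genes, 6 timepoints, 2 replicates, 2 batches."""
    tps = ("E13", "E14", "E16", "P2", "P10", "P14")
    patterns = {
        "rising": (0.15, 0.18, 0.30, 1.20, 2.80, 3.00),
        "falling": (3.00, 2.80, 2.00, 0.60, 0.25, 0.20),
        "transient": (0.30, 0.40, 0.70, 3.00, 1.20, 0.50),
        "flat": (1.0,) * 6,
    }
    return SimulationConfig(
        n_genes=500, timepoints=tps, pattern_library=patterns,
        module_spec={"rising": 80, "falling": 80, "transient": 80, "flat": 260},
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Direct z-profile simulation (for clustering/gap-statistic studies)
# ---------------------------------------------------------------------------


def _profile_centroids(k: int, n_timepoints: int) -> np.ndarray:
    """k distinct smooth temporal shapes (each z-scored across timepoints):
    sigmoids rising at staggered midpoints, their mirror images, and a
    transient bump, cycled as needed."""
    t = np.linspace(0.0, 1.0, n_timepoints)
    shapes = []
    mids = np.linspace(0.25, 0.75, max(1, (k + 1) // 2))
    for i in range(k):
        if i % 2 == 0:
            mid = mids[(i // 2) % len(mids)]
            curve = 1.0 / (1.0 + np.exp(-12.0 * (t - mid)))
        else:
            mid = mids[(i // 2) % len(mids)]
            curve = 1.0 / (1.0 + np.exp(12.0 * (t - mid)))
        if i >= 2 * len(mids):  # fall back to bumps at shifted centers
            c = (i - 2 * len(mids) + 1) / (k + 1)
            curve = np.exp(-((t - c) ** 2) / 0.02)
        z = (curve - curve.mean()) / curve.std(ddof=0)
        shapes.append(z)
    return np.array(shapes)


def simulate_zscore_profiles(n_genes: int, n_timepoints: int, k_true: int,
                             noise_sd: float = 0.25, seed: int = 0):
    """Gene x timepoint z-score profiles with ``k_true`` planted temporal
    patterns: centroid + iid Gaussian noise, then per-gene re-z-scoring (as the
    real pipeline would). Returns (X, labels) with labels in 0..k_true-1."""
    rng = np.random.Generator(np.random.PCG64(seed))
    centroids = _profile_centroids(k_true, n_timepoints)
    labels = np.repeat(np.arange(k_true), int(np.ceil(n_genes / k_true)))[:n_genes]
    X = centroids[labels] + rng.normal(0.0, noise_sd, size=(n_genes, n_timepoints))
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    X = (X - mu) / np.where(sd > 0, sd, 1.0)
    return X, labels
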