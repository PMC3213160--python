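"""Synthetic data generator for the pull-down analysis pipeline.

Emulates the statistical structure the analysis assumes, so every downstream
stage can be exercised without external data:

* probe-level expression with log-normal replicate noise across the four-arm
  design (pull-down and input, test and control miRNA, replicated);
* a planted set of true target genes with multiplicative pull-down
  enrichment and input-mRNA knockdown;
* abundance-dependent nonspecific bead background applied identically to
  both pull-down arms, so that input normalization cancels it in
  expectation;
* transcript-region sequences (5'UTR/CDS/3'UTR) with seed-match sites
  planted as a Poisson process at a higher density in targets' 3'UTRs;
* pathway collections in which a stated fraction of pathways oversample the
  target genes.

All randomness flows through a single seeded generator; the same
configuration and seed reproduce byte-identical output files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import GeneSet
from .errors import ConfigError, MirpullError
from .expression import ARMS, MIRNAS, ProbeMatrix, SampleDesign
from .hexamer import MIR34A, MatureMiRNA, RegionSequenceSet
from .pathways import Pathway, PathwayCollection

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults reflect the experimental design being emulated: duplicate
    arrays per arm, a planted target fraction of 10%, four-fold pull-down
    enrichment and two-fold input knockdown for targets, and seed-site
    densities of 5/kb (targets) vs 1/kb (background) in the 3'UTR.
    """

    n_genes: int = 2000
    probes_per_gene: int | tuple[int, int] = 2
    n_replicates: int = 2
    target_fraction: float = 0.1
    enrichment_effect: float = 4.0
    knockdown_effect: float = 0.5
    noise_sd: float = 0.35               # SD of log2-scale replicate noise
    background_affinity: float = 0.5     # exponent coupling bead capture to abundance
    abundance_log2_mean: float = 8.0
    abundance_log2_sd: float = 2.0
    probe_affinity_sd: float = 0.25      # per-probe log2 affinity spread (cancels in ratios)
    seed_density_target: float = 5.0     # expected planted sites per kb of 3'UTR
    seed_density_background: float = 1.0
    utr_length_dist: dict = field(
        default_factory=lambda: {
            "utr5": (150.0, 0.4),   # (median bp, log-scale SD)
            "cds": (1200.0, 0.3),
            "utr3": (800.0, 0.5),
        }
    )
    mirna: MatureMiRNA = field(default_factory=lambda: MIR34A)
    n_pathways: int = 50
    pathway_size_dist: tuple[int, int] = (10, 60)
    target_enriched_pathway_fraction: float = 0.3
    pathway_target_weight: float = 8.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ConfigError(f"n_genes must be positive, got {self.n_genes}")
        if self.n_replicates <= 0:
            raise ConfigError(f"n_replicates must be positive, got {self.n_replicates}")
        ppg = self.probes_per_gene
        if isinstance(ppg, int):
            if ppg <= 0:
                raise ConfigError(f"probes_per_gene must be positive, got {ppg}")
        else:
            lo, hi = ppg
            if lo <= 0 or hi < lo:
                raise ConfigError(f"probes_per_gene range invalid: {ppg}")
        if not 0 <= self.target_fraction <= 1:
            raise ConfigError(
                f"target_fraction must be in [0, 1], got {self.target_fraction}"
            )
        if self.enrichment_effect <= 1:
            raise ConfigError(
                f"enrichment_effect must be > 1, got {self.enrichment_effect}"
            )
        if not 0 < self.knockdown_effect < 1:
            raise ConfigError(
                f"knockdown_effect must be in (0, 1), got {self.knockdown_effect}"
            )
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.seed_density_target < 0:
            raise ConfigError(
                f"seed_density_target must be >= 0, got {self.seed_density_target}"
            )
        if self.seed_density_background < 0:
            raise ConfigError(
                f"seed_density_background must be >= 0, got {self.seed_density_background}"
            )
        if self.n_pathways <= 0:
            raise ConfigError(f"n_pathways must be positive, got {self.n_pathways}")
        lo, hi = self.pathway_size_dist
        if lo <= 0 or hi < lo:
            raise ConfigError(f"pathway_size_dist range invalid: {self.pathway_size_dist}")
        if not 0 <= self.target_enriched_pathway_fraction <= 1:
            raise ConfigError(
                "target_enriched_pathway_fraction must be in [0, 1], got "
                f"{self.target_enriched_pathway_fraction}"
            )
        for region, (median, log_sd) in self.utr_length_dist.items():
            if median < 20 or log_sd < 0:
                raise ConfigError(
                    f"utr_length_dist[{region!r}] invalid: {(median, log_sd)}"
                )


@dataclass
class TruthLabels:
    """Ground-truth labels for every simulated gene.

    DataFrame indexed by gene_id: ``is_target``, ``planted_enrichment``,
    ``planted_knockdown`` and (after sequence simulation)
    ``planted_sites_utr3``.
    """

    table: pd.DataFrame

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    def target_set(self, label: str = "true_targets") -> GeneSet:
        return GeneSet(
            label=label,
            members=frozenset(self.table.index[self.table["is_target"]]),
            universe=frozenset(self.table.index),
        )

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path) -> "TruthLabels":
        t = pd.read_csv(path, sep="\t", index_col="gene_id")
        t["is_target"] = t["is_target"].astype(bool)
        return cls(table=t)


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(n)]


def _make_labels(config: SimulationConfig, rng: np.random.Generator) -> TruthLabels:
    genes = _gene_ids(config.n_genes)
    n_targets = int(round(config.n_genes * config.target_fraction))
    is_target = np.zeros(config.n_genes, dtype=bool)
    if n_targets:
        is_target[rng.choice(config.n_genes, size=n_targets, replace=False)] = True
    table = pd.DataFrame(
        {
            "is_target": is_target,
            "planted_enrichment": np.where(is_target, config.enrichment_effect, 1.0),
            "planted_knockdown": np.where(is_target, config.knockdown_effect, 1.0),
        },
        index=pd.Index(genes, name="gene_id"),
    )
    return TruthLabels(table=table)


def simulate_expression(
    config: SimulationConfig,
    cell_line: str = "simA",
    labels: TruthLabels | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[ProbeMatrix, TruthLabels]:
    """Generate a four-arm probe-level expression matrix plus truth labels.

    Expected values: input_control = A (abundance), input_test = A*kd for
    targets; both pull-down arms share the nonspecific capture factor
    A**background_affinity computed from the control abundance, so the
    expected enrichment ratio is exactly ``enrichment_effect`` for targets
    and 1 otherwise, for any affinity exponent.  Replicate noise is Gaussian
    on the log2 scale (multiplicative log-normal on the linear scale).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    if labels is None:
        labels = _make_labels(config, rng)

    genes = list(labels.genes)
    n_genes = len(genes)
    if isinstance(config.probes_per_gene, int):
        ppg = np.full(n_genes, config.probes_per_gene, dtype=int)
    else:
        lo, hi = config.probes_per_gene
        ppg = rng.integers(lo, hi + 1, size=n_genes)

    probe_gene_idx = np.repeat(np.arange(n_genes), ppg)
    probe_ids = []
    for gi, count in enumerate(ppg):
        probe_ids.extend(f"{genes[gi]}_p{j + 1}" for j in range(count))
    n_probes = len(probe_ids)

    abundance = 2.0 ** rng.normal(
        config.abundance_log2_mean, config.abundance_log2_sd, size=n_genes
    )
    probe_aff = 2.0 ** rng.normal(0.0, config.probe_affinity_sd, size=n_probes)

    kd = labels.table["planted_knockdown"].to_numpy()
    enr = labels.table["planted_enrichment"].to_numpy()
    capture = abundance ** config.background_affinity  # shared by both PD arms

    expected = {
        ("input", "control"): abundance,
        ("input", "test"): abundance * kd,
        ("pulldown", "control"): abundance * capture,
        ("pulldown", "test"): abundance * capture * kd * enr,
    }

    columns = {}
    design_rows = []
    for arm in ARMS:
        for mirna in MIRNAS:
            base = expected[(arm, mirna)][probe_gene_idx] * probe_aff
            for rep in range(1, config.n_replicates + 1):
                sample_id = f"{cell_line}_{arm}_{mirna}_r{rep}"
                noise = 2.0 ** rng.normal(0.0, config.noise_sd, size=n_probes)
                columns[sample_id] = base * noise
                design_rows.append(
                    {
                        "sample_id": sample_id,
                        "arm": arm,
                        "mirna": mirna,
                        "replicate": rep,
                        "cell_line": cell_line,
                    }
                )

    values = pd.DataFrame(columns, index=pd.Index(probe_ids, name="probe_id"))
    probe_map = pd.Series(
        [genes[gi] for gi in probe_gene_idx], index=values.index, name="gene_id"
    )
    design = SampleDesign(pd.DataFrame(design_rows))
    return ProbeMatrix(values=values, probe_map=probe_map, design=design), labels


def _random_sequence(length: int, rng: np.random.Generator) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _plant_sites(
    seq: np.ndarray, site: str, n_sites: int, rng: np.random.Generator
) -> int:
    """Overwrite ``n_sites`` non-overlapping positions with ``site``.

    Rejection sampling keeps planted sites disjoint so the planted count is
    exact; gives up on a site after a bounded number of attempts (can only
    happen when the density is extreme relative to the sequence length).
    """
    k = len(site)
    site_arr = np.frombuffer(site.encode(), dtype="S1")
    if len(seq) < k:
        return 0
    taken: list[tuple[int, int]] = []
    placed = 0
    for _ in range(n_sites):
        for _attempt in range(200):
            start = int(rng.integers(0, len(seq) - k + 1))
            if all(start + k <= s or start >= e for s, e in taken):
                seq[start : start + k] = site_arr
                taken.append((start, start + k))
                placed += 1
                break
    return placed


def simulate_sequences(
    config: SimulationConfig,
    labels: TruthLabels,
    rng: np.random.Generator | None = None,
) -> RegionSequenceSet:
    """Generate per-gene 5'UTR/CDS/3'UTR sequences with planted seed sites.

    Sequences are uniform-composition DNA; seed sites (the DNA reverse
    complement of the miRNA seed window) are planted in the 3'UTR as a
    Poisson process at ``seed_density_target`` per kb for targets and
    ``seed_density_background`` otherwise, never overlapping each other.
    The planted count per gene is recorded in the labels
    (``planted_sites_utr3``).
    """
    if len(labels.genes) == 0:
        raise MirpullError("empty label set: simulate expression first")
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    site = config.mirna.seed_site
    sequences: dict[str, dict[str, str]] = {}
    planted = pd.Series(0, index=labels.genes, dtype=int)
    is_target = labels.table["is_target"]
    for gene in labels.genes:
        regions = {}
        for region, (median, log_sd) in config.utr_length_dist.items():
            length = max(20, int(round(median * np.exp(rng.normal(0.0, log_sd)))))
            seq = _random_sequence(length, rng)
            if region == "utr3":
                density = (
                    config.seed_density_target
                    if is_target.loc[gene]
                    else config.seed_density_background
                )
                n_sites = int(rng.poisson(density * length / 1000.0))
                planted.loc[gene] = _plant_sites(seq, site, n_sites, rng)
            regions[region] = seq.tobytes().decode()
        sequences[gene] = regions
    labels.table["planted_sites_utr3"] = planted
    return RegionSequenceSet(sequences=sequences, provenance={g: g for g in labels.genes})


def simulate_pathways(
    config: SimulationConfig,
    labels: TruthLabels,
    rng: np.random.Generator | None = None,
) -> PathwayCollection:
    """Generate a pathway collection over the simulated genes.

    A fraction ``target_enriched_pathway_fraction`` of pathways sample
    members with weight ``pathway_target_weight`` on target genes (so
    over-representation is recoverable); the rest sample uniformly without
    replacement.
    """
    if len(labels.genes) == 0:
        raise MirpullError("empty label set: simulate expression first")
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    genes = np.array(labels.genes)
    is_target = labels.table["is_target"].to_numpy()
    lo, hi = config.pathway_size_dist
    if hi > len(genes):
        raise MirpullError(
            f"pathway_size_dist max {hi} exceeds number of genes {len(genes)}"
        )
    n_enriched = int(round(config.n_pathways * config.target_enriched_pathway_fraction))
    pathways: dict[str, Pathway] = {}
    width = max(3, len(str(config.n_pathways)))
    for i in range(config.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        if size > len(genes):
            raise MirpullError(
                f"pathway size {size} exceeds number of genes {len(genes)}"
            )
        enriched = i < n_enriched
        if enriched and is_target.any():
            weights = np.where(is_target, config.pathway_target_weight, 1.0)
            # weighted sampling without replacement via exponential keys
            keys = rng.exponential(size=len(genes)) / weights
            members = genes[np.argsort(keys)[:size]]
        else:
            members = rng.choice(genes, size=size, replace=False)
        pid = f"P{i + 1:0{width}d}"
        name = "target_enriched" if enriched else "background"
        pathways[pid] = Pathway(pid, name, frozenset(members.tolist()))
    return PathwayCollection(pathways=pathways, universe=frozenset(genes.tolist()))


def write_probe_matrix(matrix: ProbeMatrix, prefix: Path) -> dict[str, Path]:
    """Write matrix/design/probe-map TSVs for one simulated matrix."""
    prefix = Path(prefix)
    paths = {
        "matrix": prefix.with_suffix(".matrix.tsv"),
        "design": prefix.with_suffix(".design.tsv"),
        "probe_map": prefix.with_suffix(".probe_map.tsv"),
    }
    matrix.values.to_csv(paths["matrix"], sep="\t", index_label="probe_id")
    matrix.design.table.to_csv(paths["design"], sep="\t", index=False)
    matrix.probe_map.dropna().rename("gene_id").to_csv(
        paths["probe_map"], sep="\t", index_label="probe_id"
    )
    return paths


def simulate_study(
    config: SimulationConfig,
    outdir: Path,
    cell_lines: tuple[str, str] = ("simA", "simB"),
) -> dict:
    """Simulate a complete two-cell-line study and write all input files.

    The planted target set is shared between cell lines (so cross-cell-line
    overlap is recoverable) while expression noise is independent.  Returns
    a dict of written paths plus the in-memory objects.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.rng_seed)
    streams = [np.random.default_rng(s) for s in root.spawn(len(cell_lines) + 3)]
    labels = _make_labels(config, streams[0])
    paths: dict = {"cell_lines": {}}
    for i, cl in enumerate(cell_lines):
        matrix, _ = simulate_expression(config, cell_line=cl, labels=labels,
                                        rng=streams[i + 1])
        paths["cell_lines"][cl] = {
            str(k): str(v) for k, v in write_probe_matrix(matrix, outdir / cl).items()
        }
    seqs = simulate_sequences(config, labels, rng=streams[len(cell_lines) + 1])
    fasta = outdir / "regions.fasta"
    seqs.to_fasta(fasta)
    collection = simulate_pathways(config, labels, rng=streams[len(cell_lines) + 2])
    gmt = outdir / "pathways.gmt"
    collection.to_gmt(gmt)
    truth = outdir / "truth.tsv"
    labels.to_tsv(truth)
    paths.update({"fasta": str(fasta), "gmt": str(gmt), "truth": str(truth)})
    return {"paths": paths, "labels": labels, "sequences": seqs, "pathways": collection}
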