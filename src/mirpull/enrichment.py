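"""Pull-down enrichment-ratio computation and hit calling.

The specific association of a transcript with the transfected test miRNA is
measured by the enrichment ratio

    {PD_test / PD_control} / {input_test / input_control}

where PD is the streptavidin pull-down arm and input the matched cellular
RNA.  Dividing by the input ratio cancels background bead capture that scales
with transcript abundance and folds any knockdown of the target mRNA into the
denominator.  The ratio is computed per probe per replicate, averaged
(arithmetic mean) over replicates, then averaged over a gene's probes.  Genes
are called hits when their mean ratio is at or above a threshold fitted from
the full log2-ratio distribution (log-normal background): 2**(mu + n_sd*sigma).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import MirpullError
from .expression import ExpressionFlag, ProbeMatrix, collapse_to_genes

logger = logging.getLogger(__name__)

# tolerance for inclusive threshold comparisons on recomputed fold values
_REL_EPS = 1e-12


@dataclass(frozen=True)
class GeneSet:
    """A labelled set of gene identifiers, optionally with a universe."""

    label: str
    members: frozenset
    universe: frozenset | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))
        if self.universe is not None:
            object.__setattr__(self, "universe", frozenset(self.universe))
            extra = self.members - self.universe
            if extra:
                raise MirpullError(
                    f"gene set {self.label!r}: {len(extra)} members outside "
                    f"its universe (e.g. {sorted(extra)[:3]})"
                )

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene) -> bool:
        return gene in self.members

    @classmethod
    def from_file(cls, path, label: str | None = None) -> "GeneSet":
        """Read a one-gene-per-line list (``#`` comments and blanks skipped)."""
        members = set()
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line and not line.startswith("#"):
                    members.add(line)
        return cls(label=label or str(path), members=frozenset(members))

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for gene in sorted(self.members):
                fh.write(f"{gene}\n")


def overlap(set_a: GeneSet, set_b: GeneSet) -> GeneSet:
    """Intersection of two gene sets, labelled with both parents."""
    universe = None
    if set_a.universe is not None and set_b.universe is not None:
        universe = set_a.universe & set_b.universe
    return GeneSet(
        label=f"{set_a.label}&{set_b.label}",
        members=set_a.members & set_b.members,
        universe=universe,
    )


def overlap_report(set_a: GeneSet, set_b: GeneSet) -> dict:
    """Counts for a two-set overlap: A-only, B-only, both."""
    both = set_a.members & set_b.members
    return {
        "label_a": set_a.label,
        "label_b": set_b.label,
        "n_a": len(set_a),
        "n_b": len(set_b),
        "a_only": len(set_a.members - both),
        "b_only": len(set_b.members - both),
        "both": len(both),
    }


@dataclass
class EnrichmentTable:
    """Per-gene enrichment ratios for one cell line.

    ``table`` columns: ``ratio_rep_<r>`` (per-replicate gene ratios, probes
    averaged within replicate), ``mean_ratio``, ``log2_ratio``, ``n_probes``;
    after :func:`call_hits` also ``is_hit`` and ``threshold_fold``.
    """

    table: pd.DataFrame
    cell_line: str
    n_replicates: int
    n_excluded_nonpositive: int = 0

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out["cell_line"] = self.cell_line
        out["n_replicates_used"] = self.n_replicates
        out.to_csv(path, sep="\t", index_label="gene_id")


@dataclass(frozen=True)
class HitThreshold:
    """SD-based hit threshold on the log2 enrichment-ratio distribution."""

    mu: float
    sigma: float
    n_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise MirpullError(f"sigma must be >= 0, got {self.sigma}")

    @property
    def log2_cut(self) -> float:
        return self.mu + self.n_sd * self.sigma

    @property
    def fold_equivalent(self) -> float:
        return float(2.0 ** self.log2_cut)

    def with_n_sd(self, n_sd: float) -> "HitThreshold":
        return replace(self, n_sd=n_sd)


def _arm_values(matrix: ProbeMatrix, cell_line: str, arm: str, mirna: str, rep: int):
    sample = matrix.design.sample(arm, mirna, rep, cell_line)
    return matrix.values[sample]


def _resolve_cell_line(matrix: ProbeMatrix, cell_line: str | None) -> str:
    lines = matrix.design.cell_lines
    if cell_line is None:
        if len(lines) != 1:
            raise MirpullError(
                f"matrix covers cell lines {lines}; specify one explicitly"
            )
        return lines[0]
    if cell_line not in lines:
        raise MirpullError(f"cell line {cell_line!r} not in design ({lines})")
    return cell_line


def _per_gene_ratio_table(
    matrix: ProbeMatrix,
    flags: ExpressionFlag,
    cell_line: str | None,
    numerator_arms,
    denominator_arms,
    collapse: str,
):
    """Shared machinery for enrichment ratios and input fold changes.

    ``numerator_arms``/``denominator_arms`` are lists of (arm, mirna) pairs:
    the per-replicate ratio is prod(numerators)/prod(denominators).  Genes
    with any nonpositive intensity among the terms are excluded entirely
    (ratios undefined; normalized array output should be positive).
    """
    cell_line = _resolve_cell_line(matrix, cell_line)
    reps = matrix.design.replicates(cell_line)

    mapped = matrix.probe_map.dropna()
    expressed_genes = flags.gene[flags.gene].index
    keep_probes = mapped.index[mapped.isin(expressed_genes)]

    per_rep = {}
    bad = pd.Series(False, index=keep_probes)
    for rep in reps:
        num = pd.Series(1.0, index=keep_probes)
        den = pd.Series(1.0, index=keep_probes)
        for arm, mirna in numerator_arms:
            num = num * _arm_values(matrix, cell_line, arm, mirna, rep).loc[keep_probes]
        for arm, mirna in denominator_arms:
            den = den * _arm_values(matrix, cell_line, arm, mirna, rep).loc[keep_probes]
        terms_ok = pd.Series(True, index=keep_probes)
        for arm, mirna in list(numerator_arms) + list(denominator_arms):
            v = _arm_values(matrix, cell_line, arm, mirna, rep).loc[keep_probes]
            terms_ok &= v > 0
        bad |= ~terms_ok
        ratio = num / den
        ratio[~terms_ok] = np.nan
        per_rep[rep] = ratio

    # exclude whole genes touched by any nonpositive term
    bad_genes = set(mapped.loc[bad.index[bad]].unique())
    if bad_genes:
        logger.warning(
            "%s: excluded %d gene(s) with nonpositive intensities",
            cell_line,
            len(bad_genes),
        )

    rep_frame = pd.DataFrame(per_rep)
    probe_mean = rep_frame.mean(axis=1)  # arithmetic mean over replicates

    gene_mean = collapse_to_genes(probe_mean, matrix.probe_map, method=collapse)
    gene_mean = gene_mean.drop(index=[g for g in bad_genes if g in gene_mean.index])

    per_rep_gene = {
        f"ratio_rep_{rep}": collapse_to_genes(
            rep_frame[rep], matrix.probe_map, method=collapse
        ).reindex(gene_mean.index)
        for rep in reps
    }
    n_probes = (
        mapped.loc[keep_probes]
        .groupby(mapped.loc[keep_probes])
        .size()
        .reindex(gene_mean.index)
        .astype(int)
    )
    table = pd.DataFrame(per_rep_gene)
    table["mean_ratio"] = gene_mean
    table["log2_ratio"] = np.log2(gene_mean)
    table["n_probes"] = n_probes
    table.index.name = "gene_id"
    return table, cell_line, len(reps), len(bad_genes)


def enrichment_ratio(
    matrix: ProbeMatrix,
    flags: ExpressionFlag,
    cell_line: str | None = None,
    collapse: str = "mean",
) -> EnrichmentTable:
    """Compute the per-gene pull-down enrichment ratio.

    Per probe per replicate: (PD_test/PD_control)/(input_test/input_control);
    replicate ratios are averaged (arithmetic mean) and then collapsed to
    genes.  Unexpressed genes are excluded, as are genes with any nonpositive
    intensity in a ratio term.
    """
    table, cl, n_reps, n_bad = _per_gene_ratio_table(
        matrix,
        flags,
        cell_line,
        numerator_arms=[("pulldown", "test"), ("input", "control")],
        denominator_arms=[("pulldown", "control"), ("input", "test")],
        collapse=collapse,
    )
    return EnrichmentTable(
        table=table, cell_line=cl, n_replicates=n_reps, n_excluded_nonpositive=n_bad
    )


def fit_background(table: EnrichmentTable, n_sd: float = 1.0) -> HitThreshold:
    """Fit the log-normal background of enrichment ratios.

    mu and sigma are the sample mean and sample SD (n-1 denominator) of the
    log2 mean ratios over all expressed genes — the threshold is defined from
    the full distribution, hits included.
    """
    log2 = table.table["log2_ratio"].dropna()
    if len(log2) < 2:
        raise MirpullError(
            f"need >= 2 genes with finite ratios to fit background, got {len(log2)}"
        )
    return HitThreshold(
        mu=float(log2.mean()), sigma=float(log2.std(ddof=1)), n_sd=n_sd
    )


def call_hits(
    table: EnrichmentTable, threshold: HitThreshold, label: str | None = None
) -> GeneSet:
    """Call hit genes at ``mean_ratio >= threshold.fold_equivalent`` (inclusive).

    Also annotates ``is_hit`` and ``threshold_fold`` columns on the table.
    """
    fold = threshold.fold_equivalent
    is_hit = table.table["mean_ratio"] >= fold * (1.0 - _REL_EPS)
    table.table["is_hit"] = is_hit
    table.table["threshold_fold"] = fold
    return GeneSet(
        label=label or f"{table.cell_line}_hits",
        members=frozenset(table.table.index[is_hit]),
        universe=frozenset(table.table.index),
    )
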