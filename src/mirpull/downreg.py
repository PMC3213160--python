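"""Down-regulation calling and CDF/KS comparison of gene sets.

After over-expressing the test miRNA, a gene's input-arm fold change is the
ratio of its input RNA in test-miRNA-transfected cells to input RNA in
control-transfected cells, per probe per replicate, averaged over replicates
and collapsed to genes with the same order of operations as the enrichment
stage.  Genes whose mean fold change drops by at least 20% (mean_fc <= 0.8,
roughly one SD of the log-normal fold-change distribution) are called
down-regulated.  Fold-change distributions of gene sets are compared with
empirical CDFs and the two-sample Kolmogorov-Smirnov test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import EnrichmentTable, GeneSet, _per_gene_ratio_table, _REL_EPS
from .errors import MirpullError
from .expression import ExpressionFlag, ProbeMatrix

logger = logging.getLogger(__name__)

DEFAULT_DOWN_CUTOFF = 0.8


@dataclass
class FoldChangeTable:
    """Per-gene input-arm fold changes (test/control) for one cell line."""

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
        out.to_csv(path, sep="\t", index_label="gene_id")


@dataclass(frozen=True)
class KSComparison:
    """Two-sample KS comparison of log2 fold changes of two gene sets."""

    set_a_label: str
    set_b_label: str
    ks_statistic: float
    p_value: float
    n_a: int
    n_b: int


def fold_change(
    matrix: ProbeMatrix,
    flags: ExpressionFlag,
    cell_line: str | None = None,
    collapse: str = "mean",
) -> FoldChangeTable:
    """Compute per-gene input fold changes (input_test / input_control)."""
    table, cl, n_reps, n_bad = _per_gene_ratio_table(
        matrix,
        flags,
        cell_line,
        numerator_arms=[("input", "test")],
        denominator_arms=[("input", "control")],
        collapse=collapse,
    )
    table = table.rename(
        columns={"mean_ratio": "mean_fc", "log2_ratio": "log2_fc"}
    )
    table = table.rename(
        columns={c: c.replace("ratio_rep", "fc_rep") for c in table.columns}
    )
    return FoldChangeTable(
        table=table, cell_line=cl, n_replicates=n_reps, n_excluded_nonpositive=n_bad
    )


def call_down(
    table: FoldChangeTable,
    cutoff: float = DEFAULT_DOWN_CUTOFF,
    label: str | None = None,
) -> GeneSet:
    """Call down-regulated genes at ``mean_fc <= cutoff`` (inclusive).

    The default cutoff 0.8 reads "reduced by at least 20%" literally.
    """
    if not 0 < cutoff < 1:
        raise MirpullError(f"down cutoff must be in (0, 1), got {cutoff}")
    is_down = table.table["mean_fc"] <= cutoff * (1.0 + _REL_EPS)
    table.table["is_down"] = is_down
    table.table["cutoff"] = cutoff
    return GeneSet(
        label=label or f"{table.cell_line}_down",
        members=frozenset(table.table.index[is_down]),
        universe=frozenset(table.table.index),
    )


def cdf_table(values: pd.Series) -> pd.DataFrame:
    """Empirical CDF of a series: sorted values and cumulative fraction."""
    x = np.sort(np.asarray(values.dropna(), dtype=float))
    return pd.DataFrame(
        {"log2_fc": x, "cumulative_fraction": np.arange(1, len(x) + 1) / len(x)}
    )


def cdf_compare(
    fold_changes: FoldChangeTable,
    sets: list[GeneSet],
    reference: GeneSet,
) -> tuple[list[KSComparison], dict[str, pd.DataFrame]]:
    """Compare log2 fold-change distributions of gene sets to a reference.

    Each set is intersected with the genes that have fold changes; the
    two-sample KS statistic D = sup|F_a - F_b| and its asymptotic p-value are
    computed against the reference set.  Sets with fewer than two usable
    genes are skipped with a warning.  Also returns the per-set CDF tables
    (including the reference) for plotting.
    """
    log2 = fold_changes.table["log2_fc"]
    ref_vals = log2.loc[log2.index.intersection(list(reference.members))]
    if len(ref_vals) < 2:
        raise MirpullError(
            f"reference set {reference.label!r} has <2 genes with fold changes"
        )
    comparisons: list[KSComparison] = []
    cdfs: dict[str, pd.DataFrame] = {reference.label: cdf_table(ref_vals)}
    for gs in sets:
        vals = log2.loc[log2.index.intersection(list(gs.members))]
        if len(vals) < 2:
            warnings.warn(
                f"set {gs.label!r} has {len(vals)} usable genes; comparison skipped"
            )
            continue
        d, p = stats.ks_2samp(vals.values, ref_vals.values, method="asymp")
        comparisons.append(
            KSComparison(
                set_a_label=gs.label,
                set_b_label=reference.label,
                ks_statistic=float(d),
                p_value=float(p),
                n_a=len(vals),
                n_b=len(ref_vals),
            )
        )
        cdfs[gs.label] = cdf_table(vals)
    return comparisons, cdfs


def comparisons_to_tsv(comparisons: list[KSComparison], path) -> None:
    pd.DataFrame(
        [
            {
                "set_a": c.set_a_label,
                "set_b": c.set_b_label,
                "n_a": c.n_a,
                "n_b": c.n_b,
                "ks_D": c.ks_statistic,
                "ks_p": c.p_value,
            }
            for c in comparisons
        ]
    ).to_csv(path, sep="\t", index=False)


def stratify_by_enrichment(
    table: EnrichmentTable, cutoffs: list[float], label_prefix: str | None = None
) -> list[GeneSet]:
    """Nested gene sets at increasing enrichment-ratio cutoffs.

    ``cutoffs`` must be sorted ascending; the returned sets are nested
    (higher cutoff => subset).
    """
    if list(cutoffs) != sorted(cutoffs):
        raise MirpullError("cutoffs must be sorted ascending")
    prefix = label_prefix or table.cell_line
    ratios = table.table["mean_ratio"]
    universe = frozenset(table.table.index)
    out = []
    for cut in cutoffs:
        members = frozenset(ratios.index[ratios >= cut * (1.0 - _REL_EPS)])
        out.append(GeneSet(label=f"{prefix}_ratio_ge_{cut:g}", members=members,
                           universe=universe))
    return out
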