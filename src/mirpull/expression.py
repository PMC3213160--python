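"""Reading and validation of probe-level expression data.

The experiment has a four-arm design: streptavidin pull-down (PD) and input
(whole-lysate) RNA, each measured after transfection with the test miRNA and
with a control miRNA, in one or more biological replicates per arm.  This
module reads the normalized probe x sample intensity matrix together with its
sample design sheet and probe-to-gene map, flags unexpressed probes/genes
against a background intensity, and collapses per-probe statistics to genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DesignError, ParseError

logger = logging.getLogger(__name__)

ARMS = ("pulldown", "input")
MIRNAS = ("test", "control")

_DESIGN_COLUMNS = ["sample_id", "arm", "mirna", "replicate", "cell_line"]


@dataclass(frozen=True)
class SampleDesign:
    """Sample sheet for the four-arm pull-down design.

    One row per array sample with columns ``sample_id``, ``arm``
    (``pulldown``/``input``), ``mirna`` (``test``/``control``), ``replicate``
    (integer index) and ``cell_line``.  Every (arm, mirna, replicate)
    combination must be present exactly once per cell line.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing_cols = [c for c in _DESIGN_COLUMNS if c not in t.columns]
        if missing_cols:
            raise DesignError(f"design is missing columns: {missing_cols}")
        bad_arm = set(t["arm"]) - set(ARMS)
        if bad_arm:
            raise DesignError(f"unknown arm value(s) {sorted(bad_arm)}; expected {ARMS}")
        bad_mirna = set(t["mirna"]) - set(MIRNAS)
        if bad_mirna:
            raise DesignError(
                f"unknown mirna value(s) {sorted(bad_mirna)}; expected {MIRNAS}"
            )
        if t["sample_id"].duplicated().any():
            dup = t.loc[t["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise DesignError(f"duplicate sample_id {dup!r} in design")
        for cell_line, sub in t.groupby("cell_line"):
            reps = sorted(sub["replicate"].unique())
            if not reps:
                raise DesignError(f"cell line {cell_line!r} has no replicates")
            seen = set(zip(sub["arm"], sub["mirna"], sub["replicate"]))
            if len(seen) != len(sub):
                raise DesignError(
                    f"cell line {cell_line!r}: duplicated (arm, mirna, replicate) rows"
                )
            for arm in ARMS:
                for mirna in MIRNAS:
                    for rep in reps:
                        if (arm, mirna, rep) not in seen:
                            raise DesignError(
                                f"cell line {cell_line!r} is missing sample "
                                f"(arm={arm}, mirna={mirna}, replicate={rep})"
                            )

    @property
    def cell_lines(self) -> list[str]:
        return sorted(self.table["cell_line"].unique())

    def replicates(self, cell_line: str) -> list[int]:
        sub = self.table[self.table["cell_line"] == cell_line]
        return sorted(sub["replicate"].unique())

    def sample(self, arm: str, mirna: str, replicate: int, cell_line: str) -> str:
        """Return the sample_id for one cell of the design grid."""
        t = self.table
        mask = (
            (t["arm"] == arm)
            & (t["mirna"] == mirna)
            & (t["replicate"] == replicate)
            & (t["cell_line"] == cell_line)
        )
        hit = t.loc[mask, "sample_id"]
        if len(hit) != 1:
            raise DesignError(
                f"expected exactly one sample for (arm={arm}, mirna={mirna}, "
                f"replicate={replicate}, cell_line={cell_line}); found {len(hit)}"
            )
        return hit.iloc[0]


@dataclass
class ProbeMatrix:
    """Normalized probe-level intensities plus probe-to-gene mapping.

    ``values`` is probes x samples (nonnegative); ``probe_map`` maps probe_id
    to gene_id (NaN for unmapped probes, which are retained but excluded from
    gene-level outputs).
    """

    values: pd.DataFrame
    probe_map: pd.Series
    design: SampleDesign

    def __post_init__(self) -> None:
        design_samples = set(self.design.table["sample_id"])
        matrix_samples = set(self.values.columns)
        missing = design_samples - matrix_samples
        if missing:
            raise ParseError(
                f"matrix is missing sample column(s): {sorted(missing)}"
            )
        if (self.values.values < 0).any():
            r, c = np.argwhere(self.values.values < 0)[0]
            raise ParseError(
                f"negative intensity at probe {self.values.index[r]!r}, "
                f"sample {self.values.columns[c]!r}"
            )

    @property
    def probes(self) -> pd.Index:
        return self.values.index

    def genes(self) -> pd.Index:
        return pd.Index(sorted(self.probe_map.dropna().unique()), name="gene_id")


@dataclass
class ExpressionFlag:
    """Expressed calls at probe and gene level.

    A probe is expressed iff its signal exceeds the background in at least one
    sample; a gene is expressed iff at least one of its probes is expressed.
    """

    probe: pd.Series
    gene: pd.Series
    background: float

    def expressed_genes(self) -> frozenset:
        return frozenset(self.gene.index[self.gene])


def _read_tsv(path, **kwargs) -> pd.DataFrame:
    # comment='#' and the python engine's universal newlines tolerate
    # annotated and CRLF files
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def read_matrix(matrix_file, design_file, map_file) -> ProbeMatrix:
    """Read and validate an intensity matrix, its design sheet and probe map.

    Raises :class:`ParseError` for duplicate probes, non-numeric cells or
    missing sample columns, and :class:`DesignError` for an incomplete design.
    """
    design = SampleDesign(_read_tsv(design_file))

    raw = _read_tsv(matrix_file, dtype={0: str})
    if raw.columns[0] != "probe_id":
        raise ParseError(
            f"first matrix column must be 'probe_id', got {raw.columns[0]!r}"
        )
    if raw["probe_id"].duplicated().any():
        dup = raw.loc[raw["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise ParseError(f"duplicate probe_id {dup!r} in matrix")
    values = raw.set_index("probe_id")
    for col in values.columns:
        numeric = pd.to_numeric(values[col], errors="coerce")
        if numeric.isna().any() and not values[col].isna().all():
            bad = values.index[numeric.isna() & values[col].notna()]
            if len(bad):
                raise ParseError(
                    f"non-numeric value at probe {bad[0]!r}, sample {col!r}: "
                    f"{values.loc[bad[0], col]!r}"
                )
        values[col] = numeric
    if values.isna().any().any():
        probe = values.index[values.isna().any(axis=1)][0]
        raise ParseError(f"missing value in matrix at probe {probe!r}")

    pmap = _read_tsv(map_file, dtype=str)
    if list(pmap.columns[:2]) != ["probe_id", "gene_id"]:
        raise ParseError(
            f"probe map must have columns probe_id, gene_id; got {list(pmap.columns)}"
        )
    genes_per_probe = pmap.groupby("probe_id")["gene_id"].nunique()
    multi = genes_per_probe[genes_per_probe > 1]
    if len(multi):
        raise ParseError(
            f"probe {multi.index[0]!r} maps to {multi.iloc[0]} genes; "
            "probes must map to at most one gene"
        )
    probe_map = (
        pmap.drop_duplicates("probe_id").set_index("probe_id")["gene_id"]
        .reindex(values.index)
    )
    n_unmapped = int(probe_map.isna().sum())
    if n_unmapped:
        logger.info("%d probes without gene mapping (retained, flagged)", n_unmapped)

    return ProbeMatrix(values=values, probe_map=probe_map, design=design)


def flag_expressed(
    matrix: ProbeMatrix,
    background: float | None = None,
    quantile: float = 0.05,
) -> ExpressionFlag:
    """Flag expressed probes and genes against a background intensity.

    ``background`` is an absolute intensity threshold; when omitted it is the
    ``quantile`` (default 5th percentile) of the whole matrix — a reproducible
    surrogate for array present/absent calls.  A probe is expressed iff its
    signal exceeds the background in at least one sample.
    """
    if background is None:
        background = float(np.quantile(matrix.values.values, quantile))
    if background < 0:
        raise ConfigError(f"background must be >= 0, got {background}")
    probe = (matrix.values > background).any(axis=1)
    mapped = matrix.probe_map.dropna()
    gene = probe.loc[mapped.index].groupby(mapped).any()
    gene.index.name = "gene_id"
    return ExpressionFlag(probe=probe, gene=gene, background=background)


def collapse_to_genes(
    per_probe: pd.Series, probe_map: pd.Series, method: str = "mean"
) -> pd.Series:
    """Collapse a per-probe statistic to genes.

    ``method='mean'`` takes the arithmetic mean of a gene's probe values (the
    default); ``'gmean'`` the geometric mean.  Probes without a gene mapping
    and probes with NaN values are dropped; a gene with no usable probes is
    absent from the output.
    """
    mapped = probe_map.reindex(per_probe.index).dropna()
    vals = per_probe.loc[mapped.index].dropna()
    mapped = mapped.loc[vals.index]
    if method == "mean":
        out = vals.groupby(mapped).mean()
    elif method == "gmean":
        out = np.exp(np.log(vals).groupby(mapped).mean())
    else:
        raise ValueError(f"unknown collapse method {method!r}")
    out.index.name = "gene_id"
    return out
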