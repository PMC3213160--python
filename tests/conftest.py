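"""Shared fixtures: in-memory four-arm matrices and a small synthetic study."""

import numpy as np
import pandas as pd
import pytest

from mirpull.expression import ProbeMatrix, SampleDesign
from mirpull.simulate import SimulationConfig, simulate_study


def make_design(n_replicates=1, cell_line="cl"):
    rows = []
    for arm in ("pulldown", "input"):
        for mirna in ("test", "control"):
            for rep in range(1, n_replicates + 1):
                rows.append(
                    {
                        "sample_id": f"{cell_line}_{arm}_{mirna}_r{rep}",
                        "arm": arm,
                        "mirna": mirna,
                        "replicate": rep,
                        "cell_line": cell_line,
                    }
                )
    return SampleDesign(pd.DataFrame(rows))


def make_matrix(values: dict, probe_map: dict, n_replicates=1, cell_line="cl"):
    """Build a ProbeMatrix from {probe: {(arm, mirna, rep): value}}."""
    design = make_design(n_replicates, cell_line)
    cols = list(design.table["sample_id"])
    frame = pd.DataFrame(index=pd.Index(sorted(values), name="probe_id"),
                         columns=cols, dtype=float)
    for probe, cells in values.items():
        for (arm, mirna, rep), v in cells.items():
            frame.loc[probe, f"{cell_line}_{arm}_{mirna}_r{rep}"] = v
    pm = pd.Series(probe_map, name="gene_id").reindex(frame.index)
    return ProbeMatrix(values=frame, probe_map=pm, design=design)


def uniform_probe(pd_test, pd_ctl, in_test, in_ctl, n_replicates=1):
    """Per-probe cell dict with the same four-arm values in every replicate."""
    cells = {}
    for rep in range(1, n_replicates + 1):
        cells[("pulldown", "test", rep)] = pd_test
        cells[("pulldown", "control", rep)] = pd_ctl
        cells[("input", "test", rep)] = in_test
        cells[("input", "control", rep)] = in_ctl
    return cells


@pytest.fixture(scope="session")
def small_study(tmp_path_factory):
    """A complete small synthetic study on disk, shared across tests."""
    outdir = tmp_path_factory.mktemp("study")
    config = SimulationConfig(
        n_genes=300,
        n_pathways=20,
        pathway_size_dist=(5, 30),
        rng_seed=11,
    )
    result = simulate_study(config, outdir)
    result["config"] = config
    result["outdir"] = outdir
    return result
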