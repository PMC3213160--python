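"""Synthetic-data generator: structure, planted effects, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirpull.enrichment import call_hits, enrichment_ratio, fit_background
from mirpull.errors import ConfigError, MirpullError
from mirpull.expression import flag_expressed
from mirpull.hexamer import MIR34A, count_matches
from mirpull.pathways import enrich, hypergeom_p
from mirpull.simulate import (
    SimulationConfig,
    TruthLabels,
    simulate_expression,
    simulate_pathways,
    simulate_sequences,
    simulate_study,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs, field",
        [
            ({"enrichment_effect": 1.0}, "enrichment_effect"),
            ({"knockdown_effect": 1.5}, "knockdown_effect"),
            ({"target_fraction": -0.1}, "target_fraction"),
            ({"n_genes": 0}, "n_genes"),
            ({"n_replicates": 0}, "n_replicates"),
            ({"noise_sd": -1.0}, "noise_sd"),
            ({"pathway_size_dist": (0, 5)}, "pathway_size_dist"),
        ],
    )
    def test_invalid_config_names_field(self, kwargs, field):
        with pytest.raises(ConfigError, match=field):
            SimulationConfig(**kwargs)

    def test_pathway_size_exceeding_gene_count_rejected_at_generation(self):
        config = SimulationConfig(n_genes=10, pathway_size_dist=(5, 50), rng_seed=1)
        pm, labels = simulate_expression(config)
        with pytest.raises(MirpullError, match="exceeds"):
            simulate_pathways(config, labels)


class TestSimulateExpression:
    def test_noiseless_null_gives_exact_unit_ratios(self):
        config = SimulationConfig(n_genes=30, noise_sd=0.0, target_fraction=0.0,
                                  rng_seed=1)
        pm, _ = simulate_expression(config)
        table = enrichment_ratio(pm, flag_expressed(pm, background=0.0))
        assert np.allclose(table.table["mean_ratio"], 1.0, rtol=1e-12)

    def test_noiseless_target_recovers_planted_effect_exactly(self):
        config = SimulationConfig(
            n_genes=30, noise_sd=0.0, target_fraction=1 / 30,
            enrichment_effect=4.0, rng_seed=2,
        )
        pm, labels = simulate_expression(config)
        table = enrichment_ratio(pm, flag_expressed(pm, background=0.0))
        target = labels.table.index[labels.table["is_target"]][0]
        assert table.table.loc[target, "mean_ratio"] == pytest.approx(4.0, rel=1e-12)

    def test_noiseless_knockdown_in_input_arms(self):
        from mirpull.downreg import fold_change

        config = SimulationConfig(
            n_genes=20, noise_sd=0.0, target_fraction=0.5,
            knockdown_effect=0.5, rng_seed=3,
        )
        pm, labels = simulate_expression(config)
        fc = fold_change(pm, flag_expressed(pm, background=0.0))
        expected = labels.table["planted_knockdown"].loc[fc.table.index]
        assert np.allclose(fc.table["mean_fc"], expected, rtol=1e-12)

    def test_repeated_run_is_byte_identical(self, tmp_path):
        config = SimulationConfig(
            n_genes=200, target_fraction=0.1, enrichment_effect=4.0,
            noise_sd=0.5, rng_seed=7,
        )
        frames = []
        for run in ("a", "b"):
            pm, _ = simulate_expression(config)
            path = tmp_path / f"{run}.tsv"
            pm.values.to_csv(path, sep="\t")
            frames.append(path.read_bytes())
        assert frames[0] == frames[1]

    def test_four_arm_design_complete(self):
        config = SimulationConfig(n_genes=10, n_replicates=3, rng_seed=4)
        pm, _ = simulate_expression(config)
        assert pm.values.shape[1] == 4 * 3
        assert pm.design.replicates(pm.design.cell_lines[0]) == [1, 2, 3]

    def test_probes_per_gene_range(self):
        config = SimulationConfig(n_genes=100, probes_per_gene=(1, 4), rng_seed=5)
        pm, _ = simulate_expression(config)
        counts = pm.probe_map.groupby(pm.probe_map).size()
        assert counts.min() >= 1 and counts.max() <= 4 and counts.nunique() > 1

    def test_sensitivity_matches_mixture_threshold_oracle(self):
        """Recovery of planted targets at the 1 SD threshold agrees with the
        closed-form normal-tail oracle built on the mixture distribution."""
        noise_sd, probes, reps, effect, tf = 0.5, 2, 2, 4.0, 0.1
        config = SimulationConfig(
            n_genes=2000, probes_per_gene=probes, n_replicates=reps,
            target_fraction=tf, enrichment_effect=effect, noise_sd=noise_sd,
            rng_seed=13,
        )
        pm, labels = simulate_expression(config)
        table = enrichment_ratio(pm, flag_expressed(pm, background=0.0))
        hits = call_hits(table, fit_background(table, n_sd=1.0))
        targets = labels.target_set()
        n_targets = len(targets)
        sens = len(hits.members & targets.members) / n_targets
        spec_ = 1 - len(hits.members - targets.members) / (config.n_genes - n_targets)

        # oracle (written before the pipeline): gene-level log2 ratio is
        # approximately N(d, s) for targets and N(0, s) for the rest, with s
        # from Fenton-Wilkinson moment matching; the fitted threshold sits at
        # the mixture mean + 1 mixture SD.
        k = probes * reps
        sigma_ln = 2 * noise_sd * np.log(2)
        s = np.sqrt(np.log(1 + (np.exp(sigma_ln**2) - 1) / k)) / np.log(2)
        d = np.log2(effect)
        t = tf * d + np.sqrt(s**2 + tf * (1 - tf) * d**2)
        oracle_sens = stats.norm.sf((t - d) / s)
        oracle_spec = stats.norm.cdf(t / s)

        se_sens = np.sqrt(oracle_sens * (1 - oracle_sens) / n_targets)
        se_spec = np.sqrt(oracle_spec * (1 - oracle_spec) / (config.n_genes - n_targets))
        assert abs(sens - oracle_sens) <= 3 * se_sens
        assert abs(spec_ - oracle_spec) <= 3 * se_spec


class TestSimulateSequences:
    def test_zero_density_plants_nothing(self):
        config = SimulationConfig(
            n_genes=50, seed_density_target=0.0, seed_density_background=0.0,
            rng_seed=8,
        )
        pm, labels = simulate_expression(config)
        simulate_sequences(config, labels)
        assert (labels.table["planted_sites_utr3"] == 0).all()

    def test_poisson_mean_of_planted_sites(self):
        """Density 5/kb on ~1 kb 3'UTRs: mean planted count within 3 SE."""
        config = SimulationConfig(
            n_genes=4000, target_fraction=1.0, enrichment_effect=4.0,
            seed_density_target=5.0,
            utr_length_dist={"utr3": (1000.0, 0.0)},
            rng_seed=9,
        )
        pm, labels = simulate_expression(config)
        simulate_sequences(config, labels)
        counts = labels.table["planted_sites_utr3"]
        se = np.sqrt(5.0 / len(counts))
        assert abs(counts.mean() - 5.0) <= 3 * se

    def test_planted_counts_found_by_scanner(self):
        """Every planted site is recoverable by exact scanning (sites never
        overlap), so scanned count >= planted count per gene."""
        config = SimulationConfig(n_genes=100, rng_seed=10)
        pm, labels = simulate_expression(config)
        seqs = simulate_sequences(config, labels)
        site = MIR34A.seed_site
        for gene in labels.genes[:50]:
            found = count_matches(seqs.get(gene, "utr3"), site)
            assert found >= labels.table.loc[gene, "planted_sites_utr3"]

    def test_same_seed_identical_fasta(self, tmp_path):
        outputs = []
        for run in ("a", "b"):
            config = SimulationConfig(n_genes=40, rng_seed=12)
            pm, labels = simulate_expression(config)
            seqs = simulate_sequences(config, labels)
            path = tmp_path / f"{run}.fasta"
            seqs.to_fasta(path)
            outputs.append(path.read_bytes())
        assert outputs[0] == outputs[1]

    def test_empty_labels_rejected(self):
        config = SimulationConfig(n_genes=10, rng_seed=1)
        empty = TruthLabels(table=pd.DataFrame(
            columns=["is_target", "planted_enrichment", "planted_knockdown"]
        ))
        with pytest.raises(MirpullError, match="empty"):
            simulate_sequences(config, empty)


class TestSimulatePathways:
    def test_pathway_of_exactly_target_set_minimal_p(self):
        config = SimulationConfig(n_genes=60, target_fraction=0.2, rng_seed=14)
        pm, labels = simulate_expression(config)
        collection = simulate_pathways(config, labels)
        targets = labels.target_set()
        from mirpull.pathways import Pathway

        collection.pathways["EXACT"] = Pathway("EXACT", "exact", targets.members)
        results = enrich(targets, collection, p_cut=0.001).set_index("pathway_id")
        n_t = len(targets)
        minimal = hypergeom_p(n_t, n_t, n_t, config.n_genes)
        assert results.loc["EXACT", "p"] == pytest.approx(minimal, rel=1e-9)
        assert results.loc["EXACT", "p"] == results["p"].min()

    def test_null_pathways_calibrated_against_hypergeometric(self):
        """With no target-enriched pathways, pathway overlaps follow the
        hypergeometric null: the discrete upper-tail p is super-uniform, so
        small p-values must not be over-produced."""
        config = SimulationConfig(
            n_genes=500, target_fraction=0.2,
            n_pathways=200, pathway_size_dist=(40, 40),
            target_enriched_pathway_fraction=0.0, rng_seed=15,
        )
        pm, labels = simulate_expression(config)
        collection = simulate_pathways(config, labels)
        results = enrich(labels.target_set(), collection, p_cut=0.001)
        assert (results["p"] < 0.01).sum() <= 0.01 * len(results) * 4 + 2
        assert (results["p"] < 0.10).sum() <= 0.10 * len(results) * 3 + 2

    def test_same_seed_identical_gmt(self, tmp_path):
        outputs = []
        for run in ("a", "b"):
            config = SimulationConfig(n_genes=80, n_pathways=15,
                                      pathway_size_dist=(5, 20), rng_seed=16)
            pm, labels = simulate_expression(config)
            collection = simulate_pathways(config, labels)
            path = tmp_path / f"{run}.gmt"
            collection.to_gmt(path)
            outputs.append(path.read_bytes())
        assert outputs[0] == outputs[1]

    def test_enriched_pathways_recoverable(self):
        config = SimulationConfig(
            n_genes=400, target_fraction=0.15, n_pathways=30,
            pathway_size_dist=(20, 40), target_enriched_pathway_fraction=0.5,
            pathway_target_weight=10.0, rng_seed=17,
        )
        pm, labels = simulate_expression(config)
        collection = simulate_pathways(config, labels)
        results = enrich(labels.target_set(), collection, p_cut=0.001)
        sig = set(results.loc[results["significant"], "pathway_id"])
        enriched_ids = {p for p, obj in collection.pathways.items()
                        if obj.name == "target_enriched"}
        # most detected pathways should be the planted ones
        assert sig and len(sig & enriched_ids) >= len(sig) * 0.8


class TestStudyOutputs:
    def test_study_files_exist_and_parse(self, small_study):
        from mirpull.expression import read_matrix
        from mirpull.hexamer import RegionSequenceSet
        from mirpull.pathways import PathwayCollection

        paths = small_study["paths"]
        for cl, files in paths["cell_lines"].items():
            pm = read_matrix(files["matrix"], files["design"], files["probe_map"])
            assert pm.values.shape[0] > 0
        seqs = RegionSequenceSet.from_fasta(paths["fasta"])
        assert len(seqs) == 300
        collection = PathwayCollection.from_gmt(paths["gmt"])
        assert len(collection) == 20
        labels = TruthLabels.from_tsv(paths["truth"])
        assert labels.table["is_target"].sum() == 30
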