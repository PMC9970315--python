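"""Synthetic-data generator: planted-edge soundness, seed determinism,
noise models."""

import numpy as np
import pandas as pd
import pytest

from regpath.simulate import (
    CohortGroupSpec,
    CohortSimConfig,
    NetworkSimConfig,
    QpcrSimConfig,
    default_cohort_config,
    gen_cohort,
    gen_interaction_db,
    gen_qpcr,
    infer_node_type,
)
from regpath.stats import delta_delta_ct

PATH_S_TF_MIR = ["S", "TFX", "miR-378a-3p"]
FULL_PATH = ["TGFB1", "TFX", "miR-378a-3p", "CTGF"]


def db_edge_sets(db):
    ppi = {tuple(sorted(r)) for r in
           db.ppi_edges.itertuples(index=False, name=None)}
    tfm = set(db.tf_mirna_edges.itertuples(index=False, name=None))
    votes = {}
    for table in db.prediction_tables.values():
        for mirna, gene, _ in table.itertuples(index=False, name=None):
            votes[(mirna, gene)] = votes.get((mirna, gene), 0) + 1
    return ppi, tfm, votes


class TestInteractionDB:
    def test_zero_decoys_emits_exactly_the_planted_edges(self):
        db = gen_interaction_db(
            NetworkSimConfig(planted_paths=[PATH_S_TF_MIR], seed=0)
        )
        ppi, tfm, votes = db_edge_sets(db)
        assert ppi == {("S", "TFX")}
        assert tfm == {("TFX", "miR-378a-3p")}
        assert votes == {}
        assert [list(t.nodes) for t in db.truth] == [PATH_S_TF_MIR]
        assert db.truth[0].edge_types == ("ppi", "tf_mirna")

    def test_planted_edges_present_with_correct_type_among_decoys(self):
        """Direct table-scan oracle: each planted edge must sit in the one
        table matching its type, with targets clearing the vote floor."""
        cfg = NetworkSimConfig(
            planted_paths=[FULL_PATH],
            n_decoy_genes=10,
            n_tfs=3,
            n_mirnas=2,
            ppi_edge_prob=0.3,
            seed=1,
        )
        db = gen_interaction_db(cfg)
        ppi, tfm, votes = db_edge_sets(db)
        assert ("TFX", "TGFB1") in ppi  # stored sorted; undirected pair
        assert ("TFX", "miR-378a-3p") in tfm
        assert votes.get(("miR-378a-3p", "CTGF"), 0) >= cfg.min_tools
        for t in db.truth:
            assert t.edge_types == ("ppi", "tf_mirna", "mirna_target")

    def test_seed_contract(self):
        """Same seed ⇒ byte-identical tables; different seed ⇒ same planted
        edges, different decoys."""
        def make(seed):
            return gen_interaction_db(NetworkSimConfig(
                planted_paths=[FULL_PATH], n_decoy_genes=12, n_tfs=2,
                n_mirnas=2, ppi_edge_prob=0.3, seed=seed,
            ))

        a, b, c = make(5), make(5), make(6)
        assert a.ppi_edges.to_csv() == b.ppi_edges.to_csv()
        for tool in a.prediction_tables:
            assert a.prediction_tables[tool].to_csv() == \
                b.prediction_tables[tool].to_csv()
        assert a.ppi_edges.to_csv() != c.ppi_edges.to_csv()
        ppi_c, tfm_c, votes_c = db_edge_sets(c)
        assert ("TFX", "TGFB1") in ppi_c
        assert ("TFX", "miR-378a-3p") in tfm_c
        assert votes_c.get(("miR-378a-3p", "CTGF"), 0) >= 3
        assert a.truth == c.truth

    def test_no_decoy_shortcut_below_shortest_planted_path(self):
        import networkx as nx
        cfg = NetworkSimConfig(
            planted_paths=[FULL_PATH], n_decoy_genes=15, n_tfs=4,
            n_mirnas=3, ppi_edge_prob=0.4, tf_mirna_edge_prob=0.5,
            p_decoy=0.3, seed=3,
        )
        db = gen_interaction_db(cfg)
        ppi, tfm, votes = db_edge_sets(db)
        g = nx.DiGraph()
        for a, b in ppi:
            g.add_edge(a, b)
            g.add_edge(b, a)
        g.add_edges_from(tfm)
        for (mi, gene), v in votes.items():
            if v >= cfg.min_tools:
                g.add_edge(mi, gene)
        assert nx.shortest_path_length(g, "TGFB1", "CTGF") >= 3

    def test_invalid_type_transition_rejected_naming_edge(self):
        with pytest.raises(ValueError, match="S→miR-378a-3p"):
            gen_interaction_db(NetworkSimConfig(
                planted_paths=[["S", "miR-378a-3p"]], seed=0,
            ))
        with pytest.raises(ValueError, match="miR-1→miR-2"):
            gen_interaction_db(NetworkSimConfig(
                planted_paths=[["TFX", "miR-1", "miR-2"]], seed=0,
            ))

    @pytest.mark.parametrize("bad", [
        {"ppi_edge_prob": 1.5},
        {"n_decoy_genes": -1},
        {"planted_paths": [["A"]]},
        {"planted_paths": [["A", "B", "A"]]},
        {"planted_paths": [["A", "B"], ["C", "B"]]},  # two sources
        {"min_tools": 6},
    ])
    def test_invalid_config_rejected(self, bad):
        kwargs = {"planted_paths": [["A", "B"]], "seed": 0}
        kwargs.update(bad)
        with pytest.raises(ValueError):
            NetworkSimConfig(**kwargs)

    def test_node_type_inference(self):
        assert infer_node_type("miR-378a-3p") == "miRNA"
        assert infer_node_type("hsa-miR-30b") == "miRNA"
        assert infer_node_type("TFX") == "TF"
        assert infer_node_type("CTGF") == "gene"
        assert infer_node_type("CTGF", tf_ids={"CTGF"}) == "TF"
        assert infer_node_type("CTGF", overrides={"CTGF": "TF"}) == "TF"


class TestQpcr:
    def test_noiseless_fold_is_exact_ct_shift(self):
        cfg = QpcrSimConfig(
            genes=["g", "GAPDH"],
            fold_changes={"OM": {"g": 0.5}},
            ct_noise_sd=0.0, n_replicates=3, seed=0,
        )
        table = gen_qpcr(cfg)
        om = table[(table.group == "OM") & (table.gene == "g")].ct
        ctrl = table[(table.group == "control") & (table.gene == "g")].ct
        assert np.allclose(om.values - ctrl.mean(), 1.0)  # 2^-1 = 0.5
        ref = table[table.gene == "GAPDH"].ct
        assert np.allclose(ref, cfg.baseline_ct)

    def test_fold_one_everywhere_gives_identical_groups(self):
        cfg = QpcrSimConfig(
            genes=["g", "GAPDH"], fold_changes={"OM": {"g": 1.0}},
            ct_noise_sd=0.0, n_replicates=2, seed=0,
        )
        table = gen_qpcr(cfg)
        assert table.ct.nunique() == 1

    def test_monte_carlo_recovery_of_planted_fold(self):
        """Mean downstream ΔΔCt estimate over 500 seeds within 0.02 of the
        planted fold 0.42."""
        folds = []
        for seed in range(500):
            cfg = QpcrSimConfig(
                genes=["g", "GAPDH"], fold_changes={"OM": {"g": 0.42}},
                ct_noise_sd=0.25, n_replicates=6, seed=seed,
            )
            fc = delta_delta_ct(gen_qpcr(cfg), "g", "GAPDH", "OM", "control")
            folds.append(fc.fold_change)
        assert abs(np.mean(folds) - 0.42) < 0.02

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="n_replicates"):
            QpcrSimConfig(genes=["g", "GAPDH"], fold_changes={},
                          n_replicates=0)
        with pytest.raises(ValueError, match="reference"):
            QpcrSimConfig(genes=["g"], fold_changes={}, reference_gene="R")
        with pytest.raises(ValueError, match="> 0"):
            QpcrSimConfig(genes=["g", "GAPDH"],
                          fold_changes={"OM": {"g": 0.0}})


class TestCohort:
    def test_default_cohort_has_24_and_11(self):
        cohort = gen_cohort(default_cohort_config(seed=0))
        assert len(cohort) == 35
        counts = cohort.group.value_counts()
        assert counts["non-AAC"] == 24
        assert counts["severe-AAC"] == 11

    def test_sd_zero_gives_group_mean_exactly(self):
        cfg = CohortSimConfig(group_specs=[CohortGroupSpec(
            label="a", n=5, biomarkers={"x": (3.0, 0.0)},
            age_sd=0.0,
        )], seed=0)
        cohort = gen_cohort(cfg)
        assert np.allclose(cohort.x, 3.0)

    def test_large_n_sample_mean_within_3_se(self):
        n = 10_000
        mean, sd = 10.0, 2.0
        cfg = CohortSimConfig(
            group_specs=[CohortGroupSpec(
                label="a", n=n, biomarkers={"x": (mean, sd)},
            )],
            nonnegative_clip=False, seed=1,
        )
        cohort = gen_cohort(cfg)
        assert abs(cohort.x.mean() - mean) < 3 * sd / np.sqrt(n)

    def test_seed_determinism(self):
        a = gen_cohort(default_cohort_config(seed=9))
        b = gen_cohort(default_cohort_config(seed=9))
        pd.testing.assert_frame_equal(a, b)

    def test_missing_sd_rejected(self):
        with pytest.raises(ValueError, match="missing SD"):
            CohortGroupSpec(label="a", n=5, biomarkers={"x": 3.0})
        with pytest.raises(ValueError, match="same biomarkers"):
            CohortSimConfig(group_specs=[
                CohortGroupSpec(label="a", n=5, biomarkers={"x": (1, 1)}),
                CohortGroupSpec(label="b", n=5, biomarkers={"y": (1, 1)}),
            ])

    def test_n_below_two_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            CohortGroupSpec(label="a", n=1, biomarkers={"x": (1.0, 1.0)})
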