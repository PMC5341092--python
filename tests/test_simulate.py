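"""Synthetic-data generator: copula calibration, fixtures, round trips."""

import filecmp

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from essevo import simulate as sim
from essevo import phenotype as ph
from essevo import pipeline as pl


class TestSpearmanToPearson:
    def test_endpoints(self):
        m = np.array([[1.0, 0.0], [0.0, 1.0]])
        r, projected = sim.spearman_to_pearson(m)
        assert r[0, 1] == pytest.approx(0.0)
        assert not projected
        m = np.array([[1.0, 1.0], [1.0, 1.0]])
        r, _ = sim.spearman_to_pearson(m)
        assert r[0, 1] == pytest.approx(1.0)  # 2*sin(pi/6)

    def test_half(self):
        m = np.array([[1.0, 0.5], [0.5, 1.0]])
        r, _ = sim.spearman_to_pearson(m)
        assert r[0, 1] == pytest.approx(2 * np.sin(np.pi / 12), abs=1e-12)
        assert r[0, 1] == pytest.approx(0.5176, abs=1e-4)

    def test_non_symmetric_rejected(self):
        with pytest.raises(ValueError):
            sim.spearman_to_pearson(np.array([[1.0, 0.2], [0.3, 1.0]]))

    def test_projection_recorded(self):
        # an invalid (non-PSD) pseudo-correlation matrix must be repaired
        m = np.array([
            [1.0, 0.9, -0.9],
            [0.9, 1.0, 0.9],
            [-0.9, 0.9, 1.0],
        ])
        r, projected = sim.spearman_to_pearson(m)
        assert projected
        assert np.linalg.eigvalsh(r).min() > 0


class TestSimulateGeneTable:
    def test_category_sizes_exact(self, default_simulation):
        gt, _, _ = default_simulation
        counts = gt.table["category"].value_counts()
        assert counts[ph.CATEGORY_SUBINFERTILITY] == 57
        assert counts[ph.CATEGORY_LETHALITY] == 502
        assert counts[ph.CATEGORY_NONESSENTIAL] == 406

    def test_sizes_must_sum(self):
        with pytest.raises(ValueError):
            sim.SimulationConfig(n_genes=10, category_sizes=(1, 2, 3))

    def test_dnds_strictly_below_one(self, default_simulation):
        gt, _, _ = default_simulation
        assert (gt.table["dnds"] >= 0).all()
        assert (gt.table["dnds"] < 1).all()
        assert np.isfinite(gt.table[["dn", "ds", "tau"]]).all().all()

    @pytest.mark.parametrize("seed", [0, 7, 42])
    def test_sample_spearman_near_targets(self, seed):
        gt = sim.simulate_gene_table(sim.SimulationConfig(seed=seed))
        obs = sps.spearmanr(
            gt.table[list(sim.VARIABLES)]).statistic
        target = sim.DEFAULT_TARGET_SPEARMAN
        assert np.abs(obs - target).max() < 0.08

    def test_spearman_converges_with_n(self):
        cfg = sim.SimulationConfig(
            n_genes=10_000, category_sizes=(591, 5202, 4207), seed=3)
        gt = sim.simulate_gene_table(cfg)
        obs = sps.spearmanr(gt.table[list(sim.VARIABLES)]).statistic
        assert np.abs(obs - cfg.target_spearman).max() < 0.03

    def test_median_orderings(self, default_simulation):
        gt, _, _ = default_simulation
        med = gt.table.groupby("category").median(numeric_only=True)
        sub, leth, non = (ph.CATEGORY_SUBINFERTILITY, ph.CATEGORY_LETHALITY,
                          ph.CATEGORY_NONESSENTIAL)
        assert med.loc[sub, "dnds"] > med.loc[non, "dnds"] > med.loc[leth, "dnds"]
        assert med.loc[leth, "degree"] == med.loc[:, "degree"].max()
        assert med.loc[leth, "multifunctionality"] == (
            med.loc[:, "multifunctionality"].max())
        assert med.loc[sub, "tau"] > med.loc[non, "tau"] > med.loc[leth, "tau"]

    def test_x_linked_counts_match_proportions(self, default_simulation):
        gt, _, _ = default_simulation
        t = gt.table
        by_cat = t.groupby("category")["x_linked"].sum()
        assert by_cat[ph.CATEGORY_LETHALITY] == 8
        assert by_cat[ph.CATEGORY_SUBINFERTILITY] == 5
        assert by_cat[ph.CATEGORY_NONESSENTIAL] == 27
        imm = t.groupby("category")["immunity"].sum()
        assert imm[ph.CATEGORY_LETHALITY] == 140

    def test_null_config_calibration(self):
        # no shifts, no correlation: KW on dN/dS rejects in about 5% of seeds
        zero_shifts = {k: (0.0, 0.0, 0.0) for k in sim.DEFAULT_SHIFTS}
        rejections = 0
        n_seeds = 200
        for seed in range(n_seeds):
            cfg = sim.SimulationConfig(
                n_genes=90, category_sizes=(10, 40, 40),
                target_spearman=np.eye(4), shifts=zero_shifts, seed=seed)
            t = sim.simulate_gene_table(cfg).table
            groups = [t.loc[t["category"] == c, "dnds"].to_numpy()
                      for c in sim.CATEGORIES]
            from essevo import stats as st
            if st.kruskal_wallis(groups).p_raw < 0.05:
                rejections += 1
        assert 0.02 <= rejections / n_seeds <= 0.10


class TestEmitFixtures:
    def test_same_seed_byte_identical(self, tmp_path):
        cfg = dict(n_genes=120, category_sizes=(10, 60, 50), seed=5)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        for d in (d1, d2):
            gt = sim.simulate_gene_table(sim.SimulationConfig(**cfg))
            sim.emit_fixture_files(gt, d)
        for name in [p.name for p in d1.iterdir()]:
            assert filecmp.cmp(d1 / name, d2 / name, shallow=False), name

    def test_uniform_gene_has_uniform_fpkm_row(self, tmp_path):
        cfg = sim.SimulationConfig(n_genes=12, category_sizes=(2, 5, 5), seed=1)
        gt = sim.simulate_gene_table(cfg)
        gt.table.loc[gt.table.index[0], "tau"] = 0.0
        sim.emit_fixture_files(gt, tmp_path)
        fpkm = pd.read_csv(tmp_path / "expression_fpkm.tsv", sep="\t",
                           index_col=0)
        row = fpkm.iloc[0]
        assert row.nunique() == 1 and row.iloc[0] > 0

    def test_lethality_gene_carries_preweaning_subtree_term(
            self, default_simulation, mp_ontology):
        gt, out, _ = default_simulation
        alleles = pd.read_csv(out / "phenotype_alleles.tsv", sep="\t")
        lethal_terms = (mp_ontology.subtree("MP:0010770")
                        | mp_ontology.subtree("MP:0008569")
                        | set(ph.LETHALITY_SINGLE_TERMS))
        lethal_genes = gt.table.index[
            gt.table["category"] == ph.CATEGORY_LETHALITY]
        primary = alleles[alleles["allele_id"].str.endswith("_a1")]
        primary = primary.set_index("gene_id")
        assert primary.loc[lethal_genes, "mp_terms"].isin(lethal_terms).all()

    def test_degree_sequence_realized_exactly(self, default_simulation):
        gt, out, manifest = default_simulation
        edges = pd.read_csv(out / "ppi_edges.tsv", sep="\t")
        mapping = pd.read_csv(out / "ppi_mapping.tsv", sep="\t")
        acc_to_gene = dict(zip(mapping["accession"], mapping["gene_ids"]))
        deg: dict = {}
        for a, b in edges.itertuples(index=False):
            deg[acc_to_gene[a]] = deg.get(acc_to_gene[a], 0) + 1
            deg[acc_to_gene[b]] = deg.get(acc_to_gene[b], 0) + 1
        for gene, d in gt.table["degree"].items():
            assert deg.get(gene, 0) == d


@pytest.fixture(scope="module")
def roundtrip_bundle(default_simulation):
    gt, out, _ = default_simulation
    cfg = pl.RunConfig(
        inputs={
            "expression": out / "expression_fpkm.tsv",
            "annotations": out / "annotations.gaf",
            "go_obo": out / "go_toy.obo",
            "mp_obo": out / "mp_toy.obo",
            "edges": out / "ppi_edges.tsv",
            "mapping": out / "ppi_mapping.tsv",
            "phenotypes": out / "phenotype_alleles.tsv",
            "rates": out / "ortholog_rates.tsv",
        },
        bootstrap_replicates=500,
        seed=7,
    )
    return pl.run(cfg)


class TestRoundTrip:
    def test_all_labels_recovered(self, default_simulation, roundtrip_bundle):
        gt, _, _ = default_simulation
        rec = roundtrip_bundle.records
        assert len(rec) == len(gt.table)
        joined = gt.table.join(rec, rsuffix="_out", how="inner")
        assert (joined["category"] == joined["category_out"]).all()

    def test_covariates_recovered(self, default_simulation, roundtrip_bundle):
        gt, _, _ = default_simulation
        joined = gt.table.join(roundtrip_bundle.records, rsuffix="_out",
                               how="inner")
        assert (joined["tau"] - joined["tau_out"]).abs().max() < 1e-6
        assert (joined["degree"] == joined["degree_out"]).all()
        assert (joined["multifunctionality"]
                == joined["multifunctionality_out"]).all()
        assert (joined["immunity"] == joined["immunity_out"]).all()
        assert (joined["x_linked"] == joined["x_linked_out"]).all()
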