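"""Clonotype assembly and repertoire statistics against hand oracles."""
import numpy as np
import pandas as pd
import pytest

import ggnpipe as gp


def contig_row(bc, chain, v="TRAV1", j="TRAJ1", cdr3="CAAAF", productive="true",
               hc="true"):
    return dict(barcode=bc, chain=chain, v_gene=v, j_gene=j, cdr3=cdr3,
                productive=productive, high_confidence=hc)


def toy_contigs():
    """6 cells: 4 valid pairs (two sharing both chains), 1 dual-TRB, 1 TRA-only."""
    rows = []
    # cells c1, c2 share identical TRA+TRB -> same clonotype
    for bc in ("c1", "c2"):
        rows.append(contig_row(bc, "TRA", "TRAV1", "TRAJ1", "CAXF"))
        rows.append(contig_row(bc, "TRB", "TRBV2", "TRBJ1-1", "CBYF"))
    rows.append(contig_row("c3", "TRA", "TRAV3", "TRAJ3", "CAZF"))
    rows.append(contig_row("c3", "TRB", "TRBV3", "TRBJ1-2", "CBZF"))
    rows.append(contig_row("c4", "TRA", "TRAV4", "TRAJ4", "CAWF"))
    rows.append(contig_row("c4", "TRB", "TRBV4", "TRBJ2-1", "CBWF"))
    # c5: two productive TRBs -> dropped
    rows.append(contig_row("c5", "TRA", "TRAV5", "TRAJ5", "CAVF"))
    rows.append(contig_row("c5", "TRB", "TRBV5", "TRBJ1-1", "CBVF"))
    rows.append(contig_row("c5", "TRB", "TRBV6", "TRBJ1-2", "CBUF"))
    # c6: TRA only -> dropped
    rows.append(contig_row("c6", "TRA", "TRAV6", "TRAJ6", "CATF"))
    return pd.DataFrame(rows)


class TestAssignClonotypes:
    def test_hand_enumerated_retention(self):
        table, report = gp.assign_clonotypes(toy_contigs())
        assert report["n_cells_total"] == 6
        assert report["n_retained"] == 4
        assert set(table.index) == {"c1", "c2", "c3", "c4"}
        assert report["n_clonotypes"] == 3  # c1 and c2 share both chains
        assert table.loc["c1", "clonotype_id"] == table.loc["c2", "clonotype_id"]
        assert report["retention_pct"] == pytest.approx(66.67)

    def test_unproductive_contigs_filtered(self):
        df = toy_contigs()
        df.loc[df["barcode"] == "c3", "productive"] = "false"
        table, report = gp.assign_clonotypes(df)
        assert "c3" not in table.index and report["n_retained"] == 3

    def test_malformed_chain_rows_rejected_and_counted(self):
        df = pd.concat([toy_contigs(),
                        pd.DataFrame([contig_row("c7", "Multi")])], ignore_index=True)
        table, report = gp.assign_clonotypes(df)
        assert report["n_rejected_chain_rows"] == 1
        assert "c7" not in table.index

    def test_airr_dialect_accepted(self):
        df = toy_contigs().rename(columns={
            "barcode": "cell_id", "chain": "locus", "v_gene": "v_call",
            "j_gene": "j_call", "cdr3": "junction_aa",
        }).drop(columns="high_confidence")
        table, report = gp.assign_clonotypes(df)
        assert report["n_retained"] == 4

    def test_clone_scope_sample_counts_within_sample(self):
        df = toy_contigs()
        meta = pd.DataFrame({"sample": ["s1", "s2", "s1", "s1"],
                             "group": ["nLung"] * 4},
                            index=pd.Index(["c1", "c2", "c3", "c4"], name="barcode"))
        g_table, _ = gp.assign_clonotypes(df, metadata=meta, clone_scope="global")
        s_table, _ = gp.assign_clonotypes(df, metadata=meta, clone_scope="sample")
        assert g_table.loc["c1", "clone_size"] == 2  # shared across samples
        assert s_table.loc["c1", "clone_size"] == 1  # c2 sits in another sample

    def test_invariant_to_row_order(self, small_cohort):
        _, adata, contigs, _ = small_cohort
        meta = adata.obs.rename_axis("barcode")
        t1, r1 = gp.assign_clonotypes(contigs, metadata=meta)
        shuffled = contigs.sample(frac=1.0, random_state=0).reset_index(drop=True)
        t2, r2 = gp.assign_clonotypes(shuffled, metadata=meta)
        pd.testing.assert_frame_equal(t1, t2)
        assert r1 == r2


class TestClonalFraction:
    @staticmethod
    def table_from_sizes(sizes_by_cluster):
        rows = []
        i = 0
        for cluster, sizes in sizes_by_cluster.items():
            for cid, s in enumerate(sizes):
                for _ in range(s):
                    rows.append((f"b{i}", f"{cluster}_cl{cid}", cluster, "nLung"))
                    i += 1
        t = pd.DataFrame(rows, columns=["barcode", "clonotype_id", "cluster", "group"])
        t = t.set_index("barcode")
        t["clone_size"] = t.groupby("clonotype_id")["clonotype_id"].transform("size")
        t["clonal"] = t["clone_size"] >= 2
        return t

    def test_all_singletons_fraction_zero(self):
        t = self.table_from_sizes({"A": [1] * 8})
        cf = gp.clonal_fraction(t, by="cluster")
        assert cf["fraction"].iloc[0] == 0.0

    def test_single_shared_clonotype_fraction_one(self):
        t = self.table_from_sizes({"A": [9]})
        cf = gp.clonal_fraction(t, by="cluster")
        assert cf["fraction"].iloc[0] == 1.0

    def test_expanded_cluster_beats_singleton_cluster(self, small_cohort):
        _, adata, contigs, gt = small_cohort
        table, _ = gp.assign_clonotypes(contigs, metadata=adata.obs.rename_axis("barcode"))
        cf = gp.clonal_fraction(table, by="cluster").set_index("cluster")
        assert cf.loc["T_cytotoxic", "fraction"] > cf.loc["T_naive", "fraction"]


class TestOccupancy:
    def test_five_clonotypes_fall_in_first_bin(self):
        t = TestClonalFraction.table_from_sizes({"A": [3, 2, 1, 1, 1]})
        occ = gp.clone_space_occupancy(t, by="cluster")
        assert occ.loc["A", "1-10"] == 1.0
        assert occ.loc["A"].sum() == pytest.approx(1.0)

    def test_hand_built_130_clonotypes(self):
        # top 10 clones of size 10 (100 cells) + 120 singletons = 220 cells
        t = TestClonalFraction.table_from_sizes({"A": [10] * 10 + [1] * 120})
        occ = gp.clone_space_occupancy(t, by="cluster")
        # ranks 1-10: the expanded clones; ranks 11-100: 90 singletons;
        # ranks 101-130: the remaining 30 singletons
        assert occ.loc["A", "1-10"] == pytest.approx(100 / 220)
        assert occ.loc["A", "11-100"] == pytest.approx(90 / 220)
        assert occ.loc["A", "101-1000"] == pytest.approx(30 / 220)

    def test_rows_sum_to_one_on_simulation(self, small_cohort):
        _, adata, contigs, _ = small_cohort
        table, _ = gp.assign_clonotypes(contigs, metadata=adata.obs.rename_axis("barcode"))
        occ = gp.clone_space_occupancy(table)
        assert np.allclose(occ.sum(axis=1), 1.0, atol=1e-9)

    def test_invariant_to_input_order(self):
        t = TestClonalFraction.table_from_sizes({"A": [4, 3, 1, 1]})
        t2 = t.sample(frac=1.0, random_state=1)
        pd.testing.assert_frame_equal(
            gp.clone_space_occupancy(t, by="cluster"),
            gp.clone_space_occupancy(t2, by="cluster"),
        )


class TestOverlap:
    @staticmethod
    def table_from_sets(sets):
        rows = []
        i = 0
        for cluster, ids in sets.items():
            for cid in ids:
                rows.append((f"b{i}", cid, cluster, "nLung"))
                i += 1
        t = pd.DataFrame(rows, columns=["barcode", "clonotype_id", "cluster", "group"])
        return t.set_index("barcode")

    def test_hand_set_arithmetic(self):
        t = self.table_from_sets({"A": ["c1", "c2", "c3", "c4"], "B": ["c3", "c4", "c5"]})
        pct, shared = gp.clonotype_overlap(t)
        assert pct.loc["A", "B"] == pytest.approx(100 * 2 / 3)
        assert shared.loc["A", "B"] == 2
        assert pct.loc["A", "A"] == 100.0

    def test_disjoint_and_subset(self):
        t = self.table_from_sets({"A": ["c1", "c2"], "B": ["c3"]})
        pct, _ = gp.clonotype_overlap(t)
        assert pct.loc["A", "B"] == 0.0
        t2 = self.table_from_sets({"A": ["c1", "c2", "c3"], "B": ["c1", "c2"]})
        pct2, _ = gp.clonotype_overlap(t2)
        assert pct2.loc["A", "B"] == 100.0  # subset under the min convention

    def test_overlap_coefficient_dominates_jaccard(self, small_cohort):
        _, adata, contigs, _ = small_cohort
        table, _ = gp.assign_clonotypes(contigs, metadata=adata.obs.rename_axis("barcode"))
        table = table.assign(cluster=np.where(np.arange(len(table)) % 2, "A", "B"))
        m, _ = gp.clonotype_overlap(table, mode="min")
        j, _ = gp.clonotype_overlap(table, mode="jaccard")
        assert (m.to_numpy() >= j.to_numpy() - 1e-12).all()
        assert np.allclose(m, m.T) and np.allclose(j, j.T)


class TestUsageAndSizes:
    def test_single_clonotype_single_entry(self):
        t = pd.DataFrame(
            {"clonotype_id": ["c1"] * 3, "group": "nLung",
             "tra_v": "TRAV1", "tra_j": "TRAJ1", "trb_v": "TRBV1", "trb_j": "TRBJ1-1"},
            index=pd.Index(["b0", "b1", "b2"], name="barcode"),
        )
        vj = gp.vj_usage(t, chain="TRB")
        assert len(vj) == 1 and vj["frequency"].iloc[0] == 1.0

    def test_frequencies_sum_to_one_per_group(self, small_cohort):
        _, adata, contigs, _ = small_cohort
        table, _ = gp.assign_clonotypes(contigs, metadata=adata.obs.rename_axis("barcode"))
        for chain in ("TRA", "TRB"):
            vj = gp.vj_usage(table, chain=chain)
            sums = vj.groupby("group")["frequency"].sum()
            assert np.allclose(sums, 1.0, atol=1e-9)

    def test_clone_size_distribution_conserves_cells(self, small_cohort):
        _, adata, contigs, _ = small_cohort
        table, _ = gp.assign_clonotypes(contigs, metadata=adata.obs.rename_axis("barcode"))
        dist = gp.clone_size_distribution(table)
        assert (dist["clone_size"] * dist["n_clonotypes"]).sum() == len(table)

    def test_all_singletons_single_row(self):
        t = TestClonalFraction.table_from_sizes({"A": [1] * 7})
        dist = gp.clone_size_distribution(t, by="cluster")
        assert len(dist) == 1
        assert dist["clone_size"].iloc[0] == 1 and dist["n_clonotypes"].iloc[0] == 7
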