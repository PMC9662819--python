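"""Contact maps, LRI clustering, and the structure-derived feature columns."""

import numpy as np
import pandas as pd
import pytest

import allospot as a
from allospot.structure import IMPORTED_FEATURES


def bare_dimer(ca, monomer_length=None, atoms=None):
    """A Dimer built directly from coordinates (no PDB file behind it)."""
    ca = np.asarray(ca, dtype=float)
    n = len(ca)
    if atoms is None:
        atoms = [ca[i:i + 1] for i in range(n)]
    L = monomer_length if monomer_length is not None else n
    return a.Dimer(
        ca=ca, atoms=atoms, b_factor=np.zeros(n),
        chain=np.array(["A" if i < L else "B" for i in range(n)]),
        resseq=np.arange(1, n + 1), sequence="A" * L, monomer_length=L,
        het_coords={},
    )


class TestContactMap:
    def test_collinear_chain_contacts(self):
        d = bare_dimer([[0, 0, 0], [5, 0, 0], [10, 0, 0]])
        cm = a.contact_map(d, cutoff=8.0)
        assert {(i, j) for i, j in zip(cm.pairs["i"], cm.pairs["j"])} == {(1, 2), (2, 3)}

    def test_single_residue_empty_map(self):
        cm = a.contact_map(bare_dimer([[0, 0, 0]]))
        assert cm.pairs.empty

    def test_matches_brute_force_all_pairs(self, toy_structure):
        _, dimer = toy_structure
        cm = a.contact_map(dimer, cutoff=8.0)
        got = {(i, j) for i, j in zip(cm.pairs["i"], cm.pairs["j"])}
        expect = set()
        for i in range(dimer.n_residues):
            for j in range(i + 1, dimer.n_residues):
                if np.linalg.norm(dimer.ca[i] - dimer.ca[j]) <= 8.0:
                    expect.add((i + 1, j + 1))
        assert got == expect

    def test_chain_swap_is_a_renumbering_permutation(self, toy_structure):
        _, dimer = toy_structure
        L, n = dimer.monomer_length, dimer.n_residues
        swapped = bare_dimer(np.vstack([dimer.ca[L:], dimer.ca[:L]]),
                             monomer_length=L)
        orig = a.contact_map(dimer, 8.0)
        swap = a.contact_map(swapped, 8.0)

        def perm(i):
            return i - L if i > L else i + L
        mapped = {tuple(sorted((perm(i), perm(j))))
                  for i, j in zip(swap.pairs["i"], swap.pairs["j"])}
        assert mapped == {(i, j) for i, j in zip(orig.pairs["i"], orig.pairs["j"])}

    def test_missing_ca_is_reported(self, tmp_path):
        pdb = tmp_path / "noca.pdb"
        pdb.write_text(
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00 10.00"
            "           C\n"
            "ATOM      2  CB  ALA A   2       3.800   0.000   0.000  1.00 10.00"
            "           C\n"
            "TER\n"
            "ATOM      3  CA  ALA B   1       0.000   9.000   0.000  1.00 10.00"
            "           C\nEND\n")
        with pytest.raises(ValueError, match="no CA"):
            a.load_dimer(pdb)


class TestLri:
    def test_sequence_separation_boundary(self):
        cm = a.ContactMap(
            pairs=pd.DataFrame({"i": [5, 5, 7], "j": [14, 15, 8],
                                "distance": [4.0, 4.0, 3.8]}),
            n_residues=20, monomer_length=10, chain=np.array(["A"] * 20),
            cutoff=8.0)
        lri = a.extract_lri(cm, min_sep=10)
        assert lri == {(5, 15)}

    def test_lri_equals_brute_force_filter(self, toy_structure):
        _, dimer = toy_structure
        cm = a.contact_map(dimer, 8.0)
        lri = a.extract_lri(cm, 10)
        expect = set()
        for i in range(dimer.n_residues):
            for j in range(i + 1, dimer.n_residues):
                if (j - i >= 10
                        and np.linalg.norm(dimer.ca[i] - dimer.ca[j]) <= 8.0):
                    expect.add((i + 1, j + 1))
        assert lri == expect
        got_pairs = {(i, j) for i, j in zip(cm.pairs["i"], cm.pairs["j"])}
        assert lri <= got_pairs


class TestClusterLri:
    @staticmethod
    def two_blobs(rng):
        blob1 = {(int(10 + rng.integers(0, 4)), int(40 + rng.integers(0, 4)))
                 for _ in range(30)}
        blob2 = {(int(70 + rng.integers(0, 4)), int(110 + rng.integers(0, 4)))
                 for _ in range(30)}
        return blob1 | blob2, blob1, blob2

    def test_two_blobs_chosen_k_2_and_pure_clusters(self, rng):
        lri, blob1, blob2 = self.two_blobs(rng)
        assignments, k, _ = a.cluster_lri(lri, k_range=range(1, 6), seed=0)
        assert k == 2
        lab1 = {assignments[p] for p in blob1}
        lab2 = {assignments[p] for p in blob2}
        assert len(lab1) == len(lab2) == 1 and lab1 != lab2

    def test_wcss_k1_equals_total_variance(self, rng):
        lri, _, _ = self.two_blobs(rng)
        _, _, elbow = a.cluster_lri(lri, k_range=[1], seed=0)
        X = np.asarray(sorted(lri), dtype=float)
        total_ss = ((X - X.mean(0)) ** 2).sum()
        assert elbow["wcss"].iloc[0] == pytest.approx(total_ss)

    def test_wcss_non_increasing_in_k(self, rng):
        lri, _, _ = self.two_blobs(rng)
        _, _, elbow = a.cluster_lri(lri, k_range=range(1, 7), seed=1)
        assert (np.diff(elbow["wcss"]) <= 1e-9).all()

    def test_fixed_seed_reproducible(self, rng):
        lri, _, _ = self.two_blobs(rng)
        a1, k1, _ = a.cluster_lri(lri, k_range=range(1, 6), seed=3)
        a2, k2, _ = a.cluster_lri(lri, k_range=range(1, 6), seed=3)
        assert a1 == a2 and k1 == k2

    def test_k_exceeding_pairs_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            a.cluster_lri({(1, 20), (2, 30)}, k_range=[3], seed=0)


class TestRankClusters:
    def test_hand_counted_fraction(self):
        # cluster 0 covers unique residues 1..10, five of which are hotspots
        assignments = {(i, i + 5): 0 for i in (1, 2, 3, 4, 5)}
        ranking = a.rank_clusters(assignments, {1, 2, 3, 4, 5}, monomer_length=50)
        assert ranking["pct_unique_hotspots"].iloc[0] == pytest.approx(50.0)

    def test_no_hotspot_cluster_ranked_last(self):
        assignments = {(1, 11): 0, (2, 12): 0, (30, 40): 1}
        ranking = a.rank_clusters(assignments, {1, 11}, monomer_length=50)
        assert ranking.loc[ranking["cluster"] == 1, "rank"].iloc[0] == 2
        assert ranking.loc[ranking["cluster"] == 1, "pct_unique_hotspots"].iloc[0] == 0

    def test_tie_broken_by_smaller_cluster_id(self):
        assignments = {(1, 11): 1, (2, 12): 0}
        ranking = a.rank_clusters(assignments, {1, 2}, monomer_length=50)
        assert list(ranking["cluster"]) == [0, 1]
        assert list(ranking["rank"]) == [1, 2]

    def test_dimer_copies_collapse_to_monomer_positions(self):
        # pair (3, 53) in a 50-residue monomer maps to positions {3, 3} = {3}
        assignments = {(3, 53): 0}
        ranking = a.rank_clusters(assignments, {3}, monomer_length=50)
        assert ranking["n_unique_residues"].iloc[0] == 1
        assert ranking["pct_unique_hotspots"].iloc[0] == pytest.approx(100.0)


class TestPhysicochemical:
    def test_lookup_matches_bundled_table(self):
        table = a.load_aa_properties()
        feats = a.physicochemical_features("ACDW")
        assert feats.loc[1, "molecular_weight"] == table.loc["A", "molecular_weight"]
        assert feats.loc[4, "polarizability"] == table.loc["W", "polarizability"]

    def test_homopolymer_gives_constant_columns(self):
        feats = a.physicochemical_features("GGGGG")
        assert (feats.nunique() == 1).all()

    def test_molecular_weight_distinguishes_all_but_isomers(self):
        # Leu and Ile are structural isomers with identical mass, so the
        # 20 letters map to 19 distinct molecular weights
        feats = a.physicochemical_features("ACDEFGHIKLMNPQRSTVWY")
        assert feats["molecular_weight"].nunique() == 19

    def test_non_canonical_letter_reports_position(self):
        with pytest.raises(ValueError, match="position 3"):
            a.physicochemical_features("ACXD")


class TestLocalFeatures:
    def test_atomic_density_distance_dependence(self):
        # density counts atoms of other residues within 5 A
        assert list(a.structure.atomic_density(bare_dimer([[0, 0, 0], [4, 0, 0]]))) == [1, 1]
        assert list(a.structure.atomic_density(bare_dimer([[0, 0, 0], [6, 0, 0]]))) == [0, 0]

    def test_isolated_residue_zero_density(self):
        assert list(a.structure.atomic_density(bare_dimer([[0, 0, 0]]))) == [0]

    def test_glycine_sasa_matches_monte_carlo_oracle(self, rng):
        from Bio.PDB.SASA import ATOMIC_RADII
        dimer, coords, elements = _glycine_dimer()
        sasa = a.local_features(dimer)["sasa"].iloc[0]
        oracle = _mc_sasa(coords, [ATOMIC_RADII[e] for e in elements], 1.4, rng)
        assert sasa == pytest.approx(oracle, rel=0.05)

    def test_b_factor_read_from_structure(self, toy_structure):
        synth, dimer = toy_structure
        feats = a.local_features(dimer)
        np.testing.assert_allclose(feats["b_factor"],
                                   np.round(synth.b_factor, 2), atol=5e-3)


def _glycine_dimer():
    from Bio.PDB.StructureBuilder import StructureBuilder

    names = ["N", "CA", "C", "O"]
    elements = ["N", "C", "C", "O"]
    coords = np.array([[0.0, 0.0, 0.0], [1.458, 0.0, 0.0],
                       [2.004, 1.423, 0.0], [1.251, 2.390, 0.0]])
    sb = StructureBuilder()
    sb.init_structure("gly")
    sb.init_model(0)
    sb.init_chain("A")
    sb.init_seg("    ")
    sb.init_residue("GLY", " ", 1, " ")
    for name, el, xyz in zip(names, elements, coords):
        sb.init_atom(name, xyz, 0.0, 1.0, " ", f" {name:<3s}", element=el)
    structure = sb.get_structure()
    dimer = a.Dimer(
        ca=coords[1:2], atoms=[coords], b_factor=np.zeros(1),
        chain=np.array(["A"]), resseq=np.array([1]), sequence="G",
        monomer_length=1, het_coords={}, bio_structure=structure,
    )
    return dimer, coords, elements


def _mc_sasa(coords, radii, probe, rng, n_points=4000):
    """Monte-Carlo sphere-surface integration of solvent accessibility."""
    total = 0.0
    for i, (c, r) in enumerate(zip(coords, radii)):
        R = r + probe
        v = rng.normal(size=(n_points, 3))
        pts = c + R * v / np.linalg.norm(v, axis=1, keepdims=True)
        buried = np.zeros(n_points, dtype=bool)
        for j, (cj, rj) in enumerate(zip(coords, radii)):
            if j == i:
                continue
            buried |= np.linalg.norm(pts - cj, axis=1) < rj + probe
        total += 4 * np.pi * R * R * (1 - buried.mean())
    return total


class TestGnm:
    def test_two_node_closed_form(self):
        C = a.gnm_correlation(np.array([[0.0, 0, 0], [3.0, 0, 0]]), cutoff=7.3)
        np.testing.assert_allclose(C, [[1, -1], [-1, 1]], atol=1e-10)

    def test_matches_dense_pseudoinverse_oracle(self, toy_structure):
        _, dimer = toy_structure
        ca = dimer.ca[:20]
        C = a.gnm_correlation(ca, cutoff=7.3)
        gamma = np.zeros((20, 20))
        for i in range(20):
            for j in range(20):
                if i != j and np.linalg.norm(ca[i] - ca[j]) <= 7.3:
                    gamma[i, j] = -1.0
        np.fill_diagonal(gamma, -gamma.sum(1))
        cov = np.linalg.pinv(gamma)
        d = np.sqrt(np.diag(cov))
        np.testing.assert_allclose(C, cov / np.outer(d, d), atol=1e-8)

    def test_symmetric_unit_diagonal_bounded(self, toy_structure):
        _, dimer = toy_structure
        C = a.gnm_correlation(dimer.ca, cutoff=7.3)
        np.testing.assert_allclose(C, C.T, atol=1e-10)
        np.testing.assert_allclose(np.diag(C), 1.0, atol=1e-10)
        assert np.abs(C).max() <= 1.0 + 1e-9

    def test_disconnected_network_advises_larger_cutoff(self):
        ca = np.array([[0.0, 0, 0], [3, 0, 0], [50, 0, 0], [53, 0, 0]])
        with pytest.raises(ValueError, match="cutoff"):
            a.gnm_correlation(ca, cutoff=7.3)

    def test_enm_feature_columns(self, toy_structure):
        synth, dimer = toy_structure
        feats = a.enm_features(dimer, synth.dna_sites, synth.ligand_sites)
        assert list(feats.columns) == ["corr_dna", "corr_ligand", "max_corr"]
        assert ((feats >= 0) & (feats <= 1)).all().all()
        with pytest.raises(ValueError, match="site"):
            a.enm_features(dimer, np.empty((0, 3)), synth.ligand_sites)


class TestCentrality:
    def test_path_graph_closeness_by_hand(self):
        # 5 residues in a line, only consecutive pairs within 5 A:
        # ends sum of distances 1+2+3+4=10 -> 4/10; middle 2+1+1+2 -> 4/6
        d = bare_dimer([[i * 4.0, 0, 0] for i in range(5)])
        import networkx as nx
        G = a.structure.residue_contact_graph(d, cutoff=5.0)
        clo = nx.closeness_centrality(G)
        assert clo[1] == pytest.approx(4 / 10)
        assert clo[3] == pytest.approx(4 / 6)

    def test_closeness_matches_floyd_warshall_oracle(self):
        from scipy.sparse.csgraph import shortest_path
        import networkx as nx
        synth = a.generate_structure(25, seed=4)
        d = bare_dimer(synth.ca[0])  # one chain: a connected <= 50-node graph
        G = a.structure.residue_contact_graph(d, cutoff=5.0)
        n = d.n_residues
        assert n <= 50
        adj = np.zeros((n, n))
        for u, v in G.edges:
            adj[u - 1, v - 1] = adj[v - 1, u - 1] = 1
        dist = shortest_path(adj, method="FW", unweighted=True)
        assert np.isfinite(dist).all()  # connected
        clo = nx.closeness_centrality(G)
        for i in range(n):
            assert clo[i + 1] == pytest.approx((n - 1) / dist[i].sum())

    def test_peak_residue_distance_to_itself_zero(self, toy_structure):
        synth, dimer = toy_structure
        feats = a.centrality_features(dimer)
        peaks = feats.attrs["peak_residues"]
        for k, pk in enumerate(peaks, start=1):
            if pk <= dimer.monomer_length:
                assert feats.loc[pk, f"dist_peak{k}"] == pytest.approx(0.0)

    def test_too_few_peaks_suggests_manual_list(self):
        d = bare_dimer([[i * 4.0, 0, 0] for i in range(6)])
        with pytest.raises(ValueError, match="manually"):
            a.centrality_features(d)

    def test_manual_peak_override(self, toy_structure):
        _, dimer = toy_structure
        feats = a.centrality_features(dimer, peak_residues=[3, 10, 20, 40])
        assert feats.attrs["peak_residues"] == [3, 10, 20, 40]
        assert feats.loc[3, "dist_peak1"] == pytest.approx(0.0)


class TestGeometry:
    def test_coincident_ligand_distance_zero(self):
        d = bare_dimer([[0, 0, 0], [4, 0, 0]])
        feats = a.geometry_features(d, dna_sites=[[100, 0, 0]],
                                    ligand_sites=[[0, 0, 0]])
        assert feats.loc[1, "dist_ligand"] == pytest.approx(0.0)
        assert feats.loc[1, "dist_dna"] == pytest.approx(100.0)

    def test_propagation_with_only_sequential_neighbors(self):
        d = bare_dimer([[i * 4.0, 0, 0] for i in range(5)])
        feats = a.geometry_features(d, [[0, 50, 0]], [[0, 50, 0]])
        assert feats.loc[3, "sequence_propagation"] == 1

    def test_propagation_bridges_100_positions(self):
        ca = [[i * 100.0, 0, 0] for i in range(100)] + [[4.9, 0, 0]]
        d = bare_dimer(ca)
        feats = a.geometry_features(d, [[0, 50, 0]], [[0, 50, 0]])
        assert feats.loc[1, "sequence_propagation"] == 100

    def test_empty_sites_rejected(self):
        d = bare_dimer([[0, 0, 0]])
        with pytest.raises(ValueError, match="site"):
            a.geometry_features(d, np.empty((0, 3)), [[1, 1, 1]])


@pytest.fixture(scope="module")
def computed(toy_structure):
    synth, dimer = toy_structure
    return a.compute_structure_features(dimer, synth.dna_sites,
                                        synth.ligand_sites)


class TestAssembly:

    def test_valid_assembly_with_zero_imports(self, computed):
        imported = pd.DataFrame(0.0, index=computed.index,
                                columns=sorted(IMPORTED_FEATURES))
        m = a.assemble_feature_matrix(computed, imported, {5, 6, 7})
        assert list(m.columns) == a.FEATURE_NAMES + ["label"]
        assert m["label"].sum() == 3
        prov = m.attrs["provenance"]
        assert all(prov[f] == "imported" for f in IMPORTED_FEATURES)
        assert prov["sasa"] == "computed"

    def test_missing_residue_in_import_is_named(self, computed):
        imported = pd.DataFrame(0.0, index=computed.index,
                                columns=sorted(IMPORTED_FEATURES)).drop(index=5)
        with pytest.raises(ValueError, match="5"):
            a.assemble_feature_matrix(computed, imported, set())

    def test_unknown_and_missing_features_listed(self, computed):
        imported = pd.DataFrame(0.0, index=computed.index, columns=["bogus"])
        with pytest.raises(ValueError) as err:
            a.assemble_feature_matrix(computed, imported, set())
        assert "bogus" in str(err.value) and "unresolved" in str(err.value)

    def test_tsv_round_trip(self, computed, tmp_path):
        imported = pd.DataFrame(0.0, index=computed.index,
                                columns=sorted(IMPORTED_FEATURES))
        m = a.assemble_feature_matrix(computed, imported, {2, 4})
        path = tmp_path / "features.tsv"
        a.structure.write_feature_matrix(m, path)
        back = a.structure.read_feature_matrix(path)
        pd.testing.assert_frame_equal(back, m)
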