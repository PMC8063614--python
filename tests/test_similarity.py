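"""Similarity construction: GIP kernels, ontology semantics, table loading."""

import numpy as np
import pandas as pd
import pytest

from pmdfi import (
    AssociationMatrix,
    DiseaseDAG,
    GIPParams,
    dag_contribution,
    gip_kernel,
    load_similarity_table,
    semantic_similarity,
    semantic_value,
)


class TestGIPKernel:
    def test_identity_adjacency_offdiagonal(self, identity_association):
        # two orthogonal unit profiles: gamma = 1/((1+1)/2) = 1, distance^2 = 2
        for axis in ("miRNA", "disease"):
            K = gip_kernel(identity_association, axis).to_numpy()
            assert K[0, 1] == pytest.approx(np.exp(-2), abs=1e-12)
            assert K[1, 0] == pytest.approx(np.exp(-2), abs=1e-12)
            np.testing.assert_allclose(np.diag(K), 1.0)

    def test_identical_profiles_score_one(self):
        A = AssociationMatrix(
            pd.DataFrame([[1, 0], [1, 0], [0, 1]], index=list("abc"), columns=["d1", "d2"])
        )
        K = gip_kernel(A, "miRNA").to_numpy()
        assert K[0, 1] == pytest.approx(1.0)

    def test_matches_scalar_recomputation(self):
        # independent elementwise evaluation of the kernel definition
        rng = np.random.default_rng(0)
        A = AssociationMatrix(
            pd.DataFrame(
                rng.integers(0, 2, size=(6, 5)),
                index=[f"m{i}" for i in range(6)],
                columns=[f"d{j}" for j in range(5)],
            )
        )
        lam = 1.7
        K = gip_kernel(A, "miRNA", GIPParams(lambda_prime=lam)).to_numpy()
        P = A.to_numpy()
        gamma = lam / np.mean([np.dot(p, p) for p in P])
        for i in range(6):
            for j in range(6):
                expected = 1.0 if i == j else np.exp(-gamma * np.sum((P[i] - P[j]) ** 2))
                assert K[i, j] == pytest.approx(expected, abs=1e-12)

    def test_bandwidth_normalisation_identity(self):
        # gamma * mean squared profile norm == lambda' exactly, read back off the kernel
        rng = np.random.default_rng(3)
        P = rng.integers(0, 2, size=(8, 6))
        P[0] = 1  # guarantee a nonzero profile
        A = AssociationMatrix(
            pd.DataFrame(P, index=[f"m{i}" for i in range(8)], columns=[f"d{j}" for j in range(6)])
        )
        lam = 2.5
        K = gip_kernel(A, "miRNA", GIPParams(lambda_prime=lam)).to_numpy()
        mean_sq = np.mean((P**2).sum(axis=1))
        # recover gamma from any off-diagonal pair with distinct profiles
        i, j = 0, 1
        d2 = np.sum((P[i] - P[j]) ** 2.0)
        gamma = -np.log(K[i, j]) / d2
        assert gamma * mean_sq == pytest.approx(lam, rel=1e-9)

    def test_invariant_to_nonaxis_permutation(self):
        rng = np.random.default_rng(4)
        P = rng.integers(0, 2, size=(7, 9))
        P[:, 0] = 1
        ids_m = [f"m{i}" for i in range(7)]
        ids_d = [f"d{j}" for j in range(9)]
        A1 = AssociationMatrix(pd.DataFrame(P, index=ids_m, columns=ids_d))
        perm = rng.permutation(9)
        A2 = AssociationMatrix(
            pd.DataFrame(P[:, perm], index=ids_m, columns=[ids_d[p] for p in perm])
        )
        np.testing.assert_allclose(
            gip_kernel(A1, "miRNA").to_numpy(), gip_kernel(A2, "miRNA").to_numpy()
        )

    def test_all_zero_adjacency_rejected(self):
        A = AssociationMatrix(
            pd.DataFrame(np.zeros((3, 3), dtype=int), index=list("abc"), columns=list("xyz"))
        )
        with pytest.raises(ValueError, match="miRNA"):
            gip_kernel(A, "miRNA")

    def test_unknown_axis_rejected(self, identity_association):
        with pytest.raises(ValueError, match="axis"):
            gip_kernel(identity_association, "protein")

    def test_lambda_prime_must_be_positive(self):
        with pytest.raises(ValueError):
            GIPParams(lambda_prime=0.0)


class TestDagSemantics:
    def test_chain_contributions(self, chain_dag):
        assert dag_contribution(chain_dag, "dD") == {"D": 1.0, "P": 0.5, "G": 0.25}

    def test_root_term_contribution(self, chain_dag):
        assert dag_contribution(chain_dag, "dG") == {"G": 1.0}

    def test_diamond_takes_max_not_sum(self):
        dag = DiseaseDAG(
            nodes={"G", "P1", "P2", "D"},
            parent_edges={"D": ["P1", "P2"], "P1": ["G"], "P2": ["G"]},
            annotation={"dD": "D"},
        )
        contrib = dag_contribution(dag, "dD")
        assert contrib["G"] == pytest.approx(0.25)
        assert semantic_value(dag, "dD") == pytest.approx(2.25)

    def test_chain_semantic_values(self, chain_dag):
        assert semantic_value(chain_dag, "dD") == pytest.approx(1.75)
        assert semantic_value(chain_dag, "dP") == pytest.approx(1.5)
        assert semantic_value(chain_dag, "dG") == pytest.approx(1.0)

    def test_chain_contribution_halves_per_step(self):
        # 6-node chain: contributions are exactly 0.5**g along the path
        nodes = [f"n{i}" for i in range(6)]
        edges = {nodes[i]: [nodes[i + 1]] for i in range(5)}
        dag = DiseaseDAG(nodes=set(nodes), parent_edges=edges, annotation={"d": nodes[0]})
        contrib = dag_contribution(dag, "d")
        for g, n in enumerate(nodes):
            assert contrib[n] == pytest.approx(0.5**g)

    def test_chain_pairwise_similarity(self, chain_dag):
        SS = semantic_similarity(chain_dag, ["dD", "dP", "dG"])
        assert SS.to_numpy()[0, 1] == pytest.approx(2.25 / 3.25)
        np.testing.assert_allclose(np.diag(SS.to_numpy()), 1.0)

    def test_disjoint_trees_score_zero(self):
        dag = DiseaseDAG(
            nodes={"a", "b"}, parent_edges={}, annotation={"d1": "a", "d2": "b"}
        )
        assert semantic_similarity(dag, ["d1", "d2"]).to_numpy()[0, 1] == 0.0

    def test_unannotated_disease_rejected(self, chain_dag):
        with pytest.raises(KeyError, match="ghost"):
            semantic_similarity(chain_dag, ["dD", "ghost"])

    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            DiseaseDAG(nodes={"a", "b"}, parent_edges={"a": ["b"], "b": ["a"]}, annotation={})

    def test_agrees_with_bruteforce_on_small_dags(self):
        """Exhaustive-oracle check on many random DAGs with <= 6 nodes."""

        def brute_ancestors(parents, node):
            out = {node}
            frontier = [node]
            while frontier:
                n = frontier.pop()
                for p in parents.get(n, []):
                    if p not in out:
                        out.add(p)
                        frontier.append(p)
            return out

        def brute_contrib(parents, term):
            T = brute_ancestors(parents, term)
            children = {}
            for c, ps in parents.items():
                for p in ps:
                    children.setdefault(p, []).append(c)

            def rec(d):
                if d == term:
                    return 1.0
                return 0.5 * max(rec(c) for c in children.get(d, []) if c in T)

            return {d: rec(d) for d in T}

        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(2, 7))
            nodes = [f"n{i}" for i in range(n)]
            # edges only from lower to higher index: acyclic by construction
            parents = {}
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.4:
                        parents.setdefault(nodes[i], []).append(nodes[j])
            k = int(rng.integers(2, n + 1))
            annotation = {f"d{t}": nodes[int(rng.integers(0, n))] for t in range(k)}
            dag = DiseaseDAG(nodes=set(nodes), parent_edges=parents, annotation=annotation)
            diseases = sorted(annotation)
            contribs = {d: brute_contrib(parents, next(iter(dag.annotation[d]))) for d in diseases}
            for d in diseases:
                assert dag_contribution(dag, d) == pytest.approx(contribs[d])
            SS = semantic_similarity(dag, diseases).to_numpy()
            dvs = {d: sum(contribs[d].values()) for d in diseases}
            for a, da in enumerate(diseases):
                for b, db in enumerate(diseases):
                    shared = contribs[da].keys() & contribs[db].keys()
                    expected = (
                        sum(contribs[da][t] + contribs[db][t] for t in shared)
                        / (dvs[da] + dvs[db])
                        if shared
                        else 0.0
                    )
                    if a == b:
                        expected = 1.0
                    assert SS[a, b] == pytest.approx(expected, abs=1e-12)


class TestLoadSimilarityTable:
    def _write(self, tmp_path, df, name="sim.tsv"):
        p = tmp_path / name
        df.to_csv(p, sep="\t")
        return p

    def test_identity_roundtrip(self, tmp_path):
        df = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("abc"))
        sim = load_similarity_table(self._write(tmp_path, df), kind="FS")
        np.testing.assert_allclose(sim.to_numpy(), np.eye(3))

    def test_realignment_to_expected_order(self, tmp_path):
        rng = np.random.default_rng(0)
        M = rng.random((4, 4))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 1.0)
        ids = list("abcd")
        df = pd.DataFrame(M, index=ids, columns=ids)
        perm = ["c", "a", "d", "b"]
        shuffled = df.loc[perm, perm]
        sim = load_similarity_table(self._write(tmp_path, shuffled), expected_ids=ids, kind="FS")
        np.testing.assert_allclose(sim.to_numpy(), M, atol=1e-12)

    def test_out_of_range_entry_named(self, tmp_path):
        df = pd.DataFrame(np.eye(2), index=["a", "b"], columns=["a", "b"])
        df.iloc[0, 1] = df.iloc[1, 0] = 1.2
        with pytest.raises(ValueError, match="outside"):
            load_similarity_table(self._write(tmp_path, df))

    def test_missing_expected_id_rejected(self, tmp_path):
        df = pd.DataFrame(np.eye(2), index=["a", "b"], columns=["a", "b"])
        with pytest.raises(KeyError, match="z"):
            load_similarity_table(self._write(tmp_path, df), expected_ids=["a", "z"])

    def test_asymmetry_rejected(self, tmp_path):
        df = pd.DataFrame([[1.0, 0.2], [0.4, 1.0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError, match="asymmetric"):
            load_similarity_table(self._write(tmp_path, df))
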