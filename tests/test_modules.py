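import itertools

import numpy as np
import pandas as pd
import pytest

from sfcomod.correlation import CorrelationMatrix, pearson_matrix
from sfcomod.io import ExpressionMatrix, SurvivalTable, ValidationError
from sfcomod.modules import (
    ClusterAssignment,
    _cluster_rows,
    cluster_correlation_rows,
    consensus_overlap,
    label_modules,
    stability_select_k,
)


def brute_force_complete_linkage(points: np.ndarray, k: int) -> set[frozenset]:
    """Exhaustive greedy complete-linkage: recompute all cluster-pair maxima
    at every step and merge the global minimum.  Independent oracle for small n."""
    clusters = [frozenset([i]) for i in range(len(points))]
    while len(clusters) > k:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = max(
                np.linalg.norm(points[i] - points[j])
                for i in clusters[a]
                for j in clusters[b]
            )
            if best is None or d < best[0]:
                best = (d, a, b)
        _, a, b = best
        merged = clusters[a] | clusters[b]
        clusters = [c for idx, c in enumerate(clusters) if idx not in (a, b)] + [merged]
    return {frozenset(c) for c in clusters}


def _as_partition(assignment: ClusterAssignment, ids) -> set[frozenset]:
    index = {g: i for i, g in enumerate(ids)}
    return {frozenset(index[g] for g in c) for c in assignment.clusters()}


class TestClusterRows:
    def test_one_dimensional_profile_oracle(self):
        points = np.array([[0.0], [1.0], [10.0], [11.0]])
        ids = ["a", "b", "c", "d"]
        assignment = _cluster_rows(points, ids, k=2)
        assert _as_partition(assignment, ids) == {frozenset({0, 1}), frozenset({2, 3})}
        assert _as_partition(assignment, ids) == brute_force_complete_linkage(points, 2)

    def test_matches_oracle_on_random_points(self, rng):
        for _ in range(5):
            points = rng.normal(size=(8, 3))
            ids = [f"g{i}" for i in range(8)]
            for k in (2, 3, 4):
                ours = _as_partition(_cluster_rows(points, ids, k), ids)
                assert ours == brute_force_complete_linkage(points, k)

    def test_identical_rows_always_together(self):
        points = np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0], [9.0, 9.0]])
        ids = list("abcd")
        for k in (2, 3):
            assignment = _cluster_rows(points, ids, k)
            assert assignment.labels["a"] == assignment.labels["b"]

    def test_permutation_invariance(self, rng):
        values = rng.normal(size=(12, 12))
        C_raw = np.corrcoef(values)
        ids = [f"g{i}" for i in range(12)]
        C = CorrelationMatrix(pd.DataFrame(C_raw, index=ids, columns=ids), symmetric=True)
        base = {frozenset(c) for c in cluster_correlation_rows(C, 3).clusters()}
        for _ in range(50):
            perm = rng.permutation(12)
            pids = [ids[i] for i in perm]
            Cp = CorrelationMatrix(
                pd.DataFrame(C_raw[np.ix_(perm, perm)], index=pids, columns=pids),
                symmetric=True,
            )
            shuffled = {frozenset(c) for c in cluster_correlation_rows(Cp, 3).clusters()}
            assert shuffled == base

    def test_k_out_of_range(self):
        points = np.zeros((3, 1))
        with pytest.raises(ValidationError, match="out of range"):
            _cluster_rows(points, list("abc"), k=3)


class TestStability:
    def _stable_matrix(self):
        # two tight, far-apart modules: clustering is identical under any
        # single-sample removal, so APN must be 0 for k=2
        rng = np.random.default_rng(0)
        n = 40
        a = rng.normal(0.0, 1.0, size=n)
        genes = {}
        for i in range(6):
            genes[f"p{i}"] = 10 * a + rng.normal(0, 0.1, n)
        for i in range(6):
            genes[f"m{i}"] = -10 * a + rng.normal(0, 0.1, n)
        return ExpressionMatrix(pd.DataFrame(genes).T)

    def test_perfectly_stable_clustering_has_zero_apn(self):
        X = self._stable_matrix()
        report, assigns = stability_select_k(
            X, X.gene_ids, k_min=2, k_max=3, n_remove=8, min_size=2, seed=0
        )
        assert report.apn[2] == pytest.approx(0.0)
        assert report.chosen_k == 2
        parts = {frozenset(c) for c in assigns[2].clusters()}
        assert parts == {
            frozenset(f"p{i}" for i in range(6)),
            frozenset(f"m{i}" for i in range(6)),
        }

    def test_min_size_guard_excludes_fragmenting_k(self):
        X = self._stable_matrix()
        report, _ = stability_select_k(
            X, X.gene_ids, k_min=2, k_max=4, n_remove=5, min_size=5, seed=0
        )
        # k=3,4 split one tight module into fragments below min_size
        assert 3 in report.excluded_k and 4 in report.excluded_k
        assert report.chosen_k == 2

    def test_too_few_samples_rejected(self):
        X = self._stable_matrix()
        with pytest.raises(ValidationError, match="n_remove"):
            stability_select_k(X, X.gene_ids, n_remove=45)


class TestConsensusOverlap:
    def _assignment(self, clusters: list[set[str]]) -> ClusterAssignment:
        labels = {g: i + 1 for i, c in enumerate(clusters) for g in c}
        return ClusterAssignment(labels, k=len(clusters))

    def test_identity(self):
        A = self._assignment([{"g1", "g2", "g3"}, {"g4", "g5", "g6"}])
        cons = consensus_overlap(A, A, min_size=2)
        assert sorted(map(sorted, cons.modules.values())) == [
            ["g1", "g2", "g3"],
            ["g4", "g5", "g6"],
        ]
        assert all(j == pytest.approx(1.0) for _, _, j in cons.provenance.values())

    def test_worked_example_with_exhaustive_assignment(self):
        A = self._assignment([{"g1", "g2", "g3", "g4", "g5"}, {"g6", "g7", "g8"}])
        B = self._assignment([{"g1", "g2", "g3", "g4", "g9"}, {"g6", "g7", "g10"}])
        cons = consensus_overlap(A, B, min_size=2)
        modules = sorted(map(sorted, cons.modules.values()))
        assert modules == [["g1", "g2", "g3", "g4"], ["g6", "g7"]]
        jaccards = sorted(j for _, _, j in cons.provenance.values())
        assert jaccards == [pytest.approx(1 / 2), pytest.approx(2 / 3)]

    def test_symmetric_up_to_naming(self):
        A = self._assignment([{"g1", "g2", "g3"}, {"g4", "g5"}])
        B = self._assignment([{"g1", "g2"}, {"g3", "g4", "g5"}])
        ab = consensus_overlap(A, B, min_size=1)
        ba = consensus_overlap(B, A, min_size=1)
        assert {frozenset(m) for m in ab.modules.values()} == {
            frozenset(m) for m in ba.modules.values()
        }

    def test_small_modules_discarded(self):
        A = self._assignment([{"g1", "g2", "g3", "g4", "g5"}, {"g6", "g7"}])
        B = self._assignment([{"g1", "g2", "g3", "g4", "g5"}, {"g8", "g9"}])
        cons = consensus_overlap(A, B, min_size=5)
        assert len(cons.modules) == 1

    def test_disjoint_universes_rejected(self):
        A = self._assignment([{"g1", "g2"}])
        B = self._assignment([{"h1", "h2"}])
        with pytest.raises(ValidationError, match="overlap"):
            consensus_overlap(A, B)


class TestLabelModules:
    def _cohort_with_modules(self, gamma: float, seed: int = 0, flip: bool = False):
        from sfcomod.modules import ConsensusModules
        from sfcomod.synthetic import SyntheticConfig, generate_cohort

        cfg = SyntheticConfig(
            n_samples=250,
            panel_size=40,
            n_suppressor=14,
            n_enhancer=10,
            n_background=0,
            n_null_background=0,
            n_matched_pairs=5,
            n_switch_genes=2,
            n_nonswitch_genes=2,
            gamma=-gamma if flip else gamma,
            seed=seed,
        )
        cohort = generate_cohort(cfg)
        cons = ConsensusModules(
            modules={
                "module_1": set(cohort.truth.module_genes("suppressor")),
                "module_2": set(cohort.truth.module_genes("enhancer")),
            },
            provenance={"module_1": (1, 1, 1.0), "module_2": (2, 2, 1.0)},
        )
        return cohort, cons

    def test_planted_enhancer_labeled_enhancer(self):
        cohort, cons = self._cohort_with_modules(gamma=0.5)
        labeled = label_modules(cons, cohort.expression, cohort.survival)
        assert labeled.roles.get("module_2") == "Enhancer"
        assert labeled.roles.get("module_1") == "Suppressor"

    def test_flipping_hazard_sign_flips_labels(self):
        cohort, cons = self._cohort_with_modules(gamma=0.5, flip=True)
        labeled = label_modules(cons, cohort.expression, cohort.survival)
        assert labeled.roles.get("module_1") == "Enhancer"
        assert labeled.roles.get("module_2") == "Suppressor"

    def test_null_hazard_withholds_labels(self):
        cohort, cons = self._cohort_with_modules(gamma=0.0, seed=3)
        labeled = label_modules(cons, cohort.expression, cohort.survival)
        assert labeled.roles == {}
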