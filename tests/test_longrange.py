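"""Kendall tau matrix across regions and complete-linkage dendrograms."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster

from chronotopo import longrange as lr
from oracles import brute_complete_linkage, brute_partition_at


def three_regime_medians(rng, n_subj=13):
    """Stream-level median table with three planted regimes: a correlated
    long-preferring pair, a correlated boundary-tuned pair, and a full-range
    pair, with cross-group anticorrelation (three latent directions at 120
    degrees in a 2-D subject trait space)."""
    f = rng.standard_normal((n_subj, 2))
    angles = [0.0, 2 * np.pi / 3, 4 * np.pi / 3]
    latents = [f @ np.array([np.cos(a), np.sin(a)]) for a in angles]
    eps = lambda: 0.3 * rng.standard_normal(n_subj)
    return pd.DataFrame(
        {
            "VV": 0.70 + 0.03 * (latents[0] + eps()),
            "LV": 0.68 + 0.03 * (latents[0] + eps()),
            "AI": 0.50 + 0.01 * (latents[1] + eps()),
            "IF": 0.50 + 0.01 * (latents[1] + eps()),
            "IPS": 0.50 + 0.10 * (latents[2] + eps()),
            "IP": 0.50 + 0.10 * (latents[2] + eps()),
        },
        index=[f"s{i}" for i in range(n_subj)],
    )


class TestCorrMatrix:
    def test_identical_regions_tau_one(self):
        med = pd.DataFrame({"a": [0.3, 0.5, 0.7, 0.4], "b": [0.3, 0.5, 0.7, 0.4]})
        m = lr.preference_corr_matrix(med)
        assert m.tau.loc["a", "b"] == pytest.approx(1.0)

    def test_rank_reversal_tau_minus_one(self):
        med = pd.DataFrame({"a": [0.3, 0.5, 0.7, 0.4], "b": [0.7, 0.5, 0.3, 0.6]})
        m = lr.preference_corr_matrix(med)
        assert m.tau.loc["a", "b"] == pytest.approx(-1.0)

    def test_two_block_structure_signs(self, rng):
        lat = rng.standard_normal(13)
        med = pd.DataFrame(
            {
                "a1": lat + 0.2 * rng.standard_normal(13),
                "a2": lat + 0.2 * rng.standard_normal(13),
                "b1": -lat + 0.2 * rng.standard_normal(13),
                "b2": -lat + 0.2 * rng.standard_normal(13),
            }
        )
        t = lr.preference_corr_matrix(med).tau
        assert t.loc["a1", "a2"] > 0 and t.loc["b1", "b2"] > 0
        assert t.loc["a1", "b1"] < 0 and t.loc["a2", "b2"] < 0

    def test_constant_region_emitted_missing(self):
        med = pd.DataFrame({"a": [0.3, 0.5, 0.7], "b": [0.5, 0.5, 0.5]})
        m = lr.preference_corr_matrix(med)
        assert np.isnan(m.tau.loc["a", "b"])
        assert m.tau.loc["b", "b"] == 1.0

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            lr.preference_corr_matrix(pd.DataFrame({"a": [1, 2], "b": [2, 1]}))


class TestCorrToDistance:
    def test_identical_rows_zero_distance(self):
        tau = pd.DataFrame(np.ones((2, 2)), index=["a", "b"], columns=["a", "b"])
        d = lr.corr_to_distance(lr.CorrMatrix(["a", "b"], tau))
        assert d.loc["a", "b"] == 0.0

    def test_identity_matrix_hand_value(self):
        tau = pd.DataFrame(np.eye(2), index=["a", "b"], columns=["a", "b"])
        tau.values[0, 0] = tau.values[1, 1] = 1.0
        d = lr.corr_to_distance(lr.CorrMatrix(["a", "b"], tau))
        assert d.loc["a", "b"] == pytest.approx(np.sqrt(2))

    def test_matches_brute_force_row_distances(self, rng):
        for _ in range(10):
            m = rng.uniform(-1, 1, (6, 6))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 1.0)
            tau = pd.DataFrame(m, index=list("abcdef"), columns=list("abcdef"))
            d = lr.corr_to_distance(lr.CorrMatrix(list("abcdef"), tau))
            for i in range(6):
                for j in range(6):
                    assert d.iloc[i, j] == pytest.approx(
                        np.linalg.norm(m[i] - m[j]), abs=1e-10
                    )

    def test_missing_entries_rejected(self):
        tau = pd.DataFrame([[1.0, np.nan], [np.nan, 1.0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError):
            lr.corr_to_distance(lr.CorrMatrix(["a", "b"], tau))


class TestHierarchicalCluster:
    def _dist(self, m, labels):
        return pd.DataFrame(m, index=labels, columns=labels)

    def test_forced_merge_order(self):
        d = self._dist(
            [[0, 1, 5], [1, 0, 5], [5, 5, 0]], ["A", "B", "C"]
        )
        dend = lr.hierarchical_cluster(d)
        assert dend.heights[0] == pytest.approx(1.0)
        assert dend.heights[1] == pytest.approx(5.0)
        assert dend.cut(2) == {"A": 1, "B": 1, "C": 2}

    def test_heights_non_decreasing(self, rng):
        for _ in range(10):
            x = rng.normal(size=(6, 3))
            m = np.linalg.norm(x[:, None] - x[None, :], axis=2)
            dend = lr.hierarchical_cluster(self._dist(m, list("abcdef")))
            assert np.all(np.diff(dend.heights) >= -1e-12)

    def test_matches_exhaustive_agglomeration_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(3, 7))
            x = rng.normal(size=(n, 3))
            m = np.linalg.norm(x[:, None] - x[None, :], axis=2)
            labels = list(range(n))
            dend = lr.hierarchical_cluster(self._dist(m, labels))
            history = brute_complete_linkage(m)
            assert np.allclose(sorted(dend.heights), sorted(h for *_, h in history), atol=1e-10)
            for k in range(2, n):
                scipy_part = fcluster(dend.merges, t=k, criterion="maxclust")
                scipy_sets = {
                    frozenset(np.flatnonzero(scipy_part == c)) for c in set(scipy_part)
                }
                assert scipy_sets == brute_partition_at(history, n, k)

    def test_label_permutation_equivariance(self, rng):
        x = rng.normal(size=(5, 3))
        m = np.linalg.norm(x[:, None] - x[None, :], axis=2)
        labels = list("abcde")
        base = lr.hierarchical_cluster(self._dist(m, labels)).cut(2)
        perm = rng.permutation(5)
        mp = m[np.ix_(perm, perm)]
        permuted = lr.hierarchical_cluster(
            self._dist(mp, [labels[i] for i in perm])
        ).cut(2)
        # same partition of label names, up to cluster-id relabeling
        def as_sets(assign):
            out = {}
            for lbl, c in assign.items():
                out.setdefault(c, set()).add(lbl)
            return {frozenset(v) for v in out.values()}
        assert as_sets(base) == as_sets(permuted)

    def test_newick_contains_all_leaves(self, rng):
        x = rng.normal(size=(4, 2))
        m = np.linalg.norm(x[:, None] - x[None, :], axis=2)
        dend = lr.hierarchical_cluster(self._dist(m, ["VV", "LV", "AI", "IF"]))
        nwk = dend.to_newick()
        assert nwk.endswith(";")
        for lbl in ("VV", "LV", "AI", "IF"):
            assert lbl in nwk


class TestThreeRegimeFixture:
    def test_planted_grouping_recovered_at_three_clusters(self):
        """Cutting the dendrogram at 3 clusters recovers the planted
        long / boundary / full-range stream pairs in >= 90% of 50 seeds."""
        target = {
            frozenset({"VV", "LV"}),
            frozenset({"AI", "IF"}),
            frozenset({"IPS", "IP"}),
        }
        hits = 0
        for s in range(50):
            med = three_regime_medians(np.random.default_rng(s))
            corr = lr.preference_corr_matrix(med)
            dend = lr.hierarchical_cluster(lr.corr_to_distance(corr))
            cut = dend.cut(3)
            groups = {}
            for lbl, c in cut.items():
                groups.setdefault(c, set()).add(lbl)
            hits += {frozenset(g) for g in groups.values()} == target
        assert hits >= 45
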