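"""Distance-matrix clustering, silhouette selection, position importance
and the two packing-mode classifiers."""

from __future__ import annotations

import json
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from fvpack.clustering import (
    DistanceMatrix,
    agglomerative_cluster,
    build_distance_matrix,
    classify_by_rule,
    diana_cluster,
    gini_importance,
    greedy_identity_cluster,
    nearest_centroid_classify,
    residue_frequencies,
    select_clustering,
    silhouette,
)
from fvpack.model import FvError, NumberedSequence, PositionId, extract_interface
from fvpack.synthetic import SyntheticSpec, make_mode_template, sample_structure

from _oracles import diana_terminal_partitions, naive_average_linkage_heights

pp = PositionId.parse


def _random_matrix(rng, n):
    x = rng.normal(size=(n, 3))
    d = np.linalg.norm(x[:, None, :] - x[None, :, :], axis=2)
    return DistanceMatrix([str(i) for i in range(n)], d)


def _two_block_matrix(sizes=(4, 4), inter=1.0):
    n = sum(sizes)
    d = np.full((n, n), inter)
    d[: sizes[0], : sizes[0]] = 0.0
    d[sizes[0]:, sizes[0]:] = 0.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix([str(i) for i in range(n)], d)


class TestDistanceMatrix:
    def test_validation(self):
        with pytest.raises(FvError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(FvError):
            DistanceMatrix(["a", "b"], np.array([[0.5, 1.0], [1.0, 0.0]]))

    def test_build_has_block_structure(self, small_structures, small_truth):
        dm = build_distance_matrix(small_structures)
        modes = small_truth.set_index("id").loc[dm.ids, "mode"].values
        same = dm.values[np.ix_(modes == "A", modes == "A")]
        cross = dm.values[np.ix_(modes == "A", modes == "B")]
        within = same[np.triu_indices_from(same, k=1)].mean()
        assert within < cross.mean()
        assert np.allclose(dm.values, dm.values.T)

    def test_duplicate_structures_have_zero_distance(self, small_structures):
        dm = build_distance_matrix([small_structures[0], small_structures[0]])
        assert dm.values[0, 1] == 0.0


class TestDiana:
    def test_perfect_two_blocks_recovered_first(self):
        dm = _two_block_matrix()
        res = diana_cluster(dm, k_range=[2])
        labels = res.labels_by_k[2]
        assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1
        assert labels[0] != labels[4]

    def test_all_zero_matrix_never_splits(self):
        dm = DistanceMatrix(["a", "b", "c"], np.zeros((3, 3)))
        res = diana_cluster(dm)
        assert res.labels_by_k == {}
        assert res.degenerate or res.chosen_k is None

    def test_first_split_is_terminal_under_any_move_order(self):
        """The greedy max-first split must be reachable and stable under the
        exhaustive move-order oracle; when the oracle's terminal partition
        is unique the two must coincide."""
        rng = np.random.default_rng(42)
        for _ in range(30):
            n = int(rng.integers(5, 9))
            dm = _random_matrix(rng, n)
            labels = diana_cluster(dm, k_range=[2]).labels_by_k[2]
            seed, terminals = diana_terminal_partitions(dm.values)
            split = frozenset(np.nonzero(labels == labels[seed])[0].tolist())
            assert split in terminals
            if len(terminals) == 1:
                assert split == next(iter(terminals))

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
    def test_matches_reference_r_implementation(self, tmp_path):
        """Full-hierarchy cross-check against cluster::diana: the multiset
        of division heights matches exactly, and the first split matches
        whenever the maximal separation is unique (ties make the flat cut
        representation ambiguous)."""
        rng = np.random.default_rng(7)
        mats = []
        for _ in range(12):
            n = int(rng.integers(5, 10))
            mats.append(_random_matrix(rng, n))
        (tmp_path / "mats.json").write_text(json.dumps([m.values.tolist() for m in mats]))
        script = tmp_path / "diana.R"
        script.write_text(
            f'''
            library(cluster); library(jsonlite)
            mats <- fromJSON("{tmp_path}/mats.json", simplifyMatrix=TRUE)
            out <- list()
            for (i in seq_along(mats)) {{
              di <- diana(as.dist(mats[[i]]), diss=TRUE)
              out[[i]] <- list(heights=di$height,
                               labels=as.integer(cutree(as.hclust(di), k=2)))
            }}
            write(toJSON(out, digits=12), "{tmp_path}/out.json")
            '''
        )
        proc = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True
        )
        if proc.returncode != 0 and "cluster" in proc.stderr:
            pytest.skip("R cluster package unavailable")
        assert proc.returncode == 0, proc.stderr
        ref = json.loads((tmp_path / "out.json").read_text())
        for dm, r in zip(mats, ref):
            res = diana_cluster(dm, k_range=[2])

            def heights(node, acc):
                if isinstance(node, tuple):
                    acc.append(node[2])
                    heights(node[0], acc)
                    heights(node[1], acc)
                return acc

            mine_h = np.sort(heights(res.tree, []))
            ref_h = np.sort(np.asarray(r["heights"], dtype=float))
            assert np.allclose(mine_h, ref_h, atol=1e-8)
            if np.sum(np.isclose(ref_h, ref_h[-1], atol=1e-9)) == 1:
                mine = res.labels_by_k[2]
                rl = np.asarray(r["labels"]) - 1
                assert np.array_equal(mine, rl) or np.array_equal(mine, 1 - rl)


class TestAgglomerative:
    def test_two_points_merge_at_their_distance(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0.0, 2.5], [2.5, 0.0]]))
        for method in ("average", "complete", "ward", "single"):
            res = agglomerative_cluster(dm, method, k_range=[2])
            assert res.tree[2] == pytest.approx(2.5)

    def test_single_linkage_follows_edge_weights_on_a_path(self):
        # path metric 0-1-2-3 with edge weights 1, 3, 2
        w = [1.0, 3.0, 2.0]
        d = np.zeros((4, 4))
        for i in range(4):
            for j in range(i + 1, 4):
                d[i, j] = d[j, i] = sum(w[i:j])
        dm = DistanceMatrix(list("abcd"), d)
        res = agglomerative_cluster(dm, "single")

        def heights(node, acc):
            if isinstance(node, tuple):
                acc.append(node[2])
                heights(node[0], acc)
                heights(node[1], acc)
            return acc

        assert sorted(heights(res.tree, [])) == sorted(w)

    def test_average_linkage_heights_match_naive_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            dm = _random_matrix(rng, 7)
            res = agglomerative_cluster(dm, "average")

            def heights(node, acc):
                if isinstance(node, tuple):
                    acc.append(node[2])
                    heights(node[0], acc)
                    heights(node[1], acc)
                return acc

            mine = np.sort(heights(res.tree, []))
            oracle = np.sort(naive_average_linkage_heights(dm.values))
            assert np.allclose(mine, oracle, atol=1e-10)

    def test_unknown_linkage_rejected(self):
        dm = _two_block_matrix()
        with pytest.raises(FvError, match="unknown linkage"):
            agglomerative_cluster(dm, "centroid")


class TestSilhouette:
    def test_perfect_separation_is_one(self):
        dm = _two_block_matrix()
        labels = np.array([0] * 4 + [1] * 4)
        assert silhouette(dm, labels) == 1.0

    def test_all_singletons_zero(self):
        dm = _random_matrix(np.random.default_rng(0), 5)
        assert silhouette(dm, np.arange(5)) == 0.0

    def test_matches_direct_formula_on_worked_matrix(self):
        d = np.array(
            [
                [0.0, 1.0, 4.0, 5.0],
                [1.0, 0.0, 6.0, 3.0],
                [4.0, 6.0, 0.0, 2.0],
                [5.0, 3.0, 2.0, 0.0],
            ]
        )
        dm = DistanceMatrix(list("abcd"), d)
        labels = np.array([0, 0, 1, 1])
        expected = []
        for i in range(4):
            mates = [j for j in range(4) if labels[j] == labels[i] and j != i]
            others = [j for j in range(4) if labels[j] != labels[i]]
            a = np.mean([d[i, j] for j in mates])
            b = np.mean([d[i, j] for j in others])
            expected.append((b - a) / max(a, b))
        assert silhouette(dm, labels) == pytest.approx(np.mean(expected), abs=1e-12)

    def test_single_cluster_rejected(self):
        dm = _two_block_matrix()
        with pytest.raises(FvError):
            silhouette(dm, np.zeros(8, dtype=int))


class TestSelectClustering:
    def test_recovers_planted_modes(self, small_structures, small_truth):
        dm = build_distance_matrix(small_structures)
        res = select_clustering(dm)
        assert res.chosen_k == 2
        modes = small_truth.set_index("id").loc[dm.ids, "mode"].values
        labels = res.labels
        agree = max(
            np.mean((labels == lab) == (modes == "A")) for lab in np.unique(labels)
        )
        assert agree >= 0.95

    def test_three_planted_blobs_give_k3(self):
        n = 18
        d = np.full((n, n), 1.0)
        for blk in (slice(0, 6), slice(6, 12), slice(12, 18)):
            d[blk, blk] = 0.05
        np.fill_diagonal(d, 0.0)
        rng = np.random.default_rng(0)
        noise = rng.uniform(0, 0.01, size=(n, n))
        d = d + (noise + noise.T) / 2
        np.fill_diagonal(d, 0.0)
        dm = DistanceMatrix([str(i) for i in range(n)], d)
        assert select_clustering(dm).chosen_k == 3

    def test_identical_objects_degenerate_with_warning(self):
        dm = DistanceMatrix(list("abc"), np.zeros((3, 3)))
        with pytest.warns(UserWarning, match="degenerate"):
            res = select_clustering(dm)
        assert res.degenerate

    def test_planted_silhouette_beats_label_permutations(self, small_structures, small_truth):
        dm = build_distance_matrix(small_structures)
        modes = small_truth.set_index("id").loc[dm.ids, "mode"].values
        labels = (modes == "A").astype(int)
        s_true = silhouette(dm, labels)
        rng = np.random.default_rng(1)
        for _ in range(20):
            assert s_true > silhouette(dm, rng.permutation(labels))


class TestGreedyIdentityCluster:
    def test_identical_selections_single_cluster(self, small_structures):
        from dataclasses import replace

        base = extract_interface(small_structures[0])
        sels = [replace(base, structure_id=f"s{i}") for i in range(5)]
        clusters = greedy_identity_cluster(sels, min_size=3)
        assert len(clusters) == 1
        assert sorted(clusters[0].members) == [f"s{i}" for i in range(5)]

    def test_low_identity_pair_splits(self):
        from fvpack.model import InterfaceSelection

        a = InterfaceSelection("a", tuple("A" * 20), np.zeros((20, 3)), np.zeros(20, bool))
        b = InterfaceSelection("b", tuple("G" * 5 + "A" * 15), np.zeros((20, 3)), np.zeros(20, bool))
        clusters = greedy_identity_cluster([a, b], threshold=0.80, min_size=1)
        assert len(clusters) == 2

    def test_members_reach_threshold_to_representative(self, small_structures):
        from fvpack.model import interface_identity

        sels = {s.id: extract_interface(s) for s in small_structures}
        clusters = greedy_identity_cluster(
            list(sels.values()), threshold=0.6, min_size=1
        )
        for cl in clusters:
            for m in cl.members:
                assert interface_identity(sels[cl.representative], sels[m]) >= 0.6

    def test_order_invariance(self, small_structures):
        sels = [extract_interface(s) for s in small_structures]
        res = {s.id: s.resolution for s in small_structures}
        a = greedy_identity_cluster(sels, threshold=0.6, min_size=1, resolutions=res)
        b = greedy_identity_cluster(sels[::-1], threshold=0.6, min_size=1, resolutions=res)
        assert [sorted(c.members) for c in a] == [sorted(c.members) for c in b]


def _planted_sequences(rng, n_per_class=25):
    """One perfectly separating position (L44) among iid noise positions."""
    pairs, labels = [], []
    noise_positions = ["L10", "L20", "H10", "H20", "H30"]
    for label, l44 in (("A", "P"), ("B", "F")):
        for _ in range(n_per_class):
            light = {"L44": l44}
            heavy = {}
            for p in noise_positions:
                target = light if p.startswith("L") else heavy
                target[p] = "ACDEFGHIKLMNPQRSTVWY"[rng.integers(20)]
            pairs.append(
                (NumberedSequence.from_strings(light), NumberedSequence.from_strings(heavy))
            )
            labels.append(label)
    return pairs, labels


class TestGiniImportance:
    def test_separating_position_ranks_first(self):
        rng = np.random.default_rng(0)
        wins = 0
        for trial in range(20):
            pairs, labels = _planted_sequences(rng)
            imp = gini_importance(pairs, labels, n_trees=100, seed=trial)
            wins += imp.ranking[0] == "L44"
        assert wins >= 19

    def test_constant_position_has_zero_importance(self):
        rng = np.random.default_rng(1)
        pairs, labels = _planted_sequences(rng)
        constant = [
            (NumberedSequence.from_strings({**{p.render(): r for p, r in pr[0].items()}, "L99": "W"}), pr[1])
            for pr in pairs
        ]
        imp = gini_importance(constant, labels, n_trees=100, seed=0)
        assert imp.importances["L99"] == 0.0

    def test_permuted_labels_stay_below_permutation_null(self):
        """With labels shuffled, no position should stand out against its
        own permutation-null distribution."""
        rng = np.random.default_rng(2)
        pairs, labels = _planted_sequences(rng, n_per_class=20)
        null_max = []
        for trial in range(12):
            perm = rng.permutation(labels)
            imp = gini_importance(pairs, perm, n_trees=100, seed=trial)
            null_max.append(imp.importances.max())
        # the null maxima should be tightly grouped: no permutation run
        # dominates the others the way the true labels do
        true_imp = gini_importance(pairs, labels, n_trees=100, seed=99)
        assert true_imp.importances["L44"] > np.percentile(null_max, 99)

    def test_single_class_rejected(self):
        rng = np.random.default_rng(3)
        pairs, _ = _planted_sequences(rng, n_per_class=5)
        with pytest.raises(FvError):
            gini_importance(pairs, ["A"] * len(pairs))


class TestRuleClassifier:
    @pytest.mark.parametrize("res,call", [("P", "A"), ("F", "B"), ("V", "B"), ("I", "B")])
    def test_l44_rule(self, res, call):
        seq = NumberedSequence.from_strings({"L44": res})
        assert classify_by_rule(seq) == call

    def test_absent_l44_unknown(self):
        assert classify_by_rule(NumberedSequence.from_strings({"L36": "Y"})) == "unknown"

    def test_rule_agrees_with_planted_modes(self, small_structures, small_truth):
        modes = small_truth.set_index("id")["mode"]
        calls = [classify_by_rule(s.sequences["L"]) for s in small_structures]
        agree = np.mean([c == modes[s.id] for c, s in zip(calls, small_structures)])
        assert agree >= 0.90


class TestNearestCentroid:
    def test_centroid_classifies_itself(self):
        a = extract_interface(make_mode_template("A"))
        b = extract_interface(make_mode_template("B"))
        call = nearest_centroid_classify(a, {"A": a, "B": b})
        assert call.label == "A"
        assert call.d_A == 0.0
        assert call.d_B > 0.0
        assert not call.outlier

    def test_synthetic_mode_b_classified_b(self):
        spec = SyntheticSpec()
        cents = {
            "A": extract_interface(make_mode_template("A")),
            "B": extract_interface(make_mode_template("B")),
        }
        for i in range(5):
            s = sample_structure(spec, "B", np.random.default_rng([5, i]), f"b{i}")
            assert nearest_centroid_classify(extract_interface(s), cents).label == "B"


class TestResidueFrequencies:
    def test_published_cluster_b_l44_frequencies(self):
        """Counts F:24 V:5 I:2 normalise to 24/31, 5/31, 2/31."""
        pairs = []
        for res, n in (("F", 24), ("V", 5), ("I", 2)):
            for _ in range(n):
                pairs.append(
                    (
                        NumberedSequence.from_strings({"L44": res}),
                        NumberedSequence.from_strings({"H35": "W"}),
                    )
                )
        freq = residue_frequencies(pairs, ["B"] * 31, [pp("L44")])
        table = freq.set_index("residue")["frequency"]
        assert table["F"] == pytest.approx(24 / 31)
        assert table["V"] == pytest.approx(5 / 31)
        assert table["I"] == pytest.approx(2 / 31)
        assert freq.groupby(["cluster", "position"])["frequency"].sum().iloc[0] == pytest.approx(1.0)

    def test_matches_brute_force_tally(self, small_structures, small_truth):
        pairs = [(s.sequences["L"], s.sequences["H"]) for s in small_structures]
        labels = small_truth.set_index("id").loc[[s.id for s in small_structures], "mode"].values
        positions = [pp("L36"), pp("H100B")]
        freq = residue_frequencies(pairs, labels, positions)
        for _, row in freq.iterrows():
            count = 0
            for (light, heavy), lab in zip(pairs, labels):
                if lab != row["cluster"]:
                    continue
                seq = light if row["position"].startswith("L") else heavy
                if seq.get(pp(row["position"])) == row["residue"]:
                    count += 1
            assert count == row["count"]
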