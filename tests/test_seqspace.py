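"""Anchored alignment, redundancy reduction, MDS projection, neighbours."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import silhouette_score

import hrdkit
from hrdkit.seqspace import (
    GAP,
    anchored_align,
    k_medoids,
    loop_his_profile,
    nearest_neighbours,
    numericize,
    pairwise_identity,
    project_mds,
    redundancy_reduce,
)


def _mk(i, seq):
    return hrdkit.MatureDefensin(id=f"s{i}", sequence=seq)


class TestAnchoredAlign:
    def test_fixture_width_matches_segment_maxima(self, fixtures):
        aln = anchored_align(fixtures)
        scaffolds = [hrdkit.detect_scaffold(d) for d in fixtures]
        segs = [[s.n_tail, *s.loops, s.c_tail] for s in scaffolds]
        expected = sum(
            max(len(row[j]) for row in segs) for j in range(9)
        ) + 8
        assert aln.width == expected

    def test_anchor_columns_are_pure_cysteine(self, fixtures):
        aln = anchored_align(fixtures)
        for col in aln.anchor_columns:
            assert all(row[col] == "C" for row in aln.rows)

    def test_degapping_recovers_sequences(self, fixtures):
        aln = anchored_align(fixtures)
        for i, d in enumerate(fixtures):
            assert aln.degap(i) == d.sequence

    def test_sld26_loop6_cell_is_y_then_gaps(self, fixtures):
        aln = anchored_align(fixtures)
        i = aln.ids.index("SlD26")
        start, stop = aln.loop_spans["loop6"]
        cell = aln.rows[i][start:stop]
        assert cell[0] == "Y"
        assert set(cell[1:]) <= {GAP}

    def test_single_sequence_has_no_gaps(self, by_id):
        aln = anchored_align([by_id["SlD26"]])
        assert aln.rows[0] == by_id["SlD26"].sequence

    def test_identical_sequences_align_identically(self, by_id):
        a = by_id["SlD26"]
        b = hrdkit.MatureDefensin(id="copy", sequence=a.sequence)
        aln = anchored_align([a, b])
        assert aln.rows[0] == aln.rows[1]

    def test_scaffold_failure_lists_offenders(self):
        bad = _mk(0, "ACDEF")
        with pytest.raises(hrdkit.ScaffoldError, match="s0"):
            anchored_align([bad])


class TestRedundancyReduce:
    def test_exact_duplicate_dropped(self, by_id):
        a = by_id["SlD26"]
        b = hrdkit.MatureDefensin(id="twin", sequence=a.sequence)
        aln = anchored_align([a, b])
        assert redundancy_reduce(aln) == ["SlD26"]

    def test_threshold_one_keeps_all_distinct(self, fixtures):
        aln = anchored_align(fixtures)
        assert redundancy_reduce(aln, threshold=1.0) == list(aln.ids)

    def test_agrees_with_brute_force_filter(self):
        spec = hrdkit.SyntheticSpec(
            n_sequences=60, seed=11, n_clusters=3,
            within_cluster_mutations=4, duplicate_fraction=0.2,
        )
        records, _ = hrdkit.generate_defensins(spec)
        aln = anchored_align(records)
        got = redundancy_reduce(aln, 0.99)
        # brute force: same greedy rule, all-pairs identity
        retained = []
        for i in range(len(aln.ids)):
            if all(
                pairwise_identity(aln.rows[i], aln.rows[j]) < 0.99
                for j in retained
            ):
                retained.append(i)
        assert got == [aln.ids[i] for i in retained]

    def test_planted_duplicate_groups_reduce_to_representatives(self):
        base = hrdkit.load_fixtures()
        dupes = [
            hrdkit.MatureDefensin(id=f"{d.id}-dup", sequence=d.sequence)
            for d in base
        ]
        aln = anchored_align(base + dupes)
        assert redundancy_reduce(aln) == [d.id for d in base]


class TestNumericize:
    def test_identical_rows_identical_features(self, by_id):
        a = by_id["SlD26"]
        b = hrdkit.MatureDefensin(id="twin", sequence=a.sequence)
        feats = numericize(anchored_align([a, b]))
        assert np.array_equal(feats[0], feats[1])

    def test_single_substitution_perturbs_five_features(self):
        a = _mk(0, "AC" + "CCCCCCC")  # n_tail A + 8 Cys
        b = _mk(1, "GC" + "CCCCCCC")
        feats = numericize(anchored_align([a, b]))
        diff = np.nonzero(feats[0] - feats[1])[0]
        assert len(diff) == 5
        assert set(diff) <= set(range(0, 5))

    def test_gap_cells_are_zero(self):
        a = _mk(0, "AAC" + "C" * 7)
        b = _mk(1, "AC" + "C" * 7)
        aln = anchored_align([a, b])
        feats = numericize(aln)
        # b's padded n_tail column contributes a zero block
        assert np.array_equal(feats[1, 5:10], np.zeros(5))


class TestProjectMDS:
    def test_3_4_5_triangle_recovered(self):
        pts = np.array([[0.0, 0.0], [3.0, 0.0], [3.0, 4.0]])
        space = project_mds(pts, d=2)
        d01 = np.linalg.norm(space.coords[0] - space.coords[1])
        d12 = np.linalg.norm(space.coords[1] - space.coords[2])
        d02 = np.linalg.norm(space.coords[0] - space.coords[2])
        assert sorted([d01, d12, d02]) == pytest.approx([3, 4, 5], abs=1e-9)

    def test_exactly_embeddable_points_recovered(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(40, 5))
        space = project_mds(pts, d=5)
        from scipy.spatial.distance import pdist

        assert np.max(np.abs(pdist(space.coords) - pdist(pts))) < 1e-6
        assert space.stress < 1e-9

    def test_duplicate_rows_identical_coordinates(self):
        pts = np.array([[0.0, 0], [1, 1], [1, 1], [2, 0]])
        space = project_mds(pts, d=2)
        assert np.allclose(space.coords[1], space.coords[2])

    def test_eigenvalues_non_increasing(self):
        rng = np.random.default_rng(3)
        space = project_mds(rng.normal(size=(20, 6)), d=4)
        assert np.all(np.diff(space.eigenvalues) <= 1e-9)

    def test_dimension_reduced_with_warning_for_degenerate_input(self):
        pts = np.array([[0.0], [1.0], [2.0]])  # 1-D data, ask for 2 axes
        with pytest.warns(UserWarning, match="reducing dimensions"):
            space = project_mds(pts, d=2)
        assert space.coords.shape[1] == 1

    def test_permuting_input_preserves_distances_and_silhouette(self):
        rng = np.random.default_rng(5)
        pts = np.vstack([
            rng.normal(0, 0.3, size=(10, 4)),
            rng.normal(4, 0.3, size=(10, 4)),
        ])
        labels = np.array([0] * 10 + [1] * 10)
        perm = rng.permutation(20)
        s1 = project_mds(pts, d=2)
        s2 = project_mds(pts[perm], d=2)
        from scipy.spatial.distance import pdist, squareform

        d1 = squareform(pdist(s1.coords))
        d2 = squareform(pdist(s2.coords))
        assert np.allclose(d1[np.ix_(perm, perm)], d2, atol=1e-8)
        assert silhouette_score(s1.coords, labels) == pytest.approx(
            silhouette_score(s2.coords, labels[perm]), abs=1e-8
        )

    def test_two_cluster_synthetic_defensins_separate(self):
        spec = hrdkit.SyntheticSpec(
            n_sequences=40, seed=2, n_clusters=2,
            within_cluster_mutations=4,
            connectivity_class=("standard", "shifted"),
        )
        records, truth = hrdkit.generate_defensins(spec)
        aln = anchored_align(records)
        space = project_mds(numericize(aln), d=2, ids=aln.ids)
        labels = [t.cluster for t in truth]
        assert silhouette_score(space.coords, labels) > 0.5


class TestNearestNeighbours:
    def _space(self, n=50, seed=4):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(n, 3))
        return project_mds(pts, d=3, ids=[f"p{i}" for i in range(n)]), pts

    def test_matches_exhaustive_sort(self):
        space, _ = self._space()
        for query in ["p0", "p17", "p49"]:
            qi = space.ids.index(query)
            dists = np.linalg.norm(space.coords - space.coords[qi], axis=1)
            order = [
                space.ids[i]
                for i in np.argsort(dists, kind="stable")
                if i != qi
            ]
            assert nearest_neighbours(space, query, k=10) == order[:10]

    def test_k_equals_n_minus_1_returns_everyone(self):
        space, _ = self._space(n=10)
        got = nearest_neighbours(space, "p3", k=9)
        assert sorted(got) == sorted(i for i in space.ids if i != "p3")

    def test_planted_twin_ranks_first(self):
        pts = np.vstack([np.zeros(3), np.zeros(3), np.ones(3) * 5,
                         np.ones(3) * 9])
        with pytest.warns(UserWarning):  # collinear points: rank-1 embedding
            space = project_mds(pts, d=3, ids=["q", "twin", "far", "farther"])
        assert nearest_neighbours(space, "q", k=1) == ["twin"]

    def test_unknown_id_raises(self):
        space, _ = self._space(n=5)
        with pytest.raises(KeyError, match="nope"):
            nearest_neighbours(space, "nope", k=2)


class TestLoopHisProfile:
    def test_sld26_loop5_mean_is_one(self, by_id):
        (prof,) = loop_his_profile([by_id["SlD26"]], {"SlD26": "solo"})
        assert prof.loop_means[4] == 1.0  # loop 5 is "SHGD"

    def test_his_free_group_all_zero(self):
        d = _mk(0, "AG" + "CAAG" * 7 + "C" + "GG")
        (prof,) = loop_his_profile([d], {"s0": "g"})
        assert prof.loop_means == (0.0,) * 7
        assert prof.tail_means == (0.0, 0.0)

    def test_mean_of_two_sequences(self):
        a = _mk(0, "".join("C" + "HH" for _ in range(7)) + "C")
        b = _mk(1, "".join("C" + "HHHH" for _ in range(7)) + "C")
        (prof,) = loop_his_profile([a, b], {"s0": "g", "s1": "g"})
        assert prof.loop_means == (3.0,) * 7

    def test_missing_label_rejected(self, by_id):
        with pytest.raises(ValueError, match="SlD26"):
            loop_his_profile([by_id["SlD26"]], {})

    def test_planted_enrichment_detected_in_most_replicates(self):
        hits = 0
        for seed in range(30):
            spec = hrdkit.SyntheticSpec(
                n_sequences=30, seed=seed, his_enrichment={5: 0.6}
            )
            records, _ = hrdkit.generate_defensins(spec)
            (prof,) = loop_his_profile(
                records, {d.id: "g" for d in records}
            )
            if int(np.argmax(prof.loop_means)) == 4:
                hits += 1
        assert hits >= 29


def test_k_medoids_recovers_well_separated_clusters():
    rng = np.random.default_rng(9)
    pts = np.vstack([
        rng.normal(0, 0.2, size=(15, 2)),
        rng.normal(6, 0.2, size=(15, 2)),
    ])
    from scipy.spatial.distance import pdist, squareform

    labels = k_medoids(squareform(pdist(pts)), k=2, seed=0)
    first, second = labels[:15], labels[15:]
    assert len(set(first)) == 1 and len(set(second)) == 1
    assert first[0] != second[0]
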