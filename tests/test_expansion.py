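import numpy as np
import pytest

from rbqe.core import FeatureDatabase, ImageRecord
from rbqe.expansion import (
    build_nqe,
    per_class_top_k,
    rbqe_retrieve,
    select_fnqe,
)
from rbqe.synthetic import SyntheticSpec, gen_feature_db
from .conftest import brute_force_distance, brute_force_ranking


class TestPerClassTopK:
    def test_small_class_returns_all_members(self):
        db = FeatureDatabase(
            [ImageRecord(f"a{i}", "small", [float(i)]) for i in range(3)]
            + [ImageRecord(f"b{i}", "big", [float(10 + i)]) for i in range(12)]
        )
        pools = per_class_top_k([0.0], db, k=10)
        assert len(pools["small"]) == 3
        assert len(pools["big"]) == 10

    def test_query_record_tops_its_own_class(self, random_db):
        probe = random_db["r10"].features
        pools = per_class_top_k(probe, random_db, k=5)
        assert pools[random_db["r10"].class_label][0] == "r10"

    def test_matches_filtered_global_ranking_oracle(self, random_db):
        rng = np.random.default_rng(11)
        probe = rng.normal(size=random_db.dim)
        pools = per_class_top_k(probe, random_db, k=5)
        global_rank = brute_force_ranking(probe, random_db)
        for label in random_db.classes:
            expected = [r for r in global_rank if random_db[r].class_label == label][:5]
            assert pools[label] == expected

    def test_empty_database_rejected(self):
        with pytest.raises(ValueError):
            FeatureDatabase([])


class TestBuildNqe:
    def test_worked_example_means(self, table1, table1_db):
        """The five member rows average to the printed expansion row."""
        members, expected = table1
        nqe = build_nqe(list(members), table1_db, "ct")
        assert np.round(nqe.mean_vector, 3) == pytest.approx(expected)
        # first and last printed components, individually
        assert round(nqe.mean_vector[0], 3) == -1.252
        assert round(nqe.mean_vector[-1], 2) == 8.56

    def test_single_member_is_identity(self, random_db):
        nqe = build_nqe(["r08"], random_db, random_db["r08"].class_label)
        assert nqe.mean_vector == pytest.approx(random_db["r08"].features)

    def test_matches_componentwise_loop_oracle(self):
        rng = np.random.default_rng(3)
        mat = rng.normal(size=(20, 7))
        db = FeatureDatabase(
            [ImageRecord(f"v{i}", "c", mat[i]) for i in range(20)]
        )
        nqe = build_nqe([f"v{i}" for i in range(20)], db, "c")
        for j in range(7):
            total = 0.0
            for i in range(20):
                total += mat[i, j]
            assert nqe.mean_vector[j] == pytest.approx(total / 20, rel=1e-12)

    def test_wrong_class_member_rejected(self, random_db):
        with pytest.raises(ValueError, match="class"):
            build_nqe(["r00"], random_db, "class_01")  # r00 is class_00

    def test_empty_members_rejected(self, random_db):
        with pytest.raises(ValueError):
            build_nqe([], random_db, "class_00")


class TestSelectFnqe:
    def test_exact_match_selected(self, random_db):
        from rbqe.expansion import QueryExpansion

        nqes = [
            QueryExpansion("a", np.array([1.0, 0.0]), ("x",)),
            QueryExpansion("b", np.array([0.5, 0.5]), ("y",)),
        ]
        assert select_fnqe([0.5, 0.5], nqes).class_label == "b"

    def test_hand_distances(self):
        from rbqe.expansion import QueryExpansion

        nqes = [
            QueryExpansion("near", np.array([3.0, 4.0]), ("x",)),   # distance 5
            QueryExpansion("far", np.array([5.0, 12.0]), ("y",)),   # distance 13
        ]
        assert select_fnqe([0.0, 0.0], nqes).class_label == "near"

    def test_matches_argmin_oracle(self):
        from rbqe.expansion import QueryExpansion

        rng = np.random.default_rng(21)
        query = rng.normal(size=5)
        nqes = [
            QueryExpansion(f"c{i}", rng.normal(size=5), (f"m{i}",)) for i in range(10)
        ]
        dists = [brute_force_distance(query, n.mean_vector) for n in nqes]
        best = dists.index(min(dists))
        assert select_fnqe(query, nqes) is nqes[best]

    def test_tie_goes_to_first(self):
        from rbqe.expansion import QueryExpansion

        nqes = [
            QueryExpansion("first", np.array([1.0, 0.0]), ("x",)),
            QueryExpansion("second", np.array([-1.0, 0.0]), ("y",)),
        ]
        assert select_fnqe([0.0, 0.0], nqes).class_label == "first"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_fnqe([0.0], [])


class TestRbqeRetrieve:
    def test_single_class_worked_example(self, table1, table1_db):
        """One class: the selected expansion is the printed mean row."""
        _, expected = table1
        result = rbqe_retrieve("Img1", table1_db, k=5, n_retrieved=5)
        assert len(result.per_class_nqes) == 1
        assert result.fnqe is result.per_class_nqes[0]
        assert np.round(result.fnqe.mean_vector, 3) == pytest.approx(expected)
        # degenerate class count: final ranking is just ranking vs that mean
        oracle = brute_force_ranking(result.fnqe.mean_vector, table1_db)
        assert list(result.final_ranking.ids) == oracle[:5]

    def test_high_separation_retrieves_only_query_class(self, separated_db):
        for qid in separated_db.ids[::7]:
            result = rbqe_retrieve(qid, separated_db, k=10, n_retrieved=10)
            qclass = separated_db[qid].class_label
            assert result.fnqe.class_label == qclass
            assert all(separated_db[r].class_label == qclass for r in result.final_ranking.ids)

    def test_k1_fnqe_is_query_itself(self, random_db):
        """With k=1 and the query kept in, its class expansion is the query."""
        result = rbqe_retrieve("r23", random_db, k=1, include_query=True)
        assert result.fnqe.mean_vector == pytest.approx(random_db["r23"].features)
        assert result.fnqe.member_ids == ("r23",)

    def test_exclude_query_removes_record_from_both_stages(self, random_db):
        result = rbqe_retrieve("r23", random_db, k=5, n_retrieved=len(random_db),
                               include_query=False)
        assert "r23" not in result.final_ranking.ids
        for nqe in result.per_class_nqes:
            assert "r23" not in nqe.member_ids

    def test_deterministic(self, separated_db):
        a = rbqe_retrieve("class_01/003", separated_db)
        b = rbqe_retrieve("class_01/003", separated_db)
        assert a.final_ranking.ids == b.final_ranking.ids
        assert a.fnqe.mean_vector == pytest.approx(b.fnqe.mean_vector, rel=0)

    def test_invariant_to_class_relabeling(self, separated_db):
        renamed = FeatureDatabase.from_arrays(
            separated_db.ids,
            [f"renamed_{l}" for l in separated_db.labels],
            separated_db.matrix,
        )
        a = rbqe_retrieve("class_00/000", separated_db)
        b = rbqe_retrieve("class_00/000", renamed)
        assert a.final_ranking.ids == b.final_ranking.ids
        assert b.fnqe.class_label == f"renamed_{a.fnqe.class_label}"

    def test_restrict_to_fnqe_class(self, separated_db):
        result = rbqe_retrieve("class_02/001", separated_db, n_retrieved=50,
                               restrict_to_fnqe_class=True)
        classes = {separated_db[r].class_label for r in result.final_ranking.ids}
        assert classes == {"class_02"}

    def test_unknown_query_id_rejected(self, random_db):
        with pytest.raises(KeyError):
            rbqe_retrieve("missing", random_db)


def test_fnqe_class_recovery_improves_with_separation():
    """Fraction of queries whose expansion class is correct rises to 1."""
    accuracies = []
    for separation in (0.5, 5.0, 50.0):
        hits = total = 0
        for seed in range(3):
            spec = SyntheticSpec(n_classes=3, class_sizes=(12, 12, 12), dim=8,
                                 separation=separation, sigma=1.0, seed=seed)
            db = gen_feature_db(spec)
            for qid in db.ids[::4]:
                result = rbqe_retrieve(qid, db, k=10)
                hits += result.fnqe.class_label == db[qid].class_label
                total += 1
        accuracies.append(hits / total)
    assert accuracies[-1] == 1.0
    assert accuracies[0] <= accuracies[-1]
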