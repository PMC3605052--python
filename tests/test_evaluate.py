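"""Best-hit, class-depth, alpha sweep and Rand index."""

import itertools

import numpy as np
import pandas as pd
import pytest

from motifclust.evaluate import (
    alpha_sweep,
    best_hit,
    class_depth,
    class_subsets,
    partition_from_sets,
    rand_index,
    summarize_subsets,
)
from motifclust.pfm import prepare
from motifclust.synth import FamilySpec, generate

from conftest import random_pfm


def table(entries, ids):
    df = pd.DataFrame(0.0, index=ids, columns=ids)
    for (a, b), v in entries.items():
        df.loc[a, b] = df.loc[b, a] = v
    return df


def brute_best_hit(scores, classes, m):
    """Oracle: explicit enumeration, pessimistic ties."""
    others = [x for x in scores.index if x != m]
    top = max(scores.loc[m, x] for x in others)
    winners = [x for x in others if scores.loc[m, x] == top]
    return all(classes[x] == classes[m] for x in winners)


def brute_class_depth(scores, classes, m):
    others = [x for x in scores.index if x != m]
    ranked = sorted(
        others, key=lambda x: (-scores.loc[m, x], classes[x] == classes[m])
    )
    n_same = sum(1 for x in others if classes[x] == classes[m])
    if n_same == 0:
        return 0.0
    k = 0
    for x in ranked:
        if classes[x] == classes[m]:
            k += 1
        else:
            break
    return k / n_same


class TestBestHit:
    def test_clean_two_class_table(self):
        ids = ["a1", "a2", "b1", "b2"]
        classes = dict(zip(ids, "AABB"))
        entries = {("a1", "a2"): 5.0, ("b1", "b2"): 5.0}
        entries.update({(x, y): 1.0 for x in ["a1", "a2"] for y in ["b1", "b2"]})
        per_motif, per_class = best_hit(table(entries, ids), classes)
        assert per_motif.all()
        assert per_class.to_dict() == {"A": 1.0, "B": 1.0}

    def test_cross_class_best_is_incorrect(self):
        ids = ["a1", "a2", "b1", "b2"]
        classes = dict(zip(ids, "AABB"))
        entries = {("a1", "a2"): 1.0, ("a1", "b1"): 5.0, ("b1", "b2"): 5.0}
        per_motif, _ = best_hit(table(entries, ids), classes)
        assert not per_motif["a1"]

    def test_matches_brute_force_on_random_tables(self, rng):
        ids = [f"m{i}" for i in range(6)]
        classes = {m: "XYZ"[i % 3] for i, m in enumerate(ids)}
        for _ in range(25):
            vals = rng.random((6, 6))
            vals = (vals + vals.T) / 2
            np.fill_diagonal(vals, 0)
            scores = pd.DataFrame(vals, index=ids, columns=ids)
            per_motif, _ = best_hit(scores, classes)
            for m in ids:
                assert per_motif[m] == brute_best_hit(scores, classes, m)

    def test_pessimistic_vs_optimistic_ties(self):
        ids = ["a1", "a2", "b1"]
        classes = dict(zip(ids, "AAB"))
        entries = {("a1", "a2"): 2.0, ("a1", "b1"): 2.0, ("a2", "b1"): 0.1}
        scores = table(entries, ids)
        pess, _ = best_hit(scores, classes, ties="pessimistic")
        opti, _ = best_hit(scores, classes, ties="optimistic")
        assert not pess["a1"] and opti["a1"]

    def test_catch_all_class_excluded_from_holdout(self):
        ids = ["a1", "a2", "o1"]
        classes = {"a1": "A", "a2": "A", "o1": "Other"}
        entries = {("a1", "a2"): 1.0, ("a1", "o1"): 5.0, ("a2", "o1"): 0.1}
        per_motif, _ = best_hit(table(entries, ids), classes, holdout_exclude=["Other"])
        # o1 is never held out but still beats a2 as a1's best hit
        assert set(per_motif.index) == {"a1", "a2"}
        assert not per_motif["a1"] and per_motif["a2"]


class TestClassDepth:
    def test_ranking_same_same_other_same(self):
        # class of 4: ranking [same, same, other, same] -> depth 2/3
        ids = ["m", "s1", "s2", "s3", "o1"]
        classes = {"m": "A", "s1": "A", "s2": "A", "s3": "A", "o1": "B"}
        entries = {
            ("m", "s1"): 4.0,
            ("m", "s2"): 3.0,
            ("m", "o1"): 2.0,
            ("m", "s3"): 1.0,
        }
        per_motif, _ = class_depth(table(entries, ids), classes)
        assert per_motif["m"] == pytest.approx(2 / 3)

    def test_first_ranked_other_class_gives_zero(self):
        ids = ["m", "s1", "o1"]
        classes = {"m": "A", "s1": "A", "o1": "B"}
        entries = {("m", "o1"): 5.0, ("m", "s1"): 1.0}
        per_motif, _ = class_depth(table(entries, ids), classes)
        assert per_motif["m"] == 0.0

    def test_all_members_before_any_outsider_gives_one(self):
        ids = ["m", "s1", "s2", "o1"]
        classes = {"m": "A", "s1": "A", "s2": "A", "o1": "B"}
        entries = {("m", "s1"): 5.0, ("m", "s2"): 4.0, ("m", "o1"): 1.0}
        per_motif, _ = class_depth(table(entries, ids), classes)
        assert per_motif["m"] == 1.0

    def test_matches_brute_force_on_random_tables(self, rng):
        ids = [f"m{i}" for i in range(8)]
        classes = {m: "XY"[i % 2] for i, m in enumerate(ids)}
        for _ in range(25):
            vals = rng.random((8, 8))
            vals = (vals + vals.T) / 2
            np.fill_diagonal(vals, 0)
            scores = pd.DataFrame(vals, index=ids, columns=ids)
            per_motif, _ = class_depth(scores, classes)
            for m in ids:
                assert per_motif[m] == pytest.approx(
                    brute_class_depth(scores, classes, m)
                )

    def test_quartile_summary_is_type7(self):
        ids = ["m1", "m2", "m3", "o1"]
        classes = {"m1": "A", "m2": "A", "m3": "A", "o1": "B"}
        entries = {
            ("m1", "m2"): 5.0, ("m1", "m3"): 4.0, ("m2", "m3"): 3.0,
            ("m1", "o1"): 1.0, ("m2", "o1"): 3.5, ("m3", "o1"): 4.5,
        }
        per_motif, per_class = class_depth(table(entries, ids), classes)
        vals = per_motif[["m1", "m2", "m3"]].to_numpy()
        lq, med, uq = np.percentile(vals, [25, 50, 75])
        row = per_class.loc["A"]
        assert row["median"] == pytest.approx(med)
        assert row["lower_quartile"] == pytest.approx(lq)
        assert row["upper_quartile"] == pytest.approx(uq)


class TestRandIndex:
    def test_identical_partitions(self):
        U = {"1": 0, "2": 0, "3": 1}
        assert rand_index(U, dict(U)) == 1.0

    def test_pair_vs_singletons(self):
        U = partition_from_sets([{"1", "2"}, {"3"}])
        V = partition_from_sets([{"1"}, {"2"}, {"3"}])
        # pairs: (1,2) disagree; (1,3) and (2,3) agree -> 2/3
        assert rand_index(U, V) == pytest.approx(2 / 3)

    def test_singletons_vs_one_cluster(self):
        U = {c: i for i, c in enumerate("abcd")}
        V = {c: 0 for c in "abcd"}
        assert rand_index(U, V) == 0.0

    def test_symmetric_and_relabel_invariant(self, rng):
        items = [f"i{k}" for k in range(8)]
        U = {m: int(rng.integers(3)) for m in items}
        V = {m: int(rng.integers(3)) for m in items}
        assert rand_index(U, V) == rand_index(V, U)
        relabeled = {m: 10 - v for m, v in V.items()}
        assert rand_index(U, relabeled) == rand_index(U, V)

    def test_mismatched_items_rejected(self):
        with pytest.raises(ValueError, match="different item sets"):
            rand_index({"a": 0}, {"b": 0})


@pytest.fixture(scope="module")
def collection():
    pfms, truth = generate(FamilySpec(seed=11, n_families=3, motifs_per_family=4))
    prep = [prepare(p) for p in pfms]
    classes = {p.id: p.class_label for p in prep}
    return prep, classes


class TestAlphaSweep:
    def test_single_value_grid(self, collection):
        prep, classes = collection
        out = alpha_sweep(prep, classes, "ED", "sqr", [0.5])
        assert len(out) == 1 and out.loc[0, "alpha"] == 0.5

    def test_consistency_with_direct_run(self, collection):
        from motifclust.align import all_pairs_scores
        from motifclust.colscores import ColumnScoreSpec

        prep, classes = collection
        out = alpha_sweep(prep, classes, "ED", "sqr", [0.3, 0.6])
        scores, _ = all_pairs_scores(prep, ColumnScoreSpec("ED", alpha=0.6), "sqr")
        bh, _ = best_hit(scores, classes)
        row = out[out["alpha"] == 0.6].iloc[0]
        assert row["best_hit"] == pytest.approx(bh.mean())

    def test_grid_validation(self, collection):
        prep, classes = collection
        with pytest.raises(ValueError, match="within"):
            alpha_sweep(prep, classes, "ED", "sqr", [0.0, 0.5])


def test_class_subsets_from_map():
    classes = {f"m{i}": ("A" if i < 20 else "B" if i < 30 else "C") for i in range(35)}
    subsets = class_subsets(classes, top=2, minimums=(20, 10))
    assert set(subsets["Top2"]) == {"A", "B"}
    assert subsets["Min20"] == ["A"]
    assert set(subsets["Min10"]) == {"A", "B"}


def test_summarize_subsets_shape(rng):
    ids = [f"m{i}" for i in range(9)]
    classes = {m: "ABC"[i % 3] for i, m in enumerate(ids)}
    vals = rng.random((9, 9))
    vals = (vals + vals.T) / 2
    np.fill_diagonal(vals, 0)
    scores = pd.DataFrame(vals, index=ids, columns=ids)
    report = summarize_subsets(scores, classes, subsets={"All": ["A", "B", "C"]})
    assert list(report.index) == ["All"]
    assert {"best_hit", "depth_median", "n_classes"} <= set(report.columns)
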