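"""Familial Binding Profiles: merging rules and hierarchical clustering."""

import itertools
import warnings

import numpy as np
import pytest

from motifclust.align import align
from motifclust.colscores import ColumnScoreSpec
from motifclust.fbp import (
    FBP,
    cluster,
    clusters_to_table,
    dendrogram_newick,
    fbp_detects,
    merge_fbps,
)
from motifclust.pfm import PFM, prepare, reverse_complement
from motifclust.pipelines import fit_adjustment_from_pfms, train_classifier_from_pfms
from motifclust.scoremodel import AdjustmentModel, DEFAULT_CLASSIFIER, FamilyClassifier, adjust, family_probability
from motifclust.synth import FamilySpec, generate

from conftest import random_pfm

ED = ColumnScoreSpec("ED")
IDENTITY_MODEL = AdjustmentModel(grid=[0.0, 12.0], mu=[0.0, 0.0], sigma=[1.0, 1.0])


class TestInitialWeights:
    def test_sqrt_of_sites(self, rng):
        pfm = random_pfm(rng, "m")
        pfm.n_sites = 49
        fbp = FBP.from_pfm(pfm)
        np.testing.assert_allclose(fbp.column_weights, 7.0)

    def test_site_cap_at_200(self, rng):
        pfm = random_pfm(rng, "m")
        pfm.n_sites = 1000
        fbp = FBP.from_pfm(pfm)
        np.testing.assert_allclose(fbp.column_weights, np.sqrt(200))
        assert fbp.column_weights[0] == pytest.approx(14.1421, abs=1e-4)

    def test_frequency_only_motif_gets_unit_weight(self, rng):
        pfm = random_pfm(rng, "m")
        pfm.n_sites = None
        np.testing.assert_allclose(FBP.from_pfm(pfm).column_weights, 1.0)


class TestMergeFbps:
    def test_identical_full_overlap_preserves_profile(self, rng):
        pfm = random_pfm(rng, "m", length=8)
        pfm.n_sites = 36
        a, b = FBP.from_pfm(pfm), FBP.from_pfm(pfm)
        b = FBP(profile=pfm, column_weights=b.column_weights, members={"m2": "+"})
        merged = merge_fbps(a, b, align(pfm, pfm, ED, "sqr"))
        np.testing.assert_allclose(merged.profile.probs, pfm.probs, atol=1e-12)
        np.testing.assert_allclose(merged.column_weights, 12.0)  # 6 + 6
        assert merged.member_ids == {"m", "m2"}

    def test_weighted_average_forced_arithmetic(self, make_pfm):
        p = [0.7, 0.1, 0.1, 0.1]
        a = FBP(profile=make_pfm("a", [p] * 5), column_weights=np.full(5, 3.0),
                members={"a": "+"})
        uniform = [[0.25] * 4] * 5
        b = FBP(profile=make_pfm("b", uniform), column_weights=np.full(5, 1.0),
                members={"b": "+"})
        aln = align(a.profile, b.profile, ED, "none")
        merged = merge_fbps(a, b, aln)
        expected = (3 * np.array(p) + 1 * np.full(4, 0.25)) / 4
        np.testing.assert_allclose(merged.profile.probs[:, 0], expected)
        np.testing.assert_allclose(merged.column_weights, 4.0)

    def test_left_overhang_filled_with_uniform_weight_one(self, make_pfm):
        # y carries two extra informative left columns unlike anything in x:
        # the best window is the shared 5-column core, leaving a 2-column
        # left overhang of y averaged against a uniform weight-1 partner
        core = [
            [0.85, 0.05, 0.05, 0.05],
            [0.05, 0.85, 0.05, 0.05],
            [0.05, 0.05, 0.85, 0.05],
            [0.05, 0.05, 0.05, 0.85],
            [0.85, 0.05, 0.05, 0.05],
        ]
        extra = [[0.05, 0.45, 0.45, 0.05], [0.45, 0.05, 0.05, 0.45]]
        x = make_pfm("x", core)
        y = make_pfm("y", extra + core)
        a = FBP(profile=x, column_weights=np.full(5, 5.0), members={"x": "+"})
        b = FBP(profile=y, column_weights=np.full(7, 5.0), members={"y": "+"})
        aln = align(x, y, ED, "none")
        assert (aln.start_x, aln.start_y, aln.width, aln.orientation) == (
            0, 2, 5, "forward",
        )
        merged = merge_fbps(a, b, aln)
        assert merged.profile.length == aln.width + 2
        for j in range(2):
            exp = (5 * y.probs[:, j] + 1 * 0.25) / 6
            np.testing.assert_allclose(merged.profile.probs[:, j], exp)
            assert merged.column_weights[j] == pytest.approx(6.0)
        # aligned core columns: equal profiles, weights add up
        np.testing.assert_allclose(merged.profile.probs[:, 2:], np.array(core).T)
        np.testing.assert_allclose(merged.column_weights[2:], 10.0)

    def test_larger_site_count_pulls_consensus(self, make_pfm):
        p = [0.9, 0.034, 0.033, 0.033]
        q = [0.033, 0.9, 0.034, 0.033]
        strong_cols = [p] * 6
        weak_cols = [q] * 6
        base = {"heavy": 196, "light": 16}  # weights 14 and 4
        heavy = FBP(profile=make_pfm("h", strong_cols),
                    column_weights=np.full(6, np.sqrt(base["heavy"])),
                    members={"h": "+"})
        light = FBP(profile=make_pfm("l", weak_cols),
                    column_weights=np.full(6, np.sqrt(base["light"])),
                    members={"l": "+"})
        aln = align(heavy.profile, light.profile, ED, "none")
        merged = merge_fbps(heavy, light, aln)
        # consensus closer to the heavier member in every aligned column
        d_heavy = np.abs(merged.profile.probs[:, 0] - np.array(p)).sum()
        d_light = np.abs(merged.profile.probs[:, 0] - np.array(q)).sum()
        assert d_heavy < d_light


class TestFbpDetects:
    def test_self_detection_passes(self, rng):
        pfm = random_pfm(rng, "m", length=8)
        fbp = FBP.from_pfm(pfm)
        p, ok = fbp_detects(fbp, pfm, ED, "sqr", IDENTITY_MODEL, DEFAULT_CLASSIFIER)
        assert ok and p > 0.99

    def test_strand_symmetry(self, rng):
        pfm = random_pfm(rng, "m", length=8)
        fbp = FBP.from_pfm(pfm)
        p_fwd, _ = fbp_detects(fbp, pfm, ED, "sqr", IDENTITY_MODEL, DEFAULT_CLASSIFIER)
        p_rc, _ = fbp_detects(
            fbp, reverse_complement(pfm), ED, "sqr", IDENTITY_MODEL, DEFAULT_CLASSIFIER
        )
        assert p_rc == pytest.approx(p_fwd, abs=1e-9)

    def test_unrelated_motif_fails_threshold(self, rng):
        a = random_pfm(rng, "a", length=8)
        b = random_pfm(rng, "b", length=8)
        # a model standardizing background pairs of this size
        model = AdjustmentModel(grid=[0.0, 12.0], mu=[1.0, 1.0], sigma=[0.5, 0.5])
        p, ok = fbp_detects(FBP.from_pfm(a), b, ED, "sqr", model, DEFAULT_CLASSIFIER)
        assert not ok and p < 0.5


def _trained_setup(seed, **spec_kw):
    pfms, truth = generate(FamilySpec(seed=seed, **spec_kw))
    prep = [prepare(p) for p in pfms]
    classes = {p.id: p.class_label for p in prep}
    model = fit_adjustment_from_pfms(prep, ED, "sqr", classes)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf = train_classifier_from_pfms(prep, ED, "sqr", model, truth, classes)
    return prep, truth, model, clf


class TestCluster:
    def test_two_identical_motifs_form_one_cluster(self, rng):
        base = random_pfm(rng, "m1", length=8)
        twin = PFM(id="m2", counts=base.counts.copy(), probs=base.probs.copy(),
                   n_sites=100)
        model = AdjustmentModel(grid=[0.0, 12.0], mu=[1.0, 1.0], sigma=[0.5, 0.5])
        result = cluster([base, twin], ED, "sqr", model, DEFAULT_CLASSIFIER)
        assert len(result.clusters) == 1
        assert result.clusters[0].member_ids == {"m1", "m2"}
        np.testing.assert_allclose(
            result.clusters[0].profile.probs, base.probs, atol=1e-9
        )

    def test_two_unrelated_motifs_stay_singletons(self, rng):
        a = random_pfm(rng, "a", length=8)
        b = random_pfm(rng, "b", length=8)
        model = AdjustmentModel(grid=[0.0, 12.0], mu=[1.0, 1.0], sigma=[0.5, 0.5])
        result = cluster([a, b], ED, "sqr", model, DEFAULT_CLASSIFIER)
        assert len(result.clusters) == 2
        assert (result.merge_log["outcome"].str.startswith("rejected")).sum() == 1

    def test_planted_families_recovered(self):
        from motifclust.evaluate import rand_index

        prep, truth, model, clf = _trained_setup(
            seed=123, n_families=3, motifs_per_family=5
        )
        result = cluster(prep, ED, "sqr", model, clf)
        assert rand_index(result.partition, truth) >= 0.9

    def test_partition_and_order_invariance(self):
        prep, truth, model, clf = _trained_setup(
            seed=5, n_families=3, motifs_per_family=5
        )
        r1 = cluster(prep, ED, "sqr", model, clf)
        r2 = cluster(list(reversed(prep)), ED, "sqr", model, clf)
        ids = {p.id for p in prep}
        assert set(r1.partition) == ids
        assert [sorted(f.member_ids) for f in r1.clusters] == [
            sorted(f.member_ids) for f in r2.clusters
        ]

    def test_acceptance_uses_fbp_probability_not_linkage_height(self, rng):
        # three near-identical motifs plus one unrelated one: the last
        # agglomeration step has linkage distance > 0.5 (average over the
        # unrelated pair distances) yet merges of the related motifs that
        # happen below it must be accepted purely on the FBP checks
        base = random_pfm(rng, "m1", length=8)
        jitter = rng.normal(0, 0.01, base.probs.shape)
        motifs = [base]
        for i, name in enumerate(["m2", "m3"]):
            probs = np.clip(base.probs + jitter * (i + 1), 1e-3, None)
            probs /= probs.sum(axis=0, keepdims=True)
            motifs.append(PFM(id=name, counts=probs.copy(), probs=probs, n_sites=100))
        motifs.append(random_pfm(rng, "zz", length=8))
        model = AdjustmentModel(grid=[0.0, 12.0], mu=[1.0, 1.0], sigma=[0.5, 0.5])
        result = cluster(motifs, ED, "sqr", model, DEFAULT_CLASSIFIER)
        accepted = result.merge_log[result.merge_log["outcome"] == "accepted"]
        heights = result.linkage_matrix[:, 2]
        assert {"m1", "m2", "m3"} in [f.member_ids for f in result.clusters]
        # the dendrogram's top join is far above the probability threshold
        assert heights.max() > 0.5
        assert len(accepted) >= 2

    def test_freeze_semantics_reported_as_final_clusters(self):
        prep, truth, model, clf = _trained_setup(
            seed=5, n_families=3, motifs_per_family=5
        )
        result = cluster(prep, ED, "sqr", model, clf)
        # every input appears exactly once among final clusters
        members = sorted(m for f in result.clusters for m in f.member_ids)
        assert members == sorted(p.id for p in prep)

    def test_retry_mode_runs_and_partitions(self):
        prep, truth, model, clf = _trained_setup(
            seed=6, n_families=3, motifs_per_family=5
        )
        result = cluster(prep, ED, "sqr", model, clf, freeze_on_reject=False)
        members = sorted(m for f in result.clusters for m in f.member_ids)
        assert members == sorted(p.id for p in prep)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="at least two"):
            cluster([], ED, "sqr", IDENTITY_MODEL, DEFAULT_CLASSIFIER)


def test_outputs_table_and_newick(rng):
    a = random_pfm(rng, "a", length=8)
    b = random_pfm(rng, "b", length=8)
    model = AdjustmentModel(grid=[0.0, 12.0], mu=[1.0, 1.0], sigma=[0.5, 0.5])
    result = cluster([a, b], ED, "sqr", model, DEFAULT_CLASSIFIER)
    table = clusters_to_table(result)
    assert set(table["motif_id"]) == {"a", "b"}
    nwk = dendrogram_newick(result)
    assert nwk.endswith(";") and "a" in nwk and "b" in nwk
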