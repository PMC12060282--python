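"""Confidence filtering, TM-score, chain mapping, clustering, bias ratios."""

from dataclasses import replace

import numpy as np
import pytest

from ccbarrel.clustering import (
    ClusteringError,
    best_chain_mapping,
    cluster_models,
    filter_confidence,
    identity_mapping,
    normalized_tm,
    orientation_bias,
    tm_score,
    tm_d0,
)
from ccbarrel.synthetic import (
    AssemblyModel,
    BundleParams,
    ScoreRule,
    build_bundle,
    build_ideal_helix,
    make_ensemble,
    perturb_model,
)
from conftest import random_rotation, rigid_transform_model
from oracles import tm_score_oracle


def _scored(model, iptm, model_id, plddt=80.0):
    m = replace(model, chains=[(c, t, x.copy()) for c, t, x in model.chains])
    m.scores = {"iptm": iptm, "plddt": plddt, "seed": 0, "model_index": 1}
    m.model_id = model_id
    return m


class TestFilterConfidence:
    def test_strict_threshold(self, parallel_hexamer):
        models = [
            _scored(parallel_hexamer, s, f"m{i}")
            for i, s in enumerate([0.69, 0.70, 0.71])
        ]
        kept = filter_confidence(models, 0.7)
        assert [m.scores["iptm"] for m in kept] == [0.71]

    def test_zero_floor_keeps_all(self, parallel_hexamer):
        models = [_scored(parallel_hexamer, s, f"m{i}") for i, s in enumerate([0.1, 0.5])]
        assert len(filter_confidence(models, 0.0)) == 2

    def test_missing_score_reported(self, parallel_hexamer):
        bad = replace(parallel_hexamer)
        bad.model_id = "orphan"
        bad.scores = {}
        with pytest.raises(ClusteringError, match="orphan"):
            filter_confidence([bad], 0.7)


class TestTMScore:
    def test_identity_is_one(self, antiparallel_hexamer):
        mapping = identity_mapping(antiparallel_hexamer, antiparallel_hexamer)
        assert tm_score(antiparallel_hexamer, antiparallel_hexamer, mapping) == pytest.approx(1.0)

    def test_rigid_invariance(self, antiparallel_hexamer, rng):
        R = random_rotation(rng)
        moved = rigid_transform_model(antiparallel_hexamer, R, rng.normal(size=3) * 15)
        mapping = identity_mapping(moved, antiparallel_hexamer)
        assert tm_score(moved, antiparallel_hexamer, mapping) == pytest.approx(1.0, abs=1e-6)

    def test_d0_clamped(self):
        assert tm_d0(10) == 0.5
        assert tm_d0(126) == pytest.approx(1.24 * 111 ** (1 / 3) - 1.8, abs=1e-9)

    def test_symmetry_for_equal_lengths(self, rng):
        a = AssemblyModel(chains=[("A", "A", build_ideal_helix(15))])
        b = AssemblyModel(
            chains=[("A", "A", build_ideal_helix(15) + rng.normal(0, 1.2, (15, 3)))]
        )
        mab = identity_mapping(a, b)
        mba = identity_mapping(b, a)
        assert tm_score(a, b, mab) == pytest.approx(tm_score(b, a, mba), abs=0.01)

    def test_empty_correspondence_rejected(self, parallel_hexamer):
        from ccbarrel.clustering import ChainMapping

        empty = ChainMapping(chain_pairs=[], correspondence=[])
        with pytest.raises(ClusteringError):
            tm_score(parallel_hexamer, parallel_hexamer, empty)

    @pytest.mark.parametrize("noise", [0.5, 1.5, 3.0])
    def test_matches_exhaustive_oracle_on_toys(self, noise):
        """On <= 30-residue toys the iterative search equals direct numerical
        maximisation over rigid transforms within 0.01."""
        rng = np.random.default_rng(int(noise * 10))
        n = 30
        ref = build_ideal_helix(n)
        qry = ref + rng.normal(0, noise, (n, 3))
        a = AssemblyModel(chains=[("A", "A", qry)])
        b = AssemblyModel(chains=[("A", "A", ref)])
        ours = tm_score(a, b, identity_mapping(a, b))
        oracle = tm_score_oracle(qry, ref, n)
        assert ours == pytest.approx(oracle, abs=0.01)

    def test_matches_oracle_on_bent_fragment(self):
        """Hinged toy: two rigid halves at an angle, where seed choice matters."""
        n = 24
        ref = build_ideal_helix(n)
        qry = ref.copy()
        from scipy.spatial.transform import Rotation

        hinge = Rotation.from_euler("y", 35, degrees=True).as_matrix()
        qry[n // 2 :] = (qry[n // 2 :] - qry[n // 2]) @ hinge.T + qry[n // 2]
        a = AssemblyModel(chains=[("A", "A", qry)])
        b = AssemblyModel(chains=[("A", "A", ref)])
        ours = tm_score(a, b, identity_mapping(a, b))
        oracle = tm_score_oracle(qry, ref, n)
        assert ours == pytest.approx(oracle, abs=0.01)


class TestChainMapping:
    def test_cyclic_relabeling_recovered(self, antiparallel_hexamer):
        rotated = replace(
            antiparallel_hexamer,
            chains=[antiparallel_hexamer.chains[(i + 2) % 6] for i in range(6)],
        )
        assert normalized_tm(rotated, antiparallel_hexamer) == pytest.approx(1.0, abs=1e-6)

    def test_mapping_is_type_preserving(self, antiparallel_hexamer):
        mapping = best_chain_mapping(antiparallel_hexamer, antiparallel_hexamer)
        assert mapping.type_preserving
        for qi, ri in mapping.chain_pairs:
            assert (
                antiparallel_hexamer.chains[qi][1]
                == antiparallel_hexamer.chains[ri][1]
            )

    def test_type_multiset_mismatch_rejected(self):
        a3b3 = build_bundle(BundleParams())
        a2b4 = build_bundle(BundleParams(chain_types=("A", "B", "B", "B", "A", "B")))
        with pytest.raises(ClusteringError, match="multiset"):
            best_chain_mapping(a3b3, a2b4)


class TestNormalizedTM:
    def test_identical_models_give_one(self, parallel_hexamer):
        assert normalized_tm(parallel_hexamer, parallel_hexamer) == pytest.approx(1.0)

    def test_truncation_strictly_penalised(self, parallel_hexamer):
        truncated = replace(
            parallel_hexamer,
            chains=[
                (c, t, x[: len(x) // 2] if c == "A" else x)
                for c, t, x in parallel_hexamer.chains
            ],
        )
        full = normalized_tm(parallel_hexamer, parallel_hexamer)
        part = normalized_tm(parallel_hexamer, truncated)
        assert part < full
        # fraction aligned = (126 - 11) / 126
        assert part <= (126 - 11) / 126 + 1e-9

    def test_disjoint_topologies_below_threshold(
        self, parallel_hexamer, antiparallel_hexamer
    ):
        assert normalized_tm(parallel_hexamer, antiparallel_hexamer) < 0.95


class TestClusterModels:
    def _noisy_set(self, n_parallel, n_anti, sigma=0.3):
        return make_ensemble(
            BundleParams(),
            seeds=range(n_parallel + n_anti),
            n_variants=1,
            parallel_fraction=n_parallel / (n_parallel + n_anti),
            score_rule=ScoreRule(n_high_confidence=n_parallel + n_anti),
            noise_sigma=sigma,
            rng_seed=5,
        )

    def test_threshold_one_splits_everything(self):
        models = self._noisy_set(0, 4, sigma=1.0)
        cs = cluster_models(models, threshold=0.9999)
        assert cs.sizes == [1, 1, 1, 1]

    def test_threshold_zero_single_cluster(self):
        models = self._noisy_set(2, 2)
        cs = cluster_models(models, threshold=0.0)
        assert cs.sizes == [4]

    def test_planted_composition_recovered(self):
        """2 parallel + 18 antiparallel noisy models bin into exactly two
        clusters with topology-pure membership."""
        models = self._noisy_set(2, 18)
        cs = cluster_models(models, threshold=0.95)
        assert sorted(cs.sizes) == [2, 18]
        by_id = {m.model_id: m for m in models}
        for members, topo in zip(cs.clusters, cs.topologies):
            for mid in members:
                assert by_id[mid].topology_truth == topo

    def test_representative_is_highest_confidence_member(self):
        models = self._noisy_set(0, 6)
        cs = cluster_models(models, threshold=0.95)
        by_id = {m.model_id: m for m in models}
        for rep, members in zip(cs.representatives, cs.clusters):
            assert rep in members
            rep_iptm = by_id[rep].scores["iptm"]
            assert all(rep_iptm >= by_id[m].scores["iptm"] for m in members)

    def test_order_permutation_leaves_sizes_unchanged(self):
        models = self._noisy_set(2, 8)
        cs1 = cluster_models(models, threshold=0.95)
        cs2 = cluster_models(models[::-1], threshold=0.95)
        assert sorted(cs1.sizes) == sorted(cs2.sizes)
        assert cs1.representatives == cs2.representatives

    def test_complete_linkage_agrees_on_clean_split(self):
        models = self._noisy_set(2, 6)
        leader = cluster_models(models, threshold=0.95, method="leader")
        complete = cluster_models(models, threshold=0.95, method="complete")
        assert sorted(leader.sizes) == sorted(complete.sizes)


class TestOrientationBias:
    def _clusterset(self, n_par, n_anti):
        from ccbarrel.clustering import ClusterSet

        clusters, topos, reps = [], [], []
        if n_par:
            clusters.append([f"p{i}" for i in range(n_par)])
            topos.append("parallel")
            reps.append("p0")
        if n_anti:
            clusters.append([f"a{i}" for i in range(n_anti)])
            topos.append("antiparallel")
            reps.append("a0")
        return ClusterSet(clusters, reps, topos, 0.95)

    @pytest.mark.parametrize(
        "n_par,n_anti,expected",
        [(2, 170, "1:85"), (5, 5, "1:1"), (1, 301, "1:301"), (1, 115, "1:115")],
    )
    def test_reduced_ratio(self, n_par, n_anti, expected):
        assert orientation_bias(self._clusterset(n_par, n_anti)).ratio == expected

    def test_no_parallel_degenerate(self):
        report = orientation_bias(self._clusterset(0, 7))
        assert report.ratio == "0:7 (no parallel models)"
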