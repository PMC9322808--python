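import itertools

import numpy as np
import pytest

from ecbscreen.chem import Compound, tanimoto
from ecbscreen.metrics import auroc
from ecbscreen.pairs import (
    NEGATIVE,
    POSITIVE,
    ChemicalPair,
    EcbsModel,
    TrainingConfig,
    ecbs_score,
    enumerate_ercps,
    featurize_pair,
    train_ecbs_model,
)
from ecbscreen.synthworld import WorldConfig, generate_world
from ecbscreen.targets import ActivityTable, TargetProtein, build_homology_graph

from conftest import FP_LEN, _random_compound


# ---------------------------------------------------------------------------
# Independent brute-force oracle for ERCP labeling, working directly from the
# raw identity dict + activity rows (never touching HomologyGraph).
# ---------------------------------------------------------------------------
def brute_force_ercps(records, identities, threshold, focal):
    def one_hop(t):
        out = {t}
        for pair, ident in identities.items():
            if t in pair and ident >= threshold:
                out |= pair
        return out

    targets_of = {}
    for cid, tid, active in records:
        if active:
            targets_of.setdefault(cid, set()).add(tid)

    focal_related = one_hop(focal)
    universe = {c for c, ts in targets_of.items() if ts & focal_related}
    positives = {
        tuple(sorted(p)) for p in itertools.combinations(sorted(universe), 2)
    }
    eligible_negatives = set()
    for u in universe:
        u_related = set().union(*(one_hop(t) for t in targets_of[u]))
        for d in targets_of:
            if d in universe:
                continue
            if not (targets_of[d] & u_related):
                eligible_negatives.add(tuple(sorted((u, d))))
    return universe, positives, eligible_negatives


class TestEnumerateErcps:
    def test_toy_positives(self, toy_activities, toy_graph):
        pairs = enumerate_ercps(toy_activities, toy_graph, "T1", seed=0)
        positives = {p.key for p in pairs if p.label == POSITIVE}
        # hand enumeration over all 6 unordered pairs of {c1..c4}
        assert positives == {("c1", "c2"), ("c1", "c3"), ("c2", "c3")}

    def test_toy_negatives_and_determinism(self, toy_activities, toy_graph):
        a = enumerate_ercps(toy_activities, toy_graph, "T1", 1.0, seed=7)
        b = enumerate_ercps(toy_activities, toy_graph, "T1", 1.0, seed=7)
        negs = {p.key for p in a if p.label == NEGATIVE}
        assert negs <= {("c1", "c4"), ("c2", "c4"), ("c3", "c4")}
        assert len(negs) == 3  # ratio 1.0 and only 3 eligible
        assert [(p.key, p.label) for p in a] == [(p.key, p.label) for p in b]

    def test_single_ligand_focal_errors(self, toy_activities, toy_graph):
        with pytest.raises(ValueError, match="insufficient ligands"):
            enumerate_ercps(toy_activities, toy_graph, "T3", seed=0)

    def test_shortfall_returns_all_eligible(self, toy_activities, toy_graph, caplog):
        pairs = enumerate_ercps(toy_activities, toy_graph, "T1", 10.0, seed=0)
        assert sum(p.label == NEGATIVE for p in pairs) == 3

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_on_random_worlds(self, seed):
        rng = np.random.default_rng(seed)
        n_targets = int(rng.integers(3, 7))
        n_compounds = int(rng.integers(6, 31))
        tids = [f"T{i}" for i in range(n_targets)]
        identities = {
            frozenset(p): float(rng.random())
            for p in itertools.combinations(tids, 2)
        }
        records = []
        for i in range(n_compounds):
            for tid in rng.choice(tids, size=int(rng.integers(1, 3)), replace=False):
                records.append((f"c{i:02d}", str(tid), True))
        records = sorted(set(records))
        table = ActivityTable(records)
        threshold = 0.5
        graph = build_homology_graph(
            [TargetProtein(t) for t in tids],
            identity_source="identity_table",
            threshold=threshold,
            identity_table=identities,
        )
        focal = tids[0]
        universe, positives, eligible = brute_force_ercps(
            records, identities, threshold, focal
        )
        if len(universe) < 2:
            with pytest.raises(ValueError):
                enumerate_ercps(table, graph, focal, seed=seed)
            return
        pairs = enumerate_ercps(table, graph, focal, 1.0, seed=seed)
        got_pos = {p.key for p in pairs if p.label == POSITIVE}
        got_neg = {p.key for p in pairs if p.label == NEGATIVE}
        assert got_pos == positives
        assert got_neg <= eligible
        assert len(got_neg) == min(len(positives), len(eligible))


class TestFeaturizePair:
    def test_symmetry(self, rng):
        for _ in range(10):
            a = (rng.random(FP_LEN) < 0.3).astype(np.uint8)
            b = (rng.random(FP_LEN) < 0.3).astype(np.uint8)
            assert np.array_equal(featurize_pair(a, b), featurize_pair(b, a))

    def test_identical_inputs_zero_difference_block(self, rng):
        a = (rng.random(FP_LEN) < 0.3).astype(np.uint8)
        feats = featurize_pair(a, a)
        assert not feats[FP_LEN : 2 * FP_LEN].any()  # XOR block

    def test_scalar_block_contains_tanimoto(self, rng):
        a = (rng.random(FP_LEN) < 0.3).astype(np.uint8)
        b = (rng.random(FP_LEN) < 0.3).astype(np.uint8)
        feats = featurize_pair(a, b)
        assert feats[2 * FP_LEN] == pytest.approx(tanimoto(a, b))

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            featurize_pair(np.zeros(8, dtype=np.uint8), np.zeros(9, dtype=np.uint8))


class TestChemicalPair:
    def test_canonical_ordering(self):
        p = ChemicalPair("b", "a", POSITIVE, "T1")
        assert p.key == ("a", "b")
        assert p == ChemicalPair("a", "b", POSITIVE, "T1")

    def test_self_pair_rejected(self):
        with pytest.raises(ValueError, match="self-pair"):
            ChemicalPair("a", "a", POSITIVE, "T1")


def _separable_training_setup(seed, motif_strength=1.0):
    world = generate_world(
        WorldConfig(
            n_target_families=2,
            targets_per_family=2,
            actives_per_target=5,
            n_decoys=40,
            motif_strength=motif_strength,
            fingerprint_length=256,
            seed=seed,
        )
    )
    graph = build_homology_graph(
        world.targets,
        identity_source="identity_table",
        threshold=0.4,
        identity_table=world.identity_table,
    )
    pairs = enumerate_ercps(world.activities, graph, world.focal_target, seed=seed)
    return world, pairs


class TestTraining:
    def test_separable_world_high_auroc(self):
        world, pairs = _separable_training_setup(seed=11)
        model = train_ecbs_model(
            pairs,
            world.compounds,
            TrainingConfig(ensemble_size=5, n_estimators=30, test_fraction=0.3, seed=11),
        )
        assert model.oos_auroc is not None and model.oos_auroc >= 0.95

    def test_permuted_labels_near_chance(self):
        # permutation null: average held-out AUROC over seeds should sit
        # near 0.5 (single small splits are too noisy to test alone)
        aurocs = []
        for seed in range(5):
            world, pairs = _separable_training_setup(seed=seed)
            rng = np.random.default_rng(seed)
            labels = [p.label for p in pairs]
            rng.shuffle(labels)
            shuffled = [
                ChemicalPair(p.compound_a, p.compound_b, lab, p.context_target)
                for p, lab in zip(pairs, labels)
            ]
            model = train_ecbs_model(
                shuffled,
                world.compounds,
                TrainingConfig(
                    ensemble_size=3, n_estimators=20, test_fraction=0.5, seed=seed
                ),
            )
            if model.oos_auroc is not None:
                aurocs.append(model.oos_auroc)
        assert len(aurocs) >= 3
        assert abs(float(np.mean(aurocs)) - 0.5) <= 0.15

    def test_single_label_errors(self, toy_compounds):
        pairs = [ChemicalPair("c1", "c2", POSITIVE, "T1")]
        with pytest.raises(ValueError, match="both labels"):
            train_ecbs_model(pairs, toy_compounds)

    def test_missing_compound_ids_listed(self, toy_compounds):
        pairs = [
            ChemicalPair("c1", "c2", POSITIVE, "T1"),
            ChemicalPair("c1", "cX", NEGATIVE, "T1"),
        ]
        with pytest.raises(ValueError, match="cX"):
            train_ecbs_model(pairs, toy_compounds)

    def test_reproducible_given_seed(self, rng):
        world, pairs = _separable_training_setup(seed=3)
        cfg = TrainingConfig(ensemble_size=2, n_estimators=10, seed=3)
        m1 = train_ecbs_model(pairs, world.compounds, cfg)
        m2 = train_ecbs_model(pairs, world.compounds, cfg)
        probe_a = (rng.random(256) < 0.3).astype(np.uint8)
        probe_b = (rng.random(256) < 0.3).astype(np.uint8)
        assert m1.score(probe_a, probe_b) == m2.score(probe_a, probe_b)


@pytest.fixture(scope="module")
def small_model():
    world = generate_world(
        WorldConfig(
            actives_per_target=4,
            n_decoys=30,
            fingerprint_length=128,
            seed=42,
        )
    )
    graph = build_homology_graph(
        world.targets,
        identity_source="identity_table",
        threshold=0.4,
        identity_table=world.identity_table,
    )
    pairs = enumerate_ercps(world.activities, graph, world.focal_target, seed=42)
    model = train_ecbs_model(
        pairs,
        world.compounds,
        TrainingConfig(ensemble_size=3, n_estimators=15, test_fraction=0.0, seed=42),
        focal_target=world.focal_target,
    )
    return model


class TestScoring:
    def test_symmetry_and_bounds(self, small_model, rng):
        for _ in range(20):
            a = (rng.random(128) < 0.3).astype(np.uint8)
            b = (rng.random(128) < 0.3).astype(np.uint8)
            s_ab = ecbs_score(small_model, a, b)
            assert s_ab == ecbs_score(small_model, b, a)
            assert 0.0 <= s_ab <= 1.0

    def test_singleton_ensemble_equals_member(self, rng):
        world, pairs = _separable_training_setup(seed=9)
        model = train_ecbs_model(
            pairs,
            world.compounds,
            TrainingConfig(ensemble_size=1, n_estimators=10, test_fraction=0.0, seed=9),
        )
        a = (rng.random(256) < 0.3).astype(np.uint8)
        b = (rng.random(256) < 0.3).astype(np.uint8)
        from ecbscreen.pairs import featurize_pair as fp

        member_prob = model.members[0].predict_proba(fp(a, b)[None, :])[0, 1]
        assert model.score(a, b) == pytest.approx(member_prob, abs=1e-15)

    def test_untrained_model_errors(self, rng):
        with pytest.raises(ValueError, match="no trained"):
            EcbsModel(fingerprint_length=8).score(
                np.zeros(8, dtype=np.uint8), np.zeros(8, dtype=np.uint8)
            )

    def test_fingerprint_length_mismatch_refused(self, small_model):
        with pytest.raises(ValueError, match="length"):
            small_model.score(np.zeros(64, dtype=np.uint8), np.zeros(64, dtype=np.uint8))

    def test_roundtrip_scores_stable(self, small_model, rng, tmp_path):
        path = tmp_path / "model.joblib"
        small_model.save(path)
        loaded = EcbsModel.load(path)
        for _ in range(10):
            a = (rng.random(128) < 0.3).astype(np.uint8)
            b = (rng.random(128) < 0.3).astype(np.uint8)
            assert abs(small_model.score(a, b) - loaded.score(a, b)) <= 1e-12
        assert loaded.focal_target == small_model.focal_target

    def test_corrupt_model_file(self, tmp_path):
        import joblib

        path = tmp_path / "bad.joblib"
        joblib.dump({"not": "a model"}, path)
        with pytest.raises(ValueError, match="corrupt"):
            EcbsModel.load(path)


class TestLearningSanity:
    def test_learned_not_worse_than_tanimoto_baseline(self):
        world, pairs = _separable_training_setup(seed=21)
        model = train_ecbs_model(
            pairs,
            world.compounds,
            TrainingConfig(ensemble_size=5, n_estimators=30, test_fraction=0.0, seed=21),
            focal_target=world.focal_target,
        )
        fps = {c.compound_id: c.fingerprint for c in world.compounds}
        ref_ids = sorted(world.activities.ligands_of(world.focal_target))
        lib = [c for c in world.compounds if c.compound_id not in ref_ids]
        truth = world.ground_truth - set(ref_ids)
        learned, base, flags = [], [], []
        for c in lib:
            learned.append(
                max(model.score(c.fingerprint, fps[r]) for r in ref_ids)
            )
            base.append(max(tanimoto(c.fingerprint, fps[r]) for r in ref_ids))
            flags.append(c.compound_id in truth)
        flags = np.array(flags)
        assert auroc(np.array(learned), flags) >= auroc(np.array(base), flags) - 0.02
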