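"""Fuzzy associative memory: encoding, recall, and the brute-force oracle.

The oracle re-implements max-min composition and centroid defuzzification
from first principles (pure-Python loops, its own membership formulas) and
must agree with the package's vectorized implementation everywhere.
"""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from caninescore.fam import (
    FamModel,
    OUTPUT_SETS,
    component_index,
    defuzzify_centroid,
    encode_output,
    encode_pair,
    fuzzify,
    input_partitions,
    maxmin_compose,
    recall,
    recall_auto,
    reference_model,
    train,
    update_homogeneous,
)
from caninescore.synthetic import make_training_set
from caninescore.taxonomy import BehaviorKind, category_profile
from conftest import level_grid, profile_from_levels, profile_from_row, BREED_ROWS


# ---------------------------------------------------------------------------
# independent oracle
# ---------------------------------------------------------------------------

def oracle_compose(vec, M):
    """Brute-force max-min composition with explicit loops."""
    out = []
    for j in range(len(M[0])):
        best = 0.0
        for i in range(len(vec)):
            m = min(vec[i], M[i][j])
            if m > best:
                best = m
        out.append(best)
    return out


def _oracle_low(z):
    return max(0.0, 1.0 - z / 0.3)


def _oracle_med(z):
    if z <= 0.1 or z >= 0.9:
        return 0.0
    return (z - 0.1) / 0.4 if z <= 0.5 else (0.9 - z) / 0.4


def _oracle_high(z):
    return max(0.0, (z - 0.5) / 0.5)


def oracle_centroid(out):
    """Independent centroid: trapezoid rule on its own grid and formulas."""
    zs = np.linspace(0.0, 1.0, 4001)
    mu = [
        max(min(out[0], _oracle_low(z)),
            min(out[1], _oracle_med(z)),
            min(out[2], _oracle_high(z)))
        for z in zs
    ]
    denom = np.trapezoid(mu, zs)
    if denom == 0:
        return 0.0
    return float(np.trapezoid(np.array(mu) * zs, zs) / denom)


# ---------------------------------------------------------------------------
# fuzzification
# ---------------------------------------------------------------------------

class TestFuzzify:
    def test_bin_core_gives_crisp_membership(self):
        p = category_profile({"scratch": 26, "lick": 3, "swallow": 45, "sleep": 14})
        vec = fuzzify(p)
        idx = component_index()
        for pos, (kind, level, _) in enumerate(idx):
            expected = 1.0 if level == 0 else 0.0
            assert vec[pos] == pytest.approx(expected)

    def test_boundary_memberships_split_and_sum_to_one(self):
        sets = input_partitions()[BehaviorKind.SCRATCH]
        at_boundary = [s(52.5) for s in sets]
        assert at_boundary[0] == pytest.approx(0.5)
        assert at_boundary[1] == pytest.approx(0.5)
        assert sum(at_boundary) == pytest.approx(1.0)

    def test_retriever_profile_activates_often(self):
        vec = fuzzify(profile_from_row(BREED_ROWS["retriever"]))
        idx = component_index()
        pos = next(i for i, (k, lv, lab) in enumerate(idx)
                   if k is BehaviorKind.SCRATCH and lab == "often")
        assert vec[pos] == pytest.approx(1.0)

    @given(st.floats(min_value=0, max_value=500),
           st.floats(min_value=0, max_value=60),
           st.floats(min_value=0, max_value=120),
           st.floats(min_value=0, max_value=24))
    def test_ruspini_partition_sums_to_one(self, scratch, lick, swallow, sleep):
        parts = input_partitions()
        for kind, x in ((BehaviorKind.SCRATCH, scratch),
                        (BehaviorKind.LICK, lick),
                        (BehaviorKind.SWALLOW, swallow),
                        (BehaviorKind.SLEEP, sleep)):
            total = sum(float(s(x)) for s in parts[kind])
            assert total == pytest.approx(1.0, abs=1e-9)


# ---------------------------------------------------------------------------
# storage and recall
# ---------------------------------------------------------------------------

class TestStorage:
    def test_single_pattern_perfect_recall(self):
        vec = np.zeros(14)
        vec[2] = 1.0
        vec[5] = 0.7
        out = encode_output("high")
        model = train([(vec, out)])
        recalled = maxmin_compose(vec, model.matrix())
        assert np.allclose(recalled, out)

    def test_orthogonal_patterns_both_recalled(self):
        a = np.zeros(14); a[0] = 1.0; a[4] = 1.0
        b = np.zeros(14); b[2] = 1.0; b[9] = 1.0
        model = train([(a, "low"), (b, "high")])
        M = model.matrix()
        assert np.allclose(maxmin_compose(a, M), oracle_compose(a, M))
        assert np.allclose(maxmin_compose(a, M), encode_output("low"))
        assert np.allclose(maxmin_compose(b, M), encode_output("high"))

    def test_duplicate_pair_idempotent(self):
        vec = np.zeros(14); vec[3] = 1.0
        once = train([(vec, "high")])
        twice = train([(vec, "high"), (vec, "high")])
        assert np.array_equal(once.matrix(), twice.matrix())

    def test_empty_training_rejected(self):
        with pytest.raises(ValueError):
            train([])

    def test_matrix_entries_bounded(self):
        data = make_training_set(100, 0.5, seed=3)
        model = train([encode_pair(p, lab) for p, lab in data])
        M = model.matrix()
        assert np.all(M >= 0) and np.all(M <= 1)

    def test_json_round_trip(self, tmp_path):
        data = make_training_set(50, 0.5, seed=4)
        model = train([encode_pair(p, lab) for p, lab in data])
        model = update_homogeneous(model, data[0][0])
        path = tmp_path / "fam.json"
        model.to_json(path)
        back = FamModel.from_json(path)
        assert np.array_equal(back.matrix(), model.matrix())
        assert np.array_equal(back.auto, model.auto)


class TestRecall:
    def test_recall_matches_oracle_on_full_grid(self, reference_fam):
        """Vectorized recall == brute-force composition on all 144 profiles."""
        M = reference_fam.matrix()
        for levels in level_grid():
            vec = fuzzify(profile_from_levels(levels))
            mine = maxmin_compose(vec, M)
            assert np.allclose(mine, oracle_compose(vec, M.tolist()), atol=1e-12)
            risk = recall(reference_fam, vec).value
            assert risk == pytest.approx(oracle_centroid(mine), abs=5e-3)

    def test_all_normal_profile_low_risk(self):
        healthy_profiles = [p for p, lab in make_training_set(40, 1.0, seed=6)]
        model = train([encode_pair(p, "healthy") for p in healthy_profiles])
        risk = recall(model, profile_from_levels(
            {k: 0 for k in BehaviorKind}))
        assert risk.value < 0.5

    def test_disease_exemplar_recalls_stored_risk(self):
        """A profile identical to the only stored disease exemplar recalls
        that exemplar's risk (the defuzzified pure-high value)."""
        levels = {BehaviorKind.SCRATCH: 3, BehaviorKind.LICK: 3,
                  BehaviorKind.SWALLOW: 0, BehaviorKind.SLEEP: 0}
        exemplar = profile_from_levels(levels)
        model = train([encode_pair(exemplar, "disease")])
        risk = recall(model, exemplar)
        assert risk.value == pytest.approx(defuzzify_centroid(encode_output("high")),
                                           abs=1e-9)

    def test_empty_support_flags_no_evidence(self):
        model = train([(np.eye(14)[0], "low")])
        risk = recall(model, np.zeros(14))
        assert risk.value == 0.0
        assert risk.no_evidence

    def test_untrained_model_rejected(self):
        with pytest.raises(ValueError):
            recall(FamModel(), np.zeros(14))

    def test_attribution_names_the_symptom(self, reference_fam):
        levels = {BehaviorKind.SCRATCH: 3, BehaviorKind.LICK: 0,
                  BehaviorKind.SWALLOW: 0, BehaviorKind.SLEEP: 0}
        risk = recall(reference_fam, profile_from_levels(levels))
        assert risk.attribution[BehaviorKind.SCRATCH] == pytest.approx(1.0)

    def test_monotone_in_abnormality(self, reference_fam):
        """Raising any one behavior's level never lowers recalled risk."""
        for levels in level_grid():
            base = recall(reference_fam, profile_from_levels(levels)).value
            for kind in BehaviorKind:
                n_levels = 4 if kind in (BehaviorKind.SCRATCH, BehaviorKind.LICK) else 3
                if levels[kind] + 1 >= n_levels:
                    continue
                worse = dict(levels)
                worse[kind] += 1
                worse_risk = recall(reference_fam, profile_from_levels(worse)).value
                assert worse_risk >= base - 1e-9


class TestHomogeneousUpdate:
    def test_idempotent(self):
        p = profile_from_levels({k: 0 for k in BehaviorKind})
        model = train([encode_pair(p, "healthy")])
        once = update_homogeneous(model, p)
        twice = update_homogeneous(once, p)
        assert np.array_equal(once.auto, twice.auto)

    def test_entries_never_decrease(self):
        data = make_training_set(20, 0.5, seed=8)
        model = train([encode_pair(p, lab) for p, lab in data])
        model = update_homogeneous(model, data[0][0])
        before = model.auto.copy()
        model = update_homogeneous(model, data[1][0])
        assert np.all(model.auto >= before)

    def test_recall_membership_grows_after_update(self):
        p = profile_from_levels({k: 0 for k in BehaviorKind})
        vec = fuzzify(p)
        data = make_training_set(10, 0.5, seed=9)
        model = train([encode_pair(q, lab) for q, lab in data])
        model0 = update_homogeneous(model, data[0][0])
        before = recall_auto(model0, vec)
        model1 = update_homogeneous(model0, p)
        after = recall_auto(model1, vec)
        assert np.all(after >= before - 1e-12)
        assert np.all(after >= np.minimum(vec, vec.max()) - 1e-12)


class TestSyntheticRecovery:
    def test_holdout_classification_accuracy(self):
        """Risk thresholding at 0.5 separates held-out healthy/disease labels."""
        train_set = make_training_set(200, 0.5, seed=11)
        model = train([encode_pair(p, lab) for p, lab in train_set])
        held = make_training_set(100, 0.5, seed=12)
        correct = sum(
            ("disease" if recall(model, p).value > 0.5 else "healthy") == lab
            for p, lab in held
        )
        assert correct / len(held) >= 0.9
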