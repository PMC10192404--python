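"""Frequency conversion, component summation and index scoring."""

import math

import pandas as pd
import pytest
from hypothesis import given, strategies as st

from picturesort.diet_scoring import (
    ComponentServings,
    ComponentStandard,
    ScoringError,
    component_servings,
    compute_indices,
    frequency_to_servings,
    score_cohort,
    score_component,
)


def _records(pairs):
    return pd.DataFrame(
        {
            "subject_id": "s",
            "role": "child",
            "timepoint": "baseline",
            "item_id": [p[0] for p in pairs],
            "response": [p[1] for p in pairs],
        }
    )


class TestFrequencyToServings:
    @pytest.mark.parametrize(
        "role,label,expected",
        [
            ("child", "never", 0.0),
            ("child", "sometimes", 0.5),
            ("child", "once a day", 1.0),
            ("child", "more than once per day", 2.0),
            ("adult", "never", 0.0),
            ("adult", "sometimes but not weekly", 0.033),
            ("adult", "weekly", 0.143),  # 1/7 to instrument precision
            ("adult", "every day", 1.0),
            ("adult", "more than once per day", 2.0),
        ],
    )
    def test_mapping(self, dialects, role, label, expected):
        assert frequency_to_servings(label, dialects[role]) == expected

    def test_unknown_label_names_dialect(self, dialects):
        with pytest.raises(ScoringError, match="child"):
            frequency_to_servings("weekly", dialects["child"])


class TestComponentServings:
    def test_all_never_gives_zero(self, registry, dialects):
        pairs = [(it.item_id, "never") for it in registry
                 if not it.is_alcohol]
        cs = component_servings(_records(pairs), registry, dialects["child"])
        assert cs.total_freq == 0 and cs.healthy_freq == 0
        assert cs.fv_excl_juice == 0

    def test_single_fruit_identity(self, registry, dialects):
        cs = component_servings(
            _records([("apple", "once a day")]), registry, dialects["child"]
        )
        assert cs.fruit_excl_juice == 1.0
        assert cs.total_freq == 1.0
        assert cs.healthy_freq == 1.0

    def test_juice_counted_as_ssb_not_fruit(self, registry, dialects):
        cs = component_servings(
            _records([("apple", "once a day"), ("fruit_juice", "once a day")]),
            registry, dialects["child"],
        )
        assert cs.fruit_excl_juice == 1.0
        assert cs.ssb_juice == 1.0
        assert cs.fv_excl_juice == 1.0

    def test_potato_excluded_from_vegetables_but_in_total(
        self, registry, dialects
    ):
        cs = component_servings(
            _records([("potatoes", "once a day")]), registry, dialects["child"]
        )
        assert cs.vegetables == 0.0
        assert cs.total_freq == 1.0
        assert cs.healthy_freq == 0.0

    def test_alcohol_excluded_from_total(self, registry, dialects):
        cs = component_servings(
            _records([("beer", "every day"), ("apple", "every day")]),
            registry, dialects["adult"],
        )
        assert cs.total_freq == 1.0

    def test_salad_flag_drops_salad_from_vegetables(self, registry, dialects):
        rec = _records([("green_salad", "once a day")])
        with_salad = component_servings(rec, registry, dialects["child"])
        without = component_servings(
            rec, registry, dialects["child"], include_salad=False
        )
        assert with_salad.vegetables == 1.0 and with_salad.healthy_freq == 1.0
        assert without.vegetables == 0.0 and without.healthy_freq == 0.0
        assert without.total_freq == 1.0

    def test_empty_records_error(self, registry, dialects):
        with pytest.raises(ScoringError, match="empty"):
            component_servings(_records([]), registry, dialects["child"])


class TestScoreComponent:
    veg = ComponentStandard("vegetables", "positive", 0.0, 5.0)
    ssb = ComponentStandard("ssb_juice", "reverse", 1.0, 0.0)

    def test_boundaries(self):
        assert score_component(0.0, self.veg) == 0.0
        assert score_component(5.0, self.veg) == 10.0
        assert score_component(7.0, self.veg) == 10.0  # clamped

    def test_reverse_scores_ten_at_zero_intake(self):
        assert score_component(0.0, self.ssb) == 10.0
        assert score_component(1.0, self.ssb) == 0.0
        assert score_component(2.0, self.ssb) == 0.0

    def test_linear_interpolation(self):
        assert score_component(2.5, self.veg) == 5.0

    def test_negative_servings_error(self):
        with pytest.raises(ScoringError):
            score_component(-0.1, self.veg)

    def test_equal_cutoffs_rejected(self):
        with pytest.raises(ScoringError):
            ComponentStandard("vegetables", "positive", 1.0, 1.0)


def _servings(**kw):
    base = dict(
        vegetables=0.0, fruit_excl_juice=0.0, whole_grains=0.0,
        nuts_legumes=0.0, ssb_juice=0.0, red_processed_meat=0.0,
        healthy_freq=0.0, total_freq=0.0,
    )
    base.update(kw)
    return ComponentServings(**base)


class TestComputeIndices:
    def test_full_score_intake(self, standards):
        cs = _servings(
            vegetables=5.0, fruit_excl_juice=4.0, whole_grains=1.5,
            nuts_legumes=1.0, healthy_freq=11.5, total_freq=11.5,
        )
        ix = compute_indices(cs, standards)
        assert ix.modified_ahei_total == 60.0
        assert ix.healthy_foods_score == 40.0
        assert ix.fv_score == 20.0

    def test_all_zero_intake_scores_reverse_components(self, standards):
        ix = compute_indices(_servings(), standards)
        assert ix.modified_ahei_total == 20.0  # two reverse components at 10
        assert ix.healthy_foods_score == 0.0
        assert math.isnan(ix.ratio_healthy_total)

    def test_ratio_quarter(self, standards):
        ix = compute_indices(
            _servings(healthy_freq=1.0, total_freq=4.0), standards
        )
        assert ix.ratio_healthy_total == 0.25

    def test_sum_identities(self, standards):
        cs = _servings(
            vegetables=1.0, fruit_excl_juice=2.0, whole_grains=0.5,
            nuts_legumes=0.2, ssb_juice=0.7, red_processed_meat=0.3,
            healthy_freq=3.7, total_freq=4.7,
        )
        ix = compute_indices(cs, standards)
        comp_sum = (
            ix.fruit_score + ix.veg_score + ix.whole_grain_score
            + ix.nuts_legumes_score + ix.ssb_juice_score + ix.red_meat_score
        )
        assert ix.modified_ahei_total == pytest.approx(comp_sum)
        assert ix.fv_score == pytest.approx(ix.fruit_score + ix.veg_score)
        assert ix.healthy_foods_score == pytest.approx(
            ix.fv_score + ix.whole_grain_score + ix.nuts_legumes_score
        )


# ---------------------------------------------------------------------------
# Brute-force oracle: direct summation from the registry table

def brute_force_indices(records, registry, dialect, standards):
    table = {it.item_id: it for it in registry}
    sums = {c: 0.0 for c in
            ["vegetables", "fruit", "whole_grains", "nuts_legumes",
             "ssb_juice", "red_processed_meat"]}
    healthy = total = 0.0
    for _, row in records.iterrows():
        item = table[row["item_id"]]
        s = dialect.servings_per_day[row["response"]]
        if not item.is_alcohol:
            total += s
        if item.ahei_component != "none":
            sums[item.ahei_component] += s
        if item.healthy:
            healthy += s

    def sc(x, comp):
        std = standards[comp]
        span = std.full_score_servings - std.zero_score_servings
        return min(10.0, max(0.0, 10 * (x - std.zero_score_servings) / span))

    scores = {c: sc(v, c) for c, v in sums.items()}
    return {
        "modified_ahei_total": sum(scores.values()),
        "healthy_foods_score": scores["fruit"] + scores["vegetables"]
        + scores["whole_grains"] + scores["nuts_legumes"],
        "fv_score": scores["fruit"] + scores["vegetables"],
        "ratio": healthy / total if total > 0 else math.nan,
    }


@given(st.data())
def test_oracle_equivalence_random_record_sets(data):
    from picturesort.food_registry import default_dialects, default_registry
    from picturesort.diet_scoring import default_standards

    registry = default_registry()
    dialects = default_dialects()
    standards = default_standards()
    role = data.draw(st.sampled_from(["child", "adult"]))
    dialect = dialects[role]
    item_ids = [it.item_id for it in registry if not it.is_alcohol
                or role == "adult"]
    chosen = data.draw(
        st.lists(st.sampled_from(item_ids), min_size=1, max_size=8,
                 unique=True)
    )
    labels = data.draw(
        st.lists(st.sampled_from(list(dialect.categories)),
                 min_size=len(chosen), max_size=len(chosen))
    )
    records = _records(list(zip(chosen, labels)))
    cs = component_servings(records, registry, dialect)
    ix = compute_indices(cs, standards)
    expected = brute_force_indices(records, registry, dialect, standards)
    assert ix.modified_ahei_total == pytest.approx(
        expected["modified_ahei_total"], abs=1e-12
    )
    assert ix.healthy_foods_score == pytest.approx(
        expected["healthy_foods_score"], abs=1e-12
    )
    assert ix.fv_score == pytest.approx(expected["fv_score"], abs=1e-12)
    if math.isnan(expected["ratio"]):
        assert math.isnan(ix.ratio_healthy_total)
    else:
        assert ix.ratio_healthy_total == pytest.approx(expected["ratio"])


# ---------------------------------------------------------------------------
# Invariants

@given(st.data())
def test_monotonicity_and_bounds(data):
    """Adding a healthy serving never hurts the healthy indices; adding a
    sugary drink never raises the AHEI; scores stay in their ranges."""
    from picturesort.food_registry import default_dialects, default_registry
    from picturesort.diet_scoring import default_standards

    registry = default_registry()
    dialect = default_dialects()["child"]
    standards = default_standards()
    items = [it.item_id for it in registry if not it.is_alcohol]
    n = data.draw(st.integers(min_value=1, max_value=len(items)))
    labels = data.draw(
        st.lists(st.sampled_from(list(dialect.categories)),
                 min_size=n, max_size=n)
    )
    pairs = list(zip(items[:n], labels))
    base_ix = compute_indices(
        component_servings(_records(pairs), registry, dialect), standards
    )
    assert 0 <= base_ix.modified_ahei_total <= 60
    assert 0 <= base_ix.healthy_foods_score <= 40
    for comp_score in (base_ix.fruit_score, base_ix.veg_score,
                       base_ix.ssb_juice_score, base_ix.red_meat_score):
        assert 0 <= comp_score <= 10

    def bump(pairs, item_id):
        order = list(dialect.categories)
        out, seen = [], False
        for iid, lab in pairs:
            if iid == item_id:
                seen = True
                lab = order[min(order.index(lab) + 1, len(order) - 1)]
            out.append((iid, lab))
        if not seen:
            out.append((item_id, order[1]))
        return out

    bumped_h = compute_indices(
        component_servings(_records(bump(pairs, "apple")), registry, dialect),
        standards,
    )
    assert bumped_h.healthy_foods_score >= base_ix.healthy_foods_score
    assert bumped_h.fv_score >= base_ix.fv_score
    assert (
        bumped_h.servings.healthy_freq >= base_ix.servings.healthy_freq
    )
    bumped_s = compute_indices(
        component_servings(_records(bump(pairs, "soda")), registry, dialect),
        standards,
    )
    assert bumped_s.modified_ahei_total <= base_ix.modified_ahei_total


def test_score_cohort_matches_per_subject_path(cohort, registry, dialects,
                                               standards):
    """The vectorised cohort scorer equals the scalar API subject by subject."""
    wide = score_cohort(cohort.responses, registry, dialects, standards)
    sample = wide.sample(8, random_state=0)
    for row in sample.itertuples():
        sub = cohort.responses[
            (cohort.responses["subject_id"] == row.subject_id)
            & (cohort.responses["timepoint"] == row.timepoint)
        ]
        ix = compute_indices(
            component_servings(sub, registry, dialects[row.role]), standards
        )
        assert row.modified_ahei_total == pytest.approx(ix.modified_ahei_total)
        assert row.healthy_foods_score == pytest.approx(ix.healthy_foods_score)
        if math.isnan(ix.ratio_healthy_total):
            assert math.isnan(row.ratio_healthy_total)
        else:
            assert row.ratio_healthy_total == pytest.approx(
                ix.ratio_healthy_total
            )
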