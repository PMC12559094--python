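"""Matched balanced construction, random control sampling, overlap, strata."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy.stats import chisquare

from radbalance.sampler import (
    MatchingConfig,
    MatchingError,
    TestSetSplit,
    build_balanced_set,
    build_random_set,
    compute_overlap,
    exclude_uncertain,
    read_split,
    stratify,
    write_pairs,
    write_split,
)
from radbalance.synthetic import generate_cohort, table2_defaults

from _oracles import perfect_matching_exists
from conftest import make_record


# ---------------------------------------------------------------------------
# exclusion

def test_exclude_uncertain_cases():
    clean = [make_record(f"a{i}") for i in range(4)]
    assert exclude_uncertain(clean) == clean
    assert exclude_uncertain([make_record("u", uncertain=True)]) == []
    mixed = [make_record(f"m{i}", uncertain=i in (1, 4, 7)) for i in range(10)]
    kept = exclude_uncertain(mixed)
    assert [r.image_id for r in kept] == [f"m{i}" for i in range(10) if i not in (1, 4, 7)]


# ---------------------------------------------------------------------------
# balanced construction

def test_balanced_toy_pool_hand_trace(toy_pool):
    split, pairs = build_balanced_set(toy_pool, MatchingConfig(anchor_order_seed=0))
    assert sorted(split.image_ids) == sorted(r.image_id for r in toy_pool)
    assert len(split) == 8 and len(pairs) == 6  # 2 stage-1 pairs + 4 stage-2 pairs
    stage1 = [p for p in pairs if p.stage == "difficult_to_easy"]
    assert {p.anchor_id for p in stage1} == {"d1", "d2"}
    assert {p.match_id for p in stage1} == {"e1", "e2"}
    # nearest-age: d1 (10.0) -> e1 (10.2), d2 (10.4) -> e2 (10.6) regardless of order
    by_anchor = {p.anchor_id: p.match_id for p in stage1}
    assert by_anchor == {"d1": "e1", "d2": "e2"}


def test_balanced_unmatched_anchor_is_named_error():
    pool = [
        make_record("lonely", fracture=True, difficulty="difficult", projection="oblique"),
        make_record("easy_ap", fracture=True, difficulty="easy", projection="ap"),
        make_record("ctrl", projection="oblique"),
    ]
    with pytest.raises(MatchingError, match="lonely.*difficult_to_easy"):
        build_balanced_set(pool)


def test_balanced_uncertain_images_never_selected():
    pool = [
        make_record("d", fracture=True, difficulty="difficult", age=10.0),
        make_record("e_unc", fracture=True, difficulty="easy", age=10.0, uncertain=True),
        make_record("e", fracture=True, difficulty="easy", age=10.9),
        make_record("c1", age=10.0),
        make_record("c2", age=10.9),
    ]
    split, _ = build_balanced_set(pool)
    assert "e_unc" not in split.image_ids and len(split) == 4


def test_balanced_caliper_enforced():
    pool = [
        make_record("d", fracture=True, difficulty="difficult", age=10.0),
        make_record("far", fracture=True, difficulty="easy", age=11.5),
        make_record("c1", age=10.0),
        make_record("c2", age=10.5),
    ]
    with pytest.raises(MatchingError):
        build_balanced_set(pool, MatchingConfig(age_caliper=1.0))
    split, _ = build_balanced_set(pool, MatchingConfig(age_caliper=2.0))
    assert len(split) == 4


def test_balanced_age_tie_broken_by_id():
    pool = [
        make_record("anchor", fracture=True, difficulty="difficult", age=10.0),
        make_record("zz", fracture=True, difficulty="easy", age=10.5),
        make_record("aa", fracture=True, difficulty="easy", age=9.5),
        make_record("c1", age=10.0),
        make_record("c2", age=10.0),
    ]
    _, pairs = build_balanced_set(pool)
    stage1 = [p for p in pairs if p.stage == "difficult_to_easy"]
    assert stage1[0].match_id == "aa"  # equidistant: lexicographically smaller id wins


def test_balanced_composition_invariants_on_synthetic_pools():
    """Whenever matching succeeds with A anchors: |set| = 4A, 2A fractures, A difficult,
    distinct ids, every pair respecting projection equality and the caliper."""
    from radbalance.experiment import build_study_pool

    cfg = table2_defaults(n_images=3000, seed=21)
    cfg.p_projection = (0.5, 0.5, 0.0)  # keep the toy pool free of scarce projections
    pool, split, pairs = build_study_pool(cfg, MatchingConfig(anchor_order_seed=1))
    by_id = {r.image_id: r for r in pool}
    a = sum(
        1
        for r in exclude_uncertain(pool)
        if r.fracture and r.difficulty == "difficult"
    )
    assert len(split) == 4 * a == len(set(split.image_ids))
    recs = [by_id[i] for i in split.image_ids]
    assert sum(r.fracture for r in recs) == 2 * a
    assert sum(r.difficulty == "difficult" for r in recs) == a
    assert not any(r.diagnosis_uncertain for r in recs)
    for p in pairs:
        ra, rm = by_id[p.anchor_id], by_id[p.match_id]
        assert ra.projection == rm.projection == p.projection
        assert abs(ra.patient_age - rm.patient_age) == pytest.approx(p.age_delta)
        assert p.age_delta <= 1.0 + 1e-9
    # match ids are globally distinct (matching without replacement)
    match_ids = [p.match_id for p in pairs]
    assert len(match_ids) == len(set(match_ids))


def test_balanced_max_anchors_caps_set_size():
    cfg = table2_defaults(n_images=3000, seed=5)
    cfg.p_projection = (0.5, 0.5, 0.0)
    pool = generate_cohort(cfg)
    split, _ = build_balanced_set(pool, MatchingConfig(anchor_order_seed=2), max_anchors=50)
    assert len(split) == 200
    with pytest.raises(MatchingError, match="only"):
        build_balanced_set(pool, max_anchors=10**6)


def test_balanced_deterministic_given_seed(toy_pool):
    s1, _ = build_balanced_set(toy_pool, MatchingConfig(anchor_order_seed=3))
    s2, _ = build_balanced_set(toy_pool, MatchingConfig(anchor_order_seed=3))
    assert s1.image_ids == s2.image_ids


def test_greedy_matching_vs_exhaustive_oracle(rng):
    """On tiny pools: greedy success implies a perfect matching exists; when no
    perfect matching exists under the caliper, greedy must report failure."""
    n_success = n_fail = 0
    for trial in range(250):
        k = int(rng.integers(1, 4))
        m = int(rng.integers(0, 5))
        anchors = [
            make_record(
                f"d{t}",
                fracture=True,
                difficulty="difficult",
                age=float(np.round(rng.uniform(5, 9), 1)),
                projection=str(rng.choice(["ap", "lateral"])),
            )
            for t in range(k)
        ]
        easies = [
            make_record(
                f"e{t}",
                fracture=True,
                difficulty="easy",
                age=float(np.round(rng.uniform(5, 9), 1)),
                projection=str(rng.choice(["ap", "lateral"])),
            )
            for t in range(m)
        ]
        # ample exact-age controls so stage 2 never interferes with the stage-1 oracle
        controls = [
            make_record(f"c{t}_{r.image_id}", age=r.patient_age, projection=r.projection)
            for t in range(2)
            for r in anchors + easies
        ]
        pool = anchors + easies + controls
        feasible = perfect_matching_exists(anchors, easies, caliper=1.0)
        try:
            split, _ = build_balanced_set(pool, MatchingConfig(anchor_order_seed=trial))
            assert feasible, "greedy succeeded although no perfect matching exists"
            assert len(split) == 4 * k
            n_success += 1
        except MatchingError:
            n_fail += 1
    assert n_success > 20 and n_fail > 20  # both branches genuinely exercised


# ---------------------------------------------------------------------------
# random control set

def test_random_set_boundaries():
    pool = [make_record(f"r{i}") for i in range(12)]
    full = build_random_set(pool, 12, seed=0)
    assert sorted(full.image_ids) == sorted(r.image_id for r in pool)
    assert build_random_set(pool, 0, seed=0).image_ids == []
    with pytest.raises(ValueError):
        build_random_set(pool, 13, seed=0)


def test_random_set_excludes_uncertain_and_is_seeded():
    pool = [make_record(f"r{i}", uncertain=(i % 3 == 0)) for i in range(30)]
    s = build_random_set(pool, 10, seed=4)
    assert all(not int(i[1:]) % 3 == 0 for i in s.image_ids)
    assert s.image_ids == build_random_set(pool, 10, seed=4).image_ids
    assert s.image_ids != build_random_set(pool, 10, seed=5).image_ids


def test_random_set_fracture_fraction_hypergeometric():
    """A 4588-image draw from a 20,000-image natural-frequency pool keeps the
    pool's fracture fraction to within 3 hypergeometric standard errors."""
    pool = generate_cohort(table2_defaults(n_images=20000, seed=9))
    eligible = exclude_uncertain(pool)
    p_pool = np.mean([r.fracture for r in eligible])
    n = 4588
    s = build_random_set(pool, n, seed=10)
    ids = set(s.image_ids)
    p_sample = np.mean([r.fracture for r in eligible if r.image_id in ids])
    fpc = (len(eligible) - n) / (len(eligible) - 1)
    se = math.sqrt(p_pool * (1 - p_pool) / n * fpc)
    assert abs(p_sample - p_pool) < 3 * se


def test_random_set_distributional_neutrality():
    """Aggregated over 100 seeds, per-category draw frequencies match the pool
    (chi-square goodness-of-fit not rejected at alpha = 0.01)."""
    pool = generate_cohort(table2_defaults(n_images=2000, seed=14))
    eligible = exclude_uncertain(pool)
    by_id = {r.image_id: r for r in eligible}
    cats = ["ap", "lateral", "oblique"]
    pool_freq = np.array([np.mean([r.projection == c for r in eligible]) for c in cats])
    agg = np.zeros(3)
    n_draw = 400
    for seed in range(100):
        s = build_random_set(pool, n_draw, seed=seed)
        for i in s.image_ids:
            agg[cats.index(by_id[i].projection)] += 1
    expected = pool_freq * agg.sum()
    keep = expected > 5  # chi-square validity for the tiny oblique cell
    stat, p = chisquare(agg[keep], expected[keep] * agg[keep].sum() / expected[keep].sum())
    assert p > 0.01


# ---------------------------------------------------------------------------
# overlap + strata

def test_overlap_idempotent_disjoint_and_intersection():
    a = TestSetSplit(label="custom", image_ids=["1", "2", "3"])
    b = TestSetSplit(label="custom", image_ids=["2", "3", "4"])
    assert compute_overlap(a, a).image_ids == ["1", "2", "3"]
    assert compute_overlap(a, TestSetSplit(label="custom", image_ids=["9"])).image_ids == []
    ov = compute_overlap(a, b)
    assert ov.image_ids == ["2", "3"] and ov.label == "overlap"


def test_stratify_partition_and_counts():
    records = (
        [make_record(f"e{i}", fracture=True, difficulty="easy") for i in range(254)]
        + [make_record(f"d{i}", fracture=True, difficulty="difficult") for i in range(273)]
        + [make_record(f"n{i}") for i in range(495)]
    )
    split = TestSetSplit(label="overlap", image_ids=[r.image_id for r in records])
    strata = stratify(split, records)
    assert len(strata["easy_fracture"]) == 254
    assert len(strata["difficult_fracture"]) == 273
    assert len(strata["no_fracture"]) == 495
    # conservation: disjoint union equals the split
    all_ids = strata["easy_fracture"] + strata["difficult_fracture"] + strata["no_fracture"]
    assert sorted(all_ids) == sorted(split.image_ids)
    assert len(set(all_ids)) == len(all_ids)


def test_stratify_edge_cases():
    records = [make_record(f"n{i}") for i in range(5)]
    split = TestSetSplit(label="custom", image_ids=[r.image_id for r in records])
    strata = stratify(split, records)
    assert len(strata["no_fracture"]) == 5
    assert strata["easy_fracture"] == [] and strata["difficult_fracture"] == []
    empty = stratify(TestSetSplit(label="custom", image_ids=[]), records)
    assert all(v == [] for v in empty.values())
    with pytest.raises(KeyError):
        stratify(TestSetSplit(label="custom", image_ids=["ghost"]), records)


def test_split_csv_roundtrip(tmp_path, toy_pool):
    split, pairs = build_balanced_set(toy_pool)
    write_split(split, tmp_path / "s.csv")
    back = read_split(tmp_path / "s.csv")
    assert back.image_ids == split.image_ids and back.label == "balanced"
    write_pairs(pairs, tmp_path / "p.csv")
    assert len((tmp_path / "p.csv").read_text().splitlines()) == len(pairs) + 1
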