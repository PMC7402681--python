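"""Tests for camouflaging, enrichment, Fisher r-to-z, contrast PLS and the
synthetic cohort generator."""

import math

import numpy as np
import pandas as pd
import pytest

from eispec import (
    CohortSpec,
    camouflage_score,
    enrichment_test,
    fisher_rz_compare,
    generate_synthetic_cohort,
    pls_group_contrast,
)


# ---------------------------------------------------------------------------
# camouflaging
# ---------------------------------------------------------------------------

def _aut_table(aq, ados, rmet):
    return pd.DataFrame({
        "id": [f"s{i}" for i in range(len(aq))],
        "diagnosis": ["autism"] * len(aq),
        "AQ": aq, "ADOS_SC": ados, "RMET": rmet,
    })


def test_perfectly_correlated_components_give_symmetric_scores():
    """CF1 = CF2 = (+1, +1, -1, -1) pattern: CF is (+c, +c, -c, -c) with
    full variance on the first component."""
    # S_ADOS = 0 (constant), S_AQ = +-1, -S_RMET = +-1
    t = _aut_table(aq=[50, 50, -50, -50], ados=[5, 5, 5, 5],
                   rmet=[-36, -36, 36, 36])
    cs = camouflage_score(t)
    cf = cs.table["CF"].to_numpy()
    assert cf[0] == pytest.approx(cf[1])
    assert cf[2] == pytest.approx(-cf[0])
    assert cf[0] > 0
    assert cs.variance_explained == pytest.approx(1.0)


def test_identical_subjects_rejected():
    t = _aut_table([30] * 4, [8] * 4, [20] * 4)
    with pytest.raises(ValueError):
        camouflage_score(t)
    with pytest.raises(ValueError):
        camouflage_score(t.iloc[:2])  # fewer than 3 subjects


def test_nearly_collinear_components_share_first_pc():
    rng = np.random.default_rng(0)
    n = 200
    base = rng.standard_normal(n)
    aq = 30 + 15 * base
    ados = 8 + rng.standard_normal(n) * 0.3
    rmet = 20 - 30 * base * (36.0 / 50.0) + rng.standard_normal(n) * 0.2
    cs = camouflage_score(_aut_table(aq, ados, rmet))
    assert cs.variance_explained > 0.9
    mean_cf = (
        (cs.table["CF1"] - cs.table["CF1"].mean()) / cs.table["CF1"].std()
        + (cs.table["CF2"] - cs.table["CF2"].mean()) / cs.table["CF2"].std()
    )
    r = np.corrcoef(cs.table["CF"], mean_cf)[0, 1]
    assert r > 0.99


def test_camouflage_invariant_to_instrument_offset():
    rng = np.random.default_rng(1)
    aq = rng.uniform(20, 45, 30)
    ados = rng.uniform(2, 14, 30)
    rmet = rng.uniform(15, 30, 30)
    a = camouflage_score(_aut_table(aq, ados, rmet))
    b = camouflage_score(_aut_table(aq + 5.0, ados, rmet))
    assert np.allclose(a.table["CF"], b.table["CF"], atol=1e-10)


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def _genes(n, prefix="G"):
    return [f"{prefix}{i}" for i in range(n)]


def _hypergeom_tail_by_summation(n, k_b, k_a, overlap):
    """Direct summation of the hypergeometric pmf, P(X >= overlap)."""
    total = 0.0
    for x in range(overlap, min(k_a, k_b) + 1):
        total += (
            math.comb(k_b, x) * math.comb(n - k_b, k_a - x) / math.comb(n, k_a)
        )
    return total


def test_enrichment_matches_exhaustive_summation_small_backgrounds():
    """Agreement with direct tail summation over every feasible
    (|A|, |B|, overlap) combination for a small background."""
    n = 12
    genes = _genes(n)
    for ka in range(0, n + 1):
        for kb in range(0, n + 1):
            for ov in range(max(0, ka + kb - n), min(ka, kb) + 1):
                a = genes[:ov] + _genes(ka - ov, "A")
                b = genes[:ov] + _genes(kb - ov, "B")
                # rebuild within the same universe
                a = genes[:ka] if ov == ka else genes[:ov] + genes[kb : kb + ka - ov]
                b = genes[:kb]
                if len(set(a)) != ka or len(set(a) & set(b)) != ov:
                    continue
                res = enrichment_test(a, b, n)
                expect = _hypergeom_tail_by_summation(n, kb, ka, res.overlap)
                assert res.p_value == pytest.approx(expect, rel=1e-9)


def test_enrichment_worked_example():
    genes = _genes(100)
    a = genes[:5] + _genes(5, "A")
    b = genes[:5] + _genes(15, "B")
    res = enrichment_test(a, b, 100)
    assert res.overlap == 5
    assert res.table.sum() == 100
    expect = _hypergeom_tail_by_summation(100, 20, 10, 5)
    assert res.p_value == pytest.approx(expect, rel=1e-9)
    n11, n12 = res.table[0]
    n21, n22 = res.table[1]
    assert res.odds_ratio == pytest.approx(n11 * n22 / (n12 * n21))


def test_enrichment_zero_overlap():
    res = enrichment_test(_genes(10, "A"), _genes(20, "B"), 100)
    assert res.overlap == 0
    assert res.odds_ratio == 0.0
    assert res.p_value == pytest.approx(1.0)


def test_enrichment_identical_sets_extreme_tail():
    genes = _genes(10)
    res = enrichment_test(genes, genes, 100)
    assert res.infinite_or and np.isinf(res.odds_ratio)
    assert res.p_value == pytest.approx(1.0 / math.comb(100, 10), rel=1e-9)


def test_enrichment_case_normalization_and_validation():
    res = enrichment_test(["BDNF", "gad1"], ["bdnf", "GAD1"], 50)
    assert res.overlap == 2
    with pytest.raises(ValueError):
        enrichment_test(_genes(60), _genes(5), 50)


# ---------------------------------------------------------------------------
# Fisher r-to-z
# ---------------------------------------------------------------------------

def test_fisher_rz_published_magnitude():
    z, p = fisher_rz_compare(0.60, 25, -0.10, 23)
    assert z == pytest.approx(2.58, abs=0.05)
    assert p == pytest.approx(0.0099, abs=2e-3)


def test_fisher_rz_equal_correlations_and_antisymmetry():
    z, p = fisher_rz_compare(0.42, 30, 0.42, 50)
    assert z == 0.0 and p == pytest.approx(1.0)
    z1, _ = fisher_rz_compare(0.6, 25, -0.1, 23)
    z2, _ = fisher_rz_compare(-0.1, 23, 0.6, 25)
    assert z1 == pytest.approx(-z2)


def test_fisher_rz_grows_with_sample_size():
    zs = [abs(fisher_rz_compare(0.5, n, 0.2, n)[0]) for n in (10, 30, 100)]
    assert zs[0] < zs[1] < zs[2]
    with pytest.raises(ValueError):
        fisher_rz_compare(0.5, 3, 0.2, 30)
    with pytest.raises(ValueError):
        fisher_rz_compare(1.0, 10, 0.2, 30)


# ---------------------------------------------------------------------------
# contrast PLS
# ---------------------------------------------------------------------------

def _groups(n_per):
    out = []
    for g in ("TD_M", "autism_M", "TD_F", "autism_F"):
        out += [g] * n_per
    return np.array(out)


def test_pls_perfectly_coded_parcel_dominates():
    rng = np.random.default_rng(0)
    groups = _groups(4)
    coding = {"TD_M": 1.0, "autism_M": -1.0, "TD_F": -1.0, "autism_F": 1.0}
    x = 0.05 * rng.standard_normal((16, 10))
    x[:, 3] = [coding[g] for g in groups]
    res = pls_group_contrast(x, groups, n_perm=199, n_boot=50, seed=1)
    assert np.argmax(np.abs(res.saliences[0])) == 3
    assert res.perm_p[0] == pytest.approx(1.0 / 200.0)
    assert res.top_mask[0, 3]


def test_pls_saliences_unit_norm_and_parcel_order_invariance():
    rng = np.random.default_rng(2)
    groups = _groups(6)
    x = rng.standard_normal((24, 12))
    res = pls_group_contrast(x, groups, n_perm=150, n_boot=50, seed=3)
    assert np.linalg.norm(res.saliences[0]) == pytest.approx(1.0, abs=1e-8)
    perm_cols = rng.permutation(12)
    res2 = pls_group_contrast(x[:, perm_cols], groups, n_perm=150, n_boot=50, seed=3)
    assert res2.perm_p[0] == pytest.approx(res.perm_p[0], abs=0.02)
    assert np.abs(res2.saliences[0]) == pytest.approx(
        np.abs(res.saliences[0][perm_cols]), abs=1e-10
    )


def test_pls_type_one_error_controlled_on_null_cohorts():
    """No group effect: LV significance at alpha = 0.05 in at most 10% of
    seeds (50 seeds, 200 permutations)."""
    false_pos = 0
    for seed in range(50):
        spec = CohortSpec(
            n_per_group={g: 15 for g in ("TD_M", "autism_M", "TD_F", "autism_F")},
            n_parcels=40, affected=(), male_d=0.0, female_d=0.0,
        )
        t = generate_synthetic_cohort(spec, seed=seed)
        x = t.filter(like="parcel_").to_numpy()
        groups = np.array([
            ("TD" if d == "TD" else "autism") + "_" + s
            for d, s in zip(t["diagnosis"], t["sex"])
        ])
        res = pls_group_contrast(x, groups, n_perm=200, n_boot=2, seed=seed)
        false_pos += res.perm_p[0] < 0.05
    assert false_pos <= 5


def test_pls_recovers_planted_interaction_parcels():
    """Interaction planted in 20 of 100 parcels: LV significant and >= 70%
    of planted parcels inside the top-20% BSR mask, in >= 80% of seeds."""
    hits = 0
    for seed in range(20):
        spec = CohortSpec(
            n_per_group={g: 25 for g in ("TD_M", "autism_M", "TD_F", "autism_F")},
            n_parcels=100, affected=tuple(range(20)), male_d=1.0, female_d=0.0,
        )
        t = generate_synthetic_cohort(spec, seed=seed)
        x = t.filter(like="parcel_").to_numpy()
        groups = np.array([
            ("TD" if d == "TD" else "autism") + "_" + s
            for d, s in zip(t["diagnosis"], t["sex"])
        ])
        res = pls_group_contrast(x, groups, n_perm=200, n_boot=200, seed=seed)
        recovery = res.top_mask[0][:20].mean()
        hits += (res.perm_p[0] < 0.05) and (recovery >= 0.7)
    assert hits >= 16


def test_pls_input_validation():
    groups = _groups(3)
    x = np.random.default_rng(1).standard_normal((12, 5))
    with pytest.raises(ValueError):
        pls_group_contrast(x, groups, contrast=(1.0, 1.0, -1.0, 1.0))
    with pytest.raises(ValueError):
        pls_group_contrast(x[:6], groups[:6])


# ---------------------------------------------------------------------------
# synthetic cohort generator
# ---------------------------------------------------------------------------

def test_null_generator_has_no_group_difference():
    nonsig = 0
    from scipy import stats

    for seed in range(50):
        spec = CohortSpec(
            n_per_group={g: 12 for g in ("TD_M", "autism_M", "TD_F", "autism_F")},
            n_parcels=20, affected=(), male_d=0.0, female_d=0.0,
        )
        t = generate_synthetic_cohort(spec, seed=seed)
        pooled = t.filter(like="parcel_").to_numpy().mean(axis=1)
        td = pooled[(t["diagnosis"] == "TD").to_numpy()]
        aut = pooled[(t["diagnosis"] == "autism").to_numpy()]
        nonsig += stats.ttest_ind(td, aut).pvalue > 0.05
    assert nonsig >= 45


def test_planted_male_effect_size_recovered():
    hits = 0
    for seed in range(50):
        spec = CohortSpec(
            n_per_group={g: 30 for g in ("TD_M", "autism_M", "TD_F", "autism_F")},
            n_parcels=5, affected=(0,), male_d=1.3, female_d=0.0,
        )
        t = generate_synthetic_cohort(spec, seed=seed)
        males = t[t["sex"] == "M"]
        td = males.loc[males["diagnosis"] == "TD", "parcel_000"]
        aut = males.loc[males["diagnosis"] == "autism", "parcel_000"]
        sp = np.sqrt((td.var(ddof=1) + aut.var(ddof=1)) / 2)
        d = (td.mean() - aut.mean()) / sp
        hits += 0.8 <= d <= 1.8
    assert hits >= 45


def test_female_camouflage_correlation_in_target_range():
    hits = 0
    for seed in range(50):
        spec = CohortSpec(
            n_per_group={g: 25 for g in ("TD_M", "autism_M", "TD_F", "autism_F")},
            n_parcels=10, affected=(0,), female_r=0.6,
        )
        t = generate_synthetic_cohort(spec, seed=seed)
        cs = camouflage_score(t)
        aut = t[t["diagnosis"] == "autism"]
        fem = (aut["sex"] == "F").to_numpy()
        r = np.corrcoef(
            aut["parcel_000"].to_numpy()[fem], cs.table["CF"].to_numpy()[fem]
        )[0, 1]
        hits += 0.3 <= r <= 0.8
    assert hits >= 45


def test_generator_validation():
    with pytest.raises(ValueError):
        generate_synthetic_cohort(CohortSpec(affected=(999,)), seed=0)
    with pytest.raises(ValueError):
        generate_synthetic_cohort(CohortSpec(female_r=1.0), seed=0)
    bad = CohortSpec(n_per_group={"TD_M": 2, "autism_M": 23, "TD_F": 33, "autism_F": 25})
    with pytest.raises(ValueError):
        generate_synthetic_cohort(bad, seed=0)


def test_generator_is_seeded():
    a = generate_synthetic_cohort(seed=9)
    b = generate_synthetic_cohort(seed=9)
    pd.testing.assert_frame_equal(a, b)


# ---------------------------------------------------------------------------
# property-based invariants
# ---------------------------------------------------------------------------

from hypothesis import given, settings, strategies as st


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    r1=st.floats(min_value=-0.99, max_value=0.99),
    r2=st.floats(min_value=-0.99, max_value=0.99),
    n1=st.integers(min_value=4, max_value=500),
    n2=st.integers(min_value=4, max_value=500),
)
def test_fisher_rz_antisymmetry_and_p_range(r1, r2, n1, n2):
    z, p = fisher_rz_compare(r1, n1, r2, n2)
    z_swapped, p_swapped = fisher_rz_compare(r2, n2, r1, n1)
    assert z == pytest.approx(-z_swapped, abs=1e-12)
    assert p == pytest.approx(p_swapped, abs=1e-12)
    assert 0.0 <= p <= 1.0
    if r1 == r2:
        assert z == 0.0


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    n=st.integers(min_value=2, max_value=40),
    ka=st.integers(min_value=0, max_value=40),
    kb=st.integers(min_value=0, max_value=40),
    data=st.data(),
)
def test_enrichment_p_value_bounds_property(n, ka, kb, data):
    ka, kb = min(ka, n), min(kb, n)
    ov = data.draw(st.integers(min_value=max(0, ka + kb - n), max_value=min(ka, kb)))
    genes = [f"G{i}" for i in range(n)]
    a = genes[:ov] + genes[kb : kb + ka - ov]
    b = genes[:kb]
    if len(a) != ka:
        return
    res = enrichment_test(a, b, n)
    assert 0.0 < res.p_value <= 1.0
    assert res.table.sum() == n
    assert res.overlap == ov
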