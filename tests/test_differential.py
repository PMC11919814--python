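"""Two-group differential testing, BH correction, grids, and ranking."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lipidomix.characterization import aggregate_by_characteristic, characterize
from lipidomix.differential import (
    DifferentialResult,
    differential_characteristic,
    differential_species,
    dual_characteristic_grid,
    top_k_table,
)
from lipidomix.nomenclature import parse_lipid_name

from conftest import make_experiment


def bh_stepup_oracle(pvals):
    """Brute-force Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_end in range(m, 0, -1):
        i = order[rank_from_end - 1]
        running_min = min(running_min, p[i] * m / rank_from_end)
        adj[i] = running_min
    return np.minimum(adj, 1.0)


def test_welch_t_matches_closed_form_3v3(toy_experiment):
    (res,) = differential_species(toy_experiment)
    assert res.log2_fc == pytest.approx(3.0)
    # hand computation: means 5 vs 2, each sample variance 1, n=3
    t = 3.0 / math.sqrt(1.0 / 3 + 1.0 / 3)
    df = (1.0 / 3 + 1.0 / 3) ** 2 / ((1.0 / 3) ** 2 / 2 + (1.0 / 3) ** 2 / 2)
    assert res.statistic == pytest.approx(t)
    assert res.p_value == pytest.approx(2 * stats.t.sf(t, df))
    assert res.fdr == res.p_value  # single feature


def test_identical_groups_are_ns():
    exp = make_experiment({"TAG 48:0": [1, 2, 3, 1, 2, 3]}, 3, 3)
    (res,) = differential_species(exp)
    assert res.log2_fc == 0.0
    assert res.direction == "ns"


def test_label_swap_antisymmetry(rng):
    values = pd.DataFrame(
        rng.normal(size=(30, 12)), index=[f"PC {20 + 2 * i}:1" for i in range(30)]
    )
    exp = make_experiment(values, 6, 6)
    fwd = differential_species(exp)
    rev = differential_species(exp.swap_groups())
    for a, b in zip(fwd, rev):
        assert a.log2_fc == pytest.approx(-b.log2_fc, abs=0)
        assert a.p_value == pytest.approx(b.p_value, abs=1e-12)
    up_fwd = {r.feature for r in fwd if r.direction == "up"}
    down_rev = {r.feature for r in rev if r.direction == "down"}
    assert up_fwd == down_rev


def test_zero_variance_falls_back_to_exact_permutation_p():
    exp = make_experiment({"TAG 48:0": [5, 5, 5, 2, 2, 2]}, 3, 3)
    (res,) = differential_species(exp)
    assert res.note == "zero_variance_exact_fallback"
    assert res.p_value == pytest.approx(2.0 / math.comb(6, 3))  # 0.1
    assert res.statistic > 0


def test_wilcoxon_exact_on_separated_groups():
    exp = make_experiment({"TAG 48:0": [4, 5, 6, 7, 1, 2, 2.5, 3]}, 4, 4)
    (res,) = differential_species(exp, test="wilcoxon")
    # perfectly separated 4v4: exact two-sided rank-sum p = 2/C(8,4)
    assert res.p_value == pytest.approx(2.0 / math.comb(8, 4))


def test_bh_matches_stepup_oracle_on_random_vectors(rng):
    from statsmodels.stats.multitest import multipletests

    for _ in range(1000):
        m = int(rng.integers(1, 40))
        p = rng.uniform(size=m)
        ours = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(ours, bh_stepup_oracle(p), atol=1e-12)


def test_fdr_never_below_p(rng):
    values = pd.DataFrame(
        rng.normal(size=(50, 8)), index=[f"PC {20 + 2 * i}:1" for i in range(50)]
    )
    exp = make_experiment(values, 4, 4)
    for r in differential_species(exp):
        assert r.fdr >= r.p_value - 1e-15


def test_characteristic_level_shift_recovered(rng):
    """All TAG species doubled in case -> class-level TAG log2_fc ~ 1."""
    tag_names = [f"TAG {40 + 2 * i}:{i % 3}" for i in range(10)]
    pc_names = [f"PC {30 + 2 * i}:{i % 3}" for i in range(10)]
    n = 10
    base = rng.normal(14, 1, size=(20, 1)) + rng.normal(0, 0.3, size=(20, 2 * n))
    values = pd.DataFrame(base, index=tag_names + pc_names)
    values.iloc[:10, :n] += 1.0  # +1 log2 on TAG in case group
    exp = make_experiment(values, n, n)
    recs = characterize([parse_lipid_name(x) for x in exp.lipid_names])
    mat = aggregate_by_characteristic(exp, recs, "class")
    results = {r.feature: r for r in differential_characteristic(exp, mat, fc_cut=0.5)}
    assert results["TAG"].log2_fc == pytest.approx(1.0, abs=0.35)
    assert results["TAG"].fdr < 0.05
    assert results["TAG"].direction == "up"
    assert results["PC"].direction == "ns"


def test_characteristic_single_level_fdr_equals_p(toy_experiment):
    recs = characterize([parse_lipid_name("TAG 48:0")])
    mat = aggregate_by_characteristic(toy_experiment, recs, "class")
    (res,) = differential_characteristic(toy_experiment, mat)
    assert res.fdr == res.p_value


def test_dual_grid_single_species_cells(rng):
    names = ["TAG 48:0", "TAG 50:2", "TAG 54:6"]
    values = pd.DataFrame(
        rng.normal(14, 0.2, size=(3, 12)), index=names
    )
    values.iloc[0, :6] += 2.0
    exp = make_experiment(values, 6, 6)
    recs = characterize([parse_lipid_name(x) for x in names])
    grid = dual_characteristic_grid(exp, recs, "TAG")
    species = {r.feature: r for r in differential_species(exp, fc_cut=0.0)}
    assert grid.cell_value.loc[48, 0] == pytest.approx(species["TAG 48:0"].log2_fc)
    assert int(grid.cell_n.to_numpy().sum()) == 3
    assert bool(grid.significant.loc[48, 0])
    assert not bool(grid.significant.loc[54, 6])
    # significance implies fdr below alpha
    sig = grid.significant.to_numpy()
    fdr = grid.cell_fdr.to_numpy()
    assert np.all(fdr[sig] < grid.alpha)


def test_dual_grid_partitions_class_species(rng):
    names = [f"TAG {40 + 2 * (i % 5)}:{i % 4}" for i in range(12)]
    names = list(dict.fromkeys(names))
    values = pd.DataFrame(rng.normal(14, 0.3, size=(len(names), 8)), index=names)
    exp = make_experiment(values, 4, 4)
    recs = characterize([parse_lipid_name(x) for x in names])
    grid = dual_characteristic_grid(exp, recs, "TAG")
    assert int(grid.cell_n.to_numpy().sum()) == len(names)


def test_dual_grid_unknown_class_rejected(toy_experiment):
    recs = characterize([parse_lipid_name("TAG 48:0")])
    with pytest.raises(ValueError):
        dual_characteristic_grid(toy_experiment, recs, "PC")


def _mk_result(feature, fc, fdr, direction):
    return DifferentialResult(
        feature=feature,
        mean_case=fc,
        mean_control=0.0,
        log2_fc=fc,
        statistic=fc,
        p_value=fdr,
        fdr=fdr,
        direction=direction,
    )


def test_top_k_table_matches_sort_oracle(rng):
    results = []
    for i in range(60):
        fc = float(rng.normal(scale=2))
        fdr = float(rng.uniform(0, 0.2))
        direction = "ns"
        if fdr < 0.05 and fc > 1:
            direction = "up"
        elif fdr < 0.05 and fc < -1:
            direction = "down"
        results.append(_mk_result(f"L{i:02d}", fc, fdr, direction))
    ups, downs = top_k_table(results, k=5)
    oracle_key = lambda r: (-abs(r.log2_fc), r.fdr, r.feature)
    exp_ups = sorted([r for r in results if r.direction == "up"], key=oracle_key)[:5]
    exp_downs = sorted([r for r in results if r.direction == "down"], key=oracle_key)[:5]
    assert [r.feature for r in ups] == [r.feature for r in exp_ups]
    assert [r.feature for r in downs] == [r.feature for r in exp_downs]


def test_top_k_shorter_lists_when_few_significant():
    results = [_mk_result("A", 2.0, 0.01, "up"), _mk_result("B", 0.1, 0.9, "ns")]
    ups, downs = top_k_table(results, k=10)
    assert [r.feature for r in ups] == ["A"]
    assert downs == []


def test_invalid_thresholds_rejected(toy_experiment):
    with pytest.raises(ValueError):
        differential_species(toy_experiment, alpha=2.0)
    with pytest.raises(ValueError):
        differential_species(toy_experiment, fc_cut=-1.0)
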