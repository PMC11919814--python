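"""ORA exactness and LSEA running-sum correctness."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest

from lipidomix.characterization import characterize
from lipidomix.differential import DifferentialResult
from lipidomix.enrichment import (
    LipidSetCollection,
    derive_lipid_sets,
    enrichment_score,
    lsea,
    ora,
    read_gmt,
)
from lipidomix.nomenclature import parse_lipid_name


def hypergeom_tail_oracle(M, K, n, k):
    """Exact P[X >= k] for X ~ Hypergeom(M, K, n), Fraction arithmetic."""
    total = Fraction(0)
    for kk in range(k, min(K, n) + 1):
        total += Fraction(comb(K, kk) * comb(M - K, n - kk), comb(M, n))
    return float(total)


def _de_table(universe, up=(), down=()):
    out = []
    for name in universe:
        if name in up:
            fc, fdr, d = 3.0, 0.001, "up"
        elif name in down:
            fc, fdr, d = -3.0, 0.001, "down"
        else:
            fc, fdr, d = 0.0, 0.9, "ns"
        out.append(
            DifferentialResult(
                feature=name, mean_case=fc, mean_control=0.0, log2_fc=fc,
                statistic=fc, p_value=fdr, fdr=fdr, direction=d,
            )
        )
    return out


def test_ora_matches_printed_hypergeometric_example():
    """Universe 20, set 5, query 6, overlap 4 -> p = 540/38760."""
    universe = [f"L{i:02d}" for i in range(20)]
    members = universe[:5]
    query = universe[:4] + universe[10:12]  # overlap 4
    de = _de_table(universe, up=query)
    sets = LipidSetCollection(sets={"S": frozenset(members)}, source="user_file")
    (res,) = ora(de, sets, direction="up")
    assert res.overlap == 4
    assert res.p_value == pytest.approx(540 / 38760, abs=1e-12)
    assert res.p_value == pytest.approx(hypergeom_tail_oracle(20, 5, 6, 4), abs=1e-12)


def test_ora_empty_query_gives_p_one():
    universe = [f"L{i}" for i in range(10)]
    de = _de_table(universe)
    sets = LipidSetCollection(sets={"S": frozenset(universe[:4])}, source="user_file")
    (res,) = ora(de, sets, direction="up")
    assert res.p_value == 1.0
    assert res.overlap == 0


def test_ora_set_equal_to_query_attains_enumeration_minimum():
    universe = [f"L{i}" for i in range(12)]
    query = universe[:4]
    de = _de_table(universe, up=query)
    sets = LipidSetCollection(sets={"S": frozenset(query)}, source="user_file")
    (res,) = ora(de, sets, direction="up")
    assert res.p_value == pytest.approx(hypergeom_tail_oracle(12, 4, 4, 4), abs=1e-12)
    assert res.p_value == pytest.approx(1 / comb(12, 4), abs=1e-12)


def test_ora_random_configs_match_exact_enumeration(rng):
    for _ in range(200):
        M = int(rng.integers(8, 60))
        K = int(rng.integers(1, M))
        n = int(rng.integers(1, M))
        universe = [f"L{i:03d}" for i in range(M)]
        members = list(rng.choice(universe, size=K, replace=False))
        query = list(rng.choice(universe, size=n, replace=False))
        de = _de_table(universe, up=query)
        sets = LipidSetCollection(sets={"S": frozenset(members)}, source="user_file")
        (res,) = ora(de, sets, direction="up")
        k = len(set(members) & set(query))
        assert res.overlap == k
        assert res.p_value == pytest.approx(
            hypergeom_tail_oracle(M, K, n, k), abs=1e-12
        )


def test_derive_sets_partition_and_ether_split():
    names = ["TAG 48:0", "TAG 50:1", "PC 34:1", "PC O-34:2", "PC O-36:4"]
    recs = characterize([parse_lipid_name(n) for n in names])
    coll = derive_lipid_sets(recs, by="class")
    assert set(coll.sets) == {"TAG", "PC", "PC O-"}
    assert coll.sets["PC O-"] == {"PC O-34:2", "PC O-36:4"}
    union = set().union(*coll.sets.values())
    assert union == {parse_lipid_name(n).canonical_name for n in names}


def test_user_gmt_sets_drop_unknown_members(tmp_path):
    path = tmp_path / "sets.gmt"
    path.write_text(
        "setA\tdesc\tTAG 48:0\tPC 34:1\tGHOST 1:1\n"
        "setB\tdesc\tPC 34:1\tPE 36:2\n"
    )
    coll = read_gmt(path)
    restricted = coll.restricted_to({"TAG 48:0", "PC 34:1", "PE 36:2"})
    assert restricted.sets["setA"] == {"TAG 48:0", "PC 34:1"}
    assert any("GHOST" not in m for m in restricted.sets["setA"])
    assert any("dropped 1 members" in line for line in restricted.log)


def running_sum_oracle(stats_sorted, hit_mask, weight_p):
    """Brute-force GSEA-style running sum, independent loop implementation."""
    N = len(stats_sorted)
    nh = sum(hit_mask)
    denom = sum(abs(s) ** weight_p for s, h in zip(stats_sorted, hit_mask) if h)
    best = 0.0
    acc = 0.0
    for s, h in zip(stats_sorted, hit_mask):
        if h:
            acc += (abs(s) ** weight_p) / denom if denom > 0 else 1.0 / nh
        else:
            acc -= 1.0 / (N - nh)
        if abs(acc) > abs(best) or (abs(acc) == abs(best) and acc > best):
            best = acc
    return best


def test_es_is_one_when_set_occupies_top():
    statvals = np.linspace(5, -5, 20)
    hits = np.zeros(20, dtype=bool)
    hits[:5] = True
    assert enrichment_score(statvals, hits, weight_p=0.0) == pytest.approx(1.0)


def test_es_is_minus_one_when_set_occupies_bottom():
    statvals = np.linspace(5, -5, 20)
    hits = np.zeros(20, dtype=bool)
    hits[-5:] = True
    assert enrichment_score(statvals, hits, weight_p=0.0) == pytest.approx(-1.0)


def test_es_weight_zero_equals_ks_statistic(rng):
    """With p=0 the ES is the signed sup-gap between hit and miss CDFs."""
    N, nh = 40, 8
    statvals = np.sort(rng.normal(size=N))[::-1]
    hits = np.zeros(N, dtype=bool)
    hits[rng.choice(N, nh, replace=False)] = True
    es = enrichment_score(statvals, hits, weight_p=0.0)
    hit_cdf = np.cumsum(hits) / nh
    miss_cdf = np.cumsum(~hits) / (N - nh)
    gap = hit_cdf - miss_cdf
    expected = gap[np.argmax(np.abs(gap))]
    assert es == pytest.approx(expected, abs=1e-12)


def test_es_matches_brute_force_oracle(rng):
    for _ in range(100):
        N = int(rng.integers(10, 80))
        nh = int(rng.integers(2, max(3, N // 3)))
        statvals = np.sort(rng.normal(size=N))[::-1]
        hits = np.zeros(N, dtype=bool)
        hits[rng.choice(N, nh, replace=False)] = True
        weight = float(rng.choice([0.0, 0.5, 1.0, 2.0]))
        es = enrichment_score(statvals, hits, weight_p=weight)
        assert -1.0 - 1e-12 <= es <= 1.0 + 1e-12
        assert es == pytest.approx(
            running_sum_oracle(statvals, hits, weight), abs=1e-12
        )


def _ranked(rng, N=50):
    statvals = np.sort(rng.normal(size=N))[::-1]
    return [(f"L{i:02d}", float(s)) for i, s in enumerate(statvals)]


def test_lsea_is_reproducible_given_seed(rng):
    ranked = _ranked(rng)
    names = [n for n, _ in ranked]
    sets = LipidSetCollection(
        sets={"A": frozenset(names[:8]), "B": frozenset(names[20:30])},
        source="user_file",
    )
    r1 = lsea(ranked, sets, n_perm=200, seed=5)
    r2 = lsea(ranked, sets, n_perm=200, seed=5)
    assert [(a.set_name, a.es, a.nes, a.p_value) for a in r1] == [
        (a.set_name, a.es, a.nes, a.p_value) for a in r2
    ]
    for a in r1:
        assert 1 / 201 <= a.p_value <= 1.0


def test_lsea_top_heavy_set_is_significant(rng):
    ranked = _ranked(rng)
    names = [n for n, _ in ranked]
    sets = LipidSetCollection(
        sets={"top": frozenset(names[:10]), "spread": frozenset(names[::5])},
        source="user_file",
    )
    results = {r.set_name: r for r in lsea(ranked, sets, n_perm=500, seed=2)}
    assert results["top"].es > 0
    assert results["top"].p_value <= 1 / 100
    assert results["top"].nes > 1.0


def test_lsea_skips_undersized_sets(rng):
    ranked = _ranked(rng)
    names = [n for n, _ in ranked]
    sets = LipidSetCollection(
        sets={"tiny": frozenset(names[:2]), "ok": frozenset(names[:6])},
        source="user_file",
    )
    results = lsea(ranked, sets, n_perm=100, seed=1, min_size=3)
    assert [r.set_name for r in results] == ["ok"]


def test_lsea_rejects_bad_rankings(rng):
    ranked = _ranked(rng)
    sets = LipidSetCollection(sets={"A": frozenset(n for n, _ in ranked[:5])},
                              source="user_file")
    with pytest.raises(ValueError):
        lsea(ranked[::-1], sets, n_perm=100, seed=0)  # ascending order
    with pytest.raises(ValueError):
        lsea(ranked + ranked[:1], sets, n_perm=100, seed=0)  # duplicate lipid
    with pytest.raises(ValueError):
        lsea(ranked, sets, n_perm=50, seed=0)  # too few permutations
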