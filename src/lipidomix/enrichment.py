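"""Lipid-set enrichment: over-representation (ORA) and ranked LSEA.

ORA asks whether the lipids called up (or down) in the differential step
over-represent a set, via a one-sided Fisher exact test on the 2x2 table
of set membership against query membership over the universe of tested
lipids.  Conditioning on the tested universe (rather than everything
parseable) avoids detection bias.

LSEA is the GSEA-style alternative that needs no hard significance
cutoff: lipids are ranked by a signed statistic and a running sum walks
the ranking, stepping up by ``|statistic|^weight_p`` (normalized over the
set's hits) at members and down by ``1/(N - set size)`` at non-members.
The enrichment score ES is the maximum deviation of that walk, in [-1, 1];
a positive ES means the set concentrates at the top of the ranking.
Significance comes from permuting set membership over the ranked universe
(valid at any sample size, unlike sample permutation); p is one-sided
within the observed ES sign, (b + 1) / (n_same_sign + 1), and NES divides
ES by the mean magnitude of same-sign permuted scores.  BH runs across
sets per method and direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .characterization import CharacteristicRecord
from .differential import DifferentialResult

__all__ = [
    "LipidSetCollection",
    "EnrichmentResult",
    "derive_lipid_sets",
    "ora",
    "lsea",
    "enrichment_score",
    "read_gmt",
]


@dataclass
class LipidSetCollection:
    """Named sets of canonical lipid names."""

    sets: dict[str, frozenset[str]]
    source: str  # "class" | "total_carbons_bin" | "total_double_bonds_bin" | "ether_type" | "user_file"
    log: list[str] = field(default_factory=list)

    def restricted_to(self, universe: set[str]) -> "LipidSetCollection":
        """Drop members outside the universe (logged); drop emptied sets."""
        new = {}
        log = list(self.log)
        for name, members in self.sets.items():
            kept = frozenset(m for m in members if m in universe)
            dropped = len(members) - len(kept)
            if dropped:
                log.append(f"set {name!r}: dropped {dropped} members outside universe")
            if kept:
                new[name] = kept
            else:
                log.append(f"set {name!r}: empty after restriction, removed")
        return LipidSetCollection(sets=new, source=self.source, log=log)


@dataclass
class EnrichmentResult:
    set_name: str
    method: str  # "ora" | "lsea"
    direction: str  # "up" | "down" | "two_sided"
    size: int
    overlap: int | None
    odds_ratio: float | None
    es: float | None
    nes: float | None
    p_value: float
    fdr: float


def derive_lipid_sets(
    records: list[CharacteristicRecord],
    by: str = "class",
    bin_width: int = 4,
) -> LipidSetCollection:
    """Build lipid sets from structural characteristics.

    ``by`` is one of ``class``, ``ether_type``, ``total_carbons_bin``,
    ``total_double_bonds_bin`` (numeric characteristics binned with
    ``bin_width``).  Class sets split ether lipids into their own sets
    (e.g. "PC O-"), matching how lipidomics studies report them.
    """
    sets: dict[str, set[str]] = {}
    log: list[str] = []
    for r in records:
        if by == "class":
            ether = {"none": "", "O": " O-", "P": " P-"}[r.ether_type]
            key = f"{r.lipid_class}{ether}"
        elif by == "ether_type":
            key = {"none": "ester", "O": "ether_O", "P": "ether_P"}[r.ether_type]
        elif by == "total_carbons_bin":
            lo = (r.total_carbons // bin_width) * bin_width
            key = f"C{lo}-{lo + bin_width - 1}"
        elif by == "total_double_bonds_bin":
            lo = (r.total_double_bonds // bin_width) * bin_width
            key = f"DB{lo}-{lo + bin_width - 1}"
        else:
            raise KeyError(f"unknown set source {by!r}")
        sets.setdefault(key, set()).add(r.canonical_name)
    if len(sets) < 2:
        log.append(f"warning: characteristic {by!r} has {len(sets)} level(s); "
                   "enrichment is degenerate")
    source = by if by != "class" else "class"
    return LipidSetCollection(
        sets={k: frozenset(v) for k, v in sorted(sets.items())}, source=source, log=log
    )


def read_gmt(path) -> LipidSetCollection:
    """Read a GMT-style TSV: set_name <tab> description <tab> member..."""
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = [p.strip() for p in line.rstrip("\n").split("\t")]
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = frozenset(p for p in parts[2:] if p)
    if not sets:
        raise ValueError(f"no sets found in {path}")
    return LipidSetCollection(sets=sets, source="user_file")


def _haldane_odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """Sample odds ratio with a 0.5 continuity correction when a margin is zero."""
    if 0 in (a + b, c + d, a + c, b + d) or 0 in (b, c):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def ora(
    de: list[DifferentialResult],
    sets: LipidSetCollection,
    direction: str = "up",
    alpha: float = 0.05,
    fc_cut: float = 1.0,
) -> list[EnrichmentResult]:
    """Over-representation of up- or down-called lipids in each set.

    The universe is every tested lipid; the query is the lipids called in
    ``direction`` at the given thresholds.  One-sided Fisher exact p per
    set, BH across sets.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    universe = [r.feature for r in de]
    uniset = set(universe)
    query = {
        r.feature
        for r in de
        if r.fdr < alpha and (r.log2_fc > fc_cut if direction == "up" else r.log2_fc < -fc_cut)
    }
    collection = sets.restricted_to(uniset)
    M = len(uniset)
    results = []
    pvals = []
    for name, members in collection.sets.items():
        K = len(members)
        n = len(query)
        k = len(members & query)
        if n == 0:
            p = 1.0
        else:
            # P[X >= k], X ~ Hypergeom(M, K, n)
            p = float(stats.hypergeom.sf(k - 1, M, K, n))
        a, b = k, K - k
        c, d = n - k, M - K - (n - k)
        results.append(
            EnrichmentResult(
                set_name=name,
                method="ora",
                direction=direction,
                size=K,
                overlap=k,
                odds_ratio=float(_haldane_odds_ratio(a, b, c, d)),
                es=None,
                nes=None,
                p_value=min(1.0, p),
                fdr=np.nan,
            )
        )
        pvals.append(min(1.0, p))
    if results:
        fdrs = multipletests(pvals, method="fdr_bh")[1]
        for r, f in zip(results, fdrs):
            r.fdr = float(f)
    return results


def enrichment_score(
    ranked_stats: np.ndarray, hit_mask: np.ndarray, weight_p: float = 1.0
) -> float:
    """ES of one set on one ranking: signed maximum running-sum deviation.

    ``ranked_stats`` are the signed statistics in ranking order
    (descending); ``hit_mask`` marks set members.  Hits step the walk up
    by |stat|^weight_p normalized to sum 1 over hits (uniform steps if
    all hit weights are zero), misses step down by 1/(N - n_hits).
    """
    ranked_stats = np.asarray(ranked_stats, dtype=float)
    hit_mask = np.asarray(hit_mask, dtype=bool)
    N = ranked_stats.size
    nh = int(hit_mask.sum())
    if nh == 0 or nh == N:
        raise ValueError("set must be a proper non-empty subset of the ranking")
    w = np.abs(ranked_stats[hit_mask]) ** weight_p
    total = w.sum()
    steps = np.where(hit_mask, 0.0, -1.0 / (N - nh))
    if total > 0:
        steps[hit_mask] = w / total
    else:  # all-zero weights: fall back to uniform hit increments
        steps[hit_mask] = 1.0 / nh
    running = np.cumsum(steps)
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    return float(running[i_max] if running[i_max] >= -running[i_min] else running[i_min])


def _es_batch(abs_w: np.ndarray, hit_idx: np.ndarray, N: int) -> np.ndarray:
    """Vectorized ES for many permuted hit index sets (rows of hit_idx)."""
    P, nh = hit_idx.shape
    steps = np.full((P, N), -1.0 / (N - nh))
    w = abs_w[hit_idx]  # (P, nh)
    totals = w.sum(axis=1, keepdims=True)
    zero = totals[:, 0] == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        hit_steps = np.where(zero[:, None], 1.0 / nh, w / np.where(totals == 0, 1, totals))
    rows = np.repeat(np.arange(P), nh)
    steps[rows, hit_idx.ravel()] = hit_steps.ravel()
    running = np.cumsum(steps, axis=1)
    mx = running.max(axis=1)
    mn = running.min(axis=1)
    return np.where(mx >= -mn, mx, mn)


def lsea(
    ranked: list[tuple[str, float]],
    sets: LipidSetCollection,
    weight_p: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 3,
    max_size: int = 500,
) -> list[EnrichmentResult]:
    """Ranked lipid-set enrichment with a set-membership permutation null.

    Parameters
    ----------
    ranked : list of (lipid, statistic)
        Ranked descending by statistic; duplicate lipids rejected.
    n_perm : int
        Permutations per set (>= 100); permutations redraw the set's
        positions uniformly over the ranking.
    seed : int
        Reproducibility: one seed sequence, spawned per set in order.
    """
    names = [n for n, _ in ranked]
    if len(set(names)) != len(names):
        raise ValueError("duplicate lipids in ranking")
    statvals = np.array([s for _, s in ranked], dtype=float)
    if np.any(np.diff(statvals) > 0):
        raise ValueError("ranking must be sorted by statistic descending")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    N = len(names)
    pos = {n: i for i, n in enumerate(names)}
    abs_w = np.abs(statvals) ** weight_p

    collection = sets.restricted_to(set(names))
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(collection.sets))
    results = []
    pvals = []
    for (set_name, members), child in zip(collection.sets.items(), children):
        nh = len(members)
        if nh < min_size or nh > max_size or nh >= N:
            collection.log.append(
                f"set {set_name!r}: size {nh} outside [{min_size}, {max_size}], skipped"
            )
            continue
        hit_mask = np.zeros(N, dtype=bool)
        hit_mask[[pos[m] for m in members]] = True
        es = enrichment_score(statvals, hit_mask, weight_p)

        rng = np.random.Generator(np.random.PCG64(child))
        perm_idx = np.argsort(
            rng.random((n_perm, N)), axis=1, kind="stable"
        )[:, :nh]
        perm_es = _es_batch(abs_w, perm_idx, N)
        same_sign = perm_es > 0 if es >= 0 else perm_es < 0
        n_same = int(same_sign.sum())
        b = int((np.abs(perm_es[same_sign]) >= abs(es)).sum())
        p = (b + 1) / (n_same + 1)
        mean_mag = float(np.abs(perm_es[same_sign]).mean()) if n_same else np.nan
        nes = float(es / mean_mag) if n_same and mean_mag > 0 else np.nan
        results.append(
            EnrichmentResult(
                set_name=set_name,
                method="lsea",
                direction="two_sided",
                size=nh,
                overlap=None,
                odds_ratio=None,
                es=float(es),
                nes=nes,
                p_value=float(p),
                fdr=np.nan,
            )
        )
        pvals.append(float(p))
    if results:
        fdrs = multipletests(pvals, method="fdr_bh")[1]
        for r, f in zip(results, fdrs):
            r.fdr = float(f)
    return results


def enrichment_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "set_name": r.set_name,
                "method": r.method,
                "direction": r.direction,
                "size": r.size,
                "overlap": r.overlap,
                "odds_ratio": r.odds_ratio,
                "es": r.es,
                "nes": r.nes,
                "p_value": r.p_value,
                "fdr": r.fdr,
            }
            for r in results
        ]
    )
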