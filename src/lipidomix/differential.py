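"""Two-group differential abundance analysis.

Species-level and characteristic-level testing share one engine: a
two-sided Welch t-test (or exact Mann-Whitney rank-sum) on log2
abundances, effect size as the difference of group means on the log2
scale (log2 fold change), and Benjamini-Hochberg FDR across the features
tested together.  A feature is called "up" when its FDR falls below alpha
and its log2 fold change exceeds the fold-change cutoff; "down"
symmetric; otherwise "ns".

The dual-characteristic grid crosses total chain length with total
double-bond count inside one lipid class: each occupied (carbons,
double-bonds) cell holds the mean log2 fold change of its member species
and a significance flag from testing the cell's summed abundance between
groups, with BH correction across the occupied cells.  This makes visible
e.g. whether short, saturated triacylglycerols respond as a block.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .characterization import CharacteristicMatrix, CharacteristicRecord
from .profiling import Experiment

__all__ = [
    "DifferentialResult",
    "DualCharacteristicGrid",
    "differential_species",
    "differential_characteristic",
    "dual_characteristic_grid",
    "top_k_table",
    "results_to_frame",
]

#: signed sentinel statistic when within-group variance is zero
_DEGENERATE_STAT = 1e6


@dataclass
class DifferentialResult:
    feature: str
    mean_case: float
    mean_control: float
    log2_fc: float
    statistic: float
    p_value: float
    fdr: float
    direction: str  # "up" | "down" | "ns"
    note: str = ""


@dataclass
class DualCharacteristicGrid:
    """Chain-length x double-bond grid of differential effects for one class."""

    lipid_class: str
    x_levels: list[int]  # total carbons
    y_levels: list[int]  # total double bonds
    cell_value: pd.DataFrame  # mean log2_fc; NaN where empty
    cell_fdr: pd.DataFrame
    cell_n: pd.DataFrame  # int counts; 0 where empty
    significant: pd.DataFrame  # bool
    alpha: float

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.x_levels:
            for db in self.y_levels:
                n = int(self.cell_n.loc[c, db])
                if n == 0:
                    continue
                rows.append(
                    {
                        "lipid_class": self.lipid_class,
                        "total_carbons": c,
                        "total_double_bonds": db,
                        "n_species": n,
                        "mean_log2_fc": float(self.cell_value.loc[c, db]),
                        "fdr": float(self.cell_fdr.loc[c, db]),
                        "significant": bool(self.significant.loc[c, db]),
                    }
                )
        return pd.DataFrame(rows)


def _exact_pointmass_p(n1: int, n2: int, distinct: bool) -> float:
    """Two-sided permutation p for two point-mass groups.

    When every value in each group is a constant, the permutation
    distribution of the group-mean difference puts all extreme mass on the
    two label assignments that separate the constants, so the exact
    two-sided p is 2 / C(n1+n2, n1); if the constants coincide the groups
    are indistinguishable and p = 1.
    """
    if not distinct:
        return 1.0
    return min(1.0, 2.0 / math.comb(n1 + n2, n1))


def _test_rows(
    case: np.ndarray, ctrl: np.ndarray, test: str
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Vectorized two-sided tests per row; returns (stat, p, notes)."""
    n1, n2 = case.shape[1], ctrl.shape[1]
    notes = [""] * case.shape[0]
    if test == "welch_t":
        stat, p = stats.ttest_ind(case, ctrl, axis=1, equal_var=False)
        stat = np.asarray(stat, dtype=float)
        p = np.asarray(p, dtype=float)
        var1 = case.var(axis=1, ddof=1)
        var2 = ctrl.var(axis=1, ddof=1)
        degenerate = (var1 == 0) & (var2 == 0)
        for i in np.nonzero(degenerate)[0]:
            diff = case[i].mean() - ctrl[i].mean()
            p[i] = _exact_pointmass_p(n1, n2, distinct=diff != 0)
            stat[i] = 0.0 if diff == 0 else math.copysign(_DEGENERATE_STAT, diff)
            notes[i] = "zero_variance_exact_fallback"
        bad = ~np.isfinite(p)
        if bad.any():
            # one group degenerate: Welch is still defined unless both ns==1
            for i in np.nonzero(bad)[0]:
                diff = case[i].mean() - ctrl[i].mean()
                p[i] = _exact_pointmass_p(n1, n2, distinct=diff != 0)
                stat[i] = 0.0 if diff == 0 else math.copysign(_DEGENERATE_STAT, diff)
                notes[i] = "zero_variance_exact_fallback"
    elif test == "wilcoxon":
        method = "exact" if max(n1, n2) <= 10 else "asymptotic"
        stat = np.empty(case.shape[0])
        p = np.empty(case.shape[0])
        for i in range(case.shape[0]):
            try:
                res = stats.mannwhitneyu(
                    case[i], ctrl[i], alternative="two-sided", method=method
                )
            except ValueError:
                res = stats.mannwhitneyu(
                    case[i], ctrl[i], alternative="two-sided", method="asymptotic"
                )
                notes[i] = "ties_asymptotic"
            stat[i], p[i] = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown test {test!r}; use 'welch_t' or 'wilcoxon'")
    return stat, np.clip(p, 0.0, 1.0), notes


def _call_direction(fdr: float, log2_fc: float, alpha: float, fc_cut: float) -> str:
    if fdr < alpha and log2_fc > fc_cut:
        return "up"
    if fdr < alpha and log2_fc < -fc_cut:
        return "down"
    return "ns"


def _differential_frame(
    log2_case: pd.DataFrame,
    log2_ctrl: pd.DataFrame,
    test: str,
    alpha: float,
    fc_cut: float,
) -> list[DifferentialResult]:
    case = log2_case.to_numpy(dtype=float)
    ctrl = log2_ctrl.to_numpy(dtype=float)
    stat, p, notes = _test_rows(case, ctrl, test)
    fdr = multipletests(p, method="fdr_bh")[1]
    mean_case = case.mean(axis=1)
    mean_ctrl = ctrl.mean(axis=1)
    log2_fc = mean_case - mean_ctrl
    out = []
    for i, feature in enumerate(log2_case.index):
        out.append(
            DifferentialResult(
                feature=str(feature),
                mean_case=float(mean_case[i]),
                mean_control=float(mean_ctrl[i]),
                log2_fc=float(log2_fc[i]),
                statistic=float(stat[i]),
                p_value=float(p[i]),
                fdr=float(fdr[i]),
                direction=_call_direction(float(fdr[i]), float(log2_fc[i]), alpha, fc_cut),
                note=notes[i],
            )
        )
    return out


def differential_species(
    exp: Experiment,
    test: str = "welch_t",
    alpha: float = 0.05,
    fc_cut: float = 1.0,
) -> list[DifferentialResult]:
    """Per-species two-group differential test on log2 abundances.

    Returns one :class:`DifferentialResult` per lipid, FDR-adjusted by
    Benjamini-Hochberg across all tested species.
    """
    _validate_thresholds(alpha, fc_cut)
    case = exp.log2_values("case")
    ctrl = exp.log2_values("control")
    if case.shape[1] < 2 or ctrl.shape[1] < 2:
        raise ValueError("need at least 2 samples per group")
    return _differential_frame(case, ctrl, test, alpha, fc_cut)


def differential_characteristic(
    exp: Experiment,
    charmatrix: CharacteristicMatrix,
    test: str = "welch_t",
    alpha: float = 0.05,
    fc_cut: float = 1.0,
) -> list[DifferentialResult]:
    """Differential test on characteristic-level aggregated abundances.

    Aggregated (summed) linear abundances are log2-transformed and pushed
    through the same machinery as species-level testing; BH runs within
    the characteristic's levels.
    """
    _validate_thresholds(alpha, fc_cut)
    values = charmatrix.values
    if values.empty:
        return []
    pc = 1.0 if (values.to_numpy() <= 0).any() else 0.0
    logvals = np.log2(values + pc)
    case_cols = exp.samples_in("case")
    ctrl_cols = exp.samples_in("control")
    return _differential_frame(logvals[case_cols], logvals[ctrl_cols], test, alpha, fc_cut)


def dual_characteristic_grid(
    exp: Experiment,
    records: list[CharacteristicRecord],
    lipid_class: str,
    test: str = "welch_t",
    alpha: float = 0.05,
) -> DualCharacteristicGrid:
    """Chain-length x double-bond differential grid within one class.

    Cell effect = mean species log2 fold change; cell significance from
    testing the cell's summed abundance between groups with BH across
    occupied cells.
    """
    members = [
        r
        for r in records
        if r.lipid_class == lipid_class and r.canonical_name in exp.abundance.index
    ]
    if not members:
        raise ValueError(f"no analyzed species in class {lipid_class!r}")

    species_results = {
        r.feature: r for r in differential_species(exp, test=test, alpha=alpha, fc_cut=0.0)
    }
    cells: dict[tuple[int, int], list[str]] = {}
    for r in members:
        cells.setdefault((r.total_carbons, r.total_double_bonds), []).append(
            r.canonical_name
        )
    cell_keys = sorted(cells)
    x_levels = sorted({c for c, _ in cell_keys})
    y_levels = sorted({db for _, db in cell_keys})

    # per-cell test on summed linear abundance
    case_cols = exp.samples_in("case")
    ctrl_cols = exp.samples_in("control")
    summed = pd.DataFrame(
        {  # one row per occupied cell
            str(key): exp.abundance.loc[names].sum(axis=0)
            for key, names in cells.items()
        }
    ).T
    pc = 1.0 if (summed.to_numpy() <= 0).any() else 0.0
    logsum = np.log2(summed + pc)
    stat, p, _ = _test_rows(
        logsum[case_cols].to_numpy(float), logsum[ctrl_cols].to_numpy(float), test
    )
    fdr = multipletests(p, method="fdr_bh")[1]

    shape = (len(x_levels), len(y_levels))
    cell_value = pd.DataFrame(np.full(shape, np.nan), index=x_levels, columns=y_levels)
    cell_fdr = pd.DataFrame(np.full(shape, np.nan), index=x_levels, columns=y_levels)
    cell_n = pd.DataFrame(np.zeros(shape, dtype=int), index=x_levels, columns=y_levels)
    significant = pd.DataFrame(
        np.zeros(shape, dtype=bool), index=x_levels, columns=y_levels
    )
    for i, key in enumerate(cells):
        c, db = key
        names = cells[key]
        cell_value.loc[c, db] = float(
            np.mean([species_results[n].log2_fc for n in names])
        )
        cell_fdr.loc[c, db] = float(fdr[i])
        cell_n.loc[c, db] = len(names)
        significant.loc[c, db] = bool(fdr[i] < alpha)
    return DualCharacteristicGrid(
        lipid_class=lipid_class,
        x_levels=x_levels,
        y_levels=y_levels,
        cell_value=cell_value,
        cell_fdr=cell_fdr,
        cell_n=cell_n,
        significant=significant,
        alpha=alpha,
    )


def top_k_table(
    results: list[DifferentialResult], k: int = 10
) -> tuple[list[DifferentialResult], list[DifferentialResult]]:
    """Top-k up- and down-regulated features.

    Only significant features (direction up/down) are ranked, by absolute
    log2 fold change descending, ties broken by smaller FDR then by
    feature name.  Lists may be shorter than k.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    key = lambda r: (-abs(r.log2_fc), r.fdr, r.feature)
    ups = sorted((r for r in results if r.direction == "up"), key=key)
    downs = sorted((r for r in results if r.direction == "down"), key=key)
    return ups[:k], downs[:k]


def results_to_frame(results: list[DifferentialResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature": r.feature,
                "mean_case": r.mean_case,
                "mean_control": r.mean_control,
                "log2_fc": r.log2_fc,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "fdr": r.fdr,
                "direction": r.direction,
                "note": r.note,
            }
            for r in results
        ]
    )


def _validate_thresholds(alpha: float, fc_cut: float) -> None:
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if fc_cut < 0:
        raise ValueError(f"fc_cut must be >= 0, got {fc_cut}")
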