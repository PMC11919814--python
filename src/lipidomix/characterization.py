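"""Per-lipid structural characteristics and characteristic-level aggregation.

A parsed lipid carries structural characteristics — class, category, total
chain length, total unsaturation, ether linkage, and (at molecular-species
level) per-chain composition.  Analyses at the "characteristic level" sum
species abundances within each value of a characteristic: e.g. the class
matrix has one row per lipid class holding the summed abundance of its
species in every sample.

Partition characteristics (class, category, total_carbons,
total_double_bonds, ether_type) assign each species to exactly one level,
so level sums conserve the total annotated abundance per sample.
Chain-level characteristics (chain_carbons, chain_double_bonds) are
deliberately *not* a partition: a PC 16:1_20:3 genuinely contains both a
16- and a 20-carbon chain and contributes its full abundance to both
levels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .nomenclature import Chain, ParsedLipid

__all__ = [
    "CharacteristicRecord",
    "CharacteristicMatrix",
    "PARTITION_CHARACTERISTICS",
    "CHAIN_CHARACTERISTICS",
    "characterize",
    "aggregate_by_characteristic",
]

PARTITION_CHARACTERISTICS = (
    "class",
    "category",
    "total_carbons",
    "total_double_bonds",
    "ether_type",
)
CHAIN_CHARACTERISTICS = ("chain_carbons", "chain_double_bonds")
ALL_CHARACTERISTICS = PARTITION_CHARACTERISTICS + CHAIN_CHARACTERISTICS


@dataclass(frozen=True)
class CharacteristicRecord:
    """Structural characteristics of one canonical lipid species."""

    canonical_name: str
    lipid_class: str
    category: str
    total_carbons: int
    total_double_bonds: int
    ether_type: str
    per_chain: tuple[Chain, ...]

    def characteristic_value(self, characteristic: str):
        """The (single) level this record maps to, for partition characteristics."""
        if characteristic == "class":
            return self.lipid_class
        if characteristic == "category":
            return self.category
        if characteristic == "total_carbons":
            return self.total_carbons
        if characteristic == "total_double_bonds":
            return self.total_double_bonds
        if characteristic == "ether_type":
            return self.ether_type
        raise KeyError(f"not a partition characteristic: {characteristic!r}")

    def chain_values(self, characteristic: str) -> set[int]:
        """The set of chain-level values this record contributes to."""
        if characteristic == "chain_carbons":
            return {c.carbons for c in self.per_chain}
        if characteristic == "chain_double_bonds":
            return {c.double_bonds for c in self.per_chain}
        raise KeyError(f"not a chain characteristic: {characteristic!r}")


@dataclass
class CharacteristicMatrix:
    """Characteristic-level abundance matrix (levels x samples, linear scale)."""

    characteristic: str
    values: pd.DataFrame  # index: levels, columns: samples
    is_partition: bool

    @property
    def levels(self) -> list:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


def characterize(lipids: Iterable[ParsedLipid]) -> list[CharacteristicRecord]:
    """Derive one :class:`CharacteristicRecord` per parsed lipid."""
    return [
        CharacteristicRecord(
            canonical_name=lp.canonical_name,
            lipid_class=lp.lipid_class,
            category=lp.category,
            total_carbons=lp.total_carbons,
            total_double_bonds=lp.total_double_bonds,
            ether_type=lp.ether_type,
            per_chain=lp.chains,
        )
        for lp in lipids
    ]


def records_by_name(records: Iterable[CharacteristicRecord]) -> dict[str, CharacteristicRecord]:
    return {r.canonical_name: r for r in records}


def aggregate_by_characteristic(
    experiment,
    records: Iterable[CharacteristicRecord],
    characteristic: str,
    bins: int | None = None,
) -> CharacteristicMatrix:
    """Sum species abundances by characteristic level.

    Parameters
    ----------
    experiment : Experiment
        Preprocessed experiment; aggregation runs on the linear-scale
        abundance matrix so that sums are physically meaningful.
    records : iterable of CharacteristicRecord
        Annotations; species without a record are ignored (not annotated).
    characteristic : str
        One of ``class``, ``category``, ``total_carbons``,
        ``total_double_bonds``, ``ether_type``, ``chain_carbons``,
        ``chain_double_bonds``.
    bins : int, optional
        For numeric characteristics, bin integer levels into this many
        equal-width bins (labelled "lo-hi").  Default keeps integer levels.
    """
    if characteristic not in ALL_CHARACTERISTICS:
        raise KeyError(
            f"unknown characteristic {characteristic!r}; "
            f"expected one of {ALL_CHARACTERISTICS}"
        )
    recmap = records_by_name(records)
    abundance = experiment.abundance
    is_partition = characteristic in PARTITION_CHARACTERISTICS

    level_rows: dict = {}
    for name in abundance.index:
        rec = recmap.get(name)
        if rec is None:
            continue
        if is_partition:
            levels = [rec.characteristic_value(characteristic)]
        else:
            levels = sorted(rec.chain_values(characteristic))
        for level in levels:
            level_rows.setdefault(level, []).append(name)

    if bins is not None and level_rows and all(
        isinstance(lv, (int, float)) for lv in level_rows
    ):
        level_rows = _bin_levels(level_rows, bins)

    levels_sorted = sorted(level_rows, key=lambda v: (str(type(v)), v))
    data = {
        level: abundance.loc[level_rows[level]].sum(axis=0) for level in levels_sorted
    }
    values = pd.DataFrame(data).T
    values.index.name = characteristic
    if values.empty:
        values = pd.DataFrame(columns=abundance.columns)
        values.index.name = characteristic
    return CharacteristicMatrix(characteristic=characteristic, values=values, is_partition=is_partition)


def _bin_levels(level_rows: dict, bins: int) -> dict:
    lo = min(level_rows)
    hi = max(level_rows)
    if lo == hi or bins < 1:
        return {f"{lo}-{hi}": sorted({n for v in level_rows.values() for n in v})}
    width = (hi - lo) / bins
    binned: dict[str, list[str]] = {}
    for level, names in level_rows.items():
        idx = min(int((level - lo) / width), bins - 1)
        blo = lo + idx * width
        bhi = lo + (idx + 1) * width
        label = f"{blo:g}-{bhi:g}"
        binned.setdefault(label, []).extend(names)
    return {k: sorted(set(v)) for k, v in binned.items()}
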