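"""Lipid shorthand nomenclature: parsing, canonicalization, batch recognition.

Lipidomics datasets name species in a loose family of shorthand dialects:
sum-composition names such as ``TAG 48:0`` (total acyl carbons : total
double bonds, chains unresolved) and molecular-species names such as
``PC 16:1_20:3`` that resolve the individual chains.  Vendors and labs
disagree on separators (``/``, ``_``, ``-``, and the typographic en-dash),
on class synonyms (``TG`` vs ``TAG``), and on where the ether prefix goes
(``PC O-36:4`` vs ``PC(O-16:1/20:3)``).  This module parses a defined
subset of that shorthand against a small, user-extensible class registry
and serializes every recognized name to a single canonical form, so that
downstream analyses operate on one identifier per species.

The grammar intentionally covers sum-composition and molecular-species
levels for ~20 common classes; oxidized lipids, glycan headgroups,
isotope labels and adducts are rejected with a reason code rather than
guessed at.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "Chain",
    "ParsedLipid",
    "RecognitionReport",
    "ClassRegistry",
    "LipidParseError",
    "default_registry",
    "parse_lipid_name",
    "canonicalize",
    "recognize_batch",
]

CATEGORIES = ("GL", "GP", "SP", "ST", "FA")

#: Chain separators accepted on input.  "/" conventionally asserts known
#: sn-positions; "_", "-" and the en-dash "–" leave them unknown.
_SEPARATORS = "/_-"


class LipidParseError(ValueError):
    """Raised when a lipid name cannot be recognized.

    Attributes
    ----------
    reason : str
        Machine-readable reason code: one of ``unknown_class``,
        ``malformed_composition``, ``inconsistent_totals``,
        ``unsupported_adduct``, ``chain_count_mismatch``,
        ``hydroxyl_prefix_not_allowed``, ``ether_not_allowed``,
        ``empty_name``.
    """

    def __init__(self, reason: str, message: str):
        super().__init__(message)
        self.reason = reason


@dataclass(frozen=True)
class Chain:
    """One fatty acyl / long-chain-base: carbons, double bonds, hydroxyls."""

    carbons: int
    double_bonds: int
    hydroxyls: int = 0

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.carbons, self.double_bonds, self.hydroxyls)


@dataclass(frozen=True)
class ParsedLipid:
    """Structured identity of one lipid species.

    ``raw_name`` and ``sn_position_known`` are provenance metadata and are
    excluded from structural equality (:meth:`same_structure`); all other
    fields define the species.
    """

    raw_name: str
    lipid_class: str
    category: str
    ether_type: str  # "none", "O", or "P"
    total_carbons: int
    total_double_bonds: int
    total_hydroxyls: int
    chains: tuple[Chain, ...]
    parse_level: str  # "species" or "molecular_species"
    canonical_name: str
    sn_position_known: bool = False

    def same_structure(self, other: "ParsedLipid") -> bool:
        """Field-identity ignoring provenance (raw name, sn flag)."""
        return (
            self.lipid_class == other.lipid_class
            and self.category == other.category
            and self.ether_type == other.ether_type
            and self.total_carbons == other.total_carbons
            and self.total_double_bonds == other.total_double_bonds
            and self.total_hydroxyls == other.total_hydroxyls
            and self.chains == other.chains
            and self.parse_level == other.parse_level
            and self.canonical_name == other.canonical_name
        )


@dataclass
class RecognitionReport:
    """Bookkeeping for a batch recognition pass."""

    n_input: int = 0
    n_recognized: int = 0
    n_failed: int = 0
    failures: list[tuple[str, str]] = field(default_factory=list)
    duplicates: list[str] = field(default_factory=list)

    @property
    def recognition_rate(self) -> float:
        return self.n_recognized / self.n_input if self.n_input else 0.0

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_recognized": self.n_recognized,
            "n_failed": self.n_failed,
            "recognition_rate": self.recognition_rate,
            "failures": [{"raw_name": n, "reason": r} for n, r in self.failures],
            "duplicates": list(self.duplicates),
        }


class ClassRegistry:
    """Registry of recognized lipid classes.

    Parameters
    ----------
    table : pandas.DataFrame
        Columns ``class_code``, ``synonyms`` (comma-separated, may be
        empty), ``category`` (one of GL/GP/SP/ST/FA), ``backbone_chains``
        (maximum number of resolvable chains).
    """

    def __init__(self, table: pd.DataFrame):
        required = {"class_code", "synonyms", "category", "backbone_chains"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"registry table missing columns: {sorted(missing)}")
        self.table = table.reset_index(drop=True)
        self._classes: dict[str, dict] = {}
        self._alias: dict[str, str] = {}
        for _, row in self.table.iterrows():
            code = str(row["class_code"]).strip()
            cat = str(row["category"]).strip()
            if cat not in CATEGORIES:
                raise ValueError(f"unknown category {cat!r} for class {code!r}")
            self._classes[code] = {
                "category": cat,
                "backbone_chains": int(row["backbone_chains"]),
            }
            self._alias[code.upper()] = code
            syn = row["synonyms"]
            if isinstance(syn, str) and syn.strip():
                for s in syn.split(","):
                    s = s.strip()
                    if s:
                        self._alias[s.upper()] = code

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ClassRegistry":
        return cls(pd.read_csv(path, sep="\t", keep_default_na=False))

    @property
    def class_codes(self) -> list[str]:
        return list(self._classes)

    def resolve(self, token: str) -> str | None:
        """Map a class token or synonym to its canonical code, or None."""
        return self._alias.get(token.upper())

    def category(self, code: str) -> str:
        return self._classes[code]["category"]

    def backbone_chains(self, code: str) -> int:
        return self._classes[code]["backbone_chains"]

    def __contains__(self, code: str) -> bool:
        return code in self._classes


_DEFAULT_REGISTRY: ClassRegistry | None = None


def default_registry() -> ClassRegistry:
    """The bundled class registry (loaded once, cached)."""
    global _DEFAULT_REGISTRY
    if _DEFAULT_REGISTRY is None:
        with resources.files("lipidomix.data").joinpath("class_registry.tsv").open() as fh:
            _DEFAULT_REGISTRY = ClassRegistry(pd.read_csv(fh, sep="\t", keep_default_na=False))
    return _DEFAULT_REGISTRY


_CHAIN_RE = re.compile(r"^([dt])?(\d+):(\d+)$")
_CLASS_RE = re.compile(r"^([A-Za-z][A-Za-z0-9]*)\s*(.*)$")


def _parse_chain_token(token: str, allow_hydroxyl: bool, name: str) -> Chain:
    m = _CHAIN_RE.match(token)
    if m is None:
        raise LipidParseError(
            "malformed_composition", f"cannot parse chain token {token!r} in {name!r}"
        )
    prefix, c, db = m.group(1), int(m.group(2)), int(m.group(3))
    hydroxyls = 0
    if prefix is not None:
        if not allow_hydroxyl:
            raise LipidParseError(
                "hydroxyl_prefix_not_allowed",
                f"hydroxyl prefix {prefix!r} only valid for sphingolipids: {name!r}",
            )
        hydroxyls = {"d": 2, "t": 3}[prefix]
    if c < 1:
        raise LipidParseError("malformed_composition", f"chain carbons < 1 in {name!r}")
    if db < 0 or db > c:
        raise LipidParseError(
            "malformed_composition", f"double bonds exceed carbons in {name!r}"
        )
    return Chain(c, db, hydroxyls)


def _serialize_chain(chain: Chain) -> str:
    prefix = {0: "", 2: "d", 3: "t"}.get(chain.hydroxyls)
    if prefix is None:  # pragma: no cover - unreachable through the parser
        raise ValueError(f"cannot serialize hydroxyl count {chain.hydroxyls}")
    return f"{prefix}{chain.carbons}:{chain.double_bonds}"


def parse_lipid_name(name: str, registry: ClassRegistry | None = None) -> ParsedLipid:
    """Parse one shorthand lipid name into a :class:`ParsedLipid`.

    Accepts sum-composition names (``TAG 48:0``, ``SM d34:1``) and
    molecular-species names (``PE 18:0_20:4``, ``PC(O-16:1/20:3)``), with
    ``/``, ``_``, ``-`` or en-dash chain separators and registry class
    synonyms (``TG`` for ``TAG``).  Raises :class:`LipidParseError` with a
    reason code on anything outside the grammar — never returns a partial
    record.
    """
    if registry is None:
        registry = default_registry()
    if not isinstance(name, str) or not name.strip():
        raise LipidParseError("empty_name", "lipid name is empty")
    raw = name
    work = name.strip()
    # adducts / isotope labels are out of grammar by design
    if "[" in work or "]" in work:
        raise LipidParseError(
            "unsupported_adduct", f"adduct/isotope annotation not supported: {raw!r}"
        )
    # normalize typographic dashes to plain hyphen
    work = work.replace("–", "-").replace("—", "-")

    m = _CLASS_RE.match(work)
    if m is None:
        raise LipidParseError("malformed_composition", f"cannot tokenize {raw!r}")
    class_token, rest = m.group(1), m.group(2).strip()
    code = registry.resolve(class_token)
    if code is None:
        raise LipidParseError("unknown_class", f"unknown lipid class {class_token!r}")
    category = registry.category(code)
    max_chains = registry.backbone_chains(code)

    # strip one pair of enclosing parentheses: "PC(O-16:1/20:3)"
    if rest.startswith("(") and rest.endswith(")"):
        rest = rest[1:-1].strip()
    if not rest:
        raise LipidParseError("malformed_composition", f"no composition in {raw!r}")

    ether = "none"
    em = re.match(r"^([OP])-\s*(.*)$", rest)
    if em:
        if category != "GP":
            raise LipidParseError(
                "ether_not_allowed",
                f"ether prefix on non-glycerophospholipid class {code!r}",
            )
        ether = em.group(1)
        rest = em.group(2).strip()
        if not rest:
            raise LipidParseError("malformed_composition", f"no composition in {raw!r}")

    sn_known = "/" in rest
    tokens = [t for t in re.split(r"[/_\-]", rest)]
    if any(not t.strip() for t in tokens):
        raise LipidParseError("malformed_composition", f"empty chain token in {raw!r}")
    tokens = [t.strip() for t in tokens]
    allow_oh = category == "SP"

    if len(tokens) == 1:
        chain = _parse_chain_token(tokens[0], allow_oh, raw)
        total_c, total_db, total_oh = chain.as_tuple()
        chains: tuple[Chain, ...] = ()
        level = "species"
        sn_known = False
    else:
        if len(tokens) != max_chains:
            raise LipidParseError(
                "chain_count_mismatch",
                f"{code} expects {max_chains} chains, got {len(tokens)}: {raw!r}",
            )
        parsed = [_parse_chain_token(t, allow_oh, raw) for t in tokens]
        # chains are stored in canonical (sorted) order; sn-position
        # knowledge survives only as the sn_position_known flag
        parsed.sort(key=Chain.as_tuple)
        chains = tuple(parsed)
        total_c = sum(c.carbons for c in chains)
        total_db = sum(c.double_bonds for c in chains)
        total_oh = sum(c.hydroxyls for c in chains)
        level = "molecular_species"

    if total_db > total_c:
        raise LipidParseError(
            "inconsistent_totals", f"double bonds exceed carbons in {raw!r}"
        )

    canonical = _serialize(code, ether, total_c, total_db, total_oh, chains, level)
    return ParsedLipid(
        raw_name=raw,
        lipid_class=code,
        category=category,
        ether_type=ether,
        total_carbons=total_c,
        total_double_bonds=total_db,
        total_hydroxyls=total_oh,
        chains=chains,
        parse_level=level,
        canonical_name=canonical,
        sn_position_known=sn_known,
    )


def _serialize(code, ether, total_c, total_db, total_oh, chains, level) -> str:
    prefix = {"none": "", "O": "O-", "P": "P-"}[ether]
    if level == "species":
        oh = {0: "", 2: "d", 3: "t"}.get(total_oh)
        if oh is None:
            raise ValueError(f"cannot serialize total hydroxyls {total_oh}")
        return f"{code} {prefix}{oh}{total_c}:{total_db}"
    body = "_".join(_serialize_chain(c) for c in sorted(chains, key=Chain.as_tuple))
    return f"{code} {prefix}{body}"


def canonicalize(lipid: ParsedLipid) -> str:
    """Deterministic canonical serialization of a parsed lipid.

    At molecular-species level chains are sorted ascending by
    (carbons, double_bonds, hydroxyls) and joined with ``_``;
    ``parse_lipid_name(canonicalize(x))`` reproduces ``x`` structurally.
    """
    return _serialize(
        lipid.lipid_class,
        lipid.ether_type,
        lipid.total_carbons,
        lipid.total_double_bonds,
        lipid.total_hydroxyls,
        lipid.chains,
        lipid.parse_level,
    )


def recognize_batch(
    names: list[str], registry: ClassRegistry | None = None
) -> tuple[list[ParsedLipid], RecognitionReport]:
    """Parse a list of names, collecting failures instead of raising.

    Order is preserved; names whose canonical form repeats an earlier one
    are still returned but flagged in ``report.duplicates``.
    """
    if not names:
        raise ValueError("recognize_batch requires a non-empty list of names")
    report = RecognitionReport(n_input=len(names))
    parsed: list[ParsedLipid] = []
    seen: set[str] = set()
    for name in names:
        try:
            lipid = parse_lipid_name(name, registry=registry)
        except LipidParseError as err:
            report.n_failed += 1
            report.failures.append((name, err.reason))
            continue
        report.n_recognized += 1
        if lipid.canonical_name in seen:
            report.duplicates.append(lipid.canonical_name)
        seen.add(lipid.canonical_name)
        parsed.append(lipid)
    return parsed, report
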