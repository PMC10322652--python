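"""HMDB metabocard parsing and module attribute enrichment.

A *metabocard* is the per-metabolite XML record distributed by the Human
Metabolome Database (hmdb.ca), carrying names, chemical properties,
structural substituents, a chemical taxonomy, associated enzymes, diseases
and pathways. The parser is namespace-agnostic (v4/v5 element names) and
tolerant of absent blocks: missing fields come back empty, never as a crash.

Enrichment asks, per (module, attribute value), whether the value is
over-represented among module members relative to the annotated universe,
with a one-sided Fisher's exact test and Benjamini-Hochberg adjustment over
all (module, value) pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lxml import etree
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .errors import FormatError, ParameterError
from .panel import HMDB_ID_PATTERN, MetabolitePanel
from .wmcsa import ModuleSet

logger = logging.getLogger(__name__)

ATTRIBUTE_KINDS = ("substituent", "taxonomy", "enzyme", "disease", "pathway")

TAXONOMY_RANKS = ("kingdom", "super_class", "class", "sub_class")


@dataclass
class Metabocard:
    """Structured view of one HMDB metabocard."""

    hmdb_id: str
    name: str = ""
    synonyms: list[str] = field(default_factory=list)
    formula: str = ""
    average_mass: float | None = None
    monoisotopic_mass: float | None = None
    taxonomy: dict[str, str] = field(default_factory=dict)
    substituents: set[str] = field(default_factory=set)
    enzymes: set[str] = field(default_factory=set)
    diseases: set[str] = field(default_factory=set)
    pathways: set[str] = field(default_factory=set)

    def __post_init__(self):
        if self.hmdb_id and not HMDB_ID_PATTERN.match(self.hmdb_id):
            raise FormatError(f"invalid HMDB accession {self.hmdb_id!r}")
        for m in (self.average_mass, self.monoisotopic_mass):
            if m is not None and m <= 0:
                raise FormatError(f"non-positive mass {m} in {self.hmdb_id}")


@dataclass
class AttributeTable:
    """Metabolite -> set of attribute values, for one attribute kind."""

    kind: str
    mapping: dict[str, set[str]]

    def carriers(self, value: str) -> set[str]:
        return {m for m, vals in self.mapping.items() if value in vals}

    @property
    def values(self) -> set[str]:
        out: set[str] = set()
        for vals in self.mapping.values():
            out |= vals
        return out


def _local(tag) -> str:
    tag = str(tag)
    return tag.rsplit("}", 1)[-1]


def _children(el, name):
    return [c for c in el if isinstance(c.tag, str) and _local(c.tag) == name]


def _find(el, *path):
    for name in path:
        nxt = _children(el, name)
        if not nxt:
            return None
        el = nxt[0]
    return el


def _text(el, *path) -> str:
    node = _find(el, *path)
    if node is None or node.text is None:
        return ""
    return node.text.strip()


def _float_or_none(s: str) -> float | None:
    try:
        return float(s)
    except (TypeError, ValueError):
        return None


def _iter_descendants(el, name):
    for node in el.iter():
        if isinstance(node.tag, str) and _local(node.tag) == name:
            yield node


def parse_metabocard(xml_path: str | Path) -> Metabocard:
    """Parse one metabocard XML file into a :class:`Metabocard`."""
    xml_path = Path(xml_path)
    try:
        tree = etree.parse(str(xml_path))
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"malformed metabocard XML {xml_path}: {exc}") from exc
    root = tree.getroot()
    if _local(root.tag) != "metabolite":
        raise FormatError(
            f"{xml_path}: root element {_local(root.tag)!r}, expected 'metabolite'"
        )

    synonyms = []
    syn_block = _find(root, "synonyms")
    if syn_block is not None:
        synonyms = [s.text.strip() for s in _children(syn_block, "synonym")
                    if s.text and s.text.strip()]

    taxonomy = {}
    tax = _find(root, "taxonomy")
    if tax is not None:
        for rank in TAXONOMY_RANKS:
            value = _text(tax, rank)
            if value:
                taxonomy[rank] = value

    substituents = set()
    if tax is not None:
        sub_block = _find(tax, "substituents")
        if sub_block is not None:
            substituents = {s.text.strip() for s in _children(sub_block, "substituent")
                            if s.text and s.text.strip()}

    enzymes = set()
    for prot in _iter_descendants(root, "protein"):
        for key in ("gene_name", "name"):
            value = _text(prot, key)
            if value:
                enzymes.add(value)
                break

    diseases = set()
    dis_block = _find(root, "diseases")
    if dis_block is not None:
        for dis in _children(dis_block, "disease"):
            value = _text(dis, "name")
            if value:
                diseases.add(value)

    pathways = set()
    for pw in _iter_descendants(root, "pathway"):
        value = _text(pw, "name")
        if value:
            pathways.add(value)

    return Metabocard(
        hmdb_id=_text(root, "accession"),
        name=_text(root, "name"),
        synonyms=synonyms,
        formula=_text(root, "chemical_formula"),
        average_mass=_float_or_none(_text(root, "average_molecular_weight")),
        monoisotopic_mass=_float_or_none(_text(root, "monisotopic_molecular_weight")
                                         or _text(root, "monoisotopic_molecular_weight")),
        taxonomy=taxonomy,
        substituents=substituents,
        enzymes=enzymes,
        diseases=diseases,
        pathways=pathways,
    )


def read_cards(directory: str | Path) -> list[Metabocard]:
    """Parse every ``*.xml`` metabocard in a directory (sorted by filename)."""
    return [parse_metabocard(p) for p in sorted(Path(directory).glob("*.xml"))]


def extract_attributes(
    cards: list[Metabocard],
    kind: str,
    panel: MetabolitePanel | None = None,
) -> AttributeTable:
    """Build the metabolite -> attribute-values table for one kind.

    Taxonomy values are encoded as ``rank:value`` strings. When a ``panel``
    is given, keys are panel metabolite names (joined through the HMDB
    accession); otherwise keys are accessions. Metabolites without a card
    are simply absent. Duplicate accessions: the last card wins, with a
    warning.
    """
    if kind not in ATTRIBUTE_KINDS:
        raise ParameterError(f"unknown attribute kind {kind!r}; "
                             f"expected one of {ATTRIBUTE_KINDS}")
    if not cards:
        raise ParameterError("no metabocards supplied")

    by_id: dict[str, Metabocard] = {}
    for card in cards:
        if card.hmdb_id in by_id:
            logger.warning("duplicate metabocard accession %s: keeping last",
                           card.hmdb_id)
        by_id[card.hmdb_id] = card

    id_to_key = {acc: acc for acc in by_id}
    if panel is not None:
        id_to_key = {r.hmdb_id: r.name for r in panel if r.hmdb_id in by_id}

    mapping: dict[str, set[str]] = {}
    for acc, key in id_to_key.items():
        card = by_id[acc]
        if kind == "substituent":
            vals = set(card.substituents)
        elif kind == "taxonomy":
            vals = {f"{rank}:{v}" for rank, v in card.taxonomy.items()}
        elif kind == "enzyme":
            vals = set(card.enzymes)
        elif kind == "disease":
            vals = set(card.diseases)
        else:
            vals = set(card.pathways)
        mapping[key] = vals
    return AttributeTable(kind, mapping)


def feature_enrichment(
    modules: ModuleSet,
    table: AttributeTable,
    universe: set[str],
) -> pd.DataFrame:
    """One-sided Fisher over-representation of attribute values per module.

    The scope is the annotated universe (universe members present in the
    attribute table); only attribute values carried by at least two
    metabolites in scope are tested. Returns a DataFrame with the 2x2
    counts (a = in-module carriers, b = in-module non-carriers, c =
    out-of-module carriers, d = out-of-module non-carriers), the sample odds
    ratio, raw and BH-adjusted p-values, sorted by module then raw p.
    """
    if not universe:
        raise ParameterError("empty universe")
    for mid, members in modules:
        stray = members - universe
        if stray:
            raise ParameterError(f"module {mid} members outside universe: {sorted(stray)}")

    annotated = sorted(universe & set(table.mapping))
    rows = []
    values = sorted(
        v for v in table.values
        if sum(v in table.mapping[m] for m in annotated) >= 2
    )
    for mid, members in sorted(modules.modules.items()):
        in_mod = members & set(annotated)
        out_mod = set(annotated) - in_mod
        for value in values:
            carriers = {m for m in annotated if value in table.mapping[m]}
            a = len(in_mod & carriers)
            b = len(in_mod - carriers)
            c = len(out_mod & carriers)
            d = len(out_mod - carriers)
            _, p = fisher_exact([[a, b], [c, d]], alternative="greater")
            odds = np.inf if b * c == 0 and a * d > 0 else (
                np.nan if b * c == 0 else (a * d) / (b * c)
            )
            rows.append(
                {"module_id": mid, "kind": table.kind, "value": value,
                 "a": a, "b": b, "c": c, "d": d,
                 "odds_ratio": odds, "p_value": float(p)}
            )
    result = pd.DataFrame(rows, columns=["module_id", "kind", "value", "a", "b",
                                         "c", "d", "odds_ratio", "p_value"])
    if len(result):
        result["p_adjusted"] = multipletests(result["p_value"], method="fdr_bh")[1]
        result = result.sort_values(["module_id", "p_value"], kind="stable")
        result = result.reset_index(drop=True)
    else:
        result["p_adjusted"] = pd.Series(dtype=float)
    return result
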