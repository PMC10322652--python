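import math

import numpy as np
import pytest

from metchem import (
    FormatError,
    ModuleSet,
    ParameterError,
    extract_attributes,
    feature_enrichment,
    parse_metabocard,
    read_cards,
)
from metchem.hmdb import ATTRIBUTE_KINDS, AttributeTable

CARD = """<?xml version="1.0" encoding="UTF-8"?>
<metabolite>
  <accession>HMDB0000001</accession>
  <name>1-Methylhistidine</name>
  <synonyms><synonym>Pi-methylhistidine</synonym></synonyms>
  <chemical_formula>C7H11N3O2</chemical_formula>
  <average_molecular_weight>146.1451</average_molecular_weight>
  <taxonomy>
    <kingdom>Organic compounds</kingdom>
    <super_class>Organic acids and derivatives</super_class>
    <class>Carboxylic acids and derivatives</class>
    <sub_class>Amino acids, peptides, and analogues</sub_class>
    <substituents>
      <substituent>Imidazolyl carboxylic acid</substituent>
      <substituent>Alpha-amino acid or derivatives</substituent>
    </substituents>
  </taxonomy>
  <biological_properties>
    <pathways>
      <pathway><name>Histidine metabolism</name></pathway>
    </pathways>
  </biological_properties>
  <protein_associations>
    <protein><gene_name>CNDP1</gene_name></protein>
  </protein_associations>
</metabolite>
"""


@pytest.fixture()
def card_path(tmp_path):
    p = tmp_path / "HMDB0000001.xml"
    p.write_text(CARD)
    return p


class TestParseMetabocard:
    def test_fixture_round_trip(self, card_path):
        card = parse_metabocard(card_path)
        assert card.hmdb_id == "HMDB0000001"
        assert card.substituents == {
            "Imidazolyl carboxylic acid",
            "Alpha-amino acid or derivatives",
        }
        assert card.pathways == {"Histidine metabolism"}
        assert card.enzymes == {"CNDP1"}
        assert card.taxonomy["sub_class"] == "Amino acids, peptides, and analogues"

    def test_average_mass_parsed(self, card_path):
        assert parse_metabocard(card_path).average_mass == 146.1451

    def test_missing_diseases_block_tolerated(self, card_path):
        card = parse_metabocard(card_path)
        assert card.diseases == set()

    def test_malformed_xml_raises_with_path(self, tmp_path):
        bad = tmp_path / "bad.xml"
        bad.write_text("<metabolite><accession>")
        with pytest.raises(FormatError, match="bad.xml"):
            parse_metabocard(bad)

    def test_wrong_root_element(self, tmp_path):
        bad = tmp_path / "wrong.xml"
        bad.write_text("<protein><name>x</name></protein>")
        with pytest.raises(FormatError, match="metabolite"):
            parse_metabocard(bad)

    def test_parser_total_on_fixture_corpus(self, cards_dir):
        cards = read_cards(cards_dir)
        assert len(cards) == 24
        for card in cards:
            assert card.hmdb_id.startswith("HMDB")
            assert card.average_mass is None or card.average_mass > 0


class TestExtractAttributes:
    def test_one_key_per_card(self, cards_dir):
        cards = read_cards(cards_dir)[:3]
        table = extract_attributes(cards, "substituent")
        assert len(table.mapping) == 3

    def test_taxonomy_rank_value_format(self, card_path):
        table = extract_attributes([parse_metabocard(card_path)], "taxonomy")
        values = table.mapping["HMDB0000001"]
        assert "kingdom:Organic compounds" in values
        assert all(":" in v for v in values)

    def test_duplicate_accession_last_wins(self, card_path, caplog):
        card = parse_metabocard(card_path)
        other = parse_metabocard(card_path)
        other.substituents = {"Override"}
        with caplog.at_level("WARNING"):
            table = extract_attributes([card, other], "substituent")
        assert table.mapping["HMDB0000001"] == {"Override"}
        assert "duplicate" in caplog.text

    def test_unknown_kind_rejected(self, card_path):
        with pytest.raises(ParameterError):
            extract_attributes([parse_metabocard(card_path)], "colour")

    def test_panel_maps_keys_to_names(self, cards_dir, family_panel):
        panel, _ = family_panel
        table = extract_attributes(read_cards(cards_dir), "pathway", panel=panel)
        assert set(table.mapping) <= set(panel.names)
        assert table.mapping["fa_1"] == {"Fatty acid biosynthesis"}


def hypergeom_oracle(a, b, c, d):
    """P(X >= a) for X ~ Hypergeom(N=a+b+c+d, K=a+c draws of a+b), by
    explicit summation of binomial terms."""
    N, K, n = a + b + c + d, a + c, a + b
    total = 0.0
    for x in range(a, min(K, n) + 1):
        total += (math.comb(K, x) * math.comb(N - K, n - x)) / math.comb(N, n)
    return total


class TestFeatureEnrichment:
    def universe_20(self):
        return {f"u{i}" for i in range(20)}

    def table_with_carriers(self, carriers, kind="substituent"):
        mapping = {m: ({"X"} if m in carriers else set()) for m in self.universe_20()}
        return AttributeTable(kind, mapping)

    def test_perfect_overlap_closed_form(self):
        carriers = {f"u{i}" for i in range(4)}
        modules = ModuleSet({1: frozenset(carriers)})
        res = feature_enrichment(modules, self.table_with_carriers(carriers),
                                 self.universe_20())
        row = res[res["value"] == "X"].iloc[0]
        assert row["p_value"] == pytest.approx(1 / math.comb(20, 4), rel=1e-9)
        assert (row["a"], row["b"], row["c"], row["d"]) == (4, 0, 0, 16)

    def test_universal_attribute_uninformative(self):
        carriers = self.universe_20()
        modules = ModuleSet({1: frozenset(list(carriers)[:4])})
        res = feature_enrichment(modules, self.table_with_carriers(carriers),
                                 self.universe_20())
        row = res[res["value"] == "X"].iloc[0]
        assert row["p_value"] == pytest.approx(1.0)

    def test_random_tables_match_summation_oracle(self, rng):
        universe = self.universe_20()
        for _ in range(100):
            members = set(rng.choice(sorted(universe), size=rng.integers(2, 10),
                                     replace=False))
            carriers = set(rng.choice(sorted(universe), size=rng.integers(2, 12),
                                      replace=False))
            modules = ModuleSet({1: frozenset(members)})
            res = feature_enrichment(modules, self.table_with_carriers(carriers),
                                     universe)
            row = res[res["value"] == "X"].iloc[0]
            expected = hypergeom_oracle(row["a"], row["b"], row["c"], row["d"])
            assert abs(row["p_value"] - expected) < 1e-10

    def test_counts_sum_to_annotated_scope(self):
        carriers = {f"u{i}" for i in range(6)}
        table = self.table_with_carriers(carriers)
        # only 15 universe members annotated
        table.mapping = {k: v for k, v in table.mapping.items()
                         if k not in {f"u{i}" for i in range(15, 20)}}
        modules = ModuleSet({1: frozenset({"u0", "u1", "u16"})})
        res = feature_enrichment(modules, table, self.universe_20())
        row = res.iloc[0]
        assert row[["a", "b", "c", "d"]].sum() == 15

    def test_rare_values_skipped(self):
        carriers = {"u0"}  # single carrier: below the >=2 threshold
        modules = ModuleSet({1: frozenset({"u0", "u1", "u2"})})
        res = feature_enrichment(modules, self.table_with_carriers(carriers),
                                 self.universe_20())
        assert len(res) == 0

    def test_empty_universe_rejected(self):
        with pytest.raises(ParameterError):
            feature_enrichment(ModuleSet({}), self.table_with_carriers(set()), set())

    def test_bh_monotone_and_module_order_invariant(self, rng):
        universe = self.universe_20()
        carriers = {f"u{i}" for i in range(7)}
        mods_a = ModuleSet({1: frozenset({"u0", "u1", "u2"}),
                            2: frozenset({"u8", "u9", "u10", "u11"})})
        mods_b = ModuleSet({2: frozenset({"u8", "u9", "u10", "u11"}),
                            1: frozenset({"u0", "u1", "u2"})})
        res_a = feature_enrichment(mods_a, self.table_with_carriers(carriers), universe)
        res_b = feature_enrichment(mods_b, self.table_with_carriers(carriers), universe)
        key = ["module_id", "value"]
        merged = res_a.merge(res_b, on=key, suffixes=("_a", "_b"))
        np.testing.assert_allclose(merged["p_value_a"], merged["p_value_b"])
        # monotone: sorting raw p sorts adjusted p
        srt = res_a.sort_values("p_value")
        assert (srt["p_adjusted"].diff().dropna() >= -1e-12).all()


def test_attribute_kinds_complete():
    assert set(ATTRIBUTE_KINDS) == {"substituent", "taxonomy", "enzyme",
                                    "disease", "pathway"}
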