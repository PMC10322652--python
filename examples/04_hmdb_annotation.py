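"""Parse metabocards and test module attribute enrichment.

Writes miniature synthetic metabocard XML files for the panel, extracts
substituent attributes, and asks whether a family module is enriched for
its family's substituents against the panel universe (one-sided Fisher,
Benjamini-Hochberg adjusted).
"""

import tempfile
from pathlib import Path

from metchem import (
    ModuleSet,
    extract_attributes,
    feature_enrichment,
    generate_structural_panel,
    read_cards,
    write_fixture_metabocards,
)

panel, truth = generate_structural_panel(8, seed=1)

with tempfile.TemporaryDirectory() as tmp:
    paths = write_fixture_metabocards(panel, truth, Path(tmp))
    cards = read_cards(tmp)
    print(f"parsed {len(cards)} metabocards; first: {cards[0].hmdb_id} "
          f"({cards[0].name}), substituents {sorted(cards[0].substituents)}")

table = extract_attributes(cards, "substituent", panel=panel)
modules = ModuleSet({1: truth.modules["fa_module"]})
universe = set(panel.valid_names)
enr = feature_enrichment(modules, table, universe)
print(enr[["value", "a", "b", "c", "d", "odds_ratio", "p_value",
           "p_adjusted"]].to_string(index=False))

# 'Fatty acyl chain' is carried only by the fatty-acid family, so the
# fatty-acid module should be strongly enriched for it; 'Carboxylic acid'
# is shared with the amino acids and discriminates less.
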