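"""Synthetic fixtures: structural families, concentrations, metabocards.

The generator emulates the shape of a desk-scale metabolomics study: a
panel of SMILES drawn from chemically coherent families (homologous series,
so within-family Tanimoto similarity is high and between-family similarity
low, like real chemical classes such as fatty acids or acylcarnitines), a
log-normal concentration matrix with planted module covariance and group
effects, and miniature metabocard XML files carrying family-consistent
annotations.

Families
--------
``fa``
    Straight-chain fatty acids, chain length 4 upward.
``aa``
    Alpha-amino acids with varying side chains.
``nuc``
    N9-substituted adenines (purine derivatives).

Concentration model: for each planted module a latent per-sample score is
drawn; a member's log-concentration is ``loading * score + effect * sigma *
group_indicator + sigma * noise`` and non-members are pure noise; values are
exponentiated, giving positive log-normal intensities. Effects are expressed
in units of the noise standard deviation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors
from rdkit.Chem.rdMolDescriptors import CalcMolFormula

from .errors import ParameterError
from .panel import ConcentrationMatrix, MetabolitePanel, MetaboliteRecord

_AA_SIDE_CHAINS = [
    "C", "CC", "CCC", "CC(C)C", "CCS", "CO", "C(C)O",
    "CCCC", "CC(=O)N", "CCC(=O)O", "CCCN", "Cc1ccccc1",
]

FAMILY_NAMES = ("fa", "aa", "nuc")


def _family_smiles(family: str, n: int) -> list[str]:
    if family == "fa":
        return ["C" * (i + 3) + "C(=O)O" for i in range(n)]
    if family == "aa":
        chains = list(_AA_SIDE_CHAINS)
        while len(chains) < n:
            chains.append("C" * (len(chains) - len(_AA_SIDE_CHAINS) + 5))
        return [f"NC({r})C(=O)O" for r in chains[:n]]
    if family == "nuc":
        return [f"Nc1ncnc2n({'C' * i})cnc12" for i in range(1, n + 1)]
    raise ParameterError(f"unknown family {family!r}; expected one of {FAMILY_NAMES}")


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated dataset.

    ``families`` maps metabolite name -> family label; ``modules`` maps a
    module name to its member set (each planted module lies inside one
    family); ``effects`` gives the group effect per module in noise-SD units.
    """

    families: dict[str, str]
    modules: dict[str, frozenset[str]] = field(default_factory=dict)
    effects: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    @property
    def family_labels(self) -> list[str]:
        return list(self.families.values())

    def to_json(self, path: str | Path) -> None:
        payload = {
            "families": self.families,
            "modules": {k: sorted(v) for k, v in self.modules.items()},
            "effects": self.effects,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            families=payload["families"],
            modules={k: frozenset(v) for k, v in payload["modules"].items()},
            effects=payload["effects"],
            seed=payload["seed"],
        )


def generate_structural_panel(
    n_per_family: int = 8,
    families: tuple[str, ...] = FAMILY_NAMES,
    seed: int = 0,
    module_size: int = 5,
) -> tuple[MetabolitePanel, SyntheticTruth]:
    """Panel of homologous-series SMILES from several structural families.

    One planted module per family (its first ``min(module_size, n)``
    members, effect 0 until assigned). Records get synthetic HMDB-style
    accessions so the metabocard fixtures can link back to them.
    """
    if len(families) < 2:
        raise ParameterError("need at least 2 families")
    if n_per_family < 3:
        raise ParameterError("need n_per_family >= 3")
    records, fam_of = [], {}
    modules: dict[str, frozenset[str]] = {}
    acc = 1
    for fam in families:
        names = []
        for i, smi in enumerate(_family_smiles(fam, n_per_family)):
            name = f"{fam}_{i + 1}"
            records.append(
                MetaboliteRecord(name=name, smiles=smi, hmdb_id=f"HMDB{acc:07d}")
            )
            fam_of[name] = fam
            names.append(name)
            acc += 1
        modules[f"{fam}_module"] = frozenset(names[: min(module_size, len(names))])
    truth = SyntheticTruth(
        families=fam_of,
        modules=modules,
        effects={m: 0.0 for m in modules},
        seed=int(seed),
    )
    return MetabolitePanel(records), truth


def generate_concentrations(
    panel: MetabolitePanel,
    truth: SyntheticTruth,
    n_samples_per_group: int = 6,
    noise_sd: float = 0.5,
    loading: float = 1.0,
    groups: tuple[str, ...] = ("WT", "MYC"),
    effect_group: str | None = None,
    seed: int = 0,
) -> ConcentrationMatrix:
    """Log-normal concentration matrix with planted structure.

    Each planted module contributes ``loading * latent score`` to its
    members; the module's effect (noise-SD units) shifts ``effect_group``
    (default: the last group level). Everything else is Gaussian noise in
    log space, exponentiated to positive intensities.
    """
    if noise_sd <= 0:
        raise ParameterError(f"noise_sd must be positive, got {noise_sd}")
    for mname, members in truth.modules.items():
        stray = members - set(panel.names)
        if stray:
            raise ParameterError(f"planted module {mname} not in panel: {sorted(stray)}")
    if effect_group is None:
        effect_group = groups[-1]
    if effect_group not in groups:
        raise ParameterError(f"effect_group {effect_group!r} not in groups {groups}")

    rng = np.random.default_rng(seed)
    n_samples = n_samples_per_group * len(groups)
    group = np.repeat(list(groups), n_samples_per_group)
    sample_ids = [f"{g}_{i + 1}" for g in groups for i in range(n_samples_per_group)]
    indicator = (group == effect_group).astype(float)

    names = panel.names
    log_conc = noise_sd * rng.standard_normal((n_samples, len(names)))
    col = {n: j for j, n in enumerate(names)}
    for mname, members in truth.modules.items():
        score = rng.standard_normal(n_samples)
        effect = truth.effects.get(mname, 0.0)
        for m in sorted(members):
            log_conc[:, col[m]] += loading * score + effect * noise_sd * indicator
    values = pd.DataFrame(np.exp(log_conc), index=pd.Index(sample_ids, name="sample_id"),
                          columns=names)
    return ConcentrationMatrix(values, pd.Series(group, index=values.index, name="group"))


_FAMILY_ANNOTATION = {
    "fa": {
        "substituents": ["Carboxylic acid", "Fatty acyl chain"],
        "taxonomy": {"kingdom": "Organic compounds",
                     "super_class": "Lipids and lipid-like molecules",
                     "class": "Fatty Acyls",
                     "sub_class": "Fatty acids and conjugates"},
        "pathways": ["Fatty acid biosynthesis"],
        "enzymes": ["ACSL1"],
        "diseases": ["Fatty acid oxidation disorder"],
    },
    "aa": {
        "substituents": ["Carboxylic acid", "Alpha-amino acid or derivatives"],
        "taxonomy": {"kingdom": "Organic compounds",
                     "super_class": "Organic acids and derivatives",
                     "class": "Carboxylic acids and derivatives",
                     "sub_class": "Amino acids, peptides, and analogues"},
        "pathways": ["Protein biosynthesis"],
        "enzymes": ["GPT"],
        "diseases": ["Aminoaciduria"],
    },
    "nuc": {
        "substituents": ["Purine", "Imidazole"],
        "taxonomy": {"kingdom": "Organic compounds",
                     "super_class": "Nucleosides, nucleotides, and analogues",
                     "class": "Purines and purine derivatives",
                     "sub_class": "6-aminopurines"},
        "pathways": ["Purine metabolism"],
        "enzymes": ["ADA"],
        "diseases": ["Hyperuricemia"],
    },
}


def metabocard_xml(record: MetaboliteRecord, family: str) -> str:
    """Render one synthetic miniature metabocard as an XML string."""
    ann = _FAMILY_ANNOTATION.get(family, _FAMILY_ANNOTATION["fa"])
    mol = Chem.MolFromSmiles(record.smiles) if record.smiles else None
    formula = CalcMolFormula(mol) if mol is not None else ""
    avg_mass = f"{Descriptors.MolWt(mol):.4f}" if mol is not None else ""
    mono_mass = f"{Descriptors.ExactMolWt(mol):.4f}" if mol is not None else ""
    subs = "\n".join(f"      <substituent>{s}</substituent>"
                     for s in ann["substituents"])
    pws = "\n".join(
        f"      <pathway>\n        <name>{p}</name>\n      </pathway>"
        for p in ann["pathways"]
    )
    enz = "\n".join(
        f"      <protein>\n        <gene_name>{e}</gene_name>\n      </protein>"
        for e in ann["enzymes"]
    )
    dis = "\n".join(
        f"    <disease>\n      <name>{d}</name>\n    </disease>"
        for d in ann["diseases"]
    )
    tax = "\n".join(f"    <{r}>{v}</{r}>" for r, v in ann["taxonomy"].items())
    return f"""<?xml version="1.0" encoding="UTF-8"?>
<metabolite>
  <accession>{record.hmdb_id}</accession>
  <name>{record.name}</name>
  <synonyms>
    <synonym>{record.name} (synthetic)</synonym>
  </synonyms>
  <chemical_formula>{formula}</chemical_formula>
  <average_molecular_weight>{avg_mass}</average_molecular_weight>
  <monisotopic_molecular_weight>{mono_mass}</monisotopic_molecular_weight>
  <smiles>{record.smiles}</smiles>
  <taxonomy>
{tax}
    <substituents>
{subs}
    </substituents>
  </taxonomy>
  <biological_properties>
    <pathways>
{pws}
    </pathways>
  </biological_properties>
  <diseases>
{dis}
  </diseases>
  <protein_associations>
{enz}
  </protein_associations>
</metabolite>
"""


def write_fixture_metabocards(
    panel: MetabolitePanel,
    truth: SyntheticTruth,
    out_dir: str | Path,
    max_cards: int | None = None,
) -> list[Path]:
    """Write one synthetic metabocard XML per panel record (or the first
    ``max_cards``) into ``out_dir``; returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    records = panel.records if max_cards is None else panel.records[:max_cards]
    for rec in records:
        family = truth.families.get(rec.name, "fa")
        path = out_dir / f"{rec.hmdb_id}.xml"
        path.write_text(metabocard_xml(rec, family))
        paths.append(path)
    return paths
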