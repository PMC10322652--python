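"""Metabolite panel and concentration-matrix input/output.

A *panel* lists the metabolites under study: chemical name, SMILES string and
HMDB accession. A *concentration matrix* holds one row per sample and one
column per metabolite, plus a categorical sample group. The metabolite name
is the join key between the two, and column order is kept aligned with the
panel record order throughout the pipeline.

File dialect: comma-separated with a header row. The panel CSV has columns
``name,smiles,hmdb_id``; the concentration CSV has ``sample_id`` first,
``group`` second, then one column per metabolite. Names are matched
case-sensitively after trimming surrounding whitespace.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

from .errors import AlignmentError, FormatError, ParameterError

logger = logging.getLogger(__name__)

# silence per-molecule RDKit parse warnings; invalid SMILES are an expected
# input condition handled via the `valid` flag
RDLogger.DisableLog("rdApp.error")

HMDB_ID_PATTERN = re.compile(r"^HMDB\d+$")

PANEL_COLUMNS = ("name", "smiles", "hmdb_id")


@dataclass(frozen=True)
class MetaboliteRecord:
    """One panel entry.

    ``valid`` records whether the SMILES parsed; invalid records are retained
    in the panel (so row counts and reports stay complete) but are excluded
    from every structural computation downstream.
    """

    name: str
    smiles: str
    hmdb_id: str = ""
    valid: bool = True

    def __post_init__(self):
        if not self.name:
            raise FormatError("metabolite record with empty name")
        if self.hmdb_id and not HMDB_ID_PATTERN.match(self.hmdb_id):
            raise FormatError(
                f"invalid HMDB accession {self.hmdb_id!r} for {self.name!r}"
            )


class MetabolitePanel:
    """Ordered collection of :class:`MetaboliteRecord` with a name index."""

    def __init__(self, records: list[MetaboliteRecord]):
        names = [r.name for r in records]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise FormatError(f"duplicate metabolite names: {sorted(dupes)}")
        self.records: list[MetaboliteRecord] = list(records)
        self._index = {r.name: i for i, r in enumerate(self.records)}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, name: str) -> MetaboliteRecord:
        return self.records[self._index[name]]

    def position(self, name: str) -> int:
        return self._index[name]

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.records]

    @property
    def valid_records(self) -> list[MetaboliteRecord]:
        return [r for r in self.records if r.valid]

    @property
    def valid_names(self) -> list[str]:
        return [r.name for r in self.records if r.valid]

    @property
    def n_invalid(self) -> int:
        return sum(not r.valid for r in self.records)

    def subset(self, names) -> "MetabolitePanel":
        keep = set(names)
        return MetabolitePanel([r for r in self.records if r.name in keep])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [r.name for r in self.records],
                "smiles": [r.smiles for r in self.records],
                "hmdb_id": [r.hmdb_id for r in self.records],
            }
        )


@dataclass
class ConcentrationMatrix:
    """Samples x metabolites concentrations plus a per-sample group factor.

    ``values`` is a DataFrame indexed by sample id with one column per
    metabolite, column order matching the panel.
    """

    values: pd.DataFrame
    group: pd.Series = field(repr=False)

    def __post_init__(self):
        if not self.values.index.equals(self.group.index):
            raise FormatError("sample ids of values and group differ")
        if self.group.nunique() < 1:
            raise FormatError("group factor has no levels")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def metabolites(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def subset(self, names) -> "ConcentrationMatrix":
        return ConcentrationMatrix(self.values[list(names)].copy(), self.group.copy())

    def to_frame(self) -> pd.DataFrame:
        out = self.values.copy()
        out.insert(0, "group", self.group)
        out.index.name = "sample_id"
        return out.reset_index()


def _smiles_valid(smiles: str) -> bool:
    return bool(smiles) and Chem.MolFromSmiles(smiles) is not None


def impute_missing(values: pd.DataFrame, method: str = "min") -> pd.DataFrame:
    """Impute missing concentrations per metabolite column.

    ``min`` (default) is the metabolomics floor convention: a missing value is
    read as below detection limit and replaced by the column minimum.
    ``median`` replaces by the column median; ``none`` raises if anything is
    missing.
    """
    n_missing = int(values.isna().sum().sum())
    if n_missing == 0:
        return values
    if method == "none":
        raise ParameterError(f"{n_missing} missing values and imputation disabled")
    if method == "min":
        filled = values.fillna(values.min(axis=0))
    elif method == "median":
        filled = values.fillna(values.median(axis=0))
    else:
        raise ParameterError(f"unknown imputation method {method!r}")
    logger.warning("imputed %d missing concentration values (%s)", n_missing, method)
    if filled.isna().any().any():
        empty = [c for c in filled.columns if filled[c].isna().any()]
        raise FormatError(f"columns entirely missing: {empty}")
    return filled


def read_panel(
    panel_path: str | Path,
    conc_path: str | Path,
    impute: str = "min",
) -> tuple[MetabolitePanel, ConcentrationMatrix]:
    """Read and align a panel CSV and a concentration CSV.

    Returns the panel (records whose SMILES fail to parse are flagged
    ``valid=False`` and retained) and the concentration matrix restricted to
    the overlapping metabolite names, columns ordered as in the panel.
    Concentration columns absent from the panel, and panel records absent
    from the matrix, are dropped with a logged warning.
    """
    panel_df = pd.read_csv(panel_path, dtype=str, keep_default_na=False)
    missing = [c for c in PANEL_COLUMNS if c not in panel_df.columns]
    if missing:
        raise FormatError(f"panel file missing required column(s): {missing}")

    conc_df = pd.read_csv(conc_path)
    for col in ("sample_id", "group"):
        if col not in conc_df.columns:
            raise FormatError(f"concentration file missing required column: {col!r}")

    records = []
    for _, row in panel_df.iterrows():
        name = row["name"].strip()
        smiles = row["smiles"].strip()
        records.append(
            MetaboliteRecord(
                name=name,
                smiles=smiles,
                hmdb_id=row["hmdb_id"].strip(),
                valid=_smiles_valid(smiles),
            )
        )
    panel = MetabolitePanel(records)
    if panel.n_invalid:
        logger.warning(
            "%d of %d panel records have unparseable SMILES; flagged and "
            "excluded from structural analysis",
            panel.n_invalid,
            len(panel),
        )

    conc_df = conc_df.rename(columns=lambda c: str(c).strip())
    conc_cols = [c for c in conc_df.columns if c not in ("sample_id", "group")]
    panel_names = set(panel.names)
    overlap = [c for c in conc_cols if c in panel_names]
    if not overlap:
        raise AlignmentError(
            "no overlap between panel metabolite names and concentration columns"
        )
    extra = [c for c in conc_cols if c not in panel_names]
    if extra:
        logger.warning("dropping %d concentration column(s) absent from panel: %s",
                       len(extra), extra)
    orphan = [n for n in panel.names if n not in set(conc_cols)]
    if orphan:
        logger.warning("dropping %d panel record(s) with no concentration column: %s",
                       len(orphan), orphan)
        panel = panel.subset([n for n in panel.names if n not in set(orphan)])

    values = conc_df.set_index("sample_id")[panel.names].astype(float)
    values = impute_missing(values, impute)
    group = conc_df.set_index("sample_id")["group"].astype(str)
    return panel, ConcentrationMatrix(values, group)


def write_panel(panel: MetabolitePanel, path: str | Path) -> None:
    panel.to_frame().to_csv(path, index=False)


def write_concentrations(conc: ConcentrationMatrix, path: str | Path) -> None:
    conc.to_frame().to_csv(path, index=False, float_format="%.12g")


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write any pipeline output table with a stable float format."""
    df.to_csv(path, index=index, float_format="%.12g")
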