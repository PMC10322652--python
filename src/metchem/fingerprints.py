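"""SMILES -> molecular fingerprints -> Tanimoto dissimilarity matrix.

Fingerprints are fixed-length bit vectors marking the presence of
substructural features. The default scheme is circular (Morgan /
extended-connectivity style) with radius 2 over 1024 bits, the de facto
standard for Tanimoto similarity; RDKit path fingerprints and MACCS keys are
selectable. Tanimoto dissimilarity between two fingerprints is
``1 - |A ∩ B| / |A ∪ B|`` on their set-bit sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator

from .errors import (
    IncompatibleFingerprintError,
    InsufficientDataError,
    StructureError,
)
from .panel import MetabolitePanel


@dataclass(frozen=True)
class FingerprintScheme:
    """Fingerprint family and parameters.

    kind: ``morgan`` (circular, uses ``radius``), ``rdkit`` (path-based) or
    ``maccs`` (166 structural keys; ``n_bits`` is ignored and fixed at 167).
    """

    kind: str = "morgan"
    radius: int = 2
    n_bits: int = 1024

    @property
    def length(self) -> int:
        return 167 if self.kind == "maccs" else self.n_bits


@dataclass(frozen=True)
class Fingerprint:
    """Set-bit positions of one molecule under a given scheme."""

    bits: frozenset[int]
    length: int
    scheme: FingerprintScheme

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError("fingerprint length must be positive")
        if self.bits and not all(0 <= b < self.length for b in self.bits):
            raise ValueError("bit position outside [0, length)")


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(smiles)
    return mol


def smiles_to_fingerprint(
    smiles: str, scheme: FingerprintScheme = FingerprintScheme()
) -> Fingerprint:
    """Compute the fingerprint of a SMILES string.

    Parsing into an RDKit molecule canonicalizes the structure first, so
    equivalent SMILES spellings (e.g. ``CCO`` and ``OCC``) map to identical
    fingerprints.
    """
    mol = _mol_from_smiles(smiles)
    if scheme.kind == "morgan":
        gen = rdFingerprintGenerator.GetMorganGenerator(
            radius=scheme.radius, fpSize=scheme.n_bits
        )
        bv = gen.GetFingerprint(mol)
    elif scheme.kind == "rdkit":
        gen = rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=scheme.n_bits)
        bv = gen.GetFingerprint(mol)
    elif scheme.kind == "maccs":
        bv = MACCSkeys.GenMACCSKeys(mol)
    else:
        raise ValueError(f"unknown fingerprint kind {scheme.kind!r}")
    return Fingerprint(frozenset(bv.GetOnBits()), bv.GetNumBits(), scheme)


def tanimoto_dissimilarity(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto (Jaccard) dissimilarity between two fingerprints in [0, 1].

    Two empty bit sets are identical feature-free representations, so their
    dissimilarity is defined as 0.
    """
    if a.length != b.length or a.scheme != b.scheme:
        raise IncompatibleFingerprintError(
            f"fingerprints incompatible: {a.scheme}/{a.length} vs {b.scheme}/{b.length}"
        )
    union = len(a.bits | b.bits)
    if union == 0:
        return 0.0
    return 1.0 - len(a.bits & b.bits) / union


@dataclass
class DissimilarityMatrix:
    """Symmetric metabolite x metabolite Tanimoto distance matrix in [0, 1]."""

    d: np.ndarray
    labels: list[str]

    def __post_init__(self):
        d = np.asarray(self.d, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        if len(self.labels) != d.shape[0]:
            raise ValueError("label count does not match matrix size")
        if not np.allclose(d, d.T):
            raise ValueError("dissimilarity matrix must be symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("dissimilarity matrix must have zero diagonal")
        if d.min() < 0 or d.max() > 1 + 1e-12:
            raise ValueError("dissimilarity entries must lie in [0, 1]")
        self.d = d

    @property
    def n(self) -> int:
        return self.d.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)


def fingerprint_matrix(
    panel: MetabolitePanel, scheme: FingerprintScheme = FingerprintScheme()
) -> tuple[np.ndarray, list[str]]:
    """Bit matrix (valid metabolites x bits) and the row labels."""
    valid = panel.valid_records
    B = np.zeros((len(valid), scheme.length), dtype=bool)
    for i, rec in enumerate(valid):
        fp = smiles_to_fingerprint(rec.smiles, scheme)
        B[i, list(fp.bits)] = True
    return B, [r.name for r in valid]


def dissimilarity_matrix(
    panel: MetabolitePanel, scheme: FingerprintScheme = FingerprintScheme()
) -> DissimilarityMatrix:
    """Pairwise Tanimoto dissimilarity over the panel's valid records."""
    if len(panel.valid_records) < 3:
        raise InsufficientDataError(
            f"need >=3 valid metabolites, got {len(panel.valid_records)}"
        )
    B, labels = fingerprint_matrix(panel, scheme)
    Bi = B.astype(np.int64)
    inter = Bi @ Bi.T
    pops = Bi.sum(axis=1)
    union = pops[:, None] + pops[None, :] - inter
    with np.errstate(invalid="ignore"):
        d = 1.0 - inter / union
    d[union == 0] = 0.0  # both fingerprints empty -> identical
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # exact symmetry against float round-off
    return DissimilarityMatrix(d, labels)
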