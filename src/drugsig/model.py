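"""Domain types for interaction-signature drug repurposing.

The pipeline describes each compound by its vector of predicted interaction
scores against an entire protein library (its *interaction signature*).
These types carry the minimum chemistry needed for that: hashed circular
fingerprints (ECFP4 semantics) for compounds and for the template ligands
attached to predicted protein binding sites, plus the approval/indication
metadata used for benchmarking.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .errors import ValidationError

_SPARSE_RE = re.compile(r"^\d+(;\d+)*$")


@dataclass(frozen=True)
class Fingerprint:
    """A fixed-width hashed substructure bit set.

    ``bits`` holds the indices of on-bits; ``width`` is the hash size shared
    by every fingerprint in a run. Dice similarity between two fingerprints
    is only meaningful when their widths agree.
    """

    bits: frozenset[int]
    width: int

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValidationError(f"fingerprint width must be positive, got {self.width}")
        if any(i < 0 or i >= self.width for i in self.bits):
            raise ValidationError("fingerprint bit index out of [0, width)")

    @property
    def n_bits(self) -> int:
        return len(self.bits)

    def to_sparse(self) -> str:
        """Serialize as ``i1;i2;...`` with ascending indices ('' when empty)."""
        return ";".join(str(i) for i in sorted(self.bits))

    @classmethod
    def from_sparse(cls, text: str, width: int) -> "Fingerprint":
        text = text.strip()
        if text == "":
            return cls(frozenset(), width)
        if not _SPARSE_RE.match(text):
            raise ValidationError(f"not a sparse fingerprint string: {text!r}")
        return cls(frozenset(int(t) for t in text.split(";")), width)

    @classmethod
    def from_smiles(cls, smiles: str, width: int, radius: int = 2) -> Optional["Fingerprint"]:
        """Hashed Morgan fingerprint (radius 2 = ECFP4) of a SMILES string.

        Returns None when the SMILES cannot be parsed; callers decide how to
        flag the record.
        """
        mol = _mol_from_smiles(smiles)
        if mol is None:
            return None
        from rdkit.Chem import rdFingerprintGenerator

        gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=width)
        fp = gen.GetFingerprint(mol)
        return cls(frozenset(fp.GetOnBits()), width)


def _mol_from_smiles(smiles: str):
    from rdkit import Chem, RDLogger

    RDLogger.DisableLog("rdApp.error")
    return Chem.MolFromSmiles(smiles)


def heavy_atom_count(smiles: str) -> Optional[int]:
    """Number of non-hydrogen atoms, or None for unparseable SMILES."""
    mol = _mol_from_smiles(smiles)
    return None if mol is None else mol.GetNumHeavyAtoms()


@dataclass
class Compound:
    id: str
    name: str = ""
    smiles: Optional[str] = None
    fingerprint: Optional[Fingerprint] = None
    approved: bool = False
    heavy_atoms: Optional[int] = None
    flagged: bool = False  # True when structure failed to parse

    @property
    def scoreable(self) -> bool:
        return self.fingerprint is not None


@dataclass(frozen=True)
class BindingSitePrediction:
    """A predicted binding site: template ligand plus site confidence in [0,1]."""

    protein_id: str
    site_id: str
    ligand_fingerprint: Fingerprint
    confidence: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 1.0):
            raise ValidationError(
                f"confidence for {self.protein_id}/{self.site_id} outside [0,1]: "
                f"{self.confidence}"
            )


@dataclass
class Protein:
    id: str
    name: str = ""
    predictions: list[BindingSitePrediction] = field(default_factory=list)

    def __post_init__(self) -> None:
        for p in self.predictions:
            if p.protein_id != self.id:
                raise ValidationError(
                    f"prediction protein_id {p.protein_id!r} attached to protein {self.id!r}"
                )


@dataclass
class IndicationMapping:
    """An indication and the set of compounds approved for it."""

    indication_id: str
    indication_name: str
    approved_compound_ids: frozenset[str]

    @property
    def n_approved(self) -> int:
        return len(self.approved_compound_ids)

    @property
    def benchmarkable(self) -> bool:
        """Benchmarking requires at least two approved drugs (leave-one-out)."""
        return self.n_approved >= 2


@dataclass
class GoldStandardTargets:
    """An independently curated disease-relevant protein set."""

    source_label: str
    protein_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.protein_ids:
            raise ValidationError(f"gold standard {self.source_label!r} is empty")


class SignatureMatrix:
    """Compounds × proteins matrix of interaction scores in [0, 1].

    Rows follow compound-library order, columns protein-library order.
    A compound without a fingerprint has an all-zero row; a protein without
    binding-site predictions has an all-zero column.
    """

    def __init__(self, values: np.ndarray, compound_ids: Iterable[str], protein_ids: Iterable[str]):
        self.values = np.asarray(values, dtype=float)
        self.compound_ids = list(compound_ids)
        self.protein_ids = list(protein_ids)
        if self.values.shape != (len(self.compound_ids), len(self.protein_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match labels "
                f"({len(self.compound_ids)}, {len(self.protein_ids)})"
            )
        if self.values.size and (self.values.min() < 0.0 or self.values.max() > 1.0):
            raise ValidationError("interaction scores must lie in [0, 1]")
        self._row_index = {c: i for i, c in enumerate(self.compound_ids)}
        self._col_index = {p: j for j, p in enumerate(self.protein_ids)}
        if len(self._row_index) != len(self.compound_ids):
            raise ValidationError("duplicate compound ids in matrix")
        if len(self._col_index) != len(self.protein_ids):
            raise ValidationError("duplicate protein ids in matrix")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row(self, compound_id: str) -> np.ndarray:
        try:
            return self.values[self._row_index[compound_id]]
        except KeyError:
            raise KeyError(f"compound {compound_id!r} not in matrix") from None

    def has_compound(self, compound_id: str) -> bool:
        return compound_id in self._row_index
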