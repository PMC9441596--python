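"""Amino-acid residue masses and the enzyme composition matrix.

The central object is the K x 20 composition matrix ``xi``: for each protein
k and proteinogenic amino acid l, ``xi[k, l]`` is the mass of amino acid l
polymerized into one mmol of protein k (g mmol^-1).  The matrix is built from
protein sequences using *residue* masses (free amino acid minus one water),
so that 1000 times each row sum equals the protein's polymer molecular
weight.  This identity is what keeps the amino-acid-resolved protein-pool
constraint exactly equivalent to the aggregate GECKO pool constraint.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "AA_CODES",
    "AA_NAMES",
    "RESIDUE_FORMULAS",
    "RESIDUE_MASSES",
    "WATER_MASS",
    "NonCanonicalResidueError",
    "ProteinRecord",
    "CompositionMatrix",
    "residue_mass",
    "count_residues",
    "protein_mw",
    "build_xi",
    "parse_fasta",
    "read_fasta",
]

#: Canonical ordering used by every vector/matrix in the package:
#: alphabetical by one-letter code.
AA_CODES: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")

AA_NAMES: dict[str, str] = {
    "A": "alanine", "C": "cysteine", "D": "aspartate", "E": "glutamate",
    "F": "phenylalanine", "G": "glycine", "H": "histidine", "I": "isoleucine",
    "K": "lysine", "L": "leucine", "M": "methionine", "N": "asparagine",
    "P": "proline", "Q": "glutamine", "R": "arginine", "S": "serine",
    "T": "threonine", "V": "valine", "W": "tryptophan", "Y": "tyrosine",
}

# Average atomic masses (g mol^-1), pinned once for the whole package.
_ATOMIC_MASSES = {"C": 12.011, "H": 1.008, "N": 14.007, "O": 15.999, "S": 32.06}

#: Polymeric (water-free) residue formulas of the 20 proteinogenic amino acids.
RESIDUE_FORMULAS: dict[str, str] = {
    "A": "C3H5NO",    "C": "C3H5NOS",   "D": "C4H5NO3",  "E": "C5H7NO3",
    "F": "C9H9NO",    "G": "C2H3NO",    "H": "C6H7N3O",  "I": "C6H11NO",
    "K": "C6H12N2O",  "L": "C6H11NO",   "M": "C5H9NOS",  "N": "C4H6N2O2",
    "P": "C5H7NO",    "Q": "C5H8N2O2",  "R": "C6H12N4O", "S": "C3H5NO2",
    "T": "C4H7NO2",   "V": "C5H9NO",    "W": "C11H10N2O", "Y": "C9H9NO2",
}

_FORMULA_RE = re.compile(r"([A-Z])(\d*)")


def _formula_mass(formula: str) -> float:
    total = 0.0
    for element, count in _FORMULA_RE.findall(formula):
        total += _ATOMIC_MASSES[element] * (int(count) if count else 1)
    return round(total, 3)


#: Average residue masses (g mol^-1), 3-decimal precision.
RESIDUE_MASSES: dict[str, float] = {
    code: _formula_mass(RESIDUE_FORMULAS[code]) for code in AA_CODES
}

#: Mass of one water molecule (g mol^-1); added once for a free polypeptide chain.
WATER_MASS: float = _formula_mass("H2O")

_CODE_INDEX = {code: i for i, code in enumerate(AA_CODES)}
_RESIDUE_MASS_VECTOR = np.array([RESIDUE_MASSES[c] for c in AA_CODES])


class NonCanonicalResidueError(ValueError):
    """A sequence contains a symbol outside the 20-letter canonical alphabet.

    Ambiguity codes (B, J, X, Z) and the rare residues U (selenocysteine) and
    O (pyrrolysine) are rejected rather than guessed: a silently mis-assigned
    residue mass would corrupt the protein-pool budget downstream.
    """

    def __init__(self, symbol: str, position: int | None = None,
                 protein_id: str | None = None):
        self.symbol = symbol
        self.position = position
        self.protein_id = protein_id
        where = f" at position {position}" if position is not None else ""
        who = f" in protein {protein_id!r}" if protein_id else ""
        super().__init__(f"non-canonical residue {symbol!r}{where}{who}")


def residue_mass(code: str) -> float:
    """Average mass (g mol^-1) of amino acid ``code`` as polymerized in a peptide."""
    try:
        return RESIDUE_MASSES[code]
    except KeyError:
        raise NonCanonicalResidueError(code) from None


def count_residues(sequence: str, *, policy: str = "strict",
                   protein_id: str | None = None) -> np.ndarray:
    """Count residues of ``sequence`` into a length-20 integer vector.

    The vector follows :data:`AA_CODES` order.  Under ``policy='strict'``
    (default) any non-canonical symbol raises :class:`NonCanonicalResidueError`
    naming the 1-based offending position; under ``policy='lenient'`` such
    symbols are dropped with a logged warning and excluded from the count.
    """
    if policy not in ("strict", "lenient"):
        raise ValueError(f"unknown policy {policy!r}")
    counts = np.zeros(len(AA_CODES), dtype=np.int64)
    dropped = 0
    for pos, symbol in enumerate(sequence, start=1):
        idx = _CODE_INDEX.get(symbol)
        if idx is None:
            if policy == "strict":
                raise NonCanonicalResidueError(symbol, pos, protein_id)
            dropped += 1
            continue
        counts[idx] += 1
    if dropped:
        logger.warning(
            "dropped %d non-canonical residue(s) from %s (lenient policy); "
            "their mass is excluded", dropped, protein_id or "sequence")
    return counts


def protein_mw(sequence: str, *, terminal_water: bool = False,
               policy: str = "strict") -> float:
    """Molecular weight (g mol^-1) of ``sequence`` under the residue-mass convention.

    By default returns the water-free polymer mass (sum of residue masses),
    which is the convention used throughout the composition matrix and the
    protein-pool accounting.  ``terminal_water=True`` adds one water for the
    free-chain mass of an isolated polypeptide; that variant must *not* feed
    the composition matrix, or the pool budget would drift by up to
    18 g mol^-1 per protein.
    """
    counts = count_residues(sequence, policy=policy)
    mass = float(counts @ _RESIDUE_MASS_VECTOR)
    if terminal_water and sequence:
        mass += WATER_MASS
    return mass


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence keyed by the identifier used in the metabolic model."""

    protein_id: str
    sequence: str

    @property
    def mw(self) -> float:
        """Polymer molecular weight (g mol^-1), residue-mass convention."""
        return protein_mw(self.sequence)


@dataclass(frozen=True)
class CompositionMatrix:
    """The K x 20 amino-acid composition matrix ``xi`` (g mmol^-1).

    Row k, column l holds the gram of amino acid l per mmol of protein k, so
    ``1000 * values[k].sum() == mw_k`` exactly (same summation order as
    :func:`protein_mw`).
    """

    values: np.ndarray
    protein_ids: tuple[str, ...]
    aa_codes: tuple[str, ...] = field(default=AA_CODES)

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[1] != len(self.aa_codes):
            raise ValueError(
                f"xi must be K x {len(self.aa_codes)}, got shape {values.shape}")
        if values.shape[0] != len(self.protein_ids):
            raise ValueError("row count does not match number of protein ids")
        if len(set(self.protein_ids)) != len(self.protein_ids):
            raise ValueError("duplicate protein identifiers in xi")
        if (values < 0).any():
            raise ValueError("xi entries must be non-negative")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "protein_ids", tuple(self.protein_ids))

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    def row(self, protein_id: str) -> np.ndarray:
        return self.values[self.protein_ids.index(protein_id)]

    def mw(self, protein_id: str) -> float:
        """Molecular weight (g mol^-1) implied by the row of ``protein_id``."""
        return 1000.0 * float(self.row(protein_id).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.protein_ids),
                            columns=list(self.aa_codes))

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().rename_axis("protein_id").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CompositionMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        missing = [c for c in AA_CODES if c not in frame.columns]
        if missing:
            raise ValueError(f"composition table lacks columns {missing}")
        frame = frame[list(AA_CODES)]
        return cls(frame.to_numpy(dtype=float), tuple(frame.index.astype(str)))


def build_xi(proteins: Iterable[ProteinRecord | tuple[str, str]],
             *, policy: str = "strict") -> CompositionMatrix:
    """Build the composition matrix from protein records, preserving input order.

    Each entry is ``count_kl * residue_mass_l / 1000`` (g mmol^-1).  An empty
    protein list yields a valid 0 x 20 matrix.  Proteins included in the
    matrix must have non-empty sequences.
    """
    records = [p if isinstance(p, ProteinRecord) else ProteinRecord(*p)
               for p in proteins]
    ids = [r.protein_id for r in records]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ValueError(f"duplicate protein identifiers: {sorted(dupes)}")
    rows = np.zeros((len(records), len(AA_CODES)))
    for k, record in enumerate(records):
        if not record.sequence:
            raise ValueError(f"empty sequence for protein {record.protein_id!r}")
        counts = count_residues(record.sequence, policy=policy,
                                protein_id=record.protein_id)
        rows[k] = counts * _RESIDUE_MASS_VECTOR / 1000.0
    return CompositionMatrix(rows, tuple(ids))


_UNIPROT_HEADER = re.compile(r"^(?:sp|tr)\|(?P<acc>[^|]+)\|\S+")


def parse_fasta(source: str | Path | IO[str], *,
                uniprot_headers: bool | None = None) -> list[ProteinRecord]:
    """Read protein records from FASTA text, a path, or an open handle.

    UniProt-style headers (``sp|ACC|NAME`` / ``tr|ACC|NAME``) yield the
    accession as ``protein_id``; bare headers are used verbatim (first
    whitespace-delimited token).  ``uniprot_headers=True`` makes a malformed
    UniProt header an error instead of falling back to the bare token.
    Sequences are uppercased with line breaks joined; a header with no
    sequence is an error.
    """
    if isinstance(source, Path):
        handle: IO[str] = open(source)
    elif isinstance(source, str):
        if "\n" in source or source.startswith(">"):
            handle = StringIO(source)
        else:
            handle = open(source)
    else:
        handle = source
    records: list[ProteinRecord] = []
    try:
        for rec in SeqIO.parse(handle, "fasta"):
            match = _UNIPROT_HEADER.match(rec.id)
            if match:
                protein_id = match.group("acc")
            elif uniprot_headers:
                raise ValueError(f"malformed UniProt header: {rec.description!r}")
            else:
                protein_id = rec.id
            sequence = str(rec.seq).upper()
            if not sequence:
                raise ValueError(f"empty sequence for {protein_id}")
            records.append(ProteinRecord(protein_id, sequence))
    finally:
        if handle is not source:
            handle.close()
    return records


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Alias of :func:`parse_fasta` for path arguments."""
    return parse_fasta(Path(path))
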