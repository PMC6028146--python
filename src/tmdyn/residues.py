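"""Residue numbering maps and atom selections.

The package exposes C99 numbering (residues 28-55 for the standard
construct) as the canonical residue coordinate; 0-based construct indices
are internal plumbing.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import C99_FIRST_NUMBER, C99_TAG_LENGTH, C99_WT_CONSTRUCT

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
THREE_TO_ONE = {v: k for k, v in ONE_TO_THREE.items()}


@dataclass(frozen=True)
class ResidueMap:
    """Bijection between 0-based construct indices and C99 residue numbers.

    ``numbers[i]`` is the C99 number of construct residue ``i`` (``None``
    for tag residues, which carry no C99 coordinate).
    """

    sequence: str
    numbers: tuple
    tag: tuple = ()

    def __post_init__(self):
        mapped = [n for n in self.numbers if n is not None]
        if len(set(mapped)) != len(mapped):
            raise ValueError("C99 numbers must be unique")
        if mapped and mapped != list(range(mapped[0], mapped[0] + len(mapped))):
            raise ValueError("mapped C99 numbers must be contiguous")

    @classmethod
    def c99_construct(cls, sequence: str = C99_WT_CONSTRUCT) -> "ResidueMap":
        """Map for the KKW-tagged C99(28-55) construct (WT or point mutant)."""
        if not sequence.startswith("KKW"):
            raise ValueError("C99 construct is expected to start with the KKW tag")
        n_tag = C99_TAG_LENGTH
        numbers = [None] * n_tag + list(
            range(C99_FIRST_NUMBER, C99_FIRST_NUMBER + len(sequence) - n_tag)
        )
        return cls(sequence, tuple(numbers), tag=tuple(range(n_tag)))

    @classmethod
    def linear(cls, sequence: str, start: int = 1) -> "ResidueMap":
        """Trivial map numbering every residue consecutively from ``start``."""
        return cls(sequence, tuple(range(start, start + len(sequence))))

    # -- lookups -----------------------------------------------------------
    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    def index_of(self, number: int) -> int:
        """Construct index of a C99 residue number."""
        try:
            return self.numbers.index(number)
        except ValueError:
            raise KeyError(f"C99 residue {number} is not in the mapped range")

    def number_of(self, index: int):
        return self.numbers[index]

    def code_of(self, number: int) -> str:
        return self.sequence[self.index_of(number)]

    def label(self, number: int) -> str:
        """One-letter-code label such as 'G33'."""
        return f"{self.code_of(number)}{number}"

    @property
    def mapped_numbers(self) -> list:
        return [n for n in self.numbers if n is not None]

    def indices_of_range(self, first: int, last: int) -> np.ndarray:
        """Construct indices of the inclusive C99 range ``first..last``."""
        if last < first:
            raise ValueError("empty residue range")
        return np.array([self.index_of(n) for n in range(first, last + 1)])


@dataclass(frozen=True)
class Selection:
    """Atom-role filter plus an optional residue range in C99 numbering."""

    atom_names: tuple = ("CA",)
    c99_range: tuple | None = None     # inclusive (first, last) or None = all

    def resolve(self, topology, residue_map: ResidueMap) -> np.ndarray:
        """Atom indices (sorted) matching the selection; error if empty."""
        names = set(self.atom_names) if self.atom_names else None
        if self.c99_range is not None:
            residues = set(
                residue_map.indices_of_range(*self.c99_range).tolist())
        else:
            residues = None
        idx = [
            i for i in range(topology.n_atoms)
            if (names is None or topology.atom_names[i] in names)
            and (residues is None or int(topology.atom_resid[i]) in residues)
        ]
        if not idx:
            raise ValueError(f"selection {self} resolves to zero atoms")
        return np.asarray(idx, dtype=int)

    def residue_numbers(self, residue_map: ResidueMap) -> list:
        if self.c99_range is None:
            return residue_map.mapped_numbers
        return list(range(self.c99_range[0], self.c99_range[1] + 1))


CA_SELECTION = Selection(("CA",), None)
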