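"""TM-JM receptor sequence models.

A receptor tyrosine kinase model here is its transmembrane (TM) helix plus
the first ``jm_length`` (default 20) residues of the intracellular
juxtamembrane (JM) region. Residues are classified into four physicochemical
classes (basic, acidic, polar, hydrophobic) and carry integer formal charges
(R/K = +1, D/E = -1, everything else 0; histidine is treated as neutral
polar, and the fragment termini are uncharged).

JM positions are numbered 1..jm_length starting at the first residue
C-terminal of the TM helix; every positional output in the package uses this
convention.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Tuple

from .errors import InvalidResidueError, TruncatedJMError

#: Four-way physicochemical classification of the 20 standard amino acids.
#: His is counted polar/neutral; Gly and Pro are grouped with the non-polar
#: class (the scheme has no separate "special" class).
RESIDUE_CLASSES: dict[str, str] = {
    "R": "basic",
    "K": "basic",
    "D": "acidic",
    "E": "acidic",
    "S": "polar",
    "T": "polar",
    "N": "polar",
    "Q": "polar",
    "C": "polar",
    "Y": "polar",
    "H": "polar",
    "W": "polar",
    "A": "hydrophobic",
    "V": "hydrophobic",
    "L": "hydrophobic",
    "I": "hydrophobic",
    "M": "hydrophobic",
    "F": "hydrophobic",
    "G": "hydrophobic",
    "P": "hydrophobic",
}

RESIDUE_CHARGES: dict[str, int] = {
    aa: (+1 if cls == "basic" else -1 if cls == "acidic" else 0)
    for aa, cls in RESIDUE_CLASSES.items()
}

CLASS_LABELS: tuple[str, ...] = ("basic", "acidic", "polar", "hydrophobic")


def classify_residue(aa: str) -> str:
    """Return the class label for a one-letter amino-acid code.

    Raises
    ------
    InvalidResidueError
        If ``aa`` is not one of the 20 standard codes.
    """
    try:
        return RESIDUE_CLASSES[aa.upper()]
    except KeyError:
        raise InvalidResidueError(f"unknown amino-acid code {aa!r}") from None


def residue_charge(aa: str) -> int:
    """Formal charge of a residue: R/K -> +1, D/E -> -1, otherwise 0."""
    try:
        return RESIDUE_CHARGES[aa.upper()]
    except KeyError:
        raise InvalidResidueError(f"unknown amino-acid code {aa!r}") from None


def extract_jm(sequence: str, tm_span: Tuple[int, int], jm_length: int = 20) -> str:
    """Extract the JM segment: ``jm_length`` residues after the TM span.

    ``tm_span`` is a 1-based inclusive (start, end) pair. The returned
    segment starts at ``tm_span[1] + 1`` and is renumbered 1..jm_length.

    Raises
    ------
    TruncatedJMError
        If fewer than ``jm_length`` residues follow the TM span.
    InvalidResidueError
        If the segment contains a non-standard code.
    """
    start, end = tm_span
    if not (1 <= start <= end <= len(sequence)):
        raise ValueError(f"tm_span {tm_span} invalid for sequence of length {len(sequence)}")
    if jm_length < 0:
        raise ValueError("jm_length must be non-negative")
    remaining = len(sequence) - end
    if remaining < jm_length:
        raise TruncatedJMError(
            f"only {remaining} residues follow the TM span; {jm_length} required"
        )
    jm = sequence[end : end + jm_length].upper()
    for aa in jm:
        if aa not in RESIDUE_CLASSES:
            raise InvalidResidueError(f"unknown amino-acid code {aa!r} in JM segment")
    return jm


@dataclass(frozen=True)
class TMJMModel:
    """A receptor's TM-JM fragment with per-residue annotations.

    Attributes
    ----------
    receptor_id : str
        Identifier (gene symbol or user label).
    sequence : str
        Full supplied amino-acid sequence.
    tm_span : (int, int)
        1-based inclusive TM helix span within ``sequence``.
    jm_sequence : str
        The ``jm_length`` residues immediately C-terminal of the TM span.
    per_residue_class : tuple of str
        Class label per JM residue (positions 1..jm_length).
    per_residue_charge : tuple of int
        Formal charge per JM residue.
    net_jm_charge : int
        Sum of the per-residue charges.
    """

    receptor_id: str
    sequence: str
    tm_span: Tuple[int, int]
    jm_sequence: str
    per_residue_class: Tuple[str, ...]
    per_residue_charge: Tuple[int, ...]
    net_jm_charge: int

    @property
    def jm_length(self) -> int:
        return len(self.jm_sequence)


def build_model(
    receptor_id: str,
    sequence: str,
    tm_span: Tuple[int, int],
    jm_length: int = 20,
) -> TMJMModel:
    """Validate and assemble a :class:`TMJMModel` from sequence + TM span."""
    sequence = sequence.upper()
    jm = extract_jm(sequence, tm_span, jm_length)
    classes = tuple(classify_residue(aa) for aa in jm)
    charges = tuple(residue_charge(aa) for aa in jm)
    return TMJMModel(
        receptor_id=receptor_id,
        sequence=sequence,
        tm_span=(int(tm_span[0]), int(tm_span[1])),
        jm_sequence=jm,
        per_residue_class=classes,
        per_residue_charge=charges,
        net_jm_charge=int(sum(charges)),
    )


def net_jm_charge(model: TMJMModel) -> int:
    """Net formal charge of the JM segment (R/K minus D/E counts)."""
    return int(sum(residue_charge(aa) for aa in model.jm_sequence))


def mutate_basic_to_leu(model: TMJMModel) -> TMJMModel:
    """In-silico charge-neutralising mutant: every JM R/K becomes L.

    Leucine preserves side-chain bulk while removing the positive charge,
    so the mutant isolates the electrostatic contribution of the basic
    residues. The TM span is unchanged; classes and charges are recomputed.
    Idempotent: applying it twice equals applying it once.
    """
    start, end = model.tm_span
    jm_mut = "".join("L" if aa in ("R", "K") else aa for aa in model.jm_sequence)
    seq_mut = (
        model.sequence[: end]
        + jm_mut
        + model.sequence[end + model.jm_length :]
    )
    classes = tuple(classify_residue(aa) for aa in jm_mut)
    charges = tuple(residue_charge(aa) for aa in jm_mut)
    return replace(
        model,
        sequence=seq_mut,
        jm_sequence=jm_mut,
        per_residue_class=classes,
        per_residue_charge=charges,
        net_jm_charge=int(sum(charges)),
    )
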