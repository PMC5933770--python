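"""Core domain types for truncating-variant pathogenicity prediction.

Conventions used throughout the package:

* Residue positions are 1-based and inclusive, counted from the N-terminus.
* Amino acids use the 20 standard one-letter codes in alphabetical order
  (``ACDEFGHIKLMNPQRSTVWY``); profile and composition vectors follow this
  column order.
* Conservation profiles are position-wise amino-acid frequency vectors that
  each sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: The 20 standard amino acids, alphabetical one-letter order.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Number of alternative residues at a position (missense score columns).
N_MISSENSE: int = 19

PROFILE_SUM_TOL = 1e-6
PROFILE_RENORM_TOL = 1e-3


@dataclass
class GeneAnnotations:
    """Gene-level annotations feeding the functional features.

    ``essential`` marks homology-transferred gene essentiality;
    ``disease_genecards`` and ``disease_additional`` are two independent
    disease-association sources; ``ppi_count`` is the number of known
    protein-protein interaction partners; ``domain_ranges`` lists 1-based
    inclusive ``[start, end]`` domain intervals when available.
    """

    essential: bool = False
    disease_genecards: bool = False
    disease_additional: bool = False
    ppi_count: int = 0
    domain_ranges: Optional[list[tuple[int, int]]] = None


@dataclass
class ProteinRecord:
    """One protein: sequence, C-alpha model, conservation profile, annotations.

    Parameters
    ----------
    id : str
        Protein identifier shared with the variant table.
    sequence : str
        One-letter amino-acid sequence of length ``N_r``.
    calpha : ndarray of shape (N_r, 3)
        C-alpha coordinates of the (predicted) structural model, in Angstrom.
    profile : ndarray of shape (N_r, 20)
        Position-wise amino-acid frequencies; rows sum to one.
    missense_scores : ndarray of shape (N_r, 19), optional
        Per-position pathogenicity scores of the 19 possible substitutions,
        each in [0, 1]; required only by the affected-part pathogenicity
        feature.
    annotations : GeneAnnotations
    """

    id: str
    sequence: str
    calpha: np.ndarray
    profile: np.ndarray
    missense_scores: Optional[np.ndarray] = None
    annotations: GeneAnnotations = field(default_factory=GeneAnnotations)

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    def __post_init__(self) -> None:
        self.calpha = np.asarray(self.calpha, dtype=float)
        self.profile = np.asarray(self.profile, dtype=float)
        if self.missense_scores is not None:
            self.missense_scores = np.asarray(self.missense_scores, dtype=float)


@dataclass(frozen=True)
class TruncatingVariant:
    """A frameshift or nonsense variant truncating a protein at position ``k``.

    Frameshift and nonsense variants are treated identically: both disrupt
    everything C-terminal of ``k``.
    """

    protein_id: str
    k: int
    vtype: str  # "frameshift" | "nonsense"
    label: str = "unknown"  # "pathogenic" | "neutral" | "unknown"

    def __post_init__(self) -> None:
        if self.vtype not in ("frameshift", "nonsense"):
            raise ValueError(f"unknown variant type {self.vtype!r}")
        if self.label not in ("pathogenic", "neutral", "unknown"):
            raise ValueError(f"unknown label {self.label!r}")


@dataclass(frozen=True)
class SkipRecord:
    """A variant that could not be loaded, with the reason it was skipped."""

    protein_id: str
    position: int
    vtype: str
    reason: str


def validate_protein(record: ProteinRecord) -> list[str]:
    """Check a :class:`ProteinRecord` against its invariants.

    Returns a list of human-readable violations (empty when the record is
    consistent).  Each violation names the offending field and, where
    applicable, the 1-based position index.
    """
    violations: list[str] = []
    n = record.n_residues

    bad = [aa for aa in set(record.sequence) if aa not in AA_INDEX]
    if bad:
        violations.append(
            f"sequence: non-standard residues {sorted(bad)!r}"
        )

    if record.calpha.ndim != 2 or record.calpha.shape[1] != 3:
        violations.append(f"calpha: expected shape (N, 3), got {record.calpha.shape}")
    elif record.calpha.shape[0] != n:
        violations.append(
            f"calpha: length mismatch ({record.calpha.shape[0]} coordinates "
            f"vs {n} residues)"
        )
    if not np.all(np.isfinite(record.calpha)):
        violations.append("calpha: non-finite coordinates")

    if record.profile.ndim != 2 or record.profile.shape[1] != len(AMINO_ACIDS):
        violations.append(
            f"profile: expected shape (N, 20), got {record.profile.shape}"
        )
    else:
        if record.profile.shape[0] != n:
            violations.append(
                f"profile: length mismatch ({record.profile.shape[0]} rows "
                f"vs {n} residues)"
            )
        if np.any(record.profile < 0):
            rows = np.where((record.profile < 0).any(axis=1))[0]
            violations.append(f"profile: negative frequencies at position {rows[0] + 1}")
        sums = record.profile.sum(axis=1)
        off = np.where(np.abs(sums - 1.0) > PROFILE_SUM_TOL)[0]
        for i in off:
            violations.append(
                f"profile: row at position {i + 1} sums to {sums[i]:.6g}, not 1"
            )

    if record.missense_scores is not None:
        ms = record.missense_scores
        if ms.ndim != 2 or ms.shape[1] != N_MISSENSE:
            violations.append(
                f"missense_scores: expected shape (N, 19), got {ms.shape}"
            )
        elif ms.shape[0] != n:
            violations.append(
                f"missense_scores: length mismatch ({ms.shape[0]} rows vs {n} residues)"
            )
        if ms.size and (np.nanmin(ms) < 0 or np.nanmax(ms) > 1):
            violations.append("missense_scores: values outside [0, 1]")

    ann = record.annotations
    if ann.ppi_count < 0:
        violations.append(f"annotations: ppi_count {ann.ppi_count} < 0")
    if ann.domain_ranges:
        for start, end in ann.domain_ranges:
            if not (1 <= start <= end <= n):
                violations.append(
                    f"annotations: domain interval [{start}, {end}] outside [1, {n}]"
                )

    return violations
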