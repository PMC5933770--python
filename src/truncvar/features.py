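"""Feature extraction for truncating variants.

A variant truncating protein ``r`` at 1-based position ``k`` is described by
nine feature groups:

* ``ref_aa`` (20) — one-hot of the wild-type residue at ``k``;
* ``contact_comp`` (20) — amino-acid composition of the residues whose
  C-alpha lies within a cutoff radius (default 12 A) of position ``k``'s
  C-alpha, ``q(a) = N(a) / sum_b N(b)``;
* ``domain_comp`` (20) — amino-acid composition of the annotated domain
  containing ``k`` (whole-protein composition when no domain covers ``k``);
* ``entropy`` (1) — position entropy relative to the protein mean,
  ``S_r(k) = S(k) - <S>`` with ``S = -sum_l f_l ln f_l``;
* ``frac_affected`` (1) — fraction of structure lost, ``(N_r - k) / N_r``;
* ``essential`` (1) — gene-essentiality indicator;
* ``pathogenicity`` (1) — mean, over positions strictly after ``k``, of the
  fraction of the 19 possible missense substitutions scoring at or above a
  pathogenicity threshold (default 0.45);
* ``disease`` (1) — disease-involvement count over two annotation sources
  (0, 1 or 2);
* ``ppi`` (1) — raw protein-protein interaction count.

The candidate schema carries all nine groups (66 values); the final schema
drops ``domain_comp`` (46 values).  Frameshift and nonsense variants at the
same position produce identical vectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datatypes import AA_INDEX, AMINO_ACIDS, N_MISSENSE, ProteinRecord, TruncatingVariant

logger = logging.getLogger(__name__)

DEFAULT_CONTACT_RADIUS = 12.0
DEFAULT_PATHOGENICITY_THRESHOLD = 0.45

#: Feature groups in assembly order, with their widths.
GROUP_WIDTHS: dict[str, int] = {
    "ref_aa": 20,
    "contact_comp": 20,
    "domain_comp": 20,
    "entropy": 1,
    "frac_affected": 1,
    "essential": 1,
    "pathogenicity": 1,
    "disease": 1,
    "ppi": 1,
}

ALL_GROUPS = tuple(GROUP_WIDTHS)


class FeatureError(ValueError):
    """A feature could not be computed for a variant."""


@dataclass(frozen=True)
class FeatureSchema:
    """An ordered subset of feature groups with named slots."""

    schema_id: str
    groups: tuple[str, ...]

    @classmethod
    def candidate66(cls) -> "FeatureSchema":
        return cls("candidate66", ALL_GROUPS)

    @classmethod
    def final46(cls) -> "FeatureSchema":
        return cls("final46", tuple(g for g in ALL_GROUPS if g != "domain_comp"))

    def without(self, group: str) -> "FeatureSchema":
        if group not in self.groups:
            raise ValueError(f"group {group!r} not in schema {self.schema_id!r}")
        return FeatureSchema(
            f"{self.schema_id}-no_{group}",
            tuple(g for g in self.groups if g != group),
        )

    @property
    def n_features(self) -> int:
        return sum(GROUP_WIDTHS[g] for g in self.groups)

    @property
    def columns(self) -> list[str]:
        names: list[str] = []
        for group in self.groups:
            if GROUP_WIDTHS[group] == 1:
                names.append(group)
            else:
                names.extend(f"{group}_{aa}" for aa in AMINO_ACIDS)
        return names


@dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray
    schema: FeatureSchema


def ref_aa_onehot(record: ProteinRecord, k: int) -> np.ndarray:
    """One-hot encoding of the wild-type residue at position ``k``."""
    _check_position(record, k)
    out = np.zeros(20)
    out[AA_INDEX[record.sequence[k - 1]]] = 1.0
    return out


def contact_composition(
    record: ProteinRecord, k: int, radius: float = DEFAULT_CONTACT_RADIUS
) -> np.ndarray:
    """Amino-acid composition of the structural neighborhood of position ``k``.

    Contacts are residues ``j != k`` whose C-alpha is within ``radius``
    Angstrom of position ``k``'s C-alpha (sequence neighbors included).
    Returns an all-zero block, with a warning, when no residue is in contact.
    """
    _check_position(record, k)
    if record.calpha.shape[0] != record.n_residues:
        raise FeatureError(f"{record.id}: structure/sequence length mismatch")
    delta = record.calpha - record.calpha[k - 1]
    dist = np.sqrt((delta**2).sum(axis=1))
    contact = dist <= radius
    contact[k - 1] = False
    out = np.zeros(20)
    if not contact.any():
        logger.warning(
            "%s position %d: no residue within %.1f A; zero contact block",
            record.id, k, radius,
        )
        return out
    for j in np.where(contact)[0]:
        out[AA_INDEX[record.sequence[j]]] += 1.0
    return out / out.sum()


def domain_composition(record: ProteinRecord, k: int) -> np.ndarray:
    """Amino-acid composition of the domain containing position ``k``.

    Falls back to whole-protein composition when no annotated domain covers
    ``k`` (or no domains are annotated at all).
    """
    _check_position(record, k)
    segment = record.sequence
    ranges = record.annotations.domain_ranges or []
    for start, end in ranges:
        if start <= k <= end:
            segment = record.sequence[start - 1 : end]
            break
    out = np.zeros(20)
    for aa in segment:
        out[AA_INDEX[aa]] += 1.0
    return out / out.sum()


def position_entropies(profile: np.ndarray) -> np.ndarray:
    """Shannon entropy ``-sum_l f_l ln f_l`` of each profile row (0 ln 0 = 0)."""
    profile = np.asarray(profile, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(profile > 0, profile * np.log(profile), 0.0)
    return -terms.sum(axis=1)


def sequence_entropy(record: ProteinRecord, k: int) -> float:
    """Mean-centred conservation entropy ``S_r(k) = S(k) - <S>``.

    ``<S>`` averages the per-position entropy over the entire protein, so
    the values sum to zero across positions; conserved positions are
    negative.
    """
    _check_position(record, k)
    entropies = position_entropies(record.profile)
    return float(entropies[k - 1] - entropies.mean())


def fraction_affected(n_residues: int, k: int) -> float:
    """Fraction of the structure lost to truncation: ``(N_r - k) / N_r``."""
    if not 1 <= k <= n_residues:
        raise FeatureError(f"position {k} outside [1, {n_residues}]")
    return (n_residues - k) / n_residues


def pathogenicity_affected(
    record: ProteinRecord,
    k: int,
    threshold: float = DEFAULT_PATHOGENICITY_THRESHOLD,
) -> float:
    """Mean per-position pathogenicity of the lost part of the protein.

    Each position ``j > k`` contributes the fraction of its 19 possible
    missense substitutions whose score is at or above ``threshold``; the
    truncation position itself is treated as still present.  Returns 0 when
    ``k = N_r`` (nothing is lost).
    """
    _check_position(record, k)
    if record.missense_scores is None:
        raise FeatureError(f"{record.id}: missense score matrix required")
    if k == record.n_residues:
        return 0.0
    tail = record.missense_scores[k:]
    per_position = (tail >= threshold).sum(axis=1) / N_MISSENSE
    return float(per_position.mean())


def annotation_features(record: ProteinRecord) -> tuple[int, int, int]:
    """Gene-level features: (essential 0/1, disease involvement 0-2, PPI count).

    Disease involvement adds the two annotation sources, so a gene flagged in
    both scores 2.
    """
    ann = record.annotations
    disease = int(ann.disease_genecards) + int(ann.disease_additional)
    return int(ann.essential), disease, int(ann.ppi_count)


def build_feature_vector(
    record: ProteinRecord,
    variant: TruncatingVariant,
    schema: FeatureSchema,
    contact_radius: float = DEFAULT_CONTACT_RADIUS,
    pathogenicity_threshold: float = DEFAULT_PATHOGENICITY_THRESHOLD,
) -> FeatureVector:
    """Assemble the full feature vector for one variant, in schema order.

    Frameshift and nonsense variants are featurized identically; only the
    protein and the truncation position matter.
    """
    if variant.protein_id != record.id:
        raise FeatureError(
            f"variant references {variant.protein_id!r}, record is {record.id!r}"
        )
    k = variant.k
    essential, disease, ppi = annotation_features(record)
    parts: list[np.ndarray] = []
    for group in schema.groups:
        if group == "ref_aa":
            parts.append(ref_aa_onehot(record, k))
        elif group == "contact_comp":
            parts.append(contact_composition(record, k, radius=contact_radius))
        elif group == "domain_comp":
            parts.append(domain_composition(record, k))
        elif group == "entropy":
            parts.append(np.array([sequence_entropy(record, k)]))
        elif group == "frac_affected":
            parts.append(np.array([fraction_affected(record.n_residues, k)]))
        elif group == "essential":
            parts.append(np.array([float(essential)]))
        elif group == "pathogenicity":
            parts.append(
                np.array(
                    [pathogenicity_affected(record, k, threshold=pathogenicity_threshold)]
                )
            )
        elif group == "disease":
            parts.append(np.array([float(disease)]))
        elif group == "ppi":
            parts.append(np.array([float(ppi)]))
        else:  # pragma: no cover - schema construction forbids this
            raise FeatureError(f"unknown feature group {group!r}")
    return FeatureVector(np.concatenate(parts), schema)


def featurize_dataset(
    proteins: dict[str, ProteinRecord],
    variants: list[TruncatingVariant],
    schema: FeatureSchema,
    contact_radius: float = DEFAULT_CONTACT_RADIUS,
    pathogenicity_threshold: float = DEFAULT_PATHOGENICITY_THRESHOLD,
):
    """Featurize a list of variants into a design matrix.

    Returns ``(frame, failures)`` where ``frame`` is a DataFrame with one
    named column per schema slot plus ``protein_id``, ``position``, ``type``
    and ``label``, and ``failures`` lists ``(variant, reason)`` pairs for
    variants whose features could not be computed.
    """
    import pandas as pd

    rows = []
    kept = []
    failures: list[tuple[TruncatingVariant, str]] = []
    for variant in variants:
        record = proteins.get(variant.protein_id)
        if record is None:
            failures.append((variant, "unknown protein"))
            continue
        try:
            vec = build_feature_vector(
                record,
                variant,
                schema,
                contact_radius=contact_radius,
                pathogenicity_threshold=pathogenicity_threshold,
            )
        except FeatureError as exc:
            failures.append((variant, str(exc)))
            continue
        rows.append(vec.values)
        kept.append(variant)
    frame = pd.DataFrame(
        np.asarray(rows).reshape(len(rows), schema.n_features),
        columns=schema.columns,
    )
    frame.insert(0, "protein_id", [v.protein_id for v in kept])
    frame.insert(1, "position", [v.k for v in kept])
    frame.insert(2, "type", [v.vtype for v in kept])
    frame["label"] = [v.label for v in kept]
    return frame, failures


def _check_position(record: ProteinRecord, k: int) -> None:
    if not 1 <= k <= record.n_residues:
        raise FeatureError(
            f"{record.id}: position {k} outside [1, {record.n_residues}]"
        )
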