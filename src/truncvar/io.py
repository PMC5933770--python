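"""Readers and writers for the on-disk cohort formats.

A cohort on disk consists of:

* ``proteins.fasta`` — amino-acid sequences (one record per protein id);
* ``structures/<id>.pdb`` — C-alpha coordinates (only ``ATOM``/``CA`` records
  are read; altLoc other than blank or ``A`` is ignored; residue order is
  file order and must match the sequence length);
* ``profiles/<id>.tsv`` — columns ``pos, A, C, ..., Y`` (alphabetical
  one-letter order), rows summing to one;
* ``missense/<id>.tsv`` (optional) — ``pos`` plus 19 per-substitution
  pathogenicity scores in [0, 1];
* an annotation table — ``protein_id, essential, disease_genecards,
  disease_additional, ppi_count, domains`` with domains encoded
  ``"s1-e1;s2-e2"`` (1-based inclusive) or empty;
* a variant table — ``protein_id, position, type, label``.

All positions are 1-based and inclusive.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.PDB import PDBParser

from .datatypes import (
    AMINO_ACIDS,
    N_MISSENSE,
    PROFILE_RENORM_TOL,
    PROFILE_SUM_TOL,
    GeneAnnotations,
    ProteinRecord,
    SkipRecord,
    TruncatingVariant,
    validate_protein,
)

logger = logging.getLogger(__name__)

PROFILE_COLUMNS = ["pos"] + list(AMINO_ACIDS)


class ParseError(ValueError):
    """A malformed input file; the message names the file (and row)."""


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read protein sequences keyed by record id."""
    path = Path(path)
    sequences: dict[str, str] = {}
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            sequences[rec.id] = str(rec.seq).upper()
    except (ValueError, FileNotFoundError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if not sequences:
        raise ParseError(f"{path}: no FASTA records found")
    return sequences


def read_calpha(path: str | Path) -> np.ndarray:
    """Read C-alpha coordinates from a PDB file, in file order.

    Only ``CA`` atoms with blank or ``'A'`` altLoc are kept.
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure(path.stem, str(path))
    except Exception as exc:  # Bio.PDB raises bare Exceptions on bad input
        raise ParseError(f"{path}: {exc}") from exc
    coords = []
    for atom in structure.get_atoms():
        if atom.get_name() != "CA":
            continue
        if atom.get_altloc() not in (" ", "", "A"):
            continue
        coords.append(atom.get_coord())
    if not coords:
        raise ParseError(f"{path}: no C-alpha ATOM records")
    return np.asarray(coords, dtype=float)


def read_profile(path: str | Path) -> np.ndarray:
    """Read a position-wise amino-acid frequency profile.

    Rows off unity by at most ``1e-3`` are renormalized; larger deviations
    raise :class:`ParseError`.
    """
    path = Path(path)
    frame = _read_tsv(path)
    missing = [c for c in PROFILE_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing profile columns {missing}")
    frame = frame.sort_values("pos")
    if not np.array_equal(frame["pos"].to_numpy(), np.arange(1, len(frame) + 1)):
        raise ParseError(f"{path}: positions are not contiguous from 1")
    profile = frame[list(AMINO_ACIDS)].to_numpy(dtype=float)
    sums = profile.sum(axis=1)
    off = np.abs(sums - 1.0)
    bad = np.where(off > PROFILE_RENORM_TOL)[0]
    if bad.size:
        raise ParseError(
            f"{path}: profile row at position {bad[0] + 1} sums to "
            f"{sums[bad[0]]:.6g} (tolerance {PROFILE_RENORM_TOL})"
        )
    if np.any(off > PROFILE_SUM_TOL):
        profile = profile / sums[:, None]
    return profile


def read_missense_scores(path: str | Path) -> np.ndarray:
    """Read a per-position matrix of 19 substitution pathogenicity scores."""
    path = Path(path)
    frame = _read_tsv(path)
    if "pos" not in frame.columns or frame.shape[1] != N_MISSENSE + 1:
        raise ParseError(
            f"{path}: expected 'pos' plus {N_MISSENSE} score columns, "
            f"got {frame.shape[1]}"
        )
    frame = frame.sort_values("pos")
    scores = frame.drop(columns="pos").to_numpy(dtype=float)
    if scores.size and (scores.min() < 0 or scores.max() > 1):
        raise ParseError(f"{path}: missense scores outside [0, 1]")
    return scores


def read_annotations(path: str | Path) -> dict[str, GeneAnnotations]:
    """Read the gene-level annotation table keyed by protein id."""
    path = Path(path)
    frame = _read_tsv(path)
    required = [
        "protein_id",
        "essential",
        "disease_genecards",
        "disease_additional",
        "ppi_count",
    ]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing annotation columns {missing}")
    table: dict[str, GeneAnnotations] = {}
    for row in frame.itertuples(index=False):
        domains = None
        raw = getattr(row, "domains", None)
        if isinstance(raw, str) and raw.strip():
            try:
                domains = [
                    tuple(int(x) for x in part.split("-"))
                    for part in raw.split(";")
                ]
            except ValueError as exc:
                raise ParseError(
                    f"{path}: bad domain spec {raw!r} for {row.protein_id}"
                ) from exc
        table[str(row.protein_id)] = GeneAnnotations(
            essential=bool(int(row.essential)),
            disease_genecards=bool(int(row.disease_genecards)),
            disease_additional=bool(int(row.disease_additional)),
            ppi_count=int(row.ppi_count),
            domain_ranges=domains,
        )
    return table


def read_variants(path: str | Path) -> list[TruncatingVariant]:
    """Read the variant table."""
    path = Path(path)
    frame = _read_tsv(path)
    required = ["protein_id", "position", "type", "label"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing variant columns {missing}")
    variants = []
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            variants.append(
                TruncatingVariant(
                    protein_id=str(row.protein_id),
                    k=int(row.position),
                    vtype=str(row.type),
                    label=str(row.label),
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}: line {i}: {exc}") from exc
    return variants


def _read_tsv(path: Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t")
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc


def load_dataset(
    fasta_path: str | Path,
    structure_dir: str | Path,
    profile_dir: str | Path,
    annotation_table: str | Path,
    variant_table: str | Path,
    missense_dir: Optional[str | Path] = None,
) -> tuple[dict[str, ProteinRecord], list[TruncatingVariant], list[SkipRecord]]:
    """Assemble a cohort from its on-disk pieces.

    Every returned variant references a complete, validated
    :class:`ProteinRecord`.  Variants whose protein lacks a structure,
    profile, or whose files are inconsistent are returned as
    :class:`SkipRecord` entries with a reason — never silently dropped.
    The skip records and the loaded variants exactly partition the input
    variant table.
    """
    structure_dir = Path(structure_dir)
    profile_dir = Path(profile_dir)
    missense_dir = Path(missense_dir) if missense_dir is not None else None

    sequences = read_fasta(fasta_path)
    annotations = read_annotations(annotation_table)
    all_variants = read_variants(variant_table)

    proteins: dict[str, ProteinRecord] = {}
    failure: dict[str, str] = {}
    for pid, seq in sequences.items():
        reason = None
        calpha = profile = scores = None
        spath = structure_dir / f"{pid}.pdb"
        ppath = profile_dir / f"{pid}.tsv"
        if not spath.exists():
            reason = "no structure"
        elif not ppath.exists():
            reason = "no profile"
        else:
            try:
                calpha = read_calpha(spath)
                profile = read_profile(ppath)
            except ParseError as exc:
                reason = str(exc)
        if reason is None and missense_dir is not None:
            mpath = missense_dir / f"{pid}.tsv"
            if mpath.exists():
                try:
                    scores = read_missense_scores(mpath)
                except ParseError as exc:
                    reason = str(exc)
        if reason is None:
            record = ProteinRecord(
                id=pid,
                sequence=seq,
                calpha=calpha,
                profile=profile,
                missense_scores=scores,
                annotations=annotations.get(pid, GeneAnnotations()),
            )
            if pid not in annotations:
                logger.warning("no annotation row for %s; using all-zero flags", pid)
            violations = validate_protein(record)
            if violations:
                reason = "; ".join(violations)
            else:
                proteins[pid] = record
        if reason is not None:
            failure[pid] = reason

    variants: list[TruncatingVariant] = []
    skips: list[SkipRecord] = []
    for var in all_variants:
        if var.protein_id in proteins:
            record = proteins[var.protein_id]
            if 1 <= var.k <= record.n_residues:
                variants.append(var)
            else:
                skips.append(
                    SkipRecord(var.protein_id, var.k, var.vtype, "position out of range")
                )
        else:
            reason = failure.get(var.protein_id, "unknown protein")
            skips.append(SkipRecord(var.protein_id, var.k, var.vtype, reason))
    return proteins, variants, skips


def write_predictions(
    path: str | Path,
    variants: list[TruncatingVariant],
    scores,
    p_values=None,
    cutoff: float = 0.5,
) -> None:
    """Write a prediction table: one row per variant.

    The call is ``disease-associated`` iff ``score >= cutoff`` (inclusive).
    Scores are written with six decimals.
    """
    scores = np.asarray(scores, dtype=float)
    if len(scores) != len(variants):
        raise ValueError(
            f"{len(variants)} variants but {len(scores)} scores"
        )
    if scores.size and not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if p_values is None:
        p_values = np.full(len(variants), np.nan)
    p_values = np.asarray(p_values, dtype=float)
    if len(p_values) != len(variants):
        raise ValueError(
            f"{len(variants)} variants but {len(p_values)} p-values"
        )
    frame = pd.DataFrame(
        {
            "protein_id": [v.protein_id for v in variants],
            "position": [v.k for v in variants],
            "type": [v.vtype for v in variants],
            "score": [f"{s:.6f}" for s in scores],
            "p_value": [f"{p:.6g}" if np.isfinite(p) else "NA" for p in p_values],
            "call": [
                "disease-associated" if s >= cutoff else "neutral" for s in scores
            ],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def read_predictions(path: str | Path) -> pd.DataFrame:
    """Read back a prediction table written by :func:`write_predictions`."""
    frame = pd.read_csv(path, sep="\t", na_values=["NA"])
    expected = {"protein_id", "position", "type", "score", "p_value", "call"}
    missing = expected - set(frame.columns)
    if missing:
        raise ParseError(f"{path}: missing prediction columns {sorted(missing)}")
    return frame
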