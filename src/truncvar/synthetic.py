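"""Synthetic cohort generator with controllable planted signal.

Generates complete cohorts — sequences, C-alpha models, conservation
profiles, missense score matrices, gene annotations and labeled truncating
variants — so the whole pipeline is testable without external downloads.

What it emulates: the statistical structure the classifier assumes.
Pathogenic truncations are enriched at conserved positions (low relative
entropy), in essential/disease-annotated genes, and where a large fraction
of the protein is lost.  Labels are drawn from a logistic model over those
three directions with configurable effect sizes, so ground-truth feature
informativeness is known.

What it does not emulate: real fold geometry (structures are self-avoiding
random walks — contact neighborhoods are non-degenerate but not native),
realistic family structure (a few mutated-copy homolog pairs stand in for
real homology so identity clustering has work to do), or real mutational
spectra and allele frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .datatypes import (
    AMINO_ACIDS,
    N_MISSENSE,
    GeneAnnotations,
    ProteinRecord,
    TruncatingVariant,
)

CA_STEP = 3.8  # Angstrom, consecutive C-alpha distance
MIN_CLASH = 3.4  # Angstrom, self-avoidance radius


@dataclass
class CohortSpec:
    """Generation parameters for one synthetic cohort.

    Effect sizes act on standardized feature directions in the logistic
    label model: ``beta_cons`` on position conservation, ``beta_frac`` on
    the affected fraction ``(N_r - k)/N_r``, ``beta_ann`` on the combined
    essentiality/disease annotation score.  All-zero effects give labels
    independent of every feature.
    """

    n_proteins: int = 40
    length_range: tuple[int, int] = (100, 140)
    n_homolog_pairs: int = 4
    fraction_essential: float = 0.3
    fraction_disease: float = 0.4
    fraction_disease_additional: float = 0.2
    ppi_log_mean: float = 2.5
    ppi_log_sigma: float = 1.0
    n_variants: int = 400
    pathogenic_fraction: float = 0.5
    beta_cons: float = 2.0
    beta_frac: float = 4.0
    beta_ann: float = 2.0
    seed: int = 0

    def __post_init__(self):
        for name in ("fraction_essential", "fraction_disease",
                     "fraction_disease_additional", "pathogenic_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.length_range[0] < 30:
            raise ValueError("protein lengths must be at least 30")


@dataclass
class Cohort:
    proteins: dict[str, ProteinRecord]
    variants: list[TruncatingVariant]
    spec: CohortSpec
    conservation: dict[str, np.ndarray] = field(default_factory=dict)


def _self_avoiding_walk(n: int, rng: np.random.Generator) -> np.ndarray:
    """C-alpha trace: 3.8 A steps, no two residues closer than 3.4 A."""
    for _ in range(40):  # chain restarts
        coords = np.zeros((n, 3))
        ok = True
        for i in range(1, n):
            for _ in range(120):  # per-step retries
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                candidate = coords[i - 1] + CA_STEP * direction
                if i < 2:
                    break
                dists = np.linalg.norm(coords[: i - 1] - candidate, axis=1)
                if dists.min() >= MIN_CLASH:
                    break
            else:
                ok = False
                break
            coords[i] = candidate
        if ok:
            return coords
    raise RuntimeError(f"self-avoiding walk failed for length {n}")


def _make_protein(pid: str, length: int, spec: CohortSpec,
                  rng: np.random.Generator,
                  sequence: str | None = None) -> tuple[ProteinRecord, np.ndarray]:
    if sequence is None:
        seq_idx = rng.integers(0, 20, size=length)
        sequence = "".join(AMINO_ACIDS[i] for i in seq_idx)
    else:
        seq_idx = np.array([AMINO_ACIDS.index(aa) for aa in sequence])
    calpha = _self_avoiding_walk(length, rng)

    # Per-position conservation weight: profile mixes a delta on the wild
    # type with a protein-wide background.
    conservation = rng.beta(2.0, 2.0, size=length)
    background = rng.dirichlet(np.ones(20))
    profile = conservation[:, None] * np.eye(20)[seq_idx] + (
        1.0 - conservation[:, None]
    ) * background
    profile /= profile.sum(axis=1, keepdims=True)

    # Missense scores track conservation with noise, clipped to [0, 1].
    missense = np.clip(
        conservation[:, None] + rng.normal(0.0, 0.15, size=(length, N_MISSENSE)),
        0.0,
        1.0,
    )

    domains = None
    if rng.random() < 0.7:
        n_dom = int(rng.integers(1, 3))
        edges = np.sort(rng.choice(np.arange(2, length), size=2 * n_dom, replace=False))
        domains = [
            (int(edges[2 * i]), int(edges[2 * i + 1])) for i in range(n_dom)
        ]

    annotations = GeneAnnotations(
        essential=bool(rng.random() < spec.fraction_essential),
        disease_genecards=bool(rng.random() < spec.fraction_disease),
        disease_additional=bool(rng.random() < spec.fraction_disease_additional),
        ppi_count=int(rng.lognormal(spec.ppi_log_mean, spec.ppi_log_sigma)),
        domain_ranges=domains,
    )
    record = ProteinRecord(
        id=pid,
        sequence=sequence,
        calpha=calpha,
        profile=profile,
        missense_scores=missense,
        annotations=annotations,
    )
    return record, conservation


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a cohort of proteins and labeled truncating variants.

    Fully deterministic given ``spec.seed``.  The logistic intercept is
    solved so that the expected pathogenic fraction matches the cohort spec.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.n_homolog_pairs * 2 > spec.n_proteins:
        raise ValueError("too many homolog pairs for the protein count")
    proteins: dict[str, ProteinRecord] = {}
    conservation: dict[str, np.ndarray] = {}
    n_base = spec.n_proteins - spec.n_homolog_pairs
    lengths = rng.integers(spec.length_range[0], spec.length_range[1] + 1,
                           size=n_base)
    for i in range(n_base):
        pid = f"P{i:04d}"
        record, cons = _make_protein(pid, int(lengths[i]), spec, rng)
        proteins[pid] = record
        conservation[pid] = cons
    # A few genuine homolog pairs (~60% identity) so identity clustering
    # has non-singleton clusters to keep together.
    for i in range(spec.n_homolog_pairs):
        parent = proteins[f"P{i:04d}"]
        pid = f"P{n_base + i:04d}"
        mutate = rng.random(parent.n_residues) < 0.4
        seq = "".join(
            AMINO_ACIDS[rng.integers(0, 20)] if m else aa
            for aa, m in zip(parent.sequence, mutate)
        )
        record, cons = _make_protein(pid, parent.n_residues, spec, rng, sequence=seq)
        proteins[pid] = record
        conservation[pid] = cons

    ids = sorted(proteins)
    pick = rng.integers(0, len(ids), size=spec.n_variants)
    positions = np.array(
        [rng.integers(1, proteins[ids[j]].n_residues + 1) for j in pick]
    )
    vtypes = np.where(rng.random(spec.n_variants) < 0.5, "frameshift", "nonsense")

    # Feature directions for the planted logistic label model.
    cons_raw = np.array(
        [
            conservation[ids[j]][k - 1] - conservation[ids[j]].mean()
            for j, k in zip(pick, positions)
        ]
    )
    frac_raw = np.array(
        [
            (proteins[ids[j]].n_residues - k) / proteins[ids[j]].n_residues
            for j, k in zip(pick, positions)
        ]
    )
    ann_raw = np.array(
        [
            int(proteins[ids[j]].annotations.essential)
            + int(proteins[ids[j]].annotations.disease_genecards)
            + int(proteins[ids[j]].annotations.disease_additional)
            for j in pick
        ],
        dtype=float,
    )

    def standardize(v):
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    linear = (
        spec.beta_cons * standardize(cons_raw)
        + spec.beta_frac * standardize(frac_raw)
        + spec.beta_ann * standardize(ann_raw)
    )

    target = spec.pathogenic_fraction
    if target <= 0.0:
        probs = np.zeros_like(linear)
    elif target >= 1.0:
        probs = np.ones_like(linear)
    else:
        intercept = brentq(
            lambda b: expit(linear + b).mean() - target, -60.0, 60.0
        )
        probs = expit(linear + intercept)
    labels = np.where(rng.random(spec.n_variants) < probs, "pathogenic", "neutral")

    variants = [
        TruncatingVariant(
            protein_id=ids[j],
            k=int(k),
            vtype=str(t),
            label=str(l),
        )
        for j, k, t, l in zip(pick, positions, vtypes, labels)
    ]
    return Cohort(proteins=proteins, variants=variants, spec=spec,
                  conservation=conservation)


def generate_null_scores(
    n: int, params, seed: int = 0
) -> tuple[np.ndarray, dict[str, float]]:
    """Draw i.i.d. scores from the extreme-value null, clipped to [0, 1].

    Returns the clipped scores and the fractions clipped at each end
    (``lower``: mass below 0; ``upper``: mass above 1).
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    raw = rng.gumbel(loc=params.mu, scale=params.sigma, size=n)
    clip_info = {
        "lower": float((raw < 0).mean()),
        "upper": float((raw > 1).mean()),
    }
    return np.clip(raw, 0.0, 1.0), clip_info


def write_cohort(cohort: Cohort, outdir: str | Path) -> Path:
    """Write a cohort in the exact on-disk formats the loaders read.

    Layout: ``proteins.fasta``, ``structures/<id>.pdb``,
    ``profiles/<id>.tsv``, ``missense/<id>.tsv``, ``annotations.tsv``,
    ``variants.tsv``.  Deterministic: the same cohort writes byte-identical
    files.
    """
    outdir = Path(outdir)
    (outdir / "structures").mkdir(parents=True, exist_ok=True)
    (outdir / "profiles").mkdir(exist_ok=True)
    (outdir / "missense").mkdir(exist_ok=True)

    with open(outdir / "proteins.fasta", "w") as fh:
        for pid in sorted(cohort.proteins):
            fh.write(f">{pid}\n{cohort.proteins[pid].sequence}\n")

    three_letter = {
        "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
        "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
        "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
        "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
    }
    for pid in sorted(cohort.proteins):
        record = cohort.proteins[pid]
        lines = []
        for i, (aa, xyz) in enumerate(zip(record.sequence, record.calpha), start=1):
            lines.append(
                f"ATOM  {i:5d}  CA  {three_letter[aa]} A{i:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00           C"
            )
        lines.append("END")
        (outdir / "structures" / f"{pid}.pdb").write_text("\n".join(lines) + "\n")

    for pid in sorted(cohort.proteins):
        record = cohort.proteins[pid]
        header = "pos\t" + "\t".join(AMINO_ACIDS)
        rows = [header]
        for i, freqs in enumerate(record.profile, start=1):
            rows.append(f"{i}\t" + "\t".join(f"{f:.8f}" for f in freqs))
        (outdir / "profiles" / f"{pid}.tsv").write_text("\n".join(rows) + "\n")

        header = "pos\t" + "\t".join(f"m{j}" for j in range(1, N_MISSENSE + 1))
        rows = [header]
        for i, scores in enumerate(record.missense_scores, start=1):
            rows.append(f"{i}\t" + "\t".join(f"{s:.6f}" for s in scores))
        (outdir / "missense" / f"{pid}.tsv").write_text("\n".join(rows) + "\n")

    rows = ["protein_id\tessential\tdisease_genecards\tdisease_additional\tppi_count\tdomains"]
    for pid in sorted(cohort.proteins):
        ann = cohort.proteins[pid].annotations
        domains = (
            ";".join(f"{s}-{e}" for s, e in ann.domain_ranges)
            if ann.domain_ranges
            else ""
        )
        rows.append(
            f"{pid}\t{int(ann.essential)}\t{int(ann.disease_genecards)}\t"
            f"{int(ann.disease_additional)}\t{ann.ppi_count}\t{domains}"
        )
    (outdir / "annotations.tsv").write_text("\n".join(rows) + "\n")

    rows = ["protein_id\tposition\ttype\tlabel"]
    for v in cohort.variants:
        rows.append(f"{v.protein_id}\t{v.k}\t{v.vtype}\t{v.label}")
    (outdir / "variants.tsv").write_text("\n".join(rows) + "\n")
    return outdir
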