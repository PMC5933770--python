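import numpy as np
import pytest

from truncvar import CohortSpec, GeneAnnotations, ProteinRecord, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small deterministic cohort with planted signal for plumbing tests."""
    return generate_cohort(
        CohortSpec(n_proteins=12, n_variants=60, n_homolog_pairs=2, seed=42)
    )


def make_protein(
    sequence: str,
    calpha=None,
    profile=None,
    missense=None,
    annotations=None,
    pid: str = "PX",
) -> ProteinRecord:
    """Hand-build a consistent ProteinRecord, defaulting to benign fillers."""
    n = len(sequence)
    if calpha is None:
        # collinear chain at consecutive-residue spacing
        calpha = np.column_stack([3.8 * np.arange(n), np.zeros(n), np.zeros(n)])
    if profile is None:
        profile = np.full((n, 20), 1 / 20)
    return ProteinRecord(
        id=pid,
        sequence=sequence,
        calpha=np.asarray(calpha, dtype=float),
        profile=np.asarray(profile, dtype=float),
        missense_scores=None if missense is None else np.asarray(missense, float),
        annotations=annotations or GeneAnnotations(),
    )
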