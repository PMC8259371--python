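from __future__ import annotations

import numpy as np
import pytest

from karyomorph.karyomorphometry import MeanKaryotype, chromosome_stats
from karyomorph.measurements_io import (
    AccessionDataset,
    ChromosomeMeasurement,
    MetaphasePlate,
    load_reference_matrix,
    load_reference_summaries,
)


def make_plate(arms, plate_id="plate1", accession_id="acc"):
    """Plate from a list of (arm_a, arm_b) tuples (canonicalized on build)."""
    measurements = tuple(
        ChromosomeMeasurement.canonical(accession_id, plate_id, f"c{i}", a, b)
        for i, (a, b) in enumerate(arms)
    )
    return MetaphasePlate(plate_id, measurements)


def make_dataset(plates_arms, accession_id="acc", two_n=None):
    """Dataset from a list of plates, each a list of (arm_a, arm_b)."""
    plates = tuple(
        make_plate(arms, plate_id=f"plate{i}", accession_id=accession_id)
        for i, arms in enumerate(plates_arms)
    )
    if two_n is None:
        two_n = plates[0].count
    return AccessionDataset(accession_id, two_n, plates)


def make_karyotype(arm_pairs, accession_id="acc", n_plates=1):
    """Haploid MeanKaryotype directly from (p, q) tuples."""
    chromosomes = sorted(
        (chromosome_stats(min(a, b), max(a, b)) for a, b in arm_pairs),
        key=lambda s: (-s.cl, s.ci),
    )
    return MeanKaryotype(
        accession_id=accession_id,
        chromosomes=tuple(chromosomes),
        n_plates=n_plates,
        two_n=2 * len(chromosomes),
    )


@pytest.fixture(scope="session")
def reference_matrix():
    return load_reference_matrix()


@pytest.fixture(scope="session")
def reference_summaries():
    return load_reference_summaries()


@pytest.fixture
def rng():
    return np.random.default_rng(42)
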