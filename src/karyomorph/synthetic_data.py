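"""Synthetic measurement generator with known ground truth.

Emulates the structure of real metaphase measurement campaigns: a true
haploid karyotype with a prescribed class composition and total length,
several plates per accession, a per-plate condensation scale factor, and
multiplicative measurement noise on each arm.  Everything is deterministic
given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import KaryomorphError
from .karyomorphometry import MeanKaryotype, chromosome_stats
from .measurements_io import (
    LEVAN_CLASSES,
    AccessionDataset,
    ChromosomeMeasurement,
    KaryotypeFormula,
    KaryotypeSummary,
    MetaphasePlate,
)

#: Arm-ratio sampling interval per class, kept 0.1 away from the class
#: boundaries (1.7 / 3.0 / 7.0) so noisy recovery of the class tally is a
#: fair deterministic test.  ``t`` has no upper boundary; 9.0 is arbitrary.
_RATIO_RANGES = {
    "m": (1.0, 1.6),
    "sm": (1.8, 2.9),
    "st": (3.1, 6.9),
    "t": (7.1, 9.0),
}


@dataclass(frozen=True)
class AccessionSpec:
    """Ground-truth description of one synthetic accession."""

    accession_id: str
    two_n: int
    target_kf: Mapping[str, int]
    target_thcl: float
    length_spread: float  # target CV of chromosome lengths, percent
    n_plates: int = 6
    condensation_sd: float = 0.0  # SD of log plate scale factor
    noise_sd: float = 0.0  # SD of log per-arm noise factor
    seed: int = 0
    #: minimum relative length gap between adjacent true chromosomes, so
    #: rank-based cross-plate averaging cannot mix distinct chromosomes
    #: (0 disables; ignored when length_spread is 0)
    min_length_gap: float = 0.06

    def __post_init__(self) -> None:
        object.__setattr__(self, "target_kf", dict(self.target_kf))
        if self.two_n <= 0 or self.two_n % 2:
            raise KaryomorphError(f"2n must be positive and even, got {self.two_n}")
        n = self.two_n // 2
        kf = KaryotypeFormula(self.target_kf)
        if kf.n != n:
            raise KaryomorphError(
                f"karyotype formula counts sum to {kf.n}, expected n={n}"
            )
        if self.target_thcl <= 0:
            raise KaryomorphError("target THCL must be positive")
        if self.length_spread < 0 or self.condensation_sd < 0 or self.noise_sd < 0:
            raise KaryomorphError("spreads and noise SDs must be >= 0")
        if self.n_plates < 1:
            raise KaryomorphError("need at least one plate")
        if not (0 <= self.min_length_gap < 1):
            raise KaryomorphError("min_length_gap must be in [0, 1)")

    @property
    def n(self) -> int:
        return self.two_n // 2

    @property
    def kf(self) -> KaryotypeFormula:
        return KaryotypeFormula(self.target_kf)


def _draw_lengths(spec: AccessionSpec, rng: np.random.Generator) -> np.ndarray:
    """Chromosome lengths summing exactly to target THCL with approximately
    the requested CV, via a symmetric Dirichlet draw."""
    n = spec.n
    if n == 1 or spec.length_spread == 0:
        return np.full(n, spec.target_thcl / n)
    cv = spec.length_spread / 100.0
    # CV of a symmetric Dirichlet(alpha) component is sqrt((n-1)/(n*alpha+1))
    if cv**2 >= n - 1:
        raise KaryomorphError(
            f"length_spread {spec.length_spread} is infeasible for n={n}"
        )
    alpha = ((n - 1) / cv**2 - 1.0) / n
    weights = rng.dirichlet(np.full(n, alpha))
    lengths = np.sort(weights)[::-1] * spec.target_thcl
    if spec.min_length_gap > 0:
        # cap each length at (1 - gap) of its larger neighbour, then restore
        # the exact sum; realized CV may exceed the target slightly
        for i in range(1, n):
            lengths[i] = min(lengths[i], lengths[i - 1] * (1.0 - spec.min_length_gap))
        lengths *= spec.target_thcl / lengths.sum()
    return lengths


def generate_truth(spec: AccessionSpec) -> MeanKaryotype:
    """The true haploid karyotype: lengths sum exactly to the target THCL and
    every chromosome's arm ratio sits inside its assigned class interval,
    at least 0.1 from the boundaries."""
    rng = np.random.default_rng(spec.seed)
    return _truth_with_rng(spec, rng)


def _truth_with_rng(spec: AccessionSpec, rng: np.random.Generator) -> MeanKaryotype:
    lengths = _draw_lengths(spec, rng)
    classes = [c for c in LEVAN_CLASSES for _ in range(spec.kf.count(c))]
    rng.shuffle(classes)
    chromosomes = []
    for cl, levan in zip(lengths, classes):
        lo, hi = _RATIO_RANGES[levan]
        r = float(rng.uniform(lo, hi))
        p = cl / (1.0 + r)
        chromosomes.append(chromosome_stats(p, cl - p))
    chromosomes.sort(key=lambda s: (-s.cl, s.ci))
    return MeanKaryotype(
        accession_id=spec.accession_id,
        chromosomes=tuple(chromosomes),
        n_plates=0,
        two_n=spec.two_n,
    )


def generate_dataset(spec: AccessionSpec) -> AccessionDataset:
    """Simulated measurement dataset for one accession.

    Each plate receives a lognormal condensation scale factor; each true
    chromosome is emitted twice (the homolog pair) with independent
    lognormal noise on every arm; rows are shuffled within the plate.  The
    generating truth is attached as ``dataset.truth``.
    """
    rng = np.random.default_rng(spec.seed)
    truth = _truth_with_rng(spec, rng)

    plates = []
    for plate_idx in range(spec.n_plates):
        plate_id = f"plate{plate_idx + 1:02d}"
        scale = float(rng.lognormal(0.0, spec.condensation_sd)) if spec.condensation_sd else 1.0
        rows = []
        copy_idx = 0
        for chrom in truth.chromosomes:
            for _ in range(2):  # homolog pair
                copy_idx += 1
                noise_p = float(rng.lognormal(0.0, spec.noise_sd)) if spec.noise_sd else 1.0
                noise_q = float(rng.lognormal(0.0, spec.noise_sd)) if spec.noise_sd else 1.0
                rows.append(
                    ChromosomeMeasurement.canonical(
                        spec.accession_id,
                        plate_id,
                        f"c{copy_idx:02d}",
                        chrom.p * scale * noise_p,
                        chrom.q * scale * noise_q,
                    )
                )
        order = rng.permutation(len(rows))
        plates.append(MetaphasePlate(plate_id, tuple(rows[i] for i in order)))

    return AccessionDataset(
        accession_id=spec.accession_id,
        two_n=spec.two_n,
        plates=tuple(plates),
        truth=truth,
    )


def generate_cohort(specs: Sequence[AccessionSpec]) -> list[AccessionDataset]:
    """One synthetic dataset per spec (empty input yields an empty cohort)."""
    return [generate_dataset(s) for s in specs]


def specs_from_summaries(
    summaries: Sequence[KaryotypeSummary],
    *,
    n_plates: int = 8,
    condensation_sd: float = 0.05,
    noise_sd: float = 0.03,
    seed: int = 0,
) -> list[AccessionSpec]:
    """Build accession specs whose truths mimic existing summary rows
    (class composition, THCL, and length spread taken from each row)."""
    return [
        AccessionSpec(
            accession_id=s.accession_id,
            two_n=s.two_n,
            target_kf=dict(s.kf.counts),
            target_thcl=s.thcl,
            length_spread=s.cv_cl,
            n_plates=n_plates,
            condensation_sd=condensation_sd,
            noise_sd=noise_sd,
            seed=seed + i,
        )
        for i, s in enumerate(summaries)
    ]


def write_truth_table(truth: MeanKaryotype, path, *, header_comment: str | None = None) -> None:
    """Sidecar ground-truth file: one row per true haploid chromosome."""
    from .measurements_io import _write_csv

    rows = [
        {
            "position": k + 1,
            "p": c.p,
            "q": c.q,
            "cl": c.cl,
            "ci": c.ci,
            "r": c.r,
            "class": c.levan_class,
        }
        for k, c in enumerate(truth.chromosomes)
    ]
    _write_csv(pd.DataFrame(rows), path, header_comment)
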