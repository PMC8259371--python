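"""Per-chromosome statistics, homolog pairing, mean haploid karyotypes, and
the karyotype-level descriptive and asymmetry statistics.

Conventions
-----------
* Centromeric index CI = 100·p/(p+q) on the short arm, so CI <= 50.
* Arm ratio r = q/p >= 1; centromere-position classes follow the intervals
  m: 1.0–1.7, sm: 1.7–3.0, st: 3.0–7.0, t: > 7.0, with boundary values
  assigned to the less asymmetric class.
* Coefficients of variation use the sample (n−1) standard deviation by
  default; ``sd="population"`` switches to the n denominator.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import networkx as nx
import numpy as np

from .errors import KaryomorphError, MeasurementError
from .measurements_io import (
    AccessionDataset,
    KaryotypeFormula,
    KaryotypeSummary,
    MetaphasePlate,
)

#: Upper arm-ratio bound (inclusive) per class; ``t`` is unbounded above.
LEVAN_UPPER_BOUNDS = (("m", 1.7), ("sm", 3.0), ("st", 7.0), ("t", math.inf))

PairingMode = Literal["matched", "sorted"]
AveragingMode = Literal["absolute", "relative"]
SdConvention = Literal["sample", "population"]


@dataclass(frozen=True)
class ChromosomeStats:
    """Derived morphometry of a single (possibly averaged) chromosome."""

    p: float
    q: float
    cl: float
    ci: float
    r: float
    levan_class: str

    @classmethod
    def from_arms(cls, p: float, q: float) -> "ChromosomeStats":
        return chromosome_stats(p, q)


@dataclass(frozen=True)
class MeanKaryotype:
    """Ordered haploid complement of averaged chromosomes (position 1 = longest)."""

    accession_id: str
    chromosomes: tuple[ChromosomeStats, ...]
    n_plates: int
    two_n: int
    ploidy: int = 2

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosomes", tuple(self.chromosomes))
        if len(self.chromosomes) != self.two_n // 2:
            raise KaryomorphError(
                f"haploid complement has {len(self.chromosomes)} chromosomes, "
                f"expected n={self.two_n // 2}"
            )
        lengths = [c.cl for c in self.chromosomes]
        if any(a < b - 1e-9 for a, b in zip(lengths, lengths[1:])):
            raise KaryomorphError("chromosomes not ordered by non-increasing length")

    @property
    def n(self) -> int:
        return len(self.chromosomes)

    @property
    def x(self) -> int:
        return self.two_n // self.ploidy


def classify_levan(r: float) -> str:
    """Map an arm ratio to a centromere-position class (m/sm/st/t).

    Boundary ratios go to the less asymmetric class: r=1.7 -> m,
    r=3.0 -> sm, r=7.0 -> st.
    """
    if r < 1:
        raise KaryomorphError(f"arm ratio must be >= 1, got {r}")
    for cls, upper in LEVAN_UPPER_BOUNDS:
        if r <= upper:
            return cls
    raise AssertionError("unreachable")


def chromosome_stats(p: float, q: float) -> ChromosomeStats:
    """Compute CL, CI, arm ratio and centromere class from canonical arms (0 < p <= q)."""
    if p <= 0:
        raise MeasurementError(f"short arm must be positive, got {p}")
    if p > q:
        raise MeasurementError(f"arms not canonical (p={p} > q={q})")
    cl = p + q
    r = q / p
    return ChromosomeStats(p=p, q=q, cl=cl, ci=100.0 * p / cl, r=r, levan_class=classify_levan(r))


# ---------------------------------------------------------------------------
# homolog pairing
# ---------------------------------------------------------------------------


def _pair_cost(a: ChromosomeStats, b: ChromosomeStats, mean_cl: float) -> float:
    return abs(a.cl - b.cl) / mean_cl + abs(a.ci - b.ci) / 50.0


def match_homolog_indices(
    plate: MetaphasePlate, *, mode: PairingMode = "matched"
) -> list[tuple[int, int]]:
    """Indices (into ``plate.measurements``) of the n homolog pairs.

    ``matched`` solves a minimum-cost perfect matching with cost
    |ΔCL|/mean CL + |ΔCI|/50; ``sorted`` pairs adjacent chromosomes after
    sorting by length.
    """
    if plate.count % 2:
        raise MeasurementError(
            f"plate {plate.plate_id!r} has an odd chromosome count ({plate.count})"
        )
    if plate.count == 0:
        raise MeasurementError(f"plate {plate.plate_id!r} is empty")

    stats = [chromosome_stats(m.p, m.q) for m in plate.measurements]
    if mode == "sorted":
        order = sorted(range(len(stats)), key=lambda i: (-stats[i].cl, stats[i].ci, i))
        return [(order[k], order[k + 1]) for k in range(0, len(order), 2)]
    if mode == "matched":
        mean_cl = float(np.mean([s.cl for s in stats]))
        graph = nx.Graph()
        graph.add_nodes_from(range(len(stats)))
        for i, j in itertools.combinations(range(len(stats)), 2):
            graph.add_edge(i, j, weight=_pair_cost(stats[i], stats[j], mean_cl))
        matching = nx.min_weight_matching(graph)
        return sorted(tuple(sorted(e)) for e in matching)
    raise KaryomorphError(f"unknown pairing mode {mode!r}")


def pair_homologs(
    plate: MetaphasePlate, *, mode: PairingMode = "matched"
) -> tuple[ChromosomeStats, ...]:
    """Pair the 2n chromosomes of a plate into n homolog pairs and average them arm-wise.

    Partner selection is delegated to :func:`match_homolog_indices`; the n
    averaged chromosomes are returned sorted by decreasing length.
    """
    pairs = match_homolog_indices(plate, mode=mode)
    stats = [chromosome_stats(m.p, m.q) for m in plate.measurements]
    averaged = [
        chromosome_stats((stats[i].p + stats[j].p) / 2.0, (stats[i].q + stats[j].q) / 2.0)
        for i, j in pairs
    ]
    averaged.sort(key=lambda s: (-s.cl, s.ci))
    return tuple(averaged)


def total_pairing_cost(
    stats: Sequence[ChromosomeStats], pairs: Sequence[tuple[int, int]]
) -> float:
    """Sum of pair costs for an explicit matching over *stats* (used by tests/oracles)."""
    mean_cl = float(np.mean([s.cl for s in stats]))
    return sum(_pair_cost(stats[i], stats[j], mean_cl) for i, j in pairs)


# ---------------------------------------------------------------------------
# mean karyotype
# ---------------------------------------------------------------------------


def mean_karyotype(
    dataset: AccessionDataset,
    *,
    pairing: PairingMode = "matched",
    averaging: AveragingMode = "absolute",
) -> MeanKaryotype:
    """Average the per-plate haploid complements of an accession rank-wise.

    Each plate is reduced to its sorted haploid complement (see
    :func:`pair_homologs`); chromosomes are then averaged position-wise
    across plates (rank 1 with rank 1, ...).  ``averaging="relative"``
    first expresses each plate's arm lengths as a fraction of the plate's
    haploid total length and rescales by the mean total, which removes
    between-plate condensation differences.
    """
    if dataset.n_plates == 0:
        raise MeasurementError(f"accession {dataset.accession_id!r} has no plates")

    per_plate: list[tuple[ChromosomeStats, ...]] = [
        pair_homologs(plate, mode=pairing) for plate in dataset.plates
    ]
    n = dataset.two_n // 2

    p_arr = np.array([[c.p for c in comp] for comp in per_plate], dtype=float)
    q_arr = np.array([[c.q for c in comp] for comp in per_plate], dtype=float)

    if averaging == "relative":
        plate_totals = (p_arr + q_arr).sum(axis=1, keepdims=True)
        mean_total = plate_totals.mean()
        p_arr = p_arr / plate_totals * mean_total
        q_arr = q_arr / plate_totals * mean_total
    elif averaging != "absolute":
        raise KaryomorphError(f"unknown averaging mode {averaging!r}")

    chromosomes = [
        chromosome_stats(float(p_arr[:, k].mean()), float(q_arr[:, k].mean()))
        for k in range(n)
    ]
    chromosomes.sort(key=lambda s: (-s.cl, s.ci))
    return MeanKaryotype(
        accession_id=dataset.accession_id,
        chromosomes=tuple(chromosomes),
        n_plates=dataset.n_plates,
        two_n=dataset.two_n,
        ploidy=dataset.ploidy,
    )


# ---------------------------------------------------------------------------
# karyotype-level statistics
# ---------------------------------------------------------------------------


def karyotype_formula(karyotype: MeanKaryotype) -> KaryotypeFormula:
    """Tally of centromere-position classes over the haploid complement."""
    counts: dict[str, int] = {}
    for c in karyotype.chromosomes:
        counts[c.levan_class] = counts.get(c.levan_class, 0) + 1
    return KaryotypeFormula(counts)


def thcl(karyotype: MeanKaryotype) -> float:
    """Total haploid chromosome length (µm)."""
    return float(sum(c.cl for c in karyotype.chromosomes))


def clr(karyotype: MeanKaryotype) -> tuple[float, float]:
    """Chromosome length range: (shortest, longest) mean chromosome length (µm)."""
    lengths = [c.cl for c in karyotype.chromosomes]
    return (min(lengths), max(lengths))


def _cv(values: np.ndarray, sd: SdConvention) -> float:
    if values.size < 2:
        raise KaryomorphError("coefficient of variation requires n >= 2")
    ddof = 1 if sd == "sample" else 0
    return float(100.0 * values.std(ddof=ddof) / values.mean())


def cv_cl(karyotype: MeanKaryotype, *, sd: SdConvention = "sample") -> float:
    """Interchromosomal asymmetry: CV (×100) of chromosome lengths."""
    return _cv(np.array([c.cl for c in karyotype.chromosomes]), sd)


def cv_ci(karyotype: MeanKaryotype, *, sd: SdConvention = "sample") -> float:
    """Centromere-position heterogeneity: CV (×100) of centromeric indices."""
    return _cv(np.array([c.ci for c in karyotype.chromosomes]), sd)


def m_ca(karyotype: MeanKaryotype) -> float:
    """Intrachromosomal (mean centromeric) asymmetry: 100 · mean of (q−p)/(q+p)."""
    return float(
        100.0 * np.mean([(c.q - c.p) / (c.q + c.p) for c in karyotype.chromosomes])
    )


def stebbins_class(karyotype: MeanKaryotype) -> str:
    """Two-way symmetry class: row 1–4 from the proportion of chromosomes
    with arm ratio > 2, column A–C from the largest:smallest length ratio.

    A: ratio < 2; B: 2 <= ratio <= 4; C: ratio > 4.
    1: proportion 0; 2: (0, 0.5]; 3: (0.5, 1); 4: 1.
    """
    shortest, longest = clr(karyotype)
    ratio = longest / shortest
    if ratio < 2.0:
        letter = "A"
    elif ratio <= 4.0:
        letter = "B"
    else:
        letter = "C"

    prop = sum(1 for c in karyotype.chromosomes if c.r > 2.0) / karyotype.n
    if prop == 0.0:
        row = 1
    elif prop <= 0.5:
        row = 2
    elif prop < 1.0:
        row = 3
    else:
        row = 4
    return f"{row}{letter}"


def summarize_accession(
    dataset: AccessionDataset,
    *,
    pairing: PairingMode = "matched",
    averaging: AveragingMode = "absolute",
    sd: SdConvention = "sample",
) -> KaryotypeSummary:
    """Full per-accession feature row: KF, THCL, CLR, CV_CL, CV_CI, M_CA, Stebbins class."""
    karyotype = mean_karyotype(dataset, pairing=pairing, averaging=averaging)
    return summarize_karyotype(karyotype, sd=sd)


def write_karyotype_detail(
    karyotype: MeanKaryotype, path, *, header_comment: str | None = None
) -> None:
    """Per-chromosome detail table: position, mean arms, CL, CI, r, class."""
    import pandas as pd

    from .measurements_io import _write_csv

    rows = [
        {
            "position": k + 1,
            "mean_p": round(c.p, 4),
            "mean_q": round(c.q, 4),
            "cl": round(c.cl, 4),
            "ci": round(c.ci, 4),
            "r": round(c.r, 4),
            "class": c.levan_class,
        }
        for k, c in enumerate(karyotype.chromosomes)
    ]
    _write_csv(pd.DataFrame(rows), path, header_comment)


def summarize_karyotype(
    karyotype: MeanKaryotype, *, sd: SdConvention = "sample"
) -> KaryotypeSummary:
    clr_min, clr_max = clr(karyotype)
    return KaryotypeSummary(
        accession_id=karyotype.accession_id,
        two_n=karyotype.two_n,
        kf=karyotype_formula(karyotype),
        thcl=thcl(karyotype),
        clr_min=clr_min,
        clr_max=clr_max,
        cv_cl=cv_cl(karyotype, sd=sd),
        cv_ci=cv_ci(karyotype, sd=sd),
        m_ca=m_ca(karyotype),
        stebbins=stebbins_class(karyotype),
        ploidy=karyotype.ploidy,
    )
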