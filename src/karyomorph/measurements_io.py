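"""Data model and tabular I/O for chromosome measurements and karyotype parameter tables.

All files are comma-separated UTF-8 text with a mandatory header row and "."
as the decimal separator.  Lines starting with ``#`` are treated as comments
(provenance headers written by the CLI).  Arm lengths are canonicalized on
ingest so that ``p`` (short arm) never exceeds ``q`` (long arm).
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import KaryomorphError, MeasurementError, SchemaError

logger = logging.getLogger(__name__)

#: Levan centromere-position classes in canonical rendering order.
LEVAN_CLASSES = ("m", "sm", "st", "t")

#: Fixed column order of the quantitative parameter matrix.
PARAM_COLUMNS = ("x", "2n", "thcl", "m_ca", "cv_cl", "cv_ci")

MEASUREMENT_COLUMNS = ("accession", "plate", "chromosome", "short_arm_um", "long_arm_um")

_ARM_ALIASES = {"short_arm": "short_arm_um", "long_arm": "long_arm_um"}


# ---------------------------------------------------------------------------
# karyotype formula
# ---------------------------------------------------------------------------

_KF_TERM = re.compile(r"^\s*(\d+)\s*(m|sm|st|t)\s*$")


@dataclass(frozen=True)
class KaryotypeFormula:
    """Haploid tally of chromosomes per Levan class, e.g. ``2m + 8sm``."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        clean = {c: int(n) for c, n in self.counts.items() if n}
        for c, n in clean.items():
            if c not in LEVAN_CLASSES:
                raise KaryomorphError(f"unknown Levan class {c!r} in karyotype formula")
            if n < 0:
                raise KaryomorphError(f"negative count for class {c!r}")
        object.__setattr__(self, "counts", clean)

    @property
    def n(self) -> int:
        """Haploid chromosome number implied by the formula."""
        return sum(self.counts.values())

    def count(self, levan_class: str) -> int:
        return self.counts.get(levan_class, 0)

    def __str__(self) -> str:
        parts = [f"{self.counts[c]}{c}" for c in LEVAN_CLASSES if self.counts.get(c)]
        return " + ".join(parts) if parts else "0"

    @classmethod
    def from_string(cls, text: str) -> "KaryotypeFormula":
        counts: dict[str, int] = {}
        for term in text.split("+"):
            match = _KF_TERM.match(term)
            if match is None:
                raise KaryomorphError(f"unparseable karyotype formula term {term.strip()!r}")
            n, c = int(match.group(1)), match.group(2)
            counts[c] = counts.get(c, 0) + n
        return cls(counts)


# ---------------------------------------------------------------------------
# measurement data model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChromosomeMeasurement:
    """One measured chromosome on one metaphase plate.

    ``p`` is the short-arm and ``q`` the long-arm length in µm; the
    constructor enforces ``0 < p <= q`` (use :meth:`canonical` to reorder).
    """

    accession_id: str
    plate_id: str
    chromosome_id: str
    p: float
    q: float

    def __post_init__(self) -> None:
        if not (self.p > 0 and self.q > 0):
            raise MeasurementError(
                f"nonpositive arm length (p={self.p}, q={self.q}) for chromosome "
                f"{self.chromosome_id!r} on plate {self.plate_id!r}"
            )
        if self.p > self.q:
            raise MeasurementError(
                f"short arm exceeds long arm (p={self.p} > q={self.q}); canonicalize first"
            )

    @classmethod
    def canonical(
        cls, accession_id: str, plate_id: str, chromosome_id: str, arm_a: float, arm_b: float
    ) -> "ChromosomeMeasurement":
        """Build a measurement reordering the two arms so that p <= q."""
        p, q = (arm_a, arm_b) if arm_a <= arm_b else (arm_b, arm_a)
        return cls(accession_id, plate_id, chromosome_id, float(p), float(q))


@dataclass(frozen=True)
class MetaphasePlate:
    """All 2n measured chromosomes of one cell."""

    plate_id: str
    measurements: tuple[ChromosomeMeasurement, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "measurements", tuple(self.measurements))
        for m in self.measurements:
            if m.plate_id != self.plate_id:
                raise MeasurementError(
                    f"measurement of plate {m.plate_id!r} in plate {self.plate_id!r}"
                )

    @property
    def count(self) -> int:
        return len(self.measurements)


@dataclass(frozen=True)
class AccessionDataset:
    """All plates measured for one accession."""

    accession_id: str
    two_n: int
    plates: tuple[MetaphasePlate, ...]
    taxon_name: str = ""
    ploidy: int = 2
    #: generating ground truth, attached by the synthetic generator only
    truth: object | None = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "plates", tuple(self.plates))
        if self.two_n <= 0 or self.two_n % 2:
            raise MeasurementError(f"2n must be a positive even integer, got {self.two_n}")
        if self.ploidy <= 0 or self.two_n % self.ploidy:
            raise MeasurementError(
                f"2n={self.two_n} is not divisible by ploidy={self.ploidy}"
            )
        for plate in self.plates:
            if plate.count != self.two_n:
                raise MeasurementError(
                    f"plate {plate.plate_id!r} has {plate.count} chromosomes, "
                    f"expected 2n={self.two_n}"
                )

    @property
    def x(self) -> int:
        """Base chromosome number."""
        return self.two_n // self.ploidy

    @property
    def n_plates(self) -> int:
        return len(self.plates)


@dataclass(frozen=True)
class KaryotypeSummary:
    """One row of the per-accession karyotype feature table."""

    accession_id: str
    two_n: int
    kf: KaryotypeFormula
    thcl: float
    clr_min: float
    clr_max: float
    cv_cl: float
    cv_ci: float
    m_ca: float
    stebbins: str
    ploidy: int = 2

    def __post_init__(self) -> None:
        if self.kf.n * 2 != self.two_n:
            raise KaryomorphError(
                f"karyotype formula {self.kf} implies n={self.kf.n}, "
                f"inconsistent with 2n={self.two_n}"
            )
        if self.clr_min > self.clr_max:
            raise KaryomorphError("clr_min exceeds clr_max")
        if self.kf.n >= 2 and self.thcl < self.clr_max:
            raise KaryomorphError("THCL below the longest chromosome length")
        if self.cv_cl < 0 or self.cv_ci < 0 or not (0 <= self.m_ca < 100):
            raise KaryomorphError("asymmetry index out of range")

    @property
    def x(self) -> int:
        return self.two_n // self.ploidy


@dataclass(frozen=True)
class ParameterMatrix:
    """Accessions x the six quantitative parameters (x, 2n, THCL, M_CA, CV_CL, CV_CI)."""

    labels: tuple[str, ...]
    values: np.ndarray  # shape (n_accessions, 6), column order PARAM_COLUMNS

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "labels", tuple(str(l) for l in self.labels))
        object.__setattr__(self, "values", values)
        if values.ndim != 2 or values.shape != (len(self.labels), len(PARAM_COLUMNS)):
            raise KaryomorphError(
                f"parameter matrix must be {len(self.labels)} x {len(PARAM_COLUMNS)}, "
                f"got shape {values.shape}"
            )
        if len(set(self.labels)) != len(self.labels):
            raise KaryomorphError("duplicate accession labels in parameter matrix")
        if np.isnan(values).any():
            raise KaryomorphError("parameter matrix contains missing values")

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(PARAM_COLUMNS))

    def row(self, label: str) -> np.ndarray:
        return self.values[self.labels.index(label)]

    @classmethod
    def from_summaries(cls, summaries: Sequence[KaryotypeSummary]) -> "ParameterMatrix":
        if not summaries:
            raise KaryomorphError("no accessions")
        labels = [s.accession_id for s in summaries]
        values = [[s.x, s.two_n, s.thcl, s.m_ca, s.cv_cl, s.cv_ci] for s in summaries]
        return cls(tuple(labels), np.asarray(values, dtype=float))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_csv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, comment="#", skip_blank_lines=True, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file") from exc


def read_measurements(
    path,
    *,
    two_n: int | Mapping[str, int] | None = None,
    strict: bool = False,
) -> list[AccessionDataset]:
    """Read a per-chromosome measurement table into accession datasets.

    Measurements are canonicalized (p <= q) and grouped by accession, then
    plate.  The somatic number 2n of each accession is taken from *two_n*
    (a single value or a per-accession mapping) or inferred as the modal
    plate chromosome count.  Plates whose count differs from 2n are dropped
    with a warning, or rejected outright when ``strict=True``.
    """
    df = _read_csv(path)
    df.columns = [_ARM_ALIASES.get(c.strip(), c.strip()) for c in df.columns]
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {', '.join(missing)}")

    for col in ("short_arm_um", "long_arm_um"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() | (numeric <= 0)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise MeasurementError(
                f"{path}: non-numeric or nonpositive {col} at data row {row}"
            )
        df[col] = numeric

    datasets: list[AccessionDataset] = []
    for accession_id, acc_df in df.groupby("accession", sort=False):
        plates: list[MetaphasePlate] = []
        for plate_id, plate_df in acc_df.groupby("plate", sort=False):
            measurements = tuple(
                ChromosomeMeasurement.canonical(
                    str(accession_id), str(plate_id), str(r.chromosome),
                    r.short_arm_um, r.long_arm_um,
                )
                for r in plate_df.itertuples()
            )
            plates.append(MetaphasePlate(str(plate_id), measurements))

        if isinstance(two_n, Mapping):
            expected = two_n.get(str(accession_id))
        else:
            expected = two_n
        if expected is None:
            expected = Counter(p.count for p in plates).most_common(1)[0][0]

        kept = []
        for plate in plates:
            if plate.count != expected:
                msg = (
                    f"accession {accession_id!r}: plate {plate.plate_id!r} has "
                    f"{plate.count} chromosomes, expected 2n={expected}"
                )
                if strict:
                    raise MeasurementError(msg)
                logger.warning("%s; plate excluded", msg)
            else:
                kept.append(plate)
        datasets.append(AccessionDataset(str(accession_id), int(expected), tuple(kept)))
    if not datasets:
        raise SchemaError(f"{path}: no accessions")
    return datasets


def write_measurements(
    datasets: Iterable[AccessionDataset], path, *, header_comment: str | None = None
) -> None:
    rows = [
        (m.accession_id, m.plate_id, m.chromosome_id, m.p, m.q)
        for ds in datasets
        for plate in ds.plates
        for m in plate.measurements
    ]
    df = pd.DataFrame(rows, columns=list(MEASUREMENT_COLUMNS))
    _write_csv(df, path, header_comment)


def _write_csv(df: pd.DataFrame, path, header_comment: str | None) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def read_parameter_table(path, *, ploidy: int = 2) -> ParameterMatrix:
    """Read an accession-level parameter table into a :class:`ParameterMatrix`.

    Requires columns accession, 2n, thcl, m_ca, cv_cl, cv_ci; ``x`` is
    derived as 2n/ploidy when absent.  Extra columns (kf, clr_*, stebbins,
    taxon) are ignored here — use :func:`read_summary_table` for those.
    """
    df = _read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    if df.empty:
        raise SchemaError(f"{path}: no accessions")
    required = ["accession", "2n", "thcl", "m_ca", "cv_cl", "cv_ci"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {', '.join(missing)}")

    numeric_cols = [c for c in ("x", "2n", "thcl", "m_ca", "cv_cl", "cv_ci") if c in df.columns]
    for col in numeric_cols:
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.isna().any():
            row = int(np.flatnonzero(numeric.isna().to_numpy())[0]) + 1
            raise KaryomorphError(f"{path}: non-numeric value in column {col!r}, data row {row}")
        df[col] = numeric
    if "x" not in df.columns:
        df["x"] = df["2n"] / ploidy
    if ((df["x"] % 1) != 0).any() or ((df["2n"] % 1) != 0).any():
        raise KaryomorphError(f"{path}: x and 2n must be integers")

    labels = tuple(df["accession"].astype(str))
    values = df[list(PARAM_COLUMNS)].to_numpy(dtype=float)
    return ParameterMatrix(labels, values)


_SUMMARY_COLUMNS = (
    "accession", "x", "2n", "kf", "thcl", "clr_min", "clr_max",
    "cv_cl", "cv_ci", "m_ca", "stebbins",
)


def read_summary_table(path, *, ploidy: int = 2) -> list[KaryotypeSummary]:
    """Read a full summary table (parameter columns + kf, clr, Stebbins class)."""
    df = _read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in _SUMMARY_COLUMNS if c not in df.columns and c != "x"]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {', '.join(missing)}")
    summaries = []
    for rec in df.to_dict("records"):
        summaries.append(
            KaryotypeSummary(
                accession_id=str(rec["accession"]),
                two_n=int(float(rec["2n"])),
                kf=KaryotypeFormula.from_string(str(rec["kf"])),
                thcl=float(rec["thcl"]),
                clr_min=float(rec["clr_min"]),
                clr_max=float(rec["clr_max"]),
                cv_cl=float(rec["cv_cl"]),
                cv_ci=float(rec["cv_ci"]),
                m_ca=float(rec["m_ca"]),
                stebbins=str(rec["stebbins"]),
                ploidy=ploidy,
            )
        )
    return summaries


def write_summary_table(
    summaries: Sequence[KaryotypeSummary], path, *, header_comment: str | None = None
) -> None:
    """Write summaries in the standard schema, rounded to 2 decimal places.

    The written file round-trips through :func:`read_parameter_table` and
    :func:`read_summary_table`.
    """
    if not summaries:
        raise KaryomorphError("no accessions")
    rows = [
        {
            "accession": s.accession_id,
            "x": s.x,
            "2n": s.two_n,
            "kf": str(s.kf),
            "thcl": round(s.thcl, 2),
            "clr_min": round(s.clr_min, 2),
            "clr_max": round(s.clr_max, 2),
            "cv_cl": round(s.cv_cl, 2),
            "cv_ci": round(s.cv_ci, 2),
            "m_ca": round(s.m_ca, 2),
            "stebbins": s.stebbins,
        }
        for s in summaries
    ]
    _write_csv(pd.DataFrame(rows, columns=list(_SUMMARY_COLUMNS)), path, header_comment)


# ---------------------------------------------------------------------------
# packaged reference data
# ---------------------------------------------------------------------------


def _reference_path():
    return resources.files("karyomorph.data").joinpath("daucus_reference.csv")


def load_reference_dataframe() -> pd.DataFrame:
    """The packaged 16-accession reference karyotype table as a raw DataFrame."""
    with resources.as_file(_reference_path()) as p:
        return pd.read_csv(p)


def load_reference_matrix() -> ParameterMatrix:
    """The packaged reference table as a 16 x 6 :class:`ParameterMatrix`."""
    with resources.as_file(_reference_path()) as p:
        return read_parameter_table(p)


def load_reference_summaries() -> list[KaryotypeSummary]:
    """The packaged reference table as full :class:`KaryotypeSummary` rows."""
    with resources.as_file(_reference_path()) as p:
        return read_summary_table(p)
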