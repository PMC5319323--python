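"""Domain types, dataset I/O and uncertainty normalization.

Measurements of a physical or clinical quantity are reported as ``x (+u_plus
/ -u_minus)`` where the uncertainties are *standard uncertainties*, i.e. the
half-widths of a nominal 68.3% coverage interval.  Published uncertainties
come in several conventions -- expanded intervals ``+- k*u``, 95% confidence
intervals, multiple components quoted separately ("statistical" and
"systematic") -- and :func:`normalize_uncertainty` reduces all of them to the
common 68.3% standard-uncertainty scale before any comparison is made.

A quantity enters the compatibility analysis only when it has at least
``MIN_MEASUREMENTS`` (five) independent measurements.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

__all__ = [
    "MIN_MEASUREMENTS",
    "NORMAL_95_FACTOR",
    "MeasurementRecord",
    "QuantitySeries",
    "RawUncertainty",
    "ReadReport",
    "normalize_uncertainty",
    "read_measurements",
    "write_measurements",
    "filter_independent",
]

logger = logging.getLogger("heavytails")

#: Minimum number of independent measurements for a quantity to be analysed.
MIN_MEASUREMENTS = 5

#: Two-sided Normal 95% coverage factor used to rescale 95% CIs to 68.3%.
NORMAL_95_FACTOR = 1.959964

#: Columns of the canonical CSV interchange format.
CSV_COLUMNS = [
    "quantity_id", "value", "u_plus", "u_minus", "k", "year",
    "group", "lab", "lower_bound", "upper_bound",
]


@dataclass(frozen=True)
class MeasurementRecord:
    """One published measurement of a quantity.

    ``u_plus``/``u_minus`` are the (possibly asymmetric) standard
    uncertainties at 68.3% coverage, in the same units as ``value``.
    """

    quantity_id: str
    value: float
    u_plus: float
    u_minus: float
    year: float | None = None
    group: str | None = None
    lab: str | None = None
    lower_bound: float | None = None
    upper_bound: float | None = None
    record_id: str | None = None

    def __post_init__(self) -> None:
        if not (self.u_plus > 0 and self.u_minus > 0):
            raise ValueError(
                f"record {self.record_id or self.quantity_id}: uncertainties "
                f"must be positive, got +{self.u_plus}/-{self.u_minus}"
            )
        if self.lower_bound is not None and self.value < self.lower_bound:
            raise ValueError(
                f"record {self.record_id or self.quantity_id}: value below lower bound")
        if self.upper_bound is not None and self.value > self.upper_bound:
            raise ValueError(
                f"record {self.record_id or self.quantity_id}: value above upper bound")

    @property
    def u_symmetric(self) -> float:
        """Symmetrized standard uncertainty (mean of the two sides)."""
        return 0.5 * (self.u_plus + self.u_minus)


@dataclass(frozen=True)
class QuantitySeries:
    """All measurements of one quantity; the unit of resampling/weighting."""

    quantity_id: str
    measurements: tuple[MeasurementRecord, ...]
    field_tag: str = ""

    def __post_init__(self) -> None:
        for m in self.measurements:
            if m.quantity_id != self.quantity_id:
                raise ValueError(
                    f"series {self.quantity_id} contains record of "
                    f"{m.quantity_id}")

    def __len__(self) -> int:
        return len(self.measurements)

    @property
    def eligible(self) -> bool:
        return len(self.measurements) >= MIN_MEASUREMENTS


@dataclass(frozen=True)
class RawUncertainty:
    """An uncertainty as reported, before conversion to 68.3% coverage.

    components : sequence of (magnitude, kind)
        kind is one of ``statistical|systematic|unspecified`` and is metadata
        only; all components are combined in quadrature.
    k : coverage factor of the reported interval (1 = standard uncertainty).
    interval_style : ``standard``, ``ci68`` or ``ci95``.
    """

    components: tuple[tuple[float, str], ...]
    k: float = 1.0
    interval_style: Literal["standard", "ci68", "ci95"] = "standard"

    def __post_init__(self) -> None:
        if len(self.components) == 0:
            raise ValueError("RawUncertainty needs at least one component")
        if not math.isfinite(self.k) or self.k <= 0:
            raise ValueError(f"coverage factor must be finite and > 0, got {self.k}")
        for mag, kind in self.components:
            if mag < 0:
                raise ValueError(f"negative uncertainty component {mag}")


def normalize_uncertainty(
    raw: RawUncertainty, record_name: str = "<anonymous>"
) -> tuple[float, float]:
    """Convert a reported uncertainty to a 68.3%-coverage standard uncertainty.

    Components are added in quadrature, the result divided by the coverage
    factor ``k``, and 95% confidence intervals are additionally divided by the
    Normal two-sided factor 1.959964.  Returns ``(u_plus, u_minus)`` -- equal
    for the symmetric input handled here.
    """
    quad = math.sqrt(sum(mag * mag for mag, _ in raw.components))
    u = quad / raw.k
    if raw.interval_style == "ci95":
        u /= NORMAL_95_FACTOR
    if u <= 0:
        raise ValueError(
            f"record {record_name}: combined uncertainty is non-positive ({u})")
    return u, u


@dataclass
class ReadReport:
    """Bookkeeping from :func:`read_measurements`."""

    n_rows: int = 0
    n_parsed: int = 0
    n_bad_rows: int = 0
    bad_rows: list[str] = field(default_factory=list)
    excluded_quantities: list[str] = field(default_factory=list)

    @property
    def rows_conserved(self) -> bool:
        return self.n_rows == self.n_parsed + self.n_bad_rows


def _parse_row(i: int, row: pd.Series) -> MeasurementRecord:
    qid = str(row["quantity_id"])
    value = float(row["value"])

    def opt(name: str) -> float | None:
        if name not in row or pd.isna(row[name]):
            return None
        return float(row[name])

    u_plus = opt("u_plus")
    u_minus = opt("u_minus")
    # one-sided input: the single given side is used for both
    if u_plus is None and u_minus is None:
        raise ValueError("no uncertainty given")
    if u_plus is None:
        u_plus = u_minus
    if u_minus is None:
        u_minus = u_plus
    k = opt("k")
    if k is not None and k != 1.0:
        u_plus = normalize_uncertainty(
            RawUncertainty(((u_plus, "unspecified"),), k=k), f"row {i}")[0]
        u_minus = normalize_uncertainty(
            RawUncertainty(((u_minus, "unspecified"),), k=k), f"row {i}")[0]
    group = None if "group" not in row or pd.isna(row.get("group")) else str(row["group"])
    lab = None if "lab" not in row or pd.isna(row.get("lab")) else str(row["lab"])
    return MeasurementRecord(
        quantity_id=qid, value=value, u_plus=u_plus, u_minus=u_minus,
        year=opt("year"), group=group, lab=lab,
        lower_bound=opt("lower_bound"), upper_bound=opt("upper_bound"),
        record_id=str(row["record_id"]) if "record_id" in row and pd.notna(row.get("record_id")) else f"{qid}#{i}",
    )


def read_measurements(
    path: str | Path, column_map: dict[str, str] | None = None,
) -> tuple[list[QuantitySeries], list[QuantitySeries], ReadReport]:
    """Read a CSV of measurements and group them by quantity.

    Returns ``(eligible, ineligible, report)``: series with >= 5 measurements,
    series below the inclusion threshold (retained for inspection), and a
    row-conservation report.  Unparsable rows are logged and skipped; the run
    continues.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if column_map:
        df = df.rename(columns=column_map)
    missing = {"quantity_id", "value"} - set(df.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")
    report = ReadReport(n_rows=len(df))
    if len(df) == 0:
        logger.warning("%s: empty dataset", path)
        return [], [], report

    records: dict[str, list[MeasurementRecord]] = {}
    groups: dict[str, str] = {}
    for i, row in df.iterrows():
        try:
            rec = _parse_row(i, row)
        except (ValueError, TypeError) as exc:
            report.n_bad_rows += 1
            report.bad_rows.append(f"row {i}: {exc}")
            logger.error("row %d unparsable: %s", i, exc)
            continue
        report.n_parsed += 1
        records.setdefault(rec.quantity_id, []).append(rec)
        if rec.group is not None:
            groups.setdefault(rec.quantity_id, rec.group)

    eligible: list[QuantitySeries] = []
    ineligible: list[QuantitySeries] = []
    for qid, recs in records.items():
        series = QuantitySeries(qid, tuple(recs), field_tag=groups.get(qid, ""))
        if series.eligible:
            eligible.append(series)
        else:
            ineligible.append(series)
            report.excluded_quantities.append(qid)
            logger.info("quantity %s excluded: only %d measurements", qid, len(recs))
    return eligible, ineligible, report


def write_measurements(path: str | Path, quantities: Iterable[QuantitySeries]) -> None:
    """Write series to the canonical CSV format (round-trips with reader)."""
    rows = []
    for q in quantities:
        for m in q.measurements:
            rows.append({
                "quantity_id": m.quantity_id, "value": m.value,
                "u_plus": m.u_plus, "u_minus": m.u_minus, "k": 1.0,
                "year": m.year, "group": m.group or q.field_tag or None,
                "lab": m.lab, "lower_bound": m.lower_bound,
                "upper_bound": m.upper_bound, "record_id": m.record_id,
            })
    pd.DataFrame(rows, columns=CSV_COLUMNS + ["record_id"]).to_csv(
        path, index=False, float_format="%.17g")


def filter_independent(
    series: QuantitySeries, exclusion_list: Sequence[str]
) -> QuantitySeries:
    """Drop records whose ids are in *exclusion_list* (non-independent data)."""
    excl = set(exclusion_list)
    kept = tuple(m for m in series.measurements if m.record_id not in excl)
    return replace(series, measurements=kept)
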