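"""Typed data model for the rewetted-peatland flux compilation.

The compilation is a literature table of annual greenhouse-gas fluxes
(NEE as CO2-C, CH4-C, N2O-N) from boreal and temperate rewetted peatlands,
grouped into five site categories.  Values are stored exactly as printed in
the source studies, each with the unit string its source reported, so that
unit harmonization is an explicit downstream step and the provenance of
every number survives a round-trip through the on-disk format.

Sign convention: negative = uptake by the ecosystem, positive = emission.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from typing import Iterable, Optional


class Category(str, Enum):
    """Site category of a rewetted-peatland record."""

    REWETTED_GENERAL = "rewetted_general"
    REWETTED_FOREST = "rewetted_forest"
    PALUDICULTURE = "paludiculture"
    SHALLOW_LAKE = "shallow_lake"
    OPEN_BOG_FEN = "open_bog_fen"


class NutrientStatus(str, Enum):
    RICH = "rich"
    POOR = "poor"
    MIXED = "mixed"
    UNKNOWN = "unknown"


class ValueKind(str, Enum):
    POINT = "point"
    RANGE = "range"
    POINT_WITH_SD = "point_with_sd"
    POINT_WITH_SE = "point_with_se"


class FluxTableError(ValueError):
    """Malformed flux-table content; the message names the offending cell."""


#: Flags a record may carry.  ``season_only``: the source reports a
#: growing-season rate, not an annual one, so the record is excluded from
#: annual category means.  ``review``: the row is itself a multi-site
#: literature synthesis rather than a single site.  ``co2_equivalent``: the
#: source footnote declares the values to be CO2-equivalents rather than
#: element mass.  ``ambiguous``: the printed cell admits more than one
#: reading; the chosen one is recorded with a note.
KNOWN_FLAGS = frozenset({"season_only", "review", "co2_equivalent", "ambiguous"})


@dataclass(frozen=True)
class ValueOrRange:
    """A tabulated flux value: a point, a min-to-max range, or a mean with
    a reported standard deviation or standard error."""

    kind: ValueKind
    value: float
    high: Optional[float] = None
    spread: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind is ValueKind.RANGE:
            if self.high is None:
                raise FluxTableError("range value needs a high endpoint")
            if self.value > self.high:
                raise FluxTableError(
                    f"range endpoints out of order: {self.value} > {self.high}"
                )
        elif self.kind in (ValueKind.POINT_WITH_SD, ValueKind.POINT_WITH_SE):
            if self.spread is None or self.spread < 0:
                raise FluxTableError("spread must be a non-negative number")
        elif self.kind is ValueKind.POINT:
            if self.high is not None or self.spread is not None:
                raise FluxTableError("point value carries no high/spread")

    def collapse(self) -> float:
        """Single representative value: the point, the range midpoint, or
        the central value of a mean-with-spread entry."""
        if self.kind is ValueKind.RANGE:
            return 0.5 * (self.value + self.high)
        return self.value


def collapse(v: ValueOrRange) -> float:
    return v.collapse()


_TYPOGRAPHIC = {
    "−": "-",  # minus sign
    "—": "-",  # em dash
    " ": " ",
    " ": " ",
    " ": " ",
}


def _normalize_text(cell: str) -> str:
    out = cell
    for bad, good in _TYPOGRAPHIC.items():
        out = out.replace(bad, good)
    # "- 3970" -> "-3970"
    out = re.sub(r"-\s+(?=[\d.])", "-", out)
    return out.strip()


def _parse_number(token: str, *, context: str = "") -> float:
    """Parse a printed number, accepting thousands separators ("1,609")
    and the occasional European decimal comma ("0,006")."""
    tok = token.strip().replace(" ", "")
    if not tok:
        raise FluxTableError(f"empty number{context}")
    if "," in tok:
        sign = tok[1:] if tok.startswith("-") else tok
        intpart = sign.split(",", 1)[0]
        if "." not in tok and re.fullmatch(r"\d{1,3}(,\d{3})+", sign) and intpart != "0":
            tok = tok.replace(",", "")
        elif tok.count(",") == 1 and "." not in tok:
            tok = tok.replace(",", ".")
        else:
            tok = tok.replace(",", "")
    try:
        return float(tok)
    except ValueError as exc:
        raise FluxTableError(f"malformed number {token!r}{context}") from exc


_RANGE_RE = re.compile(
    r"^(?P<a>-?[\d.,]+)\s*(?:to|–)\s*(?P<b>-?[\d.,]+)$"
)
_SPREAD_RE = re.compile(r"^(?P<v>-?[\d.,]+)\s*(?:±|\+/-)\s*(?P<s>[\d.,]+)$")


def parse_value_or_range(cell: str, spread_kind: str = "sd") -> ValueOrRange:
    """Parse a table cell: ``"-3970 to -5970"`` becomes a range,
    ``"90 ± 200"`` a mean with spread, a plain number a point.

    spread_kind selects whether a "±" entry is read as a standard
    deviation (default) or a standard error.
    """
    if spread_kind not in ("sd", "se"):
        raise ValueError("spread_kind must be 'sd' or 'se'")
    text = _normalize_text(cell)
    if not text:
        raise FluxTableError("empty cell")
    m = _RANGE_RE.match(text)
    if m:
        a = _parse_number(m.group("a"), context=f" in {cell!r}")
        b = _parse_number(m.group("b"), context=f" in {cell!r}")
        lo, hi = (a, b) if a <= b else (b, a)
        return ValueOrRange(ValueKind.RANGE, lo, high=hi)
    m = _SPREAD_RE.match(text)
    if m:
        v = _parse_number(m.group("v"), context=f" in {cell!r}")
        s = _parse_number(m.group("s"), context=f" in {cell!r}")
        kind = ValueKind.POINT_WITH_SD if spread_kind == "sd" else ValueKind.POINT_WITH_SE
        return ValueOrRange(kind, v, spread=s)
    try:
        return ValueOrRange(ValueKind.POINT, _parse_number(text))
    except FluxTableError as exc:
        raise FluxTableError(f"unparseable value cell {cell!r}") from exc


def format_value_or_range(v: Optional[ValueOrRange]) -> str:
    """Canonical text form, inverse of :func:`parse_value_or_range`."""
    if v is None:
        return ""
    if v.kind is ValueKind.RANGE:
        return f"{v.value!r} to {v.high!r}"
    if v.kind is ValueKind.POINT_WITH_SD:
        return f"{v.value!r} ± {v.spread!r}"
    if v.kind is ValueKind.POINT_WITH_SE:
        # "±se" marker keeps sd and se distinguishable on disk
        return f"{v.value!r} ±se {v.spread!r}"
    return repr(v.value)


_SE_RE = re.compile(r"^(?P<v>-?[\d.,]+)\s*±se\s*(?P<s>[\d.,]+)$")


def _read_value_cell(cell: str) -> Optional[ValueOrRange]:
    text = _normalize_text(cell)
    if not text:
        return None
    m = _SE_RE.match(text)
    if m:
        return ValueOrRange(
            ValueKind.POINT_WITH_SE,
            _parse_number(m.group("v")),
            spread=_parse_number(m.group("s")),
        )
    return parse_value_or_range(text)


@dataclass(frozen=True)
class FluxRecord:
    """One site/treatment row of the flux compilation, values as printed."""

    site_name: str
    category: Category
    subgroup: str = ""
    country: str = ""
    latitude: Optional[float] = None
    longitude: Optional[float] = None
    period: str = ""
    nutrient_status: NutrientStatus = NutrientStatus.UNKNOWN
    treatment: str = ""
    nee: Optional[ValueOrRange] = None
    ch4: Optional[ValueOrRange] = None
    n2o: Optional[ValueOrRange] = None
    nee_unit: str = ""
    ch4_unit: str = ""
    n2o_unit: str = ""
    source: str = ""
    flags: frozenset = field(default_factory=frozenset)
    note: str = ""

    def __post_init__(self) -> None:
        if self.latitude is not None and not -90.0 <= self.latitude <= 90.0:
            raise FluxTableError(f"latitude out of range: {self.latitude}")
        if self.longitude is not None and not -180.0 <= self.longitude <= 180.0:
            raise FluxTableError(f"longitude out of range: {self.longitude}")
        for gas in ("nee", "ch4", "n2o"):
            if getattr(self, gas) is not None and not getattr(self, gas + "_unit"):
                raise FluxTableError(
                    f"{self.site_name}: {gas} value present without a unit string"
                )
        unknown = set(self.flags) - KNOWN_FLAGS
        if unknown:
            raise FluxTableError(f"unknown flags {sorted(unknown)}")

    def value(self, gas: str) -> Optional[ValueOrRange]:
        if gas not in ("nee", "ch4", "n2o"):
            raise ValueError(f"unknown gas column {gas!r}")
        return getattr(self, gas)

    def unit(self, gas: str) -> str:
        return getattr(self, gas + "_unit")


COLUMNS = [
    "site_name", "category", "subgroup", "country", "latitude", "longitude",
    "period", "nutrient_status", "treatment",
    "nee", "nee_unit", "ch4", "ch4_unit", "n2o", "n2o_unit",
    "source", "flags", "note",
]


def read_flux_table(path) -> list[FluxRecord]:
    """Read a delimited-text flux table (comma-separated, UTF-8).

    Missing cells become absent values, never zero.  An unknown category
    label or a malformed number is rejected with the row (and column)
    named in the error.
    """
    records: list[FluxRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [c.strip() for c in reader.fieldnames] != COLUMNS:
            raise FluxTableError(
                f"unexpected header {reader.fieldnames!r}; expected {COLUMNS}"
            )
        for i, row in enumerate(reader, start=2):
            records.append(_record_from_row(row, i))
    return records


def _record_from_row(row: dict, lineno: int) -> FluxRecord:
    def fail(msg: str) -> FluxTableError:
        return FluxTableError(f"row {lineno} ({row.get('site_name', '?')}): {msg}")

    try:
        category = Category(row["category"].strip())
    except ValueError:
        raise fail(f"unknown category {row['category']!r}") from None
    status_txt = row.get("nutrient_status", "").strip() or "unknown"
    try:
        status = NutrientStatus(status_txt)
    except ValueError:
        raise fail(f"unknown nutrient status {status_txt!r}") from None

    def opt_float(col: str) -> Optional[float]:
        txt = row.get(col, "").strip()
        if not txt:
            return None
        try:
            return _parse_number(txt, context=f" in column {col}")
        except FluxTableError as exc:
            raise fail(str(exc)) from None

    def opt_value(col: str) -> Optional[ValueOrRange]:
        try:
            return _read_value_cell(row.get(col, ""))
        except FluxTableError as exc:
            raise fail(f"column {col}: {exc}") from None

    flags = frozenset(f for f in row.get("flags", "").split("|") if f)
    try:
        return FluxRecord(
            site_name=row["site_name"].strip(),
            category=category,
            subgroup=row.get("subgroup", "").strip(),
            country=row.get("country", "").strip(),
            latitude=opt_float("latitude"),
            longitude=opt_float("longitude"),
            period=row.get("period", "").strip(),
            nutrient_status=status,
            treatment=row.get("treatment", "").strip(),
            nee=opt_value("nee"),
            ch4=opt_value("ch4"),
            n2o=opt_value("n2o"),
            nee_unit=row.get("nee_unit", "").strip(),
            ch4_unit=row.get("ch4_unit", "").strip(),
            n2o_unit=row.get("n2o_unit", "").strip(),
            source=row.get("source", "").strip(),
            flags=flags,
            note=row.get("note", "").strip(),
        )
    except FluxTableError as exc:
        raise fail(str(exc)) from None


def write_flux_table(records: Iterable[FluxRecord], path) -> None:
    """Write records in the same delimited schema; round-trips bit-exactly."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=COLUMNS)
        writer.writeheader()
        for r in records:
            writer.writerow(
                {
                    "site_name": r.site_name,
                    "category": r.category.value,
                    "subgroup": r.subgroup,
                    "country": r.country,
                    "latitude": "" if r.latitude is None else repr(r.latitude),
                    "longitude": "" if r.longitude is None else repr(r.longitude),
                    "period": r.period,
                    "nutrient_status": r.nutrient_status.value,
                    "treatment": r.treatment,
                    "nee": format_value_or_range(r.nee),
                    "nee_unit": r.nee_unit,
                    "ch4": format_value_or_range(r.ch4),
                    "ch4_unit": r.ch4_unit,
                    "n2o": format_value_or_range(r.n2o),
                    "n2o_unit": r.n2o_unit,
                    "source": r.source,
                    "flags": "|".join(sorted(r.flags)),
                    "note": r.note,
                }
            )


def load_reference_table() -> list[FluxRecord]:
    """The packaged encoding of the published flux compilation."""
    ref = resources.files("peatghg.data").joinpath("flux_compilation.csv")
    with resources.as_file(ref) as path:
        return read_flux_table(path)
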