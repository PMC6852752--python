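"""Domain model and CSV I/O for drugstore/hospital purchase-audit records.

A purchase record is one audited cell — (region, sector, month, product,
dosage form, strength) — holding the dollars spent and units bought. The
canonical study covers three biologic molecules, each sold as an originator
brand and one biosimilar brand, across nine Canadian regions (Prince Edward
Island and Newfoundland are pooled by the audit) over July 2016 – June 2018.

Dollars are stored as integer cents and units as integers; see
:mod:`biosavings._money`.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

from ._money import format_dollars, parse_dollars

logger = logging.getLogger(__name__)

#: Audit region codes. "PEI/NL" is a single token: the audit pools Prince
#: Edward Island with Newfoundland.
REGIONS: tuple[str, ...] = ("BC", "AB", "SK", "MB", "ON", "QC", "NB", "NS", "PEI/NL")

#: Pseudo-region used by pre-aggregated national data (e.g. the packaged
#: national fixture, which has no provincial breakdown).
NATIONAL: str = "CANADA"

SECTORS: tuple[str, ...] = ("drugstore", "hospital")
ROLES: tuple[str, ...] = ("originator", "biosimilar")

#: Originator/biosimilar brand pairs per molecule for the three biologics
#: whose biosimilars entered the Canadian market in 2014-2015.
DEFAULT_PAIRING: Mapping[str, tuple[str, str]] = {
    "insulin glargine": ("Lantus", "Basaglar"),
    "filgrastim": ("Neupogen", "Grastofil"),
    "infliximab": ("Remicade", "Inflectra"),
}

CSV_COLUMNS = (
    "region",
    "sector",
    "month",
    "molecule",
    "brand",
    "role",
    "form",
    "strength",
    "dollars",
    "units",
)

_MONTH_RE = re.compile(r"^(\d{4})-(\d{2})$")


class SchemaError(ValueError):
    """The input file does not match the documented CSV schema."""


class ValidationError(ValueError):
    """A record violates a domain invariant."""


class ComparatorConfigError(ValueError):
    """Brand pairing configuration is inconsistent with the data."""


def month_index(month: str) -> int:
    """Months since year 0 for a 'YYYY-MM' label; total order on months."""
    m = _MONTH_RE.match(month)
    if m is None:
        raise ValidationError(f"month must be 'YYYY-MM', got {month!r}")
    year, mon = int(m.group(1)), int(m.group(2))
    if not 1 <= mon <= 12:
        raise ValidationError(f"month out of range: {month!r}")
    return year * 12 + (mon - 1)


@dataclass(frozen=True)
class StudyWindow:
    """Inclusive year-month range of the analysis.

    The default spans the two years following biosimilar market entry for
    all three molecules: July 2016 through June 2018.
    """

    start: str = "2016-07"
    end: str = "2018-06"

    def __post_init__(self) -> None:
        if month_index(self.start) > month_index(self.end):
            raise ValidationError(f"window start {self.start} after end {self.end}")

    def __contains__(self, month: str) -> bool:
        return month_index(self.start) <= month_index(month) <= month_index(self.end)

    @property
    def n_months(self) -> int:
        return month_index(self.end) - month_index(self.start) + 1

    @property
    def n_quarters(self) -> int:
        return (self.n_months + 2) // 3

    def months(self) -> list[str]:
        start = month_index(self.start)
        return [f"{i // 12:04d}-{i % 12 + 1:02d}" for i in range(start, start + self.n_months)]

    def quarter_of(self, month: str) -> int:
        """1-based quarter index; quarters are consecutive 3-month blocks
        anchored at the window start (not calendar quarters)."""
        if month not in self:
            raise ValidationError(f"month {month} outside window {self.start}..{self.end}")
        return (month_index(month) - month_index(self.start)) // 3 + 1

    def quarter_label(self, quarter: int) -> str:
        """Calendar-style label of a quarter's first month, e.g. '2016Q3'."""
        first = month_index(self.start) + (quarter - 1) * 3
        year, mon = first // 12, first % 12 + 1
        return f"{year}Q{(mon - 1) // 3 + 1}"


@dataclass(frozen=True)
class PurchaseRecord:
    """One audited purchase cell: dollars and units for a product in a
    region, sector and calendar month."""

    region: str
    sector: str
    month: str
    molecule: str
    brand: str
    role: str
    form: str
    strength: str
    dollars_cents: int
    units: int

    def __post_init__(self) -> None:
        if self.sector not in SECTORS:
            raise ValidationError(f"unknown sector {self.sector!r}")
        if self.role not in ROLES:
            raise ValidationError(f"unknown role {self.role!r}")
        month_index(self.month)  # format check
        if self.units < 0:
            raise ValidationError(f"negative units ({self.units})")
        if self.dollars_cents < 0:
            raise ValidationError(f"negative dollars ({self.dollars_cents} cents)")
        if self.units == 0 and self.dollars_cents > 0:
            raise ValidationError(
                "dollars > 0 with units = 0 would leave the unit price undefined"
            )

    @property
    def key(self) -> tuple[str, str]:
        """(form, strength) presentation key."""
        return (self.form, self.strength)


@dataclass(frozen=True)
class ComparatorMap:
    """Originator/biosimilar pairing for one molecule.

    Presentation keys — (dosage form, strength) pairs — sold by both brands
    are *matched*; keys sold only by the originator are *excluded* and carry
    zero potential savings downstream, because no substitutable biosimilar
    presentation exists for them.
    """

    molecule: str
    originator_brand: str
    biosimilar_brand: str
    matched_keys: frozenset[tuple[str, str]] = field(default_factory=frozenset)
    excluded_keys: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.matched_keys & self.excluded_keys:
            raise ValidationError("matched and excluded key sets overlap")


def read_purchases(
    path,
    window: StudyWindow | None = None,
    regions: Sequence[str] = REGIONS,
) -> list[PurchaseRecord]:
    """Read and validate purchase records from a CSV file.

    Records dated outside ``window`` are dropped; the count is logged at
    INFO. Schema problems (missing columns) and invariant violations
    (negative values, unknown regions) raise with the offending column or
    row named.
    """
    window = window or StudyWindow()
    region_set = set(regions)
    records: list[PurchaseRecord] = []
    dropped = 0
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in CSV_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"missing column(s) {missing} in {path}")
        for lineno, row in enumerate(reader, start=2):
            if row["region"] not in region_set:
                raise ValidationError(f"{path}:{lineno}: unknown region {row['region']!r}")
            try:
                rec = PurchaseRecord(
                    region=row["region"],
                    sector=row["sector"],
                    month=row["month"],
                    molecule=row["molecule"],
                    brand=row["brand"],
                    role=row["role"],
                    form=row["form"],
                    strength=row["strength"],
                    dollars_cents=parse_dollars(row["dollars"]),
                    units=int(row["units"]),
                )
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
            if rec.month not in window:
                dropped += 1
                continue
            records.append(rec)
    if dropped:
        logger.info("dropped %d record(s) outside window %s..%s", dropped, window.start, window.end)
    return records


def write_purchases(records: Iterable[PurchaseRecord], path) -> None:
    """Write records as CSV (UTF-8, comma, header). Round-trips exactly:
    dollars are emitted with two decimals from integer cents."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.region,
                    r.sector,
                    r.month,
                    r.molecule,
                    r.brand,
                    r.role,
                    r.form,
                    r.strength,
                    format_dollars(r.dollars_cents),
                    r.units,
                ]
            )


def build_comparator_map(
    records: Iterable[PurchaseRecord],
    pairing: Mapping[str, tuple[str, str]] = DEFAULT_PAIRING,
) -> dict[str, ComparatorMap]:
    """Partition each molecule's presentation keys into matched and excluded.

    A key is matched when both the originator and the biosimilar sold it;
    originator-only keys are excluded (no comparator exists, so no savings
    are attributed to them). A biosimilar-only key, or a biosimilar record
    for a molecule absent from the pairing, is a configuration error.
    """
    orig_keys: dict[str, set[tuple[str, str]]] = {}
    bios_keys: dict[str, set[tuple[str, str]]] = {}
    seen_molecules: set[str] = set()
    for rec in records:
        seen_molecules.add(rec.molecule)
        if rec.molecule not in pairing:
            if rec.role == "biosimilar":
                raise ComparatorConfigError(
                    f"biosimilar record for unpaired molecule {rec.molecule!r}"
                )
            continue
        target = orig_keys if rec.role == "originator" else bios_keys
        target.setdefault(rec.molecule, set()).add(rec.key)

    maps: dict[str, ComparatorMap] = {}
    for molecule in sorted(seen_molecules & set(pairing)):
        originator, biosimilar = pairing[molecule]
        o_keys = orig_keys.get(molecule, set())
        b_keys = bios_keys.get(molecule, set())
        orphan = b_keys - o_keys
        if orphan:
            raise ComparatorConfigError(
                f"{molecule}: biosimilar key(s) with no originator counterpart: {sorted(orphan)}"
            )
        matched = o_keys & b_keys
        excluded = o_keys - b_keys
        if excluded:
            logger.info(
                "%s: excluding originator-only key(s) %s from savings",
                molecule,
                sorted(excluded),
            )
        maps[molecule] = ComparatorMap(
            molecule=molecule,
            originator_brand=originator,
            biosimilar_brand=biosimilar,
            matched_keys=frozenset(matched),
            excluded_keys=frozenset(excluded),
        )
    return maps


def load_table1_fixture() -> list[PurchaseRecord]:
    """Load the packaged national aggregates for the six study products.

    Six records — one per brand — with region ``CANADA`` and the window
    start month, carrying the exact published national dollars and units
    (sectors and months already collapsed).
    """
    path = resources.files("biosavings") / "fixtures" / "table1_national.csv"
    with resources.as_file(path) as p:
        return read_purchases(p, window=StudyWindow(), regions=(NATIONAL,))
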