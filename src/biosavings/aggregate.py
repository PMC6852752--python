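"""Collapse purchase records to analysis strata and derive prices and shares.

All aggregation is plain summation of dollars (integer cents) and units over
sectors, months and matched presentation keys. Unit price is total dollars
divided by total units within a stratum — an implicitly units-weighted mean,
so the national pooled price equals the units-weighted mean of region prices
by construction.
"""

from __future__ import annotations

import logging
from fractions import Fraction
from typing import Iterable, Mapping

import pandas as pd

from ._money import div_round_half_up
from .cdh_data import ComparatorMap, PurchaseRecord, StudyWindow

logger = logging.getLogger(__name__)

SCOPES = ("national", "region")
PERIODS = ("full_window", "quarter")


class UndefinedPriceError(ZeroDivisionError):
    """Unit price requested for a stratum with zero units."""


def to_frame(records: Iterable[PurchaseRecord]) -> pd.DataFrame:
    """Records as a tidy DataFrame with integer-cent dollars."""
    return pd.DataFrame(
        [
            (r.region, r.sector, r.month, r.molecule, r.brand, r.role, r.form, r.strength, r.dollars_cents, r.units)
            for r in records
        ],
        columns=["region", "sector", "month", "molecule", "brand", "role", "form", "strength", "dollars_cents", "units"],
    )


def filter_matched(
    records: Iterable[PurchaseRecord],
    comparator_maps: Mapping[str, ComparatorMap],
) -> tuple[list[PurchaseRecord], int]:
    """Drop records on excluded (originator-only) presentation keys.

    Returns the kept records and the total excluded dollars in cents; the
    exclusion is logged so the discarded spend stays auditable.
    """
    kept: list[PurchaseRecord] = []
    excluded_cents = 0
    for r in records:
        cmap = comparator_maps.get(r.molecule)
        if cmap is not None and r.key in cmap.excluded_keys:
            excluded_cents += r.dollars_cents
            continue
        kept.append(r)
    if excluded_cents:
        logger.info(
            "excluded originator-only presentations: $%s dropped from savings base",
            excluded_cents / 100,
        )
    return kept, excluded_cents


def collapse(
    records: Iterable[PurchaseRecord],
    scope: str = "national",
    period: str = "full_window",
    window: StudyWindow | None = None,
    comparator_maps: Mapping[str, ComparatorMap] | None = None,
    by_sector: bool = False,
) -> pd.DataFrame:
    """Sum dollars and units into analysis strata.

    Sectors are pooled by default (the published national table reports a
    single combined drugstore+hospital column); pass ``by_sector=True`` to
    keep them separate. Quarters are consecutive 3-month blocks anchored at
    the window start. When ``comparator_maps`` is given, records on excluded
    presentation keys are dropped first and their dollars stashed in
    ``result.attrs["excluded_dollars_cents"]``.
    """
    if scope not in SCOPES:
        raise ValueError(f"scope must be one of {SCOPES}, got {scope!r}")
    if period not in PERIODS:
        raise ValueError(f"period must be one of {PERIODS}, got {period!r}")
    window = window or StudyWindow()
    records = list(records)
    excluded_cents = 0
    if comparator_maps is not None:
        records, excluded_cents = filter_matched(records, comparator_maps)

    df = to_frame(records)
    out_cols = ["molecule", "brand", "role"]
    if not df.empty:
        if scope == "region":
            out_cols = ["region"] + out_cols
        if period == "quarter":
            df["quarter"] = df["month"].map(window.quarter_of)
            out_cols = out_cols + ["quarter"]
        if by_sector:
            out_cols = ["sector"] + out_cols
        grouped = (
            df.groupby(out_cols, as_index=False)[["dollars_cents", "units"]]
            .sum()
            .sort_values(out_cols, ignore_index=True)
        )
        if period == "quarter":
            grouped["quarter_label"] = grouped["quarter"].map(window.quarter_label)
    else:
        cols = out_cols + (["quarter"] if period == "quarter" else []) + ["dollars_cents", "units"]
        grouped = pd.DataFrame(columns=cols)
    grouped.attrs["excluded_dollars_cents"] = excluded_cents
    return grouped


def unit_price(dollars_cents: int, units: int) -> Fraction:
    """Exact unit price in dollars (a Fraction; no rounding)."""
    if units <= 0:
        raise UndefinedPriceError("unit price undefined for zero units")
    return Fraction(dollars_cents, 100 * units)


def unit_price_cents(dollars_cents: int, units: int) -> int:
    """Unit price rounded half-up to integer cents — the presentation
    convention used by the published per-unit prices."""
    if units <= 0:
        raise UndefinedPriceError("unit price undefined for zero units")
    return div_round_half_up(dollars_cents, units)


def uptake_series(
    records: Iterable[PurchaseRecord],
    molecule: str,
    basis: str = "dollars",
    window: StudyWindow | None = None,
    comparator_maps: Mapping[str, ComparatorMap] | None = None,
) -> pd.DataFrame:
    """Quarterly biosimilar share of purchases for one molecule.

    Share = biosimilar / (biosimilar + originator) on the requested basis
    (``units`` or ``dollars``), pooled over regions, sectors and matched
    presentation keys. Quarters with a zero denominator are omitted and
    logged. Returns columns [quarter, quarter_label, share] plus the raw
    numerator/denominator.
    """
    if basis not in ("units", "dollars"):
        raise ValueError(f"basis must be 'units' or 'dollars', got {basis!r}")
    window = window or StudyWindow()
    table = collapse(records, scope="national", period="quarter", window=window, comparator_maps=comparator_maps)
    table = table[table["molecule"] == molecule]
    col = "units" if basis == "units" else "dollars_cents"
    rows = []
    for quarter, grp in table.groupby("quarter"):
        biosim = int(grp.loc[grp["role"] == "biosimilar", col].sum())
        total = int(grp[col].sum())
        if total == 0:
            logger.info("%s quarter %d: no purchases on basis %s; point omitted", molecule, quarter, basis)
            continue
        rows.append(
            {
                "molecule": molecule,
                "quarter": int(quarter),
                "quarter_label": window.quarter_label(int(quarter)),
                "basis": basis,
                "numerator": biosim,
                "denominator": total,
                "share": biosim / total,
            }
        )
    return pd.DataFrame(rows, columns=["molecule", "quarter", "quarter_label", "basis", "numerator", "denominator", "share"])
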