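"""Facial skin-thickness tables and the 31 evaluation regions.

The package ships two static resources derived from cadaveric skin
measurements: a 39-site table of mean epidermal/dermal thickness and a
31-region table mapping each evaluation ROI to its anatomical source site.
Relative-thickness ratios (eRT/dRT/RT) are normalised by the thinnest site
in each category and reported at 2-decimal precision.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources
from typing import Optional

__all__ = [
    "AnatomicalRegion",
    "ProposedRegion",
    "relative_thickness",
    "load_anatomy_table",
    "load_proposed_regions",
    "proposed_region_thickness",
    "EYE_REGION_IDS",
    "PRINTED_OUTLIER_REGION_IDS",
]

#: Eye regions carry no combined thickness (several small periocular sites merged).
EYE_REGION_IDS = frozenset({4, 5})

#: Regions whose published combined thickness does not match the sum for their
#: named source site; both the published and the recomputed value are exposed.
PRINTED_OUTLIER_REGION_IDS = frozenset({16, 17, 18})


class AnatomyError(ValueError):
    """Raised for domain errors in the anatomy tables."""


class IntegrityError(AnatomyError):
    """Packaged table content fails its consistency checks."""


def _round2(x: float) -> float:
    """Round half-up to 2 decimals (display convention for ratios/thickness)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), ROUND_HALF_UP))


@dataclass(frozen=True)
class AnatomicalRegion:
    """One cadaveric measurement site with derived relative-thickness ratios."""

    site_id: int
    name: str
    epidermal_thickness: float  # micrometres
    dermal_thickness: float  # micrometres
    eRT: float
    dRT: float
    RT: float

    @property
    def total_thickness(self) -> float:
        return self.epidermal_thickness + self.dermal_thickness


@dataclass(frozen=True)
class ProposedRegion:
    """One of the 31 evaluation ROIs.

    ``combined_thickness`` is the published value; ``recomputed_thickness`` is
    the epidermal+dermal sum of the primary source site, which differs from
    the published value for the known outlier regions (16-18).
    """

    region_id: int
    name: str
    combined_thickness: Optional[float]  # micrometres, None for eye regions
    recomputed_thickness: Optional[float]
    source_sites: tuple[int, ...]
    laterality: str  # {"left", "right", "midline"}


def relative_thickness(
    epi: float, derm: float, min_epi: float, min_derm: float, min_total: float
) -> tuple[float, float, float]:
    """Relative epidermal/dermal/total thickness ratios, 2-decimal half-up.

    Each ratio divides the site's thickness by the category minimum over the
    full 39-site table, so the thinnest site in a category scores exactly 1.00.
    """
    vals = (epi, derm, min_epi, min_derm, min_total)
    if any(not (v > 0) for v in vals):
        raise AnatomyError(f"thickness inputs must be positive, got {vals}")
    return (
        _round2(epi / min_epi),
        _round2(derm / min_derm),
        _round2((epi + derm) / min_total),
    )


def _read_resource(name: str) -> list[dict[str, str]]:
    ref = resources.files("roipulse.data").joinpath(name)
    with ref.open("r", encoding="utf-8", newline="") as fh:
        return list(csv.DictReader(fh))


def load_anatomy_table() -> list[AnatomicalRegion]:
    """Load the 39-site thickness table, verifying packaged ratio integrity."""
    rows = _read_resource("anatomical_sites.csv")
    if len(rows) != 39:
        raise IntegrityError(f"expected 39 anatomical sites, found {len(rows)}")
    raw = [(int(r["site_id"]), r["name"], float(r["epi_um"]), float(r["derm_um"])) for r in rows]
    if any(e <= 0 or d <= 0 for _, _, e, d in raw):
        raise IntegrityError("non-positive thickness in packaged table")
    min_epi = min(e for _, _, e, _ in raw)
    min_derm = min(d for _, _, _, d in raw)
    min_total = min(e + d for _, _, e, d in raw)
    out = []
    for row, (sid, name, epi, derm) in zip(rows, raw):
        ert, drt, rt = relative_thickness(epi, derm, min_epi, min_derm, min_total)
        packaged = (float(row["ert"]), float(row["drt"]), float(row["rt"]))
        if any(abs(a - b) > 0.01 + 1e-9 for a, b in zip((ert, drt, rt), packaged)):
            raise IntegrityError(f"site {sid}: packaged ratios {packaged} != recomputed")
        out.append(AnatomicalRegion(sid, name, epi, derm, ert, drt, rt))
    return out


def load_proposed_regions() -> list[ProposedRegion]:
    """Load the 31 evaluation regions with published and recomputed thickness."""
    sites = {s.site_id: s for s in load_anatomy_table()}
    rows = _read_resource("proposed_regions.csv")
    if len(rows) != 31:
        raise IntegrityError(f"expected 31 proposed regions, found {len(rows)}")
    out = []
    for r in rows:
        rid = int(r["region_id"])
        thick = float(r["thickness_um"]) if r["thickness_um"] else None
        srcs = tuple(int(s) for s in r["source_sites"].split(";"))
        recomputed = None
        if thick is not None:
            recomputed = _round2(sites[srcs[0]].total_thickness)
        if (thick is None) != (rid in EYE_REGION_IDS):
            raise IntegrityError(f"region {rid}: thickness presence inconsistent")
        out.append(ProposedRegion(rid, r["name"], thick, recomputed, srcs, r["laterality"]))
    return out


def proposed_region_thickness(region_id: int) -> Optional[float]:
    """Published combined thickness (µm) of a region; None for the eye regions."""
    for region in load_proposed_regions():
        if region.region_id == region_id:
            return region.combined_thickness
    raise KeyError(f"unknown region_id {region_id}")
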