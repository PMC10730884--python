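"""384-well destination-plate layout, sparse-matrix sampling and transfer lists.

The plate is split into three row-major contiguous zones of 128 wells each,
one per reaction scheme: A1-F8 (Ugi 4-component), F9-K16 (Ugi-formaldehyde)
and K17-P24 (Ugi-tetrazole).  Dosing follows the nanoliter stoichiometry of
the screening protocol: 0.5 M stocks for amines, oxo components and acids
(125 nL, 1 eq = 62.5 nmol), the isocyanide at 0.25 M (250 nL, 1 eq) and the
azide source at 0.6 M (250 nL, 2.4 eq = 150 nmol).
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import EnumeratedProduct, Role, SchemeName

__all__ = [
    "WellAddress",
    "TransferSpec",
    "WellAssignment",
    "PlateDesign",
    "StockRegistry",
    "DEFAULT_ZONES",
    "BASE_NMOL",
    "zone_wells",
    "sample_sparse_matrix",
    "build_transfer_list",
    "design_plate",
]

_ROWS = string.ascii_uppercase[:16]  # A..P

#: 1 eq reference amount: 125 nL of a 0.5 M stock.
BASE_NMOL = 62.5


class CoordinateError(ValueError):
    pass


class CapacityError(ValueError):
    pass


class StockRegistryError(KeyError):
    pass


@dataclass(frozen=True, order=True)
class WellAddress:
    row: str
    column: int

    def __post_init__(self) -> None:
        if self.row not in _ROWS or not 1 <= self.column <= 24:
            raise CoordinateError(f"invalid 384-well address {self.row}{self.column}")

    @property
    def index(self) -> int:
        """Row-major linear index in [0, 383]."""
        return _ROWS.index(self.row) * 24 + (self.column - 1)

    @classmethod
    def from_index(cls, idx: int) -> "WellAddress":
        if not 0 <= idx < 384:
            raise CoordinateError(f"linear index {idx} out of range")
        return cls(_ROWS[idx // 24], idx % 24 + 1)

    @classmethod
    def parse(cls, label: str) -> "WellAddress":
        if len(label) < 2:
            raise CoordinateError(f"bad well label {label!r}")
        return cls(label[0].upper(), int(label[1:]))

    def __str__(self) -> str:
        return f"{self.row}{self.column}"


#: The three reaction zones of the destination plate (inclusive spans).
DEFAULT_ZONES: dict[SchemeName, tuple[str, str]] = {
    SchemeName.U4CR: ("A1", "F8"),
    SchemeName.UGI_FA: ("F9", "K16"),
    SchemeName.UT4CR: ("K17", "P24"),
}


def zone_wells(start: WellAddress | str, end: WellAddress | str) -> list[WellAddress]:
    """Inclusive row-major contiguous list of wells from start to end."""
    if isinstance(start, str):
        start = WellAddress.parse(start)
    if isinstance(end, str):
        end = WellAddress.parse(end)
    if start.index > end.index:
        raise CoordinateError(f"{start} does not precede {end} in row-major order")
    return [WellAddress.from_index(i) for i in range(start.index, end.index + 1)]


@dataclass(frozen=True)
class TransferSpec:
    block_id: str
    stock_conc: float  # mol/L
    volume: float  # nL
    equivalents: float

    @property
    def nmol(self) -> float:
        return self.stock_conc * self.volume  # mol/L * nL = nmol


@dataclass(frozen=True)
class WellAssignment:
    well: WellAddress
    scheme: SchemeName
    product_id: str
    block_ids: tuple[str, ...]
    transfers: tuple[TransferSpec, ...] = ()


@dataclass
class PlateDesign:
    assignments: list[WellAssignment]
    seed: int
    zone_map: dict[SchemeName, tuple[str, str]] = field(
        default_factory=lambda: dict(DEFAULT_ZONES)
    )

    def __post_init__(self) -> None:
        wells = [a.well for a in self.assignments]
        if len(wells) > 384:
            raise CapacityError("more than 384 assignments")
        if len(set(wells)) != len(wells):
            raise ValueError("duplicate wells in plate design")

    def product_for_well(self, well: WellAddress) -> str:
        for a in self.assignments:
            if a.well == well:
                return a.product_id
        raise KeyError(f"well {well} not assigned")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "well": [str(a.well) for a in self.assignments],
                "scheme": [a.scheme.value for a in self.assignments],
                "blocks": ["+".join(a.block_ids) for a in self.assignments],
                "product_id": [a.product_id for a in self.assignments],
            }
        )


def _balanced_order(
    products: list[EnumeratedProduct], n: int, rng: np.random.Generator
) -> list[EnumeratedProduct]:
    """Greedy round-robin pick keeping per-parent usage counts as even as possible.

    Each step takes, among remaining products, one minimizing the current
    maximum usage count of its parents (ties broken uniformly at random), so
    every building block appears once before any appears twice whenever that
    is arithmetically feasible.
    """
    remaining = list(products)
    # Blocks shared by every product (the fixed isocyanide/formaldehyde/azide
    # reagents) carry no information for balancing and are ignored.
    common = set(products[0].parents)
    for prod in products[1:]:
        common &= set(prod.parents)
    variable = [
        tuple(p for p in prod.parents if p not in common) or prod.parents
        for prod in remaining
    ]
    usage: dict[str, int] = {}
    picked: list[EnumeratedProduct] = []
    for _ in range(n):
        scores = np.array(
            [
                (max(usage.get(p, 0) for p in var), sum(usage.get(p, 0) for p in var))
                for var in variable
            ],
            dtype=float,
        )
        best = np.flatnonzero(
            (scores[:, 0] == scores[:, 0].min())
            & (scores[:, 1] == scores[scores[:, 0] == scores[:, 0].min(), 1].min())
        )
        idx = int(rng.choice(best))
        prod = remaining.pop(idx)
        var = variable.pop(idx)
        picked.append(prod)
        for p in var:
            usage[p] = usage.get(p, 0) + 1
    return picked


def sample_sparse_matrix(
    space: list[EnumeratedProduct],
    zone: list[WellAddress],
    seed: int,
    *,
    balance: bool = False,
) -> list[WellAssignment]:
    """Seeded sparse-matrix sampling of one zone.

    Uniform sampling without replacement from the zone's product space; with
    ``balance`` a greedy round-robin evens out building-block coverage.
    Deterministic for a fixed seed.
    """
    if len(space) < len(zone):
        raise CapacityError(
            f"product space ({len(space)}) smaller than zone ({len(zone)} wells)"
        )
    rng = np.random.default_rng(seed)
    if balance:
        picked = _balanced_order(space, len(zone), rng)
    else:
        idx = rng.choice(len(space), size=len(zone), replace=False)
        picked = [space[i] for i in idx]
    schemes = {p.scheme for p in picked}
    if len(schemes) > 1:
        raise ValueError("zone space mixes reaction schemes")
    return [
        WellAssignment(
            well=w, scheme=p.scheme, product_id=p.product_id, block_ids=p.parents
        )
        for w, p in zip(zone, picked)
    ]


@dataclass
class StockRegistry:
    """Stock concentrations (mol/L) and transfer volumes (nL) per role.

    Formaldehyde (37% w/w aqueous in the protocol) is dosed at volume parity
    with the other oxo components; its effective molarity is configurable and
    defaults to the 0.5 M used for the dedicated stocks.
    """

    conc: dict[Role, float] = field(
        default_factory=lambda: {
            Role.AMINE: 0.5,
            Role.OXO: 0.5,
            Role.ACID: 0.5,
            Role.FORMALDEHYDE: 0.5,
            Role.ISOCYANIDE: 0.25,
            Role.AZIDE_SOURCE: 0.6,
        }
    )
    volume: dict[Role, float] = field(
        default_factory=lambda: {
            Role.AMINE: 125.0,
            Role.OXO: 125.0,
            Role.ACID: 125.0,
            Role.FORMALDEHYDE: 125.0,
            Role.ISOCYANIDE: 250.0,
            Role.AZIDE_SOURCE: 250.0,
        }
    )

    def transfer_for(self, block_id: str, role: Role) -> TransferSpec:
        if role not in self.conc or role not in self.volume:
            raise StockRegistryError(f"no stock entry for role {role}")
        nmol = self.conc[role] * self.volume[role]
        return TransferSpec(
            block_id=block_id,
            stock_conc=self.conc[role],
            volume=self.volume[role],
            equivalents=round(nmol / BASE_NMOL, 6),
        )


def build_transfer_list(
    assignments: list[WellAssignment],
    roles_by_block: dict[str, Role],
    registry: StockRegistry | None = None,
) -> pd.DataFrame:
    """Nanoliter transfer table (well, block_id, volume_nL, conc_M, equivalents, nmol).

    Rows are ordered by well (row-major) then by scheme role order, so the
    CSV is byte-reproducible for identical inputs.
    """
    registry = registry or StockRegistry()
    rows = []
    for a in sorted(assignments, key=lambda a: a.well.index):
        for block_id in a.block_ids:
            try:
                role = roles_by_block[block_id]
            except KeyError as exc:
                raise StockRegistryError(f"unknown block {block_id}") from exc
            t = registry.transfer_for(block_id, role)
            rows.append(
                {
                    "well": str(a.well),
                    "scheme": a.scheme.value,
                    "block_id": t.block_id,
                    "volume_nL": t.volume,
                    "conc_M": t.stock_conc,
                    "equivalents": t.equivalents,
                    "nmol": t.nmol,
                }
            )
    columns = ["well", "scheme", "block_id", "volume_nL", "conc_M", "equivalents", "nmol"]
    return pd.DataFrame(rows, columns=columns)


def design_plate(
    products: list[EnumeratedProduct],
    seed: int,
    *,
    zones: dict[SchemeName, tuple[str, str]] | None = None,
    balance: bool = False,
) -> PlateDesign:
    """Sample all three zones from the enumerated space into one plate design."""
    zones = zones or DEFAULT_ZONES
    by_scheme: dict[SchemeName, list[EnumeratedProduct]] = {}
    for p in products:
        by_scheme.setdefault(p.scheme, []).append(p)
    assignments: list[WellAssignment] = []
    for i, (scheme, (start, end)) in enumerate(sorted(zones.items(), key=lambda kv: kv[0].value)):
        zone = zone_wells(start, end)
        assignments.extend(
            sample_sparse_matrix(
                by_scheme.get(scheme, []), zone, seed + 7919 * i, balance=balance
            )
        )
    return PlateDesign(assignments=assignments, seed=seed, zone_map=dict(zones))
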