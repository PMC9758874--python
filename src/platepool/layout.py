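"""Plate-well pool layouts.

A plate-well pooling scheme for an ordered collection of ``N`` 96-well plates
uses one pool per plate plus one pool per 96-well position, ``N + 96`` pools
in total.  Every strain sorted into well (p, j) therefore appears in exactly
two pools — its plate pool and its well-position pool — and a barcode isolated
``n`` times is narrowed down to at most ``n**2`` candidate wells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ValidationError

WELL_ROWS = "ABCDEFGH"
WELL_COLUMNS = tuple(range(1, 13))

#: The 96 standard well positions in row-major order (A1, A2, ..., H12).
WELL_POSITIONS: tuple[str, ...] = tuple(
    f"{row}{col}" for row in WELL_ROWS for col in WELL_COLUMNS
)

_WELL_INDEX = {w: i for i, w in enumerate(WELL_POSITIONS)}


def well_index(position: str) -> int:
    """Row-major index (0-95) of a standard well position such as ``"B7"``."""
    try:
        return _WELL_INDEX[position]
    except KeyError:
        raise ValidationError(f"not a standard 96-well position: {position!r}") from None


@dataclass(frozen=True)
class PoolLayout:
    """Identifiers of the N plate pools and the 96 well-position pools.

    Parameters
    ----------
    plate_pool_ids:
        One identifier per plate, in plate order.
    well_pool_ids:
        One identifier per standard well position, in row-major order
        (position ``WELL_POSITIONS[i]`` is sequenced in pool
        ``well_pool_ids[i]``).  Defaults to the well positions themselves.
    """

    plate_pool_ids: tuple[str, ...]
    well_pool_ids: tuple[str, ...] = field(default=WELL_POSITIONS)

    def __post_init__(self) -> None:
        plates = tuple(self.plate_pool_ids)
        wells = tuple(self.well_pool_ids)
        object.__setattr__(self, "plate_pool_ids", plates)
        object.__setattr__(self, "well_pool_ids", wells)
        if len(plates) < 1:
            raise ValidationError("a layout needs at least one plate pool")
        if len(set(plates)) != len(plates):
            raise ValidationError("duplicate plate pool ids")
        if len(wells) != 96 or len(set(wells)) != 96:
            raise ValidationError("exactly 96 distinct well pool ids required")
        if set(plates) & set(wells):
            raise ValidationError("plate and well pool id sets must be disjoint")

    @classmethod
    def default(cls, n_plates: int) -> "PoolLayout":
        """Layout with plate pools ``P1..PN`` and well pools named by position."""
        if n_plates < 1:
            raise ValidationError("n_plates must be >= 1")
        return cls(tuple(f"P{i + 1}" for i in range(n_plates)))

    @property
    def n_plates(self) -> int:
        return len(self.plate_pool_ids)

    @property
    def n_pools(self) -> int:
        """Total pool count: N plates + 96 well positions."""
        return self.n_plates + 96

    @property
    def pool_ids(self) -> tuple[str, ...]:
        """All pool ids, plate pools first then well pools."""
        return self.plate_pool_ids + self.well_pool_ids

    def plate_index(self, pool_id: str) -> int:
        """0-based plate index for a plate pool id."""
        try:
            return self.plate_pool_ids.index(pool_id)
        except ValueError:
            raise ValidationError(f"unknown plate pool: {pool_id!r}") from None

    def well_position(self, pool_id: str) -> str:
        """Standard well position (e.g. ``"G1"``) for a well pool id."""
        try:
            return WELL_POSITIONS[self.well_pool_ids.index(pool_id)]
        except ValueError:
            raise ValidationError(f"unknown well pool: {pool_id!r}") from None
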