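"""Hydrogel construct geometry.

The constructs are thin hydrogel slabs: a fixed liquid volume (default 5 µL)
sandwiched between spacers of fixed thickness (default 100 µm).  The lateral
footprint is therefore derived, ``footprint_area = volume / thickness``, and is
modelled as a square for footprint placement purposes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InvalidGeometryError

#: µL -> µm^3 (1 µL = 1 mm^3 = 1e9 µm^3)
UL_TO_UM3 = 1.0e9


@dataclass(frozen=True)
class ConstructGeometry:
    """Slab geometry of one synthetic tissue construct.

    Parameters
    ----------
    volume_ul : float
        Total construct volume in microliters.
    thickness_um : float
        Slab thickness in micrometers (the z extent).
    """

    volume_ul: float = 5.0
    thickness_um: float = 100.0

    def __post_init__(self) -> None:
        if not (self.volume_ul > 0 and self.thickness_um > 0):
            raise InvalidGeometryError(
                f"geometry dimensions must be positive, got volume={self.volume_ul} µL, "
                f"thickness={self.thickness_um} µm"
            )

    @property
    def volume_um3(self) -> float:
        return self.volume_ul * UL_TO_UM3

    @property
    def footprint_area_mm2(self) -> float:
        """Lateral area in mm², volume[mm³] / thickness[mm]."""
        return self.volume_ul / (self.thickness_um / 1000.0)

    @property
    def footprint_area_um2(self) -> float:
        return self.volume_um3 / self.thickness_um

    @property
    def side_um(self) -> float:
        """Side of the (square-modelled) footprint in µm."""
        return math.sqrt(self.footprint_area_um2)

    def contains(self, positions) -> bool:
        """True if every (x, y, z) row lies inside the slab."""
        import numpy as np

        pos = np.asarray(positions, dtype=float)
        if pos.size == 0:
            return True
        x, y, z = pos[:, 0], pos[:, 1], pos[:, 2]
        s = self.side_um
        return bool(
            (x >= 0).all() and (x <= s).all()
            and (y >= 0).all() and (y <= s).all()
            and (z >= 0).all() and (z <= self.thickness_um).all()
        )
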