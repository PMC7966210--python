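"""ASPECTS region vocabulary.

ASPECTS divides the middle-cerebral-artery territory into 10 regions per
hemisphere: four deep ("central") structures — caudate nucleus (CN),
internal capsule (IC), insula (INS), lentiform nucleus (LN) — and six
cortical MCA territories M1–M6. One point is subtracted from 10 for each
region showing early ischemic change.
"""

from __future__ import annotations

from enum import Enum


class Region(str, Enum):
    CN = "CN"
    IC = "IC"
    INS = "INS"
    LN = "LN"
    M1 = "M1"
    M2 = "M2"
    M3 = "M3"
    M4 = "M4"
    M5 = "M5"
    M6 = "M6"

    @property
    def group(self) -> str:
        return "central" if self in CENTRAL_REGIONS else "cortical"


class Hemisphere(str, Enum):
    LEFT = "left"
    RIGHT = "right"

    @property
    def opposite(self) -> "Hemisphere":
        return Hemisphere.RIGHT if self is Hemisphere.LEFT else Hemisphere.LEFT


ALL_REGIONS: tuple[Region, ...] = tuple(Region)
CENTRAL_REGIONS: tuple[Region, ...] = (Region.CN, Region.IC, Region.INS, Region.LN)
CORTICAL_REGIONS: tuple[Region, ...] = (
    Region.M1,
    Region.M2,
    Region.M3,
    Region.M4,
    Region.M5,
    Region.M6,
)
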