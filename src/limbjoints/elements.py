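"""Joint element codes and the upper/lower limb partition.

Ten composite joint dimensions summarise each skeleton. Five belong to the
upper limb (shoulder and elbow) and five to the lower limb (hip, lumbosacral
and talocrural joints):

====  =============================================================
code  dimension (mm)
====  =============================================================
G     scapular glenoid size (geomean of SI height and width)
H     humeral head size (geomean of SI height and AP width)
B     humeral biepicondylar breadth
U     ulnar olecranon width
R     radial head diameter
F     femoral head SI diameter
Sub   femoral subtrochanteric size (geomean of ML and AP breadths)
A     acetabulum SI height
T     talar trochlear width
Sac   sacral (S1) body size (geomean of ML width and AP diameter)
====  =============================================================
"""

from __future__ import annotations

UPPER: tuple[str, ...] = ("G", "H", "B", "U", "R")
LOWER: tuple[str, ...] = ("F", "Sub", "A", "T", "Sac")
ALL_ELEMENTS: tuple[str, ...] = UPPER + LOWER

#: composite elements and the raw caliper fields they are derived from
COMPOSITES: dict[str, tuple[str, str]] = {
    "G": ("glenoid_si", "glenoid_w"),
    "H": ("humhead_si", "humhead_ap"),
    "Sub": ("subtroch_ml", "subtroch_ap"),
    "Sac": ("sacral_ml", "sacral_ap"),
}

#: single-caliper elements copied through unchanged
PASSTHROUGH: dict[str, str] = {
    "B": "biepicondylar",
    "U": "olecranon_w",
    "R": "radhead_d",
    "F": "femhead_si",
    "A": "acetabulum_si",
    "T": "talar_ml",
}

RAW_FIELDS: tuple[str, ...] = tuple(
    f for pair in COMPOSITES.values() for f in pair
) + tuple(PASSTHROUGH.values())

# plausible caliper range for adult hominoid joint dimensions (mm); values
# outside trigger a warning, not an error
PLAUSIBLE_MM = (1.0, 200.0)


def is_upper(code: str) -> bool:
    return code in UPPER


def is_lower(code: str) -> bool:
    return code in LOWER
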