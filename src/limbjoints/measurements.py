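"""Joint-size data model and the relative limb size index (RLSI).

The RLSI of one individual is the natural log of the ratio between the
geometric mean of its upper-limb joint dimensions and the geometric mean of
its lower-limb joint dimensions::

    RLSI = ln( geomean(upper elements) / geomean(lower elements) )

Positive values mean relatively larger upper-limb joints (the ape condition,
reflecting climbing and suspension); negative values mean relatively larger
lower-limb joints (the human condition, reflecting terrestrial bipedalism).

Because fossil partial skeletons preserve different subsets of joints, the
index is parameterised by a :class:`RatioSpec` naming which upper and lower
elements enter each side, and :func:`preserved_spec` truncates a spec to the
elements a given specimen actually preserves. Missing data are never imputed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .elements import (
    ALL_ELEMENTS,
    COMPOSITES,
    LOWER,
    PASSTHROUGH,
    PLAUSIBLE_MM,
    UPPER,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RawMeasurementSet",
    "JointDimensionSet",
    "RatioSpec",
    "RLSIValue",
    "FULL_SPEC",
    "geometric_mean",
    "derive_dimensions",
    "rlsi",
    "preserved_spec",
]


@dataclass(frozen=True)
class RawMeasurementSet:
    """The 14 raw caliper measurements (mm) of one specimen.

    Any field may be ``None`` (not preserved / not measured); at least one
    must be present and all present values must be positive.
    """

    specimen_id: str
    taxon: str
    glenoid_si: float | None = None
    glenoid_w: float | None = None
    humhead_si: float | None = None
    humhead_ap: float | None = None
    biepicondylar: float | None = None
    olecranon_w: float | None = None
    radhead_d: float | None = None
    acetabulum_si: float | None = None
    femhead_si: float | None = None
    subtroch_ml: float | None = None
    subtroch_ap: float | None = None
    sacral_ml: float | None = None
    sacral_ap: float | None = None
    talar_ml: float | None = None

    def __post_init__(self) -> None:
        present = self.present_fields()
        if not present:
            raise ValueError(
                f"{self.specimen_id}: no measurements present"
            )
        for name, value in present.items():
            if not math.isfinite(value) or value <= 0:
                raise ValueError(
                    f"{self.specimen_id}: non-positive measurement {name}={value!r}"
                )
            if not PLAUSIBLE_MM[0] <= value <= PLAUSIBLE_MM[1]:
                logger.warning(
                    "%s: %s=%.1f mm outside plausible range %s",
                    self.specimen_id, name, value, PLAUSIBLE_MM,
                )

    def present_fields(self) -> dict[str, float]:
        fields = (
            "glenoid_si", "glenoid_w", "humhead_si", "humhead_ap",
            "biepicondylar", "olecranon_w", "radhead_d", "acetabulum_si",
            "femhead_si", "subtroch_ml", "subtroch_ap", "sacral_ml",
            "sacral_ap", "talar_ml",
        )
        return {
            f: getattr(self, f) for f in fields if getattr(self, f) is not None
        }


@dataclass(frozen=True)
class JointDimensionSet:
    """One specimen's composite joint dimensions (mm), keyed by element code.

    ``estimated`` flags elements whose printed value was estimated rather
    than measured (e.g. a talar width estimated from tibial plafond width);
    such values are used as printed but carry the provenance flag.
    """

    specimen_id: str
    taxon: str
    values: Mapping[str, float]
    estimated: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", dict(self.values))
        object.__setattr__(self, "estimated", frozenset(self.estimated))
        bad = set(self.values) - set(ALL_ELEMENTS)
        if bad:
            raise ValueError(
                f"{self.specimen_id}: unknown element codes {sorted(bad)}"
            )
        for code, value in self.values.items():
            if not math.isfinite(value) or value <= 0:
                raise ValueError(
                    f"{self.specimen_id}: non-positive dimension {code}={value!r}"
                )
        if not self.values:
            raise ValueError(f"{self.specimen_id}: no dimensions present")

    @property
    def upper_codes(self) -> tuple[str, ...]:
        return tuple(c for c in UPPER if c in self.values)

    @property
    def lower_codes(self) -> tuple[str, ...]:
        return tuple(c for c in LOWER if c in self.values)

    def scaled(self, factor: float) -> "JointDimensionSet":
        """Uniformly rescaled copy (used by size-invariance checks)."""
        return JointDimensionSet(
            self.specimen_id, self.taxon,
            {c: v * factor for c, v in self.values.items()},
            self.estimated,
        )


@dataclass(frozen=True)
class RatioSpec:
    """Which elements enter the numerator (upper) and denominator (lower)."""

    upper: tuple[str, ...]
    lower: tuple[str, ...]
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "upper", tuple(self.upper))
        object.__setattr__(self, "lower", tuple(self.lower))
        if not self.upper or not self.lower:
            raise ValueError(f"{self.label or 'RatioSpec'}: both sides must be nonempty")
        for side, allowed, name in (
            (self.upper, UPPER, "upper"), (self.lower, LOWER, "lower"),
        ):
            bad = set(side) - set(allowed)
            if bad:
                raise ValueError(f"{name} side contains invalid codes {sorted(bad)}")
            if len(set(side)) != len(side):
                raise ValueError(f"duplicate codes on {name} side: {side}")
        if not self.label:
            object.__setattr__(self, "label", self.default_label())

    def default_label(self) -> str:
        return "+".join(self.upper) + ":" + "+".join(self.lower)

    def swapped(self) -> "RatioSpec":
        """Spec with numerator and denominator exchanged (for antisymmetry
        checks); element-side validation is bypassed deliberately."""
        s = object.__new__(RatioSpec)
        object.__setattr__(s, "upper", self.lower)
        object.__setattr__(s, "lower", self.upper)
        object.__setattr__(s, "label", f"swap({self.label})")
        return s


@dataclass(frozen=True)
class RLSIValue:
    specimen_id: str
    spec: RatioSpec
    value: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError(f"{self.specimen_id}: non-finite RLSI")


#: the full ten-element ratio used when a skeleton preserves everything
FULL_SPEC = RatioSpec(UPPER, LOWER, label="full")


def geometric_mean(values: Iterable[float]) -> float:
    """Geometric mean of positive lengths, computed as exp(mean of logs).

    Preferred over the arithmetic mean as a size proxy because it equalises
    the weight of measurements with different absolute ranges.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("geometric_mean of empty list")
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError("geometric_mean requires positive finite values")
    return float(np.exp(np.mean(np.log(arr))))


def derive_dimensions(raw: RawMeasurementSet) -> JointDimensionSet:
    """Collapse the 14 raw calipers into the 10 composite joint dimensions.

    G, H, Sub and Sac are geometric means of their two calipers and are
    produced only when both calipers are present (one of a pair present is
    logged and the element omitted); B, U, R, F, A, T pass through.
    """
    present = raw.present_fields()
    values: dict[str, float] = {}
    for code, (f1, f2) in COMPOSITES.items():
        have = [f for f in (f1, f2) if f in present]
        if len(have) == 2:
            values[code] = geometric_mean((present[f1], present[f2]))
        elif len(have) == 1:
            logger.warning(
                "%s: composite %s needs both %s and %s; only %s present — omitted",
                raw.specimen_id, code, f1, f2, have[0],
            )
    for code, fname in PASSTHROUGH.items():
        if fname in present:
            values[code] = present[fname]
    return JointDimensionSet(raw.specimen_id, raw.taxon, values)


def rlsi(dims: JointDimensionSet, spec: RatioSpec) -> RLSIValue:
    """RLSI of one specimen under a ratio spec.

    Every code named by the spec must be present in ``dims``; callers with
    partial skeletons first truncate the spec with :func:`preserved_spec`.
    """
    missing = [c for c in (*spec.upper, *spec.lower) if c not in dims.values]
    if missing:
        raise ValueError(
            f"{dims.specimen_id}: spec '{spec.label}' needs missing elements {missing}"
        )
    value = math.log(
        geometric_mean(dims.values[c] for c in spec.upper)
        / geometric_mean(dims.values[c] for c in spec.lower)
    )
    return RLSIValue(dims.specimen_id, spec, value)


def preserved_spec(dims: JointDimensionSet, full: RatioSpec = FULL_SPEC) -> RatioSpec:
    """Truncate ``full`` to the elements ``dims`` preserves.

    Mirrors the per-fossil variant analyses: each partial skeleton is
    compared under the largest ratio its preservation allows. Raises if
    either side would become empty.
    """
    upper = tuple(c for c in full.upper if c in dims.values)
    lower = tuple(c for c in full.lower if c in dims.values)
    if not upper or not lower:
        raise ValueError(
            f"{dims.specimen_id}: no {'upper' if not upper else 'lower'} "
            f"element of spec '{full.label}' is preserved"
        )
    return RatioSpec(upper, lower)
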