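"""CSV dialects, packaged fixtures, and report serialisation.

Two measurement CSV dialects are accepted, auto-detected by header:

* **composite** — columns ``specimen_id, taxon, G, H, B, U, R, F, Sub, A, T,
  Sac`` (plus optional ``estimated``, a ``;``/space-separated list of element
  codes whose values were estimated rather than measured);
* **raw** — columns ``specimen_id, taxon`` plus the 14 caliper fields
  (``glenoid_si`` ... ``talar_ml``); composites are derived on load.

Empty cells mean "not preserved". All files are UTF-8 with a header row.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd

from .elements import ALL_ELEMENTS, RAW_FIELDS
from .measurements import JointDimensionSet, RawMeasurementSet, derive_dimensions
from .synthetic import TaxonSample, TaxonSummary

__all__ = [
    "read_measurement_csv",
    "write_measurement_csv",
    "load_fossils",
    "load_extant_summaries",
    "load_character_states",
    "packaged_tree_paths",
    "read_specimen_samples",
]

_DATA = resources.files("limbjoints") / "data"


def _parse_estimated(cell) -> frozenset[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return frozenset()
    return frozenset(str(cell).replace(";", " ").split())


def read_measurement_csv(path: str | Path) -> list[JointDimensionSet]:
    """Read either dialect into composite joint-dimension sets."""
    df = pd.read_csv(path)
    cols = set(df.columns)
    if {"specimen_id", "taxon"} - cols:
        raise ValueError(f"{path}: missing specimen_id/taxon columns")
    if "G" in cols:
        dialect = "composite"
    elif "glenoid_si" in cols:
        dialect = "raw"
    else:
        raise ValueError(f"{path}: header matches neither dialect")

    out: list[JointDimensionSet] = []
    for _, row in df.iterrows():
        sid, taxon = str(row["specimen_id"]), str(row["taxon"])
        if dialect == "composite":
            values = {
                c: float(row[c])
                for c in ALL_ELEMENTS if c in cols and pd.notna(row[c])
            }
            out.append(JointDimensionSet(
                sid, taxon, values,
                estimated=_parse_estimated(row.get("estimated")),
            ))
        else:
            raw = RawMeasurementSet(sid, taxon, **{
                f: float(row[f])
                for f in RAW_FIELDS if f in cols and pd.notna(row[f])
            })
            out.append(derive_dimensions(raw))
    return out


def write_measurement_csv(dims: list[JointDimensionSet], path: str | Path) -> None:
    rows = []
    for d in dims:
        row = {"specimen_id": d.specimen_id, "taxon": d.taxon}
        row.update({c: d.values.get(c) for c in ALL_ELEMENTS})
        row["estimated"] = ";".join(sorted(d.estimated))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def samples_to_csv(samples: Mapping[str, TaxonSample], path: str | Path) -> None:
    """Write synthetic taxon samples in the composite specimen dialect."""
    frames = []
    for taxon in sorted(samples):
        df = samples[taxon].data.copy()
        df.insert(0, "taxon", taxon)
        df.insert(0, "specimen_id",
                  [f"{taxon}-{i:05d}" for i in range(len(df))])
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format="%.6f")


def read_specimen_samples(path: str | Path) -> dict[str, TaxonSample]:
    """Read a specimen-level composite CSV grouped into per-taxon samples."""
    df = pd.read_csv(path)
    elem_cols = [c for c in ALL_ELEMENTS if c in df.columns]
    out = {}
    for taxon, grp in df.groupby("taxon", sort=True):
        out[str(taxon)] = TaxonSample(str(taxon),
                                      grp[elem_cols].reset_index(drop=True))
    return out


def load_fossils() -> list[JointDimensionSet]:
    """The 16 hominin partial skeletons of the packaged fossil table."""
    with resources.as_file(_DATA / "fossils.csv") as p:
        return read_measurement_csv(p)


def load_extant_summaries() -> dict[str, TaxonSummary]:
    """Published per-element mean/SD/N for the five extant hominoid taxa."""
    with resources.as_file(_DATA / "extant_summary.csv") as p:
        df = pd.read_csv(p)
    out: dict[str, TaxonSummary] = {}
    for taxon, grp in df.groupby("taxon", sort=True):
        stats = {
            str(r.element): (float(r.mean), float(r.sd), int(r.n))
            for r in grp.itertuples()
        }
        out[str(taxon)] = TaxonSummary(str(taxon), stats)
    return out


def load_character_states() -> dict[str, str]:
    """Binary RLSI state (high/low) per taxon for the parsimony analysis."""
    with resources.as_file(_DATA / "rlsi_states.csv") as p:
        df = pd.read_csv(p)
    return {str(r.taxon): str(r.state) for r in df.itertuples()}


def packaged_tree_paths() -> dict[str, Path]:
    """Label -> path of the six packaged phylogenetic hypotheses (A-F)."""
    out = {}
    for label in "ABCDEF":
        with resources.as_file(_DATA / "trees" / f"topology_{label}.nwk") as p:
            out[label] = Path(p)
    return out


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
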