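"""Readers/writers for granule tables, contours and masks.

Measurement tables from different labs use different column names, units
and boolean encodings; a :class:`ColumnMapping` isolates that schema
uncertainty.  The canonical per-granule fields are::

    id, taxon, sample_id, max_length_um, max_width_um, proximal_dist_um,
    hilum_angle_deg, shape_class, lamellae, fissure, curved

The eccentricity ratio is recomputed as proximal_dist / max_length when
both are mapped; otherwise an ``er`` column may be mapped directly.
Rows violating the measurement invariants (width > length beyond
tolerance, ER outside [0, 0.5], non-positive lengths) are rejected with
row-numbered diagnostics (Python warnings) rather than aborting the read.

CSV dialect is RFC 4180, UTF-8, "." decimal separator.  Contours travel
as JSON lines, one object per granule; masks as PNG.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError
from .geometry import GranuleContour, GranuleMeasurement
from .synth import GranuleRecord

CANONICAL_FIELDS = ("id", "taxon", "sample_id", "max_length_um",
                    "max_width_um", "proximal_dist_um", "hilum_angle_deg",
                    "shape_class", "lamellae", "fissure", "curved")

_TRUE_TOKENS = {"1", "true", "yes", "present", "y", "t"}
_FALSE_TOKENS = {"0", "false", "no", "absent", "n", "f"}


@dataclass(frozen=True)
class ColumnMapping:
    """Canonical-field -> source-column mapping with unit scale factors.

    ``columns`` maps canonical names to source column names; a canonical
    field may be omitted (``shape_class`` defaults to oval=absent flags,
    booleans default to False, labels to placeholders).  ``scales`` are
    multiplicative unit conversions applied to the numeric fields.  An
    ``er`` entry in ``columns`` is honoured only when ``proximal_dist_um``
    is not mapped.
    """

    columns: dict = field(default_factory=dict)
    scales: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.columns) - set(CANONICAL_FIELDS) - {"er"}
        if unknown:
            raise SchemaError(f"unknown canonical fields: {sorted(unknown)}")
        for k, s in self.scales.items():
            if not s > 0:
                raise SchemaError(f"scale factor for {k!r} must be positive")

    def to_yaml(self, path) -> None:
        import yaml
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ColumnMapping":
        import yaml
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(columns=d.get("columns", {}), scales=d.get("scales", {}))


#: identity mapping for tables written by this package
DEFAULT_MAPPING = ColumnMapping(
    columns={f: f for f in CANONICAL_FIELDS})

#: best-guess mapping for the published reference deposit's spreadsheet
#: layout (adjust via YAML if the actual column names differ)
DRYAD_GUESS_MAPPING = ColumnMapping(
    columns={"taxon": "Species", "sample_id": "Sample",
             "max_length_um": "Max Length", "max_width_um": "Max Width",
             "proximal_dist_um": "Hilum to Proximal",
             "hilum_angle_deg": "Angle of Hilum", "shape_class": "Shape",
             "lamellae": "Lamellae", "fissure": "Longitudinal Fissure",
             "curved": "Curve"})


def _parse_bool(value, row: int, col: str) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    token = str(value).strip().lower()
    if token in _TRUE_TOKENS:
        return True
    if token in _FALSE_TOKENS:
        return False
    raise SchemaError(f"row {row}: cannot parse boolean {col}={value!r}")


def read_granule_csv(path, mapping: ColumnMapping = DEFAULT_MAPPING
                     ) -> list[GranuleRecord]:
    """Read a granule measurement table into validated records.

    Rows failing invariants are dropped with a row-numbered warning.
    Raises :class:`SchemaError` for an empty file, missing mapped
    columns, or unparseable numerics.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: file is empty") from None
    missing = [src for src in mapping.columns.values()
               if src not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mapped columns {missing}")

    def col(canon, default=None):
        src = mapping.columns.get(canon)
        return df[src] if src is not None else default

    def scaled(canon, series, row):
        try:
            v = float(series.iloc[row])
        except (TypeError, ValueError):
            raise SchemaError(
                f"{path}: row {row}: unparseable numeric "
                f"{canon}={series.iloc[row]!r}") from None
        return v * mapping.scales.get(canon, 1.0)

    records: list[GranuleRecord] = []
    for i in range(len(df)):
        length = scaled("max_length_um", col("max_length_um"), i)
        width = scaled("max_width_um", col("max_width_um"), i)
        angle = scaled("hilum_angle_deg", col("hilum_angle_deg"), i)
        if mapping.columns.get("proximal_dist_um") is not None:
            prox = scaled("proximal_dist_um", col("proximal_dist_um"), i)
            er = prox / length if length > 0 else np.nan
        elif mapping.columns.get("er") is not None:
            er = scaled("er", df[mapping.columns["er"]], i)
        else:
            raise SchemaError(
                f"{path}: mapping provides neither proximal_dist_um nor er")

        problems = []
        if not length > 0 or not width > 0:
            problems.append("non-positive length/width")
        if width > 1.01 * length:
            problems.append(f"width {width:.3g} > length {length:.3g}")
        if not 0.0 <= er <= 0.5 + 1e-9:
            problems.append(f"ER {er:.3g} outside [0, 0.5]")
        if not 0.0 < angle <= 180.0 + 1e-9:
            problems.append(f"hilum angle {angle:.3g} outside (0, 180]")
        if problems:
            warnings.warn(f"{path.name} row {i}: rejected "
                          f"({'; '.join(problems)})", stacklevel=2)
            continue

        shape_series = col("shape_class")
        if shape_series is not None:
            shape = str(shape_series.iloc[i]).strip().lower()
            if shape not in ("oval", "triangular"):
                warnings.warn(f"{path.name} row {i}: rejected "
                              f"(unknown shape class {shape!r})",
                              stacklevel=2)
                continue
        else:
            shape = "oval"
        flags = {}
        for canon in ("lamellae", "fissure", "curved"):
            series = col(canon)
            flags[canon] = (_parse_bool(series.iloc[i], i, canon)
                            if series is not None else False)
        idc = col("id")
        taxc = col("taxon")
        sidc = col("sample_id")
        measurement = GranuleMeasurement(
            max_length=length, max_width=width,
            eccentricity_ratio=min(er, 0.5), hilum_angle=min(angle, 180.0))
        records.append(GranuleRecord(
            measurement=measurement,
            taxon=str(taxc.iloc[i]) if taxc is not None else "unknown",
            sample_id=str(sidc.iloc[i]) if sidc is not None else "unknown",
            shape_class=shape, lamellae=flags["lamellae"],
            longitudinal_fissure=flags["fissure"], curved=flags["curved"],
            id=str(idc.iloc[i]) if idc is not None else f"row{i}"))
    return records


def write_granule_csv(records: Sequence[GranuleRecord], path) -> None:
    """Write records as a canonical granule table (lossless round trip)."""
    rows = []
    for r in records:
        m = r.measurement
        rows.append({
            "id": r.id, "taxon": r.taxon, "sample_id": r.sample_id,
            "max_length_um": m.max_length, "max_width_um": m.max_width,
            "proximal_dist_um": m.eccentricity_ratio * m.max_length,
            "hilum_angle_deg": m.hilum_angle, "shape_class": r.shape_class,
            "lamellae": r.lamellae, "fissure": r.longitudinal_fissure,
            "curved": r.curved})
    pd.DataFrame(rows, columns=list(CANONICAL_FIELDS)).to_csv(
        path, index=False)


# ---------------------------------------------------------------------------
# contours and masks
# ---------------------------------------------------------------------------

def write_contours_jsonl(contours: Sequence[GranuleContour], path,
                         taxa: Optional[Sequence[str]] = None,
                         pixel_size: Optional[float] = None) -> None:
    """One JSON object per line: {id, vertices, hilum, taxon?, pixel_size?}."""
    with open(path, "w") as fh:
        for i, c in enumerate(contours):
            obj = {"id": c.id, "vertices": c.vertices.tolist(),
                   "hilum": list(c.hilum) if c.hilum is not None else None}
            if taxa is not None:
                obj["taxon"] = taxa[i]
            if pixel_size is not None:
                obj["pixel_size"] = pixel_size
            fh.write(json.dumps(obj) + "\n")


def read_contours_jsonl(path) -> list[tuple[GranuleContour, dict]]:
    """Read contour records; returns (contour, extras) per line."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            contour = GranuleContour(
                np.asarray(obj["vertices"], dtype=float),
                tuple(obj["hilum"]) if obj.get("hilum") else None,
                obj.get("id", ""))
            extras = {k: v for k, v in obj.items()
                      if k not in ("vertices", "hilum", "id")}
            out.append((contour, extras))
    return out


def save_mask_png(mask: np.ndarray, path) -> None:
    from PIL import Image
    Image.fromarray((np.asarray(mask, dtype=bool) * 255).astype(np.uint8)
                    ).save(path)


def load_mask_png(path) -> np.ndarray:
    from PIL import Image
    return np.asarray(Image.open(path)) > 127
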