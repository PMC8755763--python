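"""File formats: ENVI cubes, 16-bit PNG label maps, annotation CSVs, reports.

The cube format is the de-facto hyperspectral standard: an ASCII ``.hdr``
header (samples/lines/bands, data type, interleave, wavelength list) next to
a flat binary payload. Only float32 (data type 4) and uint16 (12) payloads
are supported; writing is band-interleaved-by-pixel ("bip", i.e. C-order
rows x cols x bands), reading accepts bip/bil/bsq. Readers validate rather
than guess: a header/binary size mismatch, a missing wavelength list or an
unknown interleave is an error, never a silent default.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import RawCube, WavelengthGrid
from .exceptions import ConsistencyError, FormatError
from .roi import RegionAnnotation

_DTYPE_CODES = {4: np.float32, 12: np.uint16}
_CODE_FOR_DTYPE = {np.dtype(np.float32): 4, np.dtype(np.uint16): 12}

ANNOTATION_COLUMNS = ["patient_id", "region_id", "icrs_grade"]


# --------------------------------------------------------------------------
# ENVI cubes
# --------------------------------------------------------------------------


def write_envi_cube(cube: RawCube, path: str | Path) -> Path:
    """Write ``<path>.hdr`` + ``<path>.raw``; returns the header path.

    The payload is float32 unless the cube's values fit uint16 exactly.
    """
    path = Path(path)
    data = cube.intensities
    if np.array_equal(data, np.round(data)) and data.min() >= 0 and data.max() < 2**16:
        arr = data.astype(np.uint16)
    else:
        arr = data.astype(np.float32)
    rows, cols, bands = arr.shape
    wavelengths = ", ".join(f"{w:g}" for w in cube.grid.band_centers)
    header = (
        "ENVI\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_CODE_FOR_DTYPE[arr.dtype]}\n"
        "interleave = bip\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wavelengths} }}\n"
    )
    hdr = path.with_suffix(".hdr")
    hdr.write_text(header)
    arr.tofile(path.with_suffix(".raw"))
    return hdr


def _parse_envi_header(text: str) -> dict[str, str]:
    if not text.lstrip().startswith("ENVI"):
        raise FormatError("not an ENVI header (missing ENVI magic)")
    # fold brace-delimited multi-line values onto one line
    text = re.sub(
        r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text
    )
    fields: dict[str, str] = {}
    for line in text.splitlines()[1:]:
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        fields[key.strip().lower()] = value.strip()
    return fields


def read_envi_cube(path: str | Path) -> RawCube:
    """Read an ENVI header+binary pair into a :class:`RawCube`.

    The wavelength list drives the cube's :class:`WavelengthGrid`. Raises
    :class:`FormatError` on a missing wavelength list, an unsupported data
    type or interleave, or a header/binary size mismatch.
    """
    path = Path(path)
    hdr = path if path.suffix == ".hdr" else path.with_suffix(".hdr")
    if not hdr.exists():
        raise FormatError(f"missing header file {hdr}")
    fields = _parse_envi_header(hdr.read_text())
    try:
        cols = int(fields["samples"])
        rows = int(fields["lines"])
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
    except KeyError as exc:
        raise FormatError(f"ENVI header missing required field {exc}") from exc
    if "wavelength" not in fields:
        raise FormatError("ENVI header has no wavelength list")
    if dtype_code not in _DTYPE_CODES:
        raise FormatError(f"unsupported ENVI data type {dtype_code}")
    interleave = fields.get("interleave", "bip").lower()
    if interleave not in ("bip", "bil", "bsq"):
        raise FormatError(f"unsupported interleave {interleave!r}")
    wl_text = fields["wavelength"].strip().strip("{}").strip()
    wavelengths = np.array(
        [float(tok) for tok in wl_text.replace(",", " ").split()]
    )
    if wavelengths.size != bands:
        raise FormatError(
            f"wavelength list has {wavelengths.size} entries for {bands} bands"
        )
    binary = hdr.with_suffix(".raw")
    if not binary.exists():
        raise FormatError(f"missing binary file {binary}")
    dtype = np.dtype(_DTYPE_CODES[dtype_code])
    expected = rows * cols * bands * dtype.itemsize
    actual = binary.stat().st_size
    if expected != actual:
        raise FormatError(
            f"binary size {actual} B does not match header "
            f"({rows}x{cols}x{bands} {dtype.name} = {expected} B)"
        )
    flat = np.fromfile(binary, dtype=dtype)
    if interleave == "bip":
        data = flat.reshape(rows, cols, bands)
    elif interleave == "bil":
        data = flat.reshape(rows, bands, cols).transpose(0, 2, 1)
    else:  # bsq
        data = flat.reshape(bands, rows, cols).transpose(1, 2, 0)
    return RawCube(np.ascontiguousarray(data, dtype=float),
                   WavelengthGrid(wavelengths))


# --------------------------------------------------------------------------
# label maps and annotations
# --------------------------------------------------------------------------


def write_label_png(labels: np.ndarray, path: str | Path) -> Path:
    """16-bit single-channel PNG."""
    import imageio.v3 as iio

    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() >= 2**16:
        raise ValueError("labels must fit uint16")
    path = Path(path)
    iio.imwrite(path, labels.astype(np.uint16), extension=".png")
    return path


def read_label_png(path: str | Path) -> np.ndarray:
    import imageio.v3 as iio

    arr = iio.imread(Path(path))
    if arr.ndim != 2:
        raise FormatError("label map must be a single-channel image")
    return arr.astype(np.int64)


def write_annotations_csv(
    annotations: list[RegionAnnotation], path: str | Path
) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        [
            {
                "patient_id": a.patient_id,
                "region_id": a.region_id,
                "icrs_grade": a.icrs_grade,
                "tissue_class": a.tissue_class,
            }
            for a in annotations
        ]
    )
    df.to_csv(path, index=False)
    return path


def read_annotations_csv(path: str | Path) -> list[RegionAnnotation]:
    """Load annotations; the class column, if present, is re-derived.

    Raises :class:`FormatError` on missing columns, grades outside 0-4
    (grade 2 raises the scope error from annotation construction) or
    duplicate (patient, region) keys.
    """
    df = pd.read_csv(Path(path))
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"annotations CSV missing column(s) {missing}")
    if df.duplicated(["patient_id", "region_id"]).any():
        raise FormatError("duplicate (patient_id, region_id) keys")
    out = []
    for rec in df.itertuples(index=False):
        grade = int(rec.icrs_grade)
        if not 0 <= grade <= 4:
            raise FormatError(f"icrs_grade {grade} outside 0-4")
        out.append(
            RegionAnnotation(
                patient_id=str(rec.patient_id),
                region_id=int(rec.region_id),
                icrs_grade=grade,
            )
        )
    return out


def check_labels_annotations(
    labels: np.ndarray, annotations: list[RegionAnnotation]
) -> None:
    """Raise :class:`ConsistencyError` listing orphan labels/annotations."""
    present = set(int(v) for v in np.unique(labels) if v != 0)
    annotated = {a.region_id for a in annotations}
    orphan_labels = sorted(present - annotated)
    orphan_annotations = sorted(annotated - present)
    if orphan_labels or orphan_annotations:
        raise ConsistencyError(
            f"labels without annotation: {orphan_labels}; "
            f"annotations without label: {orphan_annotations}"
        )


# --------------------------------------------------------------------------
# scenes on disk
# --------------------------------------------------------------------------


def write_scene(scene, directory: str | Path) -> Path:
    """Write one phantom scene: cube + references (ENVI), labels, CSV."""
    from .core import RawCube as _RawCube

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_envi_cube(scene.raw, directory / "cube")
    grid = scene.raw.grid
    write_envi_cube(_RawCube(scene.references.white, grid), directory / "white")
    write_envi_cube(_RawCube(scene.references.dark, grid), directory / "dark")
    write_label_png(scene.labels, directory / "labels.png")
    write_annotations_csv(scene.annotations, directory / "annotations.csv")
    return directory


def read_scene(directory: str | Path):
    """Load a scene directory back into (raw, references, labels, annotations)."""
    from .core import ReferenceSet

    directory = Path(directory)
    raw = read_envi_cube(directory / "cube.hdr")
    white = read_envi_cube(directory / "white.hdr")
    dark = read_envi_cube(directory / "dark.hdr")
    labels = read_label_png(directory / "labels.png")
    annotations = read_annotations_csv(directory / "annotations.csv")
    check_labels_annotations(labels, annotations)
    return raw, ReferenceSet(white.intensities, dark.intensities), labels, annotations


# --------------------------------------------------------------------------
# reports
# --------------------------------------------------------------------------


def _to_jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _to_jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_to_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        if v == np.inf:
            return "inf"
        if v == -np.inf:
            return "-inf"
        return v
    if isinstance(obj, np.integer):
        return int(obj)
    return obj


def report_to_json(report: dict, path: str | Path | None = None) -> str:
    """Serialize an analysis report (dataclasses and arrays included)."""
    text = json.dumps(_to_jsonable(report), indent=2, sort_keys=True)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def config_digest(config) -> str:
    """Stable SHA-256 over a config dataclass, for provenance logging."""
    payload = json.dumps(_to_jsonable(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
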