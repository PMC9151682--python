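"""Spectral dataset containers and I/O.

Two on-disk formats are supported:

* a CSV dialect for per-sample mean reflectance spectra (the universal
  exchange format of this package), and
* a minimal subset of the ENVI image format — band-interleaved-by-line (BIL)
  binary cubes with a plain-text header — the layout field spectrometers
  typically export.

The CSV dialect is: first column ``sample_id``, second column ``label``
(may be empty), remaining columns named by wavelength in nm.  Values are
written at full float precision so that ``read(write(x)) == x``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import (
    CorruptFileError,
    EmptyRegionError,
    FormatError,
    UnsupportedFormatError,
)

__all__ = [
    "SpectraSet",
    "HyperCube",
    "read_spectra_csv",
    "write_spectra_csv",
    "read_envi_bil",
    "write_envi_bil",
    "extract_mean_spectra",
]

# ENVI numeric codes -> dtype; only the subset a reflectance workflow needs.
_ENVI_DTYPES = {4: np.dtype("float32"), 12: np.dtype("uint16")}
_ENVI_CODES = {v: k for k, v in _ENVI_DTYPES.items()}


@dataclass
class SpectraSet:
    """Per-sample mean reflectance spectra with class labels.

    Parameters
    ----------
    wavelengths : (n_bands,) float array, strictly increasing, in nm.
    reflectance : (n_samples, n_bands) float array, unitless.
    labels : (n_samples,) int array or None, class per sample.
    sample_ids : list of str; generated as ``s0000...`` when omitted.
    """

    wavelengths: np.ndarray
    reflectance: np.ndarray
    labels: np.ndarray | None = None
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.atleast_2d(np.asarray(self.reflectance, dtype=float))
        if self.wavelengths.ndim != 1:
            raise FormatError("wavelengths must be a 1-D vector")
        if self.reflectance.shape[1] != self.wavelengths.size:
            raise FormatError(
                f"reflectance has {self.reflectance.shape[1]} bands but "
                f"{self.wavelengths.size} wavelengths given"
            )
        if self.wavelengths.size > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise FormatError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.reflectance)):
            raise FormatError("reflectance contains non-finite values")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (self.reflectance.shape[0],):
                raise FormatError("labels length must equal sample count")
        if not self.sample_ids:
            self.sample_ids = [f"s{i:04d}" for i in range(self.n_samples)]
        elif len(self.sample_ids) != self.n_samples:
            raise FormatError("sample_ids length must equal sample count")

    @property
    def n_samples(self) -> int:
        return self.reflectance.shape[0]

    @property
    def n_bands(self) -> int:
        return self.reflectance.shape[1]

    def subset(self, idx) -> "SpectraSet":
        """Row subset preserving wavelengths and metadata."""
        idx = np.asarray(idx)
        return SpectraSet(
            wavelengths=self.wavelengths.copy(),
            reflectance=self.reflectance[idx].copy(),
            labels=None if self.labels is None else self.labels[idx].copy(),
            sample_ids=[self.sample_ids[i] for i in np.atleast_1d(idx)],
        )

    def with_reflectance(self, reflectance: np.ndarray) -> "SpectraSet":
        """Same samples, new per-band values (e.g. after preprocessing)."""
        return SpectraSet(
            wavelengths=self.wavelengths.copy(),
            reflectance=np.asarray(reflectance, dtype=float),
            labels=None if self.labels is None else self.labels.copy(),
            sample_ids=list(self.sample_ids),
        )


@dataclass
class HyperCube:
    """A raw hyperspectral image cube in (lines, samples, bands) order."""

    data: np.ndarray
    header: dict

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise FormatError("cube data must be 3-D (lines, samples, bands)")
        shape = (
            int(self.header.get("lines", self.data.shape[0])),
            int(self.header.get("samples", self.data.shape[1])),
            int(self.header.get("bands", self.data.shape[2])),
        )
        if self.data.shape != shape:
            raise CorruptFileError(
                f"cube shape {self.data.shape} does not match header {shape}"
            )

    @property
    def wavelengths(self) -> np.ndarray | None:
        wl = self.header.get("wavelength")
        return None if wl is None else np.asarray(wl, dtype=float)


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

def _as_text_handle(stream, mode: str):
    if isinstance(stream, (str, Path)):
        return open(stream, mode, encoding="utf-8"), True
    return stream, False


def write_spectra_csv(spectra: SpectraSet, stream) -> None:
    """Write a SpectraSet in the package CSV dialect (lossless floats)."""
    handle, close = _as_text_handle(stream, "w")
    try:
        cols = {"sample_id": spectra.sample_ids}
        if spectra.labels is None:
            cols["label"] = [""] * spectra.n_samples
        else:
            cols["label"] = [int(v) for v in spectra.labels]
        meta = pd.DataFrame(cols)
        values = pd.DataFrame(
            spectra.reflectance,
            columns=[repr(float(wl)) for wl in spectra.wavelengths])
        # %.17g keeps read(write(x)) == x for doubles
        pd.concat([meta, values], axis=1).to_csv(
            handle, index=False, float_format="%.17g")
    finally:
        if close:
            handle.close()


def read_spectra_csv(stream) -> SpectraSet:
    """Read the CSV dialect written by :func:`write_spectra_csv`."""
    handle, close = _as_text_handle(stream, "r")
    try:
        frame = pd.read_csv(handle, dtype={"sample_id": str},
                            float_precision="round_trip")
    except pd.errors.ParserError as exc:  # ragged rows and friends
        raise FormatError(f"malformed spectra CSV: {exc}") from exc
    finally:
        if close:
            handle.close()
    if list(frame.columns[:2]) != ["sample_id", "label"]:
        raise FormatError("first two columns must be sample_id, label")
    try:
        wavelengths = np.array([float(c) for c in frame.columns[2:]])
    except ValueError as exc:
        raise FormatError(f"non-numeric wavelength column name: {exc}") from exc
    if wavelengths.size == 0:
        raise FormatError("no wavelength columns")
    if wavelengths.size > 1 and not np.all(np.diff(wavelengths) > 0):
        raise FormatError("wavelength columns not strictly increasing")
    refl = frame.iloc[:, 2:].to_numpy()
    if not np.issubdtype(refl.dtype, np.number):
        bad = [c for c in frame.columns[2:]
               if not np.issubdtype(frame[c].dtype, np.number)]
        raise FormatError(f"non-numeric reflectance in column(s) {bad}")
    if not np.all(np.isfinite(refl)):
        rows = np.where(~np.isfinite(refl).all(axis=1))[0]
        raise FormatError(f"non-finite reflectance in row(s) {rows.tolist()}")
    label_col = frame["label"]
    labels = None if label_col.isna().all() else label_col.to_numpy(dtype=float)
    if labels is not None:
        if np.isnan(labels).any():
            raise FormatError("labels must be all present or all empty")
        labels = labels.astype(int)
    return SpectraSet(
        wavelengths=wavelengths,
        reflectance=refl.astype(float),
        labels=labels,
        sample_ids=list(frame["sample_id"].astype(str)),
    )


# ---------------------------------------------------------------------------
# ENVI BIL
# ---------------------------------------------------------------------------

def _parse_envi_header(text: str) -> dict:
    """Parse ENVI ``key = value`` pairs; `{...}` blocks may span lines."""
    if not text.lstrip().upper().startswith("ENVI"):
        raise FormatError("missing ENVI magic line in header")
    body = text.lstrip()[4:]
    header: dict = {}
    # join multi-line {...} blocks
    body = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), body)
    for line in body.splitlines():
        line = line.strip()
        if not line or "=" not in line:
            continue
        key, value = line.split("=", 1)
        key = key.strip().lower()
        value = value.strip()
        if value.startswith("{"):
            items = value.strip("{}").split(",")
            header[key] = [float(v) for v in items if v.strip()]
        else:
            header[key] = value
    return header


def read_envi_bil(header_source, payload) -> HyperCube:
    """Read a BIL cube given its ENVI header text and binary payload.

    ``header_source`` is a path, text stream or header string; ``payload`` a
    path or binary stream.  Only ``interleave = bil`` with data types 4
    (float32) and 12 (uint16) are supported; anything else raises
    :class:`UnsupportedFormatError`.
    """
    if isinstance(header_source, (str, Path)) and Path(header_source).exists():
        text = Path(header_source).read_text(encoding="utf-8")
    elif hasattr(header_source, "read"):
        text = header_source.read()
    else:
        text = str(header_source)
    header = _parse_envi_header(text)

    for key in ("samples", "lines", "bands", "data type", "interleave"):
        if key not in header:
            raise FormatError(f"header missing required field '{key}'")
    interleave = str(header["interleave"]).lower()
    if interleave != "bil":
        raise UnsupportedFormatError(
            f"interleave '{interleave}' not supported (only 'bil')")
    dtype_code = int(header["data type"])
    if dtype_code not in _ENVI_DTYPES:
        raise UnsupportedFormatError(
            f"data type {dtype_code} not supported "
            f"(supported: {sorted(_ENVI_DTYPES)})")
    dtype = _ENVI_DTYPES[dtype_code]
    if int(header.get("byte order", 0)) == 1:
        dtype = dtype.newbyteorder(">")

    lines = int(header["lines"])
    samples = int(header["samples"])
    bands = int(header["bands"])
    offset = int(header.get("header offset", 0))

    if isinstance(payload, (str, Path)):
        raw = Path(payload).read_bytes()
    else:
        raw = payload.read()
    raw = raw[offset:]
    expected = lines * samples * bands * dtype.itemsize
    if len(raw) != expected:
        raise CorruptFileError(
            f"payload has {len(raw)} bytes, header implies {expected}")
    # BIL stores [line][band][sample]; decode to [line][sample][band].
    flat = np.frombuffer(raw, dtype=dtype)
    cube = flat.reshape(lines, bands, samples).transpose(0, 2, 1)
    meta = {
        "samples": samples, "lines": lines, "bands": bands,
        "data type": dtype_code, "interleave": "bil",
        "byte order": int(header.get("byte order", 0)),
        "header offset": offset,
    }
    if "wavelength" in header:
        wl = np.asarray(header["wavelength"], dtype=float)
        if wl.size != bands:
            raise FormatError(
                f"wavelength list has {wl.size} entries for {bands} bands")
        meta["wavelength"] = wl.tolist()
    return HyperCube(data=np.ascontiguousarray(cube.astype(dtype.newbyteorder("="))),
                     header=meta)


def write_envi_bil(cube: HyperCube, header_target, payload_target) -> None:
    """Write a cube as an ENVI header + BIL payload (float32 or uint16)."""
    data = cube.data
    if data.dtype not in _ENVI_CODES:
        data = data.astype(np.float32)
    code = _ENVI_CODES[data.dtype]
    lines, samples, bands = data.shape
    parts = [
        "ENVI",
        f"samples = {samples}",
        f"lines = {lines}",
        f"bands = {bands}",
        "header offset = 0",
        f"data type = {code}",
        "interleave = bil",
        "byte order = 0",
    ]
    wl = cube.header.get("wavelength")
    if wl is not None:
        parts.append("wavelength = {" + ", ".join(repr(float(v)) for v in wl) + "}")
    text = "\n".join(parts) + "\n"
    payload = np.ascontiguousarray(data.transpose(0, 2, 1)).tobytes()

    if isinstance(header_target, (str, Path)):
        Path(header_target).write_text(text, encoding="utf-8")
    else:
        header_target.write(text)
    if isinstance(payload_target, (str, Path)):
        Path(payload_target).write_bytes(payload)
    else:
        payload_target.write(payload)


def extract_mean_spectra(cube: HyperCube, masks, labels=None,
                         sample_ids=None) -> SpectraSet:
    """Per-region mean spectra: one output sample per boolean pixel mask.

    Each mask is a (lines, samples) boolean grid; row ``s`` of the result is
    the arithmetic mean over the masked pixels in every band — the standard
    way a region of grass pixels is collapsed to one reflectance spectrum.
    """
    lines, samples, bands = cube.data.shape
    rows = []
    for s, mask in enumerate(masks):
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (lines, samples):
            raise FormatError(
                f"mask {s} has shape {mask.shape}, expected {(lines, samples)}")
        if not mask.any():
            raise EmptyRegionError(f"mask {s} selects no pixels")
        rows.append(cube.data[mask].mean(axis=0))
    wl = cube.wavelengths
    if wl is None:
        wl = np.arange(bands, dtype=float)
    return SpectraSet(
        wavelengths=wl,
        reflectance=np.asarray(rows, dtype=float),
        labels=None if labels is None else np.asarray(labels, dtype=int),
        sample_ids=list(sample_ids) if sample_ids else [],
    )
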