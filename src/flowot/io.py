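"""Readers and writers: CSV / FCS events, template bundles, label tables.

CSV files carry a header row of marker names with an optional label column.
FCS support is deliberately minimal and read-only: version 3.0/3.1, events
segment only, raw values with no compensation or transformation applied —
preprocessing is an input choice made upstream of this tool.

Template bundles are JSON documents holding a meta-partition and a list of
templates with full-precision component parameters, so a read of a written
bundle reproduces every float bitwise.
"""

from __future__ import annotations

import json
import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    CytometryError,
    EventTable,
    GatedCytometry,
    GaussianComponent,
    MixtureClustering,
    NonFiniteValueError,
)

BUNDLE_VERSION = 1


class UnknownLabelColumnError(CytometryError):
    """The named label column is absent from the file."""


class FCSFormatError(CytometryError):
    """The file is not a readable FCS 3.x dataset."""


class BundleSchemaError(CytometryError):
    """A template bundle fails schema or version validation."""


def read_events(
    path: str | Path,
    format: str | None = None,
    label_column: str | None = None,
    id: str | None = None,
) -> GatedCytometry | EventTable:
    """Read a cytometry from CSV or FCS.

    Returns a :class:`GatedCytometry` when a label column is present (CSV
    column named ``label_column``, default ``"label"`` if such a column
    exists), otherwise an :class:`EventTable`.  Marker order is preserved
    from the file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "fcs" if path.suffix.lower() == ".fcs" else "csv"
    sample_id = id if id is not None else path.stem
    if format == "csv":
        return _read_csv(path, label_column, sample_id)
    if format == "fcs":
        if label_column is not None:
            raise UnknownLabelColumnError("FCS files carry no label column")
        values, markers = _read_fcs(path)
        return EventTable(values=values, markers=markers, id=sample_id)
    raise ValueError(f"unknown format {format!r}")


def _read_csv(
    path: Path, label_column: str | None, sample_id: str
) -> GatedCytometry | EventTable:
    df = pd.read_csv(path)
    if label_column is None and "label" in df.columns:
        label_column = "label"
    if label_column is not None:
        if label_column not in df.columns:
            raise UnknownLabelColumnError(
                f"label column {label_column!r} not in {path.name}"
            )
        labels = df[label_column].astype(str).to_numpy(dtype=object)
        df = df.drop(columns=[label_column])
    else:
        labels = None
    markers = [str(c) for c in df.columns]
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise CytometryError(f"non-numeric marker cell in {path.name}: {exc}") from exc
    if not np.all(np.isfinite(values)):
        raise NonFiniteValueError(f"non-finite value in {path.name}")
    events = EventTable(values=values, markers=markers, id=sample_id)
    if labels is None:
        return events
    return GatedCytometry(events=events, labels=labels)


def write_events_csv(
    path: str | Path, data: GatedCytometry | EventTable, label_column: str = "label"
) -> None:
    """Write events (and labels, when gated) as a header-row CSV."""
    if isinstance(data, GatedCytometry):
        df = pd.DataFrame(data.events.values, columns=data.events.markers)
        df[label_column] = data.labels
    else:
        df = pd.DataFrame(data.values, columns=data.markers)
    df.to_csv(path, index=False)


# --- FCS 3.x -----------------------------------------------------------------

def _read_fcs(path: Path) -> tuple[np.ndarray, list[str]]:
    raw = path.read_bytes()
    if len(raw) < 58:
        raise FCSFormatError("file too short for an FCS header")
    version = raw[:6].decode("ascii", errors="replace")
    if version not in ("FCS3.0", "FCS3.1"):
        raise FCSFormatError(f"unsupported FCS version {version!r}")
    try:
        text_start = int(raw[10:18])
        text_end = int(raw[18:26])
        data_start = int(raw[26:34])
        data_end = int(raw[34:42])
    except ValueError as exc:
        raise FCSFormatError("malformed header offsets") from exc
    text = _parse_text_segment(raw, text_start, text_end)
    if data_start == 0 or data_end == 0:
        try:
            data_start = int(text["$BEGINDATA"])
            data_end = int(text["$ENDDATA"])
        except (KeyError, ValueError) as exc:
            raise FCSFormatError("data segment offsets missing") from exc
    try:
        n_par = int(text["$PAR"])
        n_tot = int(text["$TOT"])
        datatype = text["$DATATYPE"].strip().upper()
        byteord = text["$BYTEORD"].strip()
    except KeyError as exc:
        raise FCSFormatError(f"required keyword missing: {exc}") from exc
    if text.get("$MODE", "L").strip().upper() != "L":
        raise FCSFormatError("only list mode ($MODE L) is supported")
    little = byteord.startswith("1")
    markers = []
    bits = []
    for i in range(1, n_par + 1):
        markers.append(text.get(f"$P{i}N", f"P{i}").strip())
        bits.append(int(text.get(f"$P{i}B", "32")))
    fmt = {"F": "f", "D": "d", "I": None}.get(datatype)
    if fmt is None and datatype == "I":
        if any(b not in (16, 32) for b in bits) or len(set(bits)) != 1:
            raise FCSFormatError("integer data requires uniform 16/32-bit widths")
        fmt = "H" if bits[0] == 16 else "I"
    if fmt is None:
        raise FCSFormatError(f"unsupported $DATATYPE {datatype!r}")
    itemsize = struct.calcsize(fmt)
    need = n_par * n_tot * itemsize
    blob = raw[data_start : data_end + 1]
    if len(blob) < need:
        raise FCSFormatError(
            f"data segment holds {len(blob)} bytes, need {need}"
        )
    dt = np.dtype(("<" if little else ">") + fmt)
    values = (
        np.frombuffer(blob[:need], dtype=dt)
        .astype(float)
        .reshape(n_tot, n_par)
    )
    if not np.all(np.isfinite(values)):
        raise NonFiniteValueError(f"non-finite value in {path.name}")
    return values, markers


def _parse_text_segment(raw: bytes, start: int, end: int) -> dict[str, str]:
    if start <= 0 or end <= start or end >= len(raw):
        raise FCSFormatError("invalid TEXT segment offsets")
    seg = raw[start : end + 1]
    delim = seg[:1].decode("latin-1")
    parts = seg.decode("latin-1").split(delim)[1:]
    if len(parts) < 2:
        raise FCSFormatError("empty TEXT segment")
    pairs = {}
    for key, value in zip(parts[0::2], parts[1::2]):
        if key:
            pairs[key.strip().upper()] = value
    return pairs


# --- template bundles --------------------------------------------------------

def write_template_bundle(
    templates,
    meta_partition,
    path: str | Path,
) -> None:
    """Serialise templates and their meta-partition to a JSON bundle.

    Floats are written with full ``repr`` precision so the round trip is
    bitwise exact.
    """
    doc = {
        "version": BUNDLE_VERSION,
        "meta_partition": [list(group) for group in meta_partition.groups],
        "noise": list(meta_partition.noise),
        "templates": [
            {
                "id": t.mixture.id,
                "members": list(t.members),
                "method": t.method,
                "components": [
                    {
                        "label": c.label,
                        "weight": c.weight,
                        "mean": c.mean.tolist(),
                        "cov": c.cov.tolist(),
                    }
                    for c in t.mixture.components
                ],
            }
            for t in templates
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_template_bundle(path: str | Path):
    """Read a JSON template bundle; returns ``(templates, meta_partition)``."""
    from .templates import MetaPartition, Template  # local import avoids a cycle

    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise BundleSchemaError(f"malformed JSON bundle: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("version") != BUNDLE_VERSION:
        raise BundleSchemaError(
            f"unsupported bundle version {doc.get('version')!r}"
        )
    templates = []
    for entry in doc.get("templates", []):
        comps = []
        for c in entry["components"]:
            cov = np.array(c["cov"], dtype=float)
            w = np.linalg.eigvalsh((cov + cov.T) / 2.0)
            if w[0] <= 0:
                raise BundleSchemaError(
                    f"template {entry.get('id')!r} has a non-PSD covariance"
                )
            comps.append(
                GaussianComponent(
                    mean=np.array(c["mean"], dtype=float),
                    cov=cov,
                    weight=float(c["weight"]),
                    label=c.get("label"),
                )
            )
        templates.append(
            Template(
                mixture=MixtureClustering(components=comps, id=entry.get("id", "")),
                members=list(entry.get("members", [])),
                method=entry.get("method", "unknown"),
            )
        )
    meta = MetaPartition(
        groups=[list(g) for g in doc.get("meta_partition", [])],
        noise=list(doc.get("noise", [])),
        method={},
    )
    return templates, meta
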