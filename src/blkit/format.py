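"""Reader, writer and validator for the time-aligned brain-behavior HDF5 format.

A data file is a flat collection of named *groups* hanging off the HDF5 root.
Each group carries at least one of three datasets on a single common time axis
(seconds, ``float64``, 0 = recording start):

``data``
    a ``samples x channels`` matrix of time-series values (brain activity,
    movement traces, ...),
``timespans``
    an ``N x 2`` array of ``[start, end)`` intervals, optionally labelled via a
    parallel ``labels`` string dataset (condition blocks, stimulus epochs),
``timestamps``
    an ``N`` vector of instantaneous event times (spikes, triggers).

Metadata lives in a ``props`` subgroup with one HDF5 dataset per property.
Only ``title`` and ``type`` are required; ``type`` names the recording
modality (ECoG, fMRI, ...) or the behavior/stimulus kind, drawn from a
controlled vocabulary shipped as ``schema.yaml`` next to this module.
Property names follow camelCase. Optional ``roi`` and ``stats`` subgroups of
``props`` hold arbitrarily named masks/arrays dimension-matched to ``data``,
and a ``preprocessing`` subgroup documents provenance as free text. File-level
metadata (experiment description, subject attributes) sits in a root
``fileHeader`` group.

Timespans are half-open ``[start, end)`` so that adjacent blocks never
double-count a boundary sample.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import h5py
import numpy as np
import yaml

__all__ = [
    "BrainLinerFile",
    "FileHeader",
    "DataGroup",
    "GroupProps",
    "GroupingDescriptor",
    "Violation",
    "FormatError",
    "ValidationError",
    "load_schema",
    "read_file",
    "write_file",
    "validate",
    "suggest_grouping",
    "SAME_GROUP",
    "SEPARATE_GROUPS",
]

_CAMEL_RE = re.compile(r"^[a-z][a-zA-Z0-9]*$")
_STR_DT = h5py.string_dtype(encoding="utf-8")

SAME_GROUP = "same_group"
SEPARATE_GROUPS = "separate_groups"


class FormatError(Exception):
    """The file on disk is not a readable file of this format."""


class ValidationError(Exception):
    """Raised when writing a file whose content violates the format contract."""

    def __init__(self, violations: list["Violation"]):
        self.violations = violations
        lines = "; ".join(str(v) for v in violations)
        super().__init__(f"invalid file: {lines}")


@dataclass(frozen=True)
class Violation:
    """One validator finding. ``severity`` is ``"error"`` or ``"warning"``."""

    severity: str
    group: str | None
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        where = self.group if self.group is not None else "<file>"
        return f"[{self.severity}] {where}: {self.message}"


def load_schema(path: str | Path | None = None) -> dict:
    """Load the property-name schema (the bundled one unless *path* is given)."""
    if path is None:
        text = resources.files("blkit").joinpath("schema.yaml").read_text()
    else:
        text = Path(path).read_text()
    schema = yaml.safe_load(text)
    for key in ("group_properties", "types", "file_header_properties"):
        schema.setdefault(key, [])
    return schema


@dataclass
class FileHeader:
    """Root-level metadata: experiment description plus subject attributes."""

    description: str = ""
    attributes: dict[str, str] = field(default_factory=dict)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FileHeader):
            return NotImplemented
        return self.description == other.description and self.attributes == other.attributes


@dataclass
class GroupProps:
    """Per-group properties; ``title`` and ``type`` are the only required ones.

    Unknown property names encountered on disk are preserved verbatim in
    ``extra`` so that reading and re-writing a file never loses metadata.
    """

    title: str
    type: str
    sampling_rate: float | None = None
    channel_names: list[str] | None = None
    roi: dict[str, np.ndarray] = field(default_factory=dict)
    stats: dict[str, np.ndarray] = field(default_factory=dict)
    preprocessing: str | None = None
    extra: dict[str, object] = field(default_factory=dict)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GroupProps):
            return NotImplemented
        return (
            self.title == other.title
            and self.type == other.type
            and self.sampling_rate == other.sampling_rate
            and self.channel_names == other.channel_names
            and _dict_arrays_equal(self.roi, other.roi)
            and _dict_arrays_equal(self.stats, other.stats)
            and self.preprocessing == other.preprocessing
            and _extra_equal(self.extra, other.extra)
        )


@dataclass
class DataGroup:
    """One named unit of time-aligned data (series, intervals and/or events)."""

    name: str
    props: GroupProps
    data: np.ndarray | None = None
    timespans: np.ndarray | None = None
    labels: list[str] | None = None
    timestamps: np.ndarray | None = None

    @property
    def duration(self) -> float | None:
        """Recording length in seconds implied by ``data`` and samplingRate."""
        if self.data is None or not self.props.sampling_rate:
            return None
        return self.data.shape[0] / self.props.sampling_rate

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DataGroup):
            return NotImplemented
        return (
            self.name == other.name
            and self.props == other.props
            and _opt_array_equal(self.data, other.data)
            and _opt_array_equal(self.timespans, other.timespans)
            and self.labels == other.labels
            and _opt_array_equal(self.timestamps, other.timestamps)
        )


@dataclass
class BrainLinerFile:
    """In-memory model of one data file: a header plus ordered named groups."""

    header: FileHeader = field(default_factory=FileHeader)
    groups: list[DataGroup] = field(default_factory=list)

    def group(self, name: str) -> DataGroup:
        for g in self.groups:
            if g.name == name:
                return g
        raise KeyError(f"no group named {name!r}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BrainLinerFile):
            return NotImplemented
        return self.header == other.header and self.groups == other.groups


@dataclass(frozen=True)
class GroupingDescriptor:
    """What the grouping heuristic compares: span, rate and data kind."""

    start: float
    end: float
    kind: str
    sampling_rate: float | None = None


def _opt_array_equal(a: np.ndarray | None, b: np.ndarray | None) -> bool:
    if a is None or b is None:
        return a is None and b is None
    return a.shape == b.shape and np.array_equal(a, b)


def _dict_arrays_equal(a: Mapping[str, np.ndarray], b: Mapping[str, np.ndarray]) -> bool:
    return a.keys() == b.keys() and all(np.array_equal(a[k], b[k]) for k in a)


def _extra_equal(a: Mapping[str, object], b: Mapping[str, object]) -> bool:
    if a.keys() != b.keys():
        return False
    for k in a:
        x, y = a[k], b[k]
        if isinstance(x, np.ndarray) or isinstance(y, np.ndarray):
            if not (isinstance(x, np.ndarray) and isinstance(y, np.ndarray)):
                return False
            if not np.array_equal(x, y):
                return False
        elif x != y:
            return False
    return True


# ---------------------------------------------------------------------------
# validation


def validate(file: BrainLinerFile, schema: dict | None = None) -> list[Violation]:
    """Check *file* against the format contract.

    Returns an empty list iff every invariant holds. Content problems are
    reported, never raised: hard contract breaks (missing title/type,
    dimension mismatches, inverted timespans, a group with no datasets at
    all) come back as ``error``; advisory findings (unknown property or type
    names, a data group without samplingRate, an empty file) as ``warning``.
    """
    if schema is None:
        schema = load_schema()
    out: list[Violation] = []
    err = lambda g, m: out.append(Violation("error", g, m))
    warn = lambda g, m: out.append(Violation("warning", g, m))

    for key in file.header.attributes:
        _check_prop_name(key, schema["file_header_properties"], None, out, where="fileHeader")

    if not file.groups:
        warn(None, "file contains no data groups")

    seen: set[str] = set()
    for g in file.groups:
        if not g.name:
            err(g.name, "group name is empty")
        if g.name in seen:
            err(g.name, "duplicate group name")
        seen.add(g.name)

        if g.data is None and g.timespans is None and g.timestamps is None:
            err(g.name, "group has none of data/timespans/timestamps")

        if not g.props.title:
            err(g.name, "required property 'title' is missing or empty")
        if not g.props.type:
            err(g.name, "required property 'type' is missing or empty")
        elif g.props.type not in schema["types"]:
            warn(g.name, f"type {g.props.type!r} is not in the schema vocabulary")

        for key in g.props.extra:
            _check_prop_name(key, schema["group_properties"], g.name, out, where="props")

        if g.data is not None:
            if g.data.ndim != 2:
                err(g.name, f"data must be a samples x channels matrix, got ndim={g.data.ndim}")
            elif g.data.shape[0] < g.data.shape[1]:
                warn(
                    g.name,
                    f"data has more channels ({g.data.shape[1]}) than samples "
                    f"({g.data.shape[0]}); expected samples x channels orientation",
                )
            if g.props.sampling_rate is None:
                warn(g.name, "data group without samplingRate")
            elif g.props.sampling_rate <= 0:
                err(g.name, f"samplingRate must be positive, got {g.props.sampling_rate}")
            if g.props.channel_names is not None and g.data.ndim == 2 and len(
                g.props.channel_names
            ) != g.data.shape[1]:
                err(
                    g.name,
                    f"{len(g.props.channel_names)} channelNames for "
                    f"{g.data.shape[1]} data channels",
                )
        for kind in ("roi", "stats"):
            for dname, arr in getattr(g.props, kind).items():
                if g.data is None:
                    err(g.name, f"{kind}/{dname} present but group has no data")
                elif arr.shape != g.data.shape:
                    err(
                        g.name,
                        f"{kind}/{dname} shape {arr.shape} does not match data "
                        f"shape {g.data.shape}",
                    )

        if g.timespans is not None:
            ts = np.asarray(g.timespans)
            if ts.ndim != 2 or ts.shape[1] != 2:
                err(g.name, f"timespans must be N x 2, got shape {ts.shape}")
            else:
                if not np.all(np.isfinite(ts)):
                    err(g.name, "timespans contain non-finite values")
                bad = np.nonzero(ts[:, 0] >= ts[:, 1])[0]
                for i in bad:
                    err(g.name, f"timespan {i} has start >= end ({ts[i, 0]} >= {ts[i, 1]})")
                if g.labels is not None and len(g.labels) != ts.shape[0]:
                    err(g.name, f"{len(g.labels)} labels for {ts.shape[0]} timespans")
        elif g.labels is not None:
            err(g.name, "labels present without timespans")

        if g.timestamps is not None and not np.all(np.isfinite(g.timestamps)):
            err(g.name, "timestamps contain non-finite values")

    return out


def _check_prop_name(
    key: str, known: Iterable[str], group: str | None, out: list[Violation], where: str
) -> None:
    known = list(known)
    if key in known:
        return
    msg = f"unknown {where} property {key!r}"
    lowered = {k.lower(): k for k in known}
    if key.lower() in lowered:
        msg += f"; did you mean {lowered[key.lower()]!r}?"
    elif not _CAMEL_RE.match(key):
        msg += " (property names should be camelCase)"
    out.append(Violation("warning", group, msg))


# ---------------------------------------------------------------------------
# writing


def write_file(file: BrainLinerFile, path: str | Path) -> None:
    """Write *file* to *path* as an HDF5 file in the standard layout.

    Refuses (raising :class:`ValidationError`) if :func:`validate` reports any
    errors; warnings do not block writing. The layout written here is exactly
    what :func:`read_file` parses, and a write/read round trip reproduces the
    model field for field, floats bit-equal.
    """
    violations = [v for v in validate(file) if v.severity == "error"]
    if violations:
        raise ValidationError(violations)

    with h5py.File(path, "w", track_order=True) as h5:
        hdr = h5.create_group("fileHeader", track_order=True)
        if file.header.description:
            hdr.create_dataset("experimentDescription", data=file.header.description, dtype=_STR_DT)
        for key, value in file.header.attributes.items():
            hdr.create_dataset(key, data=value, dtype=_STR_DT)

        for g in file.groups:
            gh = h5.create_group(g.name, track_order=True)
            if g.data is not None:
                gh.create_dataset("data", data=np.asarray(g.data, dtype=np.float64))
            if g.timespans is not None:
                gh.create_dataset("timespans", data=np.asarray(g.timespans, dtype=np.float64))
                if g.labels is not None:
                    gh.create_dataset("labels", data=g.labels, dtype=_STR_DT)
            if g.timestamps is not None:
                gh.create_dataset("timestamps", data=np.asarray(g.timestamps, dtype=np.float64))

            props = gh.create_group("props", track_order=True)
            props.create_dataset("title", data=g.props.title, dtype=_STR_DT)
            props.create_dataset("type", data=g.props.type, dtype=_STR_DT)
            if g.props.sampling_rate is not None:
                props.create_dataset("samplingRate", data=float(g.props.sampling_rate))
            if g.props.channel_names is not None:
                props.create_dataset("channelNames", data=g.props.channel_names, dtype=_STR_DT)
            for key, value in g.props.extra.items():
                _write_value(props, key, value)
            for kind in ("roi", "stats"):
                entries = getattr(g.props, kind)
                if entries:
                    sub = props.create_group(kind, track_order=True)
                    for dname, arr in entries.items():
                        sub.create_dataset(dname, data=np.asarray(arr, dtype=np.float64))
            if g.props.preprocessing is not None:
                pre = props.create_group("preprocessing")
                pre.create_dataset("text", data=g.props.preprocessing, dtype=_STR_DT)


def _write_value(parent: h5py.Group, key: str, value: object) -> None:
    if isinstance(value, str):
        parent.create_dataset(key, data=value, dtype=_STR_DT)
    elif isinstance(value, (bool, int, float, np.floating, np.integer)):
        parent.create_dataset(key, data=float(value))
    elif isinstance(value, np.ndarray):
        parent.create_dataset(key, data=value)
    elif isinstance(value, (list, tuple)) and all(isinstance(v, str) for v in value):
        parent.create_dataset(key, data=list(value), dtype=_STR_DT)
    else:
        raise TypeError(f"cannot store property {key!r} of type {type(value).__name__}")


# ---------------------------------------------------------------------------
# reading


def read_file(
    path: str | Path, strict: bool = True
) -> BrainLinerFile | tuple[BrainLinerFile, list[Violation]]:
    """Read the HDF5 file at *path* into the in-memory model.

    With ``strict=True`` (default) a structurally broken file — a group
    missing its required ``title`` or ``type`` — raises
    :class:`ValidationError` naming the group and the missing field. With
    ``strict=False`` the best-effort model is returned together with the
    violation list, so downstream tools can still operate on imperfect files.

    Properties with names outside the schema are preserved verbatim
    (forward compatibility).
    """
    path = Path(path)
    if not h5py.is_hdf5(path):
        raise FormatError(f"{path} is not an HDF5 file")

    violations: list[Violation] = []
    with h5py.File(path, "r") as h5:
        header = _read_header(h5)
        groups = []
        for name, node in h5.items():
            if name == "fileHeader" or not isinstance(node, h5py.Group):
                continue
            groups.append(_read_group(name, node, violations))
    model = BrainLinerFile(header=header, groups=groups)
    if strict:
        if violations:
            raise ValidationError(violations)
        return model
    return model, violations + validate(model)


def _read_header(h5: h5py.File) -> FileHeader:
    header = FileHeader()
    if "fileHeader" not in h5:
        return header
    for key, ds in h5["fileHeader"].items():
        value = _read_scalar(ds)
        if key == "experimentDescription":
            header.description = value
        else:
            header.attributes[key] = value
    return header


def _read_group(name: str, node: h5py.Group, violations: list[Violation]) -> DataGroup:
    data = node["data"][()].astype(np.float64, copy=False) if "data" in node else None
    timespans = node["timespans"][()] if "timespans" in node else None
    labels = list(node["labels"].asstr()[()]) if "labels" in node else None
    timestamps = node["timestamps"][()] if "timestamps" in node else None

    title = type_ = ""
    sampling_rate = None
    channel_names = None
    preprocessing = None
    roi: dict[str, np.ndarray] = {}
    stats: dict[str, np.ndarray] = {}
    extra: dict[str, object] = {}
    if "props" in node:
        for key, child in node["props"].items():
            if key in ("roi", "stats") and isinstance(child, h5py.Group):
                target = roi if key == "roi" else stats
                for dname, ds in child.items():
                    target[dname] = ds[()]
            elif key == "preprocessing" and isinstance(child, h5py.Group):
                if "text" in child:
                    preprocessing = _read_scalar(child["text"])
            elif key == "title":
                title = _read_scalar(child)
            elif key == "type":
                type_ = _read_scalar(child)
            elif key == "samplingRate":
                sampling_rate = float(child[()])
            elif key == "channelNames":
                channel_names = list(child.asstr()[()])
            else:
                extra[key] = _read_scalar(child)
    for field_name, value in (("title", title), ("type", type_)):
        if not value:
            violations.append(
                Violation("error", name, f"required property {field_name!r} is missing or empty")
            )

    props = GroupProps(
        title=title,
        type=type_,
        sampling_rate=sampling_rate,
        channel_names=channel_names,
        roi=roi,
        stats=stats,
        preprocessing=preprocessing,
        extra=extra,
    )
    return DataGroup(
        name=name,
        props=props,
        data=data,
        timespans=timespans,
        labels=labels,
        timestamps=timestamps,
    )


def _read_scalar(ds: h5py.Dataset) -> object:
    if ds.shape == ():
        value = ds[()]
        if isinstance(value, bytes):
            return value.decode("utf-8")
        if isinstance(value, np.floating):
            return float(value)
        return value
    if h5py.check_string_dtype(ds.dtype):
        return list(ds.asstr()[()])
    return ds[()]


# ---------------------------------------------------------------------------
# grouping heuristic


def suggest_grouping(a: GroupingDescriptor, b: GroupingDescriptor) -> str:
    """Advise whether two datasets belong in the same group.

    Data sharing the same time span, the same sampling rate and the same kind
    (same recording modality, or same behavior/stimulus type) should live in
    one group; anything else gets its own group. Symmetric and reflexive.
    """
    same = (
        a.start == b.start
        and a.end == b.end
        and a.sampling_rate == b.sampling_rate
        and a.kind == b.kind
    )
    return SAME_GROUP if same else SEPARATE_GROUPS
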