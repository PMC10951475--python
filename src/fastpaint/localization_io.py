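"""Picasso-compatible localization table I/O.

Single-molecule localization pipelines built on Picasso produce a
``locs.hdf5`` file (a structured record array named ``locs`` with at least
``frame``, ``x``, ``y`` and ``photons`` per detected binding event) and a
YAML sidecar carrying the movie geometry (``Width``, ``Height`` in camera
pixels) and length (``Frames``).  This module reads and writes that dialect
so real Picasso outputs load unchanged, validates the tables, and implements
the frame-budget subsetting used by the fast acquisition protocol (keep the
first ``n`` frames of an ``N``-frame movie, with ``n << N``).

Coordinates are 0-based camera-pixel floats with pixel centres at
half-integer positions (``x = 0.5`` is the centre of the first pixel); a
valid position lies in ``[0, fov_width) x [0, fov_height)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import yaml

from fastpaint.errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

MANDATORY_FIELDS = ("frame", "x", "y", "photons")
OPTIONAL_FIELDS = ("lpx", "lpy")

#: dtype of one localization record, Picasso field order
_BASE_DTYPE = [("frame", "u4"), ("x", "f4"), ("y", "f4"), ("photons", "f4")]


def _locs_dtype(with_precision: bool) -> np.dtype:
    fields = list(_BASE_DTYPE)
    if with_precision:
        fields += [("lpx", "f4"), ("lpy", "f4")]
    return np.dtype(fields)


@dataclass
class LocalizationTable:
    """A validated set of localizations plus its acquisition geometry.

    Attributes
    ----------
    locs : numpy structured array
        One record per localization with fields ``frame``, ``x``, ``y``,
        ``photons`` and optionally ``lpx``/``lpy`` (localization precision,
        camera pixels).
    fov_width, fov_height : int
        Field of view in camera pixels.
    n_frames_total : int
        Movie length ``N``; every ``frame`` index lies in ``[0, N)``.
    """

    locs: np.ndarray
    fov_width: int
    fov_height: int
    n_frames_total: int

    def __post_init__(self) -> None:
        self.validate()

    def __len__(self) -> int:
        return len(self.locs)

    @property
    def has_precision(self) -> bool:
        return "lpx" in (self.locs.dtype.names or ())

    def validate(self) -> None:
        """Check field presence, frame range and FOV containment."""
        names = self.locs.dtype.names or ()
        for name in MANDATORY_FIELDS:
            if name not in names:
                raise FormatError(f"localization table is missing mandatory field {name!r}")
        if self.fov_width <= 0 or self.fov_height <= 0 or self.n_frames_total < 0:
            raise ValidationError(
                "fov dimensions must be positive and n_frames_total non-negative "
                f"(got {self.fov_width}, {self.fov_height}, {self.n_frames_total})"
            )
        if len(self.locs) == 0:
            return
        frames = self.locs["frame"]
        bad = np.nonzero(frames >= self.n_frames_total)[0]
        if bad.size:
            raise ValidationError(
                f"frame index out of range [0, {self.n_frames_total}) "
                f"at record indices {bad[:10].tolist()}"
            )
        x, y = self.locs["x"], self.locs["y"]
        bad = np.nonzero((x < 0) | (x >= self.fov_width) | (y < 0) | (y >= self.fov_height))[0]
        if bad.size:
            raise ValidationError(
                f"coordinates outside FOV {self.fov_width}x{self.fov_height} "
                f"at record indices {bad[:10].tolist()}"
            )


def make_table(
    frame,
    x,
    y,
    photons,
    fov_width: int,
    fov_height: int,
    n_frames_total: int,
    lpx=None,
    lpy=None,
) -> LocalizationTable:
    """Assemble a :class:`LocalizationTable` from per-field arrays."""
    frame = np.asarray(frame)
    n = len(frame)
    with_precision = lpx is not None and lpy is not None
    locs = np.empty(n, dtype=_locs_dtype(with_precision))
    locs["frame"] = frame
    locs["x"] = np.asarray(x)
    locs["y"] = np.asarray(y)
    locs["photons"] = np.asarray(photons)
    if with_precision:
        locs["lpx"] = np.asarray(lpx)
        locs["lpy"] = np.asarray(lpy)
    return LocalizationTable(locs, int(fov_width), int(fov_height), int(n_frames_total))


def read_localizations(hdf5_path, yaml_path=None) -> LocalizationTable:
    """Read a Picasso ``locs.hdf5`` file and its YAML metadata sidecar.

    Parameters
    ----------
    hdf5_path : path-like
        HDF5 file holding the ``locs`` record array.
    yaml_path : path-like, optional
        Metadata sidecar with ``Width``, ``Height`` and ``Frames``.  If
        omitted or missing, the FOV is inferred from the coordinate extent
        (``ceil(max + eps)``) and the frame count from the maximum frame
        index, with a logged warning.

    Raises
    ------
    FormatError
        If a mandatory record field is absent.
    ValidationError
        If any record lies outside the FOV or frame range.
    """
    hdf5_path = Path(hdf5_path)
    with h5py.File(hdf5_path, "r") as f:
        if "locs" not in f:
            raise FormatError(f"{hdf5_path}: no 'locs' dataset (not a Picasso localization file)")
        raw = f["locs"][()]
    names = raw.dtype.names or ()
    for name in MANDATORY_FIELDS:
        if name not in names:
            raise FormatError(f"{hdf5_path}: 'locs' is missing mandatory field {name!r}")

    meta = None
    if yaml_path is not None and Path(yaml_path).exists():
        with open(yaml_path) as f:
            # Picasso appends documents to the sidecar; geometry is in the first.
            docs = [d for d in yaml.safe_load_all(f) if d]
        merged: dict = {}
        for d in docs:
            merged.update(d)
        meta = merged
    if meta is None:
        logger.warning(
            "%s: no YAML sidecar; inferring FOV and frame count from the records", hdf5_path
        )
        if len(raw) == 0:
            raise FormatError(f"{hdf5_path}: empty table and no sidecar; geometry unknown")
        fov_w = math.ceil(float(raw["x"].max()) + 1e-6)
        fov_h = math.ceil(float(raw["y"].max()) + 1e-6)
        n_frames = int(raw["frame"].max()) + 1
    else:
        try:
            fov_w = int(meta["Width"])
            fov_h = int(meta["Height"])
            n_frames = int(meta["Frames"])
        except KeyError as e:
            raise FormatError(f"{yaml_path}: sidecar is missing key {e.args[0]!r}") from e

    keep = [n for n in MANDATORY_FIELDS] + [n for n in OPTIONAL_FIELDS if n in names]
    with_precision = "lpx" in keep and "lpy" in keep
    locs = np.empty(len(raw), dtype=_locs_dtype(with_precision))
    for name in keep:
        locs[name] = raw[name]
    return LocalizationTable(locs, fov_w, fov_h, n_frames)


def write_localizations(table: LocalizationTable, hdf5_path, yaml_path) -> None:
    """Write ``table`` as a Picasso-dialect ``locs.hdf5`` + YAML sidecar."""
    table.validate()
    with h5py.File(hdf5_path, "w") as f:
        f.create_dataset("locs", data=table.locs)
    meta = {
        "Width": int(table.fov_width),
        "Height": int(table.fov_height),
        "Frames": int(table.n_frames_total),
        "Generated by": "fastpaint",
    }
    with open(yaml_path, "w") as f:
        yaml.safe_dump(meta, f, default_flow_style=False)


def subset_frames(table: LocalizationTable, n_keep: int) -> LocalizationTable:
    """Restrict a table to its first ``n_keep`` frames (temporal prefix).

    The fast protocol acquires a short prefix of the conventional movie
    (e.g. 3,000 of 30,000 frames), so subsetting keeps records with
    ``frame < n_keep`` in their original order and sets ``n_frames_total``
    to ``n_keep``.

    Raises
    ------
    ValueError
        If ``n_keep`` is negative or exceeds the movie length.
    """
    n_keep = int(n_keep)
    if n_keep < 0 or n_keep > table.n_frames_total:
        raise ValueError(
            f"n_keep must be in [0, {table.n_frames_total}], got {n_keep}"
        )
    mask = table.locs["frame"] < n_keep
    return LocalizationTable(table.locs[mask], table.fov_width, table.fov_height, n_keep)
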