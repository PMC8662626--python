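"""Label-volume I/O, session-id parsing, and the region label map.

Segmentation output is a 3D integer *label volume*: voxel values are region
identifiers in 0–40 (0 = background). Volumes arrive either as NIfTI files
with a spatial header or as bare ``.npz`` array dumps (the intermediate the
segmentation stage produces), which carry no header and are assumed 1 mm
isotropic. Session identifiers follow the OASIS convention
``<SUBJECT>_MR_d<DAYS>`` where the digit suffix is days since study entry.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("brainfd")

#: Highest region label a conformant segmentation may carry.
MAX_LABEL = 40

#: Region labels anchored by the segmentation's label scheme.
DEFAULT_LABEL_MAP: dict[str, int] = {
    "right_thalamus_proper": 23,
    "left_ventral_dc": 24,
    "third_ventricle": 26,
    "right_putamen": 27,
}

_SESSION_RE = re.compile(r"^(?P<subject>[A-Za-z0-9]+)_MR_d(?P<day>\d+)$")


class DimensionalityError(ValueError):
    """Array is not a 3D volume."""


class LabelFormatError(ValueError):
    """Voxel values are not valid integer region labels."""


@dataclass(frozen=True)
class LabelVolume:
    """A segmented 3D volume of integer region labels with voxel spacing.

    Parameters
    ----------
    data:
        3D integer array; 0 is background, positive values are region labels.
    spacing:
        Per-axis voxel edge length in mm, strictly positive.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise DimensionalityError(
                f"label volume must be 3D, got {data.ndim}D shape {data.shape}"
            )
        if not np.issubdtype(data.dtype, np.integer):
            data = _coerce_integer(data)
        if data.size and data.min() < 0:
            raise LabelFormatError("negative region labels are not allowed")
        object.__setattr__(self, "data", data)
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be three positive values, got {spacing}")
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def labels_present(self) -> np.ndarray:
        """Sorted array of nonzero labels present in the volume."""
        u = np.unique(self.data)
        return u[u > 0]

    def check_conformance(self, max_label: int = MAX_LABEL) -> None:
        """Raise if any label exceeds the conformant range (default 0–40)."""
        if self.data.size and self.data.max() > max_label:
            raise LabelFormatError(
                f"labels exceed {max_label}: max present is {int(self.data.max())}"
            )


def _coerce_integer(data: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    rounded = np.rint(data)
    if np.abs(data - rounded).max(initial=0.0) > tol:
        raise LabelFormatError(
            "voxel values have fractional parts above tolerance; not a label volume"
        )
    return rounded.astype(np.int32)


# ---------------------------------------------------------------------------
# volume I/O
# ---------------------------------------------------------------------------

def _infer_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith(".npz"):
        return "npz"
    raise ValueError(f"cannot infer volume format from {path.name!r}")


def load_label_volume(path: str | Path, format: str | None = None) -> LabelVolume:
    """Read a label volume from NIfTI (``.nii``/``.nii.gz``) or ``.npz``.

    NIfTI spacing is taken from the header zooms. ``.npz`` archives carry no
    header, so spacing defaults to 1 mm isotropic; the array is looked up
    under the key ``vol`` and falls back to the first array in the archive.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "nifti":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        if data.ndim != 3:
            raise DimensionalityError(f"expected 3D NIfTI, got {data.ndim}D")
        return LabelVolume(data=data, spacing=spacing)  # type: ignore[arg-type]
    if fmt == "npz":
        with np.load(path) as archive:
            if "vol" in archive.files:
                data = archive["vol"]
            elif archive.files:
                data = archive[archive.files[0]]
            else:
                raise LabelFormatError(f"{path} contains no arrays")
        return LabelVolume(data=data, spacing=(1.0, 1.0, 1.0))
    raise ValueError(f"unknown format {fmt!r}")


def save_label_volume(volume: LabelVolume, path: str | Path) -> None:
    """Write a label volume as NIfTI or ``.npz``, chosen by file suffix.

    NIfTI output uses a diagonal affine built from the voxel spacing, so a
    save→load round trip preserves both data and spacing.
    """
    path = Path(path)
    fmt = _infer_format(path)
    if fmt == "nifti":
        affine = np.diag([*volume.spacing, 1.0])
        img = nib.Nifti1Image(volume.data.astype(np.int16), affine)
        img.header.set_zooms(volume.spacing)
        nib.save(img, str(path))
    else:
        np.savez_compressed(path, vol=volume.data)


def crop_center(volume: LabelVolume, target_shape: tuple[int, int, int]) -> LabelVolume:
    """Return the centered sub-block of exactly ``target_shape``.

    When the margin on an axis is odd, the extra voxel is dropped from the
    high-index side (offset = margin // 2). Typical use is trimming a
    conformed (256, 256, 256) volume to the (160, 192, 224) grid the
    segmentation network expects.
    """
    target = tuple(int(t) for t in target_shape)
    if any(t > s for t, s in zip(target, volume.shape)):
        raise ValueError(f"target shape {target} exceeds volume shape {volume.shape}")
    if any(t <= 0 for t in target):
        raise ValueError(f"target shape must be positive, got {target}")
    offsets = [(s - t) // 2 for s, t in zip(volume.shape, target)]
    sl = tuple(slice(o, o + t) for o, t in zip(offsets, target))
    return LabelVolume(data=volume.data[sl].copy(), spacing=volume.spacing)


# ---------------------------------------------------------------------------
# session identifiers
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class SessionRecord:
    """One MRI session: subject, session id, and days since study entry."""

    subject_id: str
    day: int
    session_id: str = field(compare=False)

    def __post_init__(self) -> None:
        if self.day < 0:
            raise ValueError(f"day must be non-negative, got {self.day}")


class SessionIdError(ValueError):
    """Session id does not match the ``<SUBJECT>_MR_d<DAYS>`` convention."""


def format_session_id(subject_id: str, day: int) -> str:
    """Build a session id; the day suffix is zero-padded to four digits."""
    return f"{subject_id}_MR_d{day:04d}"


def parse_session_id(session_id: str) -> SessionRecord:
    """Parse ``OAS30001_MR_d0129`` into subject ``OAS30001``, day 129."""
    m = _SESSION_RE.match(session_id)
    if m is None:
        raise SessionIdError(f"malformed session id: {session_id!r}")
    return SessionRecord(
        subject_id=m.group("subject"),
        day=int(m.group("day")),
        session_id=session_id,
    )


def make_session(subject_id: str, day: int) -> SessionRecord:
    return parse_session_id(format_session_id(subject_id, day))


# ---------------------------------------------------------------------------
# label map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LabelMap:
    """Mapping of region names to integer labels; names and labels unique."""

    entries: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_LABEL_MAP))

    def __post_init__(self) -> None:
        entries = {str(k): int(v) for k, v in self.entries.items()}
        labels = list(entries.values())
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate labels in label map")
        if any(not (0 < v <= MAX_LABEL) for v in labels):
            raise ValueError(f"labels must lie in 1..{MAX_LABEL}")
        object.__setattr__(self, "entries", entries)

    def label_of(self, name: str) -> int:
        return self.entries[name]

    def name_of(self, label: int) -> str | None:
        for name, lab in self.entries.items():
            if lab == label:
                return name
        return None

    @classmethod
    def from_file(cls, path: str | Path) -> "LabelMap":
        """Load a YAML or JSON file mapping region names to labels."""
        path = Path(path)
        text = path.read_text()
        entries = (
            json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
        )
        if not isinstance(entries, dict):
            raise ValueError(f"{path} does not contain a name→label mapping")
        return cls(entries=entries)


# ---------------------------------------------------------------------------
# tabular inputs
# ---------------------------------------------------------------------------

def load_sessions_csv(path: str | Path) -> list[SessionRecord]:
    """Read a session table (columns ``subject_id``, ``session_id``)."""
    df = pd.read_csv(path)
    return [parse_session_id(s) for s in df["session_id"]]


def load_cdr_csv(path: str | Path) -> pd.DataFrame:
    """Read a CDR score table (columns ``subject_id``, ``day``, ``cdr``)."""
    df = pd.read_csv(path)
    missing = {"subject_id", "day", "cdr"} - set(df.columns)
    if missing:
        raise ValueError(f"CDR table missing columns: {sorted(missing)}")
    return df
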