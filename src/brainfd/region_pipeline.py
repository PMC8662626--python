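"""Per-region masks, volume + FD measurement, multi-session comparison.

A segmented volume is split into binary region masks by label; each region
(and the whole segmented brain, the union of all nonzero labels) gets a
voxel count, a physical volume, and a box-counting FD. Measures from
repeated sessions of the same subject assemble into a wide comparison
table, with a per-region relative-variation statistic quantifying
scan-to-scan stability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .fractal_core import (
    FDResult,
    ScaleSchedule,
    estimate_fd,
    generate_scale_schedule,
)
from .io_sessions import MAX_LABEL, LabelMap, LabelVolume, SessionRecord

logger = logging.getLogger("brainfd")

#: Row name used for the union-of-all-labels measure.
WHOLE_VOLUME = "whole_volume"


@dataclass(frozen=True)
class RegionMeasure:
    """Volume and FD of one region in one session.

    ``fd`` is None exactly when the region is absent from the volume
    (voxel_count == 0). ``volume_mm3`` is voxel_count times the voxel
    volume from the spacing.
    """

    session: SessionRecord
    region_label: int | None
    region_name: str
    voxel_count: int
    volume_mm3: float
    fd: FDResult | None


def extract_region(volume: LabelVolume, label: int) -> np.ndarray:
    """Binary mask of one region: true exactly where ``data == label``.

    An absent label yields an empty mask with a logged warning; the FD
    stage then reports the region as missing rather than failing the run.
    """
    if not (0 < label <= MAX_LABEL):
        raise ValueError(f"region label must be in 1..{MAX_LABEL}, got {label}")
    mask = volume.data == label
    if not mask.any():
        logger.warning("label %d absent from volume", label)
    return mask


def whole_brain_mask(volume: LabelVolume) -> np.ndarray:
    """Union of all segmented structures: true where ``data > 0``."""
    return volume.data > 0


def measure_session(
    volume: LabelVolume,
    session: SessionRecord,
    labels: list[int],
    schedule: ScaleSchedule | None = None,
    label_map: LabelMap | None = None,
) -> list[RegionMeasure]:
    """Measure the whole segmented volume plus each requested region.

    Returns one RegionMeasure for the whole volume followed by one per
    requested label, in the order given. FD is in voxel units and is
    dimensionless; anisotropic spacing only affects ``volume_mm3`` and is
    flagged because the box grid is cubic in voxel space.
    """
    if not labels:
        raise ValueError("labels must be nonempty")
    if schedule is None:
        schedule = generate_scale_schedule()
    if label_map is None:
        label_map = LabelMap()
    if len(set(volume.spacing)) > 1:
        logger.warning(
            "anisotropic spacing %s: FD is computed on the voxel grid", volume.spacing
        )

    def _measure(mask: np.ndarray, label: int | None, name: str) -> RegionMeasure:
        count = int(mask.sum())
        return RegionMeasure(
            session=session,
            region_label=label,
            region_name=name,
            voxel_count=count,
            volume_mm3=count * volume.voxel_volume_mm3,
            fd=estimate_fd(mask, schedule) if count else None,
        )

    measures = [_measure(whole_brain_mask(volume), None, WHOLE_VOLUME)]
    for label in labels:
        name = label_map.name_of(label) or f"label_{label}"
        measures.append(_measure(extract_region(volume, label), label, name))
    return measures


def measures_to_frame(measures: list[RegionMeasure]) -> pd.DataFrame:
    """Long-form table, one row per (session, region) measure."""
    rows = []
    for m in measures:
        rows.append(
            {
                "session_id": m.session.session_id,
                "subject_id": m.session.subject_id,
                "day": m.session.day,
                "region": m.region_name,
                "region_label": m.region_label,
                "voxel_count": m.voxel_count,
                "volume_mm3": m.volume_mm3,
                "fd": m.fd.fd if m.fd else None,
                "rmse": m.fd.rmse if m.fd else None,
                "r2": m.fd.r2 if m.fd else None,
                "n_points": m.fd.n_points if m.fd else None,
            }
        )
    return pd.DataFrame(rows)


def relative_variation(values: pd.Series) -> float:
    """Scan-to-scan spread as a percentage: (max − min) / mean · 100."""
    values = values.dropna()
    if len(values) < 2 or values.mean() == 0:
        return float("nan")
    return float((values.max() - values.min()) / values.mean() * 100.0)


def compare_sessions(measures: list[RegionMeasure]) -> pd.DataFrame:
    """Wide FD table: session rows (sorted by day), region columns.

    All sessions must carry the same region set. A final ``variation_%``
    row holds the per-region relative variation; it is NaN for a single
    session.
    """
    df = measures_to_frame(measures)
    region_sets = df.groupby("session_id")["region"].apply(frozenset)
    if region_sets.nunique() != 1:
        raise ValueError("sessions carry inconsistent region sets")
    order = (
        df[["session_id", "day"]]
        .drop_duplicates()
        .sort_values(["day", "session_id"])["session_id"]
        .tolist()
    )
    regions = df["region"].drop_duplicates().tolist()
    wide = df.pivot(index="session_id", columns="region", values="fd")
    wide = wide.loc[order, regions]
    wide.loc["variation_%"] = pd.Series({r: relative_variation(wide[r]) for r in regions})
    wide.columns.name = None
    wide.index.name = "session_id"
    return wide


def save_comparison(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path)
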