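"""File I/O: multi-page TIFF stacks, 16-bit projections, CSV/JSON/YAML sidecars.

Stacks are written as single-channel multi-page TIFFs with the physical
metadata (voxel size, frame origin, channel, aspect, view azimuth) embedded
as JSON in the ImageDescription tag, so a stack round-trips losslessly.
Multi-channel OME-TIFFs written elsewhere can be read page-wise with
:func:`tifffile.imread` and wrapped manually.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd
import tifffile
import yaml

from .detect import NucleusRecord, records_from_dataframe, records_to_dataframe
from .errors import MetadataError, ParameterError
from .register import ConstellationMatch
from .stack_ops import Projection, VoxelStack
from .synthetic import GroundTruth, LensSimParams

_PARAM_ANGLE_FIELDS = {
    "margin_colatitude": "margin_colatitude_deg",
    "density_ramp_start": "density_ramp_start_deg",
    "meridional_extent": "meridional_extent_deg",
}
_PARAM_ANGLE_PAIRS = {
    "germinative_zone": "germinative_zone_deg",
    "fiber_zone": "fiber_zone_deg",
}


def write_stack(path, stack: VoxelStack) -> None:
    meta = stack.metadata()
    tifffile.imwrite(
        path,
        stack.data,
        description=json.dumps(meta),
        photometric="minisblack",
    )


def read_stack(path) -> VoxelStack:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        desc = tf.pages[0].description
    try:
        meta = json.loads(desc)
    except (TypeError, json.JSONDecodeError) as exc:
        raise MetadataError(f"stack {path} has no JSON metadata description") from exc
    if data.ndim == 2:
        data = data[None]
    return VoxelStack(
        data=np.asarray(data, dtype=np.float32),
        voxel_size=tuple(meta["voxel_size_um"]),
        channel=meta["channel"],
        aspect=meta["aspect"],
        x0=meta["x0_um"],
        y0=meta["y0_um"],
        z0=meta["z0_um"],
        view_azimuth=meta.get("view_azimuth_rad", 0.0),
    )


def write_projection(path, projection: Projection) -> None:
    """Save a projection as 16-bit TIFF (clipped), metadata preserved."""
    data = np.clip(np.round(projection.data), 0, 65535).astype(np.uint16)
    tifffile.imwrite(
        path,
        data,
        description=json.dumps(projection.metadata()),
        photometric="minisblack",
    )


def read_projection(path) -> Projection:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        desc = tf.pages[0].description
    try:
        meta = json.loads(desc)
    except (TypeError, json.JSONDecodeError) as exc:
        raise MetadataError(f"projection {path} has no JSON metadata description") from exc
    return Projection(
        data=np.asarray(data, dtype=np.float32),
        pixel_size=tuple(meta["pixel_size_um"]),
        channel=meta["channel"],
        aspect=meta["aspect"],
        x0=meta["x0_um"],
        y0=meta["y0_um"],
        view_azimuth=meta.get("view_azimuth_rad", 0.0),
    )


def write_records_csv(path, records: List[NucleusRecord]) -> None:
    records_to_dataframe(records).to_csv(path, index=False)


def read_records_csv(path) -> List[NucleusRecord]:
    return records_from_dataframe(pd.read_csv(path))


def params_to_dict(params: LensSimParams) -> dict:
    d = {}
    for key, value in vars(params).items():
        if key in _PARAM_ANGLE_FIELDS:
            d[_PARAM_ANGLE_FIELDS[key]] = math.degrees(value)
        elif key in _PARAM_ANGLE_PAIRS:
            d[_PARAM_ANGLE_PAIRS[key]] = [math.degrees(v) for v in value]
        elif isinstance(value, tuple):
            d[key] = list(value)
        else:
            d[key] = value
    return d


def params_from_dict(d: dict) -> LensSimParams:
    kwargs = {}
    inv_angles = {v: k for k, v in _PARAM_ANGLE_FIELDS.items()}
    inv_pairs = {v: k for k, v in _PARAM_ANGLE_PAIRS.items()}
    valid = set(LensSimParams.__dataclass_fields__)
    for key, value in d.items():
        if key in inv_angles:
            kwargs[inv_angles[key]] = math.radians(value)
        elif key in inv_pairs:
            kwargs[inv_pairs[key]] = tuple(math.radians(v) for v in value)
        elif key in valid:
            field_type = LensSimParams.__dataclass_fields__[key]
            kwargs[key] = tuple(value) if isinstance(value, list) else value
        else:
            raise ParameterError(f"unknown simulator parameter {key!r}")
    return LensSimParams(**kwargs)


def write_params_yaml(path, params: LensSimParams) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params_to_dict(params), fh, sort_keys=True)


def read_params_yaml(path) -> LensSimParams:
    with open(path) as fh:
        return params_from_dict(yaml.safe_load(fh) or {})


def write_match_json(path, match: ConstellationMatch, fiduciary=None) -> None:
    d = match.to_dict()
    if fiduciary is not None:
        d["fiduciary"] = {
            "id_pair": list(fiduciary.id_pair),
            "anterior_x_um": fiduciary.anterior_position.x,
            "anterior_y_um": fiduciary.anterior_position.y,
            "equatorial_x_um": fiduciary.equatorial_position.x,
            "equatorial_y_um": fiduciary.equatorial_position.y,
            "colatitude_deg": math.degrees(fiduciary.colatitude),
        }
    with open(path, "w") as fh:
        json.dump(d, fh, indent=2)


def save_overlay(path, analysis, which: str = "anterior") -> None:
    """Audit overlay: projection with the counting region and counted centroids."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib import patches

    from . import geometry
    from .stack_ops import ASPECT_ANTERIOR, ASPECT_EQUATORIAL, CHANNEL_DNA

    if which == "anterior":
        proj = analysis.scene.projections[(ASPECT_ANTERIOR, CHANNEL_DNA)]
        region = analysis.sector
        records = analysis.anterior_records
    else:
        proj = analysis.scene.projections[(ASPECT_EQUATORIAL, CHANNEL_DNA)]
        region = analysis.trapezoid
        records = analysis.equatorial_records
    fig, ax = plt.subplots(figsize=(7, 7))
    extent = [
        proj.x_coords()[0],
        proj.x_coords()[-1],
        proj.y_coords()[-1],
        proj.y_coords()[0],
    ]
    ax.imshow(proj.data, cmap="gray", extent=extent, origin="upper")
    inside = [r for r in records if geometry.point_in_region(r.centroid, region)]
    if inside:
        ax.plot(
            [r.centroid.x for r in inside],
            [r.centroid.y for r in inside],
            ".", color="lime", markersize=2,
        )
    if isinstance(region, geometry.AnteriorSector):
        th1 = math.degrees(region.orientation - region.central_angle / 2)
        th2 = math.degrees(region.orientation + region.central_angle / 2)
        ax.add_patch(
            patches.Wedge(
                (region.center.x, region.center.y),
                region.sector_radius, th1, th2,
                fill=False, edgecolor="yellow", linewidth=1.2,
            )
        )
    else:
        ha, hb = region.side_a / 2, region.side_b / 2
        xs = [-hb, hb, ha, -ha, -hb]
        ys = [region.base_y, region.base_y, region.top_y, region.top_y, region.base_y]
        ax.plot(xs, ys, color="yellow", linewidth=1.2)
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    ax.set_title(f"{which} counting region: {len(inside)} nuclei")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
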