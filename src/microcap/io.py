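"""TIFF / YAML / CSV input-output.

Stacks are written as OME-TIFF with channel order (CW, AF594, FITC), z as
the slowest axis (axes ZCYX) and voxel sizes in the OME metadata.  Label
volumes are single-channel integer TIFFs with codes
{0 water, 1 hydrogel, 2 microsphere, 3 coupon}.
"""
from __future__ import annotations

import dataclasses
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import phantom
from .quantify import PartitionResult
from .volumes import ChannelStack, DomainLabelVolume

CHANNEL_NAMES = ("CW", "AF594", "FITC")


def write_stack(path, stack: ChannelStack) -> None:
    data = stack.channels().astype(np.float32)  # (z, c, y, x)
    dx, dy, dz = stack.voxel_size_xyz
    tifffile.imwrite(
        path,
        data,
        ome=True,
        metadata={
            "axes": "ZCYX",
            "Channel": {"Name": list(CHANNEL_NAMES)},
            "PhysicalSizeX": dx,
            "PhysicalSizeY": dy,
            "PhysicalSizeZ": dz,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZUnit": "µm",
        },
    )


def _ome_voxel_sizes(tf: tifffile.TiffFile):
    if not tf.ome_metadata:
        return None
    root = ET.fromstring(tf.ome_metadata)
    ns = {"ome": root.tag.split("}")[0].strip("{")}
    px = root.find(".//ome:Pixels", ns)
    if px is None:
        return None
    try:
        return tuple(float(px.attrib[f"PhysicalSize{ax}"]) for ax in "XYZ")
    except KeyError:
        return None


def read_stack(
    path,
    channel_order: tuple[str, str, str] = ("cw", "af594", "fitc"),
    voxel_size_xyz: tuple[float, float, float] | None = None,
) -> ChannelStack:
    """Read a 3-channel stack; ``channel_order`` names the stored channel axis."""
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        meta_vox = _ome_voxel_sizes(tf)
    if data.ndim != 4:
        raise ValueError(f"expected a 4-D (z, c, y, x) stack, got shape {data.shape}")
    if data.shape[1] != 3:
        raise ValueError("stack must carry exactly 3 channels on axis 1")
    chans = {name: data[:, i].astype(float) for i, name in enumerate(channel_order)}
    vox = voxel_size_xyz or meta_vox or (1.0, 1.0, 1.0)
    return ChannelStack(chans["cw"], chans["af594"], chans["fitc"], tuple(vox))


def write_labels(path, labels: DomainLabelVolume) -> None:
    dx, dy, dz = labels.voxel_size_xyz
    tifffile.imwrite(
        path,
        labels.labels.astype(np.uint8),
        metadata={"axes": "ZYX", "spacing": dz, "unit": "um"},
        resolution=(1.0 / dx, 1.0 / dy),
    )


def read_labels(path, voxel_size_xyz=(1.0, 1.0, 1.0)) -> DomainLabelVolume:
    data = tifffile.imread(path)
    return DomainLabelVolume(np.asarray(data, dtype=np.uint8), tuple(voxel_size_xyz))


def write_domain_counts(path, labels: DomainLabelVolume) -> None:
    pd.DataFrame([labels.counts()]).to_csv(path, index=False)


# --- scenario YAML ---------------------------------------------------------

def _noise_to_dict(model: phantom.NoiseModel):
    if model is None:
        return {"kind": "none"}
    if isinstance(model, phantom.GaussianNoise):
        return {"kind": "gaussian", "sigma": model.sigma}
    return {"kind": "poisson_gaussian", "gain": model.gain, "sigma": model.sigma}


def _noise_from_dict(d) -> phantom.NoiseModel:
    kind = d.get("kind", "none")
    if kind == "none":
        return None
    if kind == "gaussian":
        return phantom.GaussianNoise(sigma=float(d["sigma"]))
    if kind == "poisson_gaussian":
        return phantom.PoissonGaussianNoise(gain=float(d["gain"]), sigma=float(d["sigma"]))
    raise ValueError(f"unknown noise model kind: {kind!r}")


def write_scenario(path, geometry: phantom.MicrocapGeometry,
                   field: phantom.ConcentrationField,
                   config: phantom.ImagingConfig) -> None:
    doc = {
        "geometry": {
            "cap_center_xy": list(geometry.cap_center_xy),
            "cap_radius": geometry.cap_radius,
            "coupon_z": geometry.coupon_z,
            "cw_penetration_depth": geometry.cw_penetration_depth,
            "spheres": [{"center": list(c), "radius": r} for c, r in geometry.spheres],
        },
        "field": dataclasses.asdict(field),
        "config": {
            "voxel_size_xyz": list(config.voxel_size_xyz),
            "stack_shape": list(config.stack_shape),
            "blur_sigma_xyz": list(config.blur_sigma_xyz) if config.blur_sigma_xyz else None,
            "noise_model": _noise_to_dict(config.noise_model),
            "seed": config.seed,
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_scenario(path):
    doc = yaml.safe_load(Path(path).read_text())
    g = doc["geometry"]
    geometry = phantom.MicrocapGeometry(
        cap_center_xy=tuple(g["cap_center_xy"]),
        cap_radius=float(g["cap_radius"]),
        coupon_z=float(g["coupon_z"]),
        cw_penetration_depth=float(g["cw_penetration_depth"]),
        spheres=tuple((tuple(s["center"]), float(s["radius"])) for s in g["spheres"]),
    )
    field = phantom.ConcentrationField(**doc["field"])
    c = doc["config"]
    config = phantom.ImagingConfig(
        voxel_size_xyz=tuple(c["voxel_size_xyz"]),
        stack_shape=tuple(c["stack_shape"]),
        blur_sigma_xyz=tuple(c["blur_sigma_xyz"]) if c.get("blur_sigma_xyz") else None,
        noise_model=_noise_from_dict(c.get("noise_model", {})),
        seed=int(c.get("seed", 0)),
    )
    return geometry, field, config


def write_qc_overlays(out_dir, stack: ChannelStack, labels: DomainLabelVolume,
                      every: int = 8) -> list[Path]:
    """Per-slice PNG overlays (FITC grayscale + domain tint) for visual QC."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cmap = ListedColormap(["none", "#1f77b4", "#d62728", "#7f7f7f"])
    written = []
    for iz in range(0, stack.shape[0], every):
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.imshow(stack.fitc[iz], cmap="gray")
        ax.imshow(labels.labels[iz], cmap=cmap, alpha=0.35, vmin=0, vmax=3,
                  interpolation="nearest")
        ax.set_title(f"z = {iz}")
        ax.axis("off")
        path = out_dir / f"overlay_z{iz:04d}.png"
        fig.savefig(path, dpi=100, bbox_inches="tight")
        plt.close(fig)
        written.append(path)
    return written


def partition_result_row(result: PartitionResult, microcap_id=None) -> dict:
    row = {"microcap": microcap_id, "kp": result.kp,
           "fitc_microcap": result.fitc_microcap, "fitc_water": result.fitc_water}
    for name, mean in result.mean_fitc_by_domain.items():
        row[f"mean_{name}"] = mean
    for name, n in result.voxel_counts.items():
        row[f"voxels_{name}"] = n
    return row


def write_partition_csv(path, results, ids=None) -> None:
    ids = ids if ids is not None else range(1, len(results) + 1)
    pd.DataFrame([partition_result_row(r, i) for r, i in zip(results, ids)]).to_csv(
        path, index=False
    )
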