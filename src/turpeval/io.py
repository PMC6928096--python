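"""Disk formats: TIFF+JSON bundles, PNG overlays, metric tables."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from turpeval.metrics import CaseMetrics, SliceMetrics
from turpeval.phantom import BreachEvent, CaseBundle
from turpeval.volume import LABEL_COLORS, LABEL_NAMES, Label, LabelVolume, SliceStack

__all__ = [
    "write_label_volume", "read_label_volume",
    "write_slice_stack", "read_slice_stack",
    "write_label_overlays", "write_case_bundle", "read_case_bundle",
    "write_breach_record", "read_breach_record",
    "case_metrics_frame", "write_case_metrics", "read_case_metrics_json",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_label_volume(volume: LabelVolume, path) -> Path:
    """Write labels as a multi-page uint8 TIFF plus a JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, volume.data, photometric="minisblack")
    _sidecar(path).write_text(json.dumps({
        "pixel_spacing_mm": volume.pixel_spacing_mm,
        "slice_spacing_mm": volume.slice_spacing_mm,
        "labels": LABEL_NAMES,
        "meta": volume.meta,
    }, indent=2, sort_keys=True))
    return path


def read_label_volume(path) -> LabelVolume:
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    side = json.loads(_sidecar(path).read_text())
    return LabelVolume(data.astype(np.uint8), side["pixel_spacing_mm"],
                       side["slice_spacing_mm"], meta=side.get("meta", {}))


def write_slice_stack(stack: SliceStack, path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, stack.data.astype(np.float32), photometric="minisblack")
    _sidecar(path).write_text(json.dumps({
        "pixel_spacing_mm": stack.pixel_spacing_mm,
        "slice_spacing_mm": stack.slice_spacing_mm,
        "meta": stack.meta,
    }, indent=2, sort_keys=True))
    return path


def read_slice_stack(path) -> SliceStack:
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    side = json.loads(_sidecar(path).read_text())
    return SliceStack(data, side["pixel_spacing_mm"], side["slice_spacing_mm"],
                      meta=side.get("meta", {}))


def write_label_overlays(volume: LabelVolume, directory, prefix: str = "slice") -> list:
    """Export each slice as an RGB PNG (peripheral blue, central red, cavity pink)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    lut = np.zeros((4, 3), dtype=np.uint8)
    for lab, rgb in LABEL_COLORS.items():
        lut[int(lab)] = rgb
    paths = []
    for k in range(volume.n_slices):
        p = directory / f"{prefix}_{k:04d}.png"
        iio.imwrite(p, lut[volume[k]])
        paths.append(p)
    return paths


def write_breach_record(events: list, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps([asdict(e) for e in events], indent=2))
    return path


def read_breach_record(path) -> list:
    return [BreachEvent(**d) for d in json.loads(Path(path).read_text())]


def write_case_bundle(bundle: CaseBundle, directory) -> Path:
    """Write a full case (stacks, labels, breach record, metadata) to a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_label_volume(bundle.pre_labels, directory / "pre_labels.tif")
    write_label_volume(bundle.post_labels, directory / "post_labels.tif")
    write_slice_stack(bundle.pre_stack, directory / "pre.tif")
    write_slice_stack(bundle.post_stack, directory / "post.tif")
    write_breach_record(bundle.breaches, directory / "breaches.json")
    (directory / "case.json").write_text(json.dumps({
        "spec": asdict(bundle.spec),
        "skill": asdict(bundle.skill),
        "noise": asdict(bundle.noise),
        "meta": bundle.meta,
    }, indent=2, sort_keys=True))
    return directory


def read_case_bundle(directory) -> CaseBundle:
    from turpeval.phantom import NoiseModel, PhantomSpec, SkillProfile

    directory = Path(directory)
    info = json.loads((directory / "case.json").read_text())
    spec_d = info["spec"]
    spec_d["central_zone_scale"] = tuple(spec_d["central_zone_scale"])
    skill_d = info["skill"]
    skill_d["roughness_harmonics"] = tuple(skill_d["roughness_harmonics"])
    return CaseBundle(
        pre_labels=read_label_volume(directory / "pre_labels.tif"),
        post_labels=read_label_volume(directory / "post_labels.tif"),
        pre_stack=read_slice_stack(directory / "pre.tif"),
        post_stack=read_slice_stack(directory / "post.tif"),
        breaches=read_breach_record(directory / "breaches.json"),
        spec=PhantomSpec(**spec_d),
        skill=SkillProfile(**skill_d),
        noise=NoiseModel(**info["noise"]),
        meta=info.get("meta", {}),
    )


def _slice_rows(metrics: list, which: str) -> list:
    rows = []
    for m in metrics:
        rows.append({"slice": m.index, "stage": which,
                     "t_min_peri_mm": m.t_min_peri_mm, "a_uret_mm2": m.a_uret_mm2,
                     "a_conv_mm2": m.a_conv_mm2, "p_uret_mm": m.p_uret_mm,
                     "circularity": m.circularity, "valid": m.valid,
                     "reason": m.reason})
    return rows


def case_metrics_frame(case: CaseMetrics) -> pd.DataFrame:
    """Per-slice metrics as a long-format DataFrame (lengths mm, areas mm^2)."""
    return pd.DataFrame(_slice_rows(case.pre, "pre") + _slice_rows(case.post, "post"))


def write_case_metrics(case: CaseMetrics, csv_path, json_path=None,
                       provenance: dict | None = None) -> None:
    """Write per-slice metrics to CSV and aggregates (+provenance) to JSON."""
    case_metrics_frame(case).to_csv(csv_path, index=False)
    if json_path is not None:
        payload = case.as_dict()
        if provenance:
            payload["provenance"] = provenance
        Path(json_path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_case_metrics_json(path) -> dict:
    return json.loads(Path(path).read_text())
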