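"""Standard-format I/O: NIfTI-1 volumes, TSV tables, YAML configs.

Synthetic voxels are written on a 3-mm isotropic grid; TR is stored in
the NIfTI time-axis zoom, and stat-map provenance in the header
description field (truncated to its 80-byte capacity).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .exceptions import InvalidArgumentError
from .types import BoldImage, RatingTrace, StatMap, SubjectEnsemble, TraitTable

__all__ = [
    "save_bold",
    "load_bold",
    "save_mask",
    "load_mask",
    "save_statmap",
    "load_statmap",
    "save_ensemble",
    "load_ensemble",
    "save_traces",
    "load_traces",
    "save_traits",
    "load_traits",
    "save_cluster_table",
    "save_quadrant_map",
]

_AFFINE = np.diag([3.0, 3.0, 3.0, 1.0])


def save_bold(path, image: BoldImage) -> None:
    img = nib.Nifti1Image(image.data.astype(np.float32), _AFFINE)
    img.header.set_zooms((3.0, 3.0, 3.0, image.tr))
    nib.save(img, str(path))


def load_bold(path, mask: np.ndarray, subject_id: str | None = None) -> BoldImage:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise InvalidArgumentError(f"{path}: expected a 4D volume")
    tr = float(img.header.get_zooms()[3])
    sid = subject_id or Path(path).name.split(".")[0]
    return BoldImage(data, tr, mask, subject_id=sid)


def save_mask(path, mask: np.ndarray) -> None:
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), _AFFINE), str(path))


def load_mask(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj) > 0


def save_statmap(path, statmap: StatMap) -> None:
    img = nib.Nifti1Image(statmap.data.astype(np.float32), _AFFINE)
    desc = f"{statmap.statistic};df={statmap.df};{statmap.provenance}"
    img.header["descrip"] = desc.encode()[:79]
    nib.save(img, str(path))


def load_statmap(path, mask: np.ndarray, statistic: str, df=None) -> StatMap:
    data = np.asarray(nib.load(str(path)).dataobj, dtype=float)
    return StatMap(data, statistic, mask, df=df, provenance=str(path))


def save_ensemble(out_dir, ensemble: SubjectEnsemble) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_mask(out / "mask.nii.gz", ensemble.mask)
    for img in ensemble.images:
        save_bold(out / f"{img.subject_id}_bold.nii.gz", img)


def load_ensemble(in_dir) -> SubjectEnsemble:
    src = Path(in_dir)
    mask = load_mask(src / "mask.nii.gz")
    paths = sorted(src.glob("*_bold.nii.gz"))
    if not paths:
        raise InvalidArgumentError(f"no *_bold.nii.gz under {src}")
    images = [load_bold(p, mask, subject_id=p.name.replace("_bold.nii.gz", "")) for p in paths]
    return SubjectEnsemble(images)


def save_traces(path, traces) -> None:
    rows = []
    for t in traces:
        for time, value in zip(t.times, t.values):
            rows.append({"time_s": time, "value": value, "rater_id": t.rater_id})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_traces(path):
    df = pd.read_csv(path, sep="\t")
    traces = []
    for rid, grp in df.groupby("rater_id", sort=True):
        grp = grp.sort_values("time_s")
        traces.append(
            RatingTrace(grp["time_s"].to_numpy(), grp["value"].to_numpy(), rater_id=str(rid))
        )
    return traces


def save_traits(path, traits: TraitTable) -> None:
    traits.df.to_csv(path, sep="\t")


def load_traits(path) -> TraitTable:
    return TraitTable(pd.read_csv(path, sep="\t"))


def save_cluster_table(path, result) -> None:
    result.table.to_csv(path, sep="\t", index=False)


def save_quadrant_map(path, quadrant) -> None:
    """Integer-coded NIfTI with a JSON legend sidecar."""
    nib.save(nib.Nifti1Image(quadrant.labels.astype(np.int16), _AFFINE), str(path))
    legend_path = Path(str(path).replace(".nii.gz", "").replace(".nii", "") + "_legend.json")
    legend_path.write_text(json.dumps({str(k): v for k, v in quadrant.legend.items()}, indent=2))


def save_yaml(path, obj: dict) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))


def load_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text())
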