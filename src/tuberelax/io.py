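"""Reading and writing of echo stacks, label maps and result tables.

Echo stacks travel as multi-page TIFF (one page per echo, via tifffile)
or NIfTI (echo on the third axis, via nibabel) with a JSON sidecar
carrying the echo spacing, echo count and generation seed; label maps
as single-page integer TIFF with the documented label code.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd

from .phantom import LABEL_CODE, MultiEchoImage, TissueLabelMap

__all__ = [
    "write_stack_tiff", "write_stack_nifti", "read_stack",
    "write_label_map", "read_label_map",
    "write_sidecar", "read_sidecar", "region_summary",
]


def write_sidecar(path: Path, te_ms: float, n_echoes: int,
                  seed: Optional[int] = None, extra: Optional[dict] = None) -> Path:
    side = Path(path).with_suffix(Path(path).suffix + ".json")
    meta: dict[str, Any] = {"te_ms": te_ms, "n_echoes": n_echoes}
    if seed is not None:
        meta["seed"] = seed
    if extra:
        meta.update(extra)
    side.write_text(json.dumps(meta, indent=2, sort_keys=True))
    return side


def read_sidecar(path: Path) -> Optional[dict]:
    side = Path(path).with_suffix(Path(path).suffix + ".json")
    if side.exists():
        return json.loads(side.read_text())
    return None


def write_stack_tiff(img: MultiEchoImage, path: Path, seed: Optional[int] = None,
                     extra: Optional[dict] = None) -> Path:
    import tifffile
    path = Path(path)
    tifffile.imwrite(path, img.data.astype(np.float32))
    write_sidecar(path, img.te_ms, img.n_echoes, seed=seed, extra=extra)
    return path


def write_stack_nifti(img: MultiEchoImage, path: Path, seed: Optional[int] = None,
                      extra: Optional[dict] = None) -> Path:
    import nibabel as nib
    path = Path(path)
    # echo on the 3rd axis: (row, col, echo)
    vol = np.moveaxis(img.data, 0, -1).astype(np.float32)
    nib.save(nib.Nifti1Image(vol, affine=np.eye(4)), str(path))
    write_sidecar(path, img.te_ms, img.n_echoes, seed=seed, extra=extra)
    return path


def read_stack(path: Path, te_ms: Optional[float] = None) -> MultiEchoImage:
    """Read a multi-echo stack from TIFF or NIfTI (sidecar supplies TE)."""
    path = Path(path)
    meta = read_sidecar(path)
    if te_ms is None:
        if meta is None or "te_ms" not in meta:
            raise ValueError(f"no echo spacing: pass te_ms or provide {path}.json")
        te_ms = float(meta["te_ms"])
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib
        vol = np.asarray(nib.load(str(path)).dataobj, dtype=float)
        data = np.moveaxis(vol, -1, 0)
    else:
        import tifffile
        data = np.asarray(tifffile.imread(path), dtype=float)
    return MultiEchoImage(data=data, te_ms=te_ms)


def write_label_map(labels: TissueLabelMap, path: Path) -> Path:
    import tifffile
    path = Path(path)
    tifffile.imwrite(path, labels.labels.astype(np.uint8))
    side = Path(str(path) + ".tuber_ids.tiff")
    tifffile.imwrite(side, labels.tuber_ids.astype(np.int32))
    write_sidecar(path, te_ms=1.0, n_echoes=1,
                  extra={"label_code": dict(labels.label_code)})
    return path


def read_label_map(path: Path) -> TissueLabelMap:
    import tifffile
    path = Path(path)
    labels = np.asarray(tifffile.imread(path))
    side = Path(str(path) + ".tuber_ids.tiff")
    tuber_ids = (np.asarray(tifffile.imread(side)) if side.exists()
                 else np.zeros_like(labels, dtype=np.int32))
    meta = read_sidecar(path) or {}
    code = meta.get("label_code", dict(LABEL_CODE))
    return TissueLabelMap(labels=labels, tuber_ids=tuber_ids, label_code=code)


def region_summary(labels: TissueLabelMap) -> pd.DataFrame:
    """Per-tuber, per-tissue pixel counts and centroids."""
    from scipy import ndimage
    rows = []
    for tid in labels.tuber_numbers:
        for tissue in ("skin", "cortex", "flesh", "pith", "vascular"):
            m = labels.tissue_mask(tissue, tuber_id=int(tid))
            if not m.any():
                continue
            r, c = ndimage.center_of_mass(m)
            rows.append({"tuber": int(tid), "tissue": tissue,
                         "pixel_count": int(m.sum()),
                         "centroid_row": float(r), "centroid_col": float(c)})
    return pd.DataFrame(rows)
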