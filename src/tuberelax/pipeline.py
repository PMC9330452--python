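"""End-to-end orchestration: phantom -> segmentation -> relaxometry -> stats.

A single flat config (YAML or dict) drives the four stages; every
intermediate artifact is written to the output directory and a manifest
records inputs, parameters, package version, seed and per-file
checksums, so a rerun with the same config is reproducible file by file.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import pandas as pd

from . import __version__
from .io import (read_stack, region_summary, write_label_map, write_stack_nifti,
                 write_stack_tiff)
from .phantom import default_phantom_spec, generate_phantom, render_noiseless
from .relaxometry import FIT_VARIABLES, fit_all_tissues
from .segmentation import SegmentationParams, segment_tissues
from .stats import compare_many, run_pca

log = logging.getLogger("tuberelax")

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Flat configuration of one pipeline run.

    Exactly one of ``phantom`` (True: generate the default synthetic
    acquisition) or ``input_image`` (path to an existing stack) must be
    set.  All defaults mirror the reference acquisition: TE 6.5 ms,
    256 echoes, 160 x 160 matrix.
    """

    out_dir: Path = Path("results/run")
    seed: int = 0
    phantom: bool = True
    input_image: Optional[Path] = None
    n_tubers: int = 8
    noise_sigma: float = 2.0
    vascular: bool = False
    snr_min: float = 7.0
    max_components: int = 3
    seg_params: SegmentationParams = field(default_factory=SegmentationParams)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.phantom == (self.input_image is not None):
            raise ValueError("set exactly one of phantom=True or input_image")

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        seg_keys = {k: d.pop(k) for k in list(d)
                    if k in ("seg_echo_index", "bg_echo_index", "erosion_kernel",
                             "cortex_strip_px", "min_tuber_area_px", "n_bins")}
        if "out_dir" in d:
            d["out_dir"] = Path(d["out_dir"])
        if d.get("input_image"):
            d["input_image"] = Path(d["input_image"])
            d.setdefault("phantom", False)
        return cls(seg_params=SegmentationParams(**seg_keys), **d)

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        import yaml
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the run manifest (also written).

    A stage failure raises :class:`PipelineError` naming the stage;
    artifacts of completed stages stay on disk.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__, "seed": config.seed,
        "stages": [], "outputs": {}, "checksums": {},
        "parameters": {
            "snr_min": config.snr_min, "max_components": config.max_components,
            "noise_sigma": config.noise_sigma, "n_tubers": config.n_tubers},
    }

    def record(stage: str, files: dict[str, Path]) -> None:
        manifest["stages"].append(stage)
        for k, p in files.items():
            manifest["outputs"][k] = str(p)
            manifest["checksums"][k] = _sha256(Path(p))

    stage = "phantom"
    try:
        if config.phantom:
            spec = default_phantom_spec(n_tubers=config.n_tubers,
                                        noise_sigma=config.noise_sigma,
                                        seed=config.seed, vascular=config.vascular)
            img, truth = generate_phantom(spec)
            noiseless, _ = render_noiseless(spec)
            files = {
                "stack_tiff": write_stack_tiff(img, out / "phantom.tiff",
                                               seed=config.seed),
                "stack_nifti": write_stack_nifti(img, out / "phantom.nii",
                                                 seed=config.seed),
                "truth_labels": write_label_map(truth, out / "truth_labels.tiff"),
            }
            record(stage, files)
            log.info("phantom: %d tubers, sigma=%.3g", spec.n_tubers, spec.noise_sigma)
        else:
            img = read_stack(config.input_image)
            log.info("loaded %s (%d echoes); phantom stage skipped",
                     config.input_image, img.n_echoes)
    except Exception as exc:  # noqa: BLE001 - stage boundary
        _write_manifest(out, manifest)
        raise PipelineError(stage, exc) from exc

    stage = "segmentation"
    try:
        labels = segment_tissues(img, config.seg_params)
        files = {"labels": write_label_map(labels, out / "labels.tiff")}
        summary = region_summary(labels)
        summary.to_csv(out / "regions.csv", index=False)
        files["regions"] = out / "regions.csv"
        record(stage, files)
        log.info("segmentation: %d tubers, %d flagged",
                 len(labels.tuber_numbers), len(labels.flags))
    except Exception as exc:  # noqa: BLE001
        _write_manifest(out, manifest)
        raise PipelineError(stage, exc) from exc

    stage = "relaxometry"
    try:
        table = fit_all_tissues(img, labels, snr_min=config.snr_min,
                                max_components=config.max_components)
        table.to_csv(out / "fits.csv", index=False)
        record(stage, {"fits": out / "fits.csv"})
        log.info("relaxometry: %d records", len(table))
    except Exception as exc:  # noqa: BLE001
        _write_manifest(out, manifest)
        raise PipelineError(stage, exc) from exc

    stage = "statistics"
    try:
        files = {}
        letters = _tissue_letter_table(table)
        letters.to_csv(out / "letters_tissue.csv")
        files["letters_tissue"] = out / "letters_tissue.csv"
        pca_vars = [v for v in ("i0_rel_2", "t2_1", "t2_2") if v in set(table["variable"])]
        wide_ok = table[table["variable"].isin(pca_vars)]["value"].notna().all()
        if len(pca_vars) >= 2 and wide_ok:
            pca = run_pca(table, pca_vars, obs_keys=["sample_id", "tissue"])
            pca.scores.to_csv(out / "pca_scores.csv")
            pca.loadings.to_csv(out / "pca_loadings.csv")
            pd.DataFrame({"component": pca.scores.columns,
                          "explained_variance_pct": pca.explained_variance_pct}
                         ).to_csv(out / "pca_variance.csv", index=False)
            files.update({"pca_scores": out / "pca_scores.csv",
                          "pca_loadings": out / "pca_loadings.csv",
                          "pca_variance": out / "pca_variance.csv"})
        record(stage, files)
    except Exception as exc:  # noqa: BLE001
        _write_manifest(out, manifest)
        raise PipelineError(stage, exc) from exc

    _write_manifest(out, manifest)
    return manifest


def _tissue_letter_table(table: pd.DataFrame) -> pd.DataFrame:
    """Letter display of the tissue effect, one row per fitted variable."""
    rows = {}
    for var in ("i0_rel_2", "t2_1", "t2_2"):
        sub = table[(table["variable"] == var) & table["value"].notna()]
        groups = {t: sub[sub["tissue"] == t]["value"].to_numpy()
                  for t in ("pith", "cortex", "flesh")}
        groups = {k: v for k, v in groups.items() if len(v) >= 2}
        if len(groups) < 3:
            continue
        out = compare_many(groups, grouping_factor="tissue")
        rows[var] = out.letters
    return pd.DataFrame(rows).T.rename_axis("variable")


def _write_manifest(out: Path, manifest: dict) -> Path:
    p = out / "manifest.json"
    p.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return p
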