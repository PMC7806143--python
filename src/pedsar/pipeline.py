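"""Stage orchestration: phantom -> properties -> EM -> safety; MR synthesis;
segmentation QC — with a manifest, JSON-line logs, and seeded reproducibility.

A single global seed is fanned out to per-stage seeds by stable hashing so
stages are independently reproducible; rerunning the same config reproduces
all non-stochastic outputs bit-identically.
"""

from __future__ import annotations

import json
import time
import zlib
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from pedsar import fdtd, mrsim, phantom as ph, safety, segqc, tissues
from pedsar.volume import LabelVolume

__all__ = ["RunConfig", "ConfigError", "ComputeError", "run_pipeline", "stage_seed"]

KNOWN_STAGES = ("phantom", "implant", "props", "em", "safety", "mr", "qc")


class ConfigError(ValueError):
    """Invalid or incomplete run configuration (detected before any compute)."""


class ComputeError(RuntimeError):
    """A stage failed during computation."""


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31 derived from the global seed."""
    return zlib.crc32(f"{global_seed}:{stage}".encode()) & 0x7FFFFFFF


@dataclass
class RunConfig:
    stages: list[str]
    out_dir: str = "pedsar_out"
    seed: int = 0
    # phantom
    phantom_spec: str | None = None  # YAML path; None -> packaged default child phantom
    phantom_spacing_mm: float = 2.0
    # implant
    implant_spec: str | None = None  # YAML path; None -> packaged default VNS geometry
    # props
    tissue_table: str | None = None  # CSV path; None -> packaged adult table
    frequency_mhz: float = 64.0
    # em
    em_spacing_mm: float = 8.0
    coil: dict = dc_field(default_factory=dict)
    grid: dict = dc_field(default_factory=dict)
    # safety
    normalization: str = "b1"  # 'b1' (2 uT at center) or 'headsar' (3.2 W/kg)
    head_z_mm: float = 0.0
    # mr
    sequence: dict = dc_field(default_factory=dict)
    mr_noise_sigma: float = 0.05
    mr_bias_amplitude: float = 0.1
    # qc
    qc_masks: list[str] = dc_field(default_factory=list)  # operator NIfTI paths
    qc_truth: str | None = None
    qc_tissues: list[str] = dc_field(default_factory=list)

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in KNOWN_STAGES]
        if unknown:
            raise ConfigError(f"unknown stages {unknown}; known: {KNOWN_STAGES}")
        if not self.stages:
            raise ConfigError("no stages requested")
        for attr in ("phantom_spec", "implant_spec", "tissue_table", "qc_truth"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{attr} file not found: {p}")
        for p in self.qc_masks:
            if not Path(p).exists():
                raise ConfigError(f"qc mask not found: {p}")
        if self.normalization not in ("b1", "headsar"):
            raise ConfigError("normalization must be 'b1' or 'headsar'")
        if "qc" in self.stages and (not self.qc_masks or self.qc_truth is None):
            raise ConfigError("qc stage requires qc_masks and qc_truth")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _log(fh, **kw):
    kw["t"] = time.time()
    fh.write(json.dumps(kw) + "\n")
    fh.flush()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in dependency order; return the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "stages": list(config.stages),
        "versions": _versions(),
        "outputs": [],
        "results": {},
    }
    log_path = out / "run_log.jsonl"
    artifacts: dict = {}

    def record(path: Path):
        manifest["outputs"].append(str(path.relative_to(out)))

    with open(log_path, "w") as log:
        for stage in [s for s in KNOWN_STAGES if s in config.stages]:
            t0 = time.time()
            _log(log, stage=stage, event="start", seed=stage_seed(config.seed, stage))
            try:
                _run_stage(stage, config, out, artifacts, manifest, record)
            except ConfigError:
                raise
            except Exception as exc:
                (out / f"{stage}.failed").write_text(str(exc))
                _log(log, stage=stage, event="failed", error=str(exc))
                raise ComputeError(f"stage {stage!r} failed: {exc}") from exc
            _log(log, stage=stage, event="done", seconds=time.time() - t0)

    manifest_path = out / "manifest.json"
    record(manifest_path)
    record(log_path)
    manifest_path.write_text(json.dumps(manifest, indent=1, default=_json_default))
    return manifest


def _run_stage(stage, config, out, artifacts, manifest, record):
    if stage == "phantom":
        if config.phantom_spec:
            spec = ph.PhantomSpec.from_yaml(config.phantom_spec)
        else:
            spec = ph.default_child_spec(config.phantom_spacing_mm,
                                         rng_seed=stage_seed(config.seed, "phantom"))
        vol = ph.build_phantom(spec)
        vol, n_filled = ph.fill_unlabeled(vol, ph.body_mask_from_labels(vol))
        p = out / "phantom.nii.gz"
        vol.to_nifti(p)
        record(p)
        record(out / "phantom.labels.json")
        artifacts["phantom"] = vol
        manifest["results"]["phantom"] = {
            "voxel_counts": vol.voxel_counts(),
            "holes_filled": n_filled,
        }

    elif stage == "implant":
        vol = artifacts.get("phantom") or _require(config, "phantom stage must run before implant")
        ispec = (ph.ImplantSpec.from_yaml(config.implant_spec)
                 if config.implant_spec else ph.default_vns_spec())
        wi = ph.insert_implant(vol, ispec)
        p = out / "phantom_implant.nii.gz"
        wi.to_nifti(p)
        record(p)
        record(out / "phantom_implant.labels.json")
        artifacts["phantom_implant"] = wi
        artifacts["implant_spec"] = ispec

    elif stage == "props":
        table = (tissues.TissueTable.from_csv(config.tissue_table)
                 if config.tissue_table else tissues.TissueTable.default())
        child = tissues.scale_to_child(table, config.frequency_mhz)
        p = out / f"child_props_{int(config.frequency_mhz)}MHz.csv"
        child.to_csv(p)
        record(p)
        artifacts["table"] = table
        artifacts["props"] = child

    elif stage == "em":
        props = artifacts.get("props") or _require(config, "props stage must run before em")
        coil = fdtd.CoilSpec(**config.coil)
        scenes = {"no_implant": artifacts.get("phantom")}
        if "phantom_implant" in artifacts:
            scenes["with_implant"] = artifacts["phantom_implant"]
        artifacts["fields"] = {}
        for name, vol in scenes.items():
            if vol is None:
                raise ComputeError("phantom stage must run before em")
            grid = fdtd.GridSpec(spacing_mm=config.em_spacing_mm,
                                 anchor_world_mm=_head_anchor(vol), **config.grid)
            f = fdtd.run_fdtd(vol, props, coil, grid)
            p = out / f"fields_{name}.h5"
            fdtd.save_fields(f, p)
            record(p)
            artifacts["fields"][name] = f

    elif stage == "safety":
        flds = artifacts.get("fields") or _require(config, "em stage must run before safety")
        results = {}
        for name, f in flds.items():
            fn = fdtd.normalize_b1(f)
            if config.normalization == "headsar":
                fn, res = safety.normalize_head_sar(fn, head_z_mm=config.head_z_mm)
            else:
                res = safety.evaluate_safety(fn, head_z_mm=config.head_z_mm)
            results[name] = res
            png = out / f"mip_10gsar_{name}.png"
            safety.mip(np.nan_to_num(res.sar10g_map), axis=1, png_path=png)
            record(png)
        summary = {name: res.summary() for name, res in results.items()}
        if {"with_implant", "no_implant"} <= results.keys():
            summary["implant_delta"] = safety.compare_implant(
                results["with_implant"], results["no_implant"]
            )
        p = out / "safety_summary.json"
        p.write_text(json.dumps(summary, indent=1, default=_json_default))
        record(p)
        manifest["results"]["safety"] = summary

    elif stage == "mr":
        vol = artifacts.get("phantom") or _require(config, "phantom stage must run before mr")
        table = artifacts.get("table") or tissues.TissueTable.default()
        seq = mrsim.SequenceParams(**config.sequence)
        img = mrsim.synth_image(vol, table, seq)
        seed = stage_seed(config.seed, "mr")
        noisy = mrsim.degrade_image(img, rician_sigma=config.mr_noise_sigma * img.max(),
                                    bias_amplitude=config.mr_bias_amplitude, seed=seed)
        cmp_ = mrsim.compare_images(img, noisy)
        import nibabel as nib

        for name, arr in (("mr_synth", img), ("mr_acquired", noisy)):
            p = out / f"{name}.nii.gz"
            affine = np.diag(list(vol.spacing_mm) + [1.0])
            affine[:3, 3] = vol.origin_mm
            nib.save(nib.Nifti1Image(arr.astype(np.float32), affine), str(p))
            record(p)
        manifest["results"]["mr"] = {"mse": cmp_.mse, "xcorr": cmp_.xcorr, "ssim": cmp_.ssim}

    elif stage == "qc":
        truth = LabelVolume.from_nifti(config.qc_truth)
        ops = {Path(p).stem: LabelVolume.from_nifti(p) for p in config.qc_masks}
        tissues_list = config.qc_tissues or [v for v in truth.label_map.values()]
        df = segqc.interoperator_report(ops, truth, tissues_list)
        p = out / "qc_report.csv"
        df.to_csv(p, index=False)
        record(p)
        manifest["results"]["qc"] = {
            "dsc_mean": df.attrs["dsc_mean"],
            "dsc_sd": df.attrs["dsc_sd"],
            "hd_mean": df.attrs["hd_mean"],
            "hd_sd": df.attrs["hd_sd"],
            "cells": df.to_dict("records"),
        }


def _head_anchor(vol: LabelVolume) -> tuple[float, float, float]:
    """Centroid of the head tissues (brain/CSF shells) in world mm, so the
    head sits at the coil center; falls back to the top decile of the body."""
    head_names = {"Brain (Grey Matter)", "Brain (White Matter)", "Cerebrospinal Fluid"}
    ids = [lid for lid, name in vol.label_map.items() if name in head_names]
    if ids:
        m = np.isin(vol.data, ids)
    else:
        nz = np.argwhere(vol.data > 0)
        zthr = np.percentile(nz[:, 2], 90)
        m = np.zeros(vol.shape, bool)
        m[:, :, int(zthr):] = vol.data[:, :, int(zthr):] > 0
    com = np.mean(np.argwhere(m), axis=0)
    return tuple(float(v) for v in (np.asarray(vol.origin_mm) + com * np.asarray(vol.spacing_mm)))


def _require(config, msg):
    raise ComputeError(msg)


def _versions() -> dict:
    import nibabel
    import numba
    import scipy
    import skimage

    import pedsar

    return {
        "pedsar": pedsar.__version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "nibabel": nibabel.__version__,
        "numba": numba.__version__,
        "skimage": skimage.__version__,
        "pandas": pd.__version__,
    }


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
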