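"""Readers and writers: NIfTI volumes, HDF5 sinograms, phantom cases
with JSON sidecars, model checkpoints, and seed fan-out."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import yaml

from .bcnn import ModelState, NetConfig
from .petsim import ScannerGeometry, Sinogram
from .phantom import LesionROI, PhantomCase

__all__ = ["read_volume", "write_volume", "save_case", "load_case",
           "save_sinogram", "load_sinogram", "save_model", "load_model",
           "stage_seed"]


def write_volume(image: np.ndarray, path, voxel_size_mm=(1.0, 1.0, 1.0)):
    """Write an array as NIfTI; voxel size goes into the affine diagonal.
    Data are written without scaling so a round-trip is bit-identical."""
    image = np.asarray(image)
    arr = image.astype(np.uint8) if image.dtype == bool else image
    affine = np.diag(list(voxel_size_mm)[:3] + [1.0])
    img = nib.Nifti1Image(arr, affine)
    img.header.set_data_dtype(arr.dtype)
    img.header["scl_slope"] = 1.0
    img.header["scl_inter"] = 0.0
    nib.save(img, str(path))


def read_volume(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a NIfTI volume; returns (data, voxel_size_mm)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(data), zooms


# ---------------------------------------------------------------------------
# phantom cases: one NIfTI per array + JSON sidecar + YAML manifest

def save_case(case: PhantomCase, out_dir):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vox = case.voxel_size_mm
    for c, name in enumerate(("inphase", "fatfrac", "waterfrac")):
        write_volume(case.mr[c], out / f"mr_{name}.nii.gz", vox)
    write_volume(case.ct, out / "ct.nii.gz", vox)
    write_volume(case.activity, out / "activity.nii.gz", vox)
    write_volume(case.labels.astype(np.int16), out / "labels.nii.gz", vox)
    write_volume(case.implant_mask, out / "implant_mask.nii.gz", vox)
    write_volume(case.body_truth, out / "body_truth.nii.gz", vox)
    meta = {
        "voxel_size_mm": list(vox),
        "seed": int(case.seed),
        "lesions": [{"klass": r.klass, "multiplier": r.multiplier,
                     "indices": [idx.tolist() for idx in r.indices]}
                    for r in case.lesions],
    }
    (out / "case.json").write_text(json.dumps(meta))


def load_case(case_dir) -> PhantomCase:
    d = Path(case_dir)
    mr = np.stack([read_volume(d / f"mr_{n}.nii.gz")[0]
                   for n in ("inphase", "fatfrac", "waterfrac")])
    ct, vox = read_volume(d / "ct.nii.gz")
    meta = json.loads((d / "case.json").read_text())
    lesions = [LesionROI(indices=tuple(np.asarray(i) for i in r["indices"]),
                         klass=r["klass"], multiplier=r["multiplier"])
               for r in meta["lesions"]]
    return PhantomCase(
        mr=mr, ct=ct,
        activity=read_volume(d / "activity.nii.gz")[0],
        labels=read_volume(d / "labels.nii.gz")[0].astype(np.int16),
        lesions=lesions,
        implant_mask=read_volume(d / "implant_mask.nii.gz")[0].astype(bool),
        body_truth=read_volume(d / "body_truth.nii.gz")[0].astype(bool),
        voxel_size_mm=tuple(meta["voxel_size_mm"]),
        seed=int(meta["seed"]))


def save_dataset_manifest(path, case_dirs, train_indices, val_indices,
                          seed: int):
    manifest = {"cases": [str(c) for c in case_dirs],
                "train_indices": list(map(int, train_indices)),
                "val_indices": list(map(int, val_indices)),
                "seed": int(seed)}
    Path(path).write_text(yaml.safe_dump(manifest))


# ---------------------------------------------------------------------------
# sinograms: HDF5 with geometry attributes

_GEOM_FIELDS = ("img_shape", "voxel_size_mm", "n_angles", "n_radial",
                "radial_width_mm", "n_tof", "tof_fwhm_mm", "tof_bin_width_mm",
                "psf_fwhm_mm", "n_subsets")


def save_sinogram(sino: Sinogram, path):
    with h5py.File(str(path), "w") as f:
        ds = f.create_dataset("counts", data=sino.data)
        ds.attrs["tof"] = sino.tof
        g = f.create_group("geometry")
        for name in _GEOM_FIELDS:
            g.attrs[name] = getattr(sino.geom, name)


def load_sinogram(path) -> Sinogram:
    with h5py.File(str(path), "r") as f:
        data = f["counts"][()]
        tof = bool(f["counts"].attrs["tof"])
        ga = f["geometry"].attrs
        geom = ScannerGeometry(
            img_shape=tuple(int(v) for v in ga["img_shape"]),
            voxel_size_mm=float(ga["voxel_size_mm"]),
            n_angles=int(ga["n_angles"]), n_radial=int(ga["n_radial"]),
            radial_width_mm=float(ga["radial_width_mm"]),
            n_tof=int(ga["n_tof"]), tof_fwhm_mm=float(ga["tof_fwhm_mm"]),
            tof_bin_width_mm=float(ga["tof_bin_width_mm"]),
            psf_fwhm_mm=float(ga["psf_fwhm_mm"]),
            n_subsets=int(ga["n_subsets"]))
    return Sinogram(data, geom, tof=tof)


# ---------------------------------------------------------------------------
# model checkpoints: npz archive with embedded config JSON

def save_model(model: ModelState, path):
    cfg = {"net_cfg": vars(model.net_cfg) | {
        "patch_size": list(model.net_cfg.patch_size)},
        "seed": int(model.seed), "iterations": int(model.iterations)}
    arrays = {f"param_{i}": p for i, p in enumerate(model.params)}
    np.savez(str(path), config=np.frombuffer(
        json.dumps(cfg).encode(), dtype=np.uint8),
        loss_history=model.loss_history, **arrays)


def load_model(path) -> ModelState:
    with np.load(str(path)) as z:
        cfg = json.loads(bytes(z["config"]).decode())
        net = dict(cfg["net_cfg"])
        net["patch_size"] = tuple(net["patch_size"])
        n_params = sum(1 for k in z.files if k.startswith("param_"))
        params = [z[f"param_{i}"] for i in range(n_params)]
        return ModelState(params=params, net_cfg=NetConfig(**net),
                          seed=cfg["seed"], iterations=cfg["iterations"],
                          loss_history=z["loss_history"])


# ---------------------------------------------------------------------------
# seed fan-out

def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed (< 2^31) from one global seed by hashing
    the stage name into a SeedSequence; stable across runs and
    platforms."""
    key = [int(global_seed)] + [b for b in stage.encode()]
    return int(np.random.SeedSequence(key).generate_state(1)[0] % (2 ** 31))
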