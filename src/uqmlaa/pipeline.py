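"""End-to-end pipeline: phantoms -> training -> Monte Carlo dropout ->
priors -> emission simulation -> all comparator reconstructions ->
evaluation.

Every stage writes its outputs plus a small manifest (stage name,
config hash, seed, package version); a stage whose manifest already
matches the requested configuration is skipped on re-run.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bcnn import MCConfig, NetConfig, TrainConfig, mc_dropout_infer, train
from .config import RunConfig, config_hash
from .humu import body_mask, eval_masks, hu_to_mu, remove_arms
from .io import (load_case, load_model, load_sinogram, save_case,
                 save_model, save_sinogram, stage_seed, write_volume)
from .metrics import lesion_report, masked_error_stats
from .mlaa import ReconConfig, mlaa_run, osem_reconstruct
from .petsim import ScannerGeometry, simulate_emission
from .phantom import (ImplantSpec, LesionSpec, default_pelvis_spec,
                      make_dataset, make_phantom)
from .priorweight import variance_to_weight, weight_to_beta

__all__ = ["run_pipeline"]


def _stage_done(stage_dir: Path, stage: str, cfg_hash: str, seed: int) -> bool:
    mf = stage_dir / "manifest.json"
    if not mf.exists():
        return False
    try:
        m = json.loads(mf.read_text())
    except json.JSONDecodeError:
        return False
    return m.get("config_hash") == cfg_hash and m.get("seed") == seed


def _write_manifest(stage_dir: Path, stage: str, cfg_hash: str, seed: int):
    (stage_dir / "manifest.json").write_text(json.dumps({
        "stage": stage, "config_hash": cfg_hash, "seed": seed,
        "version": __version__}))


def _recon_config(cfg: RunConfig) -> ReconConfig:
    r, g = cfg.recon, cfg.geometry
    return ReconConfig(outer_iterations=r.outer_iterations,
                       n_subsets=g.n_subsets,
                       osem_passes_per_outer=r.osem_passes_per_outer,
                       ostr_passes_per_outer=r.ostr_passes_per_outer,
                       beta_smooth=r.beta_smooth, mu_max=r.mu_max,
                       step_clamp=r.step_clamp, background=g.background,
                       osem_iterations=r.osem_iterations)


def _geometry(cfg: RunConfig) -> ScannerGeometry:
    p, g = cfg.phantom, cfg.geometry
    return ScannerGeometry(img_shape=(p.grid_shape[1], p.grid_shape[2]),
                           voxel_size_mm=p.voxel_size_mm[1],
                           n_angles=g.n_angles, n_radial=g.n_radial,
                           n_tof=g.n_tof, tof_fwhm_mm=g.tof_fwhm_mm,
                           psf_fwhm_mm=g.psf_fwhm_mm, n_subsets=g.n_subsets)


def run_pipeline(cfg: RunConfig, out_dir=None) -> Path:
    """Execute the full study; returns the run directory."""
    if cfg.phantom.train_with_implants:
        raise ValueError(
            "refusing to train with implant cases: the training policy "
            "requires an implant-free training set so implants remain "
            "out-of-distribution for the uncertainty estimate")

    chash = config_hash(cfg)
    run_dir = Path(out_dir) if out_dir is not None else \
        Path(cfg.out_root) / f"run_{chash}"
    run_dir.mkdir(parents=True, exist_ok=True)
    (run_dir / "config.json").write_text(
        json.dumps(cfg.model_dump(mode="json"), indent=2))
    p = cfg.phantom

    # ---- stage 1: phantoms -------------------------------------------------
    sim_dir = run_dir / "phantoms"
    seed_sim = stage_seed(cfg.seed, "simulate")
    if not _stage_done(sim_dir, "simulate", chash, seed_sim):
        sim_dir.mkdir(exist_ok=True)
        base = default_pelvis_spec(grid_shape=p.grid_shape,
                                   voxel_size_mm=p.voxel_size_mm,
                                   noise=p.noise)
        ds = make_dataset(p.n_train_cases, base, seed=seed_sim,
                          split_fraction=p.split_fraction)
        for i, case in enumerate(ds.cases):
            save_case(case, sim_dir / f"train_{i:03d}")
        imp = p.test_implant
        test_spec = default_pelvis_spec(
            seed=seed_sim + 1, grid_shape=p.grid_shape,
            voxel_size_mm=p.voxel_size_mm, noise=p.noise,
            lesion_specs=tuple(
                LesionSpec(center=l.center, radius_mm=l.radius_mm,
                           contrast=l.contrast, klass=l.klass)
                for l in p.test_lesions),
            implant_spec=ImplantSpec(center=imp.center,
                                     radius_mm=imp.radius_mm,
                                     implant_hu=imp.implant_hu,
                                     halo_radius_mm=imp.halo_radius_mm))
        save_case(make_phantom(test_spec), sim_dir / "test_000")
        (sim_dir / "split.json").write_text(json.dumps(
            {"train": ds.train_indices, "val": ds.val_indices}))
        _write_manifest(sim_dir, "simulate", chash, seed_sim)

    split = json.loads((sim_dir / "split.json").read_text())
    train_cases = [load_case(sim_dir / f"train_{i:03d}") for i in split["train"]]
    test_case = load_case(sim_dir / "test_000")

    # ---- stage 2: training -------------------------------------------------
    model_dir = run_dir / "model"
    seed_tr = stage_seed(cfg.seed, "train")
    t = cfg.train
    if not _stage_done(model_dir, "train", chash, seed_tr):
        model_dir.mkdir(exist_ok=True)
        net_cfg = NetConfig(depth=t.depth, base_channels=t.base_channels,
                            dropout=t.dropout, patch_size=t.patch_size)
        train_cfg = TrainConfig(iterations=t.iterations,
                                learning_rate=t.learning_rate,
                                batch_size=t.batch_size,
                                lambda_gdl=t.lambda_gdl,
                                lambda_ldl=t.lambda_ldl,
                                weight_decay=t.weight_decay, seed=seed_tr)
        model = train(train_cases, net_cfg, train_cfg)
        save_model(model, model_dir / "model.npz")
        _write_manifest(model_dir, "train", chash, seed_tr)
    model = load_model(model_dir / "model.npz")

    # ---- stage 3: Monte Carlo dropout inference ----------------------------
    infer_dir = run_dir / "pct"
    seed_mc = stage_seed(cfg.seed, "infer")
    vox = test_case.voxel_size_mm
    if not _stage_done(infer_dir, "infer", chash, seed_mc):
        infer_dir.mkdir(exist_ok=True)
        pct, var = mc_dropout_infer(
            model, test_case.mr,
            MCConfig(n_samples=cfg.mc.n_samples, seed=seed_mc))
        write_volume(pct, infer_dir / "pct.nii.gz", vox)
        write_volume(var, infer_dir / "variance.nii.gz", vox)
        _write_manifest(infer_dir, "infer", chash, seed_mc)
    from .io import read_volume
    pct = read_volume(infer_dir / "pct.nii.gz")[0]
    var = read_volume(infer_dir / "variance.nii.gz")[0]

    # ---- stage 4: priors ---------------------------------------------------
    prior_dir = run_dir / "priors"
    if not _stage_done(prior_dir, "priors", chash, 0):
        prior_dir.mkdir(exist_ok=True)
        body = remove_arms(body_mask(pct))
        w = variance_to_weight(var)
        beta = weight_to_beta(w, body, cfg.prior.beta_min,
                              cfg.prior.beta_max, cfg.prior.scaling)
        write_volume(body.data, prior_dir / "body.nii.gz", vox)
        write_volume(hu_to_mu(pct), prior_dir / "mu_prior.nii.gz", vox)
        write_volume(beta.astype(np.float32), prior_dir / "betamap.nii.gz", vox)
        _write_manifest(prior_dir, "priors", chash, 0)
    body = read_volume(prior_dir / "body.nii.gz")[0].astype(bool)
    mu_prior = read_volume(prior_dir / "mu_prior.nii.gz")[0]
    betamap = read_volume(prior_dir / "betamap.nii.gz")[0]

    # ---- stage 5: emission simulation --------------------------------------
    pet_dir = run_dir / "pet"
    seed_pet = stage_seed(cfg.seed, "simulate-pet")
    geom = _geometry(cfg)
    if not _stage_done(pet_dir, "simulate-pet", chash, seed_pet):
        pet_dir.mkdir(exist_ok=True)
        mu_true = hu_to_mu(test_case.ct)
        sino = simulate_emission(test_case.activity, mu_true, geom,
                                 total_counts=cfg.geometry.total_counts,
                                 background=cfg.geometry.background,
                                 seed=seed_pet)
        save_sinogram(sino, pet_dir / "sinogram.h5")
        _write_manifest(pet_dir, "simulate-pet", chash, seed_pet)
    sino = load_sinogram(pet_dir / "sinogram.h5")

    # ---- stage 6: reconstructions ------------------------------------------
    recon_dir = run_dir / "recon"
    rcfg = _recon_config(cfg)
    if not _stage_done(recon_dir, "recon", chash, 0):
        recon_dir.mkdir(exist_ok=True)
        mu_true = hu_to_mu(test_case.ct)
        recons = {"osem-ct": osem_reconstruct(sino, mu_true, rcfg,
                                              body=test_case.body_truth),
                  "osem-bpct": osem_reconstruct(sino, mu_prior, rcfg,
                                                body=body)}
        res = mlaa_run(sino, "naive", rcfg, body=body)
        recons["mlaa-naive"] = res.activity
        write_volume(res.mu, recon_dir / "mu_mlaa-naive.nii.gz", vox)
        for b in cfg.recon.uniform_betas:
            res = mlaa_run(sino, "regularized_uniform", rcfg, body=body,
                           mu_prior=mu_prior, beta_uniform=b)
            recons[f"mlaa-reg-{b:g}"] = res.activity
            write_volume(res.mu, recon_dir / f"mu_mlaa-reg-{b:g}.nii.gz", vox)
        res = mlaa_run(sino, "upct", rcfg, body=body, betamap=betamap,
                       mu_prior=mu_prior)
        recons["upct-mlaa"] = res.activity
        write_volume(res.mu, recon_dir / "mu_upct-mlaa.nii.gz", vox)
        np.savetxt(recon_dir / "objective_trace.txt", res.objective_trace)
        for name, lam in recons.items():
            write_volume(lam, recon_dir / f"activity_{name}.nii.gz", vox)
        _write_manifest(recon_dir, "recon", chash, 0)

    # ---- stage 7: evaluation -----------------------------------------------
    eval_dir = run_dir / "eval"
    if not _stage_done(eval_dir, "eval", chash, 0):
        eval_dir.mkdir(exist_ok=True)
        mu_true = hu_to_mu(test_case.ct)
        hu_eval, mu_eval = eval_masks(test_case.ct, mu_true,
                                      cfg.eval.hu_threshold,
                                      cfg.eval.mu_threshold)
        stats = {"pct_hu": vars(masked_error_stats(pct, test_case.ct, hu_eval)),
                 "mu_prior": vars(masked_error_stats(mu_prior, mu_true,
                                                     mu_eval))}
        method_pets = {}
        for f in sorted(recon_dir.glob("activity_*.nii.gz")):
            name = f.name[len("activity_"):-len(".nii.gz")]
            method_pets[name] = read_volume(f)[0]
        reference = method_pets.pop("osem-ct")
        from .phantom import BONE
        report = lesion_report(reference, method_pets, test_case.lesions,
                               test_case.labels == BONE,
                               test_case.implant_mask, vox,
                               suv_scale=cfg.eval.suv_scale)
        report.to_csv(eval_dir / "lesions.csv", index=False)
        (eval_dir / "summary.json").write_text(json.dumps(stats, indent=2))
        _write_manifest(eval_dir, "eval", chash, 0)

    return run_dir
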