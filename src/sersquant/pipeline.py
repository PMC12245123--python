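"""End-to-end pipeline wiring: simulate -> preprocess -> calibrate ->
(train) -> quantify/map -> classify -> report.

One YAML config drives every stage; a single global seed fans out to
per-stage seeds through numpy's SeedSequence spawning so stages stay
decoupled but reproducible.  Every artifact is a plain text file (CSV/JSON)
and the run manifest records seeds, config hash, checksums and record
counts; deterministic stages reproduce bit-identically for a fixed config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import dbcnet, evaluation, genotyping, ratiometric, simulate, spectra

log = logging.getLogger("sersquant")


class ConfigError(ValueError):
    """Unknown or invalid configuration key/value."""


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "run",
    "verbosity": "info",
    "simulate": {
        "gsh_levels": None,          # null -> the 6-level design
        "h2o2_levels": None,         # null -> the 8-level design
        "replicates": 5,
        "axis_points": None,         # null -> instrument axis (701 pts, 2 cm^-1);
                                     # set ~128 for fast NN training runs
        "noise_sd": 0.01,
        "baseline_max": 0.03,
        "tissue_grid": [4, 5],
    },
    "preprocess": {"crop": None, "normalize": True},
    "calibrate": {"replicates": 3, "noise_sd": 0.0},
    "train": {
        "enabled": False,
        "model": "dbcnet",
        "epochs": 8,
        "batch_size": 32,
        "bc_temperature": 1.0,
    },
    "classify": {"recipe": "ratios"},
}


def _merge_validate(defaults: dict, user: dict, path: str = "") -> dict:
    out = {}
    for key, dval in defaults.items():
        if isinstance(dval, dict) and key in user and user[key] is not None:
            if not isinstance(user[key], dict):
                raise ConfigError(f"config key '{path}{key}' must be a mapping")
            out[key] = _merge_validate(dval, user[key], f"{path}{key}.")
        else:
            out[key] = user.get(key, dval) if key in user else dval
    unknown = set(user) - set(defaults)
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(path + k for k in unknown)}")
    return out


def load_config(path=None, overrides: Optional[dict] = None) -> dict:
    """Validated run configuration (defaults <- YAML file <- overrides)."""
    user: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ConfigError("config file must contain a mapping")
            user = loaded
    cfg = _merge_validate(DEFAULT_CONFIG, user)
    if overrides:
        cfg = _merge_validate(DEFAULT_CONFIG, _deep_update(cfg, overrides))
    return cfg


def _deep_update(base: dict, upd: dict) -> dict:
    out = dict(base)
    for k, v in upd.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_update(out[k], v)
        else:
            out[k] = v
    return out


def stage_seeds(seed: int, names: tuple[str, ...]) -> dict:
    """Fan one global seed out to independent per-stage seeds (< 2^31)."""
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(names, children)
    }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _probe_for(cfg: dict) -> simulate.ProbeResponseModel:
    npts = cfg["simulate"]["axis_points"]
    probe = simulate.ProbeResponseModel()
    if npts:
        probe = probe.with_axis(np.linspace(400.0, 1800.0, int(npts)))
    return probe


def run_pipeline(cfg: dict, outdir=None) -> Path:
    """Execute every enabled stage; returns the run directory.

    Writes calibration/tissue spectra tables, fitted calibrations, the
    concentration map, genotype calls with ROC/confusion summaries, an
    optional trained model, and ``manifest.json`` with config hash, seeds and
    artifact checksums.  Stage failures propagate after the manifest records
    the failure marker.
    """
    cfg = _merge_validate(DEFAULT_CONFIG, cfg)
    out = Path(outdir or cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    level = {"debug": logging.DEBUG, "info": logging.INFO, "quiet": logging.WARNING}
    logging.basicConfig(level=level.get(cfg["verbosity"], logging.INFO))

    seeds = stage_seeds(cfg["seed"], ("simulate", "tissue", "calibrate", "train"))
    manifest: dict = {
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "seeds": seeds,
        "stages": {},
        "artifacts": {},
    }
    probe = _probe_for(cfg)
    scfg = cfg["simulate"]
    noise = simulate.NoiseModel(scfg["noise_sd"], scfg["baseline_max"])

    def _finish_stage(name: str, t0: float, n: int):
        manifest["stages"][name] = {"seconds": round(time.time() - t0, 3), "records": n}
        log.info("stage %s: %d records in %.2fs", name, n, time.time() - t0)

    try:
        # --- simulate ------------------------------------------------------
        t0 = time.time()
        cal = simulate.build_calibration_dataset(
            scfg["gsh_levels"], scfg["h2o2_levels"], scfg["replicates"],
            probe, noise, seed=seeds["simulate"],
        )
        spectra.write_spectra_table(out / "calibration.csv", cal, out / "calibration_manifest.csv")
        tissue = simulate.simulate_tissue_grid(
            grid_shape=tuple(scfg["tissue_grid"]), probe=probe, noise=noise,
            seed=seeds["tissue"],
        )
        spectra.write_spectra_table(out / "tissue.csv", tissue, out / "tissue_manifest.csv")
        _finish_stage("simulate", t0, len(cal) + len(tissue))

        # --- preprocess ----------------------------------------------------
        t0 = time.time()
        pcfg = cfg["preprocess"]
        crop = tuple(pcfg["crop"]) if pcfg["crop"] else None
        cal_pp = spectra.preprocess(cal, crop=crop, normalize=pcfg["normalize"])
        tissue_pp = spectra.preprocess(tissue, crop=crop, normalize=pcfg["normalize"])
        _finish_stage("preprocess", t0, len(cal_pp) + len(tissue_pp))

        # --- calibrate (single-analyte noiseless-by-default sweeps) --------
        t0 = time.time()
        ccfg = cfg["calibrate"]
        cal_noise = simulate.NoiseModel(ccfg["noise_sd"], 0.0)
        rng = np.random.default_rng(seeds["calibrate"])
        gsh_sweep = [
            simulate.simulate_spectrum(g, 0.0, probe, cal_noise, rng)
            for g in (scfg["gsh_levels"] or simulate.GSH_LEVELS_MM)
            for _ in range(ccfg["replicates"])
        ]
        h2o2_sweep = [
            simulate.simulate_spectrum(0.0, h, probe, cal_noise, rng)
            for h in (scfg["h2o2_levels"] or simulate.H2O2_LEVELS_UM)
            for _ in range(ccfg["replicates"])
        ]
        cal_gsh = ratiometric.calibrate_from_records(gsh_sweep, "GSH")
        cal_h2o2 = ratiometric.calibrate_from_records(h2o2_sweep, "H2O2")
        cal_gsh.to_json(out / "cal_gsh.json")
        cal_h2o2.to_json(out / "cal_h2o2.json")
        _finish_stage("calibrate", t0, len(gsh_sweep) + len(h2o2_sweep))

        # --- train (optional) ----------------------------------------------
        tcfg = cfg["train"]
        if tcfg["enabled"]:
            t0 = time.time()
            mcfg = dbcnet.ModelConfig(
                seed=seeds["train"], bc_temperature=tcfg["bc_temperature"]
            )
            if tcfg["model"] == "dbcnet":
                model = dbcnet.build_model(mcfg)
            else:
                model = dbcnet.build_baseline(tcfg["model"], mcfg)
            X = dbcnet.prepare_inputs(cal_pp, model.cfg.input_mode)
            y = dbcnet.labels_array(cal_pp)
            split = spectra.split_dataset(
                len(cal_pp), seed=seeds["train"],
                strata=spectra.concentration_strata(cal_pp),
            )
            hist = dbcnet.train(
                model, X, y, split,
                dbcnet.TrainConfig(
                    epochs=tcfg["epochs"], batch_size=tcfg["batch_size"],
                    seed=seeds["train"],
                ),
            )
            dbcnet.save_model(model, out / "model.npz")
            pred = dbcnet.predict(model, X[split.test])
            report = evaluation.evaluate_predictions(pred, y[split.test], model.kind)
            (out / "train_report.json").write_text(
                json.dumps(
                    {
                        "model": model.kind,
                        "history_tail": {k: v[-3:] for k, v in hist.items() if isinstance(v, list)},
                        "best_epoch": hist["best_epoch"],
                        "test_metrics": {
                            m: report.per_metabolite[m].as_dict() for m in ("gsh", "h2o2")
                        },
                    },
                    indent=2,
                )
            )
            _finish_stage("train", t0, len(cal_pp))

        # --- quantify / map -------------------------------------------------
        t0 = time.time()
        points = [
            ratiometric.compute_ratios(rec.spectrum, grid_xy=rec.grid_xy)
            for rec in tissue_pp
        ]
        cmap = ratiometric.build_map(points, cal_gsh, cal_h2o2)
        cmap.to_dataframe().to_csv(out / "map.csv", index=False)
        _finish_stage("quantify", t0, len(points))

        # --- classify --------------------------------------------------------
        t0 = time.time()
        feat = pd.DataFrame(
            {
                "r1": [p.r1 for p in points],
                "r2": [p.r2 for p in points],
                "tissue_class": [rec.tissue_class for rec in tissue_pp],
            }
        )
        gq = [ratiometric.quantify(p, cal_gsh, cal_h2o2) for p in points]
        feat["c_gsh"] = [g for g, _, _ in gq]
        feat["c_h2o2"] = [h for _, h, _ in gq]
        feat["h2o2_gsh"] = feat["c_h2o2"] / feat["c_gsh"].clip(lower=1e-9)
        bundle = genotyping.fit_classifier(feat, recipe=cfg["classify"]["recipe"])
        bundle.to_json(out / "classifier.json")
        calls = [genotyping.classify(row._asdict(), bundle) for row in
                 feat[["r1", "r2", "h2o2_gsh"]].itertuples(index=False)]
        cm, ppv = genotyping.confusion_matrix(calls, feat["tissue_class"])
        is_tumor = feat["tissue_class"].isin(["WT", "MUT"]).to_numpy(int)
        _, auc1 = genotyping.roc_auc(
            [genotyping.classify(
                row._asdict(), bundle).p_tumor for row in
             feat[["r1", "r2", "h2o2_gsh"]].itertuples(index=False)],
            is_tumor,
        )
        tumor = feat[is_tumor.astype(bool)]
        s2_scores = bundle.stage2.prob(
            genotyping._stage_features(tumor, bundle.recipe, 2)
        ).ravel()
        _, auc2 = genotyping.roc_auc(
            s2_scores, (tumor["tissue_class"] == "MUT").to_numpy(int)
        )
        pd.DataFrame(
            {
                "label": [c.label for c in calls],
                "p_tumor": [c.p_tumor for c in calls],
                "p_mut_given_tumor": [c.p_mut_given_tumor for c in calls],
                "truth": feat["tissue_class"],
            }
        ).to_csv(out / "calls.csv", index=False)
        (out / "classification_report.json").write_text(
            json.dumps(
                {
                    "auc_tumor_vs_normal": auc1,
                    "auc_mut_vs_wt": auc2,
                    "confusion": cm.to_dict(),
                    "predictive_values": ppv.to_dict(),
                    "accuracy": float(
                        np.mean([c.label == t for c, t in zip(calls, feat["tissue_class"])])
                    ),
                },
                indent=2,
            )
        )
        _finish_stage("classify", t0, len(calls))
    except Exception as exc:
        manifest["failed"] = repr(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise

    for p in sorted(out.iterdir()):
        if p.name != "manifest.json" and p.is_file():
            manifest["artifacts"][p.name] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out


def write_fixtures(outdir, seed: int = 0) -> Path:
    """Small deterministic spectra tables for tests and demos."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    probe = simulate.ProbeResponseModel()
    noise = simulate.NoiseModel()
    cal = simulate.build_calibration_dataset(
        (2.0, 8.0, 16.0), (1.0, 100.0, 200.0), 2, probe, noise, seed=seed
    )
    spectra.write_spectra_table(out / "calibration.csv", cal, out / "calibration_manifest.csv")
    tissue = simulate.simulate_tissue_grid(
        grid_shape=(2, 3), probe=probe, noise=noise, seed=seed + 1
    )
    spectra.write_spectra_table(out / "tissue.csv", tissue, out / "tissue_manifest.csv")
    return out
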