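"""End-to-end orchestration: phantoms -> preprocessing -> split/balance ->
GAN ensemble augmentation -> per-variant classifiers -> evaluation -> vote.

A single global seed drives every stage through stable per-stage derivation
(CRC32 of the stage name mixed into the seed), so one knob reproduces the
whole run.  Every artifact directory receives a ``run.json`` recording the
seed and a hash of the full configuration.  Completed stages can be resumed:
with ``resume=True`` a finished run returns its stored report without
retraining anything.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import sys
import zlib

import numpy as np
import yaml

from . import classifier as clf
from . import dataset as ds
from . import evaluate as ev
from . import gans as ga
from . import phantom as ph
from . import preprocess as pp
from .errors import ConfigError

logger = logging.getLogger("ganaug")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter(
        "%(asctime)s %(levelname)s %(name)s: %(message)s",
        datefmt="%Y-%m-%dT%H:%M:%S"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)

DEFAULT_CONFIG: dict = {
    "workdir": "ganaug_run",
    "seed": 0,
    "phantom": {
        "per_class": {"glioma": 100, "meningioma": 100, "pituitary": 100},
        "image_size": 32,
        "tumor_radius": 3.5,
        "noise_sigma": 6.0,
        "ring_inner": 0.38,
        "ring_outer": 0.46,
    },
    "preprocess": {"disk_radius": 5, "connectivity": 8},
    "split": {"ratios": "60:20:20"},
    "balance": {"mode": "duplicate", "k": 5},
    "gans": {
        "enabled": ["dcgan", "pggan"],
        "per_class": 20,
        "latent_dim": 32,
        "target_resolution": 16,
        "steps": 150,
        "batch_size": 16,
        "learning_rate": 2e-3,
        "fade_fraction": 0.5,
        "cycle_weight": 10.0,
    },
    "classifier": {
        "resolution": 32,
        "mode": "multiclass",
        "epochs": 20,
        "batch_size": 16,
        "learning_rate": 1e-3,
        "dropout": 0.1,
    },
    "evaluate": {"voting_rule": "mean-of-metrics"},
}

def _merge(defaults: dict, given: dict, path: str, problems: list[str]) -> dict:
    out = {}
    for key, dval in defaults.items():
        if key in given:
            gval = given[key]
            if isinstance(dval, dict) and key != "per_class":
                if not isinstance(gval, dict):
                    problems.append(f"{path}{key}: expected a mapping")
                    out[key] = dval
                else:
                    out[key] = _merge(dval, gval, f"{path}{key}.", problems)
            else:
                out[key] = gval
        else:
            out[key] = dval
    for key in given:
        if key not in defaults:
            problems.append(f"{path}{key}: unknown key")
    return out

def validate_config(raw) -> dict:
    """Parse and validate a pipeline config (YAML text, dict, or None).

    Returns the fully defaulted config dict; raises ``ConfigError`` listing
    every problem at once, each with its path into the config.
    """
    if raw is None:
        given = {}
    elif isinstance(raw, str):
        given = yaml.safe_load(raw) or {}
    elif isinstance(raw, dict):
        given = raw
    else:
        raise ConfigError("config must be YAML text or a mapping")
    problems: list[str] = []
    cfg = _merge(DEFAULT_CONFIG, given, "", problems)

    try:
        ds.SplitRatios.parse(str(cfg["split"]["ratios"]))
    except Exception as exc:
        problems.append(f"split.ratios: {exc}")
    if cfg["balance"]["mode"] not in ("duplicate", "smote"):
        problems.append(f"balance.mode: unknown mode {cfg['balance']['mode']!r}")
    for v in cfg["gans"]["enabled"]:
        if v not in ga.VARIANTS:
            problems.append(f"gans.enabled: unknown variant {v!r}")
    try:
        ga._check_resolution(int(cfg["gans"]["target_resolution"]))
    except ConfigError as exc:
        problems.append(f"gans.target_resolution: {exc}")
    try:
        clf.ClassifierConfig(resolution=int(cfg["classifier"]["resolution"]),
                             mode=cfg["classifier"]["mode"],
                             dropout=float(cfg["classifier"]["dropout"]))
    except ConfigError as exc:
        problems.append(f"classifier: {exc}")
    for cls, n in cfg["phantom"]["per_class"].items():
        if cls not in ph.TUMOR_CLASSES or int(n) < 0:
            problems.append(f"phantom.per_class.{cls}: invalid class or count")
    if problems:
        raise ConfigError("invalid config:\n  " + "\n  ".join(problems))
    return cfg

def config_hash(cfg: dict) -> str:
    """Hash of the scientific parameters; the workdir path is excluded so
    the same experiment hashes identically wherever it runs."""
    cfg = {k: v for k, v in cfg.items() if k != "workdir"}
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]

def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed derived from the single global seed."""
    return (int(global_seed) * 1000003 + zlib.crc32(stage.encode())) % (2**31 - 1)

def strip_latency(report: dict) -> dict:
    """Drop latency fields (hardware-dependent) for determinism comparisons."""
    out = json.loads(json.dumps(report))
    for row in out.get("reports", []):
        row.pop("latency_s", None)
    return out

def _write_json(path: str, obj) -> None:
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)

def run_pipeline(config: dict | str | None, resume: bool = False):
    """Execute the full pipeline; returns (VotingResult, report dict).

    Artifacts live under ``config['workdir']``; the final report is written to
    ``<workdir>/voting.json``.  With ``resume=True`` an existing final report
    is returned as-is.
    """
    cfg = validate_config(config)
    work = cfg["workdir"]
    os.makedirs(work, exist_ok=True)
    final_path = os.path.join(work, "voting.json")
    if resume and os.path.exists(final_path):
        logger.info("resume: found completed report %s", final_path)
        with open(final_path) as fh:
            report = json.load(fh)
        vote = ev.VotingResult(**report["vote"])
        return vote, report
    chash = config_hash(cfg)
    _write_json(os.path.join(work, "run.json"),
                {"seed": cfg["seed"], "config_hash": chash, "config": cfg})

    # -- stage 1: phantom cohort -------------------------------------------
    man_path = os.path.join(work, "manifest.csv")
    pcfg = cfg["phantom"]
    if resume and os.path.exists(man_path):
        manifest = ds.read_manifest(man_path)
        logger.info("resume: phantom cohort (%d images)", len(manifest))
    else:
        spec = ph.PhantomSpec(
            image_size=int(pcfg["image_size"]), tumor_radius=float(pcfg["tumor_radius"]),
            noise_sigma=float(pcfg["noise_sigma"]), ring_inner=float(pcfg["ring_inner"]),
            ring_outer=float(pcfg["ring_outer"]), tumor_class="glioma")
        manifest = ph.generate_cohort(
            {k: int(v) for k, v in pcfg["per_class"].items()}, spec,
            os.path.join(work, "phantom"), seed=stage_seed(cfg["seed"], "phantom"))
        ds.write_manifest(manifest, man_path)
        logger.info("phantom: %d images (seed=%d, cfg=%s)",
                    len(manifest), stage_seed(cfg["seed"], "phantom"), chash)

    # -- stage 2: preprocessing --------------------------------------------
    prep_path = os.path.join(work, "preprocessed.csv")
    if resume and os.path.exists(prep_path):
        manifest = ds.read_manifest(prep_path)
        logger.info("resume: preprocessing")
    else:
        out_dir = os.path.join(work, "preprocessed")
        os.makedirs(out_dir, exist_ok=True)
        se_disk = pp.StructuringElement("disk", int(cfg["preprocess"]["disk_radius"]))
        recs = []
        for r in manifest.records:
            img = ds.load_image(r.path)
            stripped, _ = pp.skull_strip(img,
                                         connectivity=int(cfg["preprocess"]["connectivity"]))
            improved = pp.contrast_improve(stripped, se_disk)
            path = os.path.join(out_dir, os.path.basename(r.path))
            ds.save_image(improved, path)
            recs.append(dataclasses.replace(r, path=path))
        manifest = ds.Manifest(recs)
        ds.write_manifest(manifest, prep_path)
        logger.info("preprocess: %d images stripped and contrast-improved",
                    len(manifest))

    # -- stage 3: split ------------------------------------------------------
    ratios = ds.SplitRatios.parse(str(cfg["split"]["ratios"]))
    manifest = ds.split_dataset(manifest, ratios, stage_seed(cfg["seed"], "split"))
    ds.write_manifest(manifest, os.path.join(work, "splits.csv"))

    # -- stage 4: balance ----------------------------------------------------
    manifest, _ = ds.balance_by_oversampling(
        manifest, "train", mode=cfg["balance"]["mode"], k=int(cfg["balance"]["k"]),
        seed=stage_seed(cfg["seed"], "balance"),
        out_dir=os.path.join(work, "smote"))
    ds.write_manifest(manifest, os.path.join(work, "balanced.csv"))
    logger.info("split+balance: train counts %s", manifest.class_counts("train"))

    # -- stage 5: GAN ensemble training + augmentation ----------------------
    gcfg = cfg["gans"]
    variants = list(gcfg["enabled"])
    res = int(gcfg["target_resolution"])
    train_imgs, train_labels = ga.load_train_images(manifest, res)
    classes = sorted(set(train_labels))
    states: dict = {}
    for variant in variants:
        vseed = stage_seed(cfg["seed"], f"gan:{variant}")
        base = dict(variant=variant, latent_dim=int(gcfg["latent_dim"]),
                    target_resolution=res, steps=int(gcfg["steps"]),
                    batch_size=int(gcfg["batch_size"]),
                    learning_rate=float(gcfg["learning_rate"]),
                    fade_fraction=float(gcfg["fade_fraction"]),
                    cycle_weight=float(gcfg["cycle_weight"]))
        if variant in ("conditional", "infogan"):
            config_v = ga.GanConfig(**base, seed=vseed,
                                    n_classes=len(classes), code_dim=len(classes))
            states[variant] = ga.train_gan(config_v, train_imgs, train_labels)
        elif variant == "cyclegan":
            per = {}
            for i, cls in enumerate(classes):
                src = classes[(i - 1) % len(classes)]
                config_v = ga.GanConfig(**base, seed=vseed + i, domains=(src, cls))
                per[cls] = ga.train_gan(config_v, train_imgs, train_labels)
            states[variant] = per
        else:  # dcgan, pggan: one unconditional model per class
            per = {}
            for i, cls in enumerate(classes):
                sel = [j for j, l in enumerate(train_labels) if l == cls]
                config_v = ga.GanConfig(**base, seed=vseed + i)
                model = ga.train_gan(config_v, train_imgs[sel])
                model.class_tag = cls
                per[cls] = model
            states[variant] = per
        logger.info("gan %s: trained (seed=%d)", variant, vseed)

    if variants:
        augmented = ga.augment_dataset(
            manifest, states, int(gcfg["per_class"]),
            os.path.join(work, "augmented"), seed=stage_seed(cfg["seed"], "augment"))
    else:
        augmented = {"baseline": manifest}
        logger.info("no GANs enabled: training a no-augmentation baseline")

    # -- stages 6+7: per-variant classifier + evaluation --------------------
    ccfg = cfg["classifier"]
    reports: list[ev.MetricReport] = []
    test_records = manifest.subset("test").records
    val_records = manifest.subset("validation").records
    for variant, aug_manifest in augmented.items():
        ccfg_v = clf.ClassifierConfig(
            resolution=int(ccfg["resolution"]), mode=ccfg["mode"],
            epochs=int(ccfg["epochs"]), batch_size=int(ccfg["batch_size"]),
            learning_rate=float(ccfg["learning_rate"]),
            dropout=float(ccfg["dropout"]),
            seed=stage_seed(cfg["seed"], f"clf:{variant}"))
        model = clf.train_classifier(ccfg_v, aug_manifest.subset("train").records,
                                     val_records)
        report = ev.timed_evaluate(model, variant, test_records)
        reports.append(report)
        logger.info("classifier %s: accuracy %.3f (latency %.2fs)",
                    variant, report.accuracy, report.latency_s)

    # -- stage 8: soft voting ------------------------------------------------
    vote = ev.soft_vote(reports, rule=cfg["evaluate"]["voting_rule"])
    report = {"seed": cfg["seed"], "config_hash": chash,
              "reports": [r.as_dict() for r in reports],
              "vote": vote.as_dict()}
    _write_json(final_path, report)
    logger.info("soft vote winner: %s", vote.winner)
    return vote, report
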