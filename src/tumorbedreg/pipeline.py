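"""End-to-end registration pipelines and the cross-validation harness.

The full method runs preprocessing, multilevel affine instance
optimization, then one of the nonrigid stages; the affine and nonrigid
fields are composed for end-to-end landmark mapping and evaluation.

Experiment identifiers follow the study shorthand:

===========  ==============================================================
AR           affine instance optimization only
ARRNI        AR + nonrigid instance optimization
ARNIP        ARRNI + tumor volume penalty
ARDN         AR + single-level displacement network, unsupervised
ARDNM        AR + multilevel displacement network, unsupervised
ARDNI        AR + single-level network, symmetric (inverse-consistency)
ARDNP        AR + single-level network with volume penalty
ARDNMP       AR + multilevel network with volume penalty (full method)
===========  ==============================================================
"""

from __future__ import annotations

import logging
import os
import time

import numpy as np

from .affine_registration import AffineConfig, register_affine
from .evaluation import evaluation_report
from .instance_nonrigid import (InstanceNonrigidConfig,
                                register_nonrigid_instance)
from .network import (NetworkConfig, TrainConfig, TrainingPair, infer, train)
from .preprocessing import DEFAULT_SPACING_MM, preprocess_pair
from .transforms import (affine_to_field, apply_affine, compose_fields)
from .volumes_io import (DisplacementField, Image3D, LandmarkSet,
                         SegmentationMask, read_landmarks, read_mask,
                         read_volume)

__all__ = ["METHODS", "LEARNED_METHODS", "run_pipeline", "cross_validate",
           "load_case", "method_configs"]

logger = logging.getLogger("tumorbedreg")

INSTANCE_METHODS = ("AR", "ARRNI", "ARNIP")
LEARNED_METHODS = ("ARDN", "ARDNM", "ARDNI", "ARDNP", "ARDNMP")
METHODS = INSTANCE_METHODS + LEARNED_METHODS

#: (single_level, training objective mode) per learned experiment
_LEARNED_SPEC = {
    "ARDN": (True, "unsupervised"),
    "ARDNM": (False, "unsupervised"),
    "ARDNI": (True, "symmetric"),
    "ARDNP": (True, "volume_penalty"),
    "ARDNMP": (False, "volume_penalty"),
}


def method_configs(method: str, net_cfg: NetworkConfig | None = None,
                   train_cfg: TrainConfig | None = None):
    """Network/training configuration implied by a learned experiment id."""
    single, mode = _LEARNED_SPEC[method]
    net_cfg = net_cfg or NetworkConfig()
    if net_cfg.single_level != single:
        from dataclasses import replace
        net_cfg = replace(net_cfg, single_level=single,
                          channels_per_level=net_cfg.channels_per_level)
    train_cfg = train_cfg or TrainConfig()
    if train_cfg.objective_mode != mode:
        from dataclasses import replace
        train_cfg = replace(train_cfg, objective_mode=mode)
    return net_cfg, train_cfg


def run_pipeline(source: Image3D, target: Image3D, method: str = "ARDNMP",
                 tumor_mask: SegmentationMask | None = None,
                 net=None,
                 moving_landmarks: LandmarkSet | None = None,
                 fixed_landmarks: LandmarkSet | None = None,
                 affine_cfg: AffineConfig | None = None,
                 nonrigid_cfg: InstanceNonrigidConfig | None = None,
                 spacing_mm: float = DEFAULT_SPACING_MM,
                 preprocess: bool = True) -> dict:
    """Run preprocessing, affine and the selected nonrigid stage on a pair.

    Returns a dict with the composed end-to-end ``field`` (fixed grid ->
    moving domain), the ``affine`` transform, the preprocessed volumes and
    an evaluation ``report`` (landmark TRE when landmarks are given, TVR
    and Jacobian statistics when a tumor mask is given). For learned
    methods a trained network must be supplied; the tumor mask is never an
    input to inference — it only enters the evaluation report.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    if method in LEARNED_METHODS and net is None:
        raise ValueError(f"method {method} needs trained network weights")
    if method == "ARNIP" and tumor_mask is None:
        raise ValueError("ARNIP needs a tumor mask")

    t0 = time.perf_counter()
    if preprocess:
        if tumor_mask is not None:
            src, tgt, msk = preprocess_pair(source, target, tumor_mask,
                                            spacing_mm)
        else:
            (src, tgt), msk = preprocess_pair(source, target,
                                              spacing_mm=spacing_mm), None
    else:
        src, tgt, msk = source, target, tumor_mask
    logger.info("preprocessing done in %.2fs", time.perf_counter() - t0)

    t0 = time.perf_counter()
    A = register_affine(src, tgt, affine_cfg)
    u_affine = affine_to_field(A, src)
    src_aligned = apply_affine(src, A)
    msk_aligned = None
    if msk is not None:
        warped = apply_affine(msk, A)
        msk_aligned = SegmentationMask(np.clip(warped.data, 0, 1),
                                       warped.spacing, warped.origin)
    logger.info("affine stage done in %.2fs", time.perf_counter() - t0)

    t0 = time.perf_counter()
    if method == "AR":
        u_total = u_affine
    else:
        if method in INSTANCE_METHODS:
            cfg = nonrigid_cfg or InstanceNonrigidConfig()
            if method == "ARNIP" and not cfg.use_volume_penalty:
                from dataclasses import replace
                cfg = replace(cfg, use_volume_penalty=True)
            if method == "ARRNI" and cfg.use_volume_penalty:
                from dataclasses import replace
                cfg = replace(cfg, use_volume_penalty=False)
            u_nonrigid = register_nonrigid_instance(
                src_aligned, tgt, cfg,
                tumor_mask=msk_aligned if method == "ARNIP" else None)
        else:
            u_nonrigid = infer(src_aligned, tgt, net)
        u_total = compose_fields(u_nonrigid, u_affine)
    logger.info("nonrigid stage (%s) done in %.2fs", method,
                time.perf_counter() - t0)

    report = evaluation_report(u_total, moving_landmarks, fixed_landmarks,
                               mask=msk)
    report["method"] = method
    return {"field": u_total, "affine": A, "source": src, "target": tgt,
            "mask": msk, "report": report}


# ---------------------------------------------------------------------------
# Leave-one-out cross-validation over a phantom (or clinical) dataset
# ---------------------------------------------------------------------------

def load_case(case_dir) -> dict:
    """Load one on-disk case (source, target, mask, landmarks)."""
    d = str(case_dir)
    case = {
        "id": os.path.basename(d.rstrip("/")),
        "source": read_volume(os.path.join(d, "source.nii.gz")),
        "target": read_volume(os.path.join(d, "target.nii.gz")),
    }
    mask_path = os.path.join(d, "tumor_mask.nii.gz")
    case["mask"] = read_mask(mask_path) if os.path.exists(mask_path) else None
    for key, name in (("landmarks_source", "landmarks_source.csv"),
                      ("landmarks_target", "landmarks_target.csv")):
        path = os.path.join(d, name)
        case[key] = read_landmarks(path) if os.path.exists(path) else None
    return case


def _case_dirs(dataset_dir):
    entries = sorted(e for e in os.listdir(dataset_dir)
                     if e.startswith("case_")
                     and os.path.isdir(os.path.join(dataset_dir, e)))
    return [os.path.join(dataset_dir, e) for e in entries]


def _aligned_training_pair(case, affine_cfg, spacing_mm) -> TrainingPair:
    """Preprocess + affine-align one case for network training (offline)."""
    if case["mask"] is not None:
        src, tgt, msk = preprocess_pair(case["source"], case["target"],
                                        case["mask"], spacing_mm)
    else:
        src, tgt = preprocess_pair(case["source"], case["target"],
                                   spacing_mm=spacing_mm)
        msk = None
    A = register_affine(src, tgt, affine_cfg)
    src_aligned = apply_affine(src, A)
    if msk is not None:
        warped = apply_affine(msk, A)
        msk = SegmentationMask(np.clip(warped.data, 0, 1), warped.spacing,
                               warped.origin)
    return TrainingPair(src_aligned, tgt, msk, pair_id=case["id"])


def cross_validate(dataset_dir, method: str = "ARDNMP",
                   net_cfg: NetworkConfig | None = None,
                   train_cfg: TrainConfig | None = None,
                   n_folds: int | None = None,
                   affine_cfg: AffineConfig | None = None,
                   nonrigid_cfg: InstanceNonrigidConfig | None = None,
                   spacing_mm: float = DEFAULT_SPACING_MM,
                   case_loader=load_case) -> dict:
    """Leave-one-out cross-validation of one experiment over a dataset.

    Each fold holds out one case as the test pair; for learned methods the
    remaining cases are split 80/20 into training and validation sets
    (seeded by ``train_cfg.seed``) and a network is trained from scratch.
    Test metrics are pooled across folds; every fold shares the same
    hyperparameters. Test-case data is never passed to training.
    """
    dirs = _case_dirs(dataset_dir)
    if len(dirs) < 3:
        raise ValueError("cross-validation needs at least 3 cases")
    if n_folds is None:
        n_folds = len(dirs)
    if not 3 <= n_folds <= len(dirs):
        raise ValueError("n_folds must lie in [3, n_cases]")

    fold_reports = []
    pooled = []
    tvrs = []
    train_cache: dict[str, TrainingPair] = {}
    for f in range(n_folds):
        test_dir = dirs[f]
        test_case = None
        net = None
        if method in LEARNED_METHODS:
            ncfg, tcfg = method_configs(method, net_cfg, train_cfg)
            pairs = []
            for d in dirs:
                if d == test_dir:
                    continue
                if d not in train_cache:
                    train_cache[d] = _aligned_training_pair(
                        case_loader(d), affine_cfg, spacing_mm)
                pairs.append(train_cache[d])
            net, _ = train(pairs, ncfg, tcfg)
        test_case = case_loader(test_dir)
        result = run_pipeline(
            test_case["source"], test_case["target"], method,
            tumor_mask=test_case["mask"], net=net,
            moving_landmarks=test_case["landmarks_source"],
            fixed_landmarks=test_case["landmarks_target"],
            affine_cfg=affine_cfg, nonrigid_cfg=nonrigid_cfg,
            spacing_mm=spacing_mm)
        rep = result["report"]
        rep["case"] = test_case["id"]
        fold_reports.append(rep)
        pooled.extend(rep.get("tre_per_landmark_mm", []))
        if "tvr" in rep:
            tvrs.append(rep["tvr"])
        logger.info("fold %d/%d (%s) done", f + 1, n_folds, test_case["id"])

    summary = {"method": method, "n_folds": n_folds}
    if pooled:
        arr = np.asarray(pooled)
        summary["tre_mm"] = {"mean": float(arr.mean()),
                             "median": float(np.median(arr)),
                             "n": int(arr.size)}
    if tvrs:
        summary["tvr"] = {"mean": float(np.mean(tvrs)),
                          "median": float(np.median(tvrs))}
    return {"folds": fold_reports, "summary": summary}
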