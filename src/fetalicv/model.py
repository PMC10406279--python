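"""Brain-model construction, the two registration pipelines, and consensus ICV.

The measurement principle is atlas-based label propagation: an average brain
model (template image + reference ICV mask) is registered to a subject's 3D
ultrasound volume through a staged pipeline of linear then B-spline free-form
registrations; the chain's inverse carries the model's ICV mask onto the
subject grid, and the ICV is the propagated mask's voxel count times the
voxel volume.

Two independently parameterized pipeline variants are run per subject:

* ``minc_style`` - four "affine" stages (each a translation+rotation
  initialization folded into a full affine optimization) followed by three
  B-spline stages.  At every stage both the model and the subject are
  registered to the average image formed at the previous stage; at the first
  stage the model itself is the target (so the model's own registration is
  the identity and the subject's first target is the model).
* ``elastix_style`` - a translation stage, then a rigid stage (escalated to a
  similarity - rotation + global scaling - stage when the rigid result fails
  the overlap-similarity check, as happens for large model/subject size
  differences), then the same average-template scheme with four B-spline
  stages.

The final ICV is the mean of the two variants' values; their standard
deviation and the elastix-style final overlap similarity feed the QC gates.
Model construction follows the same average-template scheme, seeded by one
cohort member, with four B-spline rounds, and returns the arithmetic mean of
all registered subjects.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from . import qc as _qc
from .registration import RegistrationParams, register
from .transforms import (LinearTransform, TransformChain, apply_transform,
                         compose, invert, warp_mask)
from .volume import BinaryMask, Geometry, Volume, replace_zero_voxels

__all__ = [
    "BrainModel",
    "PipelineConfig",
    "ICVResult",
    "ConsensusResult",
    "build_model",
    "attach_consensus_mask",
    "run_pipeline",
    "measure_icv_consensus",
    "default_pipeline_config",
    "default_retry_policy",
]

MINC_N_AFFINE = 4      # minc-style: four "affine" stages ...
MINC_N_BSPLINE = 3     # ... then three B-spline stages
ELASTIX_N_BSPLINE = 4  # elastix-style: translation, rigid, four B-spline
MODEL_N_AFFINE = 4     # model building: affine rounds ...
MODEL_N_BSPLINE = 4    # ... then four B-spline rounds


@dataclass
class BrainModel:
    """Average template plus its reference ICV mask."""

    template: Volume
    icv_mask: BinaryMask | None
    age_group_label: str = ""
    orientation_label: str = "unknown"
    n_subjects: int = 0

    def __post_init__(self) -> None:
        if self.icv_mask is not None:
            if not self.template.same_geometry(self.icv_mask):
                raise ValueError("template and ICV mask must share geometry")
            if self.icv_mask.voxel_count == 0:
                raise ValueError("model ICV mask is empty")


@dataclass
class PipelineConfig:
    """One variant's fixed stage plan with per-stage registration parameters."""

    variant: str
    stage_params: dict
    similarity_floor: float = _qc.SIMILARITY_FLOOR  # rigid->similarity escalation
    label: str = "default"

    def __post_init__(self) -> None:
        if self.variant not in ("minc_style", "elastix_style"):
            raise ValueError(f"unknown pipeline variant {self.variant!r}")
        missing = [s for s in self.stage_names() if s not in self.stage_params]
        if missing:
            raise ValueError(f"missing stage parameter blocks: {missing}")

    def stage_names(self) -> list[str]:
        if self.variant == "minc_style":
            return ([f"affine_{i}" for i in range(MINC_N_AFFINE)]
                    + [f"bspline_{i}" for i in range(MINC_N_BSPLINE)])
        return (["translation", "rigid", "similarity"]
                + [f"bspline_{i}" for i in range(ELASTIX_N_BSPLINE)])

    def params(self, stage: str) -> RegistrationParams:
        return self.stage_params[stage]


@dataclass
class ICVResult:
    """One pipeline variant's measurement for one subject."""

    icv_cm3: float
    pipeline_variant: str
    transform_chain: TransformChain       # subject grid -> model space
    subject_mask: BinaryMask              # propagated ICV mask, subject grid
    final_average: Volume                 # registration average, last stage
    final_warped_subject: Volume | None = None
    similarity: float | None = None       # elastix-style last-stage check
    converged: bool = True
    stage_log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.icv_cm3 <= 0:
            raise ValueError("measured ICV must be positive")
        expected = self.subject_mask.volume_cm3
        if abs(self.icv_cm3 - expected) > 1e-9:
            raise ValueError("icv_cm3 must equal mask voxel count x voxel volume")


@dataclass
class ConsensusResult:
    """Dual-pipeline consensus for one subject."""

    result_minc_style: ICVResult | None
    result_elastix_style: ICVResult | None
    mean_icv_cm3: float
    sd_icv_cm3: float
    similarity_score: float | None
    qc: _qc.QCDecision
    presets_used: dict = field(default_factory=dict)
    attempts: int = 1


# ---------------------------------------------------------------------------
# Default configurations


def _fast_kwargs(speed: str) -> dict:
    if speed == "fast":
        return dict(pyramid_schedule=(2.0, 0.0), max_iterations=20,
                    sample_fraction=0.12)
    if speed == "full":
        return dict(pyramid_schedule=(4.0, 2.0, 1.0, 0.0), max_iterations=50,
                    sample_fraction=None)
    raise ValueError(f"unknown speed preset {speed!r}")


def default_pipeline_config(variant: str, speed: str = "fast",
                            seed: int = 0) -> PipelineConfig:
    """Stock per-stage parameters for a pipeline variant.

    The two variants deliberately differ in optimizer (standard vs adaptive
    gradient descent) and in the B-spline stage metric (normalized cross
    correlation vs sum of squared differences) so their errors stay
    decoupled, which is what gives the consensus SD its diagnostic value.
    ``speed="fast"`` uses a short two-level blurring schedule and voxel
    subsampling sized for 48^3 phantoms; ``"full"`` uses the four-level
    schedule.
    """
    kw = _fast_kwargs(speed)
    opt = "standard_gd" if variant == "minc_style" else "adaptive_gd"
    bspline_metric = "ncc" if variant == "minc_style" else "ssd"
    stages = {}
    names = (([f"affine_{i}" for i in range(MINC_N_AFFINE)]
              + [f"bspline_{i}" for i in range(MINC_N_BSPLINE)])
             if variant == "minc_style" else
             (["translation", "rigid", "similarity"]
              + [f"bspline_{i}" for i in range(ELASTIX_N_BSPLINE)]))
    for i, name in enumerate(names):
        family = ("bspline" if name.startswith("bspline")
                  else "affine" if name.startswith("affine")
                  else name)
        p = RegistrationParams(
            family=family, optimizer=opt, seed=seed + 101 * i, **kw)
        if family == "bspline":
            # the variants also differ in deformability: the minc-style
            # B-splines are stiff (coarse control grid), the elastix-style
            # ones floppy (fine grid, more iterations) - a third axis of
            # decoupling between the two implementations
            if variant == "minc_style":
                p = p.with_(metric=bspline_metric, bspline_grid_spacing=8.0)
            else:
                p = p.with_(metric=bspline_metric, bspline_grid_spacing=5.0,
                            max_iterations=max(p.max_iterations, 30))
        stages[name] = p
    return PipelineConfig(variant=variant, stage_params=stages)


def model_build_params(speed: str = "fast", seed: int = 0) -> dict:
    """Per-stage parameters for groupwise model construction."""
    kw = _fast_kwargs(speed)
    out = {}
    for i in range(MODEL_N_AFFINE):
        out[f"affine_{i}"] = RegistrationParams(
            family="affine", optimizer="adaptive_gd", seed=seed + 11 * i, **kw)
    for i in range(MODEL_N_BSPLINE):
        out[f"bspline_{i}"] = RegistrationParams(
            family="bspline", optimizer="adaptive_gd",
            seed=seed + 11 * (MODEL_N_AFFINE + i), **kw)
    return out


def _preset_blur(config: PipelineConfig) -> PipelineConfig:
    """minc-style fallback: pre-blur the affine stages (sigma 2 voxels)."""
    cfg = copy.deepcopy(config)
    for name, p in cfg.stage_params.items():
        if name.startswith("affine"):
            cfg.stage_params[name] = p.with_(pre_blur_sigma=2.0)
    cfg.label = "pre_blur"
    return cfg


def _preset_standard_gd(config: PipelineConfig) -> PipelineConfig:
    """elastix-style fallback 1: standard gradient descent with doubled sp_a."""
    cfg = copy.deepcopy(config)
    for name, p in cfg.stage_params.items():
        cfg.stage_params[name] = p.with_(optimizer="standard_gd",
                                         sp_a=2.0 * p.sp_a)
    cfg.label = "standard_gd_2x"
    return cfg


def _preset_force_similarity(config: PipelineConfig) -> PipelineConfig:
    """elastix-style fallback 2: force the rigid stage up to similarity."""
    cfg = copy.deepcopy(config)
    cfg.similarity_floor = 1.1  # escalation check can never pass -> similarity
    cfg.label = "force_similarity"
    return cfg


def default_retry_policy() -> dict:
    """Fallback parameter presets per variant (at most two rounds)."""
    return {
        "minc_style": [_preset_blur],
        "elastix_style": [_preset_standard_gd, _preset_force_similarity],
    }


# ---------------------------------------------------------------------------
# Shared stage machinery


def _identity_chain() -> TransformChain:
    return TransformChain([LinearTransform.identity()])


def _mean_volume(volumes: list[Volume], geom: Geometry) -> Volume:
    data = np.mean([v.data for v in volumes], axis=0)
    return Volume(data, geom.spacing, geom.origin,
                  orientation_label=volumes[0].orientation_label)


def _ensure_preprocessed(v: Volume) -> Volume:
    """Apply the zero-voxel replacement if padding zeros are still present."""
    if (v.data == 0).any() and (v.data != 0).any():
        return replace_zero_voxels(v)
    return v


def _register_stage(fixed: Volume, moving: Volume, chain: TransformChain,
                    params: RegistrationParams, geom: Geometry,
                    full_init: bool = False, initial_transform=None):
    """Register the chain-warped moving image to ``fixed``; extend the chain.

    ``full_init`` folds a translation + rigid initialization into an affine
    stage (the "affine" stages of the minc-style plan include translation
    and rotation).  Returns (new_chain, stage_record).
    """
    warped = apply_transform(moving, chain, target_geometry=geom)
    if params.family == "affine" and full_init:
        t_tr = register(fixed, warped, params.with_(family="translation"))
        t_rg = register(fixed, warped, params.with_(family="rigid"),
                        initial_transform=t_tr.transform)
        res = register(fixed, warped, params,
                       initial_transform=t_rg.transform)
    elif initial_transform is not None and params.family != "bspline":
        res = register(fixed, warped, params,
                       initial_transform=initial_transform)
    else:
        res = register(fixed, warped, params)
    rec = {"family": params.family, "metric": res.final_metric,
           "iterations": res.iterations_used, "converged": res.converged}
    return chain.prepended(res.transform), rec


# ---------------------------------------------------------------------------
# Groupwise model construction


def build_model(scans: list[Volume], params: dict | None = None,
                masks: list[BinaryMask] | None = None,
                age_group_label: str = "", seed_index: int = 0,
                speed: str = "fast", seed: int = 0) -> BrainModel:
    """Construct an average brain model from a cohort of scans.

    Stage 0 registers every scan (affine) to a designated seed scan and
    averages; subsequent affine rounds and four B-spline rounds register
    every scan to the previous round's average and re-average, sharpening
    the template.  The returned template is the final arithmetic-mean image.

    If per-subject ICV masks are supplied, a reference model mask is attached
    by propagating every mask onto the template grid through its subject's
    chain, majority-voting, and median-smoothing.
    """
    if len(scans) < 2:
        raise ValueError("model construction needs at least 2 scans")
    orientations = {s.orientation_label for s in scans}
    if len(orientations) != 1:
        raise ValueError(f"mixed scan orientations {sorted(orientations)}; "
                         "canonicalize first")
    if params is None:
        params = model_build_params(speed=speed, seed=seed)
    scans = [_ensure_preprocessed(s) for s in scans]
    geom = scans[seed_index].geometry()
    chains = [_identity_chain() for _ in scans]

    stage_names = ([f"affine_{i}" for i in range(MODEL_N_AFFINE)]
                   + [f"bspline_{i}" for i in range(MODEL_N_BSPLINE)])
    target = scans[seed_index]
    for si, name in enumerate(stage_names):
        p = params[name]
        new_chains = []
        for i, scan in enumerate(scans):
            if si == 0 and i == seed_index:
                new_chains.append(chains[i])  # seed registers to itself
                continue
            try:
                ch, _ = _register_stage(target, scan, chains[i], p, geom,
                                        full_init=(si == 0))
            except Exception as exc:
                raise RuntimeError(
                    f"model build failed at stage {name} (#{si}), "
                    f"scan {i}: {exc}") from exc
            new_chains.append(ch)
        chains = new_chains
        warped = [apply_transform(s, c, target_geometry=geom)
                  for s, c in zip(scans, chains)]
        target = _mean_volume(warped, geom)

    model = BrainModel(template=target, icv_mask=None,
                       age_group_label=age_group_label,
                       orientation_label=scans[0].orientation_label,
                       n_subjects=len(scans))
    if masks is not None:
        model = attach_consensus_mask(model, masks, chains)
    return model


def attach_consensus_mask(model: BrainModel, masks: list[BinaryMask],
                          chains: list[TransformChain]) -> BrainModel:
    """Attach a model ICV mask by majority vote of propagated subject masks."""
    geom = model.template.geometry()
    votes = []
    for m, c in zip(masks, chains):
        w = apply_transform(Volume(m.data.astype(float), m.spacing, m.origin),
                            c, target_geometry=geom, cval=0.0)
        votes.append(w.data)
    consensus = (np.mean(votes, axis=0) >= 0.5).astype(np.uint8)
    mask = BinaryMask(consensus, geom.spacing, geom.origin,
                      orientation_label=model.orientation_label)
    mask = _qc.smooth_mask(mask)
    return BrainModel(model.template, mask, model.age_group_label,
                      model.orientation_label, model.n_subjects)


# ---------------------------------------------------------------------------
# Measurement pipelines


def _propagate_icv(subject: Volume, model: BrainModel,
                   subj_chain: TransformChain, model_chain: TransformChain
                   ) -> BinaryMask:
    """Warp the model ICV mask onto the subject grid through the inverse
    of the subject's accumulated transform (then the model's forward one)."""
    subj_total = compose(subj_chain)
    model_total = compose(model_chain)
    inv_subj = invert(subj_total)
    prop = TransformChain([*inv_subj.transforms, *model_total.transforms])
    return warp_mask(model.icv_mask, prop, target_geometry=subject.geometry())


def run_pipeline(subject: Volume, model: BrainModel,
                 config: PipelineConfig) -> ICVResult:
    """Measure one subject's ICV with one pipeline variant.

    Executes the variant's stage plan, rebuilding the model/subject average
    after every stage as the next stage's target, then propagates the model
    ICV mask through the inverse of the subject's accumulated transform and
    counts voxels on the subject grid.
    """
    if model.icv_mask is None:
        raise ValueError("model has no ICV mask attached")
    if subject.orientation_label != model.orientation_label:
        raise ValueError(
            f"orientation mismatch: subject {subject.orientation_label!r} vs "
            f"model {model.orientation_label!r}; canonicalize the subject "
            "or use the matching-orientation model")
    subject = _ensure_preprocessed(subject)
    geom = model.template.geometry()
    subj_chain = _identity_chain()
    model_chain = _identity_chain()
    log: list = []
    converged = True

    def stage(name, fixed, full_init=False, side="subject"):
        nonlocal subj_chain, model_chain, converged
        p = config.params(name)
        if side == "subject":
            subj_chain, rec = _register_stage(fixed, subject, subj_chain, p,
                                              geom, full_init)
        else:
            model_chain, rec = _register_stage(fixed, model.template,
                                               model_chain, p, geom, full_init)
        rec["stage"] = name
        rec["side"] = side
        log.append(rec)
        converged = converged and rec["converged"]

    if config.variant == "minc_style":
        # stage 0 target is the model itself; the model's own registration to
        # itself is the identity, so only the subject moves at stage 0
        target = model.template
        for i in range(MINC_N_AFFINE):
            stage(f"affine_{i}", target, full_init=(i == 0), side="subject")
            if i > 0:
                stage(f"affine_{i}", target, side="model")
            target = _stage_average(subject, model, subj_chain, model_chain, geom)
        for i in range(MINC_N_BSPLINE):
            stage(f"bspline_{i}", target, side="subject")
            stage(f"bspline_{i}", target, side="model")
            target = _stage_average(subject, model, subj_chain, model_chain, geom)
    else:
        stage("translation", model.template, side="subject")
        pre_rigid_chain = subj_chain
        stage("rigid", model.template, side="subject")
        warped = apply_transform(subject, subj_chain, target_geometry=geom)
        # the escalation check is computed on background-suppressed images so
        # it reflects cranial-shell alignment rather than the (dominant,
        # uniform) background: a subject whose ICV differs markedly in size
        # from the model's fails it after the rigid stage and is retried
        # with rotation + global scaling
        sim_rigid = _qc.overlap_similarity(_suppress_background(warped),
                                           _suppress_background(model.template))
        if sim_rigid < config.similarity_floor:
            # large size difference: escalate to rotation + global scaling,
            # initialized from the rigid pose so only the scale is new
            rigid_t = subj_chain.transforms[0]
            subj_chain = pre_rigid_chain
            log.append({"stage": "rigid", "escalated": True,
                        "similarity": sim_rigid})
            p = config.params("similarity")
            subj_chain, rec = _register_stage(
                model.template, subject, subj_chain, p, geom,
                initial_transform=rigid_t)
            rec.update(stage="similarity", side="subject")
            log.append(rec)
            converged = converged and rec["converged"]
        target = _stage_average(subject, model, subj_chain, model_chain, geom)
        for i in range(ELASTIX_N_BSPLINE):
            stage(f"bspline_{i}", target, side="subject")
            stage(f"bspline_{i}", target, side="model")
            target = _stage_average(subject, model, subj_chain, model_chain, geom)

    final_average = target
    mask = _propagate_icv(subject, model, subj_chain, model_chain)
    if mask.voxel_count == 0:
        raise RuntimeError(
            f"{config.variant}: propagated ICV mask is empty (registration "
            "failed outright)")
    warped_subject = apply_transform(subject, subj_chain, target_geometry=geom)
    similarity = None
    if config.variant == "elastix_style":
        similarity = _qc.overlap_similarity(warped_subject, final_average)
    subj_total = compose(subj_chain)
    model_total = compose(model_chain)
    full_chain = TransformChain([*invert(subj_total).transforms,
                                 *model_total.transforms])
    return ICVResult(
        icv_cm3=mask.volume_cm3, pipeline_variant=config.variant,
        transform_chain=full_chain, subject_mask=mask,
        final_average=final_average, final_warped_subject=warped_subject,
        similarity=similarity, converged=converged, stage_log=log)


def _suppress_background(v: Volume) -> Volume:
    """Clip a volume at its median so image energy concentrates in the head.

    Most voxels of a preprocessed sweep are flat background at the zero-fill
    gray level; subtracting the median and clipping at zero leaves the bright
    cranial shell and interior structure, which is what alignment checks
    should respond to.
    """
    med = float(np.median(v.data))
    out = np.clip(v.data - med, 0.0, None)
    if not out.any():
        return v
    return Volume(out, v.spacing, v.origin,
                  orientation_label=v.orientation_label)


def _stage_average(subject, model, subj_chain, model_chain, geom) -> Volume:
    ws = apply_transform(subject, subj_chain, target_geometry=geom)
    wm = apply_transform(model.template, model_chain, target_geometry=geom)
    return _mean_volume([ws, wm], geom)


# ---------------------------------------------------------------------------
# Consensus measurement with retry-then-exclude QC


def measure_icv_consensus(subject: Volume, model: BrainModel,
                          config_minc: PipelineConfig | None = None,
                          config_elastix: PipelineConfig | None = None,
                          retry_policy: dict | None = None,
                          qc_rule: str = "fraction_of_mean",
                          qc_threshold: float = 0.10,
                          similarity_floor: float = _qc.SIMILARITY_FLOOR,
                          seed: int = 0) -> ConsensusResult:
    """Run both pipeline variants independently and apply the consensus QC.

    The final ICV is the mean of the two variants' values.  If the two-value
    SD exceeds the gate (or the elastix-style overlap similarity falls below
    the floor), the offending variant(s) are re-run with fallback parameter
    presets - at most two rounds - after which the subject is marked
    excluded.  Exclusion is a recorded verdict, not an error.
    """
    config_minc = config_minc or default_pipeline_config("minc_style", seed=seed)
    config_elastix = config_elastix or default_pipeline_config("elastix_style",
                                                               seed=seed)
    if retry_policy is None:
        retry_policy = default_retry_policy()
    presets_m = list(retry_policy.get("minc_style", []))[:2]
    presets_e = list(retry_policy.get("elastix_style", []))[:2]

    def try_run(cfg):
        try:
            return run_pipeline(subject, model, cfg), None
        except (RuntimeError, ValueError) as exc:
            return None, str(exc)

    res_m, err_m = try_run(config_minc)
    res_e, err_e = try_run(config_elastix)
    presets_used = {"minc_style": config_minc.label,
                    "elastix_style": config_elastix.label}

    attempts = 1
    decision = None
    for round_idx in range(3):  # initial + at most two fallback rounds
        if res_m is None and res_e is None:
            decision = _qc.QCDecision(
                sd_value=float("nan"), sd_threshold=0.0, threshold_rule=qc_rule,
                verdict="excluded",
                reason=f"both variants failed: minc: {err_m}; elastix: {err_e}")
            return ConsensusResult(None, None, float("nan"), float("nan"),
                                   None, decision, presets_used, attempts)
        sim = res_e.similarity if res_e is not None else None
        sim_ok = sim is None or _qc.similarity_gate(sim, similarity_floor)
        if res_m is not None and res_e is not None:
            decision = _qc.sd_gate(res_m.icv_cm3, res_e.icv_cm3, qc_rule,
                                   qc_threshold)
            decision.similarity = sim
            if decision.verdict == "pass" and not sim_ok:
                decision.verdict = "retry"
                decision.reason = (f"elastix-style overlap similarity "
                                   f"{sim:.3f} below floor {similarity_floor}")
            if decision.verdict == "pass":
                break
        else:
            fails = "; ".join(f"{k}: {e}" for k, e in
                              (("minc_style", err_m), ("elastix_style", err_e))
                              if e is not None)
            decision = _qc.QCDecision(
                sd_value=float("nan"), sd_threshold=0.0, threshold_rule=qc_rule,
                similarity=sim, verdict="retry",
                reason=f"variant failed: {fails}")
        # decide which variant(s) to re-run with the next preset
        redo_e = (res_e is None) or (not sim_ok) or res_m is not None
        redo_m = (res_m is None) or (res_m is not None and res_e is not None
                                     and sim_ok)
        progressed = False
        if redo_e and presets_e:
            cfg = presets_e.pop(0)(config_elastix)
            presets_used["elastix_style"] = cfg.label
            res_e, err_e = try_run(cfg)
            progressed = True
        if redo_m and presets_m:
            cfg = presets_m.pop(0)(config_minc)
            presets_used["minc_style"] = cfg.label
            res_m, err_m = try_run(cfg)
            progressed = True
        if not progressed:
            decision.verdict = "excluded"
            if not decision.reason:
                decision.reason = "QC gate failed and fallback presets exhausted"
            break
        attempts += 1
    else:
        decision.verdict = "excluded"

    if res_m is not None and res_e is not None:
        mean = (res_m.icv_cm3 + res_e.icv_cm3) / 2.0
        sd = _qc.two_value_sd(res_m.icv_cm3, res_e.icv_cm3)
    else:
        mean, sd = float("nan"), float("nan")
    sim = res_e.similarity if res_e is not None else None
    return ConsensusResult(res_m, res_e, mean, sd, sim, decision,
                           presets_used, attempts)
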