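"""End-to-end orchestration of the coupling analysis on a synthetic cohort.

``run_pipeline`` executes simulate -> EFP -> voxel-wise GLM -> ROI
selection -> sliding-window permutation test -> reactivity coupling and
writes per-stage outputs plus a JSON manifest recording the master
seed, configuration hash and output paths, so a rerun with the same
configuration reproduces every numeric output exactly.

ROI selection runs on a separate, shorter selection run generated for
each subject (distinct from the run used for the coupling tests), as
the analysis design requires.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .efp import EFPModel, compute_efp_timecourse, demo_model, preprocess_eeg
from .glm import GLMConfig, first_level_glm, group_one_sample
from .io import save_efp_timecourse, save_json, save_ratings
from .reactivity import (
    correlate_reactivity_efp,
    efp_amplitude,
    reactivity_index,
    scene_difference_tests,
)
from .roi import ROISelectionConfig, SeedSpec, select_for_subject
from .swtest import SWConfig, above_chance_fraction, window_sweep
from .synthetic import CohortConfig, CouplingSpec, simulate_cohort, simulate_subject
from .timeline import build_run_timeline

log = logging.getLogger("efpcouple")

__all__ = ["PipelineConfig", "run_pipeline", "demo_config"]


@dataclass
class PipelineConfig:
    """Configuration of a full synthetic-cohort pipeline run."""

    n_subjects: int = 6
    master_seed: int = 0
    output_dir: str = "efpcouple-out"
    template: CouplingSpec = field(default_factory=CouplingSpec)
    between_subject_sd: float = 0.1
    cohort: CohortConfig = field(default_factory=CohortConfig)
    glm: GLMConfig = field(default_factory=GLMConfig)
    sw: SWConfig = field(default_factory=SWConfig)
    roi: ROISelectionConfig = field(default_factory=ROISelectionConfig)
    seed_sphere: SeedSpec = field(default_factory=SeedSpec)
    windows: tuple = (30,)
    model_path: str | None = None  # None -> bundled synthetic demo model
    scene_pair: tuple = ("snakes", "farewell")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in raw:
                continue
            val = raw[f.name]
            if f.name == "template":
                val = CouplingSpec(**val)
            elif f.name == "cohort":
                run = val.pop("run", None)
                val = CohortConfig(**val)
                if run is not None:
                    val.run = build_run_timeline(run if isinstance(run, str) else [tuple(b) for b in run])
            elif f.name == "glm":
                val = GLMConfig(**val)
            elif f.name == "sw":
                val = SWConfig(**val)
            elif f.name == "roi":
                val = ROISelectionConfig(**val)
            elif f.name == "seed_sphere":
                val = SeedSpec(**val)
            elif f.name in ("windows", "scene_pair"):
                val = tuple(val)
            kwargs[f.name] = val
        return cls(**kwargs)

    def config_hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return {f.name: enc(getattr(o, f.name)) for f in dataclasses.fields(o)}
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (tuple, list)):
                return [enc(v) for v in o]
            return o
        blob = json.dumps(enc(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def demo_config(output_dir: str, n_subjects: int = 6, master_seed: int = 0) -> PipelineConfig:
    """Small, fast configuration: 300-s run (200 volumes), 6 subjects."""
    run = build_run_timeline(
        [("fixation", 5.0), ("farewell", 150.0), ("fixation", 10.0),
         ("snakes", 120.0), ("fixation", 15.0)]
    )
    cohort = CohortConfig(run=run, n_brain_voxels=60, n_target_voxels=40)
    return PipelineConfig(
        n_subjects=n_subjects,
        master_seed=master_seed,
        output_dir=output_dir,
        cohort=cohort,
        sw=SWConfig(window_trs=30, n_perm=50, rng_seed=master_seed),
    )


def _selection_run(cfg: CohortConfig) -> CohortConfig:
    """Shorter companion run used only for seed-based ROI selection."""
    run = build_run_timeline(
        [("fixation", 5.0), ("snakes", 110.0), ("fixation", 15.0),
         ("farewell", 55.0), ("fixation", 15.0)]
    )
    return dataclasses.replace(cfg, run=run)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage; return (and write) the run manifest."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package_version": __version__,
        "master_seed": cfg.master_seed,
        "config_hash": cfg.config_hash(),
        "stages": {},
    }

    # ---- model -----------------------------------------------------------
    if cfg.model_path is not None:
        model_file = Path(cfg.model_path)
        if not model_file.exists():
            raise FileNotFoundError(f"EFP model file not found: {model_file}")
        model = EFPModel.load(model_file)
    else:
        model = demo_model(carrier_band=cfg.cohort.carrier_band)

    def stage(name):
        t0 = time.perf_counter()
        log.info("stage %s started", name)
        return t0

    def done(name, t0, outputs):
        log.info("stage %s finished in %.1f s", name, time.perf_counter() - t0)
        manifest["stages"][name] = {"outputs": [str(p) for p in outputs]}

    try:
        # ---- simulate ----------------------------------------------------
        t0 = stage("simulate")
        subjects = simulate_cohort(
            cfg.n_subjects, cfg.template, cfg.between_subject_sd,
            rng_seed=cfg.master_seed, cfg=cfg.cohort,
        )
        sel_cfg = _selection_run(cfg.cohort)
        selection = [
            simulate_subject(
                s.subject_id, s.truth, int(np.random.SeedSequence([s.rng_seed, 7]).generate_state(1)[0] % 2**31),
                cfg=sel_cfg, with_eeg=False, with_ratings=False,
            )
            for s in subjects
        ]
        cohort_manifest = out / "cohort.json"
        save_json(
            {
                "subjects": [
                    {"subject_id": s.subject_id, "rng_seed": s.rng_seed,
                     "truth": dataclasses.asdict(s.truth),
                     "scene_levels": s.scene_levels}
                    for s in subjects
                ]
            },
            cohort_manifest,
        )
        for s in subjects:
            save_ratings(s.ratings, out / f"{s.subject_id}_ratings.tsv", subject_id=s.subject_id)
        done("simulate", t0, [cohort_manifest])

        # ---- efp ---------------------------------------------------------
        t0 = stage("efp")
        efps = {}
        efp_paths = []
        for s in subjects:
            rec = preprocess_eeg(s.eeg)
            efps[s.subject_id] = compute_efp_timecourse(rec, model, stride_s=cfg.cohort.tr)
            p = out / f"{s.subject_id}_efp.tsv"
            save_efp_timecourse(efps[s.subject_id], p)
            efp_paths.append(p)
        done("efp", t0, efp_paths)

        # ---- glm ---------------------------------------------------------
        t0 = stage("glm")
        maps = [first_level_glm(s.bold, efps[s.subject_id], cfg.glm) for s in subjects]
        group = group_one_sample(maps)
        glm_path = out / "glm_group.tsv"
        pd.DataFrame(
            {"t": group.t, "p": group.p, "q": group.q, "sig": group.sig_mask}
        ).to_csv(glm_path, sep="\t", index=False, float_format="%.17g")
        done("glm", t0, [glm_path])

        # ---- roi ---------------------------------------------------------
        t0 = stage("roi")
        selections = {}
        roi_rows = []
        for s in selection:
            res = select_for_subject(s.bold, cfg.seed_sphere, cfg.roi)
            selections[s.subject_id] = res
            roi_rows.append((s.subject_id, res.n_salience, res.n_nonsalience))
        roi_path = out / "roi_selection.tsv"
        pd.DataFrame(roi_rows, columns=["subject", "n_salience", "n_nonsalience"]).to_csv(
            roi_path, sep="\t", index=False
        )
        done("roi", t0, [roi_path])

        # ---- swtest ------------------------------------------------------
        t0 = stage("swtest")
        per_subject = {}
        target_idx = {s.subject_id: s.bold.mask_indices(cfg.roi.target_mask_label) for s in subjects}
        for s in subjects:
            sel = selections[s.subject_id]
            vol_idx, efp_vals = _aligned(efps[s.subject_id], s.bold)
            entry = {}
            for cluster, members in (
                ("salience", sel.salience_voxels),
                ("nonsalience", sel.nonsalience_voxels),
            ):
                if len(members) == 0:
                    entry[cluster] = None
                    continue
                vox = s.bold.data[np.ix_(target_idx[s.subject_id][members], vol_idx)]
                sweep = window_sweep(
                    efp_vals, vox, cfg.windows,
                    dataclasses.replace(cfg.sw, rng_seed=cfg.sw.rng_seed + s.rng_seed % 10000),
                )
                entry[cluster] = {
                    str(w): {
                        "real_median": r.real_median,
                        "chance_level": r.chance_level,
                        "above_chance": r.above_chance,
                    }
                    for w, r in sweep.items()
                }
            per_subject[s.subject_id] = entry
        sw_path = out / "swtest.json"
        save_json(per_subject, sw_path)
        done("swtest", t0, [sw_path])

        # ---- reactivity --------------------------------------------------
        t0 = stage("reactivity")
        rows = []
        for s in subjects:
            tl = s.timeline
            for scene, trace in s.ratings.items():
                window = tl.windows(scene)[0]
                rows.append(
                    (
                        s.subject_id,
                        scene,
                        reactivity_index(trace),
                        efp_amplitude(efps[s.subject_id], window),
                    )
                )
        cohort_tbl = pd.DataFrame(rows, columns=["subject", "scene", "rating_index", "efp_amp"])
        res = scene_difference_tests(cohort_tbl, cfg.scene_pair)
        r, p = correlate_reactivity_efp(cohort_tbl, cfg.scene_pair)
        react_path = out / "reactivity.json"
        save_json(
            {
                "scene_pair": list(cfg.scene_pair),
                "paired_t_ratings": res.paired_t_ratings,
                "paired_p_ratings": res.paired_p_ratings,
                "paired_t_efp": res.paired_t_efp,
                "paired_p_efp": res.paired_p_efp,
                "cohort_r": r,
                "cohort_r_p": p,
                "n_subjects": res.n_subjects,
            },
            react_path,
        )
        done("reactivity", t0, [react_path])
    except Exception as err:
        failed = len(manifest["stages"])
        names = ["simulate", "efp", "glm", "roi", "swtest", "reactivity"]
        stage_name = names[failed] if failed < len(names) else "unknown"
        manifest["failed_stage"] = stage_name
        save_json(manifest, out / "manifest.json")
        raise RuntimeError(f"pipeline failed in stage {stage_name!r}: {err}") from err

    save_json(manifest, out / "manifest.json")
    return manifest


def _aligned(efp, bold):
    from .glm import align_efp_to_volumes

    return align_efp_to_volumes(efp, bold)
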