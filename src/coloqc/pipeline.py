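"""Pipeline configuration and stage runner.

One config object carries every tunable of the workflow, with defaults set
to the reference operating point: luminance rules 253/50, validity threshold
34%, score cutpoints 70/10/50/15, 25 fps, mini-batch 48 and the staged
150-epoch learning-rate schedule.  ``run_pipeline`` executes named stages
against a working directory and records a manifest with a hash of the
configuration so a run can be audited and reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import annotator, framedb, scoring, segnet, synthetic, video_stats
from .color_features import (
    ClassifierRules,
    ColorCube,
    RegionClass,
    build_cube,
    classify_frame,
)

log = logging.getLogger("coloqc")

STAGES = (
    "synth",
    "build-features",
    "annotate",
    "select",
    "train",
    "segment",
    "stats",
    "score",
    "agreement",
)

_CUBE_CLASSES = (RegionClass.MUCOSA, RegionClass.RESIDUE, RegionClass.LUMEN)


@dataclass
class PipelineConfig:
    workdir: str = "."
    seed: int = 0
    # frame database / synthesis
    video_id: int = 1
    n_frames: int = 75
    frame_height: int = 64
    frame_width: int = 64
    hue_overlap: float = 0.0
    fps: float = 25.0
    candidate_step: int = 10
    # rule-based classifier
    artifact_L_min: int = 253
    lumen_L_max: int = 50
    # network
    base_channels: int = 32
    batch_size: int = 48
    schedule: tuple = segnet.DEFAULT_SCHEDULE
    # statistics and scoring
    validity_threshold: float = 34.0
    mucosa_high: float = 70.0
    residue_low: float = 10.0
    mucosa_low: float = 50.0
    residue_high: float = 15.0
    bbps_source: str = "rater1"

    def rules(self) -> ClassifierRules:
        return ClassifierRules(self.artifact_L_min, self.lumen_L_max)

    def score_thresholds(self) -> scoring.ScoreThresholds:
        return scoring.ScoreThresholds(
            self.mucosa_high, self.residue_low, self.mucosa_low, self.residue_high
        )

    def segnet_config(self, **overrides) -> segnet.SegNetConfig:
        kw = dict(
            input_height=self.frame_height,
            input_width=self.frame_width,
            base_channels=self.base_channels,
            batch_size=self.batch_size,
            schedule=self.schedule,
            seed=self.seed,
        )
        kw.update(overrides)
        return segnet.SegNetConfig(**kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["schedule"] = [list(s) for s in self.schedule]
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "schedule" in data:
            data["schedule"] = tuple(tuple(s) for s in data["schedule"])
        return cls(**data)


def _dirs(cfg: PipelineConfig) -> dict[str, Path]:
    root = Path(cfg.workdir)
    return {
        "root": root,
        "frames": root / "frames",
        "truth": root / "truth",
        "cubes": root / "cubes",
        "annotations": root / "annotations",
        "predictions": root / "predictions",
    }


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing artifact {path}; run the '{producer}' stage first"
        )
    return path


def _load_cubes(cfg: PipelineConfig) -> dict[RegionClass, ColorCube]:
    d = _dirs(cfg)["cubes"]
    return {
        cls: ColorCube.load(_require(d / f"{cls.name.lower()}.npz", "build-features"))
        for cls in _CUBE_CLASSES
    }


# --------------------------------------------------------------------- stages


def stage_synth(cfg: PipelineConfig) -> None:
    """Generate a pseudo-video (frames, ground truth, planted boundaries)."""
    d = _dirs(cfg)
    palette = synthetic.RegionPalette(hue_overlap=cfg.hue_overlap)
    profiles = [
        synthetic.poor_prep_profile(),
        synthetic.good_prep_profile(),
        synthetic.good_prep_profile(),
    ]
    frames, masks, bounds, truth = synthetic.generate_video(
        cfg.n_frames,
        profiles,
        seed=cfg.seed,
        height=cfg.frame_height,
        width=cfg.frame_width,
        palette=palette,
        validity_threshold=cfg.validity_threshold,
        fps=cfg.fps,
    )
    refs = framedb.extract_frames(frames, d["frames"], cfg.video_id)
    d["truth"].mkdir(parents=True, exist_ok=True)
    for ref, mask in zip(refs, masks):
        annotator.write_training_label(mask, d["truth"] / (ref.path.stem + ".png"))
    with open(d["root"] / "boundaries.json", "w") as fh:
        json.dump({"cut_1_2": bounds.cut_1_2, "cut_2_3": bounds.cut_2_3}, fh)
    video_stats.export_report(truth, d["root"] / "truth_report")
    log.info("synth: %d frames into %s", len(refs), d["frames"])


def stage_build_features(cfg: PipelineConfig) -> None:
    """Build the three color cubes from synthetic patch libraries."""
    d = _dirs(cfg)
    d["cubes"].mkdir(parents=True, exist_ok=True)
    palette = synthetic.RegionPalette(hue_overlap=cfg.hue_overlap)
    libs = synthetic.generate_patch_libraries(palette, seed=cfg.seed + 101)
    for cls, patches in libs.items():
        cube = build_cube(patches, class_name=cls.name.lower())
        cube.save(d["cubes"] / f"{cls.name.lower()}.npz")
        log.info(
            "build-features: %s cube from %d patches (%d nuances)",
            cls.name.lower(), cube.n_patches, cube.n_nuances,
        )


def build_cubes_from_dirs(
    patch_dirs: dict[RegionClass, Path], out_dir: Path
) -> None:
    """Build cubes from on-disk patch libraries (one TIFF folder per class)."""
    import imageio.v3 as iio

    out_dir.mkdir(parents=True, exist_ok=True)
    for cls, pdir in patch_dirs.items():
        patches = [
            np.asarray(iio.imread(f))[..., :3]
            for f in sorted(Path(pdir).iterdir())
            if f.suffix.lower() in {".tif", ".tiff", ".png"}
        ]
        cube = build_cube(patches, class_name=cls.name.lower())
        cube.save(out_dir / f"{cls.name.lower()}.npz")


def stage_annotate(cfg: PipelineConfig) -> None:
    """Rule-classify every frame; emit color TIFF and grayscale PNG labels."""
    d = _dirs(cfg)
    refs = framedb.list_frames(_require(d["frames"], "synth"))
    cubes = _load_cubes(cfg)
    rules = cfg.rules()
    d["annotations"].mkdir(parents=True, exist_ok=True)
    for ref in refs:
        frame = framedb.load_frame(ref)
        labels = classify_frame(frame, cubes, rules)
        annotator.write_color_annotation(
            labels, d["annotations"] / (ref.path.stem + ".tiff"), frame=frame
        )
        annotator.write_training_label(
            labels, d["annotations"] / (ref.path.stem + ".png")
        )
    log.info("annotate: %d frames", len(refs))


def stage_select(cfg: PipelineConfig) -> None:
    """Sample every N-th frame as a review candidate list."""
    d = _dirs(cfg)
    refs = framedb.list_frames(_require(d["frames"], "synth"))
    chosen = framedb.sample_candidates(refs, cfg.candidate_step)
    with open(d["root"] / "candidates.json", "w") as fh:
        json.dump([r.path.name for r in chosen], fh)
    log.info("select: %d of %d frames", len(chosen), len(refs))


def stage_train(cfg: PipelineConfig) -> None:
    """Train the segmentation network on the annotated frames."""
    d = _dirs(cfg)
    refs = framedb.list_frames(_require(d["frames"], "synth"))
    _require(d["annotations"], "annotate")
    import imageio.v3 as iio

    frames, labels = [], []
    for ref in refs:
        frames.append(framedb.load_frame(ref))
        labels.append(np.asarray(iio.imread(d["annotations"] / (ref.path.stem + ".png"))))
    net_cfg = cfg.segnet_config(batch_size=min(cfg.batch_size, len(frames)))
    model = segnet.build_model(net_cfg)
    report = segnet.train(model, frames, labels, net_cfg)
    model.save(d["root"] / "model.npz")
    with open(d["root"] / "train_report.json", "w") as fh:
        json.dump(dataclasses.asdict(report), fh)
    log.info(
        "train: final mini-batch accuracy %.4f loss %.4f",
        report.final_accuracy, report.final_loss,
    )


def stage_segment(cfg: PipelineConfig) -> None:
    """Apply the trained network to every frame."""
    d = _dirs(cfg)
    model = segnet.SegNet.load(_require(d["root"] / "model.npz", "train"))
    refs = framedb.list_frames(_require(d["frames"], "synth"))
    d["predictions"].mkdir(parents=True, exist_ok=True)
    for ref in refs:
        labels = model.predict(framedb.load_frame(ref))
        annotator.write_training_label(
            labels, d["predictions"] / (ref.path.stem + ".png")
        )
    log.info("segment: %d frames", len(refs))


def stage_stats(cfg: PipelineConfig) -> None:
    """Per-frame statistics and per-segment aggregation of the predictions."""
    d = _dirs(cfg)
    pred = _require(d["predictions"], "segment")
    with open(_require(d["root"] / "boundaries.json", "synth")) as fh:
        b = json.load(fh)
    bounds = video_stats.SegmentBoundaries(b["cut_1_2"], b["cut_2_3"])
    stats = []
    for f in sorted(pred.glob("*.png")):
        stats.append(
            video_stats.frame_stats(annotator.read_label(f), cfg.validity_threshold)
        )
    report = video_stats.aggregate(stats, bounds, cfg.validity_threshold)
    video_stats.export_report(report, d["root"] / "report")
    log.info("stats: %d frames, %d valid", report.overall.total_frames,
             report.overall.valid_frames)


def stage_score(cfg: PipelineConfig) -> None:
    """Per-segment 1-3 quality scores from the aggregated report."""
    d = _dirs(cfg)
    rows = video_stats.read_report_csv(_require(d["root"] / "report.csv", "stats"))
    thresholds = cfg.score_thresholds()
    scores = {}
    for row in rows:
        if not row["scope"].startswith("segment_"):
            continue
        if np.isnan(row["pct_mucosa"]):
            # no valid frames at all: artifact-saturated, worst quality
            scores[row["scope"]] = 1
        else:
            scores[row["scope"]] = scoring.segment_score(
                row["pct_mucosa"], row["pct_residue"], thresholds
            )
    with open(d["root"] / "scores.json", "w") as fh:
        json.dump(scores, fh)
    log.info("score: %s", scores)


def stage_agreement(cfg: PipelineConfig) -> None:
    """Agreement statistics on the packaged per-segment test dataset."""
    d = _dirs(cfg)
    report = scoring.agreement_report(bbps_source=cfg.bbps_source)
    out = {
        name: {"spearman_rho": r.spearman_rho, "kappa": r.kappa, "n": r.n}
        for name, r in report.items()
    }
    with open(d["root"] / "agreement.json", "w") as fh:
        json.dump(out, fh, indent=2)
    log.info("agreement: %s", {k: round(v["spearman_rho"], 2) for k, v in out.items()})


_STAGE_FN = {
    "synth": stage_synth,
    "build-features": stage_build_features,
    "annotate": stage_annotate,
    "select": stage_select,
    "train": stage_train,
    "segment": stage_segment,
    "stats": stage_stats,
    "score": stage_score,
    "agreement": stage_agreement,
}


def run_pipeline(cfg: PipelineConfig, stages: list[str] | None = None) -> dict:
    """Run the named stages in order; returns the manifest.

    Each stage logs its inputs and outputs; a failure aborts with an error
    naming the stage.  The manifest (written to ``workdir/manifest.json``)
    records the configuration, its hash and the completed stages, so two
    runs with identical config and seed produce identical manifests.
    """
    stages = list(stages) if stages is not None else list(STAGES)
    unknown = [s for s in stages if s not in _STAGE_FN]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    root = Path(cfg.workdir)
    root.mkdir(parents=True, exist_ok=True)
    done = []
    for name in stages:
        try:
            _STAGE_FN[name](cfg)
        except Exception as exc:
            raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
        done.append(name)
    manifest = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "stages": done,
    }
    with open(root / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
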