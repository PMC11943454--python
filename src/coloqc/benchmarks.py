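"""Reproducible end-to-end study routines on synthetic data.

These functions re-run the pipeline's headline computations at desk scale:
the agreement statistics on the packaged per-segment test dataset, the
rule-classifier recovery rate, a scaled-down training run of the
segmentation network, the totality of model predictions, and the ordering
of quality scores between a poorly and a well prepared pseudo-video.  Each
takes an explicit seed and returns plain dictionaries, so they serve both
the test suite and reporting scripts.

Problem sizes are chosen so the full set completes in a few minutes on one
CPU: 64x64 frames, 60-frame training sets and the staged learning-rate
schedule shortened to 15+15+15 epochs with mini-batches of 8.
"""

from __future__ import annotations

import numpy as np

from . import scoring, segnet, synthetic, video_stats
from .annotator import GRAY_CODE
from .color_features import RegionClass, build_cube, classify_frame
from .synthetic import RegionPalette, SceneSpec

REDUCED_SCHEDULE = ((15, 1e-3), (15, 7e-4), (15, 49e-5))

_GRAY_LUT = np.zeros(256, dtype=np.uint8)
for _c, _g in GRAY_CODE.items():
    _GRAY_LUT[int(_c)] = _g


def agreement_summary(bbps_source: str = "rater1") -> dict:
    """The five agreement statistics on the packaged 21-segment dataset."""
    rep = scoring.agreement_report(bbps_source=bbps_source)
    return {
        "spearman_bbps_vs_pixel_score": rep["pixel_score"].spearman_rho,
        "spearman_bbps_vs_mucosa_pct": rep["mucosa_pct"].spearman_rho,
        "spearman_bbps_vs_residue_pct": rep["residue_pct"].spearman_rho,
        "spearman_bbps_vs_artifact_pct": rep["artifact_pct"].spearman_rho,
        "cohens_kappa_bbps_vs_pixel_score": rep["pixel_score"].kappa,
        "n": rep["pixel_score"].n,
    }


def _full_cubes(palette: RegionPalette, seed: int):
    libs = synthetic.generate_patch_libraries(palette, seed=seed)
    return {cls: build_cube(p, cls.name.lower()) for cls, p in libs.items()}


def rule_recovery(seed: int, n_fresh: int = 50_000) -> dict:
    """Classify fresh same-palette pixels with cubes built from full-size
    synthetic libraries (209/84/154 patches, disjoint palettes)."""
    palette = RegionPalette(hue_overlap=0.0)
    cubes = _full_cubes(palette, seed)
    rng = np.random.default_rng(seed + 1)
    hits = tot = unclassified = 0
    shape = (n_fresh // 250, 250, 3)
    for cls in (RegionClass.MUCOSA, RegionClass.RESIDUE,
                RegionClass.LUMEN, RegionClass.ARTIFACT):
        colors = palette.sample(cls, n_fresh, rng).reshape(shape)
        out = classify_frame(colors, cubes)
        hits += int((out == int(cls)).sum())
        unclassified += int((out == int(RegionClass.UNCLASSIFIED)).sum())
        tot += out.size
    return {
        "accuracy": hits / tot,
        "unclassified_rate": unclassified / tot,
        "n_pixels": tot,
    }


def _synthetic_set(n: int, palette: RegionPalette, rng: np.random.Generator,
                   size: int):
    frames, masks = [], []
    for _ in range(n):
        spec = SceneSpec(height=size, width=size,
                         seed=int(rng.integers(0, 2**31 - 1)))
        f, m = synthetic.generate_frame(spec, palette)
        frames.append(f)
        masks.append(m)
    return frames, masks


def training_benchmark(
    seed: int,
    n_train: int = 60,
    n_test: int = 15,
    frame_size: int = 64,
    hue_overlap: float = 0.5,
    base_channels: int = 32,
    batch_size: int = 8,
    schedule=REDUCED_SCHEDULE,
) -> dict:
    """Scaled-down analogue of the full training run.

    Frames use moderately overlapping mucosa/residue palettes; annotations
    come from the rule-based cube classifier (unannotated pixels excluded
    from the loss, exactly as in the full workflow); held-out accuracy is
    measured against the generator's ground truth.
    """
    palette = RegionPalette(hue_overlap=hue_overlap)
    cubes = _full_cubes(palette, seed + 101)
    rng = np.random.default_rng(seed + 5)
    frames, masks = _synthetic_set(n_train + n_test, palette, rng, frame_size)
    grays = [_GRAY_LUT[classify_frame(f, cubes)] for f in frames[:n_train]]

    cfg = segnet.SegNetConfig(
        input_height=frame_size, input_width=frame_size,
        base_channels=base_channels, batch_size=batch_size,
        schedule=schedule, seed=seed,
    )
    model = segnet.build_model(cfg)
    report = segnet.train(model, frames[:n_train], grays, cfg)

    test_frames = frames[n_train:]
    test_masks = masks[n_train:]
    accs, unclassified = [], 0
    for f, m in zip(test_frames, test_masks):
        pred = model.predict(f)
        accs.append(float((pred == m).mean()))
        unclassified += int((pred == int(RegionClass.UNCLASSIFIED)).sum())
    annotation_cov = float(np.mean([(g > 0).mean() for g in grays]))
    return {
        "holdout_accuracy": float(np.mean(accs)),
        "final_minibatch_accuracy": report.final_accuracy,
        "final_minibatch_loss": report.final_loss,
        "unclassified_rate": unclassified / (n_test * frame_size * frame_size),
        "annotation_coverage": annotation_cov,
        "model": model,
        "n_train": n_train,
        "n_test": n_test,
    }


def totality_check(seed: int, n_frames: int = 100, frame_size: int = 64,
                   model: segnet.SegNet | None = None) -> dict:
    """Fraction of unclassified pixels in model predictions (always 0)."""
    if model is None:
        cfg = segnet.SegNetConfig(input_height=frame_size,
                                  input_width=frame_size,
                                  base_channels=8, batch_size=1,
                                  schedule=((1, 1e-3),), seed=seed)
        model = segnet.build_model(cfg)
    palette = RegionPalette()
    rng = np.random.default_rng(seed + 9)
    frames, _ = _synthetic_set(n_frames, palette, rng, frame_size)
    unclassified = 0
    total = 0
    for f in frames:
        pred = model.predict(f)
        unclassified += int((pred == int(RegionClass.UNCLASSIFIED)).sum())
        total += pred.size
    return {"unclassified_pct": 100.0 * unclassified / total,
            "n_frames": n_frames}


def _video_summary(masks_or_preds, bounds, thresholds) -> dict:
    stats = [video_stats.frame_stats(m) for m in masks_or_preds]
    rep = video_stats.aggregate(stats, bounds)
    scores = [
        scoring.segment_score(s.pct[RegionClass.MUCOSA],
                              s.pct[RegionClass.RESIDUE], thresholds)
        for s in rep.segments
    ]
    return {
        "segment_scores": scores,
        "valid_fraction": rep.overall.valid_frames / rep.overall.total_frames,
        "frames_mucosa_over_75": rep.overall.n_frames_mucosa_over_75,
        "frames_residue_over_50": rep.overall.n_frames_residue_over_50,
    }


def ordering_study(seed: int, n_frames: int = 45, frame_size: int = 64) -> dict:
    """Rule-classify two pseudo-videos with planted poor and good
    preparation profiles and compare their quality summaries."""
    palette = RegionPalette(hue_overlap=0.0)
    cubes = _full_cubes(palette, seed + 301)
    thresholds = scoring.ScoreThresholds()
    out = {}
    for name, profile, sub in (
        ("poor", synthetic.poor_prep_profile(), 1),
        ("good", synthetic.good_prep_profile(), 2),
    ):
        frames, _, bounds, _ = synthetic.generate_video(
            n_frames, [profile] * 3, seed=seed + sub,
            height=frame_size, width=frame_size, palette=palette,
        )
        preds = [classify_frame(f, cubes) for f in frames]
        out[name] = _video_summary(preds, bounds, thresholds)
    return out
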