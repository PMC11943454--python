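"""Lab byte coding, occupancy cubes, and the rule-first pixel classifier."""

import numpy as np
import pytest

from coloqc.color_features import (
    ClassifierRules,
    ColorCube,
    RegionClass,
    build_cube,
    classify_frame,
    classify_lab8,
    classify_pixel,
    rgb_to_lab8,
)


# ------------------------------------------------------- independent oracle


def _reference_lab8(r, g, b):
    """Naive scalar sRGB -> XYZ(D65) -> CIELAB -> byte coding, written
    directly from the colorimetry definitions (independent of skimage)."""

    def inv_gamma(u):
        u = u / 255.0
        return u / 12.92 if u <= 0.04045 else ((u + 0.055) / 1.055) ** 2.4

    rl, gl, bl = inv_gamma(r), inv_gamma(g), inv_gamma(b)
    # sRGB primaries, D65 white
    x = 0.4124564 * rl + 0.3575761 * gl + 0.1804375 * bl
    y = 0.2126729 * rl + 0.7151522 * gl + 0.0721750 * bl
    z = 0.0193339 * rl + 0.1191920 * gl + 0.9503041 * bl
    xn, yn, zn = 0.95047, 1.0, 1.08883

    def f(t):
        d = 6 / 29
        return t ** (1 / 3) if t > d**3 else t / (3 * d * d) + 4 / 29

    fx, fy, fz = f(x / xn), f(y / yn), f(z / zn)
    L = 116 * fy - 16
    a = 500 * (fx - fy)
    bb = 200 * (fy - fz)
    code = lambda v: int(np.clip(round(v), 0, 255))
    return code(L * 255 / 100), code(a + 128), code(bb + 128)


def test_lab8_reference_points():
    assert tuple(rgb_to_lab8(np.array([0, 0, 0]))) == (0, 128, 128)
    assert tuple(rgb_to_lab8(np.array([255, 255, 255]))) == (255, 128, 128)


def test_lab8_grays_are_neutral_and_match_reference():
    """Every gray level is achromatic (a=b=128) and the coded L agrees with
    a from-scratch colorimetry computation to within one code step."""
    grays = np.stack([np.arange(256)] * 3, axis=-1).astype(np.uint8)
    coded = rgb_to_lab8(grays)
    assert np.all(coded[:, 1] == 128)
    assert np.all(coded[:, 2] == 128)
    ref = np.array([_reference_lab8(v, v, v) for v in range(256)])
    assert np.max(np.abs(coded.astype(int) - ref)) <= 1


def test_lab8_random_colors_match_reference(rng):
    rgbs = rng.integers(0, 256, (300, 3)).astype(np.uint8)
    coded = rgb_to_lab8(rgbs)
    ref = np.array([_reference_lab8(*map(int, c)) for c in rgbs])
    assert np.max(np.abs(coded.astype(int) - ref)) <= 1


# ------------------------------------------------------------------- cubes


def test_build_cube_uniform_patch_single_cell():
    patch = np.full((2, 2, 3), (140, 60, 40), dtype=np.uint8)
    cube = build_cube([patch])
    assert cube.n_patches == 1
    assert cube.n_pixels == 4
    assert cube.n_nuances == 1
    assert cube.counts[0] == 4


def test_build_cube_accepts_large_library(palette, rng):
    patches = [palette.sample(RegionClass.MUCOSA, 25, rng).reshape(5, 5, 3)
               for _ in range(209)]
    cube = build_cube(patches, "mucosa")
    assert cube.n_patches == 209
    assert cube.n_pixels == 209 * 25
    assert cube.n_nuances <= cube.n_pixels


def test_build_cube_empty_collection_errors():
    with pytest.raises(ValueError, match="no patches"):
        build_cube([])


def test_cube_additivity(palette, rng):
    a = [palette.sample(RegionClass.RESIDUE, 64, rng).reshape(8, 8, 3)
         for _ in range(4)]
    b = [palette.sample(RegionClass.RESIDUE, 64, rng).reshape(8, 8, 3)
         for _ in range(3)]
    merged = build_cube(a + b)
    summed = build_cube(a) + build_cube(b)
    assert np.array_equal(merged.keys, summed.keys)
    assert np.array_equal(merged.counts, summed.counts)
    assert summed.n_pixels == merged.n_pixels


def test_cube_save_load_roundtrip(tmp_path, small_cubes):
    cube = small_cubes[RegionClass.MUCOSA]
    path = tmp_path / "mucosa.npz"
    cube.save(path)
    loaded = ColorCube.load(path)
    assert np.array_equal(loaded.keys, cube.keys)
    assert np.array_equal(loaded.counts, cube.counts)
    assert loaded.n_patches == cube.n_patches
    assert loaded.class_name == "mucosa"


# -------------------------------------------------------------- classifier


def test_luminance_rules_take_precedence(small_cubes):
    assert classify_pixel((255, 128, 128), small_cubes) == RegionClass.ARTIFACT
    assert classify_pixel((253, 140, 150), small_cubes) == RegionClass.ARTIFACT
    assert classify_pixel((30, 140, 150), small_cubes) == RegionClass.LUMEN
    assert classify_pixel((49, 128, 128), small_cubes) == RegionClass.LUMEN


def test_membership_and_unclassified():
    one = lambda lab, n: ColorCube(
        np.array([(lab[0] << 16) | (lab[1] << 8) | lab[2]], dtype=np.uint32),
        np.array([n]), 1, n, "x")
    cubes = {
        RegionClass.MUCOSA: one((100, 160, 150), 3),
        RegionClass.RESIDUE: one((150, 135, 180), 5),
        RegionClass.LUMEN: one((60, 130, 130), 2),
    }
    assert classify_pixel((150, 135, 180), cubes) == RegionClass.RESIDUE
    assert classify_pixel((100, 160, 150), cubes) == RegionClass.MUCOSA
    assert classify_pixel((200, 200, 200), cubes) == RegionClass.UNCLASSIFIED


def test_tie_break_uses_precedence():
    lab = (120, 150, 160)
    key = np.array([(120 << 16) | (150 << 8) | 160], dtype=np.uint32)
    cubes = {
        RegionClass.MUCOSA: ColorCube(key, np.array([4]), 1, 4, "m"),
        RegionClass.RESIDUE: ColorCube(key, np.array([4]), 1, 4, "r"),
        RegionClass.LUMEN: ColorCube(np.array([1], dtype=np.uint32),
                                     np.array([1]), 1, 1, "l"),
    }
    # equal counts: residues win under the default precedence
    assert classify_pixel(lab, cubes) == RegionClass.RESIDUE
    flipped = ClassifierRules(precedence=(RegionClass.MUCOSA,
                                          RegionClass.RESIDUE,
                                          RegionClass.LUMEN))
    assert classify_pixel(lab, cubes, flipped) == RegionClass.MUCOSA


def test_higher_count_beats_precedence():
    key = np.array([(120 << 16) | (150 << 8) | 160], dtype=np.uint32)
    cubes = {
        RegionClass.MUCOSA: ColorCube(key, np.array([9]), 1, 9, "m"),
        RegionClass.RESIDUE: ColorCube(key, np.array([2]), 1, 2, "r"),
        RegionClass.LUMEN: ColorCube(np.array([1], dtype=np.uint32),
                                     np.array([1]), 1, 1, "l"),
    }
    assert classify_pixel((120, 150, 160), cubes) == RegionClass.MUCOSA


def test_missing_cube_is_configuration_error(small_cubes):
    cubes = dict(small_cubes)
    del cubes[RegionClass.RESIDUE]
    with pytest.raises(KeyError, match="RESIDUE"):
        classify_pixel((100, 150, 150), cubes)


def _reference_classify(lab, cubes, rules):
    """Naive per-pixel reference: explicit rule order and dict lookups."""
    L, a, b = (int(v) for v in lab)
    if L >= rules.artifact_L_min:
        return RegionClass.ARTIFACT
    if L < rules.lumen_L_max:
        return RegionClass.LUMEN
    best, best_count = None, 0
    for cls in rules.precedence:
        c = cubes[cls].count_at((L, a, b))
        if c > best_count:
            best, best_count = cls, c
    return best if best is not None else RegionClass.UNCLASSIFIED


def test_vectorized_classifier_matches_naive_reference(small_cubes, rng):
    rules = ClassifierRules()
    lab = rng.integers(0, 256, (10_000, 3)).astype(np.uint8)
    fast = classify_lab8(lab, small_cubes, rules)
    slow = np.array([_reference_classify(p, small_cubes, rules) for p in lab])
    assert np.array_equal(fast, slow)


def test_classification_is_total(small_cubes, rng):
    lab = rng.integers(0, 256, (64, 64, 3)).astype(np.uint8)
    out = classify_lab8(lab, small_cubes)
    assert set(np.unique(out)) <= {int(c) for c in RegionClass}
    # rule precedence invariants
    L = lab[..., 0]
    assert np.all(out[L >= 253] == int(RegionClass.ARTIFACT))
    assert np.all(out[(L < 50)] == int(RegionClass.LUMEN))


def test_classify_frame_uniform_white_is_all_artifact(small_cubes):
    frame = np.full((20, 30, 3), 255, dtype=np.uint8)
    out = classify_frame(frame, small_cubes)
    assert out.shape == (20, 30)
    assert np.all(out == int(RegionClass.ARTIFACT))


def test_classify_frame_rejects_non_rgb(small_cubes):
    with pytest.raises(ValueError):
        classify_frame(np.zeros((10, 10), dtype=np.uint8), small_cubes)


def test_patch_nuances_recovered_from_own_cube(small_cubes, palette, rng):
    """A frame tiled from mucosa-palette colors classifies as mucosa or a
    rule class (its nuances were all injected into the cube)."""
    patch = palette.sample(RegionClass.MUCOSA, 400, rng).reshape(20, 20, 3)
    cube = build_cube([patch], "mucosa")
    cubes = dict(small_cubes)
    cubes[RegionClass.MUCOSA] = cubes[RegionClass.MUCOSA] + cube
    out = classify_frame(patch, cubes)
    ok = np.isin(out, [int(RegionClass.MUCOSA), int(RegionClass.ARTIFACT),
                       int(RegionClass.LUMEN), int(RegionClass.RESIDUE)])
    assert ok.all()
    assert (out == int(RegionClass.MUCOSA)).mean() > 0.9
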