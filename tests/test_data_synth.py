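"""Dataset I/O, the six-transform augmentation bookkeeping, splitting and the
synthetic scene generator."""

import numpy as np
import pytest

from bisenext.data import (AUGMENTATION_METHODS, Sample, augment_dataset,
                           augment_six, load_dataset, split, write_sample)
from bisenext.synth import (SceneSpec, generate_dataset, generate_scene,
                            render_lesions, smoke_spec_kwargs, _layout)


@pytest.fixture(scope="module")
def scene():
    return generate_scene(SceneSpec(seed=11, size=96, n_leaves=2,
                                    lesion_density=2.0, lesion_radius_px=(5, 9)))


# -- augmentation -----------------------------------------------------------

def test_augment_six_produces_one_sample_per_method(scene):
    out = augment_six(scene, seed=0)
    assert [s.augmentation_tag for s in out] == list(AUGMENTATION_METHODS)


def test_augmented_dataset_is_seven_times_originals(scene):
    originals = [scene] * 5
    assert len(augment_dataset(originals, seed=0)) == 7 * 5


def test_augmentation_bookkeeping_reproduces_published_style_totals(scene):
    """n originals -> 7n totals, the arithmetic behind per-condition counts
    such as 532 -> 3724 and 1097 -> 7679."""
    factor = len(augment_six(scene, seed=3)) + 1
    assert factor == 7
    assert 532 * factor == 3724
    assert 565 * factor == 3955
    assert 1097 * factor == 7679


def test_photometric_augmentations_leave_mask_untouched(scene):
    for s in augment_six(scene, seed=1)[:3]:
        np.testing.assert_array_equal(s.mask, scene.mask)


def test_flip_is_an_involution(scene):
    flip = augment_six(scene, seed=0)[5]
    flip2 = augment_six(flip, seed=0)[5]
    np.testing.assert_array_equal(flip2.mask, scene.mask)
    np.testing.assert_array_equal(flip2.image, scene.image)


def test_geometric_augmentations_preserve_lesion_containment(scene):
    """No disease pixel outside leaf regions after crop/rotation/flip, given
    the input satisfies the same containment."""
    def contained(mask):
        # every lesion component sits inside leaf tissue: its 1-px dilation
        # never spills straight onto background
        from scipy import ndimage
        disease = mask == 2
        if not disease.any():
            return True
        ring = ndimage.binary_dilation(disease) & ~disease
        return (mask[ring] == 1).mean() > 0.5

    assert contained(scene.mask)
    for s in augment_six(scene, seed=2)[3:]:
        assert contained(s.mask), s.augmentation_tag


# -- split ------------------------------------------------------------------

def test_split_sizes_and_partition():
    data = generate_dataset(100, seed=5, **smoke_spec_kwargs(32))
    tr, va, te = split(data, seed=0)
    assert (len(tr), len(va), len(te)) == (70, 20, 10)
    stems = [s.stem for part in (tr, va, te) for s in part]
    assert sorted(stems) == sorted(s.stem for s in data)    # exhaustive, disjoint


def test_split_deterministic_and_seed_sensitive():
    data = generate_dataset(30, seed=5, **smoke_spec_kwargs(32))
    a = split(data, seed=1)
    b = split(data, seed=1)
    c = split(data, seed=2)
    assert [s.stem for s in a[0]] == [s.stem for s in b[0]]
    assert [s.stem for s in a[0]] != [s.stem for s in c[0]]


def test_split_rejects_bad_ratios():
    with pytest.raises(ValueError, match="positive"):
        split([], ratios=(1, 0, -1))


# -- scene generation -------------------------------------------------------

def test_scene_determinism_and_classes(scene):
    again = generate_scene(SceneSpec(seed=11, size=96, n_leaves=2,
                                     lesion_density=2.0, lesion_radius_px=(5, 9)))
    np.testing.assert_array_equal(scene.image, again.image)
    np.testing.assert_array_equal(scene.mask, again.mask)
    assert set(np.unique(scene.mask)) == {0, 1, 2}


def test_scene_without_leaves_is_all_background():
    s = generate_scene(SceneSpec(seed=0, size=64, n_leaves=0))
    assert (s.mask == 0).all()


def test_lesion_pixels_match_rerendered_stamps(scene):
    """Class-2 pixels equal the union of the individually re-rendered lesion
    stamps clipped to the visible leaf area."""
    spec = SceneSpec(seed=11, size=96, n_leaves=2, lesion_density=2.0,
                     lesion_radius_px=(5, 9))
    stamps = render_lesions(spec)
    _, visible, _, _ = _layout(spec)
    leaf_area = np.zeros((96, 96), dtype=bool)
    for v in visible:
        leaf_area |= v
    union = np.zeros((96, 96), dtype=bool)
    for s in stamps:
        union |= s
    np.testing.assert_array_equal(scene.mask == 2, union & leaf_area)


def test_excessive_lesion_density_is_capped_with_warning():
    spec = SceneSpec(seed=1, size=64, n_leaves=1, lesion_density=60,
                     lesion_radius_px=(10, 14))
    with pytest.warns(UserWarning, match="budget"):
        s = generate_scene(spec)
    leaf_px = (s.mask >= 1).sum()
    assert (s.mask == 2).sum() <= 0.7 * leaf_px


def test_every_smoke_scene_contains_all_classes():
    for s in generate_dataset(10, seed=3, **smoke_spec_kwargs(64)):
        assert set(np.unique(s.mask)) == {0, 1, 2}


# -- I/O --------------------------------------------------------------------

def test_mask_roundtrip_is_lossless(tmp_path, scene):
    write_sample(scene, tmp_path / "images", tmp_path / "masks")
    loaded = load_dataset(tmp_path / "images", tmp_path / "masks", target_size=96)
    assert len(loaded) == 1
    np.testing.assert_array_equal(loaded[0].mask, scene.mask)


def test_load_resizes_pairs(tmp_path, scene):
    write_sample(scene, tmp_path / "images", tmp_path / "masks")
    loaded = load_dataset(tmp_path / "images", tmp_path / "masks", target_size=48)
    assert loaded[0].image.shape == (48, 48, 3)
    assert loaded[0].mask.shape == (48, 48)
    assert set(np.unique(loaded[0].mask)) <= {0, 1, 2}


def test_unpaired_and_bad_colour_rejected(tmp_path, scene):
    from PIL import Image

    write_sample(scene, tmp_path / "images", tmp_path / "masks")
    Image.fromarray(scene.image).save(tmp_path / "images" / "orphan.png")
    with pytest.raises(ValueError, match="orphan"):
        load_dataset(tmp_path / "images", tmp_path / "masks")
    (tmp_path / "images" / "orphan.png").unlink()
    bad = np.zeros((8, 8, 3), dtype=np.uint8)
    bad[2, 2] = (12, 34, 56)
    Image.fromarray(scene.image).save(tmp_path / "images" / "bad.png")
    Image.fromarray(bad).save(tmp_path / "masks" / "bad.png")
    with pytest.raises(ValueError, match=r"\(12, 34, 56\)"):
        load_dataset(tmp_path / "images", tmp_path / "masks")


def test_sample_validation():
    with pytest.raises(ValueError, match="congruent"):
        Sample(image=np.zeros((4, 4, 3), dtype=np.uint8),
               mask=np.zeros((5, 5), dtype=np.uint8))
    with pytest.raises(ValueError, match="invalid labels"):
        Sample(image=np.zeros((4, 4, 3), dtype=np.uint8),
               mask=np.full((4, 4), 7, dtype=np.uint8))
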