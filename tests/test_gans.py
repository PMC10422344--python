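"""GAN variant mechanisms: schedule, fade-in, conditioning, cycle loss."""

import itertools

import numpy as np
import pytest

from ganaug.dataset import Manifest, Record
from ganaug.errors import ConfigError, DataError, UsageError
from ganaug.gans import (GanConfig, ResidualGenerator, augment_dataset,
                         cycle_loss, generate, pggan_schedule, train_gan)


@pytest.fixture(scope="module")
def tiny_images():
    rng = np.random.default_rng(0)
    return rng.random((24, 16, 16))


@pytest.fixture(scope="module")
def tiny_labels():
    return ["glioma"] * 8 + ["meningioma"] * 8 + ["pituitary"] * 8


# ---------------------------------------------------------------------------
# schedule
# ---------------------------------------------------------------------------


def test_schedule_base_case():
    assert pggan_schedule(4) == [4]


@pytest.mark.parametrize("target", [8, 16, 32, 64, 128])
def test_schedule_doubles_from_four(target):
    s = pggan_schedule(target)
    assert s[0] == 4 and s[-1] == target
    assert len(s) == int(np.log2(target / 4)) + 1
    assert all(b == 2 * a for a, b in zip(s, s[1:]))


@pytest.mark.parametrize("bad", [48, 6, 3, 0])
def test_schedule_rejects_non_power_resolutions(bad):
    with pytest.raises(ConfigError):
        pggan_schedule(bad)


# ---------------------------------------------------------------------------
# training contracts
# ---------------------------------------------------------------------------


def test_one_step_logs_one_finite_loss_pair(tiny_images):
    cfg = GanConfig(variant="dcgan", target_resolution=8, steps=1,
                    batch_size=8, latent_dim=8, seed=0)
    st = train_gan(cfg, tiny_images[:8])
    assert len(st.log) == 1
    assert np.isfinite(st.log[0]["d_loss"]) and np.isfinite(st.log[0]["g_loss"])


def test_same_seed_same_training_log(tiny_images):
    cfg = GanConfig(variant="dcgan", target_resolution=8, steps=10,
                    batch_size=8, latent_dim=8, seed=42)
    assert train_gan(cfg, tiny_images).log == train_gan(cfg, tiny_images).log


def test_empty_training_set_rejected():
    cfg = GanConfig(variant="dcgan", target_resolution=8, steps=1)
    with pytest.raises(DataError):
        train_gan(cfg, np.zeros((0, 8, 8)))


def test_pggan_log_partitions_into_schedule_stages(tiny_images):
    cfg = GanConfig(variant="pggan", target_resolution=16, steps=30,
                    batch_size=8, latent_dim=8, seed=1)
    st = train_gan(cfg, tiny_images)
    groups = [k for k, _ in itertools.groupby(e["resolution"] for e in st.log)]
    assert groups == pggan_schedule(16) == [4, 8, 16]
    sizes = [len(list(g)) for _, g in
             itertools.groupby(e["resolution"] for e in st.log)]
    assert sizes == [10, 10, 10]


def test_pggan_fade_in_rises_monotonically_from_zero(tiny_images):
    cfg = GanConfig(variant="pggan", target_resolution=16, steps=30,
                    batch_size=8, latent_dim=8, seed=1, fade_fraction=0.5)
    st = train_gan(cfg, tiny_images)
    for res in (8, 16):
        alphas = [e["alpha"] for e in st.log if e["resolution"] == res]
        assert alphas[0] == 0.0 and alphas[-1] == 1.0
        assert all(a <= b for a, b in zip(alphas, alphas[1:]))


def test_dcgan_converges_on_single_mode_data():
    """On an all-constant dataset the generator mean should approach the
    data constant within 0.15 after the desk-scale budget."""
    imgs = np.full((16, 8, 8), 0.8)
    cfg = GanConfig(variant="dcgan", target_resolution=8, steps=300,
                    batch_size=8, latent_dim=8, seed=1)
    st = train_gan(cfg, imgs)
    batch = generate(st, 32, seed=5)
    assert abs(batch.images.mean() - 0.8) < 0.15


def test_cyclegan_identity_init_has_zero_cycle_loss(rng):
    g_ab = ResidualGenerator(np.random.default_rng(0))
    g_ba = ResidualGenerator(np.random.default_rng(1))
    x = rng.random((5, 12, 12))
    assert cycle_loss(g_ab, g_ba, x) == 0.0


def test_conditional_and_infogan_training(tiny_images, tiny_labels):
    for variant in ("conditional", "infogan"):
        cfg = GanConfig(variant=variant, target_resolution=8, steps=5,
                        batch_size=8, latent_dim=8, seed=2, code_dim=3)
        st = train_gan(cfg, tiny_images, tiny_labels)
        assert len(st.log) == 5
        batch = generate(st, 4, label="glioma", seed=0)
        assert batch.images.shape == (4, 8, 8)
        assert batch.labels == ["glioma"] * 4


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def dcgan_state(tiny_images):
    cfg = GanConfig(variant="dcgan", target_resolution=16, steps=5,
                    batch_size=8, latent_dim=8, seed=3)
    return train_gan(cfg, tiny_images)


def test_generate_empty_batch(dcgan_state):
    assert generate(dcgan_state, 0).images.shape == (0, 16, 16)


def test_generate_shape_range_and_determinism(dcgan_state):
    a = generate(dcgan_state, 5, seed=9)
    b = generate(dcgan_state, 5, seed=9)
    assert a.images.shape == (5, 16, 16)
    assert a.images.min() >= 0.0 and a.images.max() <= 1.0
    assert np.array_equal(a.images, b.images)


def test_generate_label_contract(dcgan_state, tiny_images, tiny_labels):
    with pytest.raises(UsageError):
        generate(dcgan_state, 2, label="glioma")
    cfg = GanConfig(variant="conditional", target_resolution=8, steps=2,
                    batch_size=8, latent_dim=8, seed=0)
    cond = train_gan(cfg, tiny_images, tiny_labels)
    with pytest.raises(UsageError):
        generate(cond, 2)


def test_cyclegan_translates_between_domains(tiny_images, tiny_labels):
    cfg = GanConfig(variant="cyclegan", target_resolution=8, steps=3,
                    batch_size=4, seed=0, domains=("glioma", "meningioma"))
    st = train_gan(cfg, tiny_images, tiny_labels)
    out = generate(st, 3, label="meningioma", seed=1)
    assert out.images.shape == (3, 8, 8) and out.labels == ["meningioma"] * 3
    with pytest.raises(UsageError):
        generate(st, 1, label="pituitary")


# ---------------------------------------------------------------------------
# augmentation bookkeeping
# ---------------------------------------------------------------------------


def _split_manifest(tiny_labels, tmp_path, tiny_images):
    from ganaug.dataset import save_image
    recs = []
    for i, (lbl, img) in enumerate(zip(tiny_labels, tiny_images)):
        p = str(tmp_path / f"r{i}.png")
        save_image(np.rint(img * 255), p)
        split = "train" if i % 3 != 2 else ("validation" if i % 2 else "test")
        recs.append(Record(p, lbl, "axial", split))
    return Manifest(recs)


def test_augment_counts_and_split_isolation(tmp_path, tiny_images, tiny_labels,
                                            dcgan_state):
    manifest = _split_manifest(tiny_labels, tmp_path, tiny_images)
    states = {"dcgan": {}}
    for cls in ("glioma", "meningioma", "pituitary"):
        import copy
        st = copy.copy(dcgan_state)
        st.class_tag = cls
        states["dcgan"][cls] = st
    out = augment_dataset(manifest, states, 10, str(tmp_path / "aug"), seed=0)
    aug = out["dcgan"]
    added = aug.records[len(manifest.records):]
    assert len(added) == 30
    assert all(r.split == "train" and r.origin == "dcgan" for r in added)
    assert aug.subset("validation") == manifest.subset("validation")
    assert aug.subset("test") == manifest.subset("test")
    noop = augment_dataset(manifest, states, 0, str(tmp_path / "aug0"), seed=0)
    assert noop["dcgan"] == manifest


def test_augment_unknown_variant_rejected(tmp_path, tiny_images, tiny_labels):
    manifest = _split_manifest(tiny_labels, tmp_path, tiny_images)
    with pytest.raises(UsageError):
        augment_dataset(manifest, {"wgan": {}}, 1, str(tmp_path / "a"))
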