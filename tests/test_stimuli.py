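import struct

import numpy as np
import pytest
from scipy import stats

from bitstdp import stimuli
from bitstdp.stimuli import (
    EncodingConfig,
    bar_sequence,
    glyph_edge_pixels,
    glyph_mask,
    load_idx_dataset,
    moving_symbol_stream,
    oriented_bar_image,
    poisson_encode,
    random_smooth_path,
    read_idx_images,
)


class TestOrientedBar:
    def test_axis_aligned_pixel_count(self, rng):
        img = oriented_bar_image(0.0, rng=rng)
        assert int((img > 0).sum()) == 8 * 24

    def test_intensities_in_stated_range(self, rng):
        for angle in (0, 45, 90, 135):
            img = oriented_bar_image(angle, rng=rng)
            nz = img[img > 0]
            assert nz.min() >= 0.8 and nz.max() <= 1.0

    def test_vertical_mask_is_transpose_of_horizontal(self, rng):
        m0 = oriented_bar_image(0.0, rng=rng) > 0
        m90 = oriented_bar_image(90.0, rng=rng) > 0
        assert np.array_equal(m90, m0.T)

    def test_oblique_mask_roughly_same_area(self, rng):
        n45 = int((oriented_bar_image(45.0, rng=rng) > 0).sum())
        assert abs(n45 - 192) <= 20  # nearest-neighbor rasterization slack

    def test_geometry_overflow(self, rng):
        with pytest.raises(ValueError, match="fit"):
            oriented_bar_image(0.0, size=16, thickness=8, length=24, rng=rng)


class TestPoissonEncode:
    def test_zero_intensity_pixel_emits_nothing(self, rng):
        img = np.zeros((4, 4))
        img[0, 0] = 1.0
        ev = poisson_encode(img, EncodingConfig(total_spikes=500), rng)
        assert set(ev.addresses.tolist()) == {0}

    def test_total_spikes_mode_exact_count(self, rng):
        img = np.full((4, 4), 0.5)
        ev = poisson_encode(img, EncodingConfig(total_spikes=777), rng)
        assert len(ev) == 777

    def test_all_zero_image_rejected(self, rng):
        with pytest.raises(ValueError, match="all-zero"):
            poisson_encode(np.zeros((4, 4)), EncodingConfig(total_spikes=10), rng)

    def test_uniform_image_counts_uniform(self, rng):
        """Chi-square at 1%: a flat image spreads spikes uniformly."""
        img = np.full((8, 8), 0.9)
        ev = poisson_encode(img, EncodingConfig(total_spikes=64_000), rng)
        counts = np.bincount(ev.addresses, minlength=64)
        chi2 = ((counts - 1000.0) ** 2 / 1000.0).sum()
        assert chi2 < stats.chi2.ppf(0.99, df=63)

    def test_duration_mode_total_count_poisson(self, rng_factory):
        """Over 100 seeds the total event count in duration mode stays
        within 3 sigma of rate x duration (Poisson total oracle)."""
        img = np.full((4, 4), 1.0)
        cfg = EncodingConfig(total_rate=10_000.0, duration_us=100_000,
                             total_spikes=None)
        lam = 1000.0
        totals = [len(poisson_encode(img, cfg, rng_factory(s))) for s in range(100)]
        assert abs(np.mean(totals) - lam) <= 3 * np.sqrt(lam / 100)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            EncodingConfig(duration_us=10, total_spikes=10)
        with pytest.raises(ValueError):
            EncodingConfig(total_rate=-1.0)


class TestBarSequence:
    def test_epoch_times_orientation_count(self, rng):
        cfg = EncodingConfig(total_spikes=50, ist_us=5000)
        seq = bar_sequence([0, 45, 90, 135], epochs=10, config=cfg, rng=rng)
        assert len(seq) == 40
        assert sorted(set(seq.labels)) == [0, 45, 90, 135]

    def test_onset_gaps_are_duration_plus_ist(self, rng):
        cfg = EncodingConfig(total_rate=100_000.0, total_spikes=100, ist_us=7000)
        seq = bar_sequence([0, 90], epochs=3, config=cfg, rng=rng)
        gaps = np.diff(seq.onsets_us)
        assert (gaps == cfg.sample_duration_us + 7000).all()

    def test_seeded_reproducibility(self, rng_factory):
        cfg = EncodingConfig(total_spikes=80, ist_us=1000)
        a = bar_sequence([0, 45], 5, cfg, rng_factory(7))
        b = bar_sequence([0, 45], 5, cfg, rng_factory(7))
        assert a.stream == b.stream
        assert a.labels == b.labels

    def test_sample_slicing_recovers_event_counts(self, rng):
        cfg = EncodingConfig(total_spikes=60, ist_us=1000)
        seq = bar_sequence([0, 90], 4, cfg, rng)
        assert sum(len(seq.sample(k)) for k in range(len(seq))) == len(seq.stream)


class TestMovingSymbol:
    def test_stationary_path_emits_nothing(self, rng):
        path = np.column_stack([
            np.arange(0, 101_000, 1000), np.full(101, 64.0), np.full(101, 64.0)
        ])
        ev = moving_symbol_stream("diamond", path=path, duration_us=100_000, rng=rng)
        assert len(ev) == 0

    def test_events_confined_to_trajectory_envelope(self, rng):
        """Geometric containment: every event lies within the glyph's
        half-extent (plus rounding slack) of the path."""
        path = random_smooth_path(100_000, (128, 128), margin=50.0, rng=rng)
        ev = moving_symbol_stream("heart", path=path, duration_us=100_000,
                                  rng=rng, scale=4)
        assert len(ev) > 0
        half = 32.0  # scaled 16x16 glyph at scale 4 -> 64 px, half extent 32
        r = ev.addresses // 128
        c = ev.addresses % 128
        t = ev.timestamps
        pr = np.interp(t, path[:, 0], path[:, 1])
        pc = np.interp(t, path[:, 0], path[:, 2])
        assert (np.abs(r - pr) <= half + 2).all()
        assert (np.abs(c - pc) <= half + 2).all()

    def test_seeded_reproducibility(self, rng_factory):
        a = moving_symbol_stream("club", duration_us=50_000, rng=rng_factory(3))
        b = moving_symbol_stream("club", duration_us=50_000, rng=rng_factory(3))
        assert a == b

    def test_all_glyphs_have_edges(self):
        for name in stimuli.GLYPH_NAMES:
            mask = glyph_mask(name)
            assert mask.sum() > 20
            assert len(glyph_edge_pixels(mask)) > 10

    def test_unknown_glyph(self):
        with pytest.raises(ValueError):
            glyph_mask("joker")


def write_idx_images(path, images):
    with open(path, "wb") as fh:
        n, rows, cols = len(images), images[0].shape[0], images[0].shape[1]
        fh.write(struct.pack(">IIII", 0x00000803, n, rows, cols))
        for img in images:
            fh.write((img * 255).astype(np.uint8).tobytes())


def write_idx_labels(path, labels):
    with open(path, "wb") as fh:
        fh.write(struct.pack(">II", 0x00000801, len(labels)))
        fh.write(bytes(labels))


class TestIdxReader:
    def test_round_trip_synthetic_fixture(self, tmp_path, rng):
        imgs = [rng.random((5, 4)) for _ in range(3)]
        p = tmp_path / "imgs.idx"
        write_idx_images(p, imgs)
        back = read_idx_images(p)
        assert len(back) == 3
        for a, b in zip(imgs, back):
            assert np.allclose(a, b, atol=1 / 255)
            assert b.max() <= 1.0

    def test_label_image_length_mismatch(self, tmp_path, rng):
        pi = tmp_path / "imgs.idx"
        pl = tmp_path / "labels.idx"
        write_idx_images(pi, [rng.random((3, 3)) for _ in range(3)])
        write_idx_labels(pl, [0, 1])
        with pytest.raises(ValueError, match="mismatch"):
            load_idx_dataset(pi, pl)

    def test_bad_magic_number(self, tmp_path):
        p = tmp_path / "bad.idx"
        p.write_bytes(struct.pack(">IIII", 0xDEADBEEF, 1, 2, 2) + b"\x00" * 4)
        with pytest.raises(ValueError, match="magic"):
            read_idx_images(p)


def test_generators_are_pure_functions_of_seed(rng_factory):
    img1 = oriented_bar_image(45.0, rng=rng_factory(9))
    img2 = oriented_bar_image(45.0, rng=rng_factory(9))
    assert np.array_equal(img1, img2)
    cfg = EncodingConfig(total_spikes=200)
    e1 = poisson_encode(img1, cfg, rng_factory(10))
    e2 = poisson_encode(img2, cfg, rng_factory(10))
    assert e1 == e2
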