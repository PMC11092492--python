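"""Problem enumeration, glyph rendering and dataset construction."""

import struct

import numpy as np
import pytest

from pdnn import stimuli
from pdnn.stimuli import (OP_ADD, OP_SUB, ArithmeticProblem, GlyphSource,
                          MissingGlyphError, build_dataset, compose_stimulus,
                          enumerate_problems, load_dataset, render_glyph,
                          save_dataset)


class TestEnumeration:
    def test_counts(self):
        probs = enumerate_problems()
        assert len(probs) == 380
        assert sum(p.operator == OP_ADD for p in probs) == 190
        assert sum(p.operator == OP_SUB for p in probs) == 190

    def test_result_zero_counts(self):
        # exhaustive oracle: a+b=0 only for (0,0); a-b=0 for a=b=0..18
        probs = enumerate_problems()
        adds0 = [p for p in probs if p.result == 0 and p.operator == OP_ADD]
        subs0 = [p for p in probs if p.result == 0 and p.operator == OP_SUB]
        assert len(adds0) == 1 and adds0[0].operand_a == 0
        assert len(subs0) == 19
        assert all(p.operand_a == p.operand_b for p in subs0)

    def test_every_result_covered_by_both_operations(self):
        probs = enumerate_problems()
        for r in range(19):
            assert any(p.result == r and p.operator == OP_ADD for p in probs)
            assert any(p.result == r and p.operator == OP_SUB for p in probs)

    def test_canonical_order(self):
        probs = enumerate_problems()
        assert (probs[0].operand_a, probs[0].operand_b, probs[0].operator) == (0, 0, OP_ADD)
        assert probs[190].operator == OP_SUB  # first subtraction at row 191
        # additions first, then ascending result, then ascending first operand
        keys = [(p.operator, p.result, p.operand_a) for p in probs]
        assert keys == sorted(keys)

    def test_invalid_problem_rejected(self):
        with pytest.raises(ValueError):
            ArithmeticProblem(3, 4, OP_ADD, 8)
        with pytest.raises(ValueError):
            ArithmeticProblem(10, 12, OP_ADD, 22)


class TestGlyphs:
    def test_blank_is_black(self, tiny_source):
        rng = np.random.default_rng(0)
        img = render_glyph(stimuli.BLANK, tiny_source, rng)
        assert img.shape == (28, 28)
        assert np.all(img == 0)

    def test_seeded_determinism(self, tiny_source):
        a = render_glyph(stimuli.MINUS, tiny_source, np.random.default_rng(5))
        b = render_glyph(stimuli.MINUS, tiny_source, np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)

    def test_plus_has_central_cross_profile(self, tiny_source):
        # overlay of a vertical and a horizontal stroke: both the column-sum
        # and the row-sum profiles peak near the centre
        img = render_glyph(stimuli.PLUS, tiny_source, np.random.default_rng(3))
        col, row = img.sum(axis=0), img.sum(axis=1)
        assert 7 <= int(np.argmax(col)) <= 20
        assert 7 <= int(np.argmax(row)) <= 20
        # and the plus covers at least as much ink as either stroke alone
        minus = render_glyph(stimuli.MINUS, tiny_source, np.random.default_rng(3))
        assert img.sum() > minus.sum() * 1.2

    def test_minus_is_horizontal(self, tiny_source):
        img = render_glyph(stimuli.MINUS, tiny_source, np.random.default_rng(2))
        # a horizontal stroke: ink concentrated in few rows, spread over columns
        assert img.sum(axis=1).max() > img.sum(axis=0).max()
        assert (img.sum(axis=1) > 0.5).sum() < (img.sum(axis=0) > 0.5).sum()

    def test_missing_pool_raises(self):
        empty = GlyphSource("synthetic", "train", {})
        with pytest.raises(MissingGlyphError):
            render_glyph(3, empty, np.random.default_rng(0))

    def test_glyph_range(self, tiny_source):
        for d in range(10):
            pool = tiny_source.pool(d)
            assert pool.min() >= 0 and pool.max() <= 1


class TestCompose:
    def test_single_digit_layout(self, tiny_source):
        img = compose_stimulus(ArithmeticProblem(3, 4, OP_ADD, 7), tiny_source,
                               np.random.default_rng(0))
        assert img.pixels.shape == (3, 28, 140)
        # tens slots blank for single-digit operands
        assert np.all(img.pixels[:, :, 0:28] == 0)
        assert np.all(img.pixels[:, :, 84:112] == 0)
        # units and operator slots carry ink
        for lo in (28, 56, 112):
            assert img.pixels[:, :, lo:lo + 28].sum() > 0

    def test_two_digit_operand_fills_tens_slot(self, tiny_source):
        img = compose_stimulus(ArithmeticProblem(10, 2, OP_SUB, 8), tiny_source,
                               np.random.default_rng(0))
        assert img.pixels[:, :, 0:28].sum() > 0  # tens '1'
        assert np.all(img.pixels[:, :, 84:112] == 0)  # second operand tens blank

    def test_channels_identical_and_in_range(self, tiny_source):
        img = compose_stimulus(ArithmeticProblem(9, 9, OP_ADD, 18), tiny_source,
                               np.random.default_rng(1))
        np.testing.assert_array_equal(img.pixels[0], img.pixels[1])
        np.testing.assert_array_equal(img.pixels[0], img.pixels[2])
        assert img.pixels.min() >= 0 and img.pixels.max() <= 1


class TestDataset:
    def test_counts_and_labels(self, tiny_dataset):
        assert len(tiny_dataset.train) == 380
        assert len(tiny_dataset.test) == 380
        # label structure identical across splits
        np.testing.assert_array_equal(tiny_dataset.train.result, tiny_dataset.test.result)
        ok = tiny_dataset.train.operator == OP_ADD
        s = np.where(ok, tiny_dataset.train.operand_a + tiny_dataset.train.operand_b,
                     tiny_dataset.train.operand_a - tiny_dataset.train.operand_b)
        np.testing.assert_array_equal(s, tiny_dataset.train.result)

    def test_odd_variants_rejected(self, tiny_source):
        with pytest.raises(ValueError):
            build_dataset(3, tiny_source, tiny_source, seed=0)

    def test_seed_determinism(self, tiny_source):
        a = build_dataset(2, tiny_source, tiny_source, seed=11)
        b = build_dataset(2, tiny_source, tiny_source, seed=11)
        np.testing.assert_array_equal(a.train.pixels, b.train.pixels)
        np.testing.assert_array_equal(a.test.pixels, b.test.pixels)

    def test_batch_is_three_channel(self, tiny_dataset):
        x = tiny_dataset.train.batch(np.arange(3))
        assert x.shape == (3, 3, 28, 140)
        np.testing.assert_array_equal(x[:, 0], x[:, 1])

    def test_roundtrip(self, tiny_dataset, tmp_path):
        path = tmp_path / "ds.npz"
        save_dataset(tiny_dataset, path)
        back = load_dataset(path)
        np.testing.assert_array_equal(back.train.pixels, tiny_dataset.train.pixels)
        np.testing.assert_array_equal(back.test.result, tiny_dataset.test.result)
        assert back.variants_per_problem == tiny_dataset.variants_per_problem
        assert back.rng_seed == tiny_dataset.rng_seed

    def test_truncated_archive_raises(self, tiny_dataset, tmp_path):
        path = tmp_path / "ds.npz"
        save_dataset(tiny_dataset, path)
        raw = path.read_bytes()
        path.write_bytes(raw[: len(raw) // 2])
        with pytest.raises(ValueError):
            load_dataset(path)


class TestIdxReader:
    def _write_idx(self, tmp_path, images, labels):
        ip = tmp_path / "imgs"
        lp = tmp_path / "labels"
        with open(ip, "wb") as fh:
            fh.write(struct.pack(">IIII", 0x803, len(images), 28, 28))
            fh.write(images.astype(np.uint8).tobytes())
        with open(lp, "wb") as fh:
            fh.write(struct.pack(">II", 0x801, len(labels)))
            fh.write(labels.astype(np.uint8).tobytes())
        return ip, lp

    def test_roundtrip(self, tmp_path):
        rng = np.random.default_rng(0)
        images = rng.integers(0, 256, size=(30, 28, 28)).astype(np.uint8)
        labels = np.repeat(np.arange(10), 3).astype(np.uint8)
        ip, lp = self._write_idx(tmp_path, images, labels)
        src = GlyphSource.mnist(ip, lp, "train")
        assert src.backend == "mnist"
        for d in range(10):
            assert len(src.pool(d)) == 3
        np.testing.assert_allclose(src.pool(0)[0], images[labels == 0][0] / 255.0)

    def test_bad_magic_raises(self, tmp_path):
        p = tmp_path / "bad"
        p.write_bytes(struct.pack(">IIII", 0x123, 1, 28, 28) + b"\0" * 784)
        with pytest.raises(ValueError):
            stimuli.read_idx_images(p)
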