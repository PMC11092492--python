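"""Arithmetic stimulus synthesis.

The task space is every addition and subtraction over operands 0..18
whose result also lies in 0..18: 190 addition and 190 subtraction
problems, 380 in total. Each problem is rendered as a five-slot glyph
image ``T1 U1 S T2 U2`` (tens digit, units digit, operator symbol, tens
digit, units digit), each slot 28x28, concatenated to a 3x28x140 tensor
with the grayscale image replicated across the three channels. Tens
slots of single-digit operands are blank (all black).

Two glyph backends are provided: a parametric stroke renderer that
synthesizes handwritten-looking digits (segment skeletons with random
affine jitter, stroke width 2-4 px and additive pixel noise), and a
reader for the MNIST IDX files when they are available on disk. The
operator symbols are built from the digit "1": the minus sign is a "1"
rotated 90 degrees, the plus sign the pixel-wise maximum of a vertical
and a rotated "1".
"""

from __future__ import annotations

import json
import struct
import zipfile
from dataclasses import dataclass, field

import numpy as np

N_RESULTS = 19
SLOT = 28
N_SLOTS = 5
WIDTH = SLOT * N_SLOTS

OP_ADD = 0
OP_SUB = 1
_OP_NAMES = {OP_ADD: "add", OP_SUB: "sub"}


@dataclass(frozen=True)
class ArithmeticProblem:
    operand_a: int
    operand_b: int
    operator: int  # OP_ADD or OP_SUB
    result: int

    def __post_init__(self):
        expected = (
            self.operand_a + self.operand_b
            if self.operator == OP_ADD
            else self.operand_a - self.operand_b
        )
        if expected != self.result:
            raise ValueError(f"inconsistent problem {self}")
        for v in (self.operand_a, self.operand_b, self.result):
            if not 0 <= v <= 18:
                raise ValueError(f"value {v} outside 0..18 in {self}")

    def __str__(self):
        sym = "+" if self.operator == OP_ADD else "-"
        return f"{self.operand_a}{sym}{self.operand_b}={self.result}"


def enumerate_problems() -> list[ArithmeticProblem]:
    """All 380 problems in canonical order.

    Additions before subtractions; within an operation, ascending result;
    within a result, ascending first operand.
    """
    probs = []
    for r in range(N_RESULTS):
        for a in range(r + 1):
            probs.append(ArithmeticProblem(a, r - a, OP_ADD, r))
    for r in range(N_RESULTS):
        for a in range(r, N_RESULTS):
            probs.append(ArithmeticProblem(a, a - r, OP_SUB, r))
    return probs


# ---------------------------------------------------------------------------
# glyph sources

# Stroke skeletons on a [0,1]^2 design box (x right, y down). Each digit is a
# list of polylines; rendering jitters these points affinely per sample.
_SKELETONS = {
    0: [[(0.25, 0.1), (0.75, 0.1), (0.75, 0.9), (0.25, 0.9), (0.25, 0.1)]],
    1: [[(0.5, 0.08), (0.5, 0.92)]],
    2: [[(0.25, 0.15), (0.75, 0.15), (0.75, 0.5), (0.25, 0.5), (0.25, 0.88), (0.78, 0.88)]],
    3: [[(0.25, 0.12), (0.75, 0.12), (0.75, 0.5), (0.3, 0.5)],
        [(0.75, 0.5), (0.75, 0.88), (0.25, 0.88)]],
    4: [[(0.3, 0.1), (0.25, 0.55), (0.78, 0.55)], [(0.68, 0.1), (0.68, 0.9)]],
    5: [[(0.75, 0.12), (0.25, 0.12), (0.25, 0.5), (0.75, 0.5), (0.75, 0.88), (0.22, 0.88)]],
    6: [[(0.7, 0.1), (0.3, 0.45), (0.28, 0.88), (0.72, 0.88), (0.72, 0.52), (0.3, 0.52)]],
    7: [[(0.22, 0.12), (0.78, 0.12), (0.45, 0.9)]],
    8: [[(0.5, 0.1), (0.26, 0.3), (0.72, 0.68), (0.5, 0.9), (0.28, 0.68), (0.74, 0.3), (0.5, 0.1)]],
    9: [[(0.72, 0.45), (0.3, 0.45), (0.3, 0.12), (0.72, 0.12), (0.72, 0.88)]],
}

BLANK = "blank"
PLUS = "plus"
MINUS = "minus"


class MissingGlyphError(KeyError):
    """Raised when a glyph pool has no image for the requested symbol."""


def _raster_polyline(img, pts, width):
    """Stamp a polyline (in pixel coordinates) with a round brush."""
    yy, xx = np.mgrid[0:SLOT, 0:SLOT]
    for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
        length = max(abs(x1 - x0), abs(y1 - y0), 1e-6)
        n = int(length * 2) + 2
        ts = np.linspace(0.0, 1.0, n)
        for t in ts:
            cx, cy = x0 + t * (x1 - x0), y0 + t * (y1 - y0)
            d2 = (xx - cx) ** 2 + (yy - cy) ** 2
            img[:] = np.maximum(img, np.clip(1.2 - d2 / (width * 0.55) ** 2, 0, 1))
    return img


def render_digit_synthetic(digit: int, rng: np.random.Generator) -> np.ndarray:
    """One 28x28 stroke-rendered digit image in [0, 1] with random jitter."""
    angle = rng.normal(0.0, 0.08)
    scale = rng.uniform(0.85, 1.05)
    shear = rng.normal(0.0, 0.08)
    dx, dy = rng.normal(0.0, 1.0, size=2)
    width = rng.uniform(2.0, 4.0) / 2.0
    ca, sa = np.cos(angle), np.sin(angle)
    img = np.zeros((SLOT, SLOT), dtype=np.float32)
    for line in _SKELETONS[digit]:
        pts = []
        for (x, y) in line:
            # design box -> centered coords -> affine jitter -> pixels
            u, v = (x - 0.5) * 20 * scale, (y - 0.5) * 20 * scale
            u = u + shear * v
            ur, vr = ca * u - sa * v, sa * u + ca * v
            jx, jy = rng.normal(0.0, 0.4, size=2)
            pts.append((ur + 13.5 + dx + jx, vr + 13.5 + dy + jy))
        _raster_polyline(img, pts, width)
    img += rng.normal(0.0, 0.02, size=img.shape).astype(np.float32)
    return np.clip(img, 0.0, 1.0)


@dataclass
class GlyphSource:
    """Per-symbol pools of 28x28 grayscale glyphs in [0, 1]."""

    backend: str  # "mnist" or "synthetic"
    split: str  # "train" or "test"
    pools: dict = field(default_factory=dict)  # digit int -> (n, 28, 28) array

    @classmethod
    def synthetic(cls, split: str, pool_size: int = 50, seed: int = 0) -> "GlyphSource":
        # distinct streams per split so train/test glyphs never coincide
        rng = np.random.default_rng([seed, {"train": 0, "test": 1}[split]])
        pools = {
            d: np.stack([render_digit_synthetic(d, rng) for _ in range(pool_size)])
            for d in range(10)
        }
        return cls("synthetic", split, pools)

    @classmethod
    def mnist(cls, images_path, labels_path, split: str) -> "GlyphSource":
        images = read_idx_images(images_path).astype(np.float32) / 255.0
        labels = read_idx_labels(labels_path)
        pools = {d: images[labels == d] for d in range(10)}
        return cls("mnist", split, pools)

    def pool(self, digit: int) -> np.ndarray:
        p = self.pools.get(digit)
        if p is None or len(p) == 0:
            raise MissingGlyphError(f"no glyphs for digit {digit} in {self.split} pool")
        return p


def read_idx_images(path) -> np.ndarray:
    with open(path, "rb") as fh:
        magic, n, rows, cols = struct.unpack(">IIII", fh.read(16))
        if magic != 0x00000803:
            raise ValueError(f"bad IDX image magic {magic:#010x} in {path}")
        data = np.frombuffer(fh.read(n * rows * cols), dtype=np.uint8)
    if data.size != n * rows * cols:
        raise ValueError(f"truncated IDX image file {path}")
    return data.reshape(n, rows, cols)


def read_idx_labels(path) -> np.ndarray:
    with open(path, "rb") as fh:
        magic, n = struct.unpack(">II", fh.read(8))
        if magic != 0x00000801:
            raise ValueError(f"bad IDX label magic {magic:#010x} in {path}")
        data = np.frombuffer(fh.read(n), dtype=np.uint8)
    if data.size != n:
        raise ValueError(f"truncated IDX label file {path}")
    return data


def render_glyph(symbol, source: GlyphSource, rng: np.random.Generator) -> np.ndarray:
    """A 28x28 glyph for a digit 0-9, 'plus', 'minus' or 'blank'.

    Operator glyphs are composed from the digit "1": minus is a "1"
    rotated 90 degrees; plus is the pixel-wise maximum of a vertical "1"
    and its rotation.
    """
    if symbol == BLANK:
        return np.zeros((SLOT, SLOT), dtype=np.float32)
    if symbol == MINUS:
        pool = source.pool(1)
        return np.rot90(pool[rng.integers(len(pool))]).copy()
    if symbol == PLUS:
        pool = source.pool(1)
        vert = pool[rng.integers(len(pool))]
        horiz = np.rot90(pool[rng.integers(len(pool))])
        return np.maximum(vert, horiz)
    pool = source.pool(int(symbol))
    return pool[rng.integers(len(pool))].copy()


@dataclass
class StimulusImage:
    pixels: np.ndarray  # (3, 28, 140) in [0, 1]
    problem: ArithmeticProblem
    variant_id: int = 0


def compose_stimulus(
    problem: ArithmeticProblem, source: GlyphSource, rng: np.random.Generator
) -> StimulusImage:
    """Render one problem into the five-slot layout."""
    row = _compose_row(problem, source, rng)
    return StimulusImage(np.broadcast_to(row, (3, SLOT, WIDTH)).copy(), problem)


def _compose_row(problem, source, rng):
    a, b = problem.operand_a, problem.operand_b
    op = PLUS if problem.operator == OP_ADD else MINUS
    slots = [
        BLANK if a < 10 else a // 10,
        a % 10,
        op,
        BLANK if b < 10 else b // 10,
        b % 10,
    ]
    row = np.zeros((SLOT, WIDTH), dtype=np.float32)
    for i, sym in enumerate(slots):
        row[:, i * SLOT : (i + 1) * SLOT] = render_glyph(sym, source, rng)
    return row


# ---------------------------------------------------------------------------
# dataset


@dataclass
class StimulusSplit:
    """One split of rendered stimuli, stored single-channel.

    ``pixels`` is (n, 28, 140); the three identical channels are
    materialized on batch access to keep memory flat.
    """

    pixels: np.ndarray
    problem_index: np.ndarray  # index into the canonical problem list
    operand_a: np.ndarray
    operand_b: np.ndarray
    operator: np.ndarray
    result: np.ndarray
    variant_id: np.ndarray

    def __len__(self):
        return len(self.pixels)

    def batch(self, indices) -> np.ndarray:
        """(B, 3, 28, 140) float32 input tensor for the network."""
        x = self.pixels[indices]
        return np.broadcast_to(x[:, None], (len(x), 3, SLOT, WIDTH)).copy()


@dataclass
class StimulusDataset:
    problems: list
    train: StimulusSplit
    test: StimulusSplit
    variants_per_problem: int
    rng_seed: int
    backend: str


def build_dataset(
    variants_per_problem: int,
    source_train: GlyphSource,
    source_test: GlyphSource,
    seed: int = 0,
) -> StimulusDataset:
    """Render every problem ``variants_per_problem`` times, half per split."""
    if variants_per_problem % 2 != 0:
        raise ValueError("variants_per_problem must be even")
    problems = enumerate_problems()
    half = variants_per_problem // 2
    splits = {}
    for split_name, source in (("train", source_train), ("test", source_test)):
        rng = np.random.default_rng([seed, 2 + (split_name == "test")])
        n = len(problems) * half
        pixels = np.empty((n, SLOT, WIDTH), dtype=np.float32)
        meta = np.empty((n, 5), dtype=np.int16)
        k = 0
        for pi, prob in enumerate(problems):
            for v in range(half):
                pixels[k] = _compose_row(prob, source, rng)
                meta[k] = (pi, prob.operand_a, prob.operand_b, prob.operator, prob.result)
                k += 1
        variant = np.tile(np.arange(half, dtype=np.int16), len(problems))
        splits[split_name] = StimulusSplit(
            pixels, meta[:, 0].copy(), meta[:, 1].copy(), meta[:, 2].copy(),
            meta[:, 3].copy(), meta[:, 4].copy(), variant,
        )
    return StimulusDataset(
        problems, splits["train"], splits["test"], variants_per_problem, seed,
        source_train.backend,
    )


def save_dataset(dataset: StimulusDataset, path) -> None:
    meta = {
        "variants_per_problem": dataset.variants_per_problem,
        "rng_seed": dataset.rng_seed,
        "backend": dataset.backend,
    }
    arrays = {"meta_json": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)}
    for name in ("train", "test"):
        sp = getattr(dataset, name)
        for f in ("pixels", "problem_index", "operand_a", "operand_b", "operator",
                  "result", "variant_id"):
            arrays[f"{name}_{f}"] = getattr(sp, f)
    np.savez_compressed(path, **arrays)


def load_dataset(path) -> StimulusDataset:
    try:
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta_json"]).decode())
            splits = {}
            for name in ("train", "test"):
                splits[name] = StimulusSplit(
                    *(z[f"{name}_{f}"] for f in (
                        "pixels", "problem_index", "operand_a", "operand_b",
                        "operator", "result", "variant_id"))
                )
    except (KeyError, ValueError, OSError, json.JSONDecodeError,
            zipfile.BadZipFile) as exc:
        raise ValueError(f"corrupt stimulus archive {path}: {exc}") from exc
    return StimulusDataset(
        enumerate_problems(), splits["train"], splits["test"],
        meta["variants_per_problem"], meta["rng_seed"], meta["backend"],
    )
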