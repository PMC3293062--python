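"""Co-occurrence, run-length and gradient texture statistics.

Three classical statistical texture families, computed from a quantized
`GrayImage`:

* **Co-occurrence matrix (COM / GLCM)** — joint frequencies of gray-level
  pairs at a fixed pixel offset, accumulated symmetrically; eleven
  Haralick-type scalar features are derived from the normalized matrix.
* **Run-length matrix (RLM)** — counts of maximal runs of equal gray level
  along one of four directions, by level and length; five scalar features.
* **Gradient map (GRM)** — central-difference gradient magnitudes at every
  interior pixel of the *unquantized* image; five distribution moments.

`extract_features` / `TextureFeatureExtractor` bundle the three families
into one row of named descriptors per image, averaging COM and RLM features
over the four principal angles (rotation-robust aggregation) so that each
co-occurrence distance contributes one value per statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .image import GrayImage, quantize

__all__ = [
    "CooccurrenceMatrix",
    "RunLengthMatrix",
    "GradientMap",
    "TextureConfig",
    "COM_FEATURES",
    "RLM_FEATURES",
    "GRM_FEATURES",
    "compute_com",
    "com_features",
    "compute_rlm",
    "rlm_features",
    "compute_grm",
    "grm_features",
    "extract_features",
    "feature_names",
    "TextureFeatureExtractor",
]

RLM_DIRECTIONS = (0, 45, 90, 135)

COM_FEATURES = (
    "asm",
    "contrast",
    "correlation",
    "sum_of_squares",
    "idm",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
)
RLM_FEATURES = (
    "short_run_emphasis",
    "long_run_emphasis",
    "gray_level_nonuniformity",
    "run_length_nonuniformity",
    "run_percentage",
)
GRM_FEATURES = ("mean", "variance", "skewness", "kurtosis", "nonzero_pct")


@dataclass(frozen=True)
class CooccurrenceMatrix:
    """Symmetric gray-level co-occurrence counts at one pixel offset."""

    counts: np.ndarray
    offset: tuple[int, int]
    levels: int

    @property
    def normalized(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            raise ValueError("co-occurrence matrix is empty")
        return self.counts / total


@dataclass(frozen=True)
class RunLengthMatrix:
    """Counts of maximal equal-level runs, indexed (gray level, run length).

    ``counts[g, r]`` is the number of maximal runs of gray level ``g`` and
    length ``r`` (column 0 is unused).
    """

    counts: np.ndarray
    direction: int
    n_pixels: int

    @property
    def n_runs(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class GradientMap:
    """Gradient magnitudes at interior pixels (border excluded)."""

    magnitudes: np.ndarray


def _offset_slices(shape: tuple[int, int], dy: int, dx: int):
    """Index slices selecting the (p, p + offset) pixel pairs inside an image."""
    h, w = shape
    ys = slice(max(0, -dy), h - max(0, dy))
    xs = slice(max(0, -dx), w - max(0, dx))
    yt = slice(max(0, dy), h + min(0, dy))
    xt = slice(max(0, dx), w + min(0, dx))
    return (ys, xs), (yt, xt)


def compute_com(img: GrayImage, offset: tuple[int, int]) -> CooccurrenceMatrix:
    """Accumulate the symmetric co-occurrence matrix for one offset.

    Every in-bounds pixel pair ``(p, p + (dy, dx))`` increments both
    ``counts[g(p), g(p + o)]`` and its transpose entry, so the matrix is
    symmetric by construction and direction sign is immaterial.
    """
    dy, dx = int(offset[0]), int(offset[1])
    if dy == 0 and dx == 0:
        raise ValueError("offset (0, 0) is not a valid co-occurrence displacement")
    if abs(dy) >= img.height or abs(dx) >= img.width:
        raise ValueError(
            f"offset {offset} exceeds image of size {img.height}x{img.width}"
        )
    L = img.levels
    (src, tgt) = _offset_slices(img.pixels.shape, dy, dx)
    a = img.pixels[src[0], src[1]].ravel()
    b = img.pixels[tgt[0], tgt[1]].ravel()
    counts = np.bincount(a * L + b, minlength=L * L).reshape(L, L)
    counts = counts + counts.T
    return CooccurrenceMatrix(counts=counts, offset=(dy, dx), levels=L)


def com_features(M: CooccurrenceMatrix) -> dict[str, float]:
    """Eleven Haralick-type features of a normalized co-occurrence matrix.

    Gray levels are indexed 0..L-1; logarithms are base 2 with the usual
    0*log(0) = 0 convention.  Correlation of a zero-variance marginal is
    defined as 0 so feature vectors stay finite.
    """
    P = M.normalized
    L = M.levels
    i = np.arange(L, dtype=np.float64)

    px = P.sum(axis=1)  # marginal over rows; == column marginal by symmetry
    mu_x = float(i @ px)
    var_x = float(((i - mu_x) ** 2) @ px)

    # distributions of i+j (0..2L-2) and |i-j| (0..L-1)
    p_sum = np.zeros(2 * L - 1)
    p_diff = np.zeros(L)
    for k in range(L):
        p_sum[k : k + L] += P[k]
    idx = np.abs(i[:, None] - i[None, :]).astype(int)
    np.add.at(p_diff, idx.ravel(), P.ravel())

    ks = np.arange(2 * L - 1, dtype=np.float64)
    kd = np.arange(L, dtype=np.float64)

    def _entropy(p: np.ndarray) -> float:
        nz = p[p > 0]
        return float(-(nz * np.log2(nz)).sum())

    asm = float((P * P).sum())
    diff_mat = (i[:, None] - i[None, :]) ** 2
    contrast = float((diff_mat * P).sum())
    if var_x > 0:
        correlation = float(((i[:, None] * i[None, :]) * P).sum() - mu_x * mu_x) / var_x
    else:
        correlation = 0.0
    sum_of_squares = float((((i[:, None] - mu_x) ** 2) * P).sum())
    idm = float((P / (1.0 + diff_mat)).sum())
    sum_average = float(ks @ p_sum)
    sum_variance = float(((ks - sum_average) ** 2) @ p_sum)
    sum_entropy = _entropy(p_sum)
    entropy = _entropy(P.ravel())
    diff_mean = float(kd @ p_diff)
    difference_variance = float(((kd - diff_mean) ** 2) @ p_diff)
    difference_entropy = _entropy(p_diff)

    return {
        "asm": asm,
        "contrast": contrast,
        "correlation": correlation,
        "sum_of_squares": sum_of_squares,
        "idm": idm,
        "sum_average": sum_average,
        "sum_variance": sum_variance,
        "sum_entropy": sum_entropy,
        "entropy": entropy,
        "difference_variance": difference_variance,
        "difference_entropy": difference_entropy,
    }


def _direction_lines(pixels: np.ndarray, direction: int) -> Iterable[np.ndarray]:
    h, w = pixels.shape
    if direction == 0:
        yield from pixels
    elif direction == 90:
        yield from pixels.T
    elif direction == 45:  # anti-diagonals
        fl = np.fliplr(pixels)
        for k in range(-(h - 1), w):
            yield fl.diagonal(k)
    elif direction == 135:  # main diagonals
        for k in range(-(h - 1), w):
            yield pixels.diagonal(k)
    else:
        raise ValueError(f"direction must be one of {RLM_DIRECTIONS}, got {direction}")


def compute_rlm(img: GrayImage, direction: int = 0) -> RunLengthMatrix:
    """Tally maximal runs of equal gray level along one direction.

    A single pixel counts as a run of length 1, so every pixel belongs to
    exactly one maximal run and ``sum(r * counts[g, r]) == H * W``.
    """
    if direction not in RLM_DIRECTIONS:
        raise ValueError(f"direction must be one of {RLM_DIRECTIONS}, got {direction}")
    px = img.pixels
    rmax = max(px.shape)
    counts = np.zeros((img.levels, rmax + 1), dtype=np.int64)
    for line in _direction_lines(px, direction):
        if line.size == 0:
            continue
        # maximal-run boundaries: positions where the level changes
        breaks = np.flatnonzero(np.diff(line))
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks + 1, [line.size]))
        lengths = ends - starts
        np.add.at(counts, (line[starts], lengths), 1)
    return RunLengthMatrix(counts=counts, direction=direction, n_pixels=px.size)


def rlm_features(R: RunLengthMatrix) -> dict[str, float]:
    """Five classical run-length features.

    Short/long-run emphasis weight runs by 1/r^2 and r^2; the two
    nonuniformity measures penalize concentration of runs in few gray levels
    or few lengths; run percentage is runs per pixel.
    """
    n_runs = R.n_runs
    if n_runs == 0:
        raise ValueError("run-length matrix has no runs")
    r = np.arange(R.counts.shape[1], dtype=np.float64)
    runs_by_length = R.counts.sum(axis=0).astype(np.float64)
    runs_by_level = R.counts.sum(axis=1).astype(np.float64)
    inv_r2 = np.zeros_like(r)
    inv_r2[1:] = 1.0 / r[1:] ** 2
    return {
        "short_run_emphasis": float((runs_by_length * inv_r2).sum() / n_runs),
        "long_run_emphasis": float((runs_by_length * r**2).sum() / n_runs),
        "gray_level_nonuniformity": float((runs_by_level**2).sum() / n_runs),
        "run_length_nonuniformity": float((runs_by_length**2).sum() / n_runs),
        "run_percentage": float(n_runs / R.n_pixels),
    }


def compute_grm(img: GrayImage) -> GradientMap:
    """Central-difference gradient magnitudes at interior pixels.

    ``sqrt((I[y+1,x] - I[y-1,x])^2 + (I[y,x+1] - I[y,x-1])^2)`` — the
    absolute-gradient convention: the spacing of 2 is not divided out.
    Border pixels are excluded rather than padded.
    """
    if img.height < 3 or img.width < 3:
        raise ValueError("gradient map needs an image of at least 3x3")
    p = img.pixels.astype(np.float64)
    gy = p[2:, 1:-1] - p[:-2, 1:-1]
    gx = p[1:-1, 2:] - p[1:-1, :-2]
    return GradientMap(magnitudes=np.sqrt(gy * gy + gx * gx))


def grm_features(G: GradientMap) -> dict[str, float]:
    """Distribution moments of the gradient-magnitude map.

    Variance is the population variance; skewness and excess kurtosis of a
    zero-variance map are defined as 0 by convention.  ``nonzero_pct`` is
    the percentage of interior pixels with nonzero magnitude.
    """
    m = G.magnitudes.ravel()
    if m.size == 0:
        raise ValueError("gradient map is empty")
    mean = float(m.mean())
    centered = m - mean
    var = float(np.mean(centered**2))
    if var > 0:
        skew = float(np.mean(centered**3) / var**1.5)
        kurt = float(np.mean(centered**4) / var**2 - 3.0)
    else:
        skew = 0.0
        kurt = 0.0
    return {
        "mean": mean,
        "variance": var,
        "skewness": skew,
        "kurtosis": kurt,
        "nonzero_pct": float(100.0 * np.count_nonzero(m) / m.size),
    }


# one offset per (distance, angle); symmetric accumulation makes sign moot
_ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclass(frozen=True)
class TextureConfig:
    """Settings of the texture-extraction stage.

    ``levels``/``normalization`` control the quantization applied before the
    co-occurrence and run-length statistics; the gradient family always uses
    the unquantized 256-level image.  ``distances`` are the co-occurrence
    displacements, each evaluated at the four principal angles.
    """

    levels: int = 64
    normalization: str = "minmax"
    distances: tuple[int, ...] = (1, 2, 3, 4, 5)
    angles: tuple[int, ...] = (0, 45, 90, 135)
    rlm_directions: tuple[int, ...] = RLM_DIRECTIONS


def feature_names(config: TextureConfig | None = None) -> list[str]:
    """Ordered names of the descriptors `extract_features` produces."""
    config = config or TextureConfig()
    names = [
        f"com_d{d}_{feat}" for d in config.distances for feat in COM_FEATURES
    ]
    names += [f"rlm_{feat}" for feat in RLM_FEATURES]
    names += [f"grm_{feat}" for feat in GRM_FEATURES]
    return names


def _single_image_features(img: GrayImage, config: TextureConfig) -> dict[str, float]:
    if img.levels == 256:
        quantized = quantize(img, config.levels, config.normalization)
        gradient_src = img
    else:
        # already quantized upstream; gradient falls back to the same raster
        quantized = img
        gradient_src = img

    out: dict[str, float] = {}
    for d in config.distances:
        per_angle = [
            com_features(compute_com(quantized, (dy * d, dx * d)))
            for (dy, dx) in (_ANGLE_OFFSETS[a] for a in config.angles)
        ]
        for feat in COM_FEATURES:
            out[f"com_d{d}_{feat}"] = float(np.mean([f[feat] for f in per_angle]))

    per_dir = [rlm_features(compute_rlm(quantized, a)) for a in config.rlm_directions]
    for feat in RLM_FEATURES:
        out[f"rlm_{feat}"] = float(np.mean([f[feat] for f in per_dir]))

    out.update({f"grm_{k}": v for k, v in grm_features(compute_grm(gradient_src)).items()})
    return out


def extract_features(
    images: Sequence[GrayImage],
    sample_ids: Sequence[str] | None = None,
    groups: Sequence[str] | None = None,
    config: TextureConfig | None = None,
) -> pd.DataFrame:
    """Compute one row of named texture descriptors per image.

    Returns a feature table: columns ``sample_id``, ``group`` followed by
    the descriptors of `feature_names`.  COM and RLM features are averaged
    over the four angles; COM features carry the pixel distance in their
    name.  Images may differ in size.
    """
    if len(images) == 0:
        raise ValueError("no images supplied")
    config = config or TextureConfig()
    if sample_ids is None:
        sample_ids = [f"img_{k:04d}" for k in range(len(images))]
    if groups is None:
        groups = ["unlabeled"] * len(images)
    if not (len(images) == len(sample_ids) == len(groups)):
        raise ValueError("images, sample_ids and groups must have equal length")

    rows = []
    for img, sid, grp in zip(images, sample_ids, groups):
        row: dict[str, object] = {"sample_id": sid, "group": grp}
        row.update(_single_image_features(img, config))
        rows.append(row)
    return pd.DataFrame(rows, columns=["sample_id", "group"] + feature_names(config))


class TextureFeatureExtractor(TransformerMixin, BaseEstimator):
    """Stateless transformer turning gray images into texture descriptors.

    A thin scikit-learn wrapper over `extract_features`: ``transform`` maps
    a sequence of `GrayImage` (or 2-D uint8 arrays, taken as 256-level
    images) to a DataFrame of named texture features.
    """

    def __init__(
        self,
        levels: int = 64,
        normalization: str = "minmax",
        distances: tuple[int, ...] = (1, 2, 3, 4, 5),
    ) -> None:
        self.levels = levels
        self.normalization = normalization
        self.distances = distances

    def _config(self) -> TextureConfig:
        return TextureConfig(
            levels=self.levels,
            normalization=self.normalization,
            distances=tuple(self.distances),
        )

    def fit(self, X: Sequence[GrayImage], y=None) -> "TextureFeatureExtractor":
        self.feature_names_out_ = feature_names(self._config())
        return self

    def transform(self, X: Sequence[GrayImage]) -> pd.DataFrame:
        images = [
            x if isinstance(x, GrayImage) else GrayImage(np.asarray(x), levels=256)
            for x in X
        ]
        table = extract_features(images, config=self._config())
        return table.drop(columns=["sample_id", "group"])

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(feature_names(self._config()), dtype=object)
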