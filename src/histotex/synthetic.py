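"""Synthetic study data: tubule-like texture images and per-animal tables.

No micrographs or raw per-animal measurements from the emulated study are
publicly deposited, so this module generates stand-ins with the same
statistical structure, making every pipeline stage testable end to end.

**Images.**  Testis cross-sections are dominated by seminiferous tubules:
roughly circular profiles with a dark epithelial wall, a cell-stippled
lining and a pale lumen.  Toxicant damage shows as atrophy — fewer,
shrunken tubules, depleted germ-cell stippling and vacuolation.  The
generator places non-overlapping annuli on a noisy background and exposes a
continuous degeneration level ``delta`` in [0, 1]: ``delta = 0`` is intact
morphology, ``delta = 1`` fully degenerated, intermediate values model
partially protected dose groups.  ``delta`` thins the epithelial stippling
by the factor ``(1 - delta)``, reduces tubule count and wall radius, and
adds luminal vacuoles.  This is a texture phantom, not photorealistic
histology: it reproduces the *spatial statistics* contrast between classes,
which is all the downstream texture features consume.

**Tables.**  Per-animal vectors of the eight fertility and oxidative-stress
indicators (testis and epididymis weight, sperm count and motility, MDA,
MPO, CAT, SOD) are drawn independently per indicator as
``Normal(mean, SE * sqrt(n))`` from the printed group summaries (mean, SE,
n = 10) shipped in ``data/group_defaults.yaml``.  Covariances between
indicators are not published and are not modeled.
"""

from __future__ import annotations

import importlib.resources as resources
import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import yaml

from .image import GrayImage

__all__ = [
    "INDICATORS",
    "TextureClassParams",
    "GroupSpec",
    "DEFAULT_DELTA_SCHEDULE",
    "default_group_specs",
    "default_image_class_specs",
    "make_texture_image",
    "make_image_dataset",
    "make_animal_table",
]

logger = logging.getLogger(__name__)

INDICATORS = ("Testis W", "Epidid. W", "SpC", "SpM", "MDA", "MPO", "CAT", "SOD")

#: Degeneration level per group: control intact, toxicant-only fully
#: degenerated, protected groups intermediate in dose order.
DEFAULT_DELTA_SCHEDULE = {
    "N": 0.0,
    "CIS": 1.0,
    "CIS+L": 0.7,
    "CIS+M": 0.35,
    "CIS+H": 0.15,
}

# gray levels of the phantom's tissue compartments (8-bit)
_BG = 200
_WALL = 70
_CELL = 90
_LUMEN = 230
_VACUOLE = 245


@dataclass(frozen=True)
class TextureClassParams:
    """Morphology parameters of one texture class.

    tubule_density
        Expected tubule (annulus) count per 10^4 px^2 at ``delta = 0``.
    radius_range
        (min, max) outer wall radius in px.
    wall_thickness
        Thickness of the dark tubule wall in px.
    p_fill
        Per-pixel probability of an epithelial cell dot in the lining at
        ``delta = 0``; thinned to ``(1 - delta) * p_fill``.
    noise_sd
        Gaussian pixel-noise standard deviation in gray levels.
    delta
        Degeneration level in [0, 1].
    """

    tubule_density: float = 1.2
    radius_range: tuple[float, float] = (14.0, 24.0)
    wall_thickness: float = 3.0
    p_fill: float = 0.55
    noise_sd: float = 6.0
    delta: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError(f"delta must lie in [0, 1], got {self.delta}")
        if self.radius_range[0] <= 0 or self.radius_range[1] < self.radius_range[0]:
            raise ValueError(f"invalid radius range {self.radius_range}")
        if not 0.0 <= self.p_fill <= 1.0:
            raise ValueError(f"p_fill must lie in [0, 1], got {self.p_fill}")


@dataclass(frozen=True)
class GroupSpec:
    """Printed summary statistics of one animal group.

    ``means``/``ses`` map each of the eight indicators to the printed group
    mean and standard error; ``n_animals`` is the group size.
    """

    name: str
    means: dict[str, float]
    ses: dict[str, float]
    n_animals: int = 10

    def __post_init__(self) -> None:
        for ind in INDICATORS:
            if ind not in self.means or ind not in self.ses:
                raise ValueError(f"group {self.name!r} lacks indicator {ind!r}")
        if any(se <= 0 for se in self.ses.values()):
            raise ValueError(f"group {self.name!r} has a non-positive SE")
        if self.n_animals < 2:
            raise ValueError("n_animals must be at least 2")


def _load_defaults() -> dict:
    text = (resources.files("histotex") / "data" / "group_defaults.yaml").read_text()
    return yaml.safe_load(text)


def default_group_specs(groups: list[str] | None = None) -> list[GroupSpec]:
    """GroupSpecs for the six study arms, from the shipped summary table."""
    raw = _load_defaults()
    selected = groups if groups is not None else list(raw["groups"])
    specs = []
    for name in selected:
        if name not in raw["groups"]:
            raise KeyError(
                f"unknown group {name!r}; available: {list(raw['groups'])}"
            )
        entry = raw["groups"][name]
        specs.append(
            GroupSpec(
                name=name,
                means={k: float(v["mean"]) for k, v in entry.items()},
                ses={k: float(v["se"]) for k, v in entry.items()},
                n_animals=int(raw["n_animals"]),
            )
        )
    return specs


def default_image_class_specs(
    n_images: int = 36,
    base: TextureClassParams | None = None,
) -> list[tuple[str, TextureClassParams, int]]:
    """One texture class per histology group, on the default delta schedule."""
    base = base or TextureClassParams()
    return [
        (group, replace(base, delta=delta), n_images)
        for group, delta in DEFAULT_DELTA_SCHEDULE.items()
    ]


def _place_centers(
    rng: np.random.Generator,
    size: tuple[int, int],
    n_target: int,
    radius_range: tuple[float, float],
) -> list[tuple[float, float, float]]:
    h, w = size
    placed: list[tuple[float, float, float]] = []
    max_tries = 200 * max(n_target, 1)
    tries = 0
    while len(placed) < n_target and tries < max_tries:
        tries += 1
        r = rng.uniform(*radius_range)
        cy = rng.uniform(r, h - r)
        cx = rng.uniform(r, w - r)
        if all((cy - y) ** 2 + (cx - x) ** 2 >= (r + pr + 2.0) ** 2 for y, x, pr in placed):
            placed.append((cy, cx, r))
    if len(placed) < n_target:
        raise ValueError(
            f"could only place {len(placed)} of {n_target} tubules without overlap; "
            "lower tubule_density or radius_range"
        )
    return placed


def make_texture_image(
    params: TextureClassParams,
    size: tuple[int, int] = (256, 256),
    seed: int | np.random.SeedSequence | None = 0,
) -> GrayImage:
    """Render one tubule phantom as a 256-level gray image.

    Deterministic given ``(params, size, seed)``.  Raises if the requested
    density cannot be placed without overlap within a bounded number of
    rejection-sampling retries.
    """
    h, w = size
    if h < 64 or w < 64:
        raise ValueError(f"image size must be at least 64x64, got {size}")
    rng = np.random.default_rng(seed)
    delta = params.delta

    canvas = np.full((h, w), float(_BG))
    # lumen and vacuoles are optically empty: no stain granularity, so the
    # pixel noise below is confined to tissue (background, walls, cells)
    clear = np.zeros((h, w), dtype=bool)

    density = params.tubule_density * (1.0 - 0.6 * delta)
    n_target = int(round(density * h * w / 1e4))
    r_scale = 1.0 - 0.3 * delta
    radius_range = (params.radius_range[0] * r_scale, params.radius_range[1] * r_scale)
    centers = _place_centers(rng, size, n_target, radius_range)

    yy, xx = np.mgrid[0:h, 0:w]
    for cy, cx, r in centers:
        y0, y1 = max(0, int(cy - r) - 1), min(h, int(cy + r) + 2)
        x0, x1 = max(0, int(cx - r) - 1), min(w, int(cx + r) + 2)
        d = np.sqrt((yy[y0:y1, x0:x1] - cy) ** 2 + (xx[y0:y1, x0:x1] - cx) ** 2)
        local = canvas[y0:y1, x0:x1]

        local_clear = clear[y0:y1, x0:x1]
        lumen = d < r - params.wall_thickness
        wall = (d <= r) & ~lumen
        local[lumen] = _LUMEN
        local_clear[lumen] = True
        local[wall] = _WALL
        local_clear[wall] = False

        # epithelial lining: stippled cells in the inner band of the lumen
        lining = lumen & (d >= r - params.wall_thickness - 0.35 * r)
        dots = rng.random(local.shape) < (1.0 - delta) * params.p_fill
        cells = lining & dots
        local[cells] = _CELL
        local_clear[cells] = False

        # degenerate tubules develop bright luminal vacuoles
        if delta > 0:
            n_vac = rng.poisson(3.0 * delta)
            for _ in range(n_vac):
                vr = rng.uniform(0.08, 0.22) * r
                ang = rng.uniform(0, 2 * np.pi)
                rad = rng.uniform(0, max(r - params.wall_thickness - vr, 0.0))
                vy, vx = cy + rad * np.sin(ang), cx + rad * np.cos(ang)
                vd = np.sqrt(
                    (yy[y0:y1, x0:x1] - vy) ** 2 + (xx[y0:y1, x0:x1] - vx) ** 2
                )
                local[vd < vr] = _VACUOLE
                local_clear[vd < vr] = True

    if params.noise_sd > 0:
        noise = rng.normal(0.0, params.noise_sd, size=canvas.shape)
        canvas = canvas + np.where(clear, 0.0, noise)
    pixels = np.clip(np.floor(canvas + 0.5), 0, 255).astype(np.int64)
    return GrayImage(pixels, levels=256)


def make_image_dataset(
    class_specs: list[tuple[str, TextureClassParams, int]],
    size: tuple[int, int] = (256, 256),
    seed: int = 0,
) -> tuple[list[GrayImage], pd.DataFrame]:
    """Generate labeled image batches, one batch per texture class.

    Returns the images and a metadata frame (``sample_id``, ``group``,
    ``delta``, ``seed``) allowing exact regeneration of any single image.
    """
    names = [name for name, _, _ in class_specs]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate group names in class specs: {names}")
    for _, _, n_images in class_specs:
        if n_images < 1:
            raise ValueError("n_images must be at least 1")

    root = np.random.SeedSequence(seed)
    children = root.spawn(sum(n for _, _, n in class_specs))
    images: list[GrayImage] = []
    rows = []
    k = 0
    for name, params, n_images in class_specs:
        for j in range(n_images):
            child = children[k]
            images.append(make_texture_image(params, size=size, seed=child))
            rows.append(
                {
                    "sample_id": f"{name}_{j:03d}",
                    "group": name,
                    "delta": params.delta,
                    "seed_entropy": int(child.entropy),
                    "seed_spawn_key": child.spawn_key[0],
                }
            )
            k += 1
    return images, pd.DataFrame(rows)


def make_animal_table(
    specs: list[GroupSpec] | None = None,
    seed: int = 0,
    spread: str = "se",
) -> pd.DataFrame:
    """Draw per-animal indicator vectors from printed group summaries.

    Each indicator is drawn independently as ``Normal(mean, sd)`` with
    ``sd = SE * sqrt(n_animals)`` when ``spread="se"`` (the printed spread
    is a standard error) or ``sd = SE`` when ``spread="sd"``.  Negative
    draws of the physically nonnegative indicators are truncated at 0 with
    a logged warning.  Deterministic given ``(specs, seed)``.
    """
    if spread not in ("se", "sd"):
        raise ValueError(f'spread must be "se" or "sd", got {spread!r}')
    if specs is None:
        specs = default_group_specs()
    rng = np.random.default_rng(seed)
    rows = []
    for spec in specs:
        for j in range(spec.n_animals):
            row: dict[str, object] = {
                "sample_id": f"{spec.name}_a{j:02d}",
                "group": spec.name,
            }
            for ind in INDICATORS:
                sd = spec.ses[ind] * (
                    np.sqrt(spec.n_animals) if spread == "se" else 1.0
                )
                value = rng.normal(spec.means[ind], sd)
                if value < 0:
                    logger.warning(
                        "truncating negative draw %.4f of %s (%s) at 0",
                        value,
                        ind,
                        spec.name,
                    )
                    value = 0.0
                row[ind] = value
            rows.append(row)
    return pd.DataFrame(rows, columns=["sample_id", "group", *INDICATORS])
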