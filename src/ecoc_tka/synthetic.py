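"""Synthetic cohorts and toy radiographs with the study's statistical shape.

The real patient data (gender, height, weight, per-component prosthesis
sizes, knee films) are private, so every downstream stage is exercised on a
generated stand-in that reproduces the documented structure:

* 308 patients, 68 male / 240 female by default;
* gender-conditional Gaussian height and weight;
* a latent size score ``s = w_g * male + w_h * z(height) + w_w * z(weight)
  + noise`` quantile-binned into 8 femoral and 9 tibial classes with
  near-normal (bell-shaped) class frequencies;
* effect weights calibrated so the population feature-label Pearson
  correlations match the reported values (gender ~0.62, height ~0.63,
  weight ~0.41 for the femoral component);
* tibial labels share the femoral latent plus small jitter, clamped to
  +/- 1 bin of a monotone 8 -> 9 map, so the two components are strongly
  but not perfectly concordant.

Toy films are synthetic silhouettes, labelled as such: condyle / plateau
widths grow monotonically with the size labels, plus Gaussian pixel noise
and burned-in margin text placed where the default preprocessing crop
removes it.  They carry the size signal into pixels; they are not
anatomically realistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .preprocessing import RadiographPair

__all__ = [
    "CohortConfig",
    "generate_cohort",
    "render_radiograph",
    "split_cohort",
    "split_sizes",
    "gender_numeric",
]

#: Effect weights and noise level calibrated (one-off Monte-Carlo at large n)
#: so that the population correlations of gender / height / weight with the
#: binned femoral size hit the reported targets.
_CALIBRATED = {
    "w_gender": 0.6227,
    "w_height": 0.3460,
    "w_weight": 0.1763,
    "noise_sd": 0.5732,
}


@dataclass
class CohortConfig:
    """Generator settings; defaults are the emulated study conditions."""

    n_patients: int = 308
    female_fraction: float = 240 / 308
    male_height: tuple[float, float] = (172.0, 6.0)
    female_height: tuple[float, float] = (159.0, 6.0)
    male_weight: tuple[float, float] = (75.0, 10.0)
    female_weight: tuple[float, float] = (65.0, 10.0)
    w_gender: float = _CALIBRATED["w_gender"]
    w_height: float = _CALIBRATED["w_height"]
    w_weight: float = _CALIBRATED["w_weight"]
    noise_sd: float = _CALIBRATED["noise_sd"]
    #: sd (in class-index units) of the bell-shaped target class frequencies
    label_spread_femoral: float = 2.0
    label_spread_tibial: float = 2.25
    #: sd of the extra latent jitter decoupling tibial from femoral labels
    tibial_jitter: float = 0.25
    n_femoral_classes: int = 8
    n_tibial_classes: int = 9
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.female_fraction < 1:
            raise ValueError("female_fraction must lie in (0, 1)")
        for name in ("male_height", "female_height", "male_weight", "female_weight"):
            if getattr(self, name)[1] <= 0:
                raise ValueError(f"{name} sd must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_patients < self.n_femoral_classes:
            raise ValueError(
                f"need at least {self.n_femoral_classes} patients, got {self.n_patients}"
            )


def gender_numeric(gender: pd.Series | Sequence[str]) -> np.ndarray:
    """Map 'male'/'female' strings to the 1/0 coding used in correlations."""
    return np.asarray([1.0 if str(g).lower().startswith("m") else 0.0 for g in gender])


def _bell_probs(k: int, spread: float) -> np.ndarray:
    """Bell-shaped class probabilities over indices 1..k (discretized normal)."""
    idx = np.arange(1, k + 1, dtype=float)
    p = np.exp(-((idx - (k + 1) / 2.0) ** 2) / (2.0 * spread ** 2))
    return p / p.sum()


def _quantile_bin(latent: np.ndarray, probs: np.ndarray) -> np.ndarray:
    """Bin a latent score at its own sample quantiles so class frequencies
    follow ``probs``; returns 1-based ordinal labels."""
    edges = np.quantile(latent, np.cumsum(probs)[:-1])
    return np.digitize(latent, edges) + 1


def generate_cohort(config: CohortConfig | None = None) -> pd.DataFrame:
    """Generate a synthetic patient table.

    Columns: ``id, gender, height_cm, weight_kg, femoral_size, tibial_size``.
    Deterministic per ``config.seed``.
    """
    cfg = config or CohortConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients

    male = rng.random(n) >= cfg.female_fraction
    height = np.where(
        male,
        rng.normal(*cfg.male_height, size=n),
        rng.normal(*cfg.female_height, size=n),
    )
    weight = np.where(
        male,
        rng.normal(*cfg.male_weight, size=n),
        rng.normal(*cfg.female_weight, size=n),
    )

    # population (analytic) standardization of the continuous features
    p_m = 1 - cfg.female_fraction
    h_mean = p_m * cfg.male_height[0] + (1 - p_m) * cfg.female_height[0]
    h_var = (
        p_m * cfg.male_height[1] ** 2
        + (1 - p_m) * cfg.female_height[1] ** 2
        + p_m * (1 - p_m) * (cfg.male_height[0] - cfg.female_height[0]) ** 2
    )
    w_mean = p_m * cfg.male_weight[0] + (1 - p_m) * cfg.female_weight[0]
    w_var = (
        p_m * cfg.male_weight[1] ** 2
        + (1 - p_m) * cfg.female_weight[1] ** 2
        + p_m * (1 - p_m) * (cfg.male_weight[0] - cfg.female_weight[0]) ** 2
    )

    latent = (
        cfg.w_gender * male.astype(float)
        + cfg.w_height * (height - h_mean) / np.sqrt(h_var)
        + cfg.w_weight * (weight - w_mean) / np.sqrt(w_var)
        + cfg.noise_sd * rng.normal(size=n)
    )

    femoral = _quantile_bin(latent, _bell_probs(cfg.n_femoral_classes, cfg.label_spread_femoral))

    tib_latent = latent + cfg.tibial_jitter * rng.normal(size=n)
    tibial = _quantile_bin(tib_latent, _bell_probs(cfg.n_tibial_classes, cfg.label_spread_tibial))
    # coupling: tibial stays within +/-1 bin of the monotone femoral map
    anchor = np.round(
        (femoral - 1) * (cfg.n_tibial_classes - 1) / (cfg.n_femoral_classes - 1)
    ).astype(int) + 1
    tibial = np.clip(tibial, anchor - 1, anchor + 1)
    tibial = np.clip(tibial, 1, cfg.n_tibial_classes)

    return pd.DataFrame(
        {
            "id": [f"P{i:04d}" for i in range(n)],
            "gender": np.where(male, "male", "female"),
            "height_cm": np.round(height, 1),
            "weight_kg": np.round(weight, 1),
            "femoral_size": femoral.astype(int),
            "tibial_size": tibial.astype(int),
        }
    )


# ---------------------------------------------------------------------------
# Toy radiograph rendering
# ---------------------------------------------------------------------------

def render_radiograph(
    patient: pd.Series | dict,
    image_size: int = 64,
    seed: int = 0,
    noise_sd: float = 8.0,
) -> RadiographPair:
    """Render a synthetic AP / lateral film pair for one patient.

    The femoral condyle block (upper) and tibial plateau block (lower) have
    widths strictly increasing in the respective size labels; margin text is
    drawn in the top rows, entirely inside the region removed by the default
    central-85% crop.  Deterministic per ``seed``.
    """
    if image_size < 64:
        raise ValueError(f"image_size must be >= 64, got {image_size}")
    rng = np.random.default_rng(seed)
    fem = int(patient["femoral_size"])
    tib = int(patient["tibial_size"])
    s = image_size

    def view(width_scale: float) -> np.ndarray:
        img = np.full((s, s), 30.0)
        # femoral condyle block: width grows ~3 px per femoral size step
        fw = int(round((0.28 + 0.035 * fem) * s * width_scale))
        img[int(0.20 * s): int(0.45 * s), (s - fw) // 2: (s + fw) // 2] = 200.0
        # joint gap
        # tibial plateau block: width grows with tibial size
        tw = int(round((0.26 + 0.030 * tib) * s * width_scale))
        img[int(0.52 * s): int(0.75 * s), (s - tw) // 2: (s + tw) // 2] = 180.0
        # tibial shaft
        sw = int(round(0.18 * s))
        img[int(0.75 * s): s, (s - sw) // 2: (s + sw) // 2] = 160.0
        # burned-in margin "text": bright glyph blocks in the top margin rows,
        # inside the outer 7.5% stripe that the default crop discards
        margin = max(2, int(0.075 * s))
        glyphs = rng.random((margin - 1, int(0.4 * s))) > 0.5
        img[1: margin, 2: 2 + glyphs.shape[1]][glyphs] = 255.0
        if noise_sd > 0:
            img += rng.normal(scale=noise_sd, size=img.shape)
        return np.clip(np.round(img), 0, 255).astype(np.uint8)

    return RadiographPair(ap=view(1.0), lateral=view(0.8))


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def split_sizes(n: int, ratios: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of ``n`` samples into ``ratios``."""
    ratios = np.asarray(ratios, dtype=float)
    if (ratios <= 0).any():
        raise ValueError("ratios must be positive")
    quotas = n * ratios / ratios.sum()
    sizes = np.floor(quotas).astype(int)
    remainder = quotas - sizes
    # distribute leftover seats by descending remainder, ties to earlier splits
    for idx in np.argsort(-remainder, kind="stable")[: n - sizes.sum()]:
        sizes[idx] += 1
    return [int(x) for x in sizes]


def split_cohort(
    cohort: pd.DataFrame,
    ratios: Sequence[float] = (4, 1, 1),
    seed: int = 0,
    stratify_on: str = "femoral_size",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Stratified train/validation/test split at the given ratios.

    Sizes come from largest-remainder rounding (308 at 4:1:1 gives
    206/51/51).  Stratification preserves per-class proportions; if any class
    is too small to stratify, the split falls back to unstratified with a
    warning.  Splits are disjoint and cover the cohort.
    """
    n_train, n_val, n_test = split_sizes(len(cohort), ratios)

    def _two_way(frame: pd.DataFrame, test_size: int, strat: bool):
        return train_test_split(
            frame,
            test_size=test_size,
            random_state=seed,
            stratify=frame[stratify_on] if strat else None,
        )

    try:
        rest, test = _two_way(cohort, n_test, True)
        train, val = _two_way(rest, n_val, True)
    except ValueError:
        warnings.warn(
            "class too small for stratification; falling back to a plain "
            "random split",
            stacklevel=2,
        )
        rest, test = _two_way(cohort, n_test, False)
        train, val = _two_way(rest, n_val, False)
    return train, val, test
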