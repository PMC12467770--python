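"""Synthetic cohorts, feature channels with known MI, and toy radiographs.

This module generates everything the rest of the package needs to be
exercised without external data:

* an echocardiography-style cohort table (age, sex, three left-ventricular
  dimensions, and a binary severe-LVH label derived by thresholding wall
  thickness),
* linear-Gaussian feature channels whose true mutual information with each
  injected attribute is known in closed form (continuous attributes) or by
  1-D quadrature (binary attributes),
* rendered "radiograph-like" images in which a central annular cardiac
  silhouette carries the attributes at controllable strengths, and
* the class-balanced subset construction used to de-bias training splits.

All generators are deterministic given their config and seed. The default
cohort parameters are synthetic conveniences chosen for physiological
plausibility (dimension means/SDs in the echocardiographic normal range,
severe-hypertrophy thresholds near the upper reference limits); they are
not estimates from any real cohort.
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from scipy.integrate import quad

from .mine import FeatureMatrix

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "ChannelSpec",
    "RenderConfig",
    "sample_cohort",
    "make_linear_gaussian_features",
    "binary_gaussian_channel_mi",
    "gain_for_target_mi",
    "render_images",
    "make_balanced_subset",
    "assign_splits",
]


@dataclass
class CohortConfig:
    """Generative model of the attribute table.

    Age is truncated-normal (years); sex is Bernoulli(0.5) coded 0/1
    (1 = male); each LV dimension (cm) is a linear model in age and sex
    plus Gaussian noise; the severe-LVH label is 1 iff IVSDd or LVPWDd
    exceeds its sex-specific threshold.
    """

    n: int = 2000
    seed: int = 0
    age_mean: float = 62.0
    age_sd: float = 14.0
    age_range: tuple[float, float] = (18.0, 95.0)
    sex_p: float = 0.5
    # per-dimension: intercept (cm), beta_age (cm/year), beta_sex (cm), noise sd (cm)
    ivsdd: tuple[float, float, float, float] = (0.85, 0.004, 0.10, 0.22)
    lvpwdd: tuple[float, float, float, float] = (0.82, 0.004, 0.08, 0.20)
    lvidd: tuple[float, float, float, float] = (4.80, -0.005, 0.25, 0.45)
    # severe-hypertrophy wall-thickness thresholds (cm), (female, male)
    ivsdd_threshold: tuple[float, float] = (1.35, 1.45)
    lvpwdd_threshold: tuple[float, float] = (1.30, 1.40)

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("cohort size must be >= 2")
        for name in ("ivsdd", "lvpwdd", "lvidd"):
            if getattr(self, name)[3] <= 0:
                raise ValueError(f"{name} noise sd must be positive")
        if min(*self.ivsdd_threshold, *self.lvpwdd_threshold) <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class SyntheticCohort:
    """Attribute table plus generator provenance."""

    table: pd.DataFrame
    config: CohortConfig

    ATTRIBUTES = ("age", "sex", "IVSDd", "LVPWDd", "LVIDd")
    COLUMNS = ("sample_id", "age", "sex", "IVSDd", "LVPWDd", "LVIDd", "slvh")

    def __post_init__(self):
        missing = set(self.COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"cohort table missing columns {sorted(missing)}")
        if self.table.isna().any().any():
            raise ValueError("cohort table contains missing values")
        if self.table["sample_id"].duplicated().any():
            raise ValueError("sample_ids must be unique")

    @property
    def n(self) -> int:
        return len(self.table)

    def provenance(self) -> dict:
        cfg = asdict(self.config)
        blob = json.dumps(cfg, sort_keys=True, default=str)
        return {"config": cfg,
                "config_hash": hashlib.sha256(blob.encode()).hexdigest()[:12]}


def sample_cohort(cfg: CohortConfig) -> SyntheticCohort:
    """Draw a cohort from the generative model; label rule applied exactly."""
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.age_range
    a, b = (lo - cfg.age_mean) / cfg.age_sd, (hi - cfg.age_mean) / cfg.age_sd
    age = stats.truncnorm.rvs(a, b, loc=cfg.age_mean, scale=cfg.age_sd,
                              size=cfg.n, random_state=rng)
    sex = (rng.random(cfg.n) < cfg.sex_p).astype(float)

    def dim(params):
        c0, b_age, b_sex, sd = params
        return c0 + b_age * age + b_sex * sex + rng.normal(0.0, sd, cfg.n)

    ivsdd = dim(cfg.ivsdd)
    lvpwdd = dim(cfg.lvpwdd)
    lvidd = dim(cfg.lvidd)
    thr_ivs = np.where(sex == 1.0, cfg.ivsdd_threshold[1], cfg.ivsdd_threshold[0])
    thr_pw = np.where(sex == 1.0, cfg.lvpwdd_threshold[1], cfg.lvpwdd_threshold[0])
    slvh = ((ivsdd > thr_ivs) | (lvpwdd > thr_pw)).astype(int)
    if slvh.min() == slvh.max():
        raise ValueError(
            "label rule produced a single class; adjust thresholds or coefficients")
    table = pd.DataFrame({
        "sample_id": [f"s{i:06d}" for i in range(cfg.n)],
        "age": age, "sex": sex, "IVSDd": ivsdd, "LVPWDd": lvpwdd,
        "LVIDd": lvidd, "slvh": slvh,
    })
    return SyntheticCohort(table=table, config=cfg)


# ---------------------------------------------------------------------------
# Linear-Gaussian feature channels with known true MI
# ---------------------------------------------------------------------------

@dataclass
class ChannelSpec:
    """Injection of attributes into dedicated feature coordinates.

    Feature k carries its attribute as gain_k * z(attr_k) + N(0, noise_sd^2);
    the remaining (d - len(gains)) coordinates are pure noise. For a
    Gaussian(ized) continuous attribute the true MI of its coordinate is
    0.5 * ln(1 + gain^2 / sd^2) nats; for the 0/1 sex attribute it is
    computed by quadrature over the two-component mixture density.
    """

    gains: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 1.0
    d: int = 16

    def __post_init__(self):
        if self.noise_sd <= 0:
            raise ValueError("noise sd must be positive")
        if self.d < len(self.gains):
            raise ValueError("d must be at least the number of injected attributes")


def binary_gaussian_channel_mi(gain: float, noise_sd: float, p: float = 0.5) -> float:
    """MI (nats) between X~Bernoulli(p) in {0,1} and Y = gain*z(X) + noise.

    Standardizing X in {0,1} gives z = (X - p)/sqrt(p(1-p)), so the two
    conditional means of Y are mu0 = -gain*p/sqrt(p(1-p)) and
    mu1 = gain*(1-p)/sqrt(p(1-p)). MI = h(Y) - h(Y|X), where h(Y|X) is the
    Gaussian noise entropy and the mixture entropy h(Y) is evaluated by
    adaptive quadrature over the two-component density. No closed form
    exists for h(Y); the quadrature (interval +-10 noise SDs around the
    component means, scipy.integrate.quad default tolerances) is the
    stated oracle.
    """
    s = noise_sd
    sq = np.sqrt(p * (1.0 - p))
    mu0 = gain * (0.0 - p) / sq
    mu1 = gain * (1.0 - p) / sq

    def density(y):
        return ((1.0 - p) * stats.norm.pdf(y, mu0, s)
                + p * stats.norm.pdf(y, mu1, s))

    def integrand(y):
        f = density(y)
        return -f * np.log(f) if f > 0 else 0.0

    lo = min(mu0, mu1) - 10 * s
    hi = max(mu0, mu1) + 10 * s
    h_y, _ = quad(integrand, lo, hi, limit=200)
    h_y_given_x = 0.5 * np.log(2 * np.pi * np.e * s * s)
    return float(h_y - h_y_given_x)


def gain_for_target_mi(target_mi: float, noise_sd: float = 1.0,
                       binary: bool = False, p: float = 0.5) -> float:
    """Injection gain achieving a requested true MI (nats).

    Continuous channel: inverts 0.5*ln(1 + g^2/sd^2) in closed form.
    Binary channel: solves the quadrature MI for g by bisection; the
    target must stay below the entropy ceiling H(p) (ln 2 for p=0.5).
    """
    if target_mi < 0:
        raise ValueError("target MI must be non-negative")
    if not binary:
        return float(noise_sd * np.sqrt(np.expm1(2.0 * target_mi)))
    h_max = -(p * np.log(p) + (1 - p) * np.log(1 - p))
    if target_mi >= h_max:
        raise ValueError(f"binary channel MI is capped at H(p)={h_max:.4f} nats")
    if target_mi == 0.0:
        return 0.0
    from scipy.optimize import brentq
    hi = noise_sd
    while binary_gaussian_channel_mi(hi, noise_sd, p) < target_mi:
        hi *= 2.0
    return float(brentq(
        lambda g: binary_gaussian_channel_mi(g, noise_sd, p) - target_mi,
        0.0, hi, xtol=1e-10))


def make_linear_gaussian_features(cohort: SyntheticCohort, spec: ChannelSpec,
                                  seed: int = 0
                                  ) -> tuple[FeatureMatrix, dict[str, float]]:
    """Features with one dedicated coordinate per injected attribute.

    Returns the FeatureMatrix and the true MI (nats) per injected
    attribute. Attributes are z-scored before injection, so the continuous
    closed form 0.5*ln(1 + gain^2/sd^2) applies exactly to the
    Gaussian-distributed dimensions; sex uses the mixture quadrature.
    Attributes with gain 0 (or never injected) have true MI 0.
    """
    rng = np.random.default_rng(seed)
    n, d, sd = cohort.n, spec.d, spec.noise_sd
    values = rng.normal(0.0, sd, size=(n, d))
    true_mi: dict[str, float] = {}
    for k, (name, gain) in enumerate(spec.gains.items()):
        if name not in cohort.table.columns:
            raise KeyError(f"attribute {name!r} not in cohort table")
        col = cohort.table[name].to_numpy(dtype=float)
        z = (col - col.mean()) / col.std()
        values[:, k] += gain * z
        if gain == 0.0:
            true_mi[name] = 0.0
        elif name == "sex":
            p = float(col.mean())
            true_mi[name] = binary_gaussian_channel_mi(gain, sd, p)
        else:
            true_mi[name] = float(0.5 * np.log1p(gain * gain / (sd * sd)))
    fm = FeatureMatrix(values, sample_ids=cohort.table["sample_id"].tolist(),
                       layer_tag="synthetic/linear_gaussian")
    return fm, true_mi


# ---------------------------------------------------------------------------
# Toy radiograph renderer
# ---------------------------------------------------------------------------

@dataclass
class RenderConfig:
    """Geometry and noise of the annular "cardiac" structure.

    Radii and thicknesses are in pixels; per-attribute gains multiply the
    cohort z-score of that attribute. A lateral intensity asymmetry
    encodes sex; additive pixel noise is Gaussian.
    """

    size: int = 64
    base_inner_radius: float = 10.0
    base_thickness: float = 4.0
    base_silhouette: float = 26.0
    thickness_gain: float = 2.2      # per unit z of (z(IVSDd)+z(LVPWDd))/sqrt(2)
    inner_radius_gain: float = 2.0   # per unit z of LVIDd
    silhouette_gain: float = 2.0     # per unit z of age
    sex_asymmetry: float = 0.25      # relative left/right intensity shift
    exposure_sd: float = 0.18        # per-image multiplicative gain jitter
    offset_sd: float = 0.06          # per-image additive brightness jitter
    noise_sd: float = 0.08
    ring_intensity: float = 0.85
    interior_intensity: float = 0.35
    silhouette_intensity: float = 0.18

    def __post_init__(self):
        if self.size < 32:
            raise ValueError("image size must be >= 32")


def _zscore(col: np.ndarray) -> np.ndarray:
    sd = col.std()
    return (col - col.mean()) / sd if sd > 0 else np.zeros_like(col)


def render_images(cohort: SyntheticCohort, render_cfg: RenderConfig | None = None,
                  seed: int = 0, clip_z: float = 3.0) -> np.ndarray:
    """Render one grayscale image per cohort row, values in [0, 1].

    Returns an (n, size, size) float array in cohort row order. Ring
    thickness tracks wall thickness (IVSDd + LVPWDd), inner radius tracks
    LVIDd, the outer silhouette tracks age, and a left/right brightness
    asymmetry encodes sex. Attribute z-scores are clipped at ``clip_z``
    before scaling so extreme draws cannot push the geometry outside the
    frame; a config whose nominal geometry exceeds the frame errors out.
    """
    cfg = render_cfg or RenderConfig()
    t = cohort.table
    z_ivs = _zscore(t["IVSDd"].to_numpy(float))
    z_pw = _zscore(t["LVPWDd"].to_numpy(float))
    z_lvid = _zscore(t["LVIDd"].to_numpy(float))
    z_age = _zscore(t["age"].to_numpy(float))
    sex = t["sex"].to_numpy(float)

    z_ivs, z_pw, z_lvid, z_age = (np.clip(z, -clip_z, clip_z)
                                  for z in (z_ivs, z_pw, z_lvid, z_age))
    inner = cfg.base_inner_radius + cfg.inner_radius_gain * z_lvid
    # the septal (upper) and posterior (lower) walls are distinct structures;
    # each half-ring's thickness tracks its own measurement
    thick_top = np.maximum(cfg.base_thickness + cfg.thickness_gain * z_ivs, 0.5)
    thick_bot = np.maximum(cfg.base_thickness + cfg.thickness_gain * z_pw, 0.5)
    sil = cfg.base_silhouette + cfg.silhouette_gain * z_age
    inner = np.maximum(inner, 2.0)
    thick = np.maximum(thick_top, thick_bot)
    max_extent = float(np.max(np.maximum(inner + thick, sil)))
    if max_extent >= cfg.size / 2.0:
        raise ValueError(
            f"geometry (extent {max_extent:.1f}px) exceeds the {cfg.size}px frame; "
            "reduce gains or base radii")

    half = (cfg.size - 1) / 2.0
    yy, xx = np.mgrid[0:cfg.size, 0:cfg.size]
    r = np.hypot(yy - half, xx - half)
    left = (xx < half)
    top = (yy < half)

    rng = np.random.default_rng(seed)
    imgs = np.empty((cohort.n, cfg.size, cfg.size))
    for i in range(cohort.n):
        img = np.full((cfg.size, cfg.size), 0.08)
        img[r < sil[i]] = cfg.silhouette_intensity
        img[r < inner[i]] = cfg.interior_intensity
        t_map = np.where(top, thick_top[i], thick_bot[i])
        ring = (r >= inner[i]) & (r < inner[i] + t_map)
        img[ring] = cfg.ring_intensity
        shift = cfg.sex_asymmetry * (sex[i] - 0.5)
        img = img * np.where(left, 1.0 + shift, 1.0 - shift)
        # per-image exposure jitter: keeps global intensity statistics from
        # trivially encoding the anatomy (radiograph exposure varies per shot)
        if cfg.exposure_sd > 0 or cfg.offset_sd > 0:
            img = (img * (1.0 + rng.normal(0.0, cfg.exposure_sd))
                   + rng.normal(0.0, cfg.offset_sd))
        if cfg.noise_sd > 0:
            img = img + rng.normal(0.0, cfg.noise_sd, img.shape)
        imgs[i] = np.clip(img, 0.0, 1.0)
    return imgs


# ---------------------------------------------------------------------------
# Class-balanced subsets
# ---------------------------------------------------------------------------

def assign_splits(n: int, proportions: tuple[float, float, float] = (0.8, 0.1, 0.1),
                  seed: int = 0, groups=None) -> np.ndarray:
    """Random train/val/test assignment; group-aware when ``groups`` given.

    Returns an array of strings in {'train','val','test'}. With a groups
    vector (e.g. patient ids), whole groups are assigned to one split so
    no group straddles splits.
    """
    if abs(sum(proportions) - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    rng = np.random.default_rng(seed)
    names = np.array(["train", "val", "test"])
    if groups is None:
        units = np.arange(n)
        unit_of = units
    else:
        groups = np.asarray(groups)
        units, unit_of = np.unique(groups, return_inverse=True)
        units = np.arange(len(units))
    order = rng.permutation(len(units))
    cut1 = int(round(proportions[0] * len(units)))
    cut2 = cut1 + int(round(proportions[1] * len(units)))
    unit_split = np.empty(len(units), dtype=object)
    unit_split[order[:cut1]] = "train"
    unit_split[order[cut1:cut2]] = "val"
    unit_split[order[cut2:]] = "test"
    return unit_split[unit_of].astype(str)


def make_balanced_subset(labels, split, seed: int = 0) -> dict[str, np.ndarray]:
    """Equalize class counts within each split by down-sampling the majority.

    The minority class of each split is kept whole; the majority class is
    sampled without replacement to match it. Returns sorted index arrays
    per split name. Already-balanced splits come back unchanged (up to
    ordering). Errors if any split lacks a class.
    """
    labels = np.asarray(labels).astype(int)
    split = np.asarray(split)
    rng = np.random.default_rng(seed)
    out: dict[str, np.ndarray] = {}
    for name in pd.unique(split):
        idx = np.flatnonzero(split == name)
        pos = idx[labels[idx] == 1]
        neg = idx[labels[idx] == 0]
        if len(pos) == 0 or len(neg) == 0:
            raise ValueError(f"split {name!r} lacks one class; cannot balance")
        m = min(len(pos), len(neg))
        keep_pos = pos if len(pos) == m else rng.choice(pos, size=m, replace=False)
        keep_neg = neg if len(neg) == m else rng.choice(neg, size=m, replace=False)
        out[str(name)] = np.sort(np.concatenate([keep_pos, keep_neg]))
    return out
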