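"""Desk-scale biased synthetic fundus dataset generator.

Emulates the statistical structure the two-branch screening model
assumes, without any clinical data:

* multi-hot *fundus feature* labels (microaneurysm-like blobs, streaks,
  rings, dot clusters) rendered as scattered glyph instances on a noisy
  background -- pathological information in real fundus images is
  scattered across the field, and the glyphs reproduce that motif;
* multi-hot *disease* labels derived from the features through a fixed
  causal map (each disease an OR/AND of 1-3 features), so disease labels
  are a deterministic function of the rendered pathology;
* sensitive attributes (sex, nine 10-year age brackets) that bias the
  data twice: group-dependent feature prevalence (exponential tilts) and
  a group-dependent global *style* shift (brightness/tint/vignette) that
  touches pixels only, never labels -- a classic shortcut signal.

Label-density targets (mean labels per image) default to 1.94 for
diseases and 2.05 for features; a build-time root-find scales the
feature prevalences so the analytic mixture density matches the feature
target exactly, and the implied disease density is validated against its
target.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq

__all__ = [
    "AGE_BRACKETS",
    "SEXES",
    "GlyphSpec",
    "SyntheticSpec",
    "SampleSet",
    "generate_dataset",
    "load_dataset",
    "label_density",
    "inject_bias",
    "evaluate_causal_map",
]

AGE_BRACKETS = ["0-10", "11-20", "21-30", "31-40", "41-50", "51-60", "61-70", "71-80", "81-90"]
SEXES = ["female", "male"]

GLYPH_SHAPES = ("blob", "streak", "ring", "dot_cluster")

FEATURE_PREFIX = "feat_"
DISEASE_PREFIX = "dis_"


class SpecValidationError(ValueError):
    """The synthetic spec cannot realise its configured targets."""


@dataclass
class GlyphSpec:
    """Rendering recipe of one fundus-feature glyph."""

    shape: str  # one of GLYPH_SHAPES
    intensity: float  # signed additive amplitude
    rgb: tuple[float, float, float]  # per-channel gain
    size_range: tuple[int, int] = (2, 5)  # radius / half-length in px
    count_range: tuple[int, int] = (1, 3)  # instances per positive image

    def __post_init__(self) -> None:
        if self.shape not in GLYPH_SHAPES:
            raise ValueError(f"unknown glyph shape {self.shape!r}")


def _default_glyphs(n: int) -> list[GlyphSpec]:
    palettes = [
        (1.0, 0.3, 0.2),  # reddish (hemorrhage-like)
        (0.9, 0.8, 0.3),  # yellowish (drusen/exudate-like)
        (0.4, 0.9, 0.5),  # greenish
        (0.8, 0.8, 0.9),  # pale
    ]
    # salient lesions: the reference systems this emulates operate near
    # AP ceiling, so glyphs must be learnable by a small encoder within
    # a few epochs, not borderline-detectable
    glyphs = []
    for i in range(n):
        glyphs.append(
            GlyphSpec(
                shape=GLYPH_SHAPES[i % 4],
                intensity=0.65 if i % 2 == 0 else -0.5,
                rgb=palettes[(i // 2) % 4],
                size_range=(3, 5 + i % 3),
                count_range=(2, 4),
            )
        )
    return glyphs


@dataclass
class SyntheticSpec:
    """Full description of one synthetic dataset family.

    ``causal_map`` maps each disease name to ``(op, [feature names])``
    with op "or" or "and" over 1-3 features. ``sex_direction`` /
    ``age_gradient`` give each feature's bias orientation; prevalence in
    a (sex, bracket) cell is

        clip(scale * w_f * exp(sex_bias * u_f * s) * exp(age_bias * g_f * (b-4)/4))

    with s = +1 female / -1 male and b the bracket index. ``scale`` is
    solved at build time so the analytic mixture feature density equals
    ``rho_feature``.
    """

    feature_names: list[str]
    disease_names: list[str]
    causal_map: dict[str, tuple[str, list[str]]]
    base_weights: list[float]
    sex_direction: list[float]
    age_gradient: list[float]
    sex_bias: float = 0.6
    age_bias: float = 0.0  # the default biased dataset is sex-biased only
    age_distribution: list[float] = field(
        default_factory=lambda: [2, 3, 5, 8, 10, 12, 12, 8, 3]
    )
    rho_disease: float = 1.94
    rho_feature: float = 2.05
    image_size: tuple[int, int] = (64, 80)  # (height, width)
    glyphs: list[GlyphSpec] | None = None
    style_brightness: float = 0.12  # style-mode +/- brightness shift
    style_tint: float = 0.08  # style-mode channel tint
    style_vignette: float = 0.25  # dim-style vignette amplitude
    style_mix: float = 0.85  # P(bright style | female); 1-this for males
    label_noise: float = 0.0  # post-causal-map disease bit-flip rate
    # even split: group-stratified AP needs enough positives in the rarest
    # (disease, sex) test cell to be a stable measurement
    train_fraction: float = 0.5
    seed: int = 0
    min_prob: float = 0.01
    max_prob: float = 0.95
    scale: float = field(init=False)

    def __post_init__(self) -> None:
        nf, nd = len(self.feature_names), len(self.disease_names)
        if self.glyphs is None:
            self.glyphs = _default_glyphs(nf)
        if len(self.glyphs) != nf:
            raise SpecValidationError("one glyph spec per feature required")
        if not (len(self.base_weights) == len(self.sex_direction) == len(self.age_gradient) == nf):
            raise SpecValidationError("per-feature parameter lengths must match feature count")
        if min(self.base_weights) <= 0:
            raise SpecValidationError("prevalence weights must be positive")
        if set(self.causal_map) != set(self.disease_names):
            raise SpecValidationError("causal map must cover exactly the disease list")
        for d, (op, feats) in self.causal_map.items():
            if op not in ("or", "and"):
                raise SpecValidationError(f"disease {d!r}: op must be 'or' or 'and'")
            if not 1 <= len(feats) <= 3:
                raise SpecValidationError(f"disease {d!r} must reference 1-3 features")
            unknown = set(feats) - set(self.feature_names)
            if unknown:
                raise SpecValidationError(f"disease {d!r} references unknown features {unknown}")
        if not 0 <= self.label_noise < 0.5:
            raise SpecValidationError("label_noise must lie in [0, 0.5)")
        self.age_distribution = list(np.asarray(self.age_distribution, float) / np.sum(self.age_distribution))
        self.scale = self._solve_scale()
        fd, dd = self.expected_densities()
        if abs(dd - self.rho_disease) / self.rho_disease > 0.15:
            raise SpecValidationError(
                f"causal map yields analytic disease density {dd:.3f}, more than "
                f"15% from the target {self.rho_disease}"
            )

    # -- analytic prevalence model ----------------------------------------

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    @property
    def n_diseases(self) -> int:
        return len(self.disease_names)

    def cell_probs(self, sex: str, bracket_idx: int, scale: float | None = None) -> np.ndarray:
        """Per-feature Bernoulli prevalence in one (sex, age) cell."""
        s = 1.0 if sex == "female" else -1.0
        scale = self.scale if scale is None else scale
        p = (
            scale
            * np.asarray(self.base_weights)
            * np.exp(self.sex_bias * np.asarray(self.sex_direction) * s)
            * np.exp(self.age_bias * np.asarray(self.age_gradient) * (bracket_idx - 4) / 4.0)
        )
        return np.clip(p, self.min_prob, self.max_prob)

    def _disease_prob(self, p: np.ndarray) -> float:
        total = 0.0
        fidx = {f: i for i, f in enumerate(self.feature_names)}
        for d in self.disease_names:
            op, feats = self.causal_map[d]
            probs = p[[fidx[f] for f in feats]]
            total += float(np.prod(probs)) if op == "and" else float(1 - np.prod(1 - probs))
        return total

    def expected_densities(self, scale: float | None = None) -> tuple[float, float]:
        """Analytic mixture (feature, disease) label densities."""
        fd = dd = 0.0
        for sex in SEXES:
            for b, wb in enumerate(self.age_distribution):
                p = self.cell_probs(sex, b, scale=scale)
                fd += 0.5 * wb * p.sum()
                dd += 0.5 * wb * self._disease_prob(p)
        return fd, dd

    def _solve_scale(self) -> float:
        def gap(s: float) -> float:
            return self.expected_densities(scale=s)[0] - self.rho_feature

        hi = self.max_prob / max(self.base_weights)
        if gap(hi) < 0:
            raise SpecValidationError(
                f"feature density target {self.rho_feature} unreachable: even at "
                f"maximal prevalence the analytic density is {gap(hi) + self.rho_feature:.3f}"
            )
        lo = 1e-6
        if gap(lo) > 0:
            raise SpecValidationError("feature density target below the clip floor")
        return float(brentq(gap, lo, hi, xtol=1e-10))

    def relation_matrix(self) -> np.ndarray:
        """Ground-truth binary feature-disease relation (n_features, n_diseases)."""
        rel = np.zeros((self.n_features, self.n_diseases))
        fidx = {f: i for i, f in enumerate(self.feature_names)}
        for j, d in enumerate(self.disease_names):
            for f in self.causal_map[d][1]:
                rel[fidx[f], j] = 1.0
        return rel

    # -- factories ---------------------------------------------------------

    @classmethod
    def default(cls, seed: int = 0, **overrides) -> "SyntheticSpec":
        """The default biased 8-feature / 6-disease configuration."""
        features = [
            "microaneurysm", "hemorrhage", "drusen", "tortuous_vessel",
            "cotton_wool_spot", "pigment_clump", "exudate", "laser_scar",
        ]
        diseases = [
            "microangiopathy", "drusen_maculopathy", "vascular_occlusion",
            "pigmentary_degeneration", "exudative_retinopathy",
            "photocoagulation_scarring",
        ]
        # two balanced OR-diseases plus four sex-skewed single-feature
        # diseases: every disease keeps per-sex prevalence >= ~0.12 at the
        # default bias so its per-group AP is measurable at desk scale
        causal_map = {
            "microangiopathy": ("or", ["microaneurysm", "hemorrhage"]),
            "drusen_maculopathy": ("or", ["drusen"]),
            "vascular_occlusion": ("or", ["tortuous_vessel", "cotton_wool_spot"]),
            "pigmentary_degeneration": ("or", ["pigment_clump"]),
            "exudative_retinopathy": ("or", ["exudate"]),
            "photocoagulation_scarring": ("or", ["laser_scar"]),
        }
        kwargs = dict(
            feature_names=features,
            disease_names=diseases,
            causal_map=causal_map,
            base_weights=[1.0] * 8,
            sex_direction=[+1, -1, +1, -1, +1, -1, +1, -1],
            age_gradient=[+1, 0, -1, +1, 0, -1, +1, 0],
            seed=seed,
        )
        kwargs.update(overrides)
        return cls(**kwargs)

    @classmethod
    def identity(cls, n: int = 1, prevalence: float = 0.5, seed: int = 0, **overrides) -> "SyntheticSpec":
        """n features mapped one-to-one onto n diseases (test fixture)."""
        features = [f"feature_{i}" for i in range(n)]
        diseases = [f"disease_{i}" for i in range(n)]
        kwargs = dict(
            feature_names=features,
            disease_names=diseases,
            causal_map={d: ("or", [f]) for d, f in zip(diseases, features)},
            base_weights=[1.0] * n,
            sex_direction=[0.0] * n,
            age_gradient=[0.0] * n,
            sex_bias=0.0,
            age_bias=0.0,
            rho_feature=prevalence * n,
            rho_disease=prevalence * n,
            seed=seed,
        )
        kwargs.update(overrides)
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# rendering


def _render_glyph(img: np.ndarray, glyph: GlyphSpec, rng: np.random.Generator) -> None:
    """Draw the instances of one positive feature in place (no AA)."""
    h, w, _ = img.shape
    yy, xx = np.mgrid[0:h, 0:w]
    count = int(rng.integers(glyph.count_range[0], glyph.count_range[1] + 1))
    for _ in range(count):
        cy = int(rng.integers(2, h - 2))
        cx = int(rng.integers(2, w - 2))
        size = int(rng.integers(glyph.size_range[0], glyph.size_range[1] + 1))
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        if glyph.shape == "blob":
            mask = d2 <= size**2
        elif glyph.shape == "ring":
            inner = max(size - 2, 1)
            mask = (d2 <= size**2) & (d2 >= inner**2)
        elif glyph.shape == "streak":
            theta = rng.uniform(0, math.pi)
            dy, dx = math.sin(theta), math.cos(theta)
            along = (yy - cy) * dy + (xx - cx) * dx
            perp = -(yy - cy) * dx + (xx - cx) * dy
            mask = (np.abs(along) <= 3 * size) & (np.abs(perp) <= 1)
        else:  # dot_cluster
            mask = np.zeros((h, w), dtype=bool)
            for _ in range(int(rng.integers(3, 6))):
                oy = cy + int(rng.integers(-2 * size, 2 * size + 1))
                ox = cx + int(rng.integers(-2 * size, 2 * size + 1))
                mask |= (yy - oy) ** 2 + (xx - ox) ** 2 <= 1.5**2
        for ch in range(3):
            img[:, :, ch][mask] += glyph.intensity * glyph.rgb[ch]


def _render_image(
    spec: SyntheticSpec, features: np.ndarray, sex: str, rng: np.random.Generator
) -> np.ndarray:
    h, w = spec.image_size
    noise = gaussian_filter(rng.standard_normal((h, w)), sigma=6.0)
    noise_std = noise.std()
    if noise_std > 0:
        noise = 0.05 * noise / noise_std
    img = np.empty((h, w, 3))
    img[:, :, 0] = 0.42 + noise
    img[:, :, 1] = 0.30 + noise
    img[:, :, 2] = 0.22 + noise
    for fi in np.flatnonzero(features):
        _render_glyph(img, spec.glyphs[fi], rng)
    # sex-linked style shortcut: two imaging "device" styles whose mixture
    # rates depend on sex. Style is informative of sex (a shortcut) yet
    # varies within each sex, so style-reliant scoring corrupts
    # within-group rankings. Pixels only; labels untouched.
    p_style_a = spec.style_mix if sex == "female" else 1.0 - spec.style_mix
    style_a = rng.random() < p_style_a
    s = 1.0 if style_a else -1.0
    img += s * spec.style_brightness
    img[:, :, 0] += max(s, 0) * spec.style_tint
    img[:, :, 1] += max(-s, 0) * spec.style_tint
    vignette = 0.3 * spec.style_vignette if style_a else spec.style_vignette
    if vignette > 0:
        yy, xx = np.mgrid[0:h, 0:w]
        r2 = ((yy - h / 2) / (h / 2)) ** 2 + ((xx - w / 2) / (w / 2)) ** 2
        img *= 1.0 - vignette * (r2 / r2.max())[:, :, None]
    img += rng.normal(0.0, 0.02)  # per-image exposure jitter
    return (np.clip(img, 0.0, 1.0) * 255).round().astype(np.uint8)


# ---------------------------------------------------------------------------
# dataset generation


@dataclass
class SampleSet:
    """In-memory synthetic dataset: manifest plus rendered images."""

    manifest: pd.DataFrame
    images: np.ndarray  # (N, H, W, 3) uint8
    spec: SyntheticSpec | None = None

    def feature_matrix(self) -> np.ndarray:
        cols = [c for c in self.manifest.columns if c.startswith(FEATURE_PREFIX)]
        return self.manifest[cols].to_numpy(dtype=int)

    def disease_matrix(self) -> np.ndarray:
        cols = [c for c in self.manifest.columns if c.startswith(DISEASE_PREFIX)]
        return self.manifest[cols].to_numpy(dtype=int)

    @property
    def disease_names(self) -> list[str]:
        return [c[len(DISEASE_PREFIX):] for c in self.manifest.columns if c.startswith(DISEASE_PREFIX)]

    @property
    def feature_names(self) -> list[str]:
        return [c[len(FEATURE_PREFIX):] for c in self.manifest.columns if c.startswith(FEATURE_PREFIX)]

    def subset(self, mask) -> "SampleSet":
        mask = np.asarray(mask)
        return SampleSet(
            manifest=self.manifest.loc[mask].reset_index(drop=True),
            images=self.images[mask],
            spec=self.spec,
        )

    def split(self, which: str) -> "SampleSet":
        return self.subset((self.manifest["split"] == which).to_numpy())


def evaluate_causal_map(spec: SyntheticSpec, features: np.ndarray) -> np.ndarray:
    """Disease multi-hot matrix implied by a feature multi-hot matrix."""
    features = np.asarray(features).astype(bool)
    fidx = {f: i for i, f in enumerate(spec.feature_names)}
    out = np.zeros((features.shape[0], spec.n_diseases), dtype=int)
    for j, d in enumerate(spec.disease_names):
        op, feats = spec.causal_map[d]
        cols = features[:, [fidx[f] for f in feats]]
        out[:, j] = cols.all(axis=1) if op == "and" else cols.any(axis=1)
    return out


def generate_dataset(
    spec: SyntheticSpec, n_samples: int, out_dir: str | Path | None = None
) -> SampleSet:
    """Generate a seeded, reproducible biased dataset.

    Labels and attribute assignments consume a dedicated RNG stream;
    every image consumes its own per-sample stream. Identical seeds give
    bit-identical manifests and images, and the manifest is invariant to
    any style-shift setting. Each sample is one synthetic patient; the
    train/test split is drawn per patient.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    label_rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0]))
    h, w = spec.image_size

    sexes = np.asarray(SEXES)[label_rng.integers(0, 2, size=n_samples)]
    brackets = label_rng.choice(len(AGE_BRACKETS), size=n_samples, p=spec.age_distribution)
    feats = np.zeros((n_samples, spec.n_features), dtype=int)
    for i in range(n_samples):
        p = spec.cell_probs(sexes[i], int(brackets[i]))
        feats[i] = label_rng.random(spec.n_features) < p
    diseases = evaluate_causal_map(spec, feats)
    if spec.label_noise > 0:
        flips = label_rng.random(diseases.shape) < spec.label_noise
        diseases = np.where(flips, 1 - diseases, diseases)
    splits = np.where(label_rng.random(n_samples) < spec.train_fraction, "train", "test")

    images = np.zeros((n_samples, h, w, 3), dtype=np.uint8)
    for i in range(n_samples):
        pixel_rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 1, i]))
        images[i] = _render_image(spec, feats[i], sexes[i], pixel_rng)

    ids = [f"img_{i:06d}" for i in range(n_samples)]
    data = {
        "image_id": ids,
        "path": ["" for _ in ids],
        "sex": sexes,
        "age_bracket": [AGE_BRACKETS[b] for b in brackets],
        "split": splits,
    }
    for j, d in enumerate(spec.disease_names):
        data[DISEASE_PREFIX + d] = diseases[:, j]
    for j, f in enumerate(spec.feature_names):
        data[FEATURE_PREFIX + f] = feats[:, j]
    manifest = pd.DataFrame(data)

    sample_set = SampleSet(manifest=manifest, images=images, spec=spec)
    if out_dir is not None:
        _write_dataset(sample_set, Path(out_dir))
    return sample_set


def _write_dataset(ds: SampleSet, root: Path) -> None:
    root.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, row in ds.manifest.iterrows():
        sub = root / row["split"]
        sub.mkdir(exist_ok=True)
        path = sub / f"{row['image_id']}.png"
        Image.fromarray(ds.images[i]).save(path)
        paths.append(str(path.relative_to(root)))
    ds.manifest = ds.manifest.assign(path=paths)
    ds.manifest.to_csv(root / "manifest.csv", index=False)
    with open(root / "manifest.json", "w") as fh:
        json.dump(ds.manifest.to_dict(orient="records"), fh, indent=1)


def load_dataset(root: str | Path) -> SampleSet:
    """Load a generated (or identically laid out external) dataset."""
    root = Path(root)
    manifest = pd.read_csv(root / "manifest.csv")
    images = np.stack(
        [np.asarray(Image.open(root / p).convert("RGB")) for p in manifest["path"]]
    )
    return SampleSet(manifest=manifest, images=images)


# ---------------------------------------------------------------------------
# manifest-level operations


def label_density(manifest: pd.DataFrame, which: str = "diseases") -> float:
    """Mean number of positive labels per sample."""
    prefix = {"diseases": DISEASE_PREFIX, "features": FEATURE_PREFIX}[which]
    cols = [c for c in manifest.columns if c.startswith(prefix)]
    if len(manifest) == 0:
        raise ValueError("empty manifest")
    if not cols:
        raise ValueError(f"manifest has no {which} columns")
    return float(manifest[cols].to_numpy(dtype=float).sum(axis=1).mean())


def inject_bias(
    manifest: pd.DataFrame,
    attribute: str,
    strength: float,
    seed: int = 0,
    direction: np.ndarray | None = None,
) -> pd.DataFrame:
    """Tilt group-conditional disease prevalence by stochastic thinning.

    Each sample is kept with probability proportional to
    exp(strength * s_g * sum_k u_k y_k), normalised to the per-group
    maximum: at strength 0 every sample is kept (groups exchangeable);
    as strength grows the per-group prevalence ratios of each disease
    grow monotonically in expectation; extreme strengths empty
    (class, group) cells, exercising the missing-AP pathway downstream.
    """
    if attribute not in ("sex", "age"):
        raise ValueError("attribute must be 'sex' or 'age'")
    if strength < 0:
        raise ValueError("strength must be >= 0")
    cols = [c for c in manifest.columns if c.startswith(DISEASE_PREFIX)]
    y = manifest[cols].to_numpy(dtype=float)
    if direction is None:
        direction = np.asarray([1.0 if j % 2 == 0 else -1.0 for j in range(len(cols))])
    if attribute == "sex":
        s_g = np.where(manifest["sex"].to_numpy() == "female", 1.0, -1.0)
    else:
        idx = manifest["age_bracket"].map({b: i for i, b in enumerate(AGE_BRACKETS)}).to_numpy()
        s_g = (idx - 4) / 4.0
    logw = strength * s_g * (y @ direction)
    keep_p = np.ones(len(manifest))
    group_key = manifest["sex"] if attribute == "sex" else manifest["age_bracket"]
    for g in group_key.unique():
        m = (group_key == g).to_numpy()
        keep_p[m] = np.exp(logw[m] - logw[m].max())
    rng = np.random.default_rng(seed)
    keep = rng.random(len(manifest)) < keep_p
    out = manifest.loc[keep].reset_index(drop=True)
    emptied = set(group_key.unique()) - set(group_key[keep].unique())
    if emptied:
        raise ValueError(f"bias strength {strength} emptied strata: {sorted(emptied)}")
    return out
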