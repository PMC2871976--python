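"""Synthetic cohorts of grey-matter volumes with linked clinical scores.

Real cohorts of preprocessed GM segments (e.g. memory-clinic or multi-site
study data) are access-restricted, so testing the analysis chain requires a
generator whose output has the statistical structure the method assumes:

* a fixed smooth brain-like template (sum of broad Gaussians) shared by all
  subjects, with an implicit analysis mask where the template is non-trivial;
* a hidden signed spatial pattern (ellipsoidal regions); each subject's
  volume is the template minus latent-severity-scaled atrophy along that
  pattern, plus spatially smooth noise, floored at zero;
* a score that is an affine function of the inner product between the hidden
  pattern and the subject's volume, plus Gaussian noise, clipped to the
  instrument's bounds (MMSE 0-30, DRS 0-144, ADAS-Cog 0-70 reverse-scored,
  AVLT percent retention 0-100);
* AD > MCI > CN latent severity ordering, education years, and (for MCI)
  days to conversion decreasing in severity and censored at 1500 days.

All distributional choices are stand-ins — the real data are observational
and come with no generative model — and are recorded in the cohort metadata.
Everything is reproducible bit-exactly from the spec's seed: per-subject
random streams are spawned deterministically from (seed, subject index).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .features import BrainVolume, FeatureMatrix, smooth_volume, vectorize

__all__ = [
    "Instrument",
    "INSTRUMENTS",
    "EllipsoidRegion",
    "CohortSpec",
    "SyntheticSubject",
    "Cohort",
    "generate_template",
    "generate_pattern",
    "generate_cohort",
]

#: Days-to-conversion censoring value for MCI subjects who do not convert.
CONVERSION_CENSOR_DAYS = 1500.0

GROUPS = ("AD", "MCI", "CN")


@dataclass(frozen=True)
class Instrument:
    """A clinical instrument: score bounds plus direction.

    ``direction = +1`` means higher scores are better (MMSE, DRS, AVLT);
    ``-1`` means higher is worse (ADAS-Cog).
    """

    name: str
    min: float
    max: float
    direction: int

    def __post_init__(self):
        if self.min >= self.max:
            raise ValueError(
                f"instrument {self.name!r}: min ({self.min}) must be < max ({self.max})"
            )
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")

    @property
    def range(self) -> float:
        return self.max - self.min

    def clip(self, score):
        return np.clip(score, self.min, self.max)


INSTRUMENTS: dict[str, Instrument] = {
    "MMSE": Instrument("MMSE", 0.0, 30.0, +1),
    "DRS": Instrument("DRS", 0.0, 144.0, +1),
    "ADAS-Cog": Instrument("ADAS-Cog", 0.0, 70.0, -1),
    "AVLT": Instrument("AVLT", 0.0, 100.0, +1),
}


@dataclass(frozen=True)
class EllipsoidRegion:
    """An ellipsoidal pattern region with a signed weight.

    ``center`` and ``radii`` are in voxel coordinates. Inside the ellipsoid
    the pattern value is ``weight * (1 - rho^2)`` where rho is the scaled
    radial coordinate, giving a smooth bump that vanishes at the boundary.
    """

    center: tuple[float, float, float]
    radii: tuple[float, float, float]
    weight: float

    def support(self, grid_shape: tuple[int, int, int]) -> np.ndarray:
        """Unweighted bump ``max(0, 1 - rho^2)`` on the grid."""
        idx = np.indices(grid_shape, dtype=float)
        rho2 = np.zeros(grid_shape)
        for ax in range(3):
            if self.radii[ax] <= 0:
                raise ValueError("ellipsoid radii must be positive")
            rho2 += ((idx[ax] - self.center[ax]) / self.radii[ax]) ** 2
        return np.clip(1.0 - rho2, 0.0, None)

    def evaluate(self, grid_shape: tuple[int, int, int]) -> np.ndarray:
        return self.weight * self.support(grid_shape)


def default_regions(grid_shape: tuple[int, int, int]) -> list[EllipsoidRegion]:
    """A medial-temporal-like positive focus plus a smaller negative
    anatomical-adjustment focus, scaled to the grid."""
    g = np.asarray(grid_shape, dtype=float)
    as_floats = lambda v: tuple(float(x) for x in v)  # noqa: E731 (YAML-safe)
    return [
        EllipsoidRegion(
            center=as_floats(g * (0.375, 0.5, 0.375)),
            radii=as_floats(g * (0.17, 0.15, 0.15)),
            weight=1.0,
        ),
        EllipsoidRegion(
            center=as_floats(g * (0.67, 0.54, 0.62)),
            radii=as_floats(g * 0.125),
            weight=-0.6,
        ),
    ]


@dataclass
class CohortSpec:
    """Everything needed to generate a cohort deterministically.

    Severity is a latent unitless scale: 0 is healthy anatomy, larger values
    mean more atrophy along the hidden pattern. ``noise_sd`` is additive
    score noise in instrument units. ``reserve_strength`` (score units per
    education year, 0 disables) adds an education-linked offset in the
    instrument's "better" direction, emulating cognitive reserve.
    """

    n_ad: int = 20
    n_mci: int = 20
    n_cn: int = 20
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    instrument: str | Instrument = "MMSE"
    pattern_regions: list[EllipsoidRegion] | None = None
    noise_sd: float = 2.0
    severity_means: dict[str, float] = field(
        default_factory=lambda: {"AD": 2.0, "MCI": 1.0, "CN": 0.0}
    )
    severity_sds: dict[str, float] = field(
        default_factory=lambda: {"AD": 0.5, "MCI": 0.4, "CN": 0.3}
    )
    atrophy_per_severity: float = 0.08
    image_noise_sd: float = 0.02
    reserve_strength: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(g) for g in self.grid_shape)
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        for n in (self.n_ad, self.n_mci, self.n_cn):
            if n < 0:
                raise ValueError("group counts must be >= 0")
        if self.n_total < 1:
            raise ValueError("cohort must contain at least one subject")
        if any(g <= 0 for g in self.grid_shape) or len(self.grid_shape) != 3:
            raise ValueError("grid_shape must be 3 positive ints")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.image_noise_sd < 0:
            raise ValueError("image_noise_sd must be >= 0")
        if isinstance(self.instrument, str):
            if self.instrument not in INSTRUMENTS:
                raise ValueError(
                    f"unknown instrument {self.instrument!r}; "
                    f"known: {sorted(INSTRUMENTS)}"
                )
            self.instrument = INSTRUMENTS[self.instrument]
        if self.pattern_regions is None:
            self.pattern_regions = default_regions(self.grid_shape)
        regions = []
        for r in self.pattern_regions:
            if isinstance(r, dict):
                r = EllipsoidRegion(
                    center=tuple(r["center"]),
                    radii=tuple(r["radii"]),
                    weight=float(r["weight"]),
                )
            regions.append(r)
        self.pattern_regions = regions

    @property
    def n_total(self) -> int:
        return self.n_ad + self.n_mci + self.n_cn

    def group_labels(self) -> list[str]:
        return ["AD"] * self.n_ad + ["MCI"] * self.n_mci + ["CN"] * self.n_cn

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["instrument"] = {
            "name": self.instrument.name,
            "min": self.instrument.min,
            "max": self.instrument.max,
            "direction": self.instrument.direction,
        }
        d["pattern_regions"] = [dataclasses.asdict(r) for r in self.pattern_regions]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        inst = d.get("instrument", "MMSE")
        if isinstance(inst, dict):
            d["instrument"] = Instrument(
                name=inst["name"],
                min=float(inst["min"]),
                max=float(inst["max"]),
                direction=int(inst["direction"]),
            )
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown CohortSpec fields: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class SyntheticSubject:
    id: str
    volume: BrainVolume
    group: str
    true_latent_severity: float
    score: float
    education_years: int
    days_to_conversion: float | None = None


@dataclass
class Cohort:
    """Generated subjects plus the ground truth that produced them."""

    subjects: list[SyntheticSubject]
    spec: CohortSpec
    template: BrainVolume
    pattern: BrainVolume
    mask: np.ndarray

    @property
    def n(self) -> int:
        return len(self.subjects)

    @property
    def instrument(self) -> Instrument:
        return self.spec.instrument

    @property
    def subject_ids(self) -> list[str]:
        return [s.id for s in self.subjects]

    @property
    def scores(self) -> np.ndarray:
        return np.array([s.score for s in self.subjects])

    @property
    def volumes(self) -> list[BrainVolume]:
        return [s.volume for s in self.subjects]

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.subject_ids,
                "group": [s.group for s in self.subjects],
                "score": self.scores,
                "instrument": self.instrument.name,
                "education_years": [s.education_years for s in self.subjects],
                "days_to_conversion": [
                    s.days_to_conversion if s.days_to_conversion is not None else np.nan
                    for s in self.subjects
                ],
            }
        )

    def to_features(self, fwhm_mm: float = 0.0) -> FeatureMatrix:
        """Vectorize all subject volumes (optionally smoothed) on the mask."""
        vols = self.volumes
        if fwhm_mm > 0:
            vols = [smooth_volume(v, fwhm_mm) for v in vols]
        return vectorize(vols, self.mask, subject_ids=self.subject_ids)

    def subset(self, idx) -> "Cohort":
        subjects = [self.subjects[i] for i in idx]
        if not subjects:
            raise ValueError("empty cohort subset")
        return Cohort(
            subjects=subjects,
            spec=self.spec,
            template=self.template,
            pattern=self.pattern,
            mask=self.mask,
        )

    def save(self, outdir) -> None:
        """Write one NIfTI per subject, a scores CSV, and spec metadata."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for s in self.subjects:
            s.volume.save(outdir / f"{s.id}.nii.gz")
        self.template.save(outdir / "template.nii.gz")
        self.pattern.save(outdir / "true_pattern.nii.gz")
        self.table().to_csv(outdir / "scores.csv", index=False)
        meta = {
            "spec": self.spec.to_dict(),
            "note": (
                "Synthetic cohort: all distributions are stand-ins chosen for "
                "testing; they emulate preprocessed modulated GM segments and "
                "are not derived from any real dataset."
            ),
        }
        with open(outdir / "cohort.json", "w") as fh:
            json.dump(meta, fh, indent=2)

    @classmethod
    def load(cls, indir) -> "Cohort":
        indir = Path(indir)
        with open(indir / "cohort.json") as fh:
            meta = json.load(fh)
        spec = CohortSpec.from_dict(meta["spec"])
        template, mask, pattern, _ = _template_pattern_mask(spec)
        df = pd.read_csv(indir / "scores.csv")
        subjects = []
        for _, row in df.iterrows():
            vol = BrainVolume.from_nifti(indir / f"{row['id']}.nii.gz", mask=mask)
            days = row["days_to_conversion"]
            subjects.append(
                SyntheticSubject(
                    id=str(row["id"]),
                    volume=vol,
                    group=str(row["group"]),
                    true_latent_severity=np.nan,
                    score=float(row["score"]),
                    education_years=int(row["education_years"]),
                    days_to_conversion=None if pd.isna(days) else float(days),
                )
            )
        return cls(subjects=subjects, spec=spec, template=template, pattern=pattern, mask=mask)


# --------------------------------------------------------------------------
# generation internals


def generate_template(spec: CohortSpec) -> BrainVolume:
    """Fixed smooth brain-like template: a sum of broad Gaussian lobes."""
    shape = np.array(spec.grid_shape, dtype=float)
    idx = np.indices(spec.grid_shape, dtype=float)
    center = (shape - 1) / 2.0

    def lobe(offset, widths, amp):
        q = np.zeros(spec.grid_shape)
        for ax in range(3):
            q += ((idx[ax] - (center[ax] + offset[ax])) / widths[ax]) ** 2
        return amp * np.exp(-0.5 * q)

    w = shape / 4.5
    values = (
        lobe((0.0, 0.0, 0.0), w, 0.8)
        + lobe((-shape[0] / 6, 0.0, shape[2] / 10), w * 0.7, 0.35)
        + lobe((shape[0] / 6, shape[1] / 12, -shape[2] / 10), w * 0.7, 0.35)
    )
    mask = values > 0.05 * values.max()
    return BrainVolume(
        values=values, voxel_size_mm=spec.voxel_size_mm, mask=mask, signed=False
    )


def generate_pattern(spec: CohortSpec) -> BrainVolume:
    """The hidden signed weight pattern linking anatomy to score.

    Positive regions are where more grey matter raises the latent score
    axis; negative regions lower it. Zero outside the analysis mask.
    """
    template = generate_template(spec)
    values = np.zeros(spec.grid_shape)
    for i, region in enumerate(spec.pattern_regions):
        support = region.support(spec.grid_shape)
        if not np.any(support > 0):
            raise ValueError(
                f"pattern region {i} (center {region.center}, radii {region.radii}) "
                "lies fully outside the grid"
            )
        values += region.weight * support
    values[~template.mask] = 0.0
    return BrainVolume(
        values=values,
        voxel_size_mm=spec.voxel_size_mm,
        mask=template.mask,
        signed=True,
    )


#: Reference severity mapping to the "severe" end of the score calibration.
_SEVERITY_REF = 2.5
#: Fractions of the instrument range used for calibration anchors
#: (healthy end and severe end along the good-to-bad axis).
_HEALTHY_FRAC = 0.95
_SEVERE_FRAC = 0.30


def _score_calibration(spec: CohortSpec, pattern: BrainVolume, template: BrainVolume):
    """Affine map score = c0 + c1 * <pattern, volume>, fixed by two anchors.

    A severity-0 subject with no noise sits at the healthy anchor; a subject
    at severity ``_SEVERITY_REF`` sits at the severe anchor. Both anchors are
    placed along the instrument's good-to-bad axis, so the same machinery
    serves reverse-scored instruments.
    """
    inst = spec.instrument
    if inst.direction == +1:
        good = inst.min + _HEALTHY_FRAC * inst.range
        bad = inst.min + _SEVERE_FRAC * inst.range
    else:
        good = inst.min + (1 - _HEALTHY_FRAC) * inst.range
        bad = inst.min + (1 - _SEVERE_FRAC) * inst.range
    p = pattern.values
    u_healthy = float(np.sum(p * template.values))
    pp = float(np.sum(p * p))
    if pp == 0.0:
        # degenerate all-zero pattern: scores are offset + noise only
        return good, 0.0
    # u(s) = u_healthy - s * atrophy_per_severity * ||p||^2
    c1 = (good - bad) / (_SEVERITY_REF * spec.atrophy_per_severity * pp)
    c0 = good - c1 * u_healthy
    return c0, c1


def _template_pattern_mask(spec: CohortSpec):
    template = generate_template(spec)
    pattern = generate_pattern(spec)
    c0, c1 = _score_calibration(spec, pattern, template)
    return template, template.mask, pattern, (c0, c1)


def _subject_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1, index)))


def _smooth_noise_field(rng: np.random.Generator, shape, sd: float) -> np.ndarray:
    """White Gaussian noise smoothed to ~1-voxel correlation, rescaled to sd."""
    if sd == 0.0:
        return np.zeros(shape)
    field_ = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=1.0)
    observed = field_.std()
    if observed > 0:
        field_ *= sd / observed
    return field_


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate the full cohort described by ``spec`` (bit-reproducible).

    Each subject's volume is ``max(0, template - severity * a * pattern +
    noise_field)`` and the emitted score is the calibrated affine functional
    of that volume plus N(0, noise_sd) score noise (and an optional
    education-reserve offset), clipped to the instrument's bounds.
    """
    template, mask, pattern, (c0, c1) = _template_pattern_mask(spec)
    inst = spec.instrument
    labels = spec.group_labels()
    subjects: list[SyntheticSubject] = []
    p = pattern.values
    for i, group in enumerate(labels):
        rng = _subject_rng(spec.rng_seed, i)
        severity = rng.normal(spec.severity_means[group], spec.severity_sds[group])
        noise_field = _smooth_noise_field(rng, spec.grid_shape, spec.image_noise_sd)
        values = template.values - severity * spec.atrophy_per_severity * p + noise_field
        np.clip(values, 0.0, None, out=values)
        values[~mask] = 0.0
        volume = BrainVolume(
            values=values, voxel_size_mm=spec.voxel_size_mm, mask=mask, signed=False
        )
        education = int(rng.integers(12, 21))
        raw = c0 + c1 * float(np.sum(p * values))
        if spec.reserve_strength > 0:
            raw += inst.direction * spec.reserve_strength * (education - 16.0)
        raw += rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0
        score = float(inst.clip(raw))
        days = None
        if group == "MCI":
            days_raw = 2200.0 - 600.0 * severity + rng.normal(0.0, 150.0)
            days = float(np.clip(round(days_raw), 1.0, CONVERSION_CENSOR_DAYS))
        subjects.append(
            SyntheticSubject(
                id=f"S{i:03d}",
                volume=volume,
                group=group,
                true_latent_severity=float(severity),
                score=score,
                education_years=education,
                days_to_conversion=days,
            )
        )
    return Cohort(subjects=subjects, spec=spec, template=template, pattern=pattern, mask=mask)
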