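"""Synthetic brain phantoms with class-conditional regional atrophy.

Real dementia cohorts are access-restricted, so the pipeline is exercised
on phantoms that mimic the relevant structure of preprocessed T1 scans:
a smooth ellipsoidal "brain" on an exactly-zero background, participant-
specific low-frequency texture, repeat scans per participant, and a
class-specific ellipsoidal region whose intensity is reduced by a fixed
fraction — the stand-in for regional gray-matter atrophy. The two default
classes place their lesions medially/posteriorly (temporal-lobe-like) and
anteriorly (insular/frontal-like), so attribution maps can be checked for
region specificity.

All randomness flows from explicit seeds through ``numpy.random.SeedSequence``;
volumes are deterministic given (spec.seed, class_id, participant_seed, scan).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .volume import Volume, save_volume, write_manifest

__all__ = ["Ellipsoid", "PhantomSpec", "LabeledCohort",
           "generate_phantom", "generate_cohort"]


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid in fractional volume coordinates."""

    center: tuple[float, float, float]
    radii: tuple[float, float, float]

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        grids = np.ogrid[tuple(slice(0, n) for n in shape)]
        acc = np.zeros(shape)
        for g, n, c, r in zip(grids, shape, self.center, self.radii):
            acc = acc + ((g - c * (n - 1)) / (r * n)) ** 2
        return acc <= 1.0


# AD-like medial/inferior lesion vs. BV-like anterior/superior lesion; both
# sit inside the central coronal window, as hippocampus and insula do
DEFAULT_REGIONS = (
    Ellipsoid(center=(0.5, 0.42, 0.35), radii=(0.16, 0.10, 0.12)),
    Ellipsoid(center=(0.5, 0.60, 0.60), radii=(0.16, 0.10, 0.12)),
)
BRAIN = Ellipsoid(center=(0.5, 0.5, 0.5), radii=(0.42, 0.45, 0.42))


@dataclass(frozen=True)
class PhantomSpec:
    """Generative settings for one phantom cohort.

    ``effect_size`` is the fractional intensity reduction inside the
    class's atrophy region (0.3 = 30% darker); ``noise_sd`` is additive
    Gaussian noise on a [0, 1]-ish intensity scale.
    """

    shape: tuple[int, int, int] = (64, 80, 64)
    n_classes: int = 2
    atrophy_regions: tuple[Ellipsoid, ...] = DEFAULT_REGIONS
    effect_size: float = 0.3
    noise_sd: float = 0.05
    scans_per_participant: int = 1
    seed: int = 0
    class_names: tuple[str, ...] = ("AD_like", "BV_like")

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if not 0.0 <= self.effect_size < 1.0:
            raise ValueError("effect_size must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.scans_per_participant < 1:
            raise ValueError("scans_per_participant must be >= 1")
        if len(self.atrophy_regions) < self.n_classes:
            raise ValueError("one atrophy region required per class")
        if len(self.class_names) < self.n_classes:
            object.__setattr__(
                self, "class_names",
                tuple(f"class{k}" for k in range(self.n_classes)))


@dataclass
class LabeledCohort:
    """Generated volumes plus the manifest tying scans to participants."""

    volumes: list[Volume]
    manifest: pd.DataFrame


def _texture(shape, rng: np.random.Generator) -> np.ndarray:
    """Smooth low-frequency field in roughly [0.4, 1], participant-specific."""
    field = gaussian_filter(rng.standard_normal(shape), sigma=min(shape) / 10)
    field /= max(field.std(), 1e-9)
    return np.clip(0.7 + 0.12 * field, 0.05, 1.2)


def generate_phantom(spec: PhantomSpec, class_id: int, participant_seed: int,
                     scan: int = 0) -> Volume:
    """One phantom volume for a participant of the given class.

    The participant's texture is independent of class, so phantoms that
    differ only in ``class_id`` differ exactly in which region is darkened.
    """
    if not 0 <= class_id < spec.n_classes:
        raise ValueError(f"class_id {class_id} out of range [0, {spec.n_classes})")
    tex_rng = np.random.default_rng(
        np.random.SeedSequence((spec.seed, participant_seed, 0xB0D7)))
    noise_rng = np.random.default_rng(
        np.random.SeedSequence((spec.seed, participant_seed, scan, 0x4E01)))

    data = _texture(spec.shape, tex_rng)
    region = spec.atrophy_regions[class_id].mask(spec.shape)
    data = np.where(region, data * (1.0 - spec.effect_size), data)
    if spec.noise_sd > 0:
        data = data + noise_rng.normal(0.0, spec.noise_sd, spec.shape)
    data = np.where(BRAIN.mask(spec.shape), data, 0.0)

    name = spec.class_names[class_id]
    pid = f"sub-{name}{participant_seed:04d}"
    return Volume(
        data=data, coronal_axis=1, spacing=(1.0, 1.0, 1.0),
        volume_id=f"{pid}_scan-{scan}", participant_id=pid, label=name,
    )


def generate_cohort(spec: PhantomSpec, n_participants_per_class: int,
                    out_dir: str | Path | None = None) -> LabeledCohort:
    """A labeled cohort of phantoms; optionally written to disk as NIfTI + TSV.

    Every participant keeps one class across all of their
    ``spec.scans_per_participant`` scans, mirroring diagnosis-per-participant
    cohort structure.
    """
    if n_participants_per_class < 1:
        raise ValueError("n_participants_per_class must be >= 1")
    volumes: list[Volume] = []
    rows = []
    for class_id in range(spec.n_classes):
        for p in range(n_participants_per_class):
            participant_seed = class_id * 10_000 + p
            for scan in range(spec.scans_per_participant):
                v = generate_phantom(spec, class_id, participant_seed, scan)
                volumes.append(v)
                rows.append({
                    "scan_path": f"{v.volume_id}.nii.gz",
                    "participant_id": v.participant_id,
                    "diagnosis": v.label,
                })
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for v, row in zip(volumes, manifest.itertuples()):
            save_volume(v, out_dir / row.scan_path)
        manifest = manifest.assign(
            scan_path=[str(out_dir / p) for p in manifest["scan_path"]])
        write_manifest(manifest, out_dir / "manifest.tsv")
    return LabeledCohort(volumes=volumes, manifest=manifest)
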