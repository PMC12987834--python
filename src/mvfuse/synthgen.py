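"""Synthetic paired-view vessel phantoms with weak segment-level labels.

Real curved-MPR views show a bright vessel running through noisy tissue; a
culprit lesion is a localized narrowing / hypodensity somewhere along the
vessel, visible in one or both of two roughly orthogonal reconstruction
planes.  The phantom keeps exactly that structure and nothing else: each view
is a bright tube of roughly constant width along a smooth random curve over a
darker noisy background, and a lesion is a localized narrowing plus intensity
drop over a sub-interval of the tube.  The two views of a segment have
independent curve geometries but share the lesion's longitudinal position,
and lesion visibility per view is controlled explicitly — the property that
makes learned two-view fusion testably different from channel stacking.

The cohort structure mirrors the clinical dataset the package targets:
segments grouped under patients (about 6.4 segments per patient, 80 patients,
~514 segments), weak binary labels with ~12.3 % culprit prevalence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "SynthConfig",
    "CurveGeometry",
    "VesselView",
    "SegmentSample",
    "SegmentArrays",
    "sample_geometry",
    "render_vessel_view",
    "inject_lesion",
    "assign_labels",
    "generate_segments",
    "generate_dataset",
]

_BACKGROUND = 0.2   # background intensity, [0, 1] scale
_VESSEL = 0.85      # healthy tube intensity


@dataclass(frozen=True)
class SynthConfig:
    """World parameters for the phantom cohort.

    ``segments_per_patient`` is a mean: each patient receives
    ``floor(mean)`` segments plus one more with probability ``frac(mean)``;
    the default 6.425 makes 80 patients average 514 segments.  ``contrast``
    is the lesion-to-vessel intensity ratio (smaller = darker, more visible
    lesion); ``severity`` is the fractional radius narrowing at the lesion
    centre (1.0 interrupts the tube).
    """

    n_patients: int = 80
    segments_per_patient: float = 6.425
    prevalence: float = 0.123
    image_size: int = 96
    lesion_visibility: str = "mixed"   # both_views | one_view | mixed
    p_one: float = 0.5                 # P(single-view) under "mixed"
    noise_sd: float = 0.05
    contrast: float = 0.4
    severity: float = 0.8
    intensity_jitter: float = 0.08   # per-view vessel/background level variation
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must lie in [0, 1]")
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        if self.lesion_visibility not in ("both_views", "one_view", "mixed"):
            raise ValueError(f"unknown lesion_visibility {self.lesion_visibility!r}")
        if not 0.0 < self.contrast <= 1.0:
            raise ValueError("contrast must lie in (0, 1]")
        if not 0.0 < self.severity <= 1.0:
            raise ValueError("severity must lie in (0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class CurveGeometry:
    """A quadratic Bezier spanning the image, plus a tube radius in pixels."""

    p0: tuple[float, float]
    p1: tuple[float, float]
    p2: tuple[float, float]
    radius: float
    transpose: bool = False   # swap axes: vertical instead of horizontal run

    def sample_points(self, n: int) -> np.ndarray:
        """n points along the curve, shape (n, 2) as (col, row)."""
        t = np.linspace(0.0, 1.0, n)[:, None]
        p0, p1, p2 = (np.asarray(p, float) for p in (self.p0, self.p1, self.p2))
        pts = (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t ** 2 * p2
        if self.transpose:
            pts = pts[:, ::-1]
        return pts


def sample_geometry(size: int, rng: np.random.Generator) -> CurveGeometry:
    """Draw a random smooth curve spanning the image with a plausible radius."""
    ys = rng.uniform(0.25 * size, 0.75 * size, size=3)
    radius = rng.uniform(0.045, 0.075) * size
    return CurveGeometry(
        p0=(0.0, float(ys[0])), p1=(size / 2.0, float(ys[1])), p2=(float(size), float(ys[2])),
        radius=max(2.0, float(radius)), transpose=bool(rng.integers(0, 2)),
    )


def _lesion_bump(t: np.ndarray, center: float, length: float) -> np.ndarray:
    """Smooth cosine bump in [0, 1] over the arclength interval of the lesion."""
    half = length / 2.0
    x = (t - center) / half
    out = np.zeros_like(t)
    inside = np.abs(x) < 1.0
    out[inside] = 0.5 * (1.0 + np.cos(np.pi * x[inside]))
    return out


class VesselView:
    """One rendered view: tube geometry + frozen noise field.

    The final image is composed lazily from (geometry, radius profile,
    intensity profile, noise), so a lesion can be injected by re-composing
    with modified profiles while the untouched view stays bit-identical.
    """

    _SAMPLES_PER_PX = 3

    def __init__(self, size: int, geometry: CurveGeometry, noise: np.ndarray,
                 lesion: tuple[float, float, float, float] | None = None,
                 vessel: float = _VESSEL, background: float = _BACKGROUND):
        self.size = int(size)
        self.geometry = geometry
        self.noise = noise
        self.vessel = float(vessel)
        self.background = float(background)
        # lesion = (center_t, length_t, severity, contrast) or None
        self.lesion = lesion
        self._n = self._SAMPLES_PER_PX * self.size
        self._pts = geometry.sample_points(self._n)
        self._t = np.linspace(0.0, 1.0, self._n)

    # -- profiles -------------------------------------------------------------

    def _profiles(self) -> tuple[np.ndarray, np.ndarray]:
        radius = np.full(self._n, self.geometry.radius)
        intensity = np.ones(self._n)
        if self.lesion is not None:
            center, length, severity, contrast = self.lesion
            bump = _lesion_bump(self._t, center, length)
            radius = radius * (1.0 - severity * bump)
            intensity = 1.0 - (1.0 - contrast) * bump
        return radius, intensity

    def _compose(self) -> tuple[np.ndarray, np.ndarray]:
        """Render (float image in [0,1], soft tube alpha)."""
        size = self.size
        sd = np.full((size, size), np.inf)
        inten = np.ones((size, size))
        radius, intensity = self._profiles()
        for (px, py), r, it in zip(self._pts, radius, intensity):
            if r < 0.5:
                continue  # fully pinched: tube interrupted here
            x0, x1 = max(0, int(px - r - 2)), min(size, int(px + r + 3))
            y0, y1 = max(0, int(py - r - 2)), min(size, int(py + r + 3))
            if x0 >= x1 or y0 >= y1:
                continue
            yy, xx = np.mgrid[y0:y1, x0:x1]
            d = np.hypot(xx - px, yy - py) - r
            win_sd = sd[y0:y1, x0:x1]
            upd = d < win_sd
            win_sd[upd] = d[upd]
            inten[y0:y1, x0:x1][upd] = it
        alpha = np.clip(0.5 - sd, 0.0, 1.0)
        img = self.background + (self.vessel - self.background) * alpha * inten + self.noise
        return np.clip(img, 0.0, 1.0), alpha

    @property
    def image(self) -> np.ndarray:
        """8-bit grayscale image (what gets written to PNG)."""
        img, _ = self._compose()
        return np.round(img * 255.0).astype(np.uint8)

    @property
    def tube_mask(self) -> np.ndarray:
        """Boolean mask of the *healthy* tube (pre-lesion geometry)."""
        healthy = VesselView(self.size, self.geometry, self.noise, lesion=None,
                             vessel=self.vessel, background=self.background)
        _, alpha = healthy._compose()
        return alpha >= 0.5

    def lesion_mask(self) -> np.ndarray:
        """Healthy-tube pixels within the lesion's longitudinal interval."""
        if self.lesion is None:
            return np.zeros((self.size, self.size), bool)
        center, length, _, _ = self.lesion
        bump = _lesion_bump(self._t, center, length) > 0.0
        mask = np.zeros((self.size, self.size), bool)
        r = self.geometry.radius
        for (px, py), on in zip(self._pts, bump):
            if not on:
                continue
            x0, x1 = max(0, int(px - r - 2)), min(self.size, int(px + r + 3))
            y0, y1 = max(0, int(py - r - 2)), min(self.size, int(py + r + 3))
            yy, xx = np.mgrid[y0:y1, x0:x1]
            mask[y0:y1, x0:x1] |= np.hypot(xx - px, yy - py) <= r + 0.5
        return mask

    def with_lesion(self, center: float, length: float, severity: float,
                    contrast: float) -> "VesselView":
        return VesselView(self.size, self.geometry, self.noise,
                          lesion=(center, length, severity, contrast),
                          vessel=self.vessel, background=self.background)


def render_vessel_view(size: int, geometry: CurveGeometry,
                       rng: np.random.Generator, noise_sd: float = 0.05,
                       intensity_jitter: float = 0.0) -> VesselView:
    """Render a healthy vessel view: bright tube over a darker noisy background.

    ``intensity_jitter`` draws the vessel and background levels per view from
    uniform bands around their nominal values, so absolute brightness is a
    nuisance variable rather than a usable cue.
    """
    if size < 32:
        raise ValueError("size must be >= 32")
    if geometry.radius <= 0:
        raise ValueError("tube radius must be positive")
    vessel, background = _VESSEL, _BACKGROUND
    if intensity_jitter > 0:
        vessel += float(rng.uniform(-intensity_jitter, intensity_jitter))
        background += float(rng.uniform(-intensity_jitter / 2, intensity_jitter / 2))
    noise = rng.normal(0.0, noise_sd, (size, size)) if noise_sd > 0 else np.zeros((size, size))
    return VesselView(size, geometry, noise, vessel=vessel, background=background)


def inject_lesion(pair: tuple[VesselView, VesselView], visibility: str,
                  severity: float, rng: np.random.Generator,
                  contrast: float = 0.4, length: float = 0.22,
                  ) -> tuple[VesselView, VesselView]:
    """Apply a lesion to the designated view(s) of a rendered pair.

    The lesion's longitudinal position (arclength fraction) is drawn once and
    shared by both views — the phantom's stand-in for "the same physical
    lesion seen in two orthogonal planes".  A view not designated by
    ``visibility`` is returned untouched (bit-identical image).
    """
    if not 0.0 < severity <= 1.0:
        raise ValueError("severity must lie in (0, 1]")
    if visibility not in ("both", "view1_only", "view2_only"):
        raise ValueError(f"unknown visibility {visibility!r}")
    v1, v2 = pair
    center = float(rng.uniform(0.2, 0.8))
    out1 = v1.with_lesion(center, length, severity, contrast) if visibility in ("both", "view1_only") else v1
    out2 = v2.with_lesion(center, length, severity, contrast) if visibility in ("both", "view2_only") else v2
    return out1, out2


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass
class SegmentSample:
    """One arterial segment: patient id, two views, weak binary label."""

    patient_id: str
    segment_id: str
    view1: np.ndarray   # uint8 (H, W)
    view2: np.ndarray
    label: int

    def __post_init__(self):
        if self.view1.shape != self.view2.shape:
            raise ValueError("paired views must have identical dimensions")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


@dataclass
class SegmentArrays:
    """A dataset stacked into arrays ready for batched training."""

    x1: np.ndarray        # (N, 1, H, W) float32 in [0, 1]
    x2: np.ndarray
    labels: np.ndarray    # (N,) int
    patient_ids: np.ndarray
    segment_ids: np.ndarray

    def __len__(self) -> int:
        return len(self.labels)

    @staticmethod
    def from_samples(samples: list[SegmentSample]) -> "SegmentArrays":
        x1 = np.stack([s.view1 for s in samples]).astype(np.float32)[:, None] / 255.0
        x2 = np.stack([s.view2 for s in samples]).astype(np.float32)[:, None] / 255.0
        return SegmentArrays(
            x1=x1, x2=x2,
            labels=np.array([s.label for s in samples], dtype=int),
            patient_ids=np.array([s.patient_id for s in samples]),
            segment_ids=np.array([s.segment_id for s in samples]),
        )

    def subset(self, idx: np.ndarray) -> "SegmentArrays":
        return SegmentArrays(self.x1[idx], self.x2[idx], self.labels[idx],
                             self.patient_ids[idx], self.segment_ids[idx])


def assign_labels(n: int, prevalence: float, rng: np.random.Generator) -> np.ndarray:
    """Draw i.i.d. Bernoulli(prevalence) culprit labels for n segments."""
    return (rng.random(n) < prevalence).astype(int)


def _pick_visibility(config: SynthConfig, rng: np.random.Generator) -> str:
    if config.lesion_visibility == "both_views":
        return "both"
    single = "view1_only" if rng.integers(0, 2) == 0 else "view2_only"
    if config.lesion_visibility == "one_view":
        return single
    return single if rng.random() < config.p_one else "both"


def generate_segments(config: SynthConfig) -> list[SegmentSample]:
    """Generate the full cohort in memory; a pure function of the config."""
    rng_struct = np.random.default_rng([config.seed, 1])  # counts + labels
    rng_img = np.random.default_rng([config.seed, 2])     # geometry, noise, lesions
    base = int(math.floor(config.segments_per_patient))
    frac = config.segments_per_patient - base
    samples: list[SegmentSample] = []
    for p in range(config.n_patients):
        pid = f"P{p:03d}"
        n_seg = base + (1 if rng_struct.random() < frac else 0)
        labels = assign_labels(n_seg, config.prevalence, rng_struct)
        for s in range(n_seg):
            v1 = render_vessel_view(config.image_size, sample_geometry(config.image_size, rng_img),
                                    rng_img, config.noise_sd, config.intensity_jitter)
            v2 = render_vessel_view(config.image_size, sample_geometry(config.image_size, rng_img),
                                    rng_img, config.noise_sd, config.intensity_jitter)
            if labels[s] == 1:
                # lesion draws come from the structural stream so that the
                # rendered vessels are a pure function of rng_img: a cohort
                # with prevalence 0 shows the same healthy vessels
                v1, v2 = inject_lesion((v1, v2), _pick_visibility(config, rng_struct),
                                       config.severity, rng_struct, contrast=config.contrast)
            samples.append(SegmentSample(
                patient_id=pid, segment_id=f"{pid}_S{s}",
                view1=v1.image, view2=v2.image, label=int(labels[s]),
            ))
    return samples


def generate_dataset(config: SynthConfig, out_dir=None):
    """Generate the cohort and, optionally, write PNGs plus a CSV manifest.

    Returns ``(samples, manifest)`` where ``manifest`` is a DataFrame with
    columns ``patient_id, segment_id, view1_path, view2_path, label``; paths
    are relative to ``out_dir`` (empty strings when nothing is written).
    """
    import pandas as pd

    samples = generate_segments(config)
    rows = []
    if out_dir is not None:
        from pathlib import Path
        from PIL import Image

        out_dir = Path(out_dir)
        img_dir = out_dir / "images"
        img_dir.mkdir(parents=True, exist_ok=True)
        for s in samples:
            p1 = f"images/{s.segment_id}_v1.png"
            p2 = f"images/{s.segment_id}_v2.png"
            Image.fromarray(s.view1, mode="L").save(out_dir / p1)
            Image.fromarray(s.view2, mode="L").save(out_dir / p2)
            rows.append((s.patient_id, s.segment_id, p1, p2, s.label))
    else:
        rows = [(s.patient_id, s.segment_id, "", "", s.label) for s in samples]
    manifest = pd.DataFrame(rows, columns=["patient_id", "segment_id",
                                           "view1_path", "view2_path", "label"])
    if out_dir is not None:
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return samples, manifest
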