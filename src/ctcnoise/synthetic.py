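"""Synthetic cutouts and simulated observer panels.

The study's raw data — fluorescence image cutouts of candidate
circulating tumor cells and an 11-observer annotation matrix — is not
publicly deposited, so this module generates data with the same
decision-relevant structure:

* a cutout is a 100 × 100 px three-channel raster with a central
  nucleus blob (blue, DNA stain), green EpCAM/cytokeratin staining and
  an optional red CD45 counterstain.  The truth rule follows the
  annotation guideline: intact blue nucleus plus structured green and no
  red ⇒ CTC; any positive red, or a fragmented/unstained object ⇒ not a
  CTC;
* each scene carries a latent *difficulty* in [0, 1].  Difficulty 0 is
  an unambiguous scene (full staining intensity); difficulty 1 is
  maximally ambiguous (faint, unstructured staining a real observer
  could not call).  Difficulty jointly drives image faintness and
  observer error, coupling image appearance to annotation noise;
* observers are simulated as profiles that reproduce the truth exactly
  on unambiguous scenes and become unsure with probability proportional
  to difficulty.  Unsure *neutral* observers guess; unsure
  *conservative* observers always answer "no CTC", emulating the two
  false-positive-avoiding observers of the study;
* difficulties are drawn from a two-component Beta mixture — a clear
  component concentrated near 0 and an ambiguous tail — because
  disagreement is demonstrably not uniform across cutouts.  The mixture
  weight (ambiguous mass) and the tail location are the calibration
  knobs used to hit a target mean pairwise agreement and consensus
  fraction.

Truth labels are latent: they are returned for oracle testing and
calibration only, and no analysis stage reads them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .annotation import AnnotationMatrix
from .consensus import ConsensusConfig, build_partition
from .preprocess import PIXEL_AREAS, Cutout, save_cutout

SOURCE_SIDE = 100  # px, raster side of a raw cutout at any magnification


# ---------------------------------------------------------------------------
# Scene and observer models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SceneSpec:
    """Full parameterisation of one synthetic cutout."""

    truth_label: int
    difficulty: float
    pixel_area: float = 0.25  # µm² per pixel
    nucleus_radius: float = 5.0  # µm
    blue_intensity: float = 0.9
    nucleus_integrity: float = 1.0  # 1 = intact, 0 = fully fragmented
    green_intensity: float = 0.9
    green_structuredness: float = 1.0  # 1 = crisp rim, 0 = diffuse smear
    red_intensity: float = 0.0  # CD45; any positive value marks a blood cell
    n_flanking: int = 0
    noise_level: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.truth_label not in (0, 1):
            raise ValueError("truth_label must be 0 or 1")
        if not 0.0 <= self.difficulty <= 1.0:
            raise ValueError("difficulty must lie in [0, 1]")
        if self.pixel_area <= 0:
            raise ValueError("pixel_area must be positive")
        if self.truth_label == 1 and self.red_intensity > 0:
            raise ValueError("a CTC scene cannot carry positive CD45 (red) staining")

    @classmethod
    def from_difficulty(
        cls,
        truth_label: int,
        difficulty: float,
        pixel_area: float = 0.25,
        seed: int = 0,
    ) -> "SceneSpec":
        """Derive scene parameters from the latent difficulty.

        Higher difficulty fades staining intensity, degrades nucleus
        integrity and green structure, so ambiguous annotation points
        are also genuinely harder images.  Non-CTC scenes come in two
        flavours: red-positive blood cells (easy to reject, so forced
        when difficulty is low) and faint/fragmented objects.
        """
        rng = np.random.default_rng(seed)
        fade = 1.0 - 0.75 * difficulty
        if truth_label == 1:
            return cls(
                truth_label=1,
                difficulty=difficulty,
                pixel_area=pixel_area,
                blue_intensity=0.9 * fade * rng.uniform(0.75, 1.05),
                nucleus_integrity=(1.0 - 0.5 * difficulty) * rng.uniform(0.8, 1.0),
                green_intensity=0.85 * fade * rng.uniform(0.55, 1.05),
                green_structuredness=(1.0 - 0.7 * difficulty) * rng.uniform(0.65, 1.0),
                red_intensity=0.0,
                n_flanking=int(rng.poisson(0.7)),
                seed=seed,
            )
        # non-CTCs are either red-positive blood cells or red-negative
        # faint/unstructured objects; the latter overlap in appearance
        # with weakly stained CTCs (observers judge on morphology the
        # colour features only partly capture)
        red_positive = rng.random() < 0.55
        return cls(
            truth_label=0,
            difficulty=difficulty,
            pixel_area=pixel_area,
            blue_intensity=0.85 * fade * rng.uniform(0.75, 1.05),
            nucleus_integrity=(1.0 if red_positive else rng.uniform(0.3, 0.6))
            * (1.0 - 0.3 * difficulty),
            green_intensity=(0.15 if red_positive else rng.uniform(0.3, 0.75)) * fade,
            green_structuredness=0.25 if red_positive else rng.uniform(0.15, 0.7),
            red_intensity=0.8 * fade * rng.uniform(0.7, 1.05) if red_positive else 0.0,
            n_flanking=int(rng.poisson(0.7)),
            seed=seed,
        )


@dataclass(frozen=True)
class ObserverProfile:
    """Stochastic annotator.

    ``uncertainty_slope`` scales how fast the probability of being
    unsure grows with scene difficulty; an unsure neutral observer
    guesses uniformly, an unsure conservative one always answers
    "no CTC" (the bias of the study's two outlying observers).  Every
    profile reproduces the truth with probability 1 at difficulty 0.
    """

    observer_id: str
    sensitivity: float = 1.0
    uncertainty_slope: float = 1.0
    conservative_bias: bool = False
    #: an unsure conservative observer still calls a CTC this often
    #: (bias is strong but not absolute)
    conservative_leak: float = 0.1

    def p_unsure(self, difficulty: float) -> float:
        return float(np.clip(self.uncertainty_slope * difficulty, 0.0, 1.0))


def default_profiles(
    n_neutral: int = 9,
    n_conservative: int = 2,
    uncertainty_slope: float = 1.0,
    conservative_slope_factor: float = 2.5,
) -> list[ObserverProfile]:
    """The study-condition panel: 9 neutral + 2 conservative observers.

    Conservative observers demand more evidence before calling a CTC:
    they become unsure earlier (higher uncertainty slope) and resolve
    uncertainty to "no CTC".  This makes them find fewer CTCs *and*
    agree less with the neutral majority — the clustering the study
    observed for its two outlying observers.
    """
    neutral = [
        ObserverProfile(f"OBS{i+1:02d}", uncertainty_slope=uncertainty_slope)
        for i in range(n_neutral)
    ]
    conservative = [
        ObserverProfile(
            f"CON{i+1:02d}",
            uncertainty_slope=uncertainty_slope * conservative_slope_factor,
            conservative_bias=True,
        )
        for i in range(n_conservative)
    ]
    return neutral + conservative


@dataclass(frozen=True)
class DifficultyDistribution:
    """Two-component Beta mixture for latent scene difficulty.

    A fraction ``1 - ambiguous_mass`` of scenes is clear (Beta
    concentrated near 0); the rest forms an ambiguous tail whose
    location is shifted by ``ambiguous_scale``.  ``ambiguous_mass`` is
    the primary calibration knob, ``ambiguous_scale`` the secondary.
    """

    ambiguous_mass: float = 0.33
    easy_a: float = 1.0
    easy_b: float = 14.0
    ambiguous_a: float = 4.0
    ambiguous_b: float = 2.0
    ambiguous_scale: float = 1.0

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        ambiguous = rng.random(n) < self.ambiguous_mass
        d = rng.beta(self.easy_a, self.easy_b, size=n)
        n_amb = int(ambiguous.sum())
        if n_amb:
            tail = rng.beta(self.ambiguous_a, self.ambiguous_b, size=n_amb)
            d[ambiguous] = np.clip(tail * self.ambiguous_scale, 0.0, 1.0)
        return d


# ---------------------------------------------------------------------------
# Image synthesis
# ---------------------------------------------------------------------------

def _radial_blob(r_um: np.ndarray, radius_um: float) -> np.ndarray:
    """Gaussian radial intensity profile, ~1 at center, soft edge."""
    return np.exp(-0.5 * (r_um / radius_um) ** 2)


def generate_cutout(spec: SceneSpec) -> Cutout:
    """Render one 100 × 100 px cutout from a scene specification.

    The appearance is stylised, not photorealistic: blobs with Gaussian
    radial profiles, multiplicative smooth texture for structure, and
    additive background noise.  Only the decision-relevant statistics
    (channel intensities, structure, their coupling to difficulty) are
    controlled.  Bit-identical under the same spec.
    """
    rng = np.random.default_rng(spec.seed)
    side = SOURCE_SIDE
    px = np.sqrt(spec.pixel_area)  # µm per pixel side
    yy, xx = np.mgrid[0:side, 0:side]
    cy = cx = (side - 1) / 2.0
    r_um = np.hypot((yy - cy) * px, (xx - cx) * px)

    img = np.zeros((side, side, 3))

    def smooth_field(scale_px: float) -> np.ndarray:
        f = ndimage.gaussian_filter(rng.standard_normal((side, side)), scale_px)
        f -= f.min()
        peak = f.max()
        return f / peak if peak > 0 else f

    # blue nucleus; fragmentation eats holes into an intact disc
    nucleus = spec.blue_intensity * _radial_blob(r_um, spec.nucleus_radius)
    if spec.nucleus_integrity < 1.0:
        holes = smooth_field(2.0 / px)
        mask = (holes > 1.0 - spec.nucleus_integrity).astype(float)
        nucleus *= ndimage.gaussian_filter(mask, 1.0)
    img[..., 2] += nucleus

    # green staining: cytoplasmic ring around the nucleus; low
    # structuredness degrades the ring into a diffuse smear
    ring = _radial_blob(r_um, 1.8 * spec.nucleus_radius) - 0.6 * _radial_blob(
        r_um, 0.9 * spec.nucleus_radius
    )
    ring = np.clip(ring, 0.0, None)
    ring /= ring.max() if ring.max() > 0 else 1.0
    smear = _radial_blob(r_um, 2.5 * spec.nucleus_radius)
    green_shape = spec.green_structuredness * ring + (1 - spec.green_structuredness) * smear
    texture = 0.6 + 0.4 * smooth_field(1.5 / px)
    img[..., 1] += spec.green_intensity * green_shape * texture

    # red CD45 membrane staining co-located with the cell
    if spec.red_intensity > 0:
        img[..., 0] += spec.red_intensity * _radial_blob(r_um, 1.4 * spec.nucleus_radius)

    # flanking objects: small nucleated neighbours near the border
    for _ in range(spec.n_flanking):
        ang = rng.uniform(0, 2 * np.pi)
        dist = rng.uniform(0.32, 0.46) * side
        fy, fx = cy + dist * np.sin(ang), cx + dist * np.cos(ang)
        fr_um = np.hypot((yy - fy) * px, (xx - fx) * px)
        img[..., 2] += 0.5 * _radial_blob(fr_um, 0.7 * spec.nucleus_radius)
        if rng.random() < 0.5:
            img[..., 0] += 0.4 * _radial_blob(fr_um, 0.9 * spec.nucleus_radius)

    img += rng.normal(0.0, spec.noise_level, size=img.shape) + 0.02
    return Cutout(np.clip(img, 0.0, 1.0), spec.pixel_area, cutout_id=f"synth{spec.seed:07d}")


# ---------------------------------------------------------------------------
# Observer simulation
# ---------------------------------------------------------------------------

def simulate_observer(profile: ObserverProfile, spec: SceneSpec, seed: int) -> int:
    """One observer's binary call on one scene.

    With probability ``p_unsure(difficulty)`` the observer cannot
    decide: a conservative profile then answers 0, a neutral one
    guesses uniformly.  Otherwise the truth label is returned.
    """
    rng = np.random.default_rng(seed)
    if rng.random() < profile.p_unsure(spec.difficulty):
        if profile.conservative_bias:
            return int(rng.random() < profile.conservative_leak)
        return int(rng.integers(0, 2))
    return int(spec.truth_label)


def _simulate_annotations(
    truths: np.ndarray,
    difficulties: np.ndarray,
    profiles: list[ObserverProfile],
    rng: np.random.Generator,
) -> AnnotationMatrix:
    """Vectorised panel annotation (label-level; no images needed)."""
    n = truths.size
    m = len(profiles)
    unsure_draw = rng.random((n, m))
    guess = rng.integers(0, 2, size=(n, m))
    leak_draw = rng.random((n, m))
    labels = np.empty((n, m), dtype=np.int8)
    for j, prof in enumerate(profiles):
        p_unsure = np.clip(prof.uncertainty_slope * difficulties, 0.0, 1.0)
        unsure = unsure_draw[:, j] < p_unsure
        if prof.conservative_bias:
            unsure_label = (leak_draw[:, j] < prof.conservative_leak).astype(np.int8)
        else:
            unsure_label = guess[:, j]
        labels[:, j] = np.where(unsure, unsure_label, truths)
    return AnnotationMatrix(labels, tuple(p.observer_id for p in profiles))


def generate_panel(
    n_points: int,
    profiles: list[ObserverProfile] | None = None,
    difficulty_distribution: DifficultyDistribution | None = None,
    seed: int = 0,
    with_images: bool = True,
    pixel_areas=PIXEL_AREAS,
) -> tuple[list[Cutout] | None, AnnotationMatrix, np.ndarray]:
    """Generate a full study panel: scenes, images and annotations.

    Returns ``(cutouts, annotation_matrix, truth)``; ``cutouts`` is None
    when ``with_images`` is False (label-level simulation, used by the
    calibration loop).  Scene magnifications are drawn uniformly from
    ``pixel_areas``.  Fully determined by ``seed``.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    profiles = profiles if profiles is not None else default_profiles()
    if len(profiles) < 2:
        raise ValueError("need at least 2 observer profiles")
    dist = difficulty_distribution or DifficultyDistribution()
    root = np.random.SeedSequence(seed)
    scene_rng, ann_rng = (np.random.default_rng(s) for s in root.spawn(2))

    truths = (scene_rng.random(n_points) < 0.5).astype(np.int8)
    difficulties = dist.sample(n_points, scene_rng)
    ann = _simulate_annotations(truths, difficulties, profiles, ann_rng)

    cutouts = None
    if with_images:
        areas = scene_rng.choice(pixel_areas, size=n_points)
        scene_seeds = scene_rng.integers(0, 2**31 - 1, size=n_points)
        cutouts = []
        for i in range(n_points):
            spec = SceneSpec.from_difficulty(
                int(truths[i]), float(difficulties[i]), float(areas[i]), int(scene_seeds[i])
            )
            c = generate_cutout(spec)
            cutouts.append(replace(c, cutout_id=f"synth{i:05d}"))
    return cutouts, ann, truths.astype(np.int8)


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

class CalibrationError(RuntimeError):
    """Targets unreachable under the given profile family; carries the
    best parameters found."""

    def __init__(self, message: str, best: "CalibrationResult"):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class CalibrationResult:
    distribution: DifficultyDistribution
    achieved_agreement: float
    achieved_consensus_fraction: float


def _panel_statistics(
    dist: DifficultyDistribution,
    profiles: list[ObserverProfile],
    alpha: float,
    n_points: int,
    n_reps: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Mean pairwise agreement and consensus fraction, averaged over
    label-level replicate panels."""
    from .annotation import agreement_matrix  # local to avoid cycle at import

    cfg = ConsensusConfig(len(profiles), alpha)
    agr, cons = [], []
    for _ in range(n_reps):
        truths = (rng.random(n_points) < 0.5).astype(np.int8)
        difficulties = dist.sample(n_points, rng)
        ann = _simulate_annotations(truths, difficulties, profiles, rng)
        agr.append(agreement_matrix(ann).off_diagonal().mean())
        cons.append(build_partition(ann, cfg).consensus_fraction)
    return float(np.mean(agr)), float(np.mean(cons))


def calibrate_difficulty(
    target_agreement: float,
    target_consensus_fraction: float,
    profiles: list[ObserverProfile] | None = None,
    tolerance: float = 0.02,
    alpha: float = 0.05,
    n_points: int = 617,
    n_reps: int = 8,
    seed: int = 0,
) -> CalibrationResult:
    """Tune the difficulty mixture to hit aggregate annotation targets.

    Coarse grid over the ambiguous-tail scale, then bisection on the
    ambiguous-mass fraction against mean pairwise agreement (which is
    monotone in the mass), keeping the scale whose consensus fraction
    lands closest to target.  Raises :class:`CalibrationError` with the
    best parameters found if the joint targets cannot be met to within
    ``2 * tolerance`` (agreement) / ``3 * tolerance`` (consensus).
    """
    if not (0 < target_agreement <= 1 and 0 < target_consensus_fraction <= 1):
        raise ValueError("targets must lie in (0, 1]")
    profiles = profiles if profiles is not None else default_profiles()
    rng = np.random.default_rng(seed)

    if target_agreement >= 1.0:
        dist = DifficultyDistribution(ambiguous_mass=0.0, easy_a=1.0, easy_b=1e6)
        return CalibrationResult(dist, 1.0, 1.0)

    def evaluate(mass: float, scale: float) -> tuple[float, float, DifficultyDistribution]:
        dist = DifficultyDistribution(ambiguous_mass=mass, ambiguous_scale=scale)
        a, c = _panel_statistics(dist, profiles, alpha, n_points, n_reps, rng)
        return a, c, dist

    def bisect_mass(scale: float) -> tuple[float, float, DifficultyDistribution]:
        lo, hi = 0.0, 1.0  # agreement decreases with mass
        best = evaluate(0.5, scale)
        for _ in range(12):
            mid = 0.5 * (lo + hi)
            a, c, dist = evaluate(mid, scale)
            if abs(a - target_agreement) < abs(best[0] - target_agreement):
                best = (a, c, dist)
            if a > target_agreement:
                lo = mid
            else:
                hi = mid
        return best

    best: tuple[float, float, DifficultyDistribution] | None = None
    for scale in (0.7, 0.85, 1.0, 1.15, 1.3):
        a, c, dist = bisect_mass(scale)
        if best is None or abs(c - target_consensus_fraction) < abs(
            best[1] - target_consensus_fraction
        ):
            best = (a, c, dist)
    a, c, dist = best
    result = CalibrationResult(dist, a, c)
    if (
        abs(a - target_agreement) > 2 * tolerance
        or abs(c - target_consensus_fraction) > 3 * tolerance
    ):
        raise CalibrationError(
            f"calibration failed: achieved agreement {a:.3f} / consensus {c:.3f} "
            f"vs targets {target_agreement:.3f} / {target_consensus_fraction:.3f}",
            result,
        )
    return result


# ---------------------------------------------------------------------------
# On-disk export (the `synth` command)
# ---------------------------------------------------------------------------

def write_panel_dir(
    out_dir,
    n_points: int,
    profiles: list[ObserverProfile] | None = None,
    difficulty_distribution: DifficultyDistribution | None = None,
    seed: int = 0,
) -> None:
    """Write PNG cutouts, metadata sidecar, annotation CSV and latent
    truth CSV, fully determined by (config, seed)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cutouts, ann, truth = generate_panel(
        n_points, profiles, difficulty_distribution, seed=seed, with_images=True
    )
    ids = [c.cutout_id for c in cutouts]
    for c in cutouts:
        save_cutout(c, out / f"{c.cutout_id}.png")
    pd.DataFrame(
        {
            "cutout_id": ids,
            "pixel_area_um2": [c.pixel_area for c in cutouts],
            "source_image": "synthetic",
            "magnification": [
                {1.0: "10x", 0.5: "20x", 0.25: "40x"}[c.pixel_area] for c in cutouts
            ],
        }
    ).to_csv(out / "metadata.csv", index=False)
    ann.to_csv(out / "annotations.csv", cutout_ids=ids)
    pd.DataFrame({"cutout_id": ids, "truth": truth}).to_csv(out / "truth.csv", index=False)
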