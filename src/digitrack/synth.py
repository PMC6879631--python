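"""Synthetic scenes, feature banks and simulated exploration records.

Everything here is a pure function of (parameters, seed): rerunning with
the same seed reproduces the dataset bit for bit. The generators emulate
three phenotypes used throughout the tests — neurotypical exploration,
eye-region-avoidant exploration, and left-neglect (right-biased)
exploration — on procedurally rendered blob scenes, producing the same
fixation/trajectory records that real recordings would.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import Trajectory, truncate_at_path_threshold
from .maps import (AttentionMap, FixationSet, map_from_fixations,
                   map_from_trajectory)
from .saliency import FeatureStack

__all__ = [
    "Blob",
    "Scene",
    "PopulationProfile",
    "ExplorerConfig",
    "NEUROTYPICAL",
    "EYES_AVOIDANT",
    "LEFT_NEGLECT",
    "make_scene",
    "default_scene_blobs",
    "make_feature_bank",
    "simulate_eye_subject",
    "simulate_digit_subject",
    "make_population",
]

#: channel roles recognised by the population profiles
ROLES = ("eyes", "face", "object", "background")


@dataclass(frozen=True)
class Blob:
    """One Gaussian scene element: fractional center, fractional sigma,
    amplitude and a semantic role."""

    cx: float
    cy: float
    sigma: float
    amplitude: float = 1.0
    role: str = "object"


@dataclass
class Scene:
    """A rendered scene plus its generative ground truth."""

    image: np.ndarray                       # (H, W) grayscale in [0, 1]
    saliency: np.ndarray                    # normalized mixture, max = 1
    channel_truth: dict[str, np.ndarray]    # per-role unnormalized maps
    role_weights: dict[str, float]
    image_id: str = ""

    @property
    def raster(self) -> tuple[int, int]:
        return self.saliency.shape


@dataclass(frozen=True)
class PopulationProfile:
    """Dials controlling a simulated population's exploration style."""

    name: str = "neurotypical"
    role_preferences: dict[str, float] = field(
        default_factory=lambda: {"eyes": 1.0, "face": 0.7,
                                 "object": 0.5, "background": 0.1})
    lateral_bias: float | None = None   # fraction of mass right of midline
    jitter_px: float = 3.0
    n_subjects: int = 11

    def __post_init__(self) -> None:
        if self.lateral_bias is not None and not 0 <= self.lateral_bias <= 1:
            raise ValueError("lateral_bias must lie in [0, 1]")
        if any(not np.isfinite(v) for v in self.role_preferences.values()):
            raise ValueError("role preferences must be finite")


NEUROTYPICAL = PopulationProfile(name="neurotypical")
EYES_AVOIDANT = PopulationProfile(
    name="eyes_avoidant",
    role_preferences={"eyes": 0.05, "face": 1.0, "object": 0.5,
                      "background": 0.1})
LEFT_NEGLECT = PopulationProfile(name="left_neglect", lateral_bias=0.85)


@dataclass(frozen=True)
class ExplorerConfig:
    """Acquisition parameters for the simulated recordings.

    Digit defaults reproduce the real protocol's arithmetic: moving at
    1000 px/s until a 4000-px track path is reached takes about 4 s, the
    duration of an eye-tracking trial.
    """

    mode: str = "digit"
    n_fixations: int = 12           # eye mode
    trial_duration_s: float = 4.0   # eye mode
    speed_px_s: float = 1000.0      # digit mode
    sampling_rate_hz: float = 60.0
    path_threshold_px: float = 4000.0

    def __post_init__(self) -> None:
        if self.mode not in ("eye", "digit"):
            raise ValueError("mode must be 'eye' or 'digit'")
        for f in ("trial_duration_s", "speed_px_s", "sampling_rate_hz",
                  "path_threshold_px"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")


def _gaussian_blob(raster: tuple[int, int], blob: Blob) -> np.ndarray:
    h, w = raster
    yy, xx = np.mgrid[0:h, 0:w]
    sx = blob.sigma * w
    sy = blob.sigma * h
    return blob.amplitude * np.exp(
        -((xx - blob.cx * w) ** 2 / (2 * sx ** 2)
          + (yy - blob.cy * h) ** 2 / (2 * sy ** 2)))


def default_scene_blobs(rng: np.random.Generator) -> list[Blob]:
    """A face (with two eye blobs) on one side, an object on the other,
    with randomized positions."""
    left = rng.random() < 0.5
    fx = 0.28 + 0.08 * rng.random() if left else 0.64 + 0.08 * rng.random()
    fy = 0.35 + 0.15 * rng.random()
    ox = 0.68 + 0.08 * rng.random() if left else 0.18 + 0.08 * rng.random()
    oy = 0.55 + 0.2 * rng.random()
    eye_dx, eye_dy = 0.045, 0.04
    return [
        Blob(fx, fy, 0.09, 1.0, "face"),
        Blob(fx - eye_dx, fy - eye_dy, 0.018, 1.0, "eyes"),
        Blob(fx + eye_dx, fy - eye_dy, 0.018, 1.0, "eyes"),
        Blob(ox, oy, 0.06, 0.9, "object"),
        Blob(0.5, 0.5, 0.8, 0.15, "background"),
    ]


def make_scene(raster: tuple[int, int], blobs: list[Blob] | None = None,
               seed: int | np.random.Generator = 0,
               role_weights: dict[str, float] | None = None,
               image_id: str = "") -> Scene:
    """Render a blob scene and its generative ground-truth saliency.

    The ground-truth saliency is the role-weighted sum of the per-role
    channel-truth maps, scaled to max 1; the rendered image adds a light
    deterministic texture so that image-derived feature banks have
    structure to work with.
    """
    rng = np.random.default_rng(seed)
    if blobs is None:
        blobs = default_scene_blobs(rng)
    if not blobs:
        raise ValueError("need at least one blob")
    if role_weights is None:
        role_weights = {r: 1.0 for r in ROLES}

    channel_truth = {r: np.zeros(raster) for r in ROLES}
    for blob in blobs:
        if blob.role not in channel_truth:
            channel_truth[blob.role] = np.zeros(raster)
        channel_truth[blob.role] += _gaussian_blob(raster, blob)

    mixture = np.zeros(raster)
    for role, cmap in channel_truth.items():
        mixture += role_weights.get(role, 0.0) * cmap
    peak = mixture.max()
    if peak <= 0:
        raise ValueError("scene has no salient mass")
    saliency = mixture / peak

    h, w = raster
    yy, xx = np.mgrid[0:h, 0:w]
    texture = 0.05 * np.sin(xx / 3.0) * np.cos(yy / 4.0)
    image = np.clip(0.5 * saliency + 0.3 + texture
                    + 0.02 * rng.standard_normal(raster), 0.0, 1.0)
    return Scene(image=image, saliency=saliency, channel_truth=channel_truth,
                 role_weights=dict(role_weights), image_id=image_id)


def make_feature_bank(raster: tuple[int, int], k: int = 16,
                      seed: int | np.random.Generator = 0,
                      smooth_px: float = 6.0) -> FeatureStack:
    """K smooth random feature maps (Gaussian-filtered white noise).

    Serves as the synthetic stand-in for pretrained convolutional feature
    maps in the weight-recovery tests.
    """
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(seed)
    maps = np.stack([
        gaussian_filter(rng.standard_normal(raster), smooth_px, mode="reflect")
        for _ in range(k)
    ])
    # standardize each channel for comparable dynamic ranges
    maps -= maps.mean(axis=(1, 2), keepdims=True)
    maps /= maps.std(axis=(1, 2), keepdims=True)
    return FeatureStack(maps)


def scene_feature_stack(scene: Scene, extra_channels: int = 12,
                        seed: int | np.random.Generator = 0) -> FeatureStack:
    """Feature stack whose first channels are the scene's role-truth maps,
    padded with random smooth distractor channels."""
    bank = make_feature_bank(scene.raster, extra_channels, seed)
    role_maps = np.stack([scene.channel_truth[r] for r in ROLES])
    maps = np.concatenate([role_maps, bank.maps])
    return FeatureStack(maps, image_id=scene.image_id)


def _subject_saliency(scene: Scene, profile: PopulationProfile) -> np.ndarray:
    """Profile-reweighted sampling density over the scene, normalized to
    sum 1, with the optional lateral-bias mass split applied.

    Each role channel is normalized to unit mass before weighting, so the
    preference weights directly set each role's share of the exploration
    mass — the effect-size dial is faithful regardless of blob sizes.
    """
    sal = np.zeros(scene.raster)
    for role, cmap in scene.channel_truth.items():
        mass = cmap.sum()
        if mass > 0:
            sal += profile.role_preferences.get(role, 0.0) * cmap / mass
    sal = np.clip(sal, 0.0, None)
    if sal.sum() <= 0:
        raise ValueError("profile leaves no salient mass to explore")
    sal /= sal.sum()
    if profile.lateral_bias is not None:
        h, w = sal.shape
        mid = w / 2.0
        right = np.arange(w) > mid
        mr = sal[:, right].sum()
        ml = sal.sum() - mr
        if mr > 0 and ml > 0:
            sal[:, right] *= profile.lateral_bias / mr
            sal[:, ~right] *= (1.0 - profile.lateral_bias) / ml
    return sal


def _draw_waypoints(sal: np.ndarray, n: int, jitter_px: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Sample (n, 2) x/y waypoints from a pixel density, jittered and
    clipped to the raster."""
    h, w = sal.shape
    flat = rng.choice(h * w, size=n, p=sal.ravel())
    ys, xs = np.divmod(flat, w)
    pts = np.column_stack([xs, ys]).astype(float)
    pts += jitter_px * rng.standard_normal(pts.shape)
    pts[:, 0] = np.clip(pts[:, 0], 0, w - 1)
    pts[:, 1] = np.clip(pts[:, 1], 0, h - 1)
    return pts


def simulate_eye_subject(scene: Scene, profile: PopulationProfile,
                         cfg: ExplorerConfig,
                         seed: int | np.random.Generator,
                         subject_id: str = "") -> FixationSet:
    """Fixation sequence drawn from the profile-reweighted saliency.

    Durations follow a log-normal with median 250 ms (an implementation
    choice; no particular empirical distribution is claimed), clipped so a
    trial sums to about the configured duration.
    """
    rng = np.random.default_rng(seed)
    sal = _subject_saliency(scene, profile)
    pts = _draw_waypoints(sal, cfg.n_fixations, profile.jitter_px, rng)
    durations = np.exp(np.log(250.0) + 0.4 * rng.standard_normal(len(pts)))
    durations *= cfg.trial_duration_s * 1000.0 / durations.sum()
    onsets = np.concatenate([[0.0], np.cumsum(durations[:-1])]) / 1000.0
    return FixationSet(pts[:, 0], pts[:, 1], onsets, durations,
                       subject_id=subject_id, image_id=scene.image_id,
                       method="eye")


def simulate_digit_subject(scene: Scene, profile: PopulationProfile,
                           cfg: ExplorerConfig,
                           seed: int | np.random.Generator,
                           subject_id: str = "") -> Trajectory:
    """Finger trajectory: waypoints sampled like fixations, joined at
    constant speed, regularly sampled, and truncated at the path threshold.

    Constant-speed segments with implicit dwells at waypoints are the
    simplest stand-in for the alternation of fast moves and slowing around
    regions of interest; no kinematic realism is claimed.
    """
    rng = np.random.default_rng(seed)
    sal = _subject_saliency(scene, profile)
    dt = 1.0 / cfg.sampling_rate_hz

    def sampled(pts: np.ndarray) -> Trajectory:
        seg = np.hypot(*np.diff(pts, axis=0).T)
        seg_t = np.maximum(seg / cfg.speed_px_s, dt)
        knots_t = np.concatenate([[0.0], np.cumsum(seg_t)])
        times = np.arange(0.0, knots_t[-1], dt)
        xs = np.interp(times, knots_t, pts[:, 0])
        ys = np.interp(times, knots_t, pts[:, 1])
        return Trajectory(times, xs, ys, subject_id=subject_id,
                          image_id=scene.image_id)

    # the regular sampling cuts corners relative to the waypoint polyline,
    # so extend the waypoint list until the sampled path itself is long
    # enough, then cut at the threshold
    pts = _draw_waypoints(sal, 16, profile.jitter_px, rng)
    traj = sampled(pts)
    while traj.path_lengths()[-1] < cfg.path_threshold_px:
        pts = np.vstack([pts,
                         _draw_waypoints(sal, 16, profile.jitter_px, rng)])
        traj = sampled(pts)
    return truncate_at_path_threshold(traj, cfg.path_threshold_px)


@dataclass
class PopulationDataset:
    """Per subject x scene records with group labels and a manifest."""

    records: list[FixationSet | Trajectory]
    manifest: list[dict]
    scenes: list[Scene]
    cfg: ExplorerConfig


def make_population(profiles: list[PopulationProfile], scenes: list[Scene],
                    cfg: ExplorerConfig,
                    seed: int | np.random.Generator = 0) -> PopulationDataset:
    """Simulate every subject of every profile on every scene."""
    rng = np.random.default_rng(seed)
    records: list[FixationSet | Trajectory] = []
    manifest: list[dict] = []
    for profile in profiles:
        for s in range(profile.n_subjects):
            sid = f"{profile.name}_{s:03d}"
            for scene in scenes:
                sub_seed = rng.integers(0, 2 ** 31)
                if cfg.mode == "eye":
                    rec = simulate_eye_subject(scene, profile, cfg, sub_seed,
                                               subject_id=sid)
                else:
                    rec = simulate_digit_subject(scene, profile, cfg,
                                                 sub_seed, subject_id=sid)
                records.append(rec)
                manifest.append({"subject_id": sid, "group": profile.name,
                                 "image_id": scene.image_id,
                                 "method": cfg.mode,
                                 "seed": int(sub_seed)})
    return PopulationDataset(records=records, manifest=manifest,
                             scenes=scenes, cfg=cfg)


def maps_for_dataset(ds: PopulationDataset, bandwidth_px: float = 30.0
                     ) -> dict[str, dict[str, AttentionMap]]:
    """image_id -> subject_id -> attention map for a simulated dataset."""
    raster = ds.scenes[0].raster
    out: dict[str, dict[str, AttentionMap]] = {}
    for rec, meta in zip(ds.records, ds.manifest):
        if isinstance(rec, Trajectory):
            amap = map_from_trajectory(rec, bandwidth_px, raster)
        else:
            amap = map_from_fixations(rec, bandwidth_px, raster)
        out.setdefault(meta["image_id"], {})[meta["subject_id"]] = amap
    return out
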