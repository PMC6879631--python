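"""Linear feature-combination saliency model.

A stack of K aligned feature maps is linearly combined into a predicted
saliency map. Channel weights are learned from measured attention maps
either as per-channel mean correlations (wCorr, the default) or by
cross-validated lasso regression; the learned K-vector is a signature of
how strongly each feature class attracts or repels exploration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.stats import mannwhitneyu, spearmanr

from .maps import AttentionMap, ConstantMapError, _unity_normalize, \
    map_correlation

__all__ = [
    "FEATURE_RASTER",
    "FeatureStack",
    "WeightVector",
    "resize_feature_maps",
    "resize_map",
    "learn_weights_wcorr",
    "learn_weights_regression",
    "predict_saliency",
    "loo_cross_validate",
    "rank_channels",
    "most_responsive_pixels",
    "top_channel_match_pvalue",
    "compare_channel_weights",
]

log = logging.getLogger(__name__)

#: default raster the feature maps (and resampled targets) live on
FEATURE_RASTER = (227, 227)


@dataclass
class FeatureStack:
    """K feature maps on a common raster, aligned to one image."""

    maps: np.ndarray  # (K, H, W)
    channel_ids: list[int] | None = None
    image_id: str = ""

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 3:
            raise ValueError("feature stack must be (K, H, W)")
        if not np.all(np.isfinite(self.maps)):
            raise ValueError("feature maps must be finite")
        if self.channel_ids is None:
            self.channel_ids = list(range(1, self.maps.shape[0] + 1))
        if len(self.channel_ids) != self.maps.shape[0]:
            raise ValueError("channel_ids length must equal K")

    @property
    def k(self) -> int:
        return self.maps.shape[0]

    @property
    def raster(self) -> tuple[int, int]:
        return self.maps.shape[1:]


@dataclass
class WeightVector:
    """Learned per-channel weights plus provenance."""

    weights: np.ndarray
    learner: str = "wcorr"
    channel_ids: list[int] | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 1:
            raise ValueError("weights must be 1-D")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")
        if self.channel_ids is None:
            self.channel_ids = list(range(1, len(self.weights) + 1))

    def __len__(self) -> int:
        return len(self.weights)


def _bilinear_resize(grid: np.ndarray, target: tuple[int, int]) -> np.ndarray:
    """Bilinear resample with corner-aligned sampling (exact on affine fields)."""
    th, tw = target
    if th < 2 or tw < 2:
        raise ValueError("target raster must be at least 2x2")
    h, w = grid.shape
    ys = np.linspace(0.0, h - 1.0, th)
    xs = np.linspace(0.0, w - 1.0, tw)
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    return map_coordinates(grid, [yy, xx], order=1, mode="nearest")


def resize_feature_maps(raw_maps: np.ndarray,
                        target_raster: tuple[int, int] = FEATURE_RASTER,
                        channel_ids: list[int] | None = None,
                        image_id: str = "") -> FeatureStack:
    """Bilinearly interpolate each channel onto the target raster."""
    raw_maps = np.asarray(raw_maps, dtype=float)
    if raw_maps.ndim != 3 or raw_maps.shape[0] < 1:
        raise ValueError("raw_maps must be (K, h, w) with K >= 1")
    out = np.stack([_bilinear_resize(m, target_raster) for m in raw_maps])
    return FeatureStack(out, channel_ids=channel_ids, image_id=image_id)


def resize_map(amap: AttentionMap,
               target_raster: tuple[int, int]) -> AttentionMap:
    """Bilinearly resample an attention map onto another raster."""
    grid, const = _unity_normalize(_bilinear_resize(amap.grid, target_raster))
    return AttentionMap(grid, n_subjects=amap.n_subjects, method=amap.method,
                        image_id=amap.image_id, constant=const)


def _align_target(stack: FeatureStack, target: AttentionMap) -> np.ndarray:
    if target.shape != stack.raster:
        target = resize_map(target, stack.raster)
    return target.grid


def learn_weights_wcorr(stacks: list[FeatureStack],
                        targets: list[AttentionMap]) -> WeightVector:
    """Per-channel weights as the mean over images of the Pearson
    correlation between the channel map and the measured attention map.

    Channels are learned independently; an image on which a channel is
    constant is skipped for that channel (and logged).
    """
    if len(stacks) != len(targets) or not stacks:
        raise ValueError("need matching, non-empty stacks and targets")
    k = stacks[0].k
    sums = np.zeros(k)
    counts = np.zeros(k, dtype=int)
    for stack, target in zip(stacks, targets):
        if stack.k != k:
            raise ValueError("all stacks must share K")
        tgrid = _align_target(stack, target)
        for ci in range(k):
            try:
                r = map_correlation(stack.maps[ci], tgrid)
            except ConstantMapError:
                log.warning("wCorr: constant channel %d on image %r skipped",
                            ci, stack.image_id)
                continue
            sums[ci] += r
            counts[ci] += 1
    if np.any(counts == 0):
        raise ValueError("some channels were constant on every image")
    return WeightVector(sums / counts, learner="wcorr",
                        channel_ids=stacks[0].channel_ids,
                        provenance={"n_images": len(stacks)})


def learn_weights_regression(stacks: list[FeatureStack],
                             targets: list[AttentionMap],
                             cv: int = 10,
                             alphas: np.ndarray | None = None,
                             seed: int = 0) -> WeightVector:
    """Lasso-regularized linear regression of pixelwise attention on the K
    channel values, with regularization strength chosen by k-fold CV over a
    logarithmic grid."""
    from sklearn.linear_model import LassoCV

    if len(stacks) != len(targets) or not stacks:
        raise ValueError("need matching, non-empty stacks and targets")
    x = np.concatenate([s.maps.reshape(s.k, -1).T for s in stacks])
    y = np.concatenate([_align_target(s, t).ravel()
                        for s, t in zip(stacks, targets)])
    if np.ptp(y) == 0 or not np.any(np.ptp(x, axis=0) > 0):
        raise ValueError("degenerate design: zero variance")
    if alphas is None:
        alphas = np.logspace(-6, 0, 13)
    model = LassoCV(alphas=alphas, cv=cv, random_state=seed,
                    max_iter=5000).fit(x, y)
    return WeightVector(model.coef_, learner="regression",
                        channel_ids=stacks[0].channel_ids,
                        provenance={"alpha": float(model.alpha_),
                                    "intercept": float(model.intercept_),
                                    "n_images": len(stacks)})


def predict_saliency(stack: FeatureStack, w: WeightVector) -> AttentionMap:
    """Pixelwise weighted sum of the feature maps, unity-normalized.

    The raw weighted sum may be negative (weights can repel); it is shifted
    to be nonnegative and scaled to max 1. Both steps are affine, so every
    correlation-based score downstream is unaffected. An all-equal output
    (e.g. zero weights) is returned as a flagged constant map rather than
    an error.
    """
    if stack.k != len(w):
        raise ValueError(f"K mismatch: stack has {stack.k} channels, "
                         f"weights have {len(w)}")
    raw = np.tensordot(w.weights, stack.maps, axes=1)
    grid, const = _unity_normalize(raw - raw.min())
    return AttentionMap(grid, method=f"predicted:{w.learner}",
                        image_id=stack.image_id, constant=const)


def loo_cross_validate(stacks: list[FeatureStack],
                       targets: list[AttentionMap],
                       learner=learn_weights_wcorr) -> list[float | None]:
    """Leave-one-out validation: per held-out image, the CC score (Pearson
    correlation between the predicted and the measured attention map).

    A learner failure on a fold yields ``None`` for that image and the run
    continues.
    """
    n = len(stacks)
    if n < 3:
        raise ValueError("LOO validation needs at least 3 images")
    scores: list[float | None] = []
    for i in range(n):
        rest = [j for j in range(n) if j != i]
        try:
            w = learner([stacks[j] for j in rest],
                        [targets[j] for j in rest])
            pred = predict_saliency(stacks[i], w)
            scores.append(map_correlation(pred.grid,
                                          _align_target(stacks[i], targets[i])))
        except (ValueError, ConstantMapError) as exc:
            log.warning("LOO fold %d failed: %s", i, exc)
            scores.append(None)
    return scores


def rank_channels(w: WeightVector) -> list[int]:
    """Channel ids ordered by descending weight; ties broken by channel id."""
    ids = np.asarray(w.channel_ids)
    order = np.lexsort((ids, -w.weights))
    return [int(i) for i in ids[order]]


def most_responsive_pixels(stacks: list[FeatureStack], channel_index: int,
                           top_fraction: float) -> list[np.ndarray]:
    """Per image, a boolean mask of the pixels in the top ``top_fraction``
    quantile of the given channel's map."""
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    masks = []
    for stack in stacks:
        chan = stack.maps[channel_index]
        if top_fraction >= 1.0:
            masks.append(np.ones_like(chan, dtype=bool))
            continue
        thresh = np.quantile(chan, 1.0 - top_fraction)
        masks.append(chan >= thresh)
    return masks


def top_channel_match_pvalue(k: int = 256) -> float:
    """Chance probability that an independently ranked hierarchy places a
    prespecified channel first: 1/K."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return 1.0 / k


def compare_channel_weights(group_a: np.ndarray, group_b: np.ndarray,
                            channel_index: int,
                            n_tested_channels: int = 1) -> float:
    """Two-sided Wilcoxon rank-sum p-value comparing per-subject weights of
    one channel between two groups, Bonferroni-corrected for the number of
    channels tested. ``group_*`` are (n_subjects, K) signature matrices."""
    a = np.asarray(group_a, dtype=float)[:, channel_index]
    b = np.asarray(group_b, dtype=float)[:, channel_index]
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 subjects per group")
    p = mannwhitneyu(a, b, alternative="two-sided",
                     use_continuity=False).pvalue
    return float(min(1.0, p * n_tested_channels))
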