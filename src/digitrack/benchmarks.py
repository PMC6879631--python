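"""Canonical synthetic benchmarks used for acceptance-style validation.

Each routine builds its own dataset from a seed, runs the relevant part of
the pipeline end to end, and returns plain numbers. They are deliberately
small enough to run on one CPU in minutes.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.stats import spearmanr

from . import clinical, synth
from .maps import AttentionMap
from .saliency import learn_weights_wcorr, loo_cross_validate

__all__ = [
    "wcorr_recovery_benchmark",
    "neurotypicality_benchmark",
    "neurotypicality_replicates",
    "laterality_benchmark",
]

#: raster used by the simulation benchmarks (height, width); chosen so a
#: full two-population experiment stays CPU-cheap while keeping the scene
#: structure resolvable
BENCH_RASTER = (80, 96)
BENCH_BANDWIDTH = 3.0
BENCH_N_SCENES = 4


def wcorr_recovery_benchmark(k: int = 16, n_images: int = 30,
                             snr: float = 5.0, seed: int = 0,
                             raster: tuple[int, int] = (64, 64)) -> dict:
    """Learn wCorr weights on targets generated as noisy linear mixtures of
    a known channel bank; report ranking recovery and LOO prediction CC."""
    rng = np.random.default_rng(seed)
    true_w = rng.normal(0, 1, k)
    stacks, targets = [], []
    for i in range(n_images):
        bank = synth.make_feature_bank(raster, k, seed=10_000 * seed + i)
        mix = np.tensordot(true_w, bank.maps, axes=1)
        noise = gaussian_filter(rng.standard_normal(raster), 4,
                                mode="reflect")
        noise *= mix.std() / (snr * noise.std())
        tgt = mix + noise
        tgt -= tgt.min()
        tgt /= tgt.max()
        stacks.append(bank)
        targets.append(AttentionMap(tgt, image_id=f"img{i}"))
    w = learn_weights_wcorr(stacks, targets)
    scores = loo_cross_validate(stacks, targets)
    return {
        "spearman": float(spearmanr(w.weights, true_w).statistic),
        "loo_mean_cc": float(np.mean([s for s in scores if s is not None])),
        "n_images": n_images,
    }


def _bench_scenes(seed: int) -> list[synth.Scene]:
    return [synth.make_scene(BENCH_RASTER, seed=seed + i,
                             image_id=f"img{i}")
            for i in range(BENCH_N_SCENES)]


def _subject_maps(profile: synth.PopulationProfile, n: int,
                  scenes: list[synth.Scene], cfg: synth.ExplorerConfig,
                  seed) -> dict[str, dict[str, AttentionMap]]:
    """subject_id -> image_id -> map for n subjects of one profile."""
    prof = synth.PopulationProfile(name=profile.name,
                                   role_preferences=profile.role_preferences,
                                   lateral_bias=profile.lateral_bias,
                                   jitter_px=profile.jitter_px,
                                   n_subjects=n)
    ds = synth.make_population([prof], scenes, cfg, seed=seed)
    by_image = synth.maps_for_dataset(ds, bandwidth_px=BENCH_BANDWIDTH)
    by_subject: dict[str, dict[str, AttentionMap]] = {}
    for iid, d in by_image.items():
        for sid, amap in d.items():
            by_subject.setdefault(sid, {})[iid] = amap
    return by_subject


def _explorer_config(mode: str) -> synth.ExplorerConfig:
    if mode == "digit":
        # 30 Hz halves the trajectory sample count with no loss for maps
        return synth.ExplorerConfig(mode="digit", sampling_rate_hz=30)
    return synth.ExplorerConfig(mode="eye")


def neurotypicality_benchmark(mode: str = "digit", n_ref: int = 10,
                              n_per_group: int = 22,
                              seed: int = 0) -> dict:
    """Score a synthetic control and an eye-avoidant group against a
    neurotypical reference cohort; report the rank-sum p and the
    density-fitted ROC AUC (sigma = 0.6)."""
    cfg = _explorer_config(mode)
    rng = np.random.default_rng(seed)
    scenes = _bench_scenes(int(rng.integers(2 ** 30)))
    ref = _subject_maps(synth.NEUROTYPICAL, n_ref, scenes, cfg,
                        rng.integers(2 ** 31))
    by_picture: dict[str, list[AttentionMap]] = {}
    for maps in ref.values():
        for iid, amap in maps.items():
            by_picture.setdefault(iid, []).append(amap)
    cohort = clinical.ReferenceCohort(by_picture)

    def scores(profile) -> np.ndarray:
        subs = _subject_maps(profile, n_per_group, scenes, cfg,
                             rng.integers(2 ** 31))
        return np.array([
            clinical.neurotypicality_score(m, cohort).score
            for m in subs.values()
        ])

    ctrl = scores(synth.NEUROTYPICAL)
    atyp = scores(synth.EYES_AVOIDANT)
    p = clinical.group_difference_test(ctrl, atyp)
    roc = clinical.roc_from_densities(clinical.fit_score_density(ctrl),
                                      clinical.fit_score_density(atyp))
    return {"p": p, "auc": roc.auc, "scores_ctrl": ctrl,
            "scores_atypical": atyp, "n_per_group": n_per_group}


def neurotypicality_replicates(n_replicates: int = 100,
                               mode: str = "digit",
                               n_per_group: int = 22,
                               seed: int = 0,
                               alpha: float = 0.01) -> dict:
    """Fraction of seeded replicates whose rank-sum test rejects at
    ``alpha``."""
    hits = 0
    for r in range(n_replicates):
        res = neurotypicality_benchmark(mode=mode,
                                        n_per_group=n_per_group,
                                        seed=seed + r)
        hits += res["p"] < alpha
    return {"fraction_significant": hits / n_replicates,
            "n_replicates": n_replicates}


def laterality_benchmark(bias: float = 0.85, n_subjects: int = 50,
                         seed: int = 0) -> dict:
    """Mean laterality index of a lateral-bias population (eye mode,
    duration-weighted), in percent."""
    rng = np.random.default_rng(seed)
    scene = synth.make_scene(BENCH_RASTER, seed=int(rng.integers(2 ** 30)),
                             image_id="img0")
    cfg = synth.ExplorerConfig(mode="eye", n_fixations=30)
    prof = synth.PopulationProfile(name="lateral", lateral_bias=bias,
                                   jitter_px=1.0, n_subjects=n_subjects)
    ds = synth.make_population([prof], [scene], cfg,
                               seed=int(rng.integers(2 ** 31)))
    idx = [clinical.laterality_index(rec, BENCH_RASTER[1] / 2)["pct_right"]
           for rec in ds.records]
    return {"mean_pct_right": float(np.mean(idx)), "n_subjects": n_subjects}
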