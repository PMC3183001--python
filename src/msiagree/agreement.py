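"""Agreement analysis: consensus images across multivariate methods.

Different decompositions of the same imaging MS dataset often highlight the
same tissue regions, but in different components and mixed with different
extra structure.  The agreement analysis makes the consensus explicit:

1. take each method's top components in turn as a *template*;
2. for every other method, find the component image with the highest Pearson
   correlation to the template (images unfolded to 1-d vectors over the
   tissue pixels, which handles irregular tissue outlines);
3. threshold each matched image at 40% of its maximum intensity and sum the
   binary images — the *agreement plot*, an integer image counting how many
   methods mark each pixel;
4. remove redundant plots (every template that picks up the same region
   produces a near-identical plot) with a greedy *cutdown* at correlation
   0.7 on the non-thresholded plots;
5. average the matched, basepeak-normalized component spectra into a
   consensus spectrum per surviving plot.

A region marked by four or five of five independent methods is very unlikely
to be an artifact of any one method's assumptions.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import skew

from .factorize import (DEFAULT_AGREEMENT_METHODS, ComponentSet,
                        FactorizeConfig, run_methods)
from .msidata import ReducedDataset


@dataclass
class AgreementConfig:
    methods: tuple[str, ...] = DEFAULT_AGREEMENT_METHODS
    top_k: int = 8
    intensity_threshold_frac: float = 0.40
    cutdown_corr: float = 0.70
    thresholded: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.methods) < 2:
            raise ValueError("agreement needs at least two methods")
        if not 0 < self.intensity_threshold_frac < 1:
            raise ValueError("intensity_threshold_frac must be in (0, 1)")
        if not 0 < self.cutdown_corr <= 1:
            raise ValueError("cutdown_corr must be in (0, 1]")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")


@dataclass
class MatchResult:
    """One template component and its best match in every other method."""

    template: tuple[str, int]                      # (method, component index)
    matched: dict[str, tuple[int, float, bool]]    # method -> (idx, r, flip)


@dataclass
class AgreementPlot:
    image: np.ndarray              # integer consensus image, values 0..M
    continuous_image: np.ndarray   # sum of min-max scaled images, 0..M
    match: MatchResult
    consensus_spectrum: np.ndarray
    rank_key: int = 0              # matches with r >= cutdown threshold
    mean_match_r: float = 0.0

    @property
    def n_methods(self) -> int:
        return 1 + len(self.match.matched)


# ---------------------------------------------------------------------------
# Primitive operations
# ---------------------------------------------------------------------------

def unfolded_pearson(image_a: np.ndarray, image_b: np.ndarray) -> float:
    """Pearson correlation of two component images unfolded to 1-d vectors.

    Images are already stored as vectors over the tissue pixels, so
    off-tissue positions never enter the correlation.  A zero-variance image
    yields r = 0 with a warning.
    """
    a = np.asarray(image_a, dtype=float).ravel()
    b = np.asarray(image_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("images must be defined on the same pixel set")
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        warnings.warn("zero-variance image in correlation; r defined as 0",
                      stacklevel=2)
        return 0.0
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def threshold_image(image: np.ndarray, frac: float) -> np.ndarray:
    """Binary mask of pixels strictly above ``frac`` x the image maximum.

    Negative values must have been clipped beforehand; an image with a
    non-positive maximum yields an all-zero mask with a warning.
    """
    image = np.asarray(image, dtype=float)
    mx = image.max()
    if mx <= 0:
        warnings.warn("image has non-positive maximum; thresholded image is "
                      "all zero", stacklevel=2)
        return np.zeros_like(image)
    return (image > frac * mx).astype(float)


def _oriented_image(cs: ComponentSet, idx: int, flip: bool) -> np.ndarray:
    img = cs.scores[:, idx].copy()
    if flip:
        img = -img
    if not cs.sign_definite:
        img = np.clip(img, 0.0, None)
    return img


def _oriented_loading(cs: ComponentSet, idx: int, flip: bool) -> np.ndarray:
    ld = cs.loadings[idx].copy()
    return -ld if flip else ld


def _canonical(cs: ComponentSet, idx: int) -> bool:
    """Flip flag giving the canonical (non-negative skew) orientation."""
    if cs.sign_definite:
        return False
    return bool(skew(cs.scores[:, idx]) < 0)


def _minmax(image: np.ndarray) -> np.ndarray:
    lo, hi = image.min(), image.max()
    if hi <= lo:
        return np.zeros_like(image)
    return (image - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

def match_components(template: ComponentSet, others: list[ComponentSet],
                     config: AgreementConfig,
                     template_index: int) -> MatchResult:
    """Best-correlated component of every other method for one template.

    Sign-indefinite candidates are tried in both orientations and the sign
    with the larger \\|r\\| is recorded as a flip flag.  Many-to-one matching
    is allowed; ties go to the lower component index.
    """
    t_flip = _canonical(template, template_index)
    t_img = _oriented_image(template, template_index, t_flip)
    matched: dict[str, tuple[int, float, bool]] = {}
    for other in others:
        n_pix = other.scores.shape[0]
        if n_pix != template.scores.shape[0]:
            raise ValueError("component sets cover different pixel sets")
        best: tuple[float, int, float, bool] | None = None  # (score, idx, r, flip)
        for j in range(min(config.top_k, other.k)):
            base = _canonical(other, j)
            candidates = [base, not base] if not other.sign_definite else [base]
            for flip in candidates:
                r = unfolded_pearson(t_img, _oriented_image(other, j, flip))
                score = abs(r) if not other.sign_definite else r
                if best is None or score > best[0] + 1e-15:
                    best = (score, j, r, flip)
        matched[other.method] = (best[1], best[2], best[3])
    return MatchResult(template=(template.method, template_index),
                       matched=matched)


# ---------------------------------------------------------------------------
# Agreement plot construction
# ---------------------------------------------------------------------------

def build_agreement(match: MatchResult,
                    components: dict[str, ComponentSet],
                    config: AgreementConfig) -> AgreementPlot:
    """Sum the template's own and all matched images into one consensus plot.

    Every image is sign-oriented, negatives clipped, thresholded at
    ``intensity_threshold_frac`` of its maximum, and the binary images summed
    (integer image, 0..M).  The continuous variant sums the same images
    min-max scaled to [0, 1] without thresholding.  The consensus spectrum is
    the mean of the basepeak-normalized matched loadings, renormalized to a
    maximum of 1.
    """
    t_method, t_idx = match.template
    template = components[t_method]
    parts = [(template, t_idx, _canonical(template, t_idx))]
    for method, (idx, _r, flip) in match.matched.items():
        parts.append((components[method], idx, flip))

    binary_sum = None
    continuous_sum = None
    loadings = []
    for cs, idx, flip in parts:
        img = _oriented_image(cs, idx, flip)
        binary = threshold_image(img, config.intensity_threshold_frac)
        cont = _minmax(img)
        binary_sum = binary if binary_sum is None else binary_sum + binary
        continuous_sum = cont if continuous_sum is None else continuous_sum + cont
        ld = _oriented_loading(cs, idx, flip)
        mx = ld.max()
        loadings.append(ld / mx if mx > 0 else np.zeros_like(ld))

    consensus = np.mean(loadings, axis=0)
    cmax = consensus.max()
    if cmax > 0:
        consensus = consensus / cmax

    rs = [r for (_i, r, _f) in match.matched.values()]
    rank_key = int(sum(r >= config.cutdown_corr for r in rs))
    return AgreementPlot(image=binary_sum, continuous_image=continuous_sum,
                         match=match, consensus_spectrum=consensus,
                         rank_key=rank_key,
                         mean_match_r=float(np.mean(rs)) if rs else 0.0)


# ---------------------------------------------------------------------------
# Cutdown
# ---------------------------------------------------------------------------

def cutdown(plots: list[AgreementPlot],
            config: AgreementConfig) -> list[AgreementPlot]:
    """Remove redundant agreement plots.

    Plots are sorted by the number of well-correlated matched images
    (descending; ties by mean match correlation), then greedily kept unless
    the non-thresholded (continuous) plot correlates above ``cutdown_corr``
    with an already-kept plot.
    """
    if not plots:
        return []
    order = sorted(range(len(plots)),
                   key=lambda i: (-plots[i].rank_key, -plots[i].mean_match_r,
                                  i))
    kept: list[AgreementPlot] = []
    for i in order:
        cand = plots[i]
        if all(unfolded_pearson(cand.continuous_image, k.continuous_image)
               <= config.cutdown_corr for k in kept):
            kept.append(cand)
    return kept


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def run_agreement(project: ReducedDataset,
                  config: AgreementConfig | None = None,
                  factorize_config: FactorizeConfig | None = None,
                  components: dict[str, ComponentSet] | None = None
                  ) -> tuple[list[AgreementPlot], dict[str, ComponentSet]]:
    """End-to-end agreement analysis of a TIC-normalized project dataset.

    Runs every configured method, iterates each method's top components as
    templates, builds all M x top_k agreement plots and cuts them down.
    Deterministic for a fixed seed.  Returns the surviving plots (best
    first) and the fitted component sets.
    """
    config = config or AgreementConfig()
    if project.normalization != "tic":
        raise ValueError("project dataset must be TIC-normalized "
                         "(msidata.tic_normalize)")
    if components is None:
        fc = factorize_config or FactorizeConfig(
            n_components=config.top_k, seed=config.seed)
        components = run_methods(config.methods, project, fc)

    plots: list[AgreementPlot] = []
    for method in config.methods:
        template = components[method]
        others = [components[m] for m in config.methods if m != method]
        for idx in range(min(config.top_k, template.k)):
            match = match_components(template, others, config, idx)
            plots.append(build_agreement(match, components, config))
    return cutdown(plots, config), components


# ---------------------------------------------------------------------------
# k-fold cross-validated agreement
# ---------------------------------------------------------------------------

def cross_validated_agreement(projects: list[ReducedDataset], k: int,
                              seed: int,
                              config: AgreementConfig | None = None,
                              gutter: int = 5) -> np.ndarray:
    """Stability of agreement regions under k-fold dataset resampling.

    The datasets (e.g. patient tissue samples) are randomly split into k
    subgroups; agreement analysis is run on each set of k-1 retained
    subgroups.  Surviving plots are compared across folds by correlating
    their continuous images on the pixels of datasets shared by both folds.

    Returns a (k, k) matrix whose (i, j) entry is the mean, over fold i's
    plots, of the best correlation with any of fold j's plots.
    """
    from .msidata import tic_normalize
    from .reduce import merge_datasets

    if k < 2:
        raise ValueError("k must be >= 2")
    if len(projects) < k:
        raise ValueError("need at least k datasets")
    config = config or AgreementConfig(seed=seed)

    rng = np.random.default_rng(seed % 2**31)
    assignment = np.array([i % k for i in range(len(projects))])
    rng.shuffle(assignment)

    fold_plots: list[list[AgreementPlot]] = []
    fold_pixel_sources: list[list[str]] = []
    for fold in range(k):
        retained = [d for d, a in zip(projects, assignment) if a != fold]
        merged = merge_datasets(retained, gutter=gutter) \
            if len(retained) > 1 else retained[0]
        if merged.normalization != "tic":
            merged, _ = tic_normalize(merged)
        plots, _ = run_agreement(merged, config)
        fold_plots.append(plots)
        fold_pixel_sources.append(
            [p.source_id for p in merged.provenance])

    sim = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(k):
            if i == j:
                sim[i, j] = 1.0
                continue
            shared = set(fold_pixel_sources[i]) & set(fold_pixel_sources[j])
            if not shared or not fold_plots[i] or not fold_plots[j]:
                continue
            # pixels from shared datasets align across folds because merge
            # preserves dataset order and per-dataset pixel order
            idx_i = _shared_index(fold_pixel_sources[i], shared)
            idx_j = _shared_index(fold_pixel_sources[j], shared)
            best = []
            for pi in fold_plots[i]:
                vi = pi.continuous_image[idx_i]
                rs = [unfolded_pearson(vi, pj.continuous_image[idx_j])
                      for pj in fold_plots[j]]
                best.append(max(rs))
            sim[i, j] = float(np.mean(best))
    return sim


def _shared_index(sources: list[str], shared: set[str]) -> np.ndarray:
    return np.array([i for i, s in enumerate(sources) if s in shared],
                    dtype=int)
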