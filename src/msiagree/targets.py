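"""Supervised target images and validation of the unsupervised outputs.

A target image is built from a region of interest known (e.g. from a prior
classification) to be biologically distinct: the mean spectrum over the ROI
is peak-picked at S/N > 5, the image of every such peak is extracted over the
*whole* dataset, and the images are summed.  Target images therefore contain
the unrefined heterogeneity of the ROI — both its differential peaks and the
ubiquitous ones — and serve as a yardstick for the unsupervised methods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .agreement import AgreementPlot, unfolded_pearson
from .factorize import ComponentSet
from .msidata import MSIDataset, ReducedDataset, ROIMask
from .reduce import PeakList, ReduceConfig, detect_peaks, extract_features


@dataclass
class TargetImage:
    label: str
    image: np.ndarray          # per-pixel vector over the dataset's pixels
    spectrum: PeakList         # principal ROI peaks with their S/N
    feature_mz: np.ndarray     # m/z of the summed feature images
    feature_profile: np.ndarray  # ROI mean intensity at those features


def _roi_mean_spectrum(matrix: np.ndarray, rows: np.ndarray) -> np.ndarray:
    return matrix[rows].mean(axis=0)


def make_target(dataset: MSIDataset | ReducedDataset, roi: ROIMask,
                snr_threshold: float = 5.0,
                config: ReduceConfig | None = None) -> TargetImage:
    """Build a target image from an ROI mask.

    Works on profile data (peaks integrated with the configured ppm window)
    or directly on a reduced dataset (each detected peak maps to its feature
    column).
    """
    config = config or ReduceConfig()
    rows = roi.indices_in(dataset)

    if isinstance(dataset, ReducedDataset):
        # features are already peaks: select by a robust z-score against the
        # noise floor of the ROI mean feature vector (no local-maximum
        # requirement, which only makes sense on a profile axis)
        axis = dataset.feature_mz
        mean_spec = _roi_mean_spectrum(dataset.matrix, rows)
        med = np.median(mean_spec)
        sigma = 1.4826 * np.median(np.abs(mean_spec - med))
        if sigma == 0:
            sigma = np.std(mean_spec) or 1.0
        snr = (mean_spec - med) / sigma
        cols = np.flatnonzero(snr > snr_threshold)
        if len(cols) == 0:
            raise ValueError(f"ROI '{roi.label}': no peaks above "
                             f"S/N {snr_threshold}")
        peaks = PeakList(entries=[(float(axis[c]), float(snr[c]), roi.label)
                                  for c in cols], dataset_id=roi.label)
        image = dataset.matrix[:, cols].sum(axis=1)
        feature_mz = axis[cols]
        profile = mean_spec[cols]
    else:
        mean_spec = _roi_mean_spectrum(dataset.intensities, rows)
        peaks = detect_peaks(mean_spec, dataset.mz_axis, config,
                             source=roi.label, snr_threshold=snr_threshold)
        if len(peaks) == 0:
            raise ValueError(f"ROI '{roi.label}': no peaks above "
                             f"S/N {snr_threshold}")
        reduced = extract_features(dataset, peaks, config.extract_window_ppm)
        image = reduced.matrix.sum(axis=1)
        feature_mz = reduced.feature_mz
        profile = np.array([
            mean_spec[int(np.argmin(np.abs(dataset.mz_axis - c)))]
            for c in feature_mz])
    return TargetImage(label=roi.label, image=image, spectrum=peaks,
                       feature_mz=feature_mz, feature_profile=profile)


def _spectrum_r(target: TargetImage, loading: np.ndarray,
                feature_mz: np.ndarray, tolerance_ppm: float = 100.0) -> float:
    """Correlate a basepeak-normalized loading with the target's peak profile
    on features matching within the collation tolerance."""
    t_vals, l_vals = [], []
    for mz, v in zip(target.feature_mz, target.feature_profile):
        d = np.abs(feature_mz - mz)
        j = int(np.argmin(d))
        if d[j] <= tolerance_ppm * 1e-6 * mz:
            t_vals.append(v)
            l_vals.append(loading[j])
    if len(t_vals) < 3:
        return float("nan")
    t = np.asarray(t_vals)
    l = np.asarray(l_vals)
    t = t / t.max() if t.max() > 0 else t
    l = l / l.max() if l.max() > 0 else l
    return unfolded_pearson(t, l)


def validate_against_targets(targets: list[TargetImage],
                             components: dict[str, ComponentSet],
                             plots: list[AgreementPlot],
                             feature_mz: np.ndarray | None = None
                             ) -> pd.DataFrame:
    """Correlation table of targets vs each method's best component and the
    best continuous agreement plot.

    Rows: one per (target, method) and (target, 'agreement').  Columns:
    ``image_r`` (Pearson over pixels, best |r| component per method) and
    ``spectrum_r`` (basepeak-normalized loading vs target peak profile,
    for the image-selected component).
    """
    rows = []
    for target in targets:
        for method, cs in components.items():
            best = None
            for j in range(cs.k):
                r = unfolded_pearson(target.image, cs.scores[:, j])
                # sign is arbitrary for sign-indefinite methods: orient it
                score = abs(r) if not cs.sign_definite else r
                if best is None or score > best[0]:
                    best = (score, j, r)
            _score, j, r = best
            signed_r = r
            if not cs.sign_definite:
                r = abs(r)
            spec_r = np.nan
            if feature_mz is not None:
                ld = cs.loadings[j] if signed_r >= 0 else -cs.loadings[j]
                spec_r = _spectrum_r(target, np.clip(ld, 0, None), feature_mz)
            rows.append({"target": target.label, "method": method,
                         "component": j, "image_r": r, "spectrum_r": spec_r})
        if plots:
            best_plot = max(
                plots, key=lambda p: unfolded_pearson(target.image,
                                                      p.continuous_image))
            r = unfolded_pearson(target.image, best_plot.continuous_image)
            spec_r = np.nan
            if feature_mz is not None:
                spec_r = _spectrum_r(target, best_plot.consensus_spectrum,
                                     feature_mz)
            rows.append({"target": target.label, "method": "agreement",
                         "component": -1, "image_r": r, "spectrum_r": spec_r})
    return pd.DataFrame(rows)


def correlation_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-method mean and standard deviation of the image correlations."""
    return (table.groupby("method")["image_r"]
            .agg(["mean", "std", "count"]).reset_index())
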