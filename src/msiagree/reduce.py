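"""Automated feature detection and extraction.

Profile imaging MS datasets have ~1e5 channels per pixel; multivariate
analysis at that dimensionality is impractical (see :mod:`msiagree.resources`).
The reduction pipeline is:

1. compute several mass-spectral *representations* of the dataset, including
   ones that highlight features confined to small regions and therefore
   diluted out of the mean spectrum;
2. pick peaks in each representation at a signal-to-noise threshold;
3. collate the per-representation (and, for multi-sample projects, the
   per-dataset) peak lists with a ppm mass tolerance;
4. integrate a ppm window around every collated peak in every pixel spectrum,
   giving the pixels x features matrix.

Multiple reduced datasets are merged side by side on one virtual grid using
pixel offsets, so the multivariate methods see all tissues at once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from scipy.ndimage import median_filter

from .msidata import MSIDataset, PixelProvenance, ReducedDataset

MAD_TO_SIGMA = 1.4826  # consistent estimator of sigma for Gaussian noise


@dataclass
class ReduceConfig:
    snr_threshold: float = 4.0
    peak_width_ppm: float = 500.0       # applied as +/-
    collate_tolerance_ppm: float = 100.0
    extract_window_ppm: float = 500.0   # applied as +/-
    representations: tuple[str, ...] = (
        "mean", "basepeak", "variance_ratio", "block_max")

    def __post_init__(self) -> None:
        for name in ("snr_threshold", "peak_width_ppm",
                     "collate_tolerance_ppm", "extract_window_ppm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.representations:
            raise ValueError("at least one representation is required")


@dataclass
class PeakList:
    """Detected peaks: (mz_center, snr, source_representation) entries."""

    entries: list[tuple[float, float, str]]
    dataset_id: str = ""

    @property
    def centers(self) -> np.ndarray:
        return np.array([e[0] for e in self.entries])

    def __len__(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# Representations
# ---------------------------------------------------------------------------

def spectral_representations(dataset: MSIDataset,
                             block: int = 8) -> dict[str, np.ndarray]:
    """Summary spectra of a dataset used for peak detection.

    ``mean``            per-channel mean over pixels.
    ``basepeak``        per-channel maximum over pixels — a peak present in
                        even a single pixel survives at full height.
    ``variance_ratio``  per-channel variance/mean (zero where the mean is 0) —
                        localized features have high spatial variance relative
                        to their mean.
    ``block_max``       grid split into ``block`` x ``block`` pixel blocks;
                        per-channel maximum over the block means — localized
                        but noisy features are averaged within a block before
                        the maximum is taken.
    """
    if dataset.n_pixels == 0:
        raise ValueError("dataset has no pixels")
    X = dataset.intensities
    mean = X.mean(axis=0)
    basepeak = X.max(axis=0)
    var = X.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        vmr = np.where(mean > 0, var / mean, 0.0)

    keys = dataset.pixels // block
    block_means = []
    for key in np.unique(keys, axis=0):
        sel = np.all(keys == key, axis=1)
        block_means.append(X[sel].mean(axis=0))
    block_max = np.max(block_means, axis=0)

    return {"mean": mean, "basepeak": basepeak,
            "variance_ratio": vmr, "block_max": block_max}


# ---------------------------------------------------------------------------
# Peak detection
# ---------------------------------------------------------------------------

def _sliding_mad_noise(spectrum: np.ndarray, window_frac: float = 0.02
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Local floor and noise level: running median and 1.4826 x median
    absolute deviation in a sliding window spanning 2% of the axis length."""
    n = len(spectrum)
    w = max(3, int(round(window_frac * n)) | 1)  # odd, >= 3
    med = median_filter(spectrum, size=w, mode="nearest")
    mad = median_filter(np.abs(spectrum - med), size=w, mode="nearest")
    return med, MAD_TO_SIGMA * mad


def detect_peaks(spectrum: np.ndarray, mz_axis: np.ndarray,
                 config: ReduceConfig | None = None,
                 source: str = "spectrum",
                 snr_threshold: float | None = None) -> PeakList:
    """Local-maximum picker with a sliding-MAD noise estimate.

    A channel is a peak if it is a local maximum and its intensity above the
    local median floor is at least ``snr_threshold`` times the local noise
    (median-relative signal keeps S/N well defined when a residual baseline
    offset survives correction).  Maxima closer than the configured peak
    width (ppm of the lower mass) are merged, keeping the higher apex.
    """
    config = config or ReduceConfig()
    thr = config.snr_threshold if snr_threshold is None else snr_threshold
    spectrum = np.asarray(spectrum, dtype=float)
    mz_axis = np.asarray(mz_axis, dtype=float)

    floor_level, noise = _sliding_mad_noise(spectrum)
    if np.all(noise == 0):
        warnings.warn(f"{source}: zero noise estimate (constant spectrum?); "
                      "no peaks detected", stacklevel=2)
        return PeakList(entries=[], dataset_id=source)

    idx, _ = find_peaks(spectrum)
    # find_peaks never reports endpoints; a boundary channel higher than its
    # sole neighbour is still an apex (matters for short feature-space axes)
    n = len(spectrum)
    ends = []
    if n == 1:
        ends = [0]
    else:
        if spectrum[0] > spectrum[1]:
            ends.append(0)
        if spectrum[-1] > spectrum[-2]:
            ends.append(n - 1)
    if ends:
        idx = np.sort(np.concatenate([idx, ends]).astype(int))
    floor = np.median(noise[noise > 0])
    snr = (spectrum[idx] - floor_level[idx]) / np.maximum(noise[idx], floor)
    idx = idx[snr >= thr]
    snr = snr[snr >= thr]

    # merge apexes closer than the peak width, keeping the higher one
    order = np.argsort(spectrum[idx])[::-1]  # tallest first
    kept: list[int] = []
    kept_snr: list[float] = []
    for o in order:
        i = idx[o]
        if all(abs(mz_axis[i] - mz_axis[k])
               > config.peak_width_ppm * 1e-6 * min(mz_axis[i], mz_axis[k])
               for k in kept):
            kept.append(i)
            kept_snr.append(float(snr[o]))
    entries = sorted(
        ((float(mz_axis[i]), s, source) for i, s in zip(kept, kept_snr)),
        key=lambda e: e[0])
    return PeakList(entries=entries, dataset_id=source)


def detect_dataset_peaks(dataset: MSIDataset,
                         config: ReduceConfig | None = None) -> PeakList:
    """Dataset-specific peak list: detect in every representation, collate."""
    config = config or ReduceConfig()
    reps = spectral_representations(dataset)
    lists = []
    for name in config.representations:
        if name not in reps:
            raise ValueError(f"unknown representation '{name}'")
        lists.append(detect_peaks(reps[name], dataset.mz_axis, config,
                                  source=name))
    merged = collate_peaklists(lists, config.collate_tolerance_ppm)
    merged.dataset_id = dataset.dataset_id
    return merged


# ---------------------------------------------------------------------------
# Collation
# ---------------------------------------------------------------------------

def collate_peaklists(lists: list[PeakList], tolerance_ppm: float) -> PeakList:
    """Single-linkage merge of peak lists with a ppm mass tolerance.

    Entries whose centers differ by at most ``tolerance_ppm`` (relative to the
    lower mass) join one cluster; a cluster's center is the unweighted mean of
    its members.  The result is sorted and deduplicated, and the operation is
    idempotent.
    """
    entries = sorted((e for pl in lists for e in pl.entries),
                     key=lambda e: (e[0], e[1]))
    if not entries:
        return PeakList(entries=[])
    clusters: list[list[tuple[float, float, str]]] = [[entries[0]]]
    for e in entries[1:]:
        prev = clusters[-1][-1]
        if (e[0] - prev[0]) <= tolerance_ppm * 1e-6 * prev[0]:
            clusters[-1].append(e)
        else:
            clusters.append([e])
    out = []
    for members in clusters:
        center = float(np.mean([m[0] for m in members]))
        snr = float(max(m[1] for m in members))
        srcs = sorted({m[2] for m in members})
        out.append((center, snr, "+".join(srcs)))
    return PeakList(entries=out)


# ---------------------------------------------------------------------------
# Extraction and merging
# ---------------------------------------------------------------------------

def extract_features(dataset: MSIDataset, peaks: PeakList,
                     window_ppm: float = 500.0) -> ReducedDataset:
    """Integrate a +/- ppm window around every peak in every pixel.

    Windows may overlap: a channel can contribute to two adjacent features.
    A window containing no channel yields a zero feature and a warning.
    """
    if len(peaks) == 0:
        raise ValueError("peak list is empty")
    centers = peaks.centers
    matrix = np.zeros((dataset.n_pixels, len(centers)))
    for j, c in enumerate(centers):
        half = window_ppm * 1e-6 * c
        lo = np.searchsorted(dataset.mz_axis, c - half, side="left")
        hi = np.searchsorted(dataset.mz_axis, c + half, side="right")
        if hi <= lo:
            warnings.warn(f"integration window around m/z {c:.3f} contains "
                          "no channel; feature set to 0", stacklevel=2)
            continue
        matrix[:, j] = dataset.intensities[:, lo:hi].sum(axis=1)
    return ReducedDataset(
        pixels=dataset.pixels.copy(),
        features=[(float(c), float(window_ppm)) for c in centers],
        matrix=matrix,
        normalization="none",
        dataset_id=dataset.dataset_id,
    )


def merge_datasets(reduced: list[ReducedDataset],
                   gutter: int = 5) -> ReducedDataset:
    """Place reduced datasets side by side on one virtual grid.

    Datasets are laid out left to right with a fixed horizontal gutter of
    empty pixels between them; each pixel's provenance records its source
    dataset and the applied offset, so the merge is exactly invertible.
    All inputs must have been extracted against the same project peak list.
    """
    if not reduced:
        raise ValueError("nothing to merge")
    feats = reduced[0].features
    for d in reduced[1:]:
        if d.features != feats:
            raise ValueError("datasets were extracted against different "
                             "feature lists; re-extract with a project list")
    if len({d.normalization for d in reduced}) != 1:
        raise ValueError("mixed normalization states")

    pixels, matrix, provenance = [], [], []
    x_cursor = 0
    for d in reduced:
        off_x = x_cursor - int(d.pixels[:, 0].min())
        for (x, y), prov, row in zip(d.pixels, d.provenance, d.matrix):
            pixels.append((int(x) + off_x, int(y)))
            provenance.append(PixelProvenance(
                prov.source_id, prov.source_xy, (off_x, 0)))
            matrix.append(row)
        x_cursor = max(p[0] for p in pixels) + 1 + gutter
    return ReducedDataset(
        pixels=np.array(pixels),
        features=list(feats),
        matrix=np.array(matrix),
        normalization=reduced[0].normalization,
        provenance=provenance,
        dataset_id="+".join(d.dataset_id for d in reduced),
    )


def unmerge_dataset(merged: ReducedDataset) -> list[ReducedDataset]:
    """Invert :func:`merge_datasets` using the recorded provenance."""
    by_source: dict[str, list[int]] = {}
    for i, prov in enumerate(merged.provenance):
        by_source.setdefault(prov.source_id, []).append(i)
    out = []
    for source_id, rows in by_source.items():
        rows = np.array(rows)
        out.append(ReducedDataset(
            pixels=np.array([merged.provenance[i].source_xy for i in rows]),
            features=list(merged.features),
            matrix=merged.matrix[rows].copy(),
            normalization=merged.normalization,
            provenance=[PixelProvenance(source_id,
                                        merged.provenance[i].source_xy)
                        for i in rows],
            dataset_id=source_id,
        ))
    return out


def reduce_project(datasets: list[MSIDataset],
                   config: ReduceConfig | None = None,
                   gutter: int = 5
                   ) -> tuple[ReducedDataset, PeakList, list[PeakList]]:
    """Full reduction of a multi-dataset project.

    Per-dataset peak lists are collated into a project list; every dataset is
    re-integrated from its raw spectra against the project list; the reduced
    datasets are merged with pixel offsets.

    Returns (merged project dataset, project peak list, per-dataset lists).
    """
    config = config or ReduceConfig()
    per_dataset = [detect_dataset_peaks(d, config) for d in datasets]
    project = collate_peaklists(per_dataset, config.collate_tolerance_ppm)
    reduced = [extract_features(d, project, config.extract_window_ppm)
               for d in datasets]
    merged = merge_datasets(reduced, gutter=gutter) if len(reduced) > 1 \
        else reduced[0]
    return merged, project, per_dataset
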