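"""Data model and I/O for imaging mass spectrometry datasets.

An imaging MS experiment rasters a MALDI ion source over a tissue section and
records one mass spectrum per pixel.  Two containers cover the pipeline:

* :class:`MSIDataset` — pixel spectra on a shared m/z axis (profile data,
  typically tens of thousands of channels).
* :class:`ReducedDataset` — the pixels x features matrix obtained after
  automated peak detection and integration, small enough for multivariate
  analysis.

Coordinates are 0-based ``(x, y)`` with ``x`` the column and ``y`` the row;
imzML's 1-based coordinates are shifted on read and restored on write.
"""

from __future__ import annotations

import dataclasses
import io
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class MSIDataset:
    """Grid of pixel spectra on a shared, strictly increasing m/z axis."""

    pixels: np.ndarray          # (n_pixels, 2) int, columns (x, y), 0-based
    mz_axis: np.ndarray         # (n_channels,) strictly increasing, Da
    intensities: np.ndarray     # (n_pixels, n_channels) non-negative
    pixel_size_um: float = 100.0
    dataset_id: str = "dataset"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=int)
        self.mz_axis = np.asarray(self.mz_axis, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.shape[1] != 2:
            raise ValueError("pixels must be an (n, 2) array of (x, y)")
        if len({tuple(p) for p in self.pixels}) != len(self.pixels):
            raise ValueError("pixel coordinates must be unique")
        if self.intensities.shape != (len(self.pixels), len(self.mz_axis)):
            raise ValueError("intensities shape does not match pixels x mz_axis")
        if np.any(np.diff(self.mz_axis) <= 0):
            raise ValueError("mz_axis must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def n_pixels(self) -> int:
        return len(self.pixels)

    @property
    def n_channels(self) -> int:
        return len(self.mz_axis)

    def grid_shape(self) -> tuple[int, int]:
        """(n_rows, n_cols) of the bounding grid."""
        return int(self.pixels[:, 1].max()) + 1, int(self.pixels[:, 0].max()) + 1


@dataclass
class PixelProvenance:
    """Origin of one pixel in a (possibly merged) reduced dataset."""

    source_id: str
    source_xy: tuple[int, int]
    offset_xy: tuple[int, int] = (0, 0)

    def to_record(self) -> dict:
        return {
            "source_id": self.source_id,
            "source_xy": list(self.source_xy),
            "offset_xy": list(self.offset_xy),
        }

    @classmethod
    def from_record(cls, rec: dict) -> "PixelProvenance":
        return cls(rec["source_id"], tuple(rec["source_xy"]),
                   tuple(rec.get("offset_xy", (0, 0))))


@dataclass
class ReducedDataset:
    """Pixels x extracted-features matrix with provenance.

    ``features`` is a list of ``(mz_center, window_ppm)`` pairs describing the
    integration window used for each column.
    """

    pixels: np.ndarray                   # (n_pixels, 2) int (x, y)
    features: list[tuple[float, float]]  # (mz_center Da, window_ppm)
    matrix: np.ndarray                   # (n_pixels, n_features) >= 0
    normalization: str = "none"          # {"none", "tic"}
    provenance: list[PixelProvenance] | None = None
    dataset_id: str = "reduced"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=int)
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.features = [(float(m), float(w)) for m, w in self.features]
        if self.provenance is None:
            self.provenance = [
                PixelProvenance(self.dataset_id, (int(x), int(y)))
                for x, y in self.pixels
            ]
        centers = np.array([m for m, _ in self.features])
        if len(centers) and np.any(np.diff(centers) <= 0):
            raise ValueError("feature centers must be strictly increasing")
        if self.matrix.shape != (len(self.pixels), len(self.features)):
            raise ValueError("matrix shape does not match pixels x features")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("matrix must be finite")
        if self.normalization not in ("none", "tic"):
            raise ValueError("normalization must be 'none' or 'tic'")
        if len(self.provenance) != len(self.pixels):
            raise ValueError("provenance length must match pixel count")
        if self.normalization == "tic":
            sums = self.matrix.sum(axis=1)
            bad = np.abs(sums[sums > 0] - 1.0) > 1e-9
            if np.any(bad):
                raise ValueError("tic-normalized rows must sum to 1")

    @property
    def n_pixels(self) -> int:
        return len(self.pixels)

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def feature_mz(self) -> np.ndarray:
        return np.array([m for m, _ in self.features])

    def grid_shape(self) -> tuple[int, int]:
        return int(self.pixels[:, 1].max()) + 1, int(self.pixels[:, 0].max()) + 1


@dataclass
class ROIMask:
    """Binary region-of-interest over a dataset's pixel grid."""

    dataset_id: str
    pixels: np.ndarray  # (n, 2) int (x, y) of positive pixels
    label: str = "roi"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=int)
        if self.pixels.ndim != 2 or self.pixels.shape[1] != 2:
            raise ValueError("mask pixels must be an (n, 2) array")
        if len(self.pixels) == 0:
            raise ValueError("mask must contain at least one positive pixel")

    def indices_in(self, dataset) -> np.ndarray:
        """Row indices of the dataset's pixels covered by this mask."""
        ours = {tuple(p) for p in self.pixels}
        idx = [i for i, p in enumerate(dataset.pixels) if tuple(p) in ours]
        if len(idx) != len(ours):
            raise ValueError(
                f"mask '{self.label}' covers pixels absent from the dataset")
        return np.array(idx, dtype=int)


# ---------------------------------------------------------------------------
# imzML I/O
# ---------------------------------------------------------------------------

def read_imzml(path: str | Path) -> MSIDataset:
    """Read a continuous- or processed-mode imzML file.

    Processed-mode spectra (per-pixel m/z axes) are resampled onto the union
    of all axes by linear interpolation; outside a spectrum's own axis the
    intensity is taken as zero.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    path = Path(path)
    try:
        parser = ImzMLParser(str(path))
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise FormatError(f"malformed imzML file {path.name}: {exc}") from exc

    n = len(parser.coordinates)
    if n == 0:
        raise FormatError(f"imzML file {path.name} contains no spectra")

    pixels = np.array([(c[0] - 1, c[1] - 1) for c in parser.coordinates])
    spectra = [parser.getspectrum(i) for i in range(n)]
    axes = [np.asarray(mz, dtype=float) for mz, _ in spectra]

    same_axis = all(len(a) == len(axes[0]) and np.array_equal(a, axes[0])
                    for a in axes[1:])
    if same_axis:
        mz_axis = axes[0]
        inten = np.array([np.asarray(i, dtype=float) for _, i in spectra])
    else:
        mz_axis = np.unique(np.concatenate(axes))
        inten = np.zeros((n, len(mz_axis)))
        for row, (mz, ii) in enumerate(spectra):
            inten[row] = np.interp(mz_axis, np.asarray(mz, float),
                                   np.asarray(ii, float), left=0.0, right=0.0)

    pix_size = float(parser.imzmldict.get("pixel size x", 100.0) or 100.0)
    return MSIDataset(pixels=pixels, mz_axis=mz_axis,
                      intensities=np.clip(inten, 0.0, None),
                      pixel_size_um=pix_size, dataset_id=path.stem)


def write_imzml(dataset: MSIDataset, path: str | Path) -> None:
    """Write a dataset as continuous-mode imzML (restores 1-based coords)."""
    from pyimzml.ImzMLWriter import ImzMLWriter

    with ImzMLWriter(str(path), mode="continuous") as writer:
        for (x, y), spec in zip(dataset.pixels, dataset.intensities):
            writer.addSpectrum(dataset.mz_axis, spec,
                               (int(x) + 1, int(y) + 1, 1))


# ---------------------------------------------------------------------------
# Reduced-dataset TSV dialect
# ---------------------------------------------------------------------------
#
# Plain tab-separated text:  '#'-prefixed metadata lines, a header row, then
# one row per pixel:  x  y  source_id  src_x  src_y  off_x  off_y  <features>.

def write_reduced(dataset: ReducedDataset, path: str | Path) -> None:
    path = Path(path)
    meta = {
        "dataset_id": dataset.dataset_id,
        "normalization": dataset.normalization,
        "features": [[m, w] for m, w in dataset.features],
    }
    cols = ["x", "y", "source_id", "src_x", "src_y", "off_x", "off_y"]
    cols += [f"{m:.6f}" for m, _ in dataset.features]
    with open(path, "w") as fh:
        fh.write("# msiagree reduced dataset v1\n")
        fh.write("# meta: " + json.dumps(meta) + "\n")
        fh.write("\t".join(cols) + "\n")
        for (x, y), prov, row in zip(dataset.pixels, dataset.provenance,
                                     dataset.matrix):
            fields = [str(int(x)), str(int(y)), prov.source_id,
                      str(prov.source_xy[0]), str(prov.source_xy[1]),
                      str(prov.offset_xy[0]), str(prov.offset_xy[1])]
            fields += [repr(float(v)) for v in row]
            fh.write("\t".join(fields) + "\n")


def read_reduced(path: str | Path) -> ReducedDataset:
    path = Path(path)
    meta = None
    with open(path) as fh:
        text = fh.read()
    body_lines = []
    for line in text.splitlines():
        if line.startswith("# meta:"):
            meta = json.loads(line[len("# meta:"):])
        elif not line.startswith("#"):
            body_lines.append(line)
    if meta is None:
        raise FormatError(f"{path.name}: missing '# meta:' header")
    df = pd.read_csv(io.StringIO("\n".join(body_lines)), sep="\t",
                     float_precision="round_trip")
    for col in ("x", "y", "source_id", "src_x", "src_y", "off_x", "off_y"):
        if col not in df.columns:
            raise FormatError(f"{path.name}: missing column '{col}'")
    features = [(float(m), float(w)) for m, w in meta["features"]]
    if len(df.columns) != 7 + len(features):
        raise FormatError(
            f"{path.name}: {len(df.columns) - 7} feature columns but "
            f"{len(features)} features declared in header")
    matrix = df.iloc[:, 7:].to_numpy(dtype=float)
    provenance = [
        PixelProvenance(str(r.source_id), (int(r.src_x), int(r.src_y)),
                        (int(r.off_x), int(r.off_y)))
        for r in df.itertuples()
    ]
    return ReducedDataset(
        pixels=df[["x", "y"]].to_numpy(dtype=int),
        features=features,
        matrix=matrix,
        normalization=meta.get("normalization", "none"),
        provenance=provenance,
        dataset_id=meta.get("dataset_id", path.stem),
    )


# ---------------------------------------------------------------------------
# Masks and image export
# ---------------------------------------------------------------------------

def read_roi_csv(path: str | Path, dataset_id: str = "",
                 label: str | None = None) -> ROIMask:
    """Read a mask as a CSV/TSV of positive-pixel (x, y) coordinates."""
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    if not {"x", "y"}.issubset(df.columns):
        raise FormatError(f"{path.name}: ROI file needs 'x' and 'y' columns")
    return ROIMask(dataset_id=dataset_id,
                   pixels=df[["x", "y"]].to_numpy(dtype=int),
                   label=label or path.stem)


def write_roi_csv(mask: ROIMask, path: str | Path) -> None:
    pd.DataFrame(mask.pixels, columns=["x", "y"]).to_csv(path, index=False)


def image_to_grid(values: np.ndarray, pixels: np.ndarray) -> np.ndarray:
    """Render a per-pixel vector onto its grid; off-tissue pixels are NaN."""
    values = np.asarray(values, dtype=float)
    nrow = int(pixels[:, 1].max()) + 1
    ncol = int(pixels[:, 0].max()) + 1
    grid = np.full((nrow, ncol), np.nan)
    grid[pixels[:, 1], pixels[:, 0]] = values
    return grid


def write_image_csv(values: np.ndarray, pixels: np.ndarray,
                    path: str | Path) -> None:
    np.savetxt(path, image_to_grid(values, pixels), delimiter=",", fmt="%.9g")


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def tic_normalize(dataset: ReducedDataset) -> tuple[ReducedDataset, list[int]]:
    """Divide every pixel row by its total ion count.

    Rows whose TIC is zero are left as zeros and their indices returned so the
    caller can report them; pixel geometry is never altered.

    Returns
    -------
    (normalized dataset, list of zero-TIC row indices)
    """
    if dataset.normalization == "tic":
        raise ValueError("dataset is already TIC-normalized")
    sums = dataset.matrix.sum(axis=1)
    zero_rows = np.flatnonzero(sums == 0)
    safe = np.where(sums == 0, 1.0, sums)
    matrix = dataset.matrix / safe[:, None]
    out = ReducedDataset(
        pixels=dataset.pixels.copy(),
        features=list(dataset.features),
        matrix=matrix,
        normalization="tic",
        provenance=list(dataset.provenance),
        dataset_id=dataset.dataset_id,
    )
    if len(zero_rows):
        warnings.warn(f"{len(zero_rows)} pixel(s) had zero TIC and were left "
                      "as zero vectors", stacklevel=2)
    return out, list(map(int, zero_rows))
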