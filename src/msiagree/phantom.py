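"""Synthetic imaging MS phantoms with ground truth.

The generator emulates linear-TOF MALDI datasets of heterogeneous tumor
tissue: a rectangular tissue grid carrying a panel of ubiquitous
peptide/protein peaks, plus elliptical *nodules* each expressing its own
differential peak panel — the nodular intratumor structure the agreement
analysis is designed to recover.  Peaks live in m/z 2,000–25,000.

Two output levels:

* :func:`generate_profile_phantom` — full profile spectra (Gaussian peaks +
  exponential chemical baseline + noise), for exercising preprocessing and
  peak picking;
* :func:`generate_reduced_phantom` — the reduced pixels x features matrix
  directly, for fast multivariate/agreement tests.

Both return a :class:`PhantomTruth` with the planted region masks and peak
panels, and are bit-reproducible from their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .msidata import MSIDataset, ReducedDataset, ROIMask

MZ_MIN, MZ_MAX = 2000.0, 25000.0


@dataclass
class EllipseRegion:
    cx: float
    cy: float
    rx: float
    ry: float

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        ny, nx = shape
        y, x = np.mgrid[0:ny, 0:nx]
        return (((x - self.cx) / self.rx) ** 2
                + ((y - self.cy) / self.ry) ** 2) <= 1.0


@dataclass
class PhantomSpec:
    """Study conditions for one synthetic dataset.

    ``shared_panel`` peaks appear in every tissue pixel; the i-th
    ``region_panels`` entry appears only inside the i-th region.  Peaks are
    (mz_center, mean_intensity, width_ppm) triples.  Noise is i.i.d.
    Gaussian (clipped at zero); each pixel additionally carries a lognormal
    total-ion-count factor emulating shot-to-shot MALDI yield drift.
    """

    grid_shape: tuple[int, int] = (48, 64)          # (rows, cols)
    regions: list[EllipseRegion] = field(default_factory=list)
    shared_panel: list[tuple[float, float, float]] = field(default_factory=list)
    region_panels: list[list[tuple[float, float, float]]] = field(
        default_factory=list)
    baseline_amplitude: float = 0.0
    baseline_decay: float = 3000.0                  # Da
    noise_sd: float = 5.0
    tic_drift_sd: float = 0.15                      # lognormal sigma
    seed: int = 0
    n_channels: int = 4000                          # profile axis length
    dataset_id: str = "phantom"

    def __post_init__(self) -> None:
        if len(self.region_panels) != len(self.regions):
            raise ValueError("one differential panel per region required")
        for panel in [self.shared_panel] + list(self.region_panels):
            for mz, inten, width in panel:
                if not MZ_MIN <= mz <= MZ_MAX:
                    raise ValueError(f"peak m/z {mz} outside the axis "
                                     f"[{MZ_MIN}, {MZ_MAX}]")
        all_diff = [p for panel in self.region_panels for p in panel]
        for i, (m1, _, w1) in enumerate(all_diff):
            for m2, _, w2 in all_diff[i + 1:]:
                min_sep = 2e-6 * max(w1, w2) * max(m1, m2)
                if abs(m1 - m2) < min_sep:
                    raise ValueError(
                        f"differential peaks at {m1} and {m2} overlap within "
                        "2x their width; ground truth would be ambiguous")


@dataclass
class PhantomTruth:
    region_masks: list[np.ndarray]      # boolean grids, one per region
    tissue_mask: np.ndarray
    peak_panel: list[dict]              # rows: mz, intensity, width, region
    expected_profiles: np.ndarray | None = None  # (n_regions+1, F), reduced

    def region_roi(self, i: int, dataset_id: str = "phantom") -> ROIMask:
        ys, xs = np.nonzero(self.region_masks[i])
        return ROIMask(dataset_id=dataset_id,
                       pixels=np.column_stack([xs, ys]),
                       label=f"region_{i}")


def truth_target(truth: PhantomTruth, pixels: np.ndarray, region: int):
    """Ground-truth target image for one planted region.

    The planted panels define the expected target exactly: the noise-free
    algebraic sum of the region's principal peaks (its differential panel
    plus the shared panel) over the pixel grid.  This is what the supervised
    target machinery would recover from noiseless data, so it isolates
    decomposition error from phantom noise when validating components.
    """
    from .reduce import PeakList
    from .targets import TargetImage

    shared = [r for r in truth.peak_panel if r["region"] == -1]
    diff = [r for r in truth.peak_panel if r["region"] == region]
    if not diff:
        raise ValueError(f"no planted panel for region {region}")
    shared_sum = sum(r["intensity"] for r in shared)
    diff_sum = sum(r["intensity"] for r in diff)
    mask = truth.region_masks[region]
    inside = mask[pixels[:, 1], pixels[:, 0]].astype(float)
    image = shared_sum + diff_sum * inside
    rows = sorted(shared + diff, key=lambda r: r["mz"])
    return TargetImage(
        label=f"region_{region}",
        image=image,
        spectrum=PeakList(entries=[(r["mz"], r["intensity"],
                                    f"region_{region}") for r in rows],
                          dataset_id=f"region_{region}"),
        feature_mz=np.array([r["mz"] for r in rows]),
        feature_profile=np.array([r["intensity"] for r in rows]),
    )


def default_nodule_spec(seed: int, n_features: int = 100,
                        n_regions: int = 3,
                        grid_shape: tuple[int, int] = (48, 64),
                        differential_intensity: float = 80.0,
                        shared_intensity: float = 40.0,
                        noise_sd: float = 5.0) -> PhantomSpec:
    """Three-nodule study phantom: ~3,000 pixels, ~100 features.

    Shared panel of 12 peaks at mean intensity 40; per-nodule differential
    panels of 6 peaks each at mean intensity 80; noise sd 5 (differential
    peak S/N 16).  Peak positions are drawn from the seed on a fixed m/z
    lattice so panels never collide.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed % 2**31, 5]))
    ny, nx = grid_shape
    # fixed, well-separated nodules (about 8-10% of the grid each)
    regions = [
        EllipseRegion(nx * 0.22, ny * 0.28, nx * 0.13, ny * 0.16),
        EllipseRegion(nx * 0.70, ny * 0.25, nx * 0.15, ny * 0.14),
        EllipseRegion(nx * 0.48, ny * 0.72, nx * 0.16, ny * 0.15),
    ][:n_regions]

    n_diff = 6 * n_regions
    n_shared = 12
    lattice = np.linspace(MZ_MIN + 300, MZ_MAX - 300, n_features)
    picks = rng.choice(n_features, size=n_diff + n_shared, replace=False)
    jitter = rng.uniform(-20, 20, size=picks.shape)
    centers = np.sort(lattice[picks] + jitter)
    order = rng.permutation(n_diff + n_shared)
    shared_panel = [(float(centers[j]),
                     float(shared_intensity * rng.uniform(0.7, 1.3)), 500.0)
                    for j in order[:n_shared]]
    region_panels = []
    for r in range(n_regions):
        sl = order[n_shared + 6 * r: n_shared + 6 * (r + 1)]
        region_panels.append([
            (float(centers[j]),
             float(differential_intensity * rng.uniform(0.7, 1.3)), 500.0)
            for j in sl])
    return PhantomSpec(grid_shape=grid_shape, regions=regions,
                       shared_panel=shared_panel,
                       region_panels=region_panels,
                       noise_sd=noise_sd, seed=seed,
                       dataset_id=f"phantom_{seed}")


def _truth(spec: PhantomSpec) -> tuple[list[np.ndarray], np.ndarray]:
    masks = [r.mask(spec.grid_shape) for r in spec.regions]
    tissue = np.ones(spec.grid_shape, dtype=bool)
    return masks, tissue


def _panel_table(spec: PhantomSpec) -> list[dict]:
    rows = [{"mz": mz, "intensity": a, "width_ppm": w, "region": -1}
            for mz, a, w in spec.shared_panel]
    for i, panel in enumerate(spec.region_panels):
        rows += [{"mz": mz, "intensity": a, "width_ppm": w, "region": i}
                 for mz, a, w in panel]
    return sorted(rows, key=lambda r: r["mz"])


def generate_profile_phantom(spec: PhantomSpec
                             ) -> tuple[MSIDataset, PhantomTruth]:
    """Full profile spectra on a uniform m/z axis.

    Per pixel: sum of Gaussian peaks (shared panel everywhere, differential
    panel inside its region) + exponential baseline + i.i.d. Gaussian noise,
    clipped at zero, then scaled by a lognormal per-pixel TIC factor.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([spec.seed % 2**31, 7]))
    masks, tissue = _truth(spec)
    ny, nx = spec.grid_shape
    axis = np.linspace(MZ_MIN, MZ_MAX, spec.n_channels)

    def peak_shape(mz: float, amp: float, width_ppm: float) -> np.ndarray:
        sigma = width_ppm * 1e-6 * mz / 2.355  # FWHM in ppm of the center
        return amp * np.exp(-0.5 * ((axis - mz) / sigma) ** 2)

    shared = sum((peak_shape(*p) for p in spec.shared_panel),
                 np.zeros_like(axis))
    region_specs = [sum((peak_shape(*p) for p in panel),
                        np.zeros_like(axis))
                    for panel in spec.region_panels]
    baseline = spec.baseline_amplitude * np.exp(
        -(axis - MZ_MIN) / spec.baseline_decay)

    ys, xs = np.nonzero(tissue)
    pixels = np.column_stack([xs, ys])
    inten = np.empty((len(pixels), spec.n_channels))
    tic = np.exp(rng.normal(0.0, spec.tic_drift_sd, size=len(pixels))) \
        if spec.tic_drift_sd > 0 else np.ones(len(pixels))
    for row, (x, y) in enumerate(pixels):
        clean = shared + baseline
        for m, rs in zip(masks, region_specs):
            if m[y, x]:
                clean = clean + rs
        noisy = clean + rng.normal(0.0, spec.noise_sd, size=spec.n_channels) \
            if spec.noise_sd > 0 else clean
        inten[row] = np.clip(noisy, 0.0, None) * tic[row]

    dataset = MSIDataset(pixels=pixels, mz_axis=axis, intensities=inten,
                         dataset_id=spec.dataset_id)
    truth = PhantomTruth(region_masks=masks, tissue_mask=tissue,
                         peak_panel=_panel_table(spec))
    return dataset, truth


def generate_reduced_phantom(spec: PhantomSpec, n_features: int = 100
                             ) -> tuple[ReducedDataset, PhantomTruth]:
    """Reduced pixels x features matrix, skipping the profile stage.

    Feature centers are the union of the panel m/z values and noise-only
    filler features on a uniform lattice, ``n_features`` in total.  Region
    and noise semantics match the profile generator.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([spec.seed % 2**31, 9]))
    masks, tissue = _truth(spec)

    panel = _panel_table(spec)
    panel_mz = [row["mz"] for row in panel]
    n_filler = max(0, n_features - len(panel_mz))
    if n_filler:
        # oversample the lattice, keep candidates clear of panel positions
        cand = np.linspace(MZ_MIN + 100, MZ_MAX - 100, 3 * n_filler + 2)[1:-1]
        cand = cand[[np.all(np.abs(np.array(panel_mz) - f) > 50.0)
                     for f in cand]]
        filler = cand[np.linspace(0, len(cand) - 1, n_filler).astype(int)] \
            if len(cand) >= n_filler else cand
    else:
        filler = np.array([])
    centers = np.sort(np.concatenate([panel_mz, filler]))
    col = {mz: int(np.searchsorted(centers, mz)) for mz in panel_mz}

    F = len(centers)
    base_profile = np.zeros(F)
    for row in panel:
        if row["region"] == -1:
            base_profile[col[row["mz"]]] += row["intensity"]
    region_profiles = []
    for i in range(len(spec.regions)):
        prof = base_profile.copy()
        for row in panel:
            if row["region"] == i:
                prof[col[row["mz"]]] += row["intensity"]
        region_profiles.append(prof)

    ys, xs = np.nonzero(tissue)
    pixels = np.column_stack([xs, ys])
    clean = np.tile(base_profile, (len(pixels), 1))
    for i, m in enumerate(masks):
        inside = m[pixels[:, 1], pixels[:, 0]]
        clean[inside] = region_profiles[i]
    noisy = clean + rng.normal(0.0, spec.noise_sd, size=clean.shape) \
        if spec.noise_sd > 0 else clean
    tic = np.exp(rng.normal(0.0, spec.tic_drift_sd, size=len(pixels))) \
        if spec.tic_drift_sd > 0 else np.ones(len(pixels))
    matrix = np.clip(noisy, 0.0, None) * tic[:, None]

    reduced = ReducedDataset(
        pixels=pixels,
        features=[(float(c), 500.0) for c in centers],
        matrix=matrix,
        normalization="none",
        dataset_id=spec.dataset_id,
    )
    truth = PhantomTruth(
        region_masks=masks, tissue_mask=tissue, peak_panel=panel,
        expected_profiles=np.vstack([base_profile] + region_profiles))
    return reduced, truth
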