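"""Dataload and floating-point-operation accounting.

Why data reduction matters in practice: a raw linear-TOF imaging MS pixel
spectrum occupies ~400 kB, so a modest tissue runs to gigabytes, and the
classic PCA operation count

    flops = 14 * k * N**2 + 8 * N**3

(k pixels, N channels) reaches the petaflop scale at raw dimensionality but
only tens of gigaflops after reduction to a few hundred features.  The MB
convention here is binary (1 MB = 1024 kB = 1024**2 bytes); the decimal
convention does not reproduce the standard figures.
"""

from __future__ import annotations

from dataclasses import dataclass

BYTES_PER_VARIABLE = 8
KB_PER_SPECTRUM = 400
KB = 1024
MB = 1024 * KB


def pca_flops(k: int, N: int) -> float:
    """Floating-point operations of the reference PCA algorithm."""
    if k < 0 or N < 0:
        raise ValueError("k and N must be non-negative")
    return 14.0 * k * N ** 2 + 8.0 * N ** 3


def dataload(k: int, N: int | None = None, raw: bool = False) -> float:
    """Dataset size in (binary) megabytes.

    Raw data is costed at 400 kB per spectrum regardless of N; reduced data
    at 8 bytes per matrix entry (k pixels x N features).
    """
    if k < 0 or (N is not None and N < 0):
        raise ValueError("k and N must be non-negative")
    if raw:
        return k * KB_PER_SPECTRUM * KB / MB
    if N is None:
        raise ValueError("reduced dataload requires the feature count N")
    return k * N * BYTES_PER_VARIABLE / MB


@dataclass
class ResourceEstimate:
    k: int
    N: int
    raw_channels: int | None = None

    @property
    def dataload_mb(self) -> float:
        return dataload(self.k, self.N)

    @property
    def raw_dataload_mb(self) -> float:
        return dataload(self.k, raw=True)

    @property
    def flops(self) -> float:
        return pca_flops(self.k, self.N)

    @property
    def raw_flops(self) -> float | None:
        if self.raw_channels is None:
            return None
        return pca_flops(self.k, self.raw_channels)

    def summary(self) -> str:
        lines = [
            f"pixels (k)            : {self.k}",
            f"features (N)          : {self.N}",
            f"reduced dataload (MB) : {self.dataload_mb:.1f}",
            f"raw dataload (MB)     : {self.raw_dataload_mb:.1f}",
            f"reduced PCA FLOPs     : {self.flops:.2g}",
        ]
        if self.raw_flops is not None:
            lines.append(f"raw PCA FLOPs         : {self.raw_flops:.2g}")
        return "\n".join(lines)


def round_sig(value: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (for table-style reporting)."""
    if value == 0:
        return 0.0
    from math import floor, log10
    return round(value, -int(floor(log10(abs(value)))) + (sig - 1))
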