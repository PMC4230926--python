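"""Kernel-density clustering of VAFs and purity estimation.

Mutations from copy-number-neutral regions cluster at VAFs reflecting the
cellular prevalence of the clone carrying them: a heterozygous mutation
present in every tumor cell of a specimen of purity ``rho`` sits near
``50 * rho`` percent.  A Gaussian KDE of the VAF distribution therefore shows
one peak per clonal population; the highest-VAF significant peak is the
founding clone and purity is estimated as twice its position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, peak_prominences

GRID_SIZE = 512
DEFAULT_MIN_PROMINENCE_FRAC = 0.10
DEFAULT_MIN_SEPARATION = 5.0


@dataclass
class DensityCurve:
    """Gaussian KDE of VAFs on a fixed grid over [0, 100] percent."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(self.density < 0):
            raise ValueError("density must be nonnegative")


@dataclass
class ClonalArchitecture:
    """Clusters, founding clone and purity for one tumor specimen."""

    peak_vafs: list[float]  # descending by VAF
    cluster_members: list[list[int]]  # indices into the input VAF list
    founding_index: int
    purity: float
    curve: DensityCurve | None = field(default=None, repr=False)

    @property
    def n_subclones(self) -> int:
        return len(self.peak_vafs) - 1

    @property
    def founding_peak_vaf(self) -> float:
        return self.peak_vafs[self.founding_index]


def nrd0_bandwidth(vafs: np.ndarray) -> float:
    """Silverman's rule-of-thumb bandwidth: 0.9 min(sd, IQR/1.34) n^(-1/5).

    Falls back through IQR -> sd -> |x| -> 1 when spread estimates vanish,
    mirroring the conventional nrd0 behavior for degenerate samples.
    """
    n = len(vafs)
    sd = float(np.std(vafs, ddof=1))
    q75, q25 = np.percentile(vafs, [75, 25])
    iqr = float(q75 - q25)
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        spread = max(abs(float(vafs[0])), 1.0)
    return 0.9 * spread * n ** (-0.2)


def kde(vafs, bandwidth: float | str = "auto") -> DensityCurve:
    """Gaussian kernel density of VAF percents on a 512-point [0,100] grid.

    The curve is renormalized to integrate to 1 over the grid (kernel mass
    leaking outside [0, 100] near the boundaries is folded back by the
    normalization; peak positions are unaffected).
    """
    vafs = np.asarray(vafs, dtype=float)
    if vafs.size < 2:
        raise ValueError("kde requires at least 2 VAF values")
    h = nrd0_bandwidth(vafs) if bandwidth == "auto" else float(bandwidth)
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    grid = np.linspace(0.0, 100.0, GRID_SIZE)
    z = (grid[:, None] - vafs[None, :]) / h
    density = np.exp(-0.5 * z * z).sum(axis=1) / (vafs.size * h * np.sqrt(2 * np.pi))
    area = np.trapezoid(density, grid)
    return DensityCurve(grid=grid, density=density / area, bandwidth=h)


def find_significant_peaks(
    curve: DensityCurve,
    min_prominence_frac: float = DEFAULT_MIN_PROMINENCE_FRAC,
    min_separation: float = DEFAULT_MIN_SEPARATION,
) -> list[float]:
    """Significant local maxima of the density, descending by VAF.

    A peak is significant when its topographic prominence is at least
    ``min_prominence_frac`` of the global density maximum; peaks closer than
    ``min_separation`` VAF points are merged, keeping the denser one.  A flat
    or monotone curve yields the single global maximum.
    """
    d = curve.density
    idx, _ = find_peaks(d)
    # interior maxima only; fall back to the global max if none found
    if idx.size == 0:
        return [float(curve.grid[int(np.argmax(d))])]
    prominences = peak_prominences(d, idx)[0]
    threshold = min_prominence_frac * float(d.max())
    idx = idx[prominences >= threshold]
    if idx.size == 0:
        return [float(curve.grid[int(np.argmax(d))])]

    # merge close peaks, keeping the denser; scan in density order
    kept: list[int] = []
    for i in sorted(idx, key=lambda i: -d[i]):
        if all(abs(curve.grid[i] - curve.grid[j]) >= min_separation for j in kept):
            kept.append(i)
    return [float(curve.grid[i]) for i in sorted(kept, key=lambda i: -curve.grid[i])]


def assign_clusters(vafs, peaks: list[float], curve: DensityCurve | None = None) -> list[list[int]]:
    """Assign each VAF to a peak using density valleys as cluster boundaries.

    Boundaries between adjacent peaks are the density minima of ``curve``
    (midpoints when no curve is given); a VAF landing exactly on a valley
    goes to the higher-VAF cluster.  Returns member-index lists ordered like
    ``peaks`` (descending VAF).
    """
    if not peaks:
        raise ValueError("need at least one peak")
    vafs = np.asarray(vafs, dtype=float)
    order = np.argsort(peaks)  # ascending
    asc_peaks = [peaks[i] for i in order]
    boundaries = []
    for lo, hi in zip(asc_peaks, asc_peaks[1:]):
        if curve is not None:
            mask = (curve.grid > lo) & (curve.grid < hi)
            if mask.any():
                seg = np.where(mask)[0]
                boundaries.append(float(curve.grid[seg[np.argmin(curve.density[seg])]]))
                continue
        boundaries.append((lo + hi) / 2.0)
    asc_members: list[list[int]] = [[] for _ in asc_peaks]
    for i, v in enumerate(vafs):
        k = int(np.searchsorted(boundaries, v, side="right"))  # valley ties go up
        asc_members[k].append(i)
    members = [[] for _ in peaks]
    for asc_rank, orig_idx in enumerate(order):
        members[orig_idx] = asc_members[asc_rank]
    return members


def estimate_purity(founding_peak_vaf: float) -> float:
    """Tumor purity (percent) = 2 x founding-clone VAF, capped at 100.

    Valid for heterozygous mutations in copy-number-neutral regions: every
    tumor cell carries the founding mutations on one of two alleles, so the
    cell fraction is twice the allele fraction.  Reported to 1 decimal.
    """
    if founding_peak_vaf <= 0:
        raise ValueError("founding peak VAF must be positive")
    return round(min(2.0 * founding_peak_vaf, 100.0), 1)


def correct_vaf(vaf: float, purity: float) -> float:
    """Rescale a VAF (percent) to what it would be in a 100%-pure specimen."""
    if not 0 < purity <= 100:
        raise ValueError("purity must be in (0, 100]")
    return min(100.0 * vaf / purity, 100.0)


def infer_architecture(
    vafs,
    bandwidth: float | str = "auto",
    min_prominence_frac: float = DEFAULT_MIN_PROMINENCE_FRAC,
    min_separation: float = DEFAULT_MIN_SEPARATION,
) -> ClonalArchitecture:
    """End-to-end clustering: KDE -> peaks -> assignment -> purity.

    The founding clone is the highest-VAF significant cluster even when a
    subclone holds more mutations.
    """
    curve = kde(vafs, bandwidth)
    peaks = find_significant_peaks(curve, min_prominence_frac, min_separation)
    members = assign_clusters(vafs, peaks, curve)
    return ClonalArchitecture(
        peak_vafs=peaks,
        cluster_members=members,
        founding_index=0,  # peaks are descending by VAF
        purity=estimate_purity(peaks[0]),
        curve=curve,
    )
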