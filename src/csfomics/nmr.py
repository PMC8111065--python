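"""1D 1H-NMR spectral binning and internal-standard quantification.

A processed CSF spectrum (phased, baseline-corrected upstream) is reduced
to a feature vector by integrating fixed-width chemical-shift buckets
(0.02 ppm by default) between 0.83 and 8.47 ppm, dropping every bucket
that overlaps the residual-water region (4.13-5.22 ppm).  Metabolite
integrals are converted to absolute concentrations against a 1 mM maleic
acid internal standard (a two-proton singlet), and NMR-derived
concentrations can be compared with an independent assay through Pearson
correlation and Bland-Altman limits of agreement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CoverageError, DomainError

#: chemical shift of the maleic acid reference singlet (ppm)
MALEIC_ACID_PPM = 6.01
#: protons contributing to the maleic acid singlet
MALEIC_ACID_PROTONS = 2

WATER_REGION = (4.13, 5.22)

# overlap smaller than this (in ppm) is treated as touching, not overlapping,
# so a bin edge that lands exactly on the exclusion boundary is retained
_EDGE_TOL = 1e-9


@dataclass
class Spectrum:
    """A 1D spectrum on a strictly monotone ppm axis.

    Stored internally with the axis ascending; CSV export follows the
    field convention of a descending ppm axis.
    """

    ppm: np.ndarray
    intensity: np.ndarray
    ref_ppm: float = MALEIC_ACID_PPM
    ref_conc: float = 1.0  # mM
    ref_protons: int = MALEIC_ACID_PROTONS

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.shape != self.intensity.shape or self.ppm.ndim != 1:
            raise DomainError("ppm and intensity must be 1D arrays of equal length")
        if not (np.isfinite(self.ppm).all() and np.isfinite(self.intensity).all()):
            raise DomainError("spectrum contains non-finite values")
        d = np.diff(self.ppm)
        if (d > 0).all():
            pass
        elif (d < 0).all():
            self.ppm = self.ppm[::-1].copy()
            self.intensity = self.intensity[::-1].copy()
        else:
            raise DomainError("ppm axis must be strictly monotone")
        if self.ref_conc <= 0:
            raise DomainError("reference concentration must be positive")

    def integral(self, lo: float, hi: float) -> float:
        """Trapezoid integral of intensity over [lo, hi] ppm.

        The endpoints are linearly interpolated onto the native grid, so
        adjacent windows tile exactly (no double counting or gaps).
        """
        if lo > hi:
            lo, hi = hi, lo
        lo = max(lo, float(self.ppm[0]))
        hi = min(hi, float(self.ppm[-1]))
        if hi <= lo:
            return 0.0
        mask = (self.ppm > lo) & (self.ppm < hi)
        xs = np.concatenate(([lo], self.ppm[mask], [hi]))
        ys = np.concatenate(
            (
                [np.interp(lo, self.ppm, self.intensity)],
                self.intensity[mask],
                [np.interp(hi, self.ppm, self.intensity)],
            )
        )
        return float(np.trapezoid(ys, xs))

    def to_csv(self, path) -> None:
        df = pd.DataFrame({"ppm": self.ppm[::-1], "intensity": self.intensity[::-1]})
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "Spectrum":
        df = pd.read_csv(path)
        return cls(ppm=df.iloc[:, 0].to_numpy(), intensity=df.iloc[:, 1].to_numpy(), **kwargs)


@dataclass
class BinnedSpectrum:
    """Fixed-width buckets with trapezoid integrals, water region removed."""

    bin_edges: np.ndarray  # (n_bins, 2), retained bins only, ascending
    integrals: np.ndarray
    excluded_region: tuple[float, float] = WATER_REGION
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.integrals = np.asarray(self.integrals, dtype=float)

    @property
    def bin_centers(self) -> np.ndarray:
        return self.bin_edges.mean(axis=1)

    def feature_ids(self) -> list[str]:
        return [f"bin_{c:.2f}" for c in self.bin_centers]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_center": self.bin_centers,
                "edge_lo": self.bin_edges[:, 0],
                "edge_hi": self.bin_edges[:, 1],
                "integral": self.integrals,
            }
        )


def bin_spectrum(
    s: Spectrum,
    lo: float = 0.83,
    hi: float = 8.47,
    width: float = 0.02,
    exclude: tuple[float, float] = WATER_REGION,
    normalize: bool = False,
) -> BinnedSpectrum:
    """Bucket a spectrum into fixed-width bins over [lo, hi).

    Bins tile the range left-closed/right-open starting at ``lo``.  Any
    bin with nonzero overlap of the exclusion interval is dropped.  With
    ``normalize=True`` the retained integrals are divided by their total
    (total-area normalization, off by default).
    """
    if not lo < hi:
        raise DomainError("lo must be < hi")
    if width <= 0:
        raise DomainError("bin width must be positive")
    if s.ppm[0] > lo + _EDGE_TOL or s.ppm[-1] < hi - _EDGE_TOL:
        raise CoverageError(
            f"spectrum covers [{s.ppm[0]:.3f}, {s.ppm[-1]:.3f}] ppm, "
            f"binning requires [{lo}, {hi}]"
        )
    n_bins = int(np.floor((hi - lo) / width + _EDGE_TOL))
    ex_lo, ex_hi = min(exclude), max(exclude)

    edges, integrals = [], []
    n_dropped = 0
    for i in range(n_bins):
        b_lo = lo + i * width
        b_hi = lo + (i + 1) * width
        overlap = min(b_hi, ex_hi) - max(b_lo, ex_lo)
        if overlap > _EDGE_TOL:
            n_dropped += 1
            continue
        edges.append((b_lo, b_hi))
        integrals.append(s.integral(b_lo, b_hi))
    integrals = np.asarray(integrals)
    if normalize:
        total = integrals.sum()
        if total == 0:
            raise DomainError("cannot total-area normalize an all-zero spectrum")
        integrals = integrals / total
    return BinnedSpectrum(
        bin_edges=np.asarray(edges),
        integrals=integrals,
        excluded_region=(ex_lo, ex_hi),
        n_dropped=n_dropped,
    )


def quantify(
    metabolite_integral: float,
    metabolite_protons: int,
    s: Spectrum,
    ref_integral: float,
) -> float:
    """Absolute concentration (mM) from the internal-standard area ratio.

    conc = (A_met / H_met) / (A_ref / H_ref) * c_ref
    """
    if metabolite_integral < 0 or ref_integral < 0:
        raise DomainError("integrals must be nonnegative")
    if metabolite_protons < 1:
        raise DomainError("proton count must be >= 1")
    if ref_integral == 0:
        raise DomainError("degenerate reference: zero internal-standard integral")
    return (metabolite_integral / metabolite_protons) / (
        ref_integral / s.ref_protons
    ) * s.ref_conc


class MethodAgreement(NamedTuple):
    pearson_r: float
    bias: float
    loa_low: float
    loa_high: float


def method_agreement(x, y) -> MethodAgreement:
    """Pearson correlation plus Bland-Altman bias and 95% limits of agreement.

    ``bias`` is mean(x - y); limits are bias +/- 1.96 * SD(x - y).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("series must be 1D and of equal length")
    if len(x) < 3:
        raise DomainError("need at least 3 paired measurements")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DomainError("correlation undefined: a series has zero variance")
    r = float(stats.pearsonr(x, y).statistic)
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return MethodAgreement(r, bias, bias - 1.96 * sd, bias + 1.96 * sd)
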