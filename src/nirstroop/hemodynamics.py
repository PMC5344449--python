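"""Modified Beer-Lambert law conversion between optical density and
chromophore concentration changes.

A continuous-wave NIRS instrument measures light intensity per channel at
several wavelengths (here 780, 805 and 830 nm).  Intensity changes relative
to baseline give optical-density changes

    dOD(lambda, t) = -log10( I(t) / I_baseline ),

and the modified Beer-Lambert law relates them linearly to concentration
changes of oxy- and deoxyhemoglobin,

    dOD(lambda, t) = [ eps_HbO(lambda) dHbO(t) + eps_HbR(lambda) dHbR(t) ] L,

with eps the molar extinction coefficients and L the effective optical
pathlength.  With three wavelengths and two chromophores the system is
overdetermined and is solved per channel and time point by least squares.
Because the differential pathlength factor of the head is unknown, L is
folded into the reported units: concentrations are relative (uM-equivalent
per unit pathlength), which is all the downstream GLM contrasts need.
Concentration values are interpreted as micromolar (the uM -> M factor is
applied inside the forward and inverse transforms), so a 1 uM change over
a unit path gives optical densities of order 1e-4.

The 805 nm wavelength sits near the hemoglobin isosbestic point, where the
HbO and HbR extinction coefficients nearly coincide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Concentration unit of HemoTimeSeries relative to the molar extinction
#: coefficients: values are micromolar.
MICROMOLAR = 1e-6

__all__ = [
    "ExtinctionTable",
    "OpticalDensityRecording",
    "HemoTimeSeries",
    "od_from_intensity",
    "mbll_invert",
    "forward_mbll",
]


@dataclass
class ExtinctionTable:
    """Molar extinction coefficients per wavelength, units 1/(M*mm).

    Defaults are interpolated from the hemoglobin compilation of S. Prahl
    (Oregon Medical Laser Center, after W. B. Gratzer and N. Kollias),
    converted from 1/(M*cm).
    """

    wavelengths: np.ndarray = field(
        default_factory=lambda: np.array([780.0, 805.0, 830.0]))
    eps_hbo: np.ndarray = field(
        default_factory=lambda: np.array([73.5, 85.8, 97.4]))
    eps_hbr: np.ndarray = field(
        default_factory=lambda: np.array([109.8, 84.0, 69.3]))

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, float)
        self.eps_hbo = np.asarray(self.eps_hbo, float)
        self.eps_hbr = np.asarray(self.eps_hbr, float)
        if not (len(self.wavelengths) == len(self.eps_hbo) == len(self.eps_hbr)):
            raise ValueError("wavelengths and coefficients must align")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")

    @property
    def matrix(self) -> np.ndarray:
        """(n_wavelengths, 2) extinction matrix, columns (HbO, HbR)."""
        return np.column_stack([self.eps_hbo, self.eps_hbr])

    def require_full_rank(self) -> None:
        if np.linalg.matrix_rank(self.matrix) < 2:
            raise ValueError("extinction matrix is rank deficient; "
                             "chromophores are not separable")

    def subset(self, wavelengths) -> "ExtinctionTable":
        """Rows for the requested wavelengths (error if any is missing)."""
        idx = []
        for wl in np.asarray(wavelengths, float):
            hits = np.where(np.isclose(self.wavelengths, wl))[0]
            if len(hits) == 0:
                raise KeyError(f"wavelength {wl} nm not in extinction table")
            idx.append(hits[0])
        return ExtinctionTable(self.wavelengths[idx], self.eps_hbo[idx],
                               self.eps_hbr[idx])


@dataclass
class OpticalDensityRecording:
    """Channel x wavelength x time optical-density changes (dimensionless)."""

    od: np.ndarray                # (n_channels, n_wavelengths, n_times)
    wavelengths: np.ndarray       # nm
    sample_period: float          # s
    baseline: slice | None = None
    bad_samples: np.ndarray | None = None  # boolean, same shape as od

    def __post_init__(self) -> None:
        self.od = np.asarray(self.od, float)
        self.wavelengths = np.asarray(self.wavelengths, float)
        if self.od.ndim != 3 or self.od.shape[1] != len(self.wavelengths):
            raise ValueError("od must be (channels, wavelengths, times)")

    @property
    def n_channels(self) -> int:
        return self.od.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.od.shape[2]) * self.sample_period


@dataclass
class HemoTimeSeries:
    """Relative chromophore concentration changes per channel.

    ``hbo`` and ``hbr`` are (n_channels, n_times) in uM-equivalent units
    (concentration times pathlength; see module docstring).
    """

    hbo: np.ndarray
    hbr: np.ndarray
    sample_period: float

    def __post_init__(self) -> None:
        self.hbo = np.asarray(self.hbo, float)
        self.hbr = np.asarray(self.hbr, float)
        if self.hbo.shape != self.hbr.shape:
            raise ValueError("hbo and hbr must share a shape")

    @property
    def n_channels(self) -> int:
        return self.hbo.shape[0]

    @property
    def n_times(self) -> int:
        return self.hbo.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_times) * self.sample_period

    def signal(self, chromophore: str) -> np.ndarray:
        if chromophore == "hbo":
            return self.hbo
        if chromophore == "hbr":
            return self.hbr
        raise KeyError("chromophore must be 'hbo' or 'hbr'")


def od_from_intensity(
    intensity: np.ndarray,
    sample_period: float,
    wavelengths,
    baseline: slice | None = None,
) -> OpticalDensityRecording:
    """Optical-density changes from raw intensities.

    dOD = -log10(I(t) / mean I over the baseline window) per channel and
    wavelength.  Nonpositive intensities cannot be log-transformed; those
    samples are set to 0 OD and flagged in ``bad_samples`` for channel QC.
    """
    I = np.asarray(intensity, float)
    if I.ndim != 3:
        raise ValueError("intensity must be (channels, wavelengths, times)")
    baseline = baseline if baseline is not None else slice(None)
    bad = ~(I > 0)
    Isafe = np.where(bad, np.nan, I)
    ref = np.nanmean(Isafe[:, :, baseline], axis=2, keepdims=True)
    if np.any(~np.isfinite(ref)) or np.any(ref <= 0):
        raise ValueError("baseline window has no positive intensities "
                         "for some channel/wavelength")
    with np.errstate(invalid="ignore", divide="ignore"):
        od = -np.log10(Isafe / ref)
    od[bad] = 0.0
    return OpticalDensityRecording(
        od=od, wavelengths=np.asarray(wavelengths, float),
        sample_period=sample_period, baseline=baseline,
        bad_samples=bad if bad.any() else None,
    )


def forward_mbll(
    hemo: HemoTimeSeries,
    ext: ExtinctionTable | None = None,
    pathlength: float = 1.0,
    wavelengths=None,
) -> OpticalDensityRecording:
    """Forward model: optical density from chromophore concentrations.

    dOD(lambda, t) = [eps_HbO(lambda) dHbO + eps_HbR(lambda) dHbR] * L per
    channel.  Used by the synthetic-data generator to produce raw-style
    recordings with known ground truth.
    """
    ext = ext if ext is not None else ExtinctionTable()
    if wavelengths is not None:
        ext = ext.subset(wavelengths)
    conc = np.stack([hemo.hbo, hemo.hbr], axis=1)      # (C, 2, T), uM
    od = np.einsum("wk,ckt->cwt", ext.matrix, conc) * pathlength * MICROMOLAR
    return OpticalDensityRecording(od=od, wavelengths=ext.wavelengths,
                                   sample_period=hemo.sample_period)


def mbll_invert(
    od: OpticalDensityRecording,
    ext: ExtinctionTable | None = None,
    pathlength: float = 1.0,
) -> HemoTimeSeries:
    """Least-squares inversion of the modified Beer-Lambert law.

    Solves dOD(lambda) = eps * dc * L for dc = (dHbO, dHbR) per channel and
    time point.  With >= 2 wavelengths and a full-rank extinction matrix
    this is the normal-equations solution; with exactly 2 it is exact.
    """
    ext = ext if ext is not None else ExtinctionTable()
    ext = ext.subset(od.wavelengths)
    if len(ext.wavelengths) < 2:
        raise ValueError("need >= 2 wavelengths to separate HbO and HbR")
    ext.require_full_rank()
    E = ext.matrix * pathlength * MICROMOLAR
    pinv = np.linalg.pinv(E)                           # (2, n_wavelengths)
    conc = np.einsum("kw,cwt->ckt", pinv, od.od)
    return HemoTimeSeries(hbo=conc[:, 0], hbr=conc[:, 1],
                          sample_period=od.sample_period)
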