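"""Radiocarbon combination and calibration.

A conventional radiocarbon determination ``age +/- sigma`` (14C yr BP) is
mapped onto the calendar scale through a calibration curve giving the
atmospheric 14C age mu(t) and its uncertainty s(t) at calendar age t
(cal BP).  Under a flat calendar prior the posterior density is

    p(t)  proportional to  exp( -(age - mu(t))^2 / (2 (sigma^2 + s(t)^2)) )

evaluated on a 1-yr interpolated grid and normalised.  Reported intervals
are highest-posterior-density (HPD) ranges: the smallest density-ranked
set of calendar ages reaching the requested mass (default 95.4%), merged
into contiguous ranges.

Replicate determinations on the same sample are combined by the
inverse-variance weighted mean, with a chi-square consistency check on
the residuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class RadiocarbonMeasurement:
    """A conventional radiocarbon age in 14C yr BP with its 1-sigma error."""

    age: float
    sigma: float
    lab_code: str = ""

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass
class CalibrationCurve:
    """Calendar-age grid with curve 14C age mu(t) and 1-sigma s(t)."""

    cal_bp: np.ndarray
    c14_age: np.ndarray
    sigma: np.ndarray
    name: str = "synthetic"

    def __post_init__(self) -> None:
        self.cal_bp = np.asarray(self.cal_bp, dtype=float)
        self.c14_age = np.asarray(self.c14_age, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not (len(self.cal_bp) == len(self.c14_age) == len(self.sigma)):
            raise ValueError("curve columns must have equal length")
        order = np.argsort(self.cal_bp)
        self.cal_bp = self.cal_bp[order]
        self.c14_age = self.c14_age[order]
        self.sigma = self.sigma[order]
        if np.any(np.diff(self.cal_bp) <= 0):
            raise ValueError("cal BP grid must be strictly monotone")
        if np.any(self.sigma < 0):
            raise ValueError("curve sigma must be non-negative")

    @classmethod
    def from_intcal(cls, path: str, name: str | None = None) -> "CalibrationCurve":
        """Read an IntCal-format file.

        Lines beginning with ``#`` are headers; data lines are
        comma-separated ``CAL BP, 14C age, Error[, ...]`` (whitespace
        separation is tolerated).
        """
        cal, age, err = [], [], []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = [p for p in line.replace(",", " ").split() if p]
                if len(parts) < 3:
                    continue
                try:
                    vals = [float(parts[0]), float(parts[1]), float(parts[2])]
                except ValueError:
                    continue
                cal.append(vals[0])
                age.append(vals[1])
                err.append(vals[2])
        if not cal:
            raise ValueError(f"no data rows parsed from {path!r}")
        return cls(np.array(cal), np.array(age), np.array(err),
                   name=name or str(path))

    def to_csv(self, path: str) -> None:
        header = f"# calibration curve: {self.name}\n# CAL BP, 14C age, Error\n"
        with open(path, "w") as fh:
            fh.write(header)
            for c, a, s in zip(self.cal_bp, self.c14_age, self.sigma):
                fh.write(f"{c:.1f},{a:.2f},{s:.2f}\n")

    def interpolate(self, grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        mu = np.interp(grid, self.cal_bp, self.c14_age)
        s = np.interp(grid, self.cal_bp, self.sigma)
        return mu, s


@dataclass
class CalibratedDate:
    """Posterior over cal BP with HPD ranges (older bound first)."""

    cal_bp: np.ndarray
    density: np.ndarray
    hpd_ranges: list[tuple[float, float, float]]  # (older, younger, mass)
    mass: float
    measurement: RadiocarbonMeasurement
    curve_name: str = ""

    @property
    def mode(self) -> float:
        return float(self.cal_bp[int(np.argmax(self.density))])

    def as_dict(self) -> dict:
        return {
            "age": self.measurement.age,
            "sigma": self.measurement.sigma,
            "curve": self.curve_name,
            "mode_cal_bp": self.mode,
            "mass": self.mass,
            "hpd_ranges": [
                {"older": o, "younger": y, "mass": m} for o, y, m in self.hpd_ranges
            ],
        }


def combine_measurements(
    measurements: list[RadiocarbonMeasurement],
) -> tuple[RadiocarbonMeasurement, dict]:
    """Inverse-variance weighted combination of replicate determinations.

    The combined error is ``(sum of weights)**-0.5``.  Consistency of the
    replicates is assessed with a chi-square test on the weighted
    residuals (df = n - 1); an inconsistent set triggers a warning entry
    in the report but the combination is still returned.
    """
    if not measurements:
        raise ValueError("need at least one measurement")
    if len(measurements) == 1:
        m = measurements[0]
        return m, {"n": 1, "chi2": 0.0, "df": 0, "p": 1.0, "consistent": True}
    ages = np.array([m.age for m in measurements], dtype=float)
    sig = np.array([m.sigma for m in measurements], dtype=float)
    w = 1.0 / sig**2
    mean = float((w * ages).sum() / w.sum())
    comb_sigma = float(w.sum() ** -0.5)
    chi2 = float((w * (ages - mean) ** 2).sum())
    df = len(ages) - 1
    p = float(stats.chi2.sf(chi2, df))
    consistent = p >= 0.05
    report = {"n": len(ages), "chi2": chi2, "df": df, "p": p,
              "consistent": consistent}
    code = "+".join(m.lab_code for m in measurements if m.lab_code)
    return RadiocarbonMeasurement(mean, comb_sigma, lab_code=code), report


def calibrate(
    measurement: RadiocarbonMeasurement,
    curve: CalibrationCurve,
    mass: float = 0.954,
    grid_step: float = 1.0,
) -> CalibratedDate:
    """Calibrate a conventional radiocarbon age against a curve."""
    if not 0 < mass < 1:
        raise ValueError("mass must be in (0, 1)")
    grid = np.arange(curve.cal_bp[0], curve.cal_bp[-1] + grid_step / 2, grid_step)
    mu, s = curve.interpolate(grid)
    var = measurement.sigma**2 + s**2
    lo = mu.min() - 3 * np.sqrt(var.max())
    hi = mu.max() + 3 * np.sqrt(var.max())
    if not (lo <= measurement.age <= hi):
        raise ValueError(
            f"age {measurement.age} outside curve 14C support "
            f"[{mu.min():.0f}, {mu.max():.0f}] (+/- 3 sigma)"
        )
    logd = -((measurement.age - mu) ** 2) / (2.0 * var)
    dens = np.exp(logd - logd.max())
    dens /= dens.sum()
    ranges = _hpd_ranges(grid, dens, mass)
    return CalibratedDate(
        cal_bp=grid,
        density=dens,
        hpd_ranges=ranges,
        mass=mass,
        measurement=measurement,
        curve_name=curve.name,
    )


def _hpd_ranges(grid, dens, mass) -> list[tuple[float, float, float]]:
    order = np.argsort(dens)[::-1]
    csum = np.cumsum(dens[order])
    ncut = int(np.searchsorted(csum, mass)) + 1
    sel = np.zeros(len(grid), dtype=bool)
    sel[order[:ncut]] = True
    ranges: list[tuple[float, float, float]] = []
    i = 0
    n = len(grid)
    while i < n:
        if sel[i]:
            j = i
            while j + 1 < n and sel[j + 1]:
                j += 1
            m = float(dens[i : j + 1].sum())
            ranges.append((float(grid[j]), float(grid[i]), m))  # older, younger
            i = j + 1
        else:
            i += 1
    ranges.sort(key=lambda r: -r[0])
    return ranges
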