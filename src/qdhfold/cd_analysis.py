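"""CD population decomposition and melting-temperature extraction.

Two analyses accompany the structure work:

* **Two-component decomposition** — a mixture spectrum (e.g. a construct
  populating both QDH forms) is fit as ``w1*comp1 + w2*comp2`` with
  ``w1 + w2 = 1`` and both weights non-negative, using the pure-form
  spectra as components.  The constrained least-squares weight has the
  closed form ``w1 = <m - c2, c1 - c2> / |c1 - c2|^2`` (clipped to the
  simplex).
* **Melting analysis** — molar ellipticity at a fixed wavelength versus
  temperature, with linear folded/unfolded baselines fitted over user
  windows.  The folded fraction is
  ``theta(T) = (y(T) - y_u(T)) / (y_f(T) - y_u(T))`` and the melting
  temperature is where ``theta`` crosses 0.5 (linear interpolation
  between bracketing grid points).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CDSpectrum",
    "MeltCurve",
    "MeltFit",
    "decompose_two_state",
    "fit_baselines",
    "melt_tm",
    "read_xy_tsv",
    "write_xy_tsv",
]


@dataclass(frozen=True)
class CDSpectrum:
    """Wavelength (nm, strictly increasing) vs molar ellipticity."""

    wavelength: np.ndarray
    ellipticity: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.wavelength, float)
        y = np.asarray(self.ellipticity, float)
        if w.ndim != 1 or w.shape != y.shape:
            raise ValueError("wavelength and ellipticity must be equal-length 1-D")
        if np.any(np.diff(w) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        object.__setattr__(self, "wavelength", w)
        object.__setattr__(self, "ellipticity", y)

    def resample(self, grid: np.ndarray) -> "CDSpectrum":
        return CDSpectrum(grid, np.interp(grid, self.wavelength, self.ellipticity))


@dataclass(frozen=True)
class MeltCurve:
    """Temperature (deg C, strictly increasing) vs ellipticity at a fixed
    wavelength (conventionally 295 nm for quadruplexes)."""

    temperature: np.ndarray
    ellipticity: np.ndarray
    wavelength_nm: float = 295.0

    def __post_init__(self):
        t = np.asarray(self.temperature, float)
        y = np.asarray(self.ellipticity, float)
        if t.ndim != 1 or t.shape != y.shape:
            raise ValueError("temperature and ellipticity must be equal-length 1-D")
        if np.any(np.diff(t) <= 0):
            raise ValueError("temperature grid must be strictly increasing")
        object.__setattr__(self, "temperature", t)
        object.__setattr__(self, "ellipticity", y)


@dataclass(frozen=True)
class Baseline:
    slope: float
    intercept: float

    def __call__(self, t: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(t, float) + self.intercept


@dataclass(frozen=True)
class MeltFit:
    folded_baseline: Baseline
    unfolded_baseline: Baseline
    tm: float
    theta: np.ndarray  # folded fraction on the curve's grid, clipped to [0, 1]


def decompose_two_state(
    mixture: CDSpectrum, comp1: CDSpectrum, comp2: CDSpectrum
) -> tuple[float, float, float]:
    """Simplex-constrained two-component fit of a mixture spectrum.

    Returns ``(w1, w2, residual_norm)`` with ``w1 + w2 = 1`` and both
    weights in [0, 1].  Spectra are resampled by linear interpolation onto
    the common support of all three grids.
    """
    lo = max(s.wavelength[0] for s in (mixture, comp1, comp2))
    hi = min(s.wavelength[-1] for s in (mixture, comp1, comp2))
    if hi <= lo:
        raise ValueError("spectra have no common wavelength support")
    grid = mixture.wavelength[(mixture.wavelength >= lo) & (mixture.wavelength <= hi)]
    m = mixture.resample(grid).ellipticity
    c1 = comp1.resample(grid).ellipticity
    c2 = comp2.resample(grid).ellipticity
    diff = c1 - c2
    denom = float(diff @ diff)
    if denom < 1e-12 * max(1.0, float(c1 @ c1)):
        raise ValueError("component spectra are (near-)identical: degenerate design")
    w1 = float(np.clip((m - c2) @ diff / denom, 0.0, 1.0))
    resid = float(np.linalg.norm(m - (w1 * c1 + (1 - w1) * c2)))
    return w1, 1.0 - w1, resid


def fit_baselines(
    curve: MeltCurve,
    low_window: tuple[float, float],
    high_window: tuple[float, float],
) -> tuple[Baseline, Baseline]:
    """Least-squares linear baselines of the folded (low-temperature) and
    unfolded (high-temperature) states over the given windows (deg C,
    inclusive, each covering >= 3 grid points, non-overlapping)."""
    if low_window[1] >= high_window[0]:
        raise ValueError("folded and unfolded baseline windows overlap")
    out = []
    for name, (lo, hi) in (("folded", low_window), ("unfolded", high_window)):
        mask = (curve.temperature >= lo) & (curve.temperature <= hi)
        if mask.sum() < 3:
            raise ValueError(
                f"{name} baseline window {lo}-{hi} C contains "
                f"{int(mask.sum())} points; need at least 3"
            )
        slope, intercept = np.polyfit(
            curve.temperature[mask], curve.ellipticity[mask], 1
        )
        out.append(Baseline(float(slope), float(intercept)))
    return out[0], out[1]


def melt_tm(curve: MeltCurve, baselines: tuple[Baseline, Baseline]) -> MeltFit:
    """Baseline-referenced melting temperature.

    The folded fraction ``theta`` is clipped to [0, 1]; Tm is the first
    downward crossing of 0.5 located by linear interpolation.  Raises if
    the transition is incomplete (no crossing)."""
    folded, unfolded = baselines
    t = curve.temperature
    span = folded(t) - unfolded(t)
    if np.any(np.abs(span) < 1e-12):
        raise ValueError("folded and unfolded baselines intersect inside the grid")
    theta = np.clip((curve.ellipticity - unfolded(t)) / span, 0.0, 1.0)
    above = theta >= 0.5
    crossing = None
    for i in range(len(t) - 1):
        if above[i] and not above[i + 1]:
            crossing = i
            break
    if crossing is None:
        raise ValueError("folded fraction never crosses 0.5: incomplete transition")
    th0, th1 = theta[crossing], theta[crossing + 1]
    frac = (th0 - 0.5) / (th0 - th1)
    tm = float(t[crossing] + frac * (t[crossing + 1] - t[crossing]))
    return MeltFit(folded, unfolded, tm, theta)


# ---------------------------------------------------------------------------
# Two-column TSV I/O (wavelength_nm or temperature_C, ellipticity)

def read_xy_tsv(path) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"line {lineno}: expected 2 tab-separated columns")
            try:
                xs.append(float(parts[0]))
                ys.append(float(parts[1]))
            except ValueError:
                if lineno == 1:
                    continue  # header row
                raise ValueError(f"line {lineno}: non-numeric value") from None
    return np.array(xs), np.array(ys)


def write_xy_tsv(path, x: np.ndarray, y: np.ndarray, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(header.rstrip("\n") + "\n")
        for xi, yi in zip(x, y):
            fh.write(f"{xi:.6g}\t{yi:.6g}\n")
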