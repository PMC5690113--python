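"""Analytic proton depth-dose model and Bragg-peak pull-back estimation
of relative stopping power (RSP).

The depth-dose curve of a monoenergetic pencil beam in water is modelled
as a power-law stopping curve D0(z) ~ (R0 - z)^(1/p - 1), p = 1.77,
convolved with a Gaussian range-straggling kernel whose width follows
the empirical scaling sigma = 0.012 * R^0.935 cm.  The nominal range R
is defined at the distal 80% dose level (d80), the standard clinical
range surrogate, and the internal endpoint R0 is calibrated so that
d80 of the generated curve equals R.

When a uniform slab of material of physical thickness t and relative
stopping power rsp intercepts the beam, the curve shifts upstream by the
slab's water-equivalent thickness WET = t * rsp; the pull-back of the
distal range therefore measures rsp = (d80_ref - d80_sample) / t.  The
first-order slab model translates the curve rigidly and neglects the
extra straggling accumulated in the slab, which is adequate because the
estimator uses only the shift.  A 1-D slab has no orientation, so the
model is insensitive to sample rotation by construction.

All depths are centimetres of water; doses are normalized to peak 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "BeamModel",
    "DepthDoseCurve",
    "bragg_curve",
    "apply_slab",
    "distal_range",
    "estimate_rsp",
    "add_noise",
]

DEFAULT_GRID_SPACING_CM = 0.01  # 0.1 mm


@dataclass
class DepthDoseCurve:
    """Normalized depth-dose curve: depth in water (cm) vs dose."""

    depth_cm: np.ndarray
    dose: np.ndarray

    def __post_init__(self) -> None:
        self.depth_cm = np.asarray(self.depth_cm, dtype=float)
        self.dose = np.asarray(self.dose, dtype=float)
        if self.depth_cm.ndim != 1 or self.depth_cm.shape != self.dose.shape:
            raise ValueError("depth and dose must be 1-D arrays of equal length")
        if len(self.depth_cm) < 10:
            raise ValueError("curve needs at least 10 samples")
        if np.any(np.diff(self.depth_cm) <= 0):
            raise ValueError("depth grid must be strictly ascending")
        if np.any(self.dose < 0):
            raise ValueError("dose must be nonnegative")

    def normalized(self) -> "DepthDoseCurve":
        peak = self.dose.max()
        if peak <= 0:
            raise ValueError("curve has no dose")
        return DepthDoseCurve(self.depth_cm, self.dose / peak)

    def to_csv(self, path) -> None:
        """Two-column CSV: depth_mm, dose (normalized)."""
        np.savetxt(
            path,
            np.column_stack([self.depth_cm * 10.0, self.dose]),
            delimiter=",",
            header="depth_mm,dose",
            comments="",
        )

    @classmethod
    def from_csv(cls, path) -> "DepthDoseCurve":
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls(data[:, 0] / 10.0, data[:, 1])


@dataclass
class BeamModel:
    """Monoenergetic proton pencil-beam parameters.

    range_cm     : distal 80% range in water (cm)
    sigma_cm     : range-straggling width; default 0.012 * R^0.935
    p            : range-energy power-law exponent (~1.77 for protons)
    """

    range_cm: float = 15.0
    sigma_cm: float = None
    p: float = 1.77

    def __post_init__(self) -> None:
        if self.range_cm <= 0:
            raise ValueError("range must be positive")
        if self.sigma_cm is None:
            self.sigma_cm = 0.012 * self.range_cm**0.935
        if self.sigma_cm <= 0:
            raise ValueError("sigma must be positive")
        if self.p <= 1:
            raise ValueError("power-law exponent must exceed 1")


def _powerlaw_dose(grid: np.ndarray, h: float, r0: float, p: float) -> np.ndarray:
    """Cell-averaged (r0 - z)^(1/p - 1) over [z - h/2, z + h/2).

    The cell average integrates the integrable singularity at r0
    analytically, so the discrete curve is insensitive to how the grid
    straddles the endpoint.
    """
    a = 1.0 / p
    lo = np.clip(grid - h / 2, None, r0)
    hi = np.clip(grid + h / 2, None, r0)
    width = np.maximum(hi - lo, 0.0)
    val = np.zeros_like(grid)
    mask = width > 0
    val[mask] = ((r0 - lo[mask]) ** a - (r0 - hi[mask]) ** a) / (a * h)
    return val


def _raw_curve(
    grid: np.ndarray, r0: float, sigma: float, p: float
) -> np.ndarray:
    h = float(grid[1] - grid[0])
    s = _powerlaw_dose(grid, h, r0, p)
    half = int(np.ceil(5 * sigma / h))
    k = np.exp(-0.5 * ((np.arange(-half, half + 1) * h) / sigma) ** 2)
    k /= k.sum()
    return np.convolve(s, k, mode="same")


def bragg_curve(b: BeamModel, grid_cm: np.ndarray = None) -> DepthDoseCurve:
    """Generate a normalized pristine Bragg curve for a beam model.

    The endpoint of the underlying power law is calibrated (1-D root
    find) so the distal 80% level of the generated curve sits exactly at
    ``b.range_cm``.  The grid must span [0, R + 5 sigma] with spacing
    no coarser than sigma / 2.
    """
    if grid_cm is None:
        grid_cm = np.arange(
            0.0, b.range_cm + 5 * b.sigma_cm + DEFAULT_GRID_SPACING_CM,
            DEFAULT_GRID_SPACING_CM,
        )
    grid_cm = np.asarray(grid_cm, dtype=float)
    h = np.diff(grid_cm)
    if np.ptp(h) > 1e-9:
        raise ValueError("grid must be uniform")
    if h[0] > b.sigma_cm / 2:
        raise ValueError(
            f"grid spacing {h[0]:.4g} cm too coarse for sigma={b.sigma_cm:.4g} cm "
            "(need <= sigma/2)"
        )
    if grid_cm[-1] < b.range_cm + 5 * b.sigma_cm - 1e-9:
        raise ValueError("grid must span [0, R + 5 sigma]")

    def d80_minus_target(r0: float) -> float:
        dose = _raw_curve(grid_cm, r0, b.sigma_cm, b.p)
        c = DepthDoseCurve(grid_cm, dose / dose.max())
        return distal_range(c, level=0.8) - b.range_cm

    lo = b.range_cm - 5 * b.sigma_cm
    hi = b.range_cm + 4 * b.sigma_cm
    r0 = brentq(d80_minus_target, lo, hi, xtol=1e-6)
    dose = _raw_curve(grid_cm, r0, b.sigma_cm, b.p)
    return DepthDoseCurve(grid_cm, dose / dose.max())


def apply_slab(
    c: DepthDoseCurve, thickness_cm: float, rsp: float
) -> DepthDoseCurve:
    """Shift a depth-dose curve upstream by a slab's water-equivalent
    thickness WET = thickness * rsp (first-order model: rigid
    translation, straggling growth in the slab neglected)."""
    if thickness_cm < 0 or rsp < 0:
        raise ValueError("thickness and rsp must be nonnegative")
    wet = thickness_cm * rsp
    if wet >= c.depth_cm[-1]:
        raise ValueError("slab WET exceeds the curve's depth range")
    dose = np.interp(
        c.depth_cm + wet, c.depth_cm, c.dose, right=float(c.dose[-1])
    )
    return DepthDoseCurve(c.depth_cm, dose).normalized()


def distal_range(c: DepthDoseCurve, level: float = 0.8) -> float:
    """Depth on the distal falloff where dose first drops to
    ``level`` x peak, by linear interpolation between samples."""
    if not 0 < level <= 1:
        raise ValueError("level must be in (0, 1]")
    dose = c.dose
    peak = dose.max()
    i_pk = int(np.argmax(dose))
    if level == 1.0:
        return float(c.depth_cm[i_pk])
    target = level * peak
    below = np.flatnonzero(dose[i_pk:] < target)
    if len(below) == 0:
        raise ValueError(f"curve never falls below {level:.0%} of peak distally")
    j = i_pk + below[0]
    d0, d1 = dose[j - 1], dose[j]
    z0, z1 = c.depth_cm[j - 1], c.depth_cm[j]
    return float(z0 + (d0 - target) / (d0 - d1) * (z1 - z0))


def estimate_rsp(
    reference: DepthDoseCurve,
    with_sample: DepthDoseCurve,
    thickness_cm: float,
    level: float = 0.8,
) -> float:
    """Relative stopping power from the Bragg-peak pull-back:
    rsp = (d_level(reference) - d_level(with_sample)) / thickness."""
    if thickness_cm <= 0:
        raise ValueError("sample thickness must be positive")
    pullback = distal_range(reference, level) - distal_range(with_sample, level)
    rsp = pullback / thickness_cm
    if rsp < -0.05:
        warnings.warn(
            f"negative pull-back (rsp={rsp:.3f}); check curve ordering"
        )
    return float(rsp)


def add_noise(
    c: DepthDoseCurve, relative_sd: float, seed: int
) -> DepthDoseCurve:
    """Apply i.i.d. multiplicative Gaussian noise (chamber-measurement
    emulation) and renormalize.  Deterministic under a fixed seed."""
    if relative_sd < 0:
        raise ValueError("relative_sd must be nonnegative")
    if relative_sd == 0:
        return DepthDoseCurve(c.depth_cm.copy(), c.dose.copy())
    rng = np.random.default_rng(seed)
    noisy = np.clip(c.dose * (1 + relative_sd * rng.standard_normal(len(c.dose))), 0, None)
    return DepthDoseCurve(c.depth_cm, noisy).normalized()
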