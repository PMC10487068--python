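"""Penetration-test texture indices for cheese paste.

A cylindrical probe (default 3 mm diameter) penetrates the paste at
constant speed while force and displacement are logged.  The record is
converted to true strain and true stress,

    ε = ln(h₀ / (h₀ − Δh)),        δ = F / A   (MPa = N/mm²),

with h₀ the original sample height, Δh the penetration depth and A the
probe cross-section (constant for a cylindrical probe).  From the
stress–strain curve three indices are extracted: Young's modulus (slope of
the initial linear region), and the stress and strain at fracture (first
stress peak followed by a clear drop).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PenetrationCurve",
    "StressStrainCurve",
    "TextureIndices",
    "true_strain",
    "true_stress",
    "to_stress_strain",
    "young_modulus",
    "fracture_point",
    "texture_indices",
]

DEFAULT_PROBE_DIAMETER_MM = 3.0

#: default strain window for the modulus fit
LINEAR_WINDOW = (0.005, 0.05)

#: minimum linearity for an accepted modulus fit
MIN_R2 = 0.99

#: fracture detection: relative stress drop required within the strain lookahead
FRACTURE_DROP = 0.10
FRACTURE_LOOKAHEAD = 0.02


@dataclass
class PenetrationCurve:
    displacement_mm: np.ndarray
    force_N: np.ndarray
    h0_mm: float
    probe_diameter_mm: float = DEFAULT_PROBE_DIAMETER_MM

    def __post_init__(self) -> None:
        self.displacement_mm = np.asarray(self.displacement_mm, dtype=float)
        self.force_N = np.asarray(self.force_N, dtype=float)
        if self.displacement_mm.shape != self.force_N.shape or self.displacement_mm.ndim != 1:
            raise ValueError("displacement and force must be 1-D of equal length")
        if self.displacement_mm.size < 10:
            raise ValueError("need at least 10 points")
        if self.probe_diameter_mm <= 0 or self.h0_mm <= 0:
            raise ValueError("probe diameter and sample height must be positive")
        if np.any(self.displacement_mm < 0) or np.any(np.diff(self.displacement_mm) <= 0):
            raise ValueError("displacement must be non-negative and increasing")
        if self.displacement_mm[-1] >= self.h0_mm:
            raise ValueError("displacement reaches the sample height (full penetration)")

    @property
    def contact_area_mm2(self) -> float:
        return float(np.pi * (self.probe_diameter_mm / 2.0) ** 2)


@dataclass
class StressStrainCurve:
    strain: np.ndarray
    stress_MPa: np.ndarray

    def __post_init__(self) -> None:
        self.strain = np.asarray(self.strain, dtype=float)
        self.stress_MPa = np.asarray(self.stress_MPa, dtype=float)
        if self.strain.shape != self.stress_MPa.shape or self.strain.ndim != 1:
            raise ValueError("strain and stress must be 1-D of equal length")
        if self.strain.size == 0:
            raise ValueError("empty stress-strain curve")
        if np.any(self.strain < 0) or np.any(np.diff(self.strain) <= 0):
            raise ValueError("strain must be non-negative and increasing")
        if not np.all(np.isfinite(self.stress_MPa)):
            raise ValueError("stress must be finite")


@dataclass
class TextureIndices:
    young_modulus_MPa: float
    linear_region: tuple[float, float]
    modulus_r2: float
    modulus_flagged: bool
    fracture_stress_MPa: float | None
    fracture_strain: float | None
    fracture_detected: bool


def true_strain(h0_mm: float, delta_h_mm: float | np.ndarray) -> float | np.ndarray:
    """Hencky strain ε = ln(h₀/(h₀−Δh))."""
    delta = np.asarray(delta_h_mm, dtype=float)
    if h0_mm <= 0:
        raise ValueError("sample height must be positive")
    if np.any(delta < 0) or np.any(delta >= h0_mm):
        raise ValueError("penetration depth must satisfy 0 <= dh < h0")
    out = np.log(h0_mm / (h0_mm - delta))
    return float(out) if np.isscalar(delta_h_mm) else out


def true_stress(force_N: float | np.ndarray, contact_area_mm2: float) -> float | np.ndarray:
    """δ = F/A in MPa (N and mm²)."""
    if contact_area_mm2 <= 0:
        raise ValueError("contact area must be positive")
    out = np.asarray(force_N, dtype=float) / contact_area_mm2
    return float(out) if np.isscalar(force_N) else out


def to_stress_strain(curve: PenetrationCurve) -> StressStrainCurve:
    """Pointwise conversion of a force–displacement record."""
    eps = true_strain(curve.h0_mm, curve.displacement_mm)
    sig = true_stress(curve.force_N, curve.contact_area_mm2)
    return StressStrainCurve(strain=eps, stress_MPa=sig)


def young_modulus(
    ss: StressStrainCurve,
    window: tuple[float, float] = LINEAR_WINDOW,
    min_r2: float = MIN_R2,
) -> tuple[float, tuple[float, float], float, bool]:
    """Initial-region slope of the true stress–strain curve.

    Least-squares line over ε ∈ window (default [0.005, 0.05]); if the fit
    is not linear enough (R² < 0.99) the upper end is shrunk until it is.
    Returns (modulus_MPa, (ε_lo, ε_hi), R², flagged); ``flagged`` is True
    when no sub-window of ≥ 5 points reaches the R² bar and the best-effort
    slope is returned instead.
    """
    lo, hi = window
    sel = (ss.strain >= lo) & (ss.strain <= hi)
    if sel.sum() < 10:
        raise ValueError("need >= 10 points in the initial strain window")
    idx = np.where(sel)[0]
    best: tuple[float, tuple[float, float], float] | None = None
    upper = idx[-1]
    while upper - idx[0] + 1 >= 5:
        x = ss.strain[idx[0] : upper + 1]
        y = ss.stress_MPa[idx[0] : upper + 1]
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
        cand = (float(slope), (float(x[0]), float(x[-1])), float(r2))
        if best is None or r2 > best[2]:
            best = cand
        if r2 >= min_r2:
            return cand[0], cand[1], cand[2], False
        upper -= max(1, (upper - idx[0]) // 10)
    assert best is not None
    return best[0], best[1], best[2], True


def fracture_point(
    ss: StressStrainCurve,
    drop: float = FRACTURE_DROP,
    lookahead: float = FRACTURE_LOOKAHEAD,
) -> tuple[float, float] | None:
    """(fracture stress MPa, fracture strain) or None when no fracture.

    Fracture is declared at the first local stress maximum followed, within
    the next ``lookahead`` strain, by a relative drop of at least ``drop``
    (thresholds reject instrument noise blips); the reported point is the
    sample immediately preceding the steepest single-step relative drop in
    that window, which pins the strain to the actual stress collapse rather
    than to a noise ripple on the flat pre-fracture plateau.
    """
    sig, eps = ss.stress_MPa, ss.strain
    n = sig.size
    for i in range(1, n - 1):
        if not (sig[i] >= sig[i - 1] and sig[i] > sig[i + 1]):
            continue
        ahead = (eps > eps[i]) & (eps <= eps[i] + lookahead)
        if not ahead.any():
            continue
        if sig[ahead].min() > sig[i] * (1.0 - drop):
            continue
        j_hi = int(np.where(ahead)[0][-1])
        steps = np.where(sig[i:j_hi] > 0, (sig[i:j_hi] - sig[i + 1 : j_hi + 1]) / sig[i:j_hi], 0.0)
        fidx = i + int(np.argmax(steps))
        return float(sig[fidx]), float(eps[fidx])
    return None


def texture_indices(curve: PenetrationCurve) -> TextureIndices:
    """Full index extraction from a raw penetration record."""
    ss = to_stress_strain(curve)
    modulus, region, r2, flagged = young_modulus(ss)
    frac = fracture_point(ss)
    return TextureIndices(
        young_modulus_MPa=modulus,
        linear_region=region,
        modulus_r2=r2,
        modulus_flagged=flagged,
        fracture_stress_MPa=frac[0] if frac else None,
        fracture_strain=frac[1] if frac else None,
        fracture_detected=frac is not None,
    )
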