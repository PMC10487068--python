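"""Ground-truth fixture generators for every pipeline stage.

Each generator returns ``(fixture, SyntheticTruth)`` where the truth object
records every planted parameter, so recovery by the corresponding analysis
stage can be tested quantitatively.  All randomness flows through a single
integer seed; the same seed reproduces the fixture bit for bit.

What is emulated — and what is not: slice scans are a flat paste field
over a black backdrop with hard-edged elliptical/capsule openings and
additive Gaussian pixel noise (no rind, crystals, shading or JPEG
artefacts); CPMG decays are ideal multiexponentials with additive Gaussian
noise of constant σ = S₀/SNR (no magnitude bias, baseline drift or
spurious echoes); penetration curves are linear-elastic to a smooth yield,
fracture with a 60 % stress drop (no serrated fracture or probe friction);
group samples are plain normal draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .imaging import SliceImage
from .relaxometry import CpmgDecay, ProtonPopulation, decay_model
from .stats import PeakRecord
from .texture import PenetrationCurve

__all__ = [
    "SyntheticTruth",
    "make_slice_image",
    "make_cpmg_decay",
    "make_penetration_curve",
    "make_group_samples",
    "make_peak_table",
    "twelve_ellipse_fixture",
    "porosity_fixture",
    "NDC_POPULATIONS",
    "DC_POPULATIONS",
]

PASTE_LEVEL = 0.75       # scanned paste intensity
OPENING_LEVEL = 0.05     # backdrop seen through a hole
BACKDROP_LEVEL = 0.02    # black field around the slice

#: 4-population reference parameters (abundance %, T2 ms) of 20-month
#: hard cheese: non-defective (NDC) and defective (DC) group means.
NDC_POPULATIONS = [
    ProtonPopulation("A", 5.44, 1.55),
    ProtonPopulation("B", 55.06, 10.78),
    ProtonPopulation("C", 23.58, 51.10),
    ProtonPopulation("D", 15.92, 170.79),
]
DC_POPULATIONS = [
    ProtonPopulation("A", 5.32, 1.62),
    ProtonPopulation("B", 54.55, 11.13),
    ProtonPopulation("C", 23.71, 54.07),
    ProtonPopulation("D", 16.42, 180.54),
]


@dataclass
class SyntheticTruth:
    """The planted parameters of one generated fixture."""

    stage: str  # imaging | relaxometry | texture | stats
    parameters: dict[str, Any] = field(default_factory=dict)
    seed: int | None = None


# --------------------------------------------------------------------------
# slice images


def _ellipse_mask(shape, centre_px, a_px, b_px, angle_rad):
    rr, cc = np.indices(shape)
    dy = rr - centre_px[0]
    dx = cc - centre_px[1]
    u = dx * math.cos(angle_rad) + dy * math.sin(angle_rad)
    v = -dx * math.sin(angle_rad) + dy * math.cos(angle_rad)
    return (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0


def _capsule_mask(shape, centre_px, length_px, width_px, angle_rad):
    """Rectangle with half-disc caps: distance to the axis segment <= w/2."""
    rr, cc = np.indices(shape)
    dy = rr - centre_px[0]
    dx = cc - centre_px[1]
    u = dx * math.cos(angle_rad) + dy * math.sin(angle_rad)
    v = -dx * math.sin(angle_rad) + dy * math.cos(angle_rad)
    half = max((length_px - width_px) / 2.0, 0.0)
    du = np.clip(np.abs(u) - half, 0.0, None)
    return du**2 + v**2 <= (width_px / 2.0) ** 2


def _shape_geometry(area_mm2: float, axis_ratio: float) -> tuple[str, float, float]:
    """(kind, long, short) in mm for a planted opening.

    Ellipse for axis_ratio >= 0.1 (semi-axes), capsule (slit) below
    (full length and width).
    """
    if not (0 < axis_ratio <= 1):
        raise ValueError("axis_ratio must be in (0, 1]")
    if area_mm2 <= 0:
        raise ValueError("area must be positive")
    if axis_ratio >= 0.1:
        a = math.sqrt(area_mm2 / (math.pi * axis_ratio))
        return "ellipse", a, axis_ratio * a
    r = axis_ratio
    length = math.sqrt(area_mm2 / (r - r**2 + math.pi * r**2 / 4.0))
    return "capsule", length, r * length


def make_slice_image(
    section_mm: tuple[float, float] = (100.0, 100.0),
    openings: Sequence[tuple] = (),
    resolution: float = 236.0,
    noise_sd: float = 0.02,
    seed: int | None = 0,
    margin_mm: float = 3.0,
) -> tuple[SliceImage, SyntheticTruth]:
    """Synthetic scanned slice with planted openings.

    ``openings`` is a sequence of ``(area_mm2, axis_ratio)`` or
    ``(area_mm2, axis_ratio, angle_deg)`` or
    ``(area_mm2, axis_ratio, angle_deg, (row_mm, col_mm))`` tuples; omitted
    angles/positions are drawn at random, with non-overlapping placement
    retried up to 100 times per opening.  Rasterisation is a hard pixel-
    centre test (no anti-aliasing) so planted areas are countable.
    """
    rng = np.random.default_rng(seed)
    w_mm, h_mm = float(section_mm[0]), float(section_mm[1])
    px_per_mm = resolution / 10.0
    margin_px = int(round(margin_mm * px_per_mm))
    sec_rows = int(round(h_mm * px_per_mm))
    sec_cols = int(round(w_mm * px_per_mm))
    shape = (sec_rows + 2 * margin_px, sec_cols + 2 * margin_px)
    img = np.full(shape, BACKDROP_LEVEL)
    img[margin_px : margin_px + sec_rows, margin_px : margin_px + sec_cols] = PASTE_LEVEL

    placed: list[tuple[float, float, float]] = []  # (row_mm, col_mm, radius_mm)
    truth_openings = []
    for spec_entry in openings:
        entry = tuple(spec_entry)
        area, ratio = float(entry[0]), float(entry[1])
        angle = float(entry[2]) if len(entry) > 2 and entry[2] is not None else float(rng.uniform(0, 180))
        pos = entry[3] if len(entry) > 3 else None
        kind, long_mm, short_mm = _shape_geometry(area, ratio)
        reach = long_mm if kind == "ellipse" else long_mm / 2.0  # bounding radius
        clearance = reach + 1.5
        if pos is not None:
            row_mm, col_mm = float(pos[0]), float(pos[1])
        else:
            for attempt in range(100):
                row_mm = rng.uniform(clearance, h_mm - clearance)
                col_mm = rng.uniform(clearance, w_mm - clearance)
                if all(
                    math.hypot(row_mm - r0, col_mm - c0) > clearance + rad0 + 0.5
                    for r0, c0, rad0 in placed
                ):
                    break
            else:
                raise RuntimeError("could not place opening without overlap after 100 tries")
        placed.append((row_mm, col_mm, reach))
        centre_px = (margin_px + row_mm * px_per_mm, margin_px + col_mm * px_per_mm)
        ang = math.radians(angle)
        if kind == "ellipse":
            mask = _ellipse_mask(shape, centre_px, long_mm * px_per_mm, short_mm * px_per_mm, ang)
        else:
            mask = _capsule_mask(shape, centre_px, long_mm * px_per_mm, short_mm * px_per_mm, ang)
        img[mask] = OPENING_LEVEL
        truth_openings.append(
            {
                "area_mm2": area,
                "axis_ratio": ratio,
                "eccentricity": math.sqrt(max(1.0 - ratio**2, 0.0)),
                "angle_deg": angle,
                "centre_mm": (row_mm, col_mm),
                "kind": kind,
            }
        )
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=shape)
    img = np.clip(img, 0.0, 1.0)
    section_area = w_mm * h_mm
    total = sum(o["area_mm2"] for o in truth_openings)
    truth = SyntheticTruth(
        stage="imaging",
        parameters={
            "section_mm": (w_mm, h_mm),
            "section_area_mm2": section_area,
            "openings": truth_openings,
            "total_opening_area_mm2": total,
            "porosity_pct": 100.0 * total / section_area,
            "n_eyes": sum(1 for o in truth_openings if o["eccentricity"] < 0.9),
            "resolution": resolution,
            "noise_sd": noise_sd,
        },
        seed=seed,
    )
    return SliceImage(pixels=img, resolution=resolution), truth


def twelve_ellipse_fixture(
    seed: int = 0, resolution: float = 236.0, noise_sd: float = 0.02
) -> tuple[SliceImage, SyntheticTruth]:
    """Benchmark slice: 12 ellipses spanning the eye/crack boundary.

    Axis ratios 0.9 … 0.20 (planted eccentricities 0.44 … 0.98, so nine
    openings fall below the 0.9 eye threshold and three at or above it),
    areas 1–5 mm²; the near-threshold shapes carry the largest areas so
    pixelisation cannot flip their class.
    """
    pairs = [  # (axis_ratio, area_mm2)
        (0.9, 2.0), (0.8, 1.5), (0.7, 2.5), (0.6, 1.0), (0.55, 3.0), (0.5, 3.5),
        (0.5, 2.0), (0.48, 4.5), (0.46, 5.0), (0.40, 5.0), (0.30, 3.0), (0.20, 4.0),
    ]
    return make_slice_image(
        section_mm=(60.0, 60.0),
        openings=[(area, ratio) for ratio, area in pairs],
        resolution=resolution,
        noise_sd=noise_sd,
        seed=seed,
    )


def porosity_fixture(
    porosity_pct: float = 0.26,
    seed: int = 0,
    resolution: float = 236.0,
    noise_sd: float = 0.02,
) -> tuple[SliceImage, SyntheticTruth]:
    """Slice planted so openings total ``porosity_pct`` % of a 100×100 mm
    section (default 0.26 %, the porosity of the defective cheeses)."""
    weights = np.array([0.5, 0.8, 1.0, 1.2, 1.5, 1.8, 2.0, 2.2, 2.5, 3.0, 4.0, 5.5])
    areas = weights / weights.sum() * (porosity_pct / 100.0 * 100.0 * 100.0)
    ratios = [0.95, 0.85, 0.75, 0.9, 0.65, 0.8, 0.55, 0.7, 0.85, 0.6, 0.75, 0.8]
    return make_slice_image(
        section_mm=(100.0, 100.0),
        openings=list(zip(areas.tolist(), ratios)),
        resolution=resolution,
        noise_sd=noise_sd,
        seed=seed,
    )


# --------------------------------------------------------------------------
# CPMG decays


def make_cpmg_decay(
    populations: Sequence[ProtonPopulation] | Sequence[tuple[float, float]] = NDC_POPULATIONS,
    tau_us: float = 80.0,
    n_points: int = 30_000,
    snr: float | None = 1000.0,
    s0: float = 100.0,
    seed: int | None = 0,
) -> tuple[CpmgDecay, SyntheticTruth]:
    """CPMG echo train from the forward multiexponential model plus
    additive Gaussian noise of σ = S₀/SNR (``snr=None`` for noiseless)."""
    pairs = [
        (p.abundance_pct, p.t2_ms) if isinstance(p, ProtonPopulation) else tuple(p)
        for p in populations
    ]
    total = sum(p for p, _ in pairs)
    if abs(total - 100.0) > 1e-6:
        raise ValueError(f"abundances must sum to 100, got {total}")
    k = np.arange(n_points)
    t_ms = 2.0 * (tau_us * 1e-3) * (k + 1)
    y = decay_model(pairs, t_ms, s0=s0)
    if snr is not None and np.isfinite(snr):
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, s0 / snr, size=n_points)
    decay = CpmgDecay(echo_times=t_ms, amplitudes=y, tau_us=tau_us)
    truth = SyntheticTruth(
        stage="relaxometry",
        parameters={
            "abundances_pct": [p for p, _ in pairs],
            "t2_ms": [t2 for _, t2 in pairs],
            "s0": s0,
            "tau_us": tau_us,
            "n_points": n_points,
            "snr": snr,
        },
        seed=seed,
    )
    return decay, truth


# --------------------------------------------------------------------------
# penetration curves


def make_penetration_curve(
    E_MPa: float = 7.55,
    fracture: tuple[float | None, float] = (None, 0.3),
    h0_mm: float = 20.0,
    probe_diameter_mm: float = 3.0,
    n_points: int = 500,
    noise_rel: float = 0.0,
    seed: int | None = 0,
) -> tuple[PenetrationCurve, SyntheticTruth]:
    """Force–displacement record of a linear-elastic paste that fractures.

    True stress is E·ε up to a yield strain, bends smoothly (cubic Hermite,
    zero slope at the peak) to the fracture point (δ*, ε*), then drops by
    60 %.  ``fracture`` is (stress_MPa | None, strain); a None stress
    defaults to the end of the linear branch, δ* = E·ε*·0.75.  The curve is
    inverted to displacement/force through the true-strain and true-stress
    definitions, with optional multiplicative force noise.
    """
    frac_stress, frac_strain = fracture
    if frac_strain <= 0.05:
        raise ValueError("fracture strain must exceed the linear window (0.05)")
    if frac_stress is None:
        frac_stress = 0.75 * E_MPa * frac_strain
    # linear limit: stay linear through the modulus window but keep the
    # Hermite branch monotone (slope <= 3 x secant slope)
    eps_lin = min(0.06, 0.75 * frac_stress / E_MPa)
    eps_lin = max(eps_lin, 0.051)
    if E_MPa * eps_lin >= frac_stress:
        raise ValueError("fracture stress below the linear branch; increase it")
    eps_max = frac_strain + 0.1
    eps = np.linspace(0.0, eps_max, n_points + 1)[1:]  # skip dh=0 duplicate
    sig = np.empty_like(eps)
    lin = eps <= eps_lin
    sig[lin] = E_MPa * eps[lin]
    mid = (~lin) & (eps <= frac_strain)
    h = frac_strain - eps_lin
    s = (eps[mid] - eps_lin) / h
    d_lin = E_MPa * eps_lin
    m0 = min(E_MPa, 3.0 * (frac_stress - d_lin) / h)  # Fritsch-Carlson bound
    h00 = 2 * s**3 - 3 * s**2 + 1
    h10 = s**3 - 2 * s**2 + s
    h01 = -2 * s**3 + 3 * s**2
    sig[mid] = h00 * d_lin + h10 * h * m0 + h01 * frac_stress
    post = eps > frac_strain
    sig[post] = 0.4 * frac_stress  # 60 % drop after fracture
    area = math.pi * (probe_diameter_mm / 2.0) ** 2
    force = sig * area
    if noise_rel > 0:
        rng = np.random.default_rng(seed)
        force = force * (1.0 + rng.normal(0.0, noise_rel, size=force.size))
    dh = h0_mm * (1.0 - np.exp(-eps))
    curve = PenetrationCurve(
        displacement_mm=dh, force_N=force, h0_mm=h0_mm, probe_diameter_mm=probe_diameter_mm
    )
    truth = SyntheticTruth(
        stage="texture",
        parameters={
            "E_MPa": E_MPa,
            "fracture_stress_MPa": frac_stress,
            "fracture_strain": frac_strain,
            "h0_mm": h0_mm,
            "probe_diameter_mm": probe_diameter_mm,
            "noise_rel": noise_rel,
        },
        seed=seed,
    )
    return curve, truth


# --------------------------------------------------------------------------
# group samples and peak tables


def make_group_samples(
    mean: float,
    sd: float,
    n: int = 3,
    seed: int | None = 0,
    exact: bool = False,
) -> tuple[np.ndarray, SyntheticTruth]:
    """Normal replicate draws; ``exact=True`` affinely rescales the draws
    so the sample mean and SD (ddof=1) hit the targets to machine
    precision — useful for reconstructing raw samples behind a published
    mean ± SD."""
    if sd < 0 or n < 2:
        raise ValueError("need sd >= 0 and n >= 2")
    rng = np.random.default_rng(seed)
    x = rng.normal(mean, sd if sd > 0 else 1.0, size=n)
    if sd == 0:
        x = np.full(n, float(mean))
    elif exact:
        z = (x - x.mean()) / x.std(ddof=1)
        x = mean + sd * z
    truth = SyntheticTruth(
        stage="stats", parameters={"mean": mean, "sd": sd, "n": n, "exact": exact}, seed=seed
    )
    return x, truth


def make_peak_table(
    ratios: dict[str, float] | None = None,
    seed: int | None = 0,
) -> tuple[list[PeakRecord], SyntheticTruth]:
    """CZE peak table planted to yield the given casein-fragment ratios.

    ``ratios`` keys: as1I_over_as1, as_f1_23_over_as1plus0, as1PL_over_as1,
    gamma_over_beta (defaults are the non-defective group means).  Raw
    areas are back-computed from random migration times so the corrected
    areas deliver the ratios exactly.
    """
    if ratios is None:
        ratios = {
            "as1I_over_as1": 0.38,
            "as_f1_23_over_as1plus0": 0.19,
            "as1PL_over_as1": 0.68,
            "gamma_over_beta": 4.38,
        }
    rng = np.random.default_rng(seed)
    # parent corrected areas (arbitrary detector units)
    as1, as0, beta = 100.0, 40.0, 50.0
    corrected = {
        "as1": as1,
        "as0": as0,
        "beta": beta,
        "as1-I": ratios["as1I_over_as1"] * as1,
        "as1-f1-23": ratios["as_f1_23_over_as1plus0"] * (as1 + as0),
        "as1-PL": ratios["as1PL_over_as1"] * as1,
        "gamma": ratios["gamma_over_beta"] * beta,
    }
    peaks = []
    for name, ca in corrected.items():
        mt = float(rng.uniform(8.0, 25.0))  # minutes
        peaks.append(PeakRecord(peak_id=name, raw_area=ca * mt, migration_time=mt))
    truth = SyntheticTruth(stage="stats", parameters={"ratios": dict(ratios)}, seed=seed)
    return peaks, truth
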