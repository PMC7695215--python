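"""Synthetic Laurdan spectra and bilayer snapshots with known ground truth.

Every generator returns the data *and* a truth record holding the exact
quantities the generator planted (band parameters, relative areas, leaflet
and near-channel tags, planted water counts), so downstream analyses can
be validated against construction rather than against copied numbers.

Spectra are sums of two asymmetric log-normal bands whose blue-band
fraction follows a saturating dose law in peptide concentration —
increasing for liposome-like systems (melittin packs the headgroups) and
decreasing for cell-like systems (heterogeneous membranes fluidize).
Bilayer frames are jittered lattices of lipid head positions at a
prescribed packing density, optionally with a transmembrane channel
surrounded by a densified first lipid shell whose tessellation areas are
known exactly by construction.

All randomness flows through one :class:`numpy.random.Generator` seeded
from the config; the same seed reproduces the same data bit for bit.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .deconvolution import (
    LogNormalPeak,
    compute_gp,
    derive_parameters,
    evaluate_lognormal,
    peak_area,
)
from .exceptions import LipidOrderError
from .geometry import BilayerFrame
from .spectra import Spectrum

# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------


def _default_grid() -> np.ndarray:
    return np.arange(400.0, 601.0, 1.0)


@dataclass(frozen=True)
class SpectrumGeneratorConfig:
    """Parameters of one synthetic Laurdan spectrum.

    The two bands are placed at liposome-like positions by default; the
    blue-band relative area is set via ``target_s_b`` by scaling the two
    amplitudes at fixed shapes.  Noise is Gaussian with standard deviation
    ``noise_sigma_frac`` times the peak of the noiseless sum (0.02 ≈ the
    smoothness of published cuvette spectra); a Poisson option treats
    intensities as counts.  Optional artifacts: a narrow Raman band of
    water near 433 nm (for 378 nm excitation) and a flat baseline.
    """

    target_s_b: float = 0.5
    blue_position: float = 444.0
    blue_fwhm: float = 48.0
    blue_rho: float = 1.35
    green_position: float = 497.0
    green_fwhm: float = 52.0
    green_rho: float = 1.35
    total_area: float = 50_000.0
    noise_sigma_frac: float = 0.02
    poisson: bool = False
    raman_amplitude_frac: float = 0.0
    raman_position: float = 433.0
    raman_fwhm: float = 6.0
    baseline: float = 0.0
    wavelengths: np.ndarray = field(default_factory=_default_grid)
    seed: int = 0
    label: str = ""

    def config_hash(self) -> str:
        """Stable short hash of the configuration, for run manifests."""
        text = repr(
            {f: getattr(self, f).tolist() if f == "wavelengths" else getattr(self, f)
             for f in sorted(self.__dataclass_fields__)}
        )
        return hashlib.sha256(text.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class SpectrumTruth:
    """Exact generator parameters behind one synthetic spectrum."""

    blue: LogNormalPeak
    green: LogNormalPeak
    s_b: float
    s_g: float
    delta_s_r: float
    r_s: float
    #: GP of the noiseless two-band sum (artifacts excluded).
    gp: float
    melittin_um: float = 0.0


def generate_spectrum(cfg: SpectrumGeneratorConfig) -> tuple[Spectrum, SpectrumTruth]:
    """One synthetic spectrum plus its truth record (seed-deterministic)."""
    if not 0.0 < cfg.target_s_b < 1.0:
        raise LipidOrderError(f"target S_b must be in (0, 1), got {cfg.target_s_b}")
    if cfg.noise_sigma_frac < 0:
        raise LipidOrderError("noise sigma must be >= 0")
    # amplitudes from target areas at unit-amplitude shape factors
    k_b = peak_area(LogNormalPeak(1.0, cfg.blue_position, cfg.blue_fwhm, cfg.blue_rho))
    k_g = peak_area(LogNormalPeak(1.0, cfg.green_position, cfg.green_fwhm, cfg.green_rho))
    area_b = cfg.target_s_b * cfg.total_area
    area_g = (1.0 - cfg.target_s_b) * cfg.total_area
    blue = LogNormalPeak(area_b / k_b, cfg.blue_position, cfg.blue_fwhm, cfg.blue_rho)
    green = LogNormalPeak(area_g / k_g, cfg.green_position, cfg.green_fwhm, cfg.green_rho)

    lam = np.asarray(cfg.wavelengths, dtype=float)
    clean = evaluate_lognormal(blue, lam) + evaluate_lognormal(green, lam)
    truth_spectrum = Spectrum(lam, clean, label=cfg.label)
    delta_s_r, r_s = derive_parameters(cfg.target_s_b, 1.0 - cfg.target_s_b)
    truth = SpectrumTruth(
        blue=blue,
        green=green,
        s_b=cfg.target_s_b,
        s_g=1.0 - cfg.target_s_b,
        delta_s_r=delta_s_r,
        r_s=r_s,
        gp=compute_gp(truth_spectrum),
    )

    signal = clean + cfg.baseline
    if cfg.raman_amplitude_frac:
        sigma = cfg.raman_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        signal = signal + (
            cfg.raman_amplitude_frac
            * clean.max()
            * np.exp(-0.5 * ((lam - cfg.raman_position) / sigma) ** 2)
        )
    rng = np.random.default_rng(cfg.seed)
    if cfg.poisson:
        signal = rng.poisson(np.clip(signal, 0.0, None)).astype(float)
    if cfg.noise_sigma_frac:
        signal = signal + rng.normal(0.0, cfg.noise_sigma_frac * clean.max(), lam.size)
    signal = np.clip(signal, 0.0, None)  # detectors report nonnegative counts
    return Spectrum(lam, signal, label=cfg.label), truth


@dataclass(frozen=True)
class DoseResponseModel:
    """Saturating dose law for the blue-band fraction.

    ``S_b(c) = S_b0 + ΔS_max · c/(c + K)`` with half-effect concentration
    ``K`` (µM).  ``ΔS_max > 0`` emulates liposome-like stiffening,
    ``ΔS_max < 0`` cell-like fluidization.  The hyperbolic form captures
    the rapid change below ~0.25–0.5 µM followed by a slowing rate; it is
    a modelling choice, not a mechanism claim.
    """

    s_b0: float
    delta_s_max: float
    k_um: float = 0.3
    concentrations: tuple[float, ...] = (0.0, 0.1, 0.25, 0.5, 1.0, 2.5)

    def __post_init__(self) -> None:
        if self.k_um <= 0:
            raise LipidOrderError("half-effect concentration K must be > 0")
        for c in self.concentrations:
            s = self.s_b_at(c)
            if not 0.0 < s < 1.0:
                raise LipidOrderError(
                    f"S_b({c} µM) = {s:.3f} leaves (0, 1); adjust S_b0/ΔS_max"
                )

    def s_b_at(self, c: float) -> float:
        return self.s_b0 + self.delta_s_max * c / (c + self.k_um)


def generate_dose_series(
    model: DoseResponseModel,
    cfg: SpectrumGeneratorConfig,
    system: str = "DOPC LUV",
    temperature_c: float = 37.0,
) -> list[tuple[Spectrum, SpectrumTruth]]:
    """One synthetic spectrum per concentration, labelled ``system;T;c``.

    Each concentration gets its own sub-seed derived from ``cfg.seed`` so
    the series is reproducible yet the noise differs between doses.
    """
    out = []
    for i, c in enumerate(model.concentrations):
        sub = replace(
            cfg,
            target_s_b=model.s_b_at(c),
            seed=(cfg.seed * 1000 + i) % (2**31),
            label=f"{system};{temperature_c};{c}",
        )
        spectrum, truth = generate_spectrum(sub)
        out.append((spectrum, replace(truth, melittin_um=c)))
    return out


#: Dose models and band positions emulating the study's membrane systems at
#: 37 °C: control and highest-dose blue-band fractions with band modes in the
#: printed ranges.  Liposome presets shift blue-ward (ΔS_max > 0), cell
#: presets fluidize (ΔS_max < 0).
SPECTRUM_PRESETS: dict[str, tuple[DoseResponseModel, dict]] = {
    "dopc-luv": (
        DoseResponseModel(0.225, 0.0336),
        dict(blue_position=443.0, green_position=497.0),
    ),
    "dopc-chol-luv": (
        DoseResponseModel(0.41, 0.056),
        dict(blue_position=439.0, green_position=499.0),
    ),
    "dopc-chol-mlv": (
        DoseResponseModel(0.52, 0.0224),
        dict(blue_position=438.0, green_position=500.0),
    ),
    "cell-l929": (
        DoseResponseModel(0.82, -0.2576),
        dict(blue_position=456.0, green_position=511.0, blue_fwhm=55.0, green_fwhm=58.0),
    ),
    "cell-ht29": (
        DoseResponseModel(0.74, -0.0896),
        dict(blue_position=451.0, green_position=506.0, blue_fwhm=55.0, green_fwhm=58.0),
    ),
    "cell-hepg2": (
        DoseResponseModel(0.73, -0.1008),
        dict(blue_position=459.0, green_position=518.0, blue_fwhm=55.0, green_fwhm=58.0),
    ),
    "cell-mg63": (
        DoseResponseModel(0.65, -0.0448),
        dict(blue_position=462.0, green_position=520.0, blue_fwhm=55.0, green_fwhm=58.0),
    ),
}


def preset_series(
    name: str, seed: int = 0
) -> list[tuple[Spectrum, SpectrumTruth]]:
    """Generate the dose series of a named membrane-system preset."""
    if name not in SPECTRUM_PRESETS:
        raise LipidOrderError(
            f"unknown preset {name!r}; available: {sorted(SPECTRUM_PRESETS)}"
        )
    model, band_kwargs = SPECTRUM_PRESETS[name]
    cfg = SpectrumGeneratorConfig(seed=seed, **band_kwargs)
    return generate_dose_series(model, cfg, system=name)


# ---------------------------------------------------------------------------
# bilayer frames
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FrameGeneratorConfig:
    """Parameters of a synthetic planar-bilayer snapshot.

    Bulk lipids sit on a square lattice of spacing ``sqrt(bulk_apl)``
    (0.683 nm² is a fluid-phase PC packing), optionally jittered.  With
    ``channel=True`` a ring of ``n_near`` lipids is packed around a
    cylinder of pseudo-atoms in the box center; ring radii are chosen so
    that the region owned by the ring lipids is exactly a regular
    ``n_near``-gon of per-lipid area ``near_apl`` — the planted
    near-channel packing.  A guard ring of bulk lipids shares the ring
    angles to pin that boundary; the lattice starts far enough out not to
    perturb it.  Waters: ``waters_in_shell`` are planted inside the
    carbonyl shells (one per distinct lipid), the rest in the solvent
    slabs outside the membrane, beyond reach of any shell.
    """

    lipids_per_side: int = 12
    bulk_apl: float = 0.683
    channel: bool = False
    near_apl: float = 0.417
    n_near: int = 20
    channel_radius: float = 0.9
    channel_atom_count: int = 20
    near_ring_offset: float = 0.25
    leaflet_z: float = 1.8
    carbonyl_depth: float = 0.45
    water_cutoff: float = 0.3
    waters_in_shell: int = 7
    waters_bulk: int = 100
    jitter_sigma: float = 0.0
    seed: int = 0

    def config_hash(self) -> str:
        text = repr(
            {f: getattr(self, f) for f in sorted(self.__dataclass_fields__)}
        )
        return hashlib.sha256(text.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class FrameTruth:
    """Planted ground truth of a synthetic frame.

    APL truths are exact partition arithmetic of the construction: the
    near-channel region is a regular polygon of total area
    ``n_near · near_apl`` per leaflet, the rest of the leaflet belongs to
    the bulk group, and the overall mean is ``Lx·Ly / n_lipids``.
    """

    upper_ids: np.ndarray
    lower_ids: np.ndarray
    near_ids: np.ndarray
    overall_apl: float
    near_apl: Optional[float]
    bulk_apl: Optional[float]
    water_count: int
    box: np.ndarray


def generate_frame(cfg: FrameGeneratorConfig) -> tuple[BilayerFrame, FrameTruth]:
    """Build one synthetic bilayer frame plus its truth record."""
    rng = np.random.default_rng(cfg.seed)
    s = float(np.sqrt(cfg.bulk_apl))
    m = cfg.lipids_per_side
    lx = ly = m * s
    lz = 2.0 * cfg.leaflet_z + 2.4
    box = np.array([lx, ly, lz])
    # the channel sits anywhere in the periodic box (it is not pinned to a
    # grid-symmetric point, and analyses must not assume it is)
    center = rng.uniform(0.0, [lx, ly]) if cfg.channel else np.array([lx / 2, ly / 2])

    grid_1d = (np.arange(m) + 0.5) * s
    lattice = np.stack(
        [np.repeat(grid_1d, m), np.tile(grid_1d, m)], axis=1
    )
    jitter_clip = min(3.0 * cfg.jitter_sigma, 0.3 * s)

    def leaflet_xy(leaflet_rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """(xy positions, near mask) for one leaflet."""
        if not cfg.channel:
            jit = leaflet_rng.normal(0.0, cfg.jitter_sigma, lattice.shape)
            xy = lattice + np.clip(jit, -jitter_clip, jitter_clip)
            return xy % np.array([lx, ly]), np.zeros(len(lattice), dtype=bool)
        n = cfg.n_near
        apothem = np.sqrt(cfg.near_apl / np.tan(np.pi / n))
        r1 = cfg.channel_radius + cfg.near_ring_offset
        r2 = 2.0 * apothem - r1
        if r2 <= r1:
            raise LipidOrderError(
                "near_apl too small for the channel radius: guard ring collapses"
            )
        if r2 <= cfg.channel_radius + 2.0 * cfg.near_ring_offset:
            raise LipidOrderError("guard ring would fall inside the near cutoff")
        r_excl = max(
            2.0 * apothem / np.cos(np.pi / n) - r1 + 0.1 + 2.0 * jitter_clip,
            r2 + 0.4 * s,
        )
        if r_excl >= min(lx, ly) / 2.0 - s:
            raise LipidOrderError(
                f"channel region (r={r_excl:.2f} nm) does not fit the "
                f"{lx:.2f} nm box; increase lipids_per_side"
            )
        theta = 2.0 * np.pi * np.arange(n) / n
        box2 = np.array([lx, ly])
        ring1 = (center + r1 * np.stack([np.cos(theta), np.sin(theta)], axis=1)) % box2
        ring2 = (center + r2 * np.stack([np.cos(theta), np.sin(theta)], axis=1)) % box2
        d = lattice - center
        d -= box2 * np.round(d / box2)
        keep = np.linalg.norm(d, axis=1) >= r_excl
        bulk = lattice[keep]
        jit = leaflet_rng.normal(0.0, cfg.jitter_sigma, bulk.shape)
        bulk = (bulk + np.clip(jit, -jitter_clip, jitter_clip)) % np.array([lx, ly])
        xy = np.vstack([ring1, ring2, bulk])
        near = np.zeros(len(xy), dtype=bool)
        near[:n] = True
        return xy, near

    xy_up, near_up = leaflet_xy(rng)
    xy_lo, near_lo = leaflet_xy(rng)
    n_up, n_lo = len(xy_up), len(xy_lo)
    upper_ids = np.arange(1, n_up + 1)
    lower_ids = np.arange(n_up + 1, n_up + n_lo + 1)

    z_head_up = lz / 2.0 + cfg.leaflet_z
    z_head_lo = lz / 2.0 - cfg.leaflet_z
    z_carb_up = lz / 2.0 + (cfg.leaflet_z - cfg.carbonyl_depth)
    z_carb_lo = lz / 2.0 - (cfg.leaflet_z - cfg.carbonyl_depth)

    heads = np.vstack(
        [
            np.column_stack([xy_up, np.full(n_up, z_head_up)]),
            np.column_stack([xy_lo, np.full(n_lo, z_head_lo)]),
        ]
    )
    # four reference atoms in a small cross around the carbonyl point
    offsets = 0.08 * np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0]], dtype=float
    )
    carb_pts = np.vstack(
        [
            np.column_stack([xy_up, np.full(n_up, z_carb_up)]),
            np.column_stack([xy_lo, np.full(n_lo, z_carb_lo)]),
        ]
    )
    carbonyls = (carb_pts[:, None, :] + offsets[None, :, :]) % box

    peptide = None
    near_ids = np.array([], dtype=int)
    if cfg.channel:
        theta = 2.0 * np.pi * np.arange(cfg.channel_atom_count) / cfg.channel_atom_count
        zs = np.linspace(z_head_lo, z_head_up, cfg.channel_atom_count)
        peptide = np.column_stack(
            [
                (center[0] + cfg.channel_radius * np.cos(theta)) % lx,
                (center[1] + cfg.channel_radius * np.sin(theta)) % ly,
                zs,
            ]
        )
        near_ids = np.concatenate([upper_ids[near_up], lower_ids[near_lo]])

    # waters: planted inside carbonyl shells + far solvent
    all_ids = np.concatenate([upper_ids, lower_ids])
    centers = carb_pts  # carbonyl cross is symmetric: its center is carb_pts
    planted = []
    if cfg.waters_in_shell:
        if cfg.waters_in_shell > len(all_ids):
            raise LipidOrderError("cannot plant more shell waters than lipids")
        chosen = rng.choice(len(all_ids), size=cfg.waters_in_shell, replace=False)
        for idx in chosen:
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            radius = rng.uniform(0.05, 0.8 * cfg.water_cutoff)
            planted.append(centers[idx] + radius * direction)
    solvent = []
    if cfg.waters_bulk:
        xy = rng.uniform(0.0, [lx, ly], size=(cfg.waters_bulk, 2))
        margin = 0.5
        z_lo = rng.uniform(0.0, lz / 2.0 - cfg.leaflet_z - margin, cfg.waters_bulk)
        top = rng.random(cfg.waters_bulk) < 0.5
        z = np.where(top, lz - z_lo, z_lo)
        solvent = np.column_stack([xy, z])
    waters = np.vstack([p for p in (planted, solvent) if len(p)]) if (
        len(planted) or len(solvent)
    ) else np.zeros((0, 3))

    frame = BilayerFrame(
        box=box,
        lipid_ids=all_ids,
        heads=heads % box,
        carbonyls=carbonyls,
        waters=waters % box,
        peptide=peptide,
    )
    truth = FrameTruth(
        upper_ids=upper_ids,
        lower_ids=lower_ids,
        near_ids=near_ids,
        overall_apl=lx * ly / n_up,
        near_apl=cfg.near_apl if cfg.channel else None,
        bulk_apl=(
            (lx * ly - cfg.n_near * cfg.near_apl) / (n_up - cfg.n_near)
            if cfg.channel
            else cfg.bulk_apl
        ),
        water_count=len(planted),
        box=box,
    )
    return frame, truth


def generate_frames(
    cfg: FrameGeneratorConfig,
    n_frames: int,
    apl_jitter_sigma: float = 0.0,
) -> list[tuple[BilayerFrame, FrameTruth]]:
    """A sequence of frames; per-frame packing density may itself fluctuate.

    ``apl_jitter_sigma`` draws each frame's bulk APL from
    ``N(bulk_apl, σ)``, emulating the box-area breathing of a
    constant-pressure simulation; each frame gets its own sub-seed.
    """
    rng = np.random.default_rng(cfg.seed)
    out = []
    for i in range(n_frames):
        apl = cfg.bulk_apl
        if apl_jitter_sigma:
            apl = float(rng.normal(cfg.bulk_apl, apl_jitter_sigma))
            if apl <= 0:
                raise LipidOrderError("APL jitter produced a nonpositive density")
        sub = replace(cfg, bulk_apl=apl, seed=(cfg.seed * 10_000 + i + 1) % (2**31))
        out.append(generate_frame(sub))
    return out
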