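"""Synthetic raw-data generators for every pipeline stage.

These generators emulate the statistical structure of the study's raw data so
every analysis stage is testable end-to-end without instrument files:

* seeded-aggregation ThT traces drawn from the generalized logistic model
  with i.i.d. Gaussian replicate noise (normalized convention: plateau = 1;
  an optional raw mode adds a baseline and gain for testing normalization);
* high-seed elongation traces, ``M(t) = 1 - exp(-rho t)``, linear at early
  times with initial slope ``rho``;
* 16-point 1:1.75 serial-dilution saturation-binding titrations;
* diffraction-limited TIRF stacks: immobile Gaussian-PSF spots on a constant
  camera offset plus Gaussian read noise (so frame-averaging raises SNR by
  sqrt(n_frames), as in a pull-down assay);
* super-resolution localization clouds for rod- and disc-shaped aggregates
  with isotropic Gaussian localization error.

Randomness is a single explicit integer seed per call; replicate ``r`` (or
helper draws) uses the sub-stream ``seed + r`` so outputs are byte-identical
for equal seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .binding import BindingCurve
from .exceptions import InvalidInputError
from .imaging import DEFAULT_PIXEL_NM, ImageStack, LocalizationTable
from .kinetics import ThTTrace, fibril_mass

__all__ = [
    "KineticGroundTruth",
    "SpotGroundTruth",
    "ShapeGroundTruth",
    "gen_tht_traces",
    "gen_elongation_traces",
    "gen_binding_curve",
    "gen_tirf_stack",
    "gen_localizations",
    "gen_spot_counts",
    "random_spot_positions",
    "default_time_grid",
]


# ---------------------------------------------------------------------------
# ground-truth descriptors
# ---------------------------------------------------------------------------


@dataclass
class KineticGroundTruth:
    """True parameters behind a set of simulated low-seed ThT replicates.

    Defaults reflect a typical low-seed secondary-nucleation assay: 40 uM
    monomer, half-time of ~3 h on a 0-2000 min time course, three technical
    replicates and 2% (normalized units) plate-reader noise.
    """

    a: float = 50.0
    kappa: float = 0.02  # per minute
    c: float = 0.3
    m_tot: float = 40.0  # uM
    r_plus: float = 0.002  # effective elongation rate 2 k+ m_tot (per minute)
    noise_sd: float = 0.02
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.kappa <= 0 or not (0 < self.c <= 1):
            raise InvalidInputError("require a > 0, kappa > 0, 0 < c <= 1")
        if self.noise_sd < 0 or self.n_replicates < 1:
            raise InvalidInputError("require noise_sd >= 0 and n_replicates >= 1")


@dataclass
class SpotGroundTruth:
    """Planted spots of one simulated SiMPull field of view."""

    positions: np.ndarray  # (n, 2) sub-pixel (row, col)
    psf_sigma: float = 1.4  # pixels
    amplitude: float = 200.0
    background: float = 100.0
    read_noise_sd: float = 20.0
    n_frames: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 2)
        if self.psf_sigma <= 0 or self.n_frames < 1:
            raise InvalidInputError("require psf_sigma > 0 and n_frames >= 1")


@dataclass
class ShapeGroundTruth:
    """A rod- or disc-shaped aggregate to be sampled as localizations."""

    kind: str = "rod"  # 'rod' | 'disc'
    length_nm: float = 200.0
    diameter_nm: float = 300.0
    n_localizations: int = 500
    precision_nm: float = 20.0
    seed: int = 0
    center_nm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.kind not in ("rod", "disc"):
            raise InvalidInputError("kind must be 'rod' or 'disc'")
        if self.kind == "rod" and self.length_nm <= 0:
            raise InvalidInputError("rod length must be positive")
        if self.kind == "disc" and self.diameter_nm <= 0:
            raise InvalidInputError("disc diameter must be positive")
        if self.n_localizations < 10 or self.precision_nm < 0:
            raise InvalidInputError("require n_localizations >= 10, precision >= 0")


# ---------------------------------------------------------------------------
# kinetics
# ---------------------------------------------------------------------------


def default_time_grid(t_end: float = 2000.0, dt: float = 2.0) -> np.ndarray:
    """Plate-reader-like time grid in minutes, starting at 0."""
    return np.arange(0.0, t_end + dt / 2, dt)


def _check_grid(t_grid: np.ndarray) -> np.ndarray:
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size < 2 or not np.all(np.diff(t) > 0):
        raise InvalidInputError("t_grid must be 1-D and strictly increasing")
    if abs(t[0]) > 1e-12:
        raise InvalidInputError("t_grid must start at 0")
    return t


def gen_tht_traces(
    truth: KineticGroundTruth,
    t_grid: np.ndarray,
    condition: str = "control",
    raw_baseline: float | None = None,
    raw_gain: float | None = None,
) -> list[ThTTrace]:
    """Simulate low-seed ThT replicates from the generalized logistic model.

    Normalized mode (default): signal = M(t) + N(0, noise_sd) per sample.
    Raw mode (both ``raw_baseline`` and ``raw_gain`` given): signal =
    baseline + gain * (M(t) + noise), for exercising trace normalization.
    """
    t = _check_grid(t_grid)
    raw_mode = raw_baseline is not None or raw_gain is not None
    if raw_mode and (raw_baseline is None or raw_gain is None):
        raise InvalidInputError("raw mode needs both raw_baseline and raw_gain")
    clean = fibril_mass(t, truth.a, truth.kappa, truth.c)
    traces = []
    for r in range(truth.n_replicates):
        rng = np.random.default_rng(truth.seed + r)
        sig = clean + rng.normal(0.0, truth.noise_sd, size=t.size)
        if raw_mode:
            sig = raw_baseline + raw_gain * sig
        traces.append(
            ThTTrace(
                time=t.copy(),
                signal=sig,
                condition=condition,
                seed_fraction=0.06,
                m_tot=truth.m_tot,
                replicate=r,
                normalized=not raw_mode,
            )
        )
    return traces


def gen_elongation_traces(
    slope: float = 0.002,
    t_grid: np.ndarray | None = None,
    noise_sd: float = 0.005,
    n_replicates: int = 3,
    seed: int = 0,
    condition: str = "control",
    m_tot: float = 40.0,
) -> list[ThTTrace]:
    """Simulate normalized high-seed (elongation-only) traces.

    The noiseless curve is ``M(t) = 1 - exp(-slope * t)``: saturating growth
    whose initial derivative equals ``slope``, as for a heavily seeded
    reaction sampled once per minute.
    """
    if slope <= 0:
        raise InvalidInputError("slope must be positive")
    t = _check_grid(default_time_grid(60.0, 1.0) if t_grid is None else t_grid)
    clean = 1.0 - np.exp(-slope * t)
    traces = []
    for r in range(n_replicates):
        rng = np.random.default_rng(seed + r)
        sig = clean + rng.normal(0.0, noise_sd, size=t.size)
        traces.append(
            ThTTrace(
                time=t.copy(),
                signal=sig,
                condition=condition,
                seed_fraction=15.0,
                m_tot=m_tot,
                replicate=r,
                normalized=True,
            )
        )
    return traces


# ---------------------------------------------------------------------------
# binding
# ---------------------------------------------------------------------------


def gen_binding_curve(
    kd: float = 1.0,
    bmax: float = 10.0,
    top_conc: float = 100.0,
    n_points: int = 16,
    dilution: float = 1.75,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> BindingCurve:
    """Simulate a serial-dilution saturation-binding titration.

    Concentrations form the descending geometric series
    ``top_conc * dilution**(-i)`` for i = 0..n_points-1 (default: 16 points,
    1:1.75 dilution); responses follow ``B_Max * x / (K_D + x)`` plus
    Gaussian noise.
    """
    if kd <= 0:
        raise InvalidInputError("kd must be positive")
    if dilution <= 1:
        raise InvalidInputError("dilution ratio must exceed 1")
    if n_points < 4:
        raise InvalidInputError("need at least 4 titration points")
    x = top_conc * dilution ** (-np.arange(n_points, dtype=float))
    y = bmax * x / (kd + x)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, size=n_points)
    return BindingCurve(x=x, y=y)


# ---------------------------------------------------------------------------
# imaging
# ---------------------------------------------------------------------------


def random_spot_positions(
    n_spots: int,
    shape: tuple[int, int] = (512, 512),
    seed: int = 0,
    margin: float = 10.0,
    min_separation: float = 5.0,
) -> np.ndarray:
    """Uniform sub-pixel spot positions with a minimum mutual separation.

    Single-molecule pull-down fields are sparse by design, so the default
    keeps planted spots at least 5 px apart (rejection sampling).
    """
    rng = np.random.default_rng(seed)
    pos: list[np.ndarray] = []
    attempts = 0
    while len(pos) < n_spots:
        cand = np.array(
            [
                rng.uniform(margin, shape[0] - margin),
                rng.uniform(margin, shape[1] - margin),
            ]
        )
        if all(np.linalg.norm(cand - p) >= min_separation for p in pos):
            pos.append(cand)
        attempts += 1
        if attempts > 1000 * max(n_spots, 1):
            raise InvalidInputError("cannot place spots at this density")
    return np.array(pos)


def gen_tirf_stack(
    truth: SpotGroundTruth, shape: tuple[int, int] = (512, 512)
) -> ImageStack:
    """Simulate a TIRF stack: immobile Gaussian spots + offset + read noise."""
    if shape[0] < 64 or shape[1] < 64:
        raise InvalidInputError("frame must be at least 64 x 64")
    pos = truth.positions
    if pos.size and (
        pos.min() < 0 or pos[:, 0].max() >= shape[0] or pos[:, 1].max() >= shape[1]
    ):
        raise InvalidInputError("spot positions must lie within the frame")
    base = np.full(shape, truth.background, dtype=float)
    half = int(np.ceil(5 * truth.psf_sigma))
    for r0, c0 in pos:
        r_lo, r_hi = max(0, int(r0) - half), min(shape[0], int(r0) + half + 1)
        c_lo, c_hi = max(0, int(c0) - half), min(shape[1], int(c0) + half + 1)
        rr = np.arange(r_lo, r_hi)[:, None]
        cc = np.arange(c_lo, c_hi)[None, :]
        base[r_lo:r_hi, c_lo:c_hi] += truth.amplitude * np.exp(
            -((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * truth.psf_sigma**2)
        )
    rng = np.random.default_rng(truth.seed)
    if truth.read_noise_sd > 0:
        frames = base + rng.normal(
            0.0, truth.read_noise_sd, size=(truth.n_frames, *shape)
        )
    else:
        frames = np.broadcast_to(base, (truth.n_frames, *shape)).copy()
    return ImageStack(
        frames=frames,
        pixel_nm=DEFAULT_PIXEL_NM,
        exposure_ms=50.0,
        metadata={"n_true_spots": int(pos.shape[0]), "seed": truth.seed},
    )


def gen_spot_counts(
    mean: float, sd: float, n_fields: int, seed: int = 0
) -> np.ndarray:
    """Simulate spots-per-field-of-view counts (truncated-normal, >= 0)."""
    if n_fields < 1 or sd < 0:
        raise InvalidInputError("require n_fields >= 1 and sd >= 0")
    rng = np.random.default_rng(seed)
    return np.clip(np.round(rng.normal(mean, sd, size=n_fields)), 0, None)


# ---------------------------------------------------------------------------
# localizations
# ---------------------------------------------------------------------------


def gen_localizations(truth: ShapeGroundTruth) -> LocalizationTable:
    """Sample a localization cloud for one rod- or disc-shaped aggregate.

    Rods: points uniform along a segment of the stated end-to-end length at a
    random orientation; discs: uniform over the disc. Each point is jittered
    by isotropic Gaussian localization error of s.d. ``precision_nm``.
    """
    rng = np.random.default_rng(truth.seed)
    n = truth.n_localizations
    cx, cy = truth.center_nm
    if truth.kind == "rod":
        theta = rng.uniform(0.0, np.pi)
        s = rng.uniform(-truth.length_nm / 2, truth.length_nm / 2, size=n)
        x = cx + s * np.cos(theta)
        y = cy + s * np.sin(theta)
    else:
        radius = truth.diameter_nm / 2
        r = radius * np.sqrt(rng.uniform(0.0, 1.0, size=n))
        phi = rng.uniform(0.0, 2 * np.pi, size=n)
        x = cx + r * np.cos(phi)
        y = cy + r * np.sin(phi)
    if truth.precision_nm > 0:
        x = x + rng.normal(0.0, truth.precision_nm, size=n)
        y = y + rng.normal(0.0, truth.precision_nm, size=n)
    return LocalizationTable(
        x_nm=x,
        y_nm=y,
        frame=np.arange(n),
        intensity=rng.uniform(500.0, 2000.0, size=n),
    )
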