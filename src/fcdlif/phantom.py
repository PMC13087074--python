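"""Synthetic dynamic-PET phantoms with known ground-truth input functions.

The generator places ellipsoidal "organs" on a voxel grid.  A blood-pool
ellipsoid carries the (frame-averaged) arterial input function; every other
organ carries a tissue time-activity curve produced by the irreversible
two-tissue compartment model driven by that input function.  Per-frame
Poisson count noise reproduces the duration-dependent signal-to-noise of
real framing: expected counts are value x duration x noise_scale, so short
early frames come out visibly noisier than the long late frames.

The ground-truth AIF is a Feng-style tri-exponential: a sharp bolus peak
(linear rise times fast decay) plus two slower washout exponentials.  The
defaults emulate an FDG bolus in a mouse — peak around SUV 10 shortly after
arrival, tail near SUV 1 decaying over hours.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .formats_io import (
    BloodCurve,
    DynamicPETImage,
    FrameSchedule,
    canonical_schedule,
)

#: Grid used for desk-scale experiments; the canonical 96x48x48 grid is a
#: spec knob, not a separate code path.
REDUCED_SHAPE: tuple[int, int, int] = (32, 16, 16)


@dataclass(frozen=True)
class AIFParams:
    """Tri-exponential arterial input function parameters.

    C(t) = (A1*tau - A2 - A3) e^{-l1 tau} + A2 e^{-l2 tau} + A3 e^{-l3 tau}
    with tau = t - t0 and C = 0 before the arrival delay t0.  A1 is in
    SUV/s, A2 and A3 in SUV, decay rates in 1/s with l1 > l2 > l3 > 0.
    """

    A1: float = 1.6
    A2: float = 1.5
    A3: float = 0.85
    l1: float = 0.05
    l2: float = 0.01
    l3: float = 1.0e-4
    t0: float = 5.0

    def __post_init__(self) -> None:
        if not (self.l1 > self.l2 > self.l3 > 0):
            raise ValueError("decay rates must satisfy l1 > l2 > l3 > 0")
        if self.A2 < 0 or self.A3 < 0:
            raise ValueError("A2 and A3 must be non-negative")
        if self.t0 < 0:
            raise ValueError("arrival delay t0 must be non-negative")


@dataclass(frozen=True)
class KineticParams:
    """Irreversible two-tissue compartment rates.

    K1 in mL/cm^3/min, k2..k4 in 1/min, vB the fractional blood volume.
    k4 must be 0 (irreversible model).
    """

    K1: float
    k2: float
    k3: float
    k4: float = 0.0
    vB: float = 0.0

    def __post_init__(self) -> None:
        for name in ("K1", "k2", "k3", "k4"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.k4 != 0.0:
            raise ValueError("irreversible model requires k4 = 0")
        if not 0.0 <= self.vB <= 1.0:
            raise ValueError("vB must lie in [0, 1]")

    @property
    def Ki(self) -> float:
        """Net influx rate K1*k3/(k2+k3), per minute."""
        if self.k2 + self.k3 == 0:
            return 0.0
        return self.K1 * self.k3 / (self.k2 + self.k3)


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid in voxel coordinates: center and semi-axes."""

    center: tuple[float, float, float]
    axes: tuple[float, float, float]

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        grids = np.ogrid[: shape[0], : shape[1], : shape[2]]
        r = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, self.center, self.axes))
        return r <= 1.0


@dataclass(frozen=True)
class Organ:
    name: str
    region: Ellipsoid
    kinetics: KineticParams


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic scan: geometry, kinetics, dose, noise."""

    grid_shape: tuple[int, int, int] = REDUCED_SHAPE
    spacing: tuple[float, float, float] = (0.8, 0.8, 0.8)
    blood_pool: Ellipsoid = Ellipsoid(center=(10.0, 8.0, 8.0), axes=(3.0, 2.5, 2.5))
    organs: tuple[Organ, ...] = ()
    background: KineticParams | None = None
    aif: AIFParams = AIFParams()
    body_weight_g: float = 25.0
    injected_dose_kBq: float = 8000.0
    noise_scale: float = 0.0
    schedule: FrameSchedule = field(default_factory=canonical_schedule)

    def __post_init__(self) -> None:
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        for organ in self.organs:
            c, a = organ.region.center, organ.region.axes
            for ci, ai, n in zip(c, a, self.grid_shape):
                if ci - ai < -0.5 or ci + ai > n - 0.5:
                    raise ValueError(f"organ {organ.name!r} extends outside the grid")


def default_phantom_spec(
    grid_shape: tuple[int, int, int] = REDUCED_SHAPE,
    noise_scale: float = 0.0,
    aif: AIFParams | None = None,
    schedule: FrameSchedule | None = None,
) -> PhantomSpec:
    """A mouse-like phantom: blood pool, myocardium-like and brain-like organs.

    Kinetic defaults are plausible FDG values for mouse myocardium
    (K1 0.7, k2 1.2, k3 0.1), brain (K1 0.15, k2 0.25, k3 0.05) and a soft
    low-uptake background.
    """
    d, h, w = grid_shape
    organs = (
        Organ(
            "myocardium",
            Ellipsoid(center=(d * 0.31, h * 0.5, w * 0.22), axes=(d * 0.07, h * 0.16, w * 0.14)),
            KineticParams(K1=0.7, k2=1.2, k3=0.1, vB=0.1),
        ),
        Organ(
            "brain",
            Ellipsoid(center=(d * 0.09, h * 0.5, w * 0.5), axes=(d * 0.07, h * 0.18, w * 0.18)),
            KineticParams(K1=0.15, k2=0.25, k3=0.05, vB=0.04),
        ),
        Organ(
            "liver",
            Ellipsoid(center=(d * 0.55, h * 0.5, w * 0.55), axes=(d * 0.1, h * 0.25, w * 0.25)),
            KineticParams(K1=0.45, k2=0.7, k3=0.01, vB=0.08),
        ),
    )
    blood = Ellipsoid(center=(d * 0.31, h * 0.5, w * 0.6), axes=(d * 0.06, h * 0.14, w * 0.14))
    return PhantomSpec(
        grid_shape=grid_shape,
        blood_pool=blood,
        organs=organs,
        background=KineticParams(K1=0.05, k2=0.3, k3=0.005, vB=0.02),
        aif=aif if aif is not None else AIFParams(),
        noise_scale=noise_scale,
        schedule=schedule if schedule is not None else canonical_schedule(),
    )


# ---------------------------------------------------------------------------
# Ground-truth curves
# ---------------------------------------------------------------------------

def aif_model(params: AIFParams, t: np.ndarray | float) -> np.ndarray:
    """Evaluate the tri-exponential input function at times t (seconds)."""
    t = np.asarray(t, dtype=float)
    tau = t - params.t0
    c = np.where(
        tau < 0,
        0.0,
        (params.A1 * tau - params.A2 - params.A3) * np.exp(-params.l1 * np.maximum(tau, 0.0))
        + params.A2 * np.exp(-params.l2 * np.maximum(tau, 0.0))
        + params.A3 * np.exp(-params.l3 * np.maximum(tau, 0.0)),
    )
    return c if c.ndim else float(c)


def simulate_2tcm(
    params: KineticParams,
    plasma: Callable[[np.ndarray], np.ndarray],
    t_grid: np.ndarray,
    whole_blood: Callable[[np.ndarray], np.ndarray] | None = None,
) -> np.ndarray:
    """Tissue concentration of the irreversible two-tissue compartment model.

    Solves dC1/dt = K1*Cp - (k2+k3)*C1, dC2/dt = k3*C1 (rates converted
    from per-minute to per-second) and returns
    (1 - vB)(C1 + C2) + vB * Cwb on ``t_grid``.  ``whole_blood`` defaults
    to the plasma function.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be 1-D and strictly increasing")
    if whole_blood is None:
        whole_blood = plasma

    K1 = params.K1 / 60.0
    k23 = (params.k2 + params.k3) / 60.0
    k3 = params.k3 / 60.0

    t0 = min(0.0, t_grid[0])
    if params.K1 == 0.0:
        c1 = np.zeros_like(t_grid)
        c2 = np.zeros_like(t_grid)
    else:
        def rhs(t, y):
            cp = float(plasma(t))
            return [K1 * cp - k23 * y[0], k3 * y[0]]

        sol = solve_ivp(
            rhs,
            (t0, float(t_grid[-1])),
            [0.0, 0.0],
            t_eval=t_grid,
            method="LSODA",
            rtol=1e-9,
            atol=1e-12,
            max_step=10.0,
        )
        if not sol.success:  # pragma: no cover - LSODA is robust on this linear system
            raise RuntimeError(f"compartment ODE solve failed: {sol.message}")
        c1, c2 = sol.y
    tissue = (1.0 - params.vB) * (c1 + c2)
    if params.vB > 0:
        tissue = tissue + params.vB * np.asarray(whole_blood(t_grid), dtype=float)
    return tissue


def frame_average(
    func: Callable[[np.ndarray], np.ndarray],
    schedule: FrameSchedule,
    points_per_frame: int = 129,
    kind: str = "whole-blood",
) -> BloodCurve:
    """Average a continuous curve over each acquisition frame.

    Uses composite trapezoid quadrature with ``points_per_frame`` samples
    per frame (relative error well below 0.1% for bolus-like curves);
    the result is a BloodCurve sampled at frame midpoints.
    """
    values = np.empty(schedule.n_frames)
    for i, (s, d) in enumerate(zip(schedule.starts, schedule.durations)):
        ts = np.linspace(s, s + d, points_per_frame)
        values[i] = np.trapezoid(np.asarray(func(ts), dtype=float), ts) / d
    return BloodCurve(times=schedule.midpoints, values=values, kind=kind)


# ---------------------------------------------------------------------------
# Image synthesis
# ---------------------------------------------------------------------------

def _tissue_curve(
    kinetics: KineticParams, aif: AIFParams, schedule: FrameSchedule
) -> BloodCurve:
    """Frame-averaged 2TCM tissue TAC driven by the analytic input function."""
    end = schedule.end_time
    dense_t = np.linspace(0.0, end, max(int(end * 2), 512))
    plasma = lambda t: aif_model(aif, t)  # noqa: E731 - ratio 1 inside the phantom
    tissue_dense = simulate_2tcm(kinetics, plasma, dense_t)

    def interp(t):
        return np.interp(t, dense_t, tissue_dense)

    return frame_average(interp, schedule)


def generate_phantom(
    spec: PhantomSpec, seed: int
) -> tuple[DynamicPETImage, BloodCurve, dict]:
    """Render a phantom scan.

    Returns the dynamic image, the ground-truth (frame-averaged, whole-blood)
    input function, and a mask dict with an integer ``labels`` volume plus a
    ``names`` mapping and the generator ``seed``.

    Regions are painted background first, then organs in listed order, then
    the blood pool; overlapping organ ellipsoids trigger a warning and the
    later region wins.
    """
    rng = np.random.default_rng(seed)
    schedule = spec.schedule
    T = schedule.n_frames
    shape = spec.grid_shape

    aif_frames = frame_average(lambda t: aif_model(spec.aif, t), schedule)

    image = np.zeros((T,) + tuple(shape), dtype=np.float64)
    labels = np.zeros(shape, dtype=np.int16)
    names: dict[int, str] = {0: "background"}

    if spec.background is not None and spec.background.K1 + spec.background.vB > 0:
        bg = _tissue_curve(spec.background, spec.aif, schedule)
        image += bg.values[:, None, None, None]

    claimed = np.zeros(shape, dtype=bool)
    regions: list[tuple[str, np.ndarray, BloodCurve]] = []
    for organ in spec.organs:
        regions.append((organ.name, organ.region.mask(shape), _tissue_curve(organ.kinetics, spec.aif, schedule)))
    regions.append(("blood_pool", spec.blood_pool.mask(shape), aif_frames))

    for idx, (name, mask, curve) in enumerate(regions, start=1):
        if np.any(mask & claimed):
            warnings.warn(
                f"region {name!r} overlaps a previously placed region; last writer wins",
                stacklevel=2,
            )
        claimed |= mask
        image[:, mask] = curve.values[:, None]
        labels[mask] = idx
        names[idx] = name

    if spec.noise_scale > 0:
        scale = spec.noise_scale * schedule.durations[:, None, None, None]
        lam = np.clip(image, 0.0, None) * scale
        image = rng.poisson(lam).astype(np.float64) / scale

    pet = DynamicPETImage(values=image.astype(np.float32), schedule=schedule, spacing=spec.spacing)
    masks = {"labels": labels, "names": names, "seed": int(seed)}
    return pet, aif_frames, masks


def sample_spec(base: PhantomSpec, rng: np.random.Generator) -> PhantomSpec:
    """Randomly perturb a phantom spec to emulate inter-animal variability.

    Input-function amplitudes, decay rates and arrival delay, and every
    organ's rate constants, are jittered multiplicatively by ~±30%, the
    range of variation seen across healthy adult mice.
    """
    def jitter(x, lo=0.7, hi=1.3):
        return float(x * rng.uniform(lo, hi))

    aif = base.aif
    new_aif = AIFParams(
        A1=jitter(aif.A1),
        A2=jitter(aif.A2),
        A3=jitter(aif.A3),
        l1=jitter(aif.l1),
        l2=jitter(aif.l2),
        l3=jitter(aif.l3),
        t0=float(rng.uniform(0.0, 15.0)),
    )
    new_organs = tuple(
        Organ(
            o.name,
            o.region,
            KineticParams(
                K1=jitter(o.kinetics.K1),
                k2=jitter(o.kinetics.k2),
                k3=jitter(o.kinetics.k3),
                vB=min(1.0, jitter(o.kinetics.vB)),
            ),
        )
        for o in base.organs
    )
    return replace(base, aif=new_aif, organs=new_organs)


def sample_dataset(
    n: int,
    seed: int,
    base: PhantomSpec | None = None,
) -> list[tuple[DynamicPETImage, BloodCurve]]:
    """Generate ``n`` phantoms with randomized physiology; deterministic per seed."""
    if base is None:
        base = default_phantom_spec()
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        spec = sample_spec(base, rng)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        image, aif, _ = generate_phantom(spec, seed=sub_seed)
        out.append((image, aif))
    return out
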