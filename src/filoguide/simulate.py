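"""Stochastic simulation of neurite tips advancing on (swallowtail) gratings.

Each neurite is a polyline anchored at a soma.  The tip advances in discrete
time steps ``dt`` at a fixed extension speed; its heading follows a biased
persistent random walk

    theta[t+dt] = theta[t] + omega_t + lambda * (beta*_t - theta[t])

(all angles in degrees, measured in the local grating frame), where
``omega_t ~ N(0, sigma_omega**2)`` is the intrinsic turning noise and the
deterministic relaxation pulls the heading toward the current limit angle
``beta*_t`` delivered by the growth-cone/ridge contact classification:
unambiguous in case 2, drawn at random between the two candidates in case 1
(the symmetric left/right possibility), absent without contact.  The gain

    lambda = (1 - f(r_w, r_d)) * (1 - exp(-xi * dt))

combines the guidance-strength constant ``xi`` (default 75 per hour) with
the decoupling factor ``f`` of the analytic model, so a flat substrate
(``f = 1``) degenerates to a pure Gaussian random walk of the heading.

Neurites start at length 11.38 um (the flat-substrate initial length) with a
heading drawn from a truncated Laplacian around the grating axis, then
undergo extension/retraction cycles: each phase runs until the length
crosses a target drawn from N(18.98, 2.65) um, retraction following the
stored path backwards.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .grating import (Grating, GrowthConeDisk, SwallowtailGrating, Surface,
                      classify_contact)
from .guidance import GuidanceParams, f_ridge

__all__ = [
    "SimParams",
    "Neurite",
    "Population",
    "InteractionSettings",
    "TurningRule",
    "SwallowtailOutcome",
    "SwallowtailResult",
    "initial_direction",
    "guidance_term",
    "step_tip",
    "grow_neurite",
    "run_population",
    "simulate_swallowtail",
    "neurite_rngs",
    "trajectories_frame",
    "write_swc",
]

#: Calibrated default of the per-step Gaussian turning noise (degrees).
SIGMA_OMEGA_DEFAULT = 5.0
#: Calibrated default scale of the truncated-Laplacian initial heading (deg).
LAPLACE_SCALE_DEFAULT = 25.0


@dataclass(frozen=True)
class SimParams:
    """All constants of the tip-advance model (lengths um, times h)."""

    dt: float = 0.05
    v_ext: float = 20.0
    v_ret: float = 20.0
    initial_length: float = 11.38
    target_mean: float = 18.98
    target_sd: float = 2.65
    sigma_omega: float = SIGMA_OMEGA_DEFAULT
    laplace_scale: float = LAPLACE_SCALE_DEFAULT
    laplace_interval: tuple[float, float] = (-30.0, 30.0)
    cycle_counter: int = 240          # cap on steps per phase (12 h default)
    soma_diameter: float = 10.0
    seed: int = 0
    guidance: GuidanceParams = field(default_factory=GuidanceParams)

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.v_ext <= 0:
            raise ValueError("dt and v_ext must be positive")
        if self.v_ret < 0 or self.sigma_omega < 0 or self.laplace_scale < 0:
            raise ValueError("v_ret, sigma_omega, laplace_scale must be >= 0")
        if self.initial_length < 0:
            raise ValueError("initial_length must be non-negative")
        lo, hi = self.laplace_interval
        if not lo < 0 < hi:
            raise ValueError("laplace_interval must straddle 0")


def initial_direction(rng: np.random.Generator, params: SimParams) -> float:
    """Initial heading offset from the grating axis (degrees).

    Zero-mode Laplacian truncated to ``params.laplace_interval``, sampled by
    inverse CDF so a fixed generator state yields a fixed draw.  A zero
    scale degenerates to the mode (the grating axis).
    """
    b = params.laplace_scale
    if b == 0.0:
        rng.random()  # keep the stream aligned with the b > 0 path
        return 0.0
    lo, hi = params.laplace_interval
    u = rng.random()
    # inverse CDF of the symmetric truncated Laplace distribution
    mass_lo = 0.5 * math.exp(lo / b)            # F(lo), lo < 0
    mass_hi = 1.0 - 0.5 * math.exp(-hi / b)     # F(hi)
    q = mass_lo + u * (mass_hi - mass_lo)
    if q < 0.5:
        return b * math.log(2.0 * q)
    return -b * math.log(2.0 * (1.0 - q))


def _wrap180(angle: float) -> float:
    return (angle + 180.0) % 360.0 - 180.0


def _local_grating(surface: Surface, point) -> Grating:
    if isinstance(surface, Grating):
        return surface
    return surface.local_grating(point)


def _guidance_from_u(heading_deg: float, tip, surface: Surface,
                     params: SimParams, u: float) -> float:
    """Deterministic core of the guidance term given the uniform draw ``u``.

    Mirror-equivariant: reflecting the whole configuration across the
    grating axis and replacing ``u`` by ``1 - u`` (antithetic coupling)
    negates the returned contribution.
    """
    g = _local_grating(surface, tip)
    if g.is_flat:
        return 0.0
    f = f_ridge(g.ridge_width, g.ridge_depth, params.guidance)
    lam = (1.0 - f) * (1.0 - math.exp(-params.guidance.xi * params.dt))
    if lam == 0.0:
        return 0.0
    contact = classify_contact(
        GrowthConeDisk(tuple(tip), params.guidance.r_bar), g)
    if contact.case == "no_contact":
        return 0.0
    if contact.case == "case1":
        beta = contact.candidates[0] if u < 0.5 else contact.candidates[1]
    else:
        beta = contact.candidates[0]
    theta_loc = _wrap180(heading_deg - g.angle_deg)
    return lam * (beta - theta_loc)


def guidance_term(heading_deg: float, tip, surface: Surface,
                  params: SimParams, rng: np.random.Generator) -> float:
    """Topographic turning contribution (degrees) for one step.

    Case 2 uses the unambiguous limit angle; case 1 chooses uniformly at
    random between the two candidates; no contact (or a flat substrate)
    contributes nothing.
    """
    return _guidance_from_u(heading_deg, tip, surface, params, rng.random())


Phase = Literal["extending", "retracting", "stalled"]


@dataclass
class Neurite:
    """A growing neurite: soma anchor, current polyline, tip time series."""

    soma: tuple[float, float]
    rng: np.random.Generator
    points: list[np.ndarray]
    heading_deg: float
    target_length: float
    phase: Phase = "extending"
    length: float = 0.0
    phase_steps: int = 0
    t: float = 0.0
    history: list[tuple[float, float, float, str]] = field(default_factory=list)
    # swallowtail bookkeeping
    crossed_branch: bool = False
    turned: bool | None = None
    branch: str | None = None
    approach_angle: float | None = None

    @property
    def tip(self) -> np.ndarray:
        return self.points[-1]

    def path_points(self) -> np.ndarray:
        return np.asarray(self.points)

    def record(self) -> None:
        self.history.append((self.t, float(self.tip[0]), float(self.tip[1]),
                             self.phase))


def _draw_target(neurite: Neurite, params: SimParams) -> float:
    t = neurite.rng.normal(params.target_mean, params.target_sd)
    return max(t, 1.0)


def _spawn_neurite(soma, surface: Surface, params: SimParams,
                   rng: np.random.Generator) -> Neurite:
    axis = _local_grating(surface, soma).angle_deg
    heading = axis + initial_direction(rng, params)
    e = np.array([math.cos(math.radians(heading)),
                  math.sin(math.radians(heading))])
    root = np.asarray(soma, dtype=float) + 0.5 * params.soma_diameter * e
    n = Neurite(soma=tuple(soma), rng=rng,
                points=[root, root + params.initial_length * e],
                heading_deg=heading, target_length=0.0,
                length=params.initial_length)
    n.target_length = _draw_target(n, params)
    if n.target_length <= n.length:
        n.phase = "retracting"
    n.record()
    return n


def step_tip(neurite: Neurite, surface: Surface, params: SimParams,
             rng: np.random.Generator | None = None) -> Neurite:
    """Advance the tip by one extension step of length ``v_ext * dt``.

    The new heading combines the previous heading, Gaussian turning noise
    and the topographic guidance term; the displacement magnitude is exactly
    ``v_ext * dt``.
    """
    rng = rng if rng is not None else neurite.rng
    omega = rng.normal(0.0, params.sigma_omega)
    g = guidance_term(neurite.heading_deg, neurite.tip, surface, params, rng)
    neurite.heading_deg = neurite.heading_deg + omega + g
    a = math.radians(neurite.heading_deg)
    step = params.v_ext * params.dt * np.array([math.cos(a), math.sin(a)])
    neurite.points.append(neurite.tip + step)
    neurite.length += params.v_ext * params.dt
    return neurite


def _retract(neurite: Neurite, params: SimParams) -> None:
    """Retract along the stored path by ``v_ret * dt``."""
    remaining = params.v_ret * params.dt
    while remaining > 0.0 and len(neurite.points) > 2:
        seg = neurite.points[-1] - neurite.points[-2]
        seg_len = float(np.hypot(*seg))
        if seg_len <= remaining + 1e-12:
            neurite.points.pop()
            neurite.length -= seg_len
            remaining -= seg_len
        else:
            neurite.points[-1] = neurite.points[-1] - seg * (remaining / seg_len)
            neurite.length -= remaining
            remaining = 0.0
    seg = neurite.points[-1] - neurite.points[-2]
    if np.hypot(*seg) > 1e-12:
        neurite.heading_deg = math.degrees(math.atan2(seg[1], seg[0]))


def _switch_phase(neurite: Neurite, params: SimParams) -> None:
    hit = (neurite.length >= neurite.target_length
           if neurite.phase == "extending"
           else neurite.length <= neurite.target_length)
    if hit or neurite.phase_steps >= params.cycle_counter:
        neurite.target_length = _draw_target(neurite, params)
        neurite.phase = ("retracting"
                         if neurite.target_length < neurite.length
                         else "extending")
        neurite.phase_steps = 0


def _advance(neurite: Neurite, surface: Surface, params: SimParams) -> None:
    if neurite.phase == "stalled":
        neurite.t += params.dt
        neurite.record()
        return
    if neurite.phase == "extending":
        step_tip(neurite, surface, params)
    else:
        _retract(neurite, params)
    neurite.t += params.dt
    neurite.phase_steps += 1
    _switch_phase(neurite, params)
    neurite.record()


def neurite_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Independent per-neurite generators derived from one root seed.

    Derived by spawning, so enlarging a population never perturbs the
    streams of the existing neurites.
    """
    return [np.random.default_rng(s)
            for s in np.random.SeedSequence(seed).spawn(n)]


def grow_neurite(soma, surface: Surface, params: SimParams, duration: float,
                 rng: np.random.Generator | None = None) -> Neurite:
    """Grow a single neurite for ``duration`` hours and return it."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = rng if rng is not None else neurite_rngs(params.seed, 1)[0]
    n = _spawn_neurite(soma, surface, params, rng)
    for _ in range(round(duration / params.dt)):
        _advance(n, surface, params)
    return n


@dataclass(frozen=True)
class InteractionSettings:
    """Minimal cell-cell interaction model.

    ``repulsion`` displaces tip pairs closer than ``contact_distance`` back
    to exactly that distance (hard core, prevents overlap); ``attraction``
    biases the headings of nearby, roughly parallel tips toward each other
    (fasciculation via adhesion), bounded by ``max_turn_deg`` per step.
    """

    repulsion: bool = False
    attraction: bool = False
    contact_distance: float = 1.0
    attraction_range: float = 3.0
    attraction_strength: float = 0.3
    max_turn_deg: float = 2.0
    parallel_tol_deg: float = 45.0


@dataclass
class Population:
    """Somata with their neurites, advanced concurrently in lockstep."""

    somata: list[tuple[float, float]]
    interactions: InteractionSettings = field(default_factory=InteractionSettings)
    neurites: list[Neurite] = field(default_factory=list)


def _apply_repulsion(pop: Population) -> None:
    d0 = pop.interactions.contact_distance
    tips = [n for n in pop.neurites if n.phase != "stalled"]
    for i in range(len(tips)):
        for j in range(i + 1, len(tips)):
            delta = tips[j].tip - tips[i].tip
            dist = float(np.hypot(*delta))
            if 0.0 < dist < d0:
                push = 0.5 * (d0 - dist) * delta / dist
                tips[i].points[-1] = tips[i].tip - push
                tips[j].points[-1] = tips[j].tip + push


def _apply_attraction(pop: Population) -> None:
    s = pop.interactions
    tips = [n for n in pop.neurites if n.phase == "extending"]
    new_headings = []
    for n in tips:
        best, best_d = None, s.attraction_range
        for m in tips:
            if m is n:
                continue
            d = float(np.hypot(*(m.tip - n.tip)))
            if d < best_d and abs(_wrap180(m.heading_deg - n.heading_deg)) \
                    <= s.parallel_tol_deg:
                best, best_d = m, d
        if best is None:
            new_headings.append(n.heading_deg)
            continue
        bearing = math.degrees(math.atan2(*(best.tip - n.tip)[::-1]))
        turn = s.attraction_strength * _wrap180(bearing - n.heading_deg)
        turn = max(-s.max_turn_deg, min(s.max_turn_deg, turn))
        new_headings.append(n.heading_deg + turn)
    for n, h in zip(tips, new_headings):
        n.heading_deg = h


def run_population(pop: Population, surface: Surface, params: SimParams,
                   duration: float) -> Population:
    """Advance all neurites in lockstep ``dt`` with pairwise interactions.

    With interactions disabled the trajectories are identical to
    independent :func:`grow_neurite` runs using the same per-neurite
    streams (:func:`neurite_rngs`).
    """
    if not pop.somata:
        raise ValueError("population requires at least one soma")
    rngs = neurite_rngs(params.seed, len(pop.somata))
    pop.neurites = [_spawn_neurite(s, surface, params, r)
                    for s, r in zip(pop.somata, rngs)]

    def interact() -> None:
        if pop.interactions.attraction:
            _apply_attraction(pop)
        if pop.interactions.repulsion:
            _apply_repulsion(pop)
            for n in pop.neurites:   # history reflects corrected tips
                n.history[-1] = (n.t, float(n.tip[0]), float(n.tip[1]),
                                 n.phase)

    interact()
    for _ in range(round(duration / params.dt)):
        for n in pop.neurites:
            _advance(n, surface, params)
        interact()
    return pop


@dataclass(frozen=True)
class TurningRule:
    """Approach-angle turning rule at a swallowtail bifurcation.

    The probability of turning is a logistic fall-off in the approach angle
    ``alpha`` between the tip heading and the branch ridge border:
    ``p = 1 / (1 + exp((alpha - alpha50) / width))``.  Defaults calibrated
    once against the reference turning fractions (docs/methods.md).
    """

    alpha50: float = 61.0
    width: float = 16.0

    def probability(self, alpha_deg: float) -> float:
        return 1.0 / (1.0 + math.exp((alpha_deg - self.alpha50) / self.width))


@dataclass(frozen=True)
class SwallowtailOutcome:
    reached: bool
    turned: bool | None
    branch: str | None
    approach_angle: float | None
    final_position: tuple[float, float]


class SwallowtailResult(dict):
    """Per-axon outcomes plus the turning fraction among reaching axons."""

    def __init__(self, outcomes: Sequence[SwallowtailOutcome], phi_deg: float):
        reached = [o for o in outcomes if o.reached]
        turned = sum(1 for o in reached if o.turned)
        super().__init__(
            phi_deg=phi_deg,
            n_cells=len(outcomes),
            n_reached=len(reached),
            n_turned=turned,
            turning_fraction=(turned / len(reached)) if reached else float("nan"),
        )
        self.outcomes = list(outcomes)

    @property
    def turning_fraction(self) -> float:
        return self["turning_fraction"]


def _maybe_classify_crossing(n: Neurite, surface: SwallowtailGrating,
                             rule: TurningRule) -> None:
    if n.crossed_branch or n.phase == "stalled":
        return
    region = surface.region(n.tip)
    if region == "trunk":
        return
    n.crossed_branch = True
    n.branch = region
    branch_axis = (surface.upper if region == "upper"
                   else surface.lower).angle_deg
    n.approach_angle = abs(_wrap180(n.heading_deg - branch_axis))
    n.turned = bool(n.rng.random() < rule.probability(n.approach_angle))
    if not n.turned:
        n.phase = "stalled"  # failed axons stop in proximity of the corner


def simulate_swallowtail(n_cells: int, phi_deg: float, params: SimParams,
                         duration: float = 24.0,
                         rule: TurningRule | None = None,
                         soma_offset: float = 22.0,
                         spread_periods: int = 20) -> SwallowtailResult:
    """Beam-splitting experiment: axons approaching a swallowtail branch.

    ``n_cells`` somata are placed ``soma_offset`` um upstream of the branch
    line, laterally scattered over ``spread_periods`` grating periods.  Each
    axon that reaches the branch region is classified as turned (it follows
    a branch direction) or stalled at the corner, via ``rule``.
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    rule = rule or TurningRule()
    trunk = Grating(0.5, 0.5, 0.25)
    surface = SwallowtailGrating(trunk, phi_deg)
    rngs = neurite_rngs(params.seed, n_cells + 1)
    placer, rngs = rngs[0], rngs[1:]
    span = spread_periods * trunk.period
    neurites = []
    for rng in rngs:
        soma = (-soma_offset, float(placer.uniform(-span / 2, span / 2)))
        neurites.append(_spawn_neurite(soma, surface, params, rng))
    for n in neurites:
        _maybe_classify_crossing(n, surface, rule)
    for _ in range(round(duration / params.dt)):
        for n in neurites:
            _advance(n, surface, params)
            _maybe_classify_crossing(n, surface, rule)
    outcomes = [
        SwallowtailOutcome(n.crossed_branch, n.turned, n.branch,
                           n.approach_angle,
                           (float(n.tip[0]), float(n.tip[1])))
        for n in neurites
    ]
    return SwallowtailResult(outcomes, phi_deg)


def trajectories_frame(neurites: Sequence[Neurite]) -> pd.DataFrame:
    """Tip time series of a set of neurites as a tidy table."""
    rows = []
    for i, n in enumerate(neurites):
        for t, x, y, phase in n.history:
            rows.append((i, t, x, y, phase))
    return pd.DataFrame(rows, columns=["neurite_id", "t_h", "x_um", "y_um",
                                       "phase"])


def write_swc(neurite: Neurite, path, radius: float = 0.5) -> None:
    """Write the current morphology as a single-tree SWC file.

    Soma as type 1, neurite points as type 2, planar points with z = 0.
    """
    lines = ["# SWC export (um); soma sample then neurite polyline"]
    sx, sy = neurite.soma
    lines.append(f"1 1 {sx:.6f} {sy:.6f} 0.0 5.0 -1")
    for k, p in enumerate(neurite.points, start=2):
        lines.append(f"{k} 2 {p[0]:.6f} {p[1]:.6f} 0.0 {radius} {k - 1}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
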