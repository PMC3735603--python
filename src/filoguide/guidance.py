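"""Analytic model of mean neurite alignment on a nanograting.

The model predicts the mean unsigned angle ``beta_mean`` between outgrowing
neurites and the grating axis from the grating geometry and the growth-cone
radius.  Its ingredients:

* the *limit angle* of a filopodium through a K-type ridge-edge point at
  lateral offset ``d`` on the disk boundary, ``beta_lim = arcsin(d/r_bar)``;
* the geometric angle set by the stable on-ridge filopodium, whose lateral
  reach is a fraction ``a`` of the ridge width and whose along-axis reach is
  the median K-point height ``h_tilde``:  ``beta_geom = arctan(a*r_w /
  h_tilde)``;
* a dimensionless decoupling factor ``f(r_w, r_d) = exp(-eps * r_d / r_w)``
  measuring how much of the unguided (flat-substrate) behaviour survives:
  ``f = 1`` on flat substrates, and ``f`` decays as ridges get deeper
  relative to their width.  ``eps`` is the single fitted parameter.

The mean alignment interpolates between the unguided limit (90 deg, no
preferred direction) and the geometric angle::

    beta_mean = 90 * f + beta_geom * (1 - f)        [degrees]

This form is monotone non-decreasing in ridge width, non-increasing in
ridge depth, reaches the flat limit both for ``r_d -> 0`` and for
``r_w -> inf`` (the vertical asymptote of the inverse design problem), and
collapses to 0 for narrow, deep ridges.

``h_tilde`` is approximated once per grating by quadrature over uniform
disk placements across one period (the distribution of simulated K-point
heights); see :func:`median_intersection_height`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy import optimize

from .grating import Grating

__all__ = [
    "GuidanceParams",
    "EpsilonFit",
    "limit_angle",
    "f_ridge",
    "mean_beta",
    "median_intersection_height",
    "ridge_width_for_alignment",
    "fit_epsilon",
]

#: Default guidance-strength constant (per hour) of the tip-advance rule.
XI_DEFAULT = 75.0

#: Shipped default for the fitted decoupling parameter ``eps``.  Set once by
#: the period-1 calibration described in docs/methods.md.
EPSILON_DEFAULT = 8.0

_H_TILDE_SEED = 20130806  # fixed stream for the h_tilde approximation
_H_TILDE_DRAWS = 100_000


@dataclass(frozen=True)
class GuidanceParams:
    """Parameters of the analytic guidance model.

    Parameters
    ----------
    epsilon
        Dimensionless decoupling parameter of ``f``; fitted to alignment
        data (larger = stronger depth effect).
    a
        Fraction of the ridge width locating the stable filopodium's
        lateral reach ``h* = a * r_w``; in (0, 1].
    h_tilde
        Median K-point height (um).  ``None`` means: approximate it from
        the grating geometry at evaluation time.
    r_bar
        Growth-cone disk radius (um).
    xi
        Guidance-strength constant of the stochastic tip-advance rule
        (1/h); kept here because it belongs to the same calibrated family.
    """

    epsilon: float = EPSILON_DEFAULT
    a: float = 0.5
    h_tilde: float | None = None
    r_bar: float = 1.14
    xi: float = XI_DEFAULT

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if not 0.0 < self.a <= 1.0:
            raise ValueError("a must lie in (0, 1]")
        if self.h_tilde is not None and not 0.0 < self.h_tilde <= self.r_bar:
            raise ValueError("h_tilde must lie in (0, r_bar]")
        if self.xi <= 0:
            raise ValueError("xi must be positive")


def limit_angle(edge_offset: float, radius: float) -> float:
    """Limit angle (degrees) of the filopodium through a K point.

    Angle between the grating axis and the segment from the disk centre to
    the ridge-edge point at lateral offset ``edge_offset`` on the disk
    boundary: ``arcsin(d / radius)``; monotone increasing in ``d``.
    """
    if edge_offset < 0:
        raise ValueError("edge offset must be non-negative")
    if edge_offset > radius:
        raise ValueError(
            f"no K point: edge offset {edge_offset} exceeds radius {radius}"
        )
    return math.degrees(math.asin(edge_offset / radius))


def f_ridge(ridge_width: float, ridge_depth: float,
            params: GuidanceParams) -> float:
    """Decoupling factor ``f = exp(-eps * r_d / r_w)`` (dimensionless).

    Continuous in both arguments; 1 on flat substrates, strictly decreasing
    in ridge depth and increasing in ridge width.  It weights how much of
    the unguided behaviour survives the topographic constraint.
    """
    if ridge_width <= 0:
        raise ValueError("ridge_width must be positive")
    if ridge_depth < 0:
        raise ValueError("ridge_depth must be non-negative")
    return math.exp(-params.epsilon * ridge_depth / ridge_width)


_h_tilde_cache: dict[tuple, float] = {}


def median_intersection_height(grating: Grating,
                               r_bar: float = 1.14,
                               n_draws: int = _H_TILDE_DRAWS) -> float:
    """Median K-point height ``h_tilde`` (um) for uniform disk placements.

    The disk centre is placed uniformly across one grating period
    (``n_draws`` fixed-stream draws); for every placement the lateral
    offsets of all ridge edges within one radius are collected and
    converted to heights ``h = sqrt(r_bar**2 - d**2)``.  The median of the
    pooled heights is returned.  Deterministic: the underlying uniform
    stream is fixed, so the value is a reproducible function of the
    geometry alone.
    """
    key = (round(grating.ridge_width, 9), round(grating.groove_width, 9),
           round(r_bar, 9), n_draws)
    if key in _h_tilde_cache:
        return _h_tilde_cache[key]
    rng = np.random.default_rng(_H_TILDE_SEED)
    c = rng.random(n_draws) * grating.period
    rw, gw = grating.ridge_width, grating.groove_width
    on_ridge = c <= rw
    # in-ridge placements: offsets to both ridge borders
    d_ridge = np.concatenate([c[on_ridge], rw - c[on_ridge]])
    # in-groove placements: offsets to the facing edges of both neighbours
    off = c[~on_ridge] - rw
    d_groove = np.concatenate([off, gw - off])
    d = np.concatenate([d_ridge, d_groove])
    d = d[d <= r_bar]
    if d.size == 0:
        # grooves so wide the disk sees no edge from anywhere: no K points
        h = float(r_bar)
    else:
        h = float(np.median(np.sqrt(r_bar * r_bar - d * d)))
    _h_tilde_cache[key] = h
    return h


def _resolved_h_tilde(grating: Grating, params: GuidanceParams) -> float:
    if params.h_tilde is not None:
        return params.h_tilde
    return median_intersection_height(grating, params.r_bar)


def mean_beta(grating: Grating, params: GuidanceParams) -> float:
    """Mean alignment angle ``beta_mean`` (degrees) for a grating.

    ``90*f + arctan(a*r_w/h_tilde)*(1-f)``: the flat substrate (``r_d = 0``,
    ``f = 1``) is the unguided limit of 90 deg; narrow deep ridges drive
    the angle toward 0.
    """
    if grating.is_flat:
        return 90.0
    f = f_ridge(grating.ridge_width, grating.ridge_depth, params)
    h = _resolved_h_tilde(grating, params)
    beta_geom = math.degrees(math.atan2(params.a * grating.ridge_width, h))
    return 90.0 * f + beta_geom * (1.0 - f)


def _beta_of_width(r_w: float, r_d: float, params: GuidanceParams,
                   groove_width: float) -> float:
    return mean_beta(Grating(r_w, groove_width, r_d), params)


def ridge_width_for_alignment(beta_target: float, ridge_depth: float,
                              params: GuidanceParams,
                              groove_width: float = 0.5) -> float:
    """Invert the model: the ridge width achieving a given mean alignment.

    ``beta_mean`` is strictly increasing in ridge width at fixed positive
    depth, so the inverse is found by monotone root bracketing.  The
    attainable range is the open interval (0, 90) deg; the flat limit is a
    vertical asymptote (``r_w -> inf`` as ``beta_target -> 90``).
    """
    if ridge_depth <= 0:
        raise ValueError("ridge_depth must be positive for the inversion")
    if not 0.0 < beta_target < 90.0:
        raise ValueError(
            f"beta_target {beta_target} outside the attainable open interval "
            "(0, 90) degrees"
        )
    lo, hi = 1e-4, 1.0
    while _beta_of_width(hi, ridge_depth, params, groove_width) < beta_target:
        hi *= 2.0
        if hi > 1e7:
            raise ValueError(
                f"beta_target {beta_target} not attainable below r_w = 1e7 um "
                "(vertical-asymptote regime)"
            )
    while _beta_of_width(lo, ridge_depth, params, groove_width) > beta_target:
        lo *= 0.5
        if lo < 1e-12:
            raise ValueError(f"beta_target {beta_target} below attainable range")
    return float(optimize.brentq(
        lambda w: _beta_of_width(w, ridge_depth, params, groove_width)
        - beta_target,
        lo, hi, xtol=1e-12, rtol=8.9e-16, maxiter=200,
    ))


class EpsilonFit(NamedTuple):
    """Least-squares fit of the decoupling parameter."""

    epsilon: float
    residuals: np.ndarray      # beta_model - beta_obs, degrees
    sse: float
    r_squared: float           # square of corr(observed, predicted)
    params: GuidanceParams


def fit_epsilon(observations: Iterable[Sequence[float]],
                params: GuidanceParams | None = None,
                groove_width: float = 0.5) -> EpsilonFit:
    """Fit ``eps`` to observed mean alignments by least squares.

    Parameters
    ----------
    observations
        Rows ``(ridge_width_um, ridge_depth_um, beta_deg)`` with angles in
        (0, 90) degrees.
    params
        Template supplying ``a``, ``r_bar`` etc.; its ``epsilon`` is
        ignored.

    Bounded 1-D minimisation of the sum of squared angle residuals over
    ``eps`` in [1e-4, 1e4], restarted from three log-spaced sub-brackets.
    Reports R^2 as the squared correlation between observed and predicted
    angles (NaN when fewer than two observations).
    """
    obs = np.atleast_2d(np.asarray(list(observations), dtype=float))
    if obs.size == 0:
        raise ValueError("fit_epsilon requires at least one observation")
    if obs.shape[1] != 3:
        raise ValueError("observations must be (r_w, r_d, beta_deg) rows")
    if np.any((obs[:, 2] <= 0) | (obs[:, 2] >= 90)):
        raise ValueError("observed angles must lie strictly in (0, 90) deg")
    geom = obs[:, :2]
    if len(obs) > 1 and np.all(np.all(geom == geom[0], axis=1)) \
            and not np.allclose(obs[:, 2], obs[0, 2]):
        raise ValueError(
            "degenerate input: identical geometries with conflicting angles"
        )
    template = params or GuidanceParams()

    def predict(eps: float) -> np.ndarray:
        p = replace(template, epsilon=eps)
        return np.array([
            _beta_of_width(rw, rd, p, groove_width) for rw, rd in geom
        ])

    def sse(log_eps: float) -> float:
        r = predict(math.exp(log_eps)) - obs[:, 2]
        return float(r @ r)

    lo, hi = math.log(1e-4), math.log(1e4)
    edges = np.linspace(lo, hi, 4)
    best = None
    for a, b in zip(edges[:-1], edges[1:]):
        res = optimize.minimize_scalar(
            sse, bounds=(a, b), method="bounded",
            options={"xatol": 1e-12},
        )
        if best is None or res.fun < best.fun:
            best = res
    eps = float(math.exp(best.x))
    fitted = replace(template, epsilon=eps)
    pred = predict(eps)
    resid = pred - obs[:, 2]
    if len(obs) >= 2 and np.std(obs[:, 2]) > 0 and np.std(pred) > 0:
        r2 = float(np.corrcoef(obs[:, 2], pred)[0, 1] ** 2)
    else:
        r2 = float("nan")
    return EpsilonFit(eps, resid, float(resid @ resid), r2, fitted)
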