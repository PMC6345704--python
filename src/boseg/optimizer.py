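"""Local minimization of the cost functional with graduated relaxation.

Within one relaxation scale the minimizer is a gradient descent whose step
length comes from a parabolic line fit: the functional is close to
quadratic near a minimum, so three cost samples along the negative
gradient locate the line minimum in one shot; a backtracking fallback
guarantees descent when the fit is unreliable.  Scales are chained coarse
to fine — the minimizer found at scale s seeds the search at s * s_r —
which steers the search past shallow minima of the unsmoothed functional.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "RelaxationSchedule",
    "DescentSettings",
    "parabolic_step",
    "minimize_at_scale",
    "gradual_relaxation",
]


@dataclass(frozen=True)
class RelaxationSchedule:
    """Geometric coarse-to-fine schedule of the relaxation scale s."""

    s0: float = 1.0
    s_r: float = 0.5
    s_m: float = 0.1

    def __post_init__(self) -> None:
        if not (self.s0 >= self.s_m > 0):
            raise ValueError("need s0 >= s_m > 0")
        if not (0 < self.s_r < 1):
            raise ValueError("need 0 < s_r < 1")

    def scales(self) -> list[float]:
        """All scale values visited: s0, s0*s_r, ... down to the first <= s_m."""
        out = [self.s0]
        while out[-1] > self.s_m:
            out.append(out[-1] * self.s_r)
        return out


@dataclass(frozen=True)
class DescentSettings:
    max_iter: int = 500
    tol: float = 1e-6           # relative cost decrease
    tol_streak: int = 3         # consecutive below-tol iterations to stop
    step_init: float = 1.0
    step_growth: float = 2.0
    max_backtracks: int = 25
    grad_floor: float = 1e-12

    def __post_init__(self) -> None:
        for name in ("max_iter", "tol", "tol_streak", "step_init", "step_growth",
                     "max_backtracks", "grad_floor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def parabolic_step(cost_fn, b, grad, cost_b=None, step=1.0, settings=None):
    """One descent step along -grad with a parabolic line fit.

    Samples the cost at steps t and 2t, fits a parabola through the three
    values and jumps to its vertex if that lowers the cost; otherwise takes
    the best sampled point, halving t as needed.  Returns
    (b_next, cost_next, step_next, ok); ``ok`` is False when no descent
    point was found (step failure), in which case b is returned unchanged.
    """
    settings = settings or DescentSettings()
    f0 = cost_fn(b) if cost_b is None else cost_b
    gnorm = float(np.sqrt(np.sum(grad**2)))
    if gnorm <= settings.grad_floor:
        return b, f0, step, True
    d = -grad
    t = step
    for _ in range(settings.max_backtracks):
        f1 = cost_fn(b + t * d)
        f2 = cost_fn(b + 2.0 * t * d)
        if np.isfinite(f1) and np.isfinite(f2):
            # parabola through (0, f0), (t, f1), (2t, f2)
            denom = f2 - 2.0 * f1 + f0
            best_t, best_f = min(((t, f1), (2.0 * t, f2)), key=lambda p: p[1])
            if denom > 0:
                t_star = t * (3.0 * f0 - 4.0 * f1 + f2) / (2.0 * denom)
                # moderate extrapolation bound; the vertex is only accepted
                # after an explicit cost evaluation confirms it descends
                if 0 < t_star <= 6.0 * t:
                    f_star = cost_fn(b + t_star * d)
                    if np.isfinite(f_star) and f_star < best_f:
                        best_t, best_f = t_star, f_star
            if best_f < f0:
                return b + best_t * d, best_f, best_t, True
        t *= 0.5
    return b, f0, t, False


def minimize_at_scale(cost_and_grad, b0, settings=None, cost_fn=None):
    """Iterate parabolic steps until the relative cost decrease stays below
    tolerance for ``tol_streak`` consecutive iterations (or max_iter).

    ``cost_and_grad(b) -> (cost, grad)``; ``cost_fn`` defaults to the cost
    part of it.  Returns (b_star, cost_star, info) with a non-increasing
    cost sequence; info['converged'] is False on a persistent step failure.
    """
    settings = settings or DescentSettings()
    if cost_fn is None:
        cost_fn = lambda b: cost_and_grad(b)[0]
    b = np.asarray(b0, dtype=float)
    f, g = cost_and_grad(b)
    step = settings.step_init
    streak = 0
    info = {"iterations": 0, "converged": True}
    for it in range(settings.max_iter):
        if float(np.sqrt(np.sum(g**2))) <= settings.grad_floor:
            break
        b_next, f_next, step, ok = parabolic_step(cost_fn, b, g, cost_b=f,
                                                  step=step, settings=settings)
        if not ok:
            logger.warning("step failure after %d iterations (cost %.6g)", it, f)
            info["converged"] = False
            break
        rel = (f - f_next) / max(abs(f), 1e-300)
        b = b_next
        f, g = cost_and_grad(b)
        info["iterations"] = it + 1
        streak = streak + 1 if rel < settings.tol else 0
        if streak >= settings.tol_streak:
            break
        step *= settings.step_growth  # optimistic growth; next fit shrinks it
    return b, f, info


def gradual_relaxation(objective, b_init, schedule=None, settings=None,
                       final_settings=None):
    """Chain minimizations from coarse to fine relaxation scale.

    ``objective.at_scale(s)`` must return an engine with ``cost(b)`` and
    ``cost_and_grad(b)``.  The minimizer at each scale seeds the next; the
    returned cost is evaluated at the finest scale.  ``final_settings``,
    when given, replaces ``settings`` for the last (finest) pass — used to
    polish converged interpretations beyond the budget of the coarse
    passes.
    """
    schedule = schedule or RelaxationSchedule()
    settings = settings or DescentSettings()
    b = np.asarray(b_init, dtype=float)
    f = np.inf
    info_all = []
    scales = schedule.scales()
    for i, s in enumerate(scales):
        st = final_settings if (final_settings and i == len(scales) - 1) else settings
        eng = objective.at_scale(s)
        b, f, info = minimize_at_scale(eng.cost_and_grad, b, st, eng.cost)
        info["scale"] = s
        info_all.append(info)
        logger.info("scale %.4g: cost %.6g after %d iterations", s, f, info["iterations"])
    return b, f, info_all
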