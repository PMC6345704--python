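"""Enumerating image interpretations as multiple local minima.

Each local minimum of the cost functional is one self-consistent reading
of the image (which regions are objects, which side owns each boundary).
To find several, an inverse-distance "repulsive particle" is planted at
every minimum already found: restarting the relaxation from the *same*
random initial map, the augmented functional pushes the search out of the
known basin; the point it reaches is then re-relaxed without repulsion to
land on a genuine minimum of the pure functional.  Minima closer than a
distance threshold to a known one are duplicates; each duplicate escalates
the repulsion strength by a factor tau until tau_max ends the search.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .bo_core import bo_distance, random_init
from .cost import CostEngine, ModelParams, ScaleMultipliers, edge_responses
from .optimizer import DescentSettings, RelaxationSchedule, gradual_relaxation

logger = logging.getLogger(__name__)

__all__ = [
    "RepulsionSettings",
    "Interpretation",
    "ImageObjective",
    "repulsion_term",
    "find_interpretations",
    "classify_illusory",
]


@dataclass(frozen=True)
class RepulsionSettings:
    rho: float = 2e-3          # base particle strength
    d_t: float = 0.03          # distance threshold separating interpretations
    tau: float = 4.0           # escalation factor on a duplicate
    tau_max: float = 4.0       # stop once the factor would exceed this
    eps_rep: float = 0.01      # regularizer; keeps the potential finite
    max_interpretations: int = 4
    max_cost_excess: float = 0.2   # drop minima this far (relative) above the best

    def __post_init__(self) -> None:
        if self.rho <= 0 or self.d_t <= 0 or self.eps_rep <= 0:
            raise ValueError("rho, d_t and eps_rep must be positive")
        if not (1 < self.tau <= self.tau_max):
            raise ValueError("need 1 < tau <= tau_max")
        if self.max_interpretations < 1:
            raise ValueError("max_interpretations must be >= 1")


@dataclass
class Interpretation:
    """A converged BO map with its pure (repulsion-free) final-scale cost."""

    bo_map: np.ndarray
    cost: float
    rank: int = 0
    provenance: dict = field(default_factory=dict)


def repulsion_term(b, particles, factor, settings: RepulsionSettings) -> float:
    """Inverse-distance potential of the stored particles at map b."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    return factor * settings.rho * sum(
        1.0 / (bo_distance(b, p) + settings.eps_rep) for p in particles
    )


class ImageObjective:
    """Cost-engine factory for one image: ``at_scale(s)`` -> CostEngine."""

    def __init__(self, image, params: ModelParams,
                 multipliers: ScaleMultipliers | None = None):
        self.image = np.asarray(image, dtype=float)
        self.params = params
        self.multipliers = multipliers or ScaleMultipliers()
        self._cache: dict[float, CostEngine] = {}

    @property
    def dims(self):
        return self.image.shape + (self.params.L,)

    def at_scale(self, s: float) -> CostEngine:
        if s not in self._cache:
            self._cache[s] = CostEngine(self.image, self.params, s, self.multipliers)
        return self._cache[s]

    def signature(self, b: np.ndarray):
        """Ownership reading of a map: dominant direction at each image edge.

        An interpretation, in this model's sense, is an assignment of
        ownership to the image's boundaries.  Local minima frequently come
        in micro-variants (the boundary ring sitting on either flank of a
        two-pixel intensity step, corners rounded differently) that encode
        the SAME reading; no distance on raw or smoothed maps separates
        those variants from genuine ownership flips, but the dominant
        ownership direction at the image's edge sites does.  Returns
        (dominant direction index per edge site, edge-site mask).
        """
        from .bo_core import smooth_bo

        e = smooth_bo(b, self.params.sigma_sa, self.params.sigma_sx) ** 2
        A = np.abs(edge_responses(self.image, self.params.sigma_a,
                                  self.params.L)).max(axis=2)
        mask = A > 0.5 * A.max()
        sub = e[mask]
        return sub.argmax(axis=1), sub.max(axis=1)

    def same_reading(self, sig1, sig2, angle_tol=None, frac_tol=0.2) -> bool:
        """Two readings match when the dominant ownership agrees (within
        +-60 deg) on at least 1 - frac_tol of the jointly supported edge
        mass (sites where either map holds little ownership carry little
        weight: their argmax is noise, not a reading)."""
        L = self.params.L
        tol = L // 4 if angle_tol is None else angle_tol
        dom1, s1 = sig1
        dom2, s2 = sig2
        d = np.abs((dom1 - dom2 + L // 2) % L - L // 2)
        w = np.minimum(s1, s2)
        total = float(w.sum())
        if total == 0:
            return True
        return float(w[d >= tol].sum() / total) < frac_tol

    def canonical(self, b: np.ndarray) -> np.ndarray:
        """Representation used to compare interpretations: a smoothed map.

        The functional consumes only the smoothed map, so raw maps of the
        same reading can differ in cost-invisible high-frequency detail —
        which flank of a two-pixel intensity step carries the mass, how a
        corner is rounded.  Comparing maps smoothed with twice the model's
        spatial width collapses such one-pixel rearrangements while
        ownership flips (direction-index differences) remain fully
        separated, since spatial smoothing never mixes directions.
        """
        from .bo_core import smooth_bo

        return smooth_bo(b, self.params.sigma_sa, 2.0 * self.params.sigma_sx)


class _Repulsed:
    """Objective augmented with the repulsive-particle potential.

    Distances to particles are measured on the canonical (smoothed)
    representation when the base objective provides one: in raw map space
    a search can satisfy the repulsion by drifting along directions the
    smoothing annihilates, escaping the particle without ever changing
    the interpretation it encodes.
    """

    def __init__(self, base, particles, factor, settings: RepulsionSettings):
        self.base = base
        self.canonical = getattr(base, "canonical", lambda b: b)
        self.particles = [self.canonical(np.asarray(p)) for p in particles]
        self.factor = factor
        self.settings = settings

    def at_scale(self, s):
        return _RepulsedEngine(self.base.at_scale(s), self.particles,
                               self.factor, self.settings, self.canonical)


class _RepulsedEngine:
    def __init__(self, engine, canon_particles, factor, settings, canonical):
        self.engine = engine
        self.particles = canon_particles
        self.factor = factor
        self.settings = settings
        self.canonical = canonical

    def cost(self, b):
        return self.engine.cost(b) + repulsion_term(
            self.canonical(b), self.particles, self.factor, self.settings)

    def cost_and_grad(self, b):
        f, g = self.engine.cost_and_grad(b)
        st = self.settings
        c = self.canonical(b)
        T = c.size
        rep = 0.0
        gacc = np.zeros_like(c)
        for p in self.particles:
            diff = c**2 - p**2
            d = float(np.abs(diff).mean()) + st.eps_rep
            rep += self.factor * st.rho / d
            # d/dc of 1/(dist+eps): -(dist+eps)^-2 * (2/T) * sign(diff) * c
            gacc -= self.factor * st.rho / d**2 * (2.0 / T) * np.sign(diff) * c
        if self.particles:
            # chain through the (self-adjoint) canonical smoothing
            g = g + self.canonical(gacc)
        return f + rep, g


def find_interpretations(objective, seed: int,
                         schedule: RelaxationSchedule | None = None,
                         settings: DescentSettings | None = None,
                         repulsion: RepulsionSettings | None = None,
                         dims=None,
                         final_settings: DescentSettings | None = None) -> list[Interpretation]:
    """Find multiple local minima of the objective, ranked by pure cost.

    The search protocol: relax from the fixed random start to the first
    minimum; then repeatedly (1) relax from the same start under repulsion
    from all accepted minima (plus any rejected intermediate points of the
    current escalation round), (2) re-relax the result without repulsion,
    (3) accept it if it is farther than d_t from every accepted minimum,
    resetting the repulsion factor, else escalate the factor by tau.  The
    search stops when the factor would exceed tau_max without a new
    minimum, or at the interpretation cap.
    """
    schedule = schedule or RelaxationSchedule()
    settings = settings or DescentSettings()
    final_settings = final_settings or DescentSettings(max_iter=800, tol=1e-8)
    rep = repulsion or RepulsionSettings()
    dims = dims if dims is not None else objective.dims
    canonical = getattr(objective, "canonical", lambda b: b)
    if hasattr(objective, "signature"):
        sig_of = objective.signature
        same = objective.same_reading
    else:
        sig_of = canonical
        same = lambda c1, c2: bo_distance(c1, c2) <= rep.d_t
    b_r = random_init(dims, seed)

    b1, f1, _ = gradual_relaxation(objective, b_r, schedule, settings, final_settings)
    accepted = [Interpretation(b1, f1, provenance={"seed": seed, "round": 0})]
    sigs = [sig_of(b1)]
    factor = 1.0
    auxiliary: list[np.ndarray] = []   # rejected landing points, current round only
    round_no = 0
    while len(accepted) < rep.max_interpretations:
        round_no += 1
        repulsed = _Repulsed(objective, [a.bo_map for a in accepted] + auxiliary,
                             factor, rep)
        b_prime, _, _ = gradual_relaxation(repulsed, b_r, schedule, settings)
        # every cost term is at least quadratic in b, so b = 0 (and any
        # all-but-zero slice) is a stationary saddle; if the repulsion pushed
        # the landing point onto that manifold, nudge it back to the random
        # -init magnitude floor before the repulsion-free descent
        sgn = np.sign(b_prime)
        sgn[sgn == 0] = 1.0
        b_start = sgn * np.maximum(np.abs(b_prime), 0.01)
        # repulsion-free cleanup at the final scale only: re-annealing from
        # the coarsest scale would erase the basin the repulsion just
        # pushed into (coarse smoothing merges the basins)
        fine = RelaxationSchedule(s0=schedule.s_m, s_r=schedule.s_r, s_m=schedule.s_m)
        b_new, f_new, _ = gradual_relaxation(objective, b_start, fine, settings,
                                             final_settings)
        s_new = sig_of(b_new)
        dup = [i for i, s in enumerate(sigs) if same(s_new, s)]
        if not dup:
            accepted.append(Interpretation(
                b_new, f_new,
                provenance={"seed": seed, "round": round_no, "factor": factor}))
            sigs.append(s_new)
            factor = 1.0
            auxiliary = []
            logger.info("accepted interpretation %d (cost %.6g)", len(accepted), f_new)
        else:
            # same reading as a known interpretation; keep the better
            # representative if this descent went deeper
            i = dup[0]
            if f_new < accepted[i].cost:
                accepted[i] = Interpretation(
                    b_new, f_new,
                    provenance={**accepted[i].provenance, "refined_round": round_no})
                sigs[i] = s_new
                logger.info("refined interpretation %d (cost %.6g)", i + 1, f_new)
            auxiliary.append(b_prime)
            factor *= rep.tau
            logger.info("duplicate minimum; escalating repulsion to %.3g", factor)
            if factor > rep.tau_max:
                break
    # a refinement can leave two representatives encoding the same reading;
    # keep only the cheaper of any such pair.  Minima far above the best
    # one are not plausible percepts and are dropped as well.
    accepted.sort(key=lambda a: a.cost)
    best = accepted[0].cost
    sigs = [sig_of(a.bo_map) for a in accepted]
    kept, kept_sigs = [], []
    for a, s in zip(accepted, sigs):
        if best < 0 and (a.cost - best) > rep.max_cost_excess * abs(best):
            # only meaningful against a clearly attained best cost; toy
            # objectives with a zero-cost optimum keep everything
            logger.info("dropped implausible interpretation (cost %.6g)", a.cost)
        elif all(not same(s, ks) for ks in kept_sigs):
            kept.append(a)
            kept_sigs.append(s)
        else:
            logger.info("merged interpretation (cost %.6g) into an equal reading", a.cost)
    for i, a in enumerate(kept):
        a.rank = i + 1
    return kept


def classify_illusory(interp: Interpretation, image, params: ModelParams,
                      fraction_threshold: float = 0.02,
                      edge_quantile: float = 0.1,
                      core_margin: int = 2) -> tuple[bool, float]:
    """Flag interpretations that hold ownership deep inside edge-free regions.

    The smoothed squared map is scored by the fraction of its mass sitting
    in the *core* of the no-edge region: sites whose oriented edge
    response is below ``edge_quantile`` of the image maximum, eroded by
    ``core_margin`` pixels.  The erosion discounts the halo that map
    smoothing spreads around real edges, so a positive score requires
    ownership genuinely bridging a gradient-free gap — the signature of
    an illusory boundary.
    """
    from scipy.ndimage import binary_erosion

    from .bo_core import smooth_bo

    c = smooth_bo(np.asarray(interp.bo_map), params.sigma_sa, params.sigma_sx)
    esite = (c**2).sum(axis=2)
    A = np.abs(edge_responses(image, params.sigma_a, params.L)).max(axis=2)
    core = binary_erosion(A < edge_quantile * A.max(), iterations=core_margin)
    total = float(esite.sum())
    if total == 0:
        return False, 0.0
    score = float(esite[core].sum() / total)
    return score > fraction_threshold, score
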