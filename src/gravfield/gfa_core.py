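"""Gravitation field algorithm (GFA) engine.

GFA is a population-based global/multimodal optimizer inspired by the solar
nebular disk model of planetary formation.  Candidate solutions ("dusts")
carry a *mass* — the objective value, sign-adjusted so that larger is always
better internally.  Each epoch the search domain is divided into *groups*,
the best dust of a group becomes its stationary *centre dust*, every other
group member moves straight toward the centre by a pace proportional to its
distance (pace = M * dis, with the golden-section weight M = 0.0618 by
default), and once a group has contracted (or become overcrowded) its
surrounding dusts are *absorbed*: deleted, leaving only the centre to seed
the next epoch.  Absorbed-group survivors are archived, which is what makes
top-k multimodal search possible.

The module exposes both the object-level operations (``move_dust``,
``update_centre``, ``absorb`` on :class:`Dust`/:class:`Group`) that define
the algorithm's semantics, and a vectorized epoch engine (``run_epoch`` /
``optimize`` / ``multi_minima``) that applies the same update rules to whole
populations at once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "MassFunction",
    "Dust",
    "Group",
    "GFAConfig",
    "OptimizationResult",
    "GFAState",
    "evaluate_mass",
    "initialize_dusts",
    "divide_average",
    "divide_power_weight",
    "assign_to_groups",
    "move_dust",
    "update_centre",
    "absorb",
    "run_epoch",
    "optimize",
    "multi_minima",
    "pseudo_peak_probability",
    "simulate_pseudo_peak_frequency",
    "factorize_near_equal",
]


# ---------------------------------------------------------------------------
# mass functions


@dataclass
class MassFunction:
    """A box-constrained objective.

    Parameters
    ----------
    fn:
        Vectorized callable mapping an ``(N, D)`` array of positions to an
        ``(N,)`` array of objective values.
    domain:
        ``(D, 2)`` array of per-dimension closed intervals ``[lo, hi]``.
    sense:
        ``"maximize"`` or ``"minimize"``.  Internally GFA always maximizes
        mass; minimization is handled by negating f (the maximizer of -f is
        the minimizer of f).
    """

    fn: Callable[[np.ndarray], np.ndarray]
    domain: np.ndarray
    sense: str = "minimize"
    name: str = ""

    def __post_init__(self) -> None:
        self.domain = np.asarray(self.domain, dtype=float)
        if self.domain.ndim != 2 or self.domain.shape[1] != 2:
            raise ValueError("domain must be a (D, 2) array of intervals")
        if np.any(self.domain[:, 0] >= self.domain[:, 1]):
            raise ValueError("each domain interval needs lo < hi")
        if self.sense not in ("maximize", "minimize"):
            raise ValueError(f"unknown sense {self.sense!r}")

    @property
    def dimension(self) -> int:
        return self.domain.shape[0]

    @property
    def widths(self) -> np.ndarray:
        return self.domain[:, 1] - self.domain[:, 0]

    @property
    def diagonal(self) -> float:
        return float(np.linalg.norm(self.widths))

    def clip(self, X: np.ndarray) -> np.ndarray:
        return np.clip(X, self.domain[:, 0], self.domain[:, 1])

    def raw(self, X: np.ndarray) -> np.ndarray:
        """Objective values on the original scale (positions clipped first)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.atleast_1d(np.asarray(self.fn(self.clip(X)), dtype=float))

    def mass(self, X: np.ndarray) -> np.ndarray:
        """Sign-adjusted objective: larger mass is always better.

        Non-finite objective values mark an invalid dust and are mapped to
        ``-inf`` (worst possible mass).
        """
        out = self.raw(X)
        if self.sense == "minimize":
            out = -out
        out[~np.isfinite(out)] = -np.inf
        return out

    def value(self, mass: float | np.ndarray):
        """Convert internal mass back to the original objective scale."""
        return -mass if self.sense == "minimize" else mass


def evaluate_mass(f: MassFunction, position: Sequence[float]) -> float:
    """Mass of a single position: f(x) for maximization, -f(x) otherwise.

    Positions outside the box are clipped before evaluation.
    """
    position = np.asarray(position, dtype=float)
    if position.shape != (f.dimension,):
        raise ValueError(
            f"position has length {position.size}, expected {f.dimension}"
        )
    return float(f.mass(position[None, :])[0])


# ---------------------------------------------------------------------------
# dusts, groups, configuration


@dataclass
class Dust:
    """A candidate solution: position, mass and centre flag."""

    position: np.ndarray
    mass: float
    is_centre: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)


@dataclass
class Group:
    """One region of the domain with a single centre dust.

    ``region`` is a ``(D, 2)`` sub-box of the domain (the power distance of
    the centre).  The centre's mass is at least every surrounding mass.
    """

    region: np.ndarray
    centre: Dust
    surrounding: list[Dust] = field(default_factory=list)

    @property
    def dust_count(self) -> int:
        return 1 + len(self.surrounding)


@dataclass
class GFAConfig:
    """All algorithm knobs.

    Parameters
    ----------
    n, m, s:
        Dusts per group, number of groups, moves per dust per epoch.  The
        total dust budget is ``n * m``.
    M:
        Pace weight: every move covers ``M * dis`` of the current distance to
        the centre.  The golden-section value 0.618/10 is the default.
    absorb_distance_eps:
        A group whose surrounding dusts all sit closer than this to the
        centre is absorbed.  ``None`` resolves to 1e-6 of the domain diagonal.
    crowd_threshold:
        Groups holding more surrounding dusts than this are absorbed
        immediately, to save running time.  ``None`` resolves to ``3 * n``.
    replenish:
        Refill each group to ``n`` dusts at the start of an epoch by uniform
        sampling inside its region (survivors are kept).  Without it the
        population shrinks monotonically.
    jitter_rate:
        Per-coordinate probability that a moved dust's coordinate is
        resampled uniformly over the domain (uniform mutation; the centre is
        never jittered).  Set to 0 for the pure contraction dynamics.
    division:
        ``"power"`` (mass-weighted regions around elected centres) or
        ``"average"`` (static equal-volume grid).
    min_sep:
        Minimum Euclidean separation enforced between centres under power
        division; ``None`` resolves to 5% of the domain diagonal.
    max_power_distance:
        Cap, in length units per dimension, on any group's linear extent
        under power division.
    merge_radius:
        Archive entries closer than this are merged in multimodal search;
        ``None`` resolves to 1% of the domain diagonal.
    stall_epochs:
        A run is declared converged once the surviving dusts sit within the
        absorption distance of each other *and* the best value has not
        improved for this many consecutive epochs.  Keeps easy runs short
        without cutting off slow late-stage refinement.
    """

    n: int = 50
    m: int = 200
    s: int = 10
    M: float = 0.0618
    max_epochs: int = 1000
    absorb_distance_eps: float | None = None
    crowd_threshold: int | None = None
    replenish: bool = True
    jitter_rate: float = 0.02
    division: str = "power"
    min_sep: float | None = None
    max_power_distance: float = 5.0
    merge_radius: float | None = None
    stall_epochs: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.M < 1.0):
            raise ValueError("pace weight M must lie in (0, 1)")
        if self.n < 2:
            raise ValueError("need at least 2 dusts per group")
        if self.m < 1:
            raise ValueError("need at least 1 group")
        if self.s < 1:
            raise ValueError("need at least 1 move per epoch")
        if not (0.0 <= self.jitter_rate <= 1.0):
            raise ValueError("jitter_rate must lie in [0, 1]")
        if self.division not in ("power", "average"):
            raise ValueError(f"unknown division strategy {self.division!r}")

    def resolved_eps(self, f: MassFunction) -> float:
        if self.absorb_distance_eps is not None:
            return self.absorb_distance_eps
        return 1e-6 * f.diagonal

    def resolved_crowd(self) -> int:
        return self.crowd_threshold if self.crowd_threshold is not None else 3 * self.n

    def resolved_min_sep(self, f: MassFunction) -> float:
        if self.min_sep is not None:
            return self.min_sep
        return 0.05 * f.diagonal

    def resolved_merge_radius(self, f: MassFunction) -> float:
        if self.merge_radius is not None:
            return self.merge_radius
        return 1e-2 * f.diagonal


@dataclass
class OptimizationResult:
    """Outcome of a run, reported on the original objective scale."""

    best_position: np.ndarray
    best_value: float
    minima: list[tuple[np.ndarray, float]]
    epochs_used: int
    history: list[float]
    converged: bool
    complete: bool = True  # False when fewer than k distinct optima were found


# ---------------------------------------------------------------------------
# initialization


def initialize_dusts(
    f: MassFunction,
    config: GFAConfig,
    rng: np.random.Generator,
    prior_density: Callable[[np.random.Generator, int], np.ndarray] | None = None,
) -> list[Dust]:
    """Place the initial ``n * m`` dusts and evaluate their masses.

    Positions are uniform over the box, or drawn from ``prior_density`` when
    prior knowledge about likely optima is available.  No centre flags are
    set at this stage.
    """
    budget = config.n * config.m
    X = _initial_positions(f, budget, rng, prior_density)
    mass = f.mass(X)
    return [Dust(x, float(w)) for x, w in zip(X, mass)]


def _initial_positions(f, budget, rng, prior_density=None):
    if budget < 1:
        raise ValueError("dust budget must be positive")
    if prior_density is not None:
        X = np.asarray(prior_density(rng, budget), dtype=float)
        if X.shape != (budget, f.dimension):
            raise ValueError("prior_density must return a (budget, D) array")
        return f.clip(X)
    lo, hi = f.domain[:, 0], f.domain[:, 1]
    return rng.uniform(lo, hi, size=(budget, f.dimension))


# ---------------------------------------------------------------------------
# division strategies


def factorize_near_equal(m: int, D: int) -> list[int]:
    """Split ``m`` into ``D`` integer factors as close as possible.

    Greedy over the prime factorization: each prime factor (largest first)
    multiplies the currently smallest running factor.  For ``D = 2`` this
    recovers the factor pair closest to sqrt(m).
    """
    if m < 1 or D < 1:
        raise ValueError("m and D must be positive")
    primes: list[int] = []
    rest, p = m, 2
    while p * p <= rest:
        while rest % p == 0:
            primes.append(p)
            rest //= p
        p += 1
    if rest > 1:
        primes.append(rest)
    factors = [1] * D
    for q in sorted(primes, reverse=True):
        factors[int(np.argmin(factors))] *= q
    return sorted(factors, reverse=True)


class GridRegions:
    """Equal-volume axis-aligned grid over the domain (average division).

    Cells are half-open ``[lo, hi)`` with the top-most cell closed, so every
    point of the box belongs to exactly one cell.
    """

    kind = "grid"

    def __init__(self, domain: np.ndarray, factors: Sequence[int]):
        self.domain = np.asarray(domain, dtype=float)
        self.factors = np.asarray(factors, dtype=int)
        self.widths = (self.domain[:, 1] - self.domain[:, 0]) / self.factors
        self.strides = np.concatenate(
            ([1], np.cumprod(self.factors[:-1]))
        ).astype(int)

    def __len__(self) -> int:
        return int(np.prod(self.factors))

    def assign(self, X: np.ndarray) -> np.ndarray:
        idx = np.floor((X - self.domain[:, 0]) / self.widths).astype(int)
        np.clip(idx, 0, self.factors - 1, out=idx)  # closes the top cell
        return idx @ self.strides

    def bounds(self, gid: int) -> np.ndarray:
        idx = (gid // self.strides) % self.factors
        lo = self.domain[:, 0] + idx * self.widths
        return np.stack([lo, lo + self.widths], axis=1)

    def sample(self, gid: int, count: int, rng: np.random.Generator) -> np.ndarray:
        b = self.bounds(gid)
        return rng.uniform(b[:, 0], b[:, 1], size=(count, len(b)))


class IntervalRegions:
    """1-D power-weight partition: interval lengths proportional to mass."""

    kind = "interval"

    def __init__(self, domain: np.ndarray, edges: np.ndarray, centre_positions: np.ndarray):
        self.domain = np.asarray(domain, dtype=float)
        self.edges = np.asarray(edges, dtype=float)  # length g+1, increasing
        self.centre_positions = centre_positions

    def __len__(self) -> int:
        return len(self.edges) - 1

    def assign(self, X: np.ndarray) -> np.ndarray:
        gid = np.searchsorted(self.edges, X[:, 0], side="right") - 1
        return np.clip(gid, 0, len(self) - 1)

    def bounds(self, gid: int) -> np.ndarray:
        return np.array([[self.edges[gid], self.edges[gid + 1]]])

    def sample(self, gid: int, count: int, rng: np.random.Generator) -> np.ndarray:
        lo, hi = self.edges[gid], self.edges[gid + 1]
        return rng.uniform(lo, hi, size=(count, 1))


class BoxRegions:
    """Power-weight regions for D >= 2.

    Each elected centre owns an axis-aligned box whose per-dimension extent
    is the centre's mass share of the domain width (scaled by the fraction of
    configured groups actually placed, and capped by the max power distance).
    Assignment is by nearest centre, so the regions jointly cover the box.
    """

    kind = "box"

    def __init__(self, domain, centres, halfwidths):
        self.domain = np.asarray(domain, dtype=float)
        self.centres = np.asarray(centres, dtype=float)  # (g, D)
        self.halfwidths = np.asarray(halfwidths, dtype=float)  # (g, D)

    def __len__(self) -> int:
        return self.centres.shape[0]

    def assign(self, X: np.ndarray) -> np.ndarray:
        d2 = ((X[:, None, :] - self.centres[None, :, :]) ** 2).sum(axis=2)
        return np.argmin(d2, axis=1)

    def bounds(self, gid: int) -> np.ndarray:
        lo = np.maximum(self.centres[gid] - self.halfwidths[gid], self.domain[:, 0])
        hi = np.minimum(self.centres[gid] + self.halfwidths[gid], self.domain[:, 1])
        return np.stack([lo, hi], axis=1)

    def sample(self, gid: int, count: int, rng: np.random.Generator) -> np.ndarray:
        b = self.bounds(gid)
        return rng.uniform(b[:, 0], b[:, 1], size=(count, len(b)))


def divide_average(domain: np.ndarray, m: int, D: int) -> GridRegions:
    """Cut the box into ``m`` equal-volume grid cells.

    For D = 2 the grid is the a x b factorization of m with the factor pair
    closest to sqrt(m); higher dimensions use the analogous near-equal
    factorization.  A prime m with D >= 2 cannot form a grid and falls back
    to an m x 1 slicing (with a warning).
    """
    domain = np.asarray(domain, dtype=float)
    if m < 1:
        raise ValueError("m must be >= 1")
    factors = factorize_near_equal(m, D)
    if D >= 2 and m > 1 and factors[1] == 1 and factors[0] == m:
        warnings.warn(
            f"group count {m} is prime; falling back to an {m} x 1 division",
            stacklevel=2,
        )
    return GridRegions(domain, factors)


def _select_centres(X, mass, m, min_sep):
    """Greedy centre election: best mass first, enforcing min separation."""
    order = np.argsort(-mass, kind="stable")
    chosen: list[int] = []
    for i in order:
        if not np.isfinite(mass[i]):
            continue
        if len(chosen) == m:
            break
        if chosen:
            d = np.linalg.norm(X[chosen] - X[i], axis=1)
            if np.any(d < min_sep):
                continue
        chosen.append(int(i))
    if not chosen:  # all masses -inf: keep the first dust
        chosen = [int(order[0])]
    return np.array(chosen, dtype=int)


def divide_power_weight(
    dusts_or_positions,
    m: int,
    *,
    domain: np.ndarray,
    masses: np.ndarray | None = None,
    min_sep: float = 0.0,
    max_power_distance: float = 5.0,
    m_configured: int | None = None,
):
    """Mass-weighted division: regions follow the current best dusts.

    The m best-separated high-mass dusts become provisional centres; each is
    allotted a region whose linear extent is proportional to its mass share,
    capped at ``max_power_distance`` length units per dimension.  In one
    dimension the regions are a proportional partition of the domain; in
    higher dimensions they are boxes around the centres with assignment by
    nearest centre.
    """
    if masses is None:
        X = np.stack([d.position for d in dusts_or_positions])
        masses = np.array([d.mass for d in dusts_or_positions])
    else:
        X = np.asarray(dusts_or_positions, dtype=float)
        masses = np.asarray(masses, dtype=float)
    if X.shape[0] == 0:
        raise ValueError("power-weight division needs at least one dust")
    domain = np.asarray(domain, dtype=float)
    m = min(m, X.shape[0])
    m_configured = m_configured or m

    idx = _select_centres(X, masses, m, min_sep)
    C, cm = X[idx], masses[idx]
    g = len(idx)

    # Mass shares: use raw masses when all positive (so a mass-3 centre owns
    # three times the extent of a mass-1 centre); otherwise shift so the worst
    # centre still receives a positive share.
    finite = cm[np.isfinite(cm)]
    lo = finite.min() if finite.size else 0.0
    if lo > 0 and np.all(np.isfinite(cm)):
        w = cm.copy()
    else:
        span = (finite.max() - lo) if finite.size else 0.0
        w = np.where(np.isfinite(cm), cm - lo, 0.0) + (span if span > 0 else 1.0)
    share = w / w.sum()

    widths = domain[:, 1] - domain[:, 0]
    if domain.shape[0] == 1:
        order = np.argsort(C[:, 0], kind="stable")
        lengths = np.minimum(share[order] * widths[0], max_power_distance)
        lengths *= widths[0] / lengths.sum()  # re-fill the domain after capping
        edges = np.concatenate(([domain[0, 0]], domain[0, 0] + np.cumsum(lengths)))
        edges[-1] = domain[0, 1]
        return IntervalRegions(domain, edges, C[order])

    # D >= 2: per-dimension extent = width * share * (g / m_configured),
    # so the boxes stay at the ~width/m refinement scale even when niches merge.
    extent = np.minimum(
        widths[None, :] * share[:, None] * (g / m_configured), max_power_distance
    )
    return BoxRegions(domain, C, extent / 2.0)


def assign_to_groups(dusts: list[Dust], regions) -> list[Group]:
    """Partition dusts over regions and flag each group's max-mass centre.

    Each dust lands in exactly one region; empty regions are dropped.  Ties
    for the maximum mass go to the lowest-index dust.
    """
    if not dusts:
        return []
    X = np.stack([d.position for d in dusts])
    gid = regions.assign(X)
    groups: list[Group] = []
    for g in np.unique(gid):
        members = [dusts[i] for i in np.flatnonzero(gid == g)]
        best = max(range(len(members)), key=lambda i: (members[i].mass, -i))
        for i, d in enumerate(members):
            d.is_centre = i == best
        centre = members[best]
        groups.append(
            Group(
                region=regions.bounds(int(g)),
                centre=centre,
                surrounding=[d for i, d in enumerate(members) if i != best],
            )
        )
    return groups


# ---------------------------------------------------------------------------
# motion, re-election, absorption (object-level semantics)


def move_dust(dust: Dust, centre: Dust, M: float, f: MassFunction) -> Dust:
    """Move a surrounding dust toward the centre by pace = M * dis.

    The dust travels along the straight segment to the centre, so its new
    distance is exactly (1 - M) times the old one.  Its mass is re-evaluated
    at the new position.  A dust already at the centre does not move.
    """
    if dust.is_centre:
        raise ValueError("centre dusts do not move within an epoch")
    delta = centre.position - dust.position
    dis = float(np.linalg.norm(delta))
    if dis == 0.0:
        return dust
    new_pos = dust.position + M * delta
    return Dust(new_pos, evaluate_mass(f, new_pos), is_centre=False)


def update_centre(group: Group) -> Group:
    """Re-elect the centre if a surrounding dust now has strictly more mass.

    Ties keep the incumbent; the winning dust swaps roles with the old
    centre (positions are untouched — a centre never moves within an epoch).
    """
    if not group.surrounding:
        return group
    best = int(np.argmax([d.mass for d in group.surrounding]))
    challenger = group.surrounding[best]
    if challenger.mass > group.centre.mass:
        old = group.centre
        old.is_centre = False
        challenger.is_centre = True
        group.surrounding[best] = old
        group.centre = challenger
    return group


def absorb(group: Group, config: GFAConfig, eps: float | None = None) -> Dust | None:
    """Absorb the group when it has contracted or grown too crowded.

    All surrounding dusts are deleted; the centre survives with its flag
    reset, re-entering the next epoch as an ordinary dust.  Returns the
    survivor, or ``None`` when neither trigger holds.
    """
    if eps is None:
        eps = config.absorb_distance_eps if config.absorb_distance_eps is not None else 0.0
    crowd = config.resolved_crowd()
    dists = [
        float(np.linalg.norm(d.position - group.centre.position))
        for d in group.surrounding
    ]
    if len(group.surrounding) > crowd or all(d < eps for d in dists):
        survivor = group.centre
        survivor.is_centre = False
        group.surrounding = []
        return survivor
    return None


# ---------------------------------------------------------------------------
# the vectorized epoch engine


@dataclass
class GFAState:
    """Population state carried between epochs (array form)."""

    X: np.ndarray  # (N, D) positions
    mass: np.ndarray  # (N,)
    best_position: np.ndarray
    best_mass: float
    epoch: int = 0
    converged: bool = False
    stall: int = 0  # consecutive epochs without best-value improvement
    archive_X: list = field(default_factory=list)  # absorbed-group survivors
    archive_mass: list = field(default_factory=list)
    history: list[float] = field(default_factory=list)  # per-epoch best mass


def _divide(f: MassFunction, config: GFAConfig, X, mass):
    if config.division == "average":
        return divide_average(f.domain, config.m, f.dimension)
    return divide_power_weight(
        X,
        config.m,
        domain=f.domain,
        masses=mass,
        min_sep=config.resolved_min_sep(f),
        max_power_distance=config.max_power_distance,
        m_configured=config.m,
    )


def run_epoch(
    state: GFAState, f: MassFunction, config: GFAConfig, rng: np.random.Generator
) -> GFAState:
    """One epoch: divide -> replenish -> assign -> s move rounds -> absorb.

    Within the move rounds every surrounding dust steps toward its group's
    centre (pace = M * dis) with optional per-coordinate uniform mutation,
    masses are re-evaluated, and centres are re-elected whenever a mover
    strictly beats the incumbent.  At the end of the epoch every group is
    absorbed: only centres survive.  Groups exceeding the crowd threshold are
    absorbed immediately; groups contracting below the absorption distance
    are absorbed early.
    """
    eps = config.resolved_eps(f)
    crowd = config.resolved_crowd()
    regions = _divide(f, config, state.X, state.mass)
    gid = regions.assign(state.X)

    X, mass, gid = state.X, state.mass, gid
    if config.replenish:
        present, counts = np.unique(gid, return_counts=True)
        count_of = dict(zip(present.tolist(), counts.tolist()))
        new_X, new_gid = [], []
        for g in range(len(regions)):
            need = config.n - count_of.get(g, 0)
            # only refill regions that already hold dusts under power division
            # (grid cells are refilled regardless: they tile the domain)
            if regions.kind != "grid" and g not in count_of:
                continue
            if need > 0:
                new_X.append(regions.sample(g, need, rng))
                new_gid.append(np.full(need, g))
        if new_X:
            Xn = np.concatenate(new_X)
            mn = f.mass(Xn)
            X = np.concatenate([X, Xn])
            mass = np.concatenate([mass, mn])
            gid = np.concatenate([gid, np.concatenate(new_gid)])

    # order members by group; remember original order for deterministic ties
    order = np.argsort(gid, kind="stable")
    X, mass, gid = X[order], mass[order], gid[order]
    boundaries = np.flatnonzero(np.diff(gid)) + 1
    starts = np.concatenate(([0], boundaries))
    stops = np.concatenate((boundaries, [gid.size]))

    centre_idx = np.empty(len(starts), dtype=int)
    active = np.ones(len(starts), dtype=bool)
    survivors_X, survivors_mass = [], []

    for k, (a, b) in enumerate(zip(starts, stops)):
        centre_idx[k] = a + int(np.argmax(mass[a:b]))
        if (b - a) - 1 > crowd:  # overcrowded: absorb immediately
            active[k] = False

    lo, hi = f.domain[:, 0], f.domain[:, 1]
    for _ in range(config.s):
        if not np.any(active):
            break
        mover = np.ones(gid.size, dtype=bool)
        mover[centre_idx] = False
        for k in np.flatnonzero(~active):
            mover[starts[k]: stops[k]] = False
        if not np.any(mover):
            break
        idx = np.flatnonzero(mover)
        # groups are contiguous after sorting, so map gid -> segment index:
        seg = np.searchsorted(gid[starts], gid[idx])
        C = X[centre_idx[seg]]
        moved = X[idx] + config.M * (C - X[idx])
        if config.jitter_rate > 0:
            jit = rng.random(moved.shape) < config.jitter_rate
            if np.any(jit):
                u = rng.uniform(lo, hi, size=moved.shape)
                moved = np.where(jit, u, moved)
        moved = np.clip(moved, lo, hi)
        X[idx] = moved
        mass[idx] = f.mass(moved)
        # update global best and re-elect centres
        for k in np.flatnonzero(active):
            a, b = starts[k], stops[k]
            j = a + int(np.argmax(mass[a:b]))
            if mass[j] > mass[centre_idx[k]]:
                centre_idx[k] = j
            # early absorption once the whole group has contracted
            d = np.linalg.norm(X[a:b] - X[centre_idx[k]], axis=1)
            if np.all(d < eps):
                active[k] = False

    # end of epoch: absorb everything, centres survive
    for k in range(len(starts)):
        survivors_X.append(X[centre_idx[k]])
        survivors_mass.append(mass[centre_idx[k]])

    sX = np.stack(survivors_X)
    sm = np.asarray(survivors_mass)

    # track the global best over every evaluation made this epoch
    j = int(np.argmax(mass))
    best_position, best_mass = state.best_position, state.best_mass
    improved = mass[j] > best_mass
    if improved:
        best_position, best_mass = X[j].copy(), float(mass[j])
    stall = 0 if improved else state.stall + 1

    archive_X = state.archive_X + [sX.copy()]
    archive_mass = state.archive_mass + [sm.copy()]
    history = state.history + [best_mass]

    if sX.shape[0] == 1:
        contracted = True
    else:
        spread = np.linalg.norm(sX - sX.mean(axis=0), axis=1).max()
        contracted = bool(2 * spread < eps)
    converged = contracted and stall >= config.stall_epochs

    return GFAState(
        X=sX,
        mass=sm,
        best_position=best_position,
        best_mass=best_mass,
        epoch=state.epoch + 1,
        converged=converged,
        stall=stall,
        archive_X=archive_X,
        archive_mass=archive_mass,
        history=history,
    )


def _initial_state(f, config, rng, prior_density=None):
    X = _initial_positions(f, config.n * config.m, rng, prior_density)
    mass = f.mass(X)
    j = int(np.argmax(mass))
    return GFAState(
        X=X, mass=mass, best_position=X[j].copy(), best_mass=float(mass[j])
    )


def optimize(
    f: MassFunction,
    config: GFAConfig,
    prior_density=None,
) -> OptimizationResult:
    """Run GFA to convergence or ``max_epochs``; single-optimum search.

    The best value is reported on the original objective scale (un-negated
    for minimization).  A fixed seed reproduces the run exactly.
    """
    rng = np.random.default_rng(config.seed)
    state = _initial_state(f, config, rng, prior_density)
    for _ in range(config.max_epochs):
        state = run_epoch(state, f, config, rng)
        if state.converged:
            break
    history = [float(f.value(h)) for h in state.history]
    return OptimizationResult(
        best_position=state.best_position,
        best_value=float(f.value(state.best_mass)),
        minima=[(state.best_position, float(f.value(state.best_mass)))],
        epochs_used=state.epoch,
        history=history,
        converged=state.converged,
    )


def _merge_archive(X, mass, merge_radius, max_keep=None):
    """Greedy merge: best mass first, drop entries within the merge radius."""
    order = np.argsort(-mass, kind="stable")
    kept: list[int] = []
    for i in order:
        if not np.isfinite(mass[i]):
            continue
        if kept and np.any(np.linalg.norm(X[kept] - X[i], axis=1) < merge_radius):
            continue
        kept.append(int(i))
        if max_keep is not None and len(kept) >= max_keep:
            break
    return kept


def _is_local_optimum(f: MassFunction, x: np.ndarray, m: float, delta: float) -> bool:
    """Axis-aligned probe test: no neighbouring point (clipped to the box)
    has strictly larger mass."""
    D = x.size
    probes = np.repeat(x[None, :], 2 * D, axis=0)
    probes[:D, :] += delta * np.eye(D)
    probes[D:, :] -= delta * np.eye(D)
    probes = f.clip(probes)
    # probes that clip back onto the candidate (domain boundary) carry no
    # information and must not veto a boundary optimum
    informative = np.linalg.norm(probes - x, axis=1) > 0.5 * delta
    if not np.any(informative):
        return True
    return bool(
        np.all(f.mass(probes[informative]) <= m + 1e-12 * max(1.0, abs(m)))
    )


def multi_minima(f: MassFunction, config: GFAConfig, k: int) -> OptimizationResult:
    """Top-k multimodal search.

    Every absorbed-group survivor is archived during the run; afterwards
    archive entries closer than the merge radius collapse onto the better
    value and the k best distinct optima are returned, sorted best first.
    When fewer than k distinct optima exist the result is flagged
    (``complete=False``) and all found optima are returned.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(config.seed)
    state = _initial_state(f, config, rng)
    for _ in range(config.max_epochs):
        state = run_epoch(state, f, config, rng)
        if state.converged:
            break
    aX = np.concatenate([state.best_position[None, :]] + state.archive_X)
    am = np.concatenate([[state.best_mass]] + state.archive_mass)
    radius = config.resolved_merge_radius(f)
    kept = _merge_archive(aX, am, radius, max_keep=20 * k + 50)
    # discard archive entries that are not local optima (stale trajectory
    # points from early epochs survive merging but sit on slopes)
    delta = 0.5 * radius
    kept = [i for i in kept if _is_local_optimum(f, aX[i], am[i], delta)]
    kept = kept[:k]
    if not kept:  # degenerate: fall back to the best point found
        kept = [0]
    minima = [(aX[i].copy(), float(f.value(am[i]))) for i in kept]
    history = [float(f.value(h)) for h in state.history]
    return OptimizationResult(
        best_position=aX[kept[0]].copy(),
        best_value=minima[0][1],
        minima=minima,
        epochs_used=state.epoch,
        history=history,
        converged=state.converged,
        complete=len(minima) >= k,
    )


# ---------------------------------------------------------------------------
# pseudo-peak probability (the convergence theory)


def pseudo_peak_probability(l_max: float, l_total: float, n: int) -> float:
    """Probability that a group locks onto a pseudo peak.

    With n dusts uniformly placed over a group of linear extent ``l_total``
    whose apparent maximum sits ``l_max`` away from the nearest valley, the
    group converges to the pseudo peak exactly when all n-1 surrounding
    dusts fall on the maximum's side of the valley:
    p = (l_max / l_total) ** (n - 1).  This vanishes as n grows, which is
    the engine of the global-convergence guarantee.
    """
    if n < 2:
        raise ValueError("a group needs at least 2 dusts")
    if l_total <= 0:
        raise ValueError("l_total must be positive")
    if not (0.0 <= l_max < l_total):
        raise ValueError("need 0 <= l_max < l_total")
    return (l_max / l_total) ** (n - 1)


def simulate_pseudo_peak_frequency(
    x_max: float,
    valley: float,
    interval: tuple[float, float],
    n: int,
    trials: int,
    seed: int = 0,
) -> float:
    """Empirical pseudo-peak frequency for a 1-D group.

    The apparent maximum sits at ``x_max``; ``valley`` is the nearest valley
    separating it from the real peak; the group spans ``interval``.  Each
    trial places n-1 surrounding dusts uniformly over the group and counts a
    pseudo-peak event when all of them land on ``x_max``'s side of the
    valley (none can pull the group across).  The frequency estimates
    (l_max / l_total) ** (n - 1).
    """
    lo, hi = interval
    if not (lo <= x_max <= hi and lo <= valley <= hi):
        raise ValueError("x_max and valley must lie inside the group interval")
    rng = np.random.default_rng(seed)
    pos = rng.uniform(lo, hi, size=(trials, n - 1))
    if x_max <= valley:
        events = np.all(pos <= valley, axis=1)
    else:
        events = np.all(pos >= valley, axis=1)
    return float(events.mean())
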