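"""ZDT two-objective benchmark suite, analytic Pareto fronts, and
front-quality metrics (IGD, hypervolume).

Each :class:`ZdtProblem` exposes the unit-cube encoding the optimizers use;
problems whose native domain is not [0, 1]^D (ZDT4's tail variables live in
[-5, 5]) map the encoding affinely onto their bounds, so a single optimizer
code path covers the whole suite.

ZDT5 is Boolean-coded and excluded; the suite is ZDT1-ZDT4 and ZDT6.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .optimizer import ALGORITHMS, OptimizerConfig, RunResult, run

__all__ = [
    "ZDT_IDS",
    "ZdtProblem",
    "zdt_eval",
    "analytic_front",
    "igd",
    "hypervolume_2d",
    "zdt_campaign",
    "FRONT_ATTAINED_IGD",
]

ZDT_IDS = ("ZDT1", "ZDT2", "ZDT3", "ZDT4", "ZDT6")

#: Operational definition of "the front was attained": median IGD below this.
FRONT_ATTAINED_IGD = 0.1


@dataclass
class ZdtProblem:
    """One ZDT instance at a given dimension, evaluated via the unit cube."""

    id: str
    dimension: int = 10
    n_objectives: int = 2
    lower: np.ndarray = field(init=False)
    upper: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.id not in ZDT_IDS:
            raise ValueError(f"unknown problem {self.id!r}; choose from {ZDT_IDS}")
        if self.dimension < 2:
            raise ValueError("dimension must be >= 2")
        self.lower = np.zeros(self.dimension)
        self.upper = np.ones(self.dimension)
        if self.id == "ZDT4":
            self.lower[1:] = -5.0
            self.upper[1:] = 5.0

    def to_domain(self, u: np.ndarray) -> np.ndarray:
        """Affine map of a unit-cube position onto the native bounds."""
        return self.lower + np.asarray(u, dtype=float) * (self.upper - self.lower)

    def evaluate(self, u: np.ndarray) -> np.ndarray:
        return zdt_eval(self, self.to_domain(u))


def zdt_eval(p: ZdtProblem, x: np.ndarray) -> np.ndarray:
    """Standard ZDT objective pair at a native-domain point."""
    x = np.asarray(x, dtype=float)
    if x.shape != (p.dimension,):
        raise ValueError("point dimension mismatch")
    if np.any(x < p.lower - 1e-12) or np.any(x > p.upper + 1e-12):
        raise ValueError("point outside the problem domain")
    tail = x[1:]
    d = p.dimension
    if p.id == "ZDT1":
        f1 = x[0]
        g = 1.0 + 9.0 * tail.sum() / (d - 1)
        f2 = g * (1.0 - np.sqrt(f1 / g))
    elif p.id == "ZDT2":
        f1 = x[0]
        g = 1.0 + 9.0 * tail.sum() / (d - 1)
        f2 = g * (1.0 - (f1 / g) ** 2)
    elif p.id == "ZDT3":
        f1 = x[0]
        g = 1.0 + 9.0 * tail.sum() / (d - 1)
        f2 = g * (1.0 - np.sqrt(f1 / g) - (f1 / g) * np.sin(10.0 * np.pi * f1))
    elif p.id == "ZDT4":
        f1 = x[0]
        g = 1.0 + 10.0 * (d - 1) + np.sum(tail**2 - 10.0 * np.cos(4.0 * np.pi * tail))
        f2 = g * (1.0 - np.sqrt(f1 / g))
    else:  # ZDT6
        f1 = 1.0 - np.exp(-4.0 * x[0]) * np.sin(6.0 * np.pi * x[0]) ** 6
        g = 1.0 + 9.0 * (tail.sum() / (d - 1)) ** 0.75
        f2 = g * (1.0 - (f1 / g) ** 2)
    return np.array([f1, f2])


def _nondominated_mask(points: np.ndarray) -> np.ndarray:
    le = (points[:, None, :] <= points[None, :, :]).all(axis=2)
    lt = (points[:, None, :] < points[None, :, :]).any(axis=2)
    dominated = (le & lt).any(axis=0)
    return ~dominated


def analytic_front(p: ZdtProblem, n_points: int = 1000) -> np.ndarray:
    """Sampled true Pareto front as an (n, 2) array.

    Closed forms (g = 1): ZDT1/ZDT4 f2 = 1 - sqrt(f1); ZDT2 f2 = 1 - f1^2;
    ZDT6 the same over its restricted f1 range.  ZDT3's disconnected
    segments are obtained by dense sampling of the g = 1 curve followed by a
    non-domination filter.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if p.id in ("ZDT1", "ZDT4"):
        f1 = np.linspace(0.0, 1.0, n_points)
        return np.column_stack([f1, 1.0 - np.sqrt(f1)])
    if p.id == "ZDT2":
        f1 = np.linspace(0.0, 1.0, n_points)
        return np.column_stack([f1, 1.0 - f1**2])
    if p.id == "ZDT6":
        x1 = np.linspace(0.0, 1.0, 20 * n_points)
        f1 = 1.0 - np.exp(-4.0 * x1) * np.sin(6.0 * np.pi * x1) ** 6
        f1 = np.linspace(f1.min(), 1.0, n_points)
        return np.column_stack([f1, 1.0 - f1**2])
    # ZDT3: dense sample then keep the non-dominated part
    f1 = np.linspace(0.0, 1.0, 20 * n_points)
    f2 = 1.0 - np.sqrt(f1) - f1 * np.sin(10.0 * np.pi * f1)
    pts = np.column_stack([f1, f2])
    pts = pts[_nondominated_mask(pts)]
    step = max(1, pts.shape[0] // n_points)
    return pts[::step]


def igd(archive_objectives: np.ndarray, reference_front: np.ndarray) -> float:
    """Inverted generational distance: mean Euclidean distance from each
    reference-front sample to its nearest obtained point.  Lower is better;
    0 means the archive covers every reference sample."""
    a = np.atleast_2d(np.asarray(archive_objectives, dtype=float))
    r = np.atleast_2d(np.asarray(reference_front, dtype=float))
    if a.size == 0 or r.size == 0:
        raise ValueError("igd needs non-empty archive and reference front")
    return float(cdist(r, a).min(axis=1).mean())


def hypervolume_2d(points: np.ndarray, reference: tuple[float, float] = (1.1, 1.1)) -> float:
    """Dominated hypervolume of a 2-objective point set w.r.t. a reference
    point (minimization); points beyond the reference contribute nothing."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    pts = pts[_nondominated_mask(pts)]
    pts = pts[(pts[:, 0] < reference[0]) & (pts[:, 1] < reference[1])]
    if pts.size == 0:
        return 0.0
    pts = pts[np.argsort(pts[:, 0])]
    hv = 0.0
    prev_x = reference[0]
    for x, y in pts[::-1]:
        hv += (prev_x - x) * (reference[1] - y)
        prev_x = x
    return float(hv)


def zdt_campaign(
    algorithms: tuple[str, ...] = ALGORITHMS,
    problems: tuple[str, ...] = ZDT_IDS,
    dimensions: tuple[int, ...] = (10, 50),
    n_trials: int = 20,
    cfg: OptimizerConfig | None = None,
    seed: int = 0,
    n_front_points: int = 1000,
) -> pd.DataFrame:
    """Seeded trial matrix over (algorithm, problem, dimension).

    Each cell runs ``n_trials`` independent optimizations (30 particles,
    50 iterations by default) and records the final-archive IGD and
    hypervolume.  Returns a tidy DataFrame with one row per trial plus a
    ``front_attained`` flag per cell (median IGD < 0.1).
    """
    base = cfg or OptimizerConfig()
    rows = []
    for problem_id in problems:
        for d in dimensions:
            prob = ZdtProblem(problem_id, dimension=d)
            front = analytic_front(prob, n_front_points)
            for alg in algorithms:
                for trial in range(n_trials):
                    trial_seed = int(
                        np.random.SeedSequence(
                            entropy=seed,
                            spawn_key=(ZDT_IDS.index(problem_id), d, ALGORITHMS.index(alg), trial),
                        ).generate_state(1)[0] % (2**31 - 1)
                    )
                    trial_cfg = OptimizerConfig(
                        **{**base.__dict__, "seed": trial_seed}
                    )
                    res: RunResult = run(alg, prob, trial_cfg)
                    objs = res.final_objectives
                    rows.append(
                        {
                            "algorithm": alg,
                            "problem": problem_id,
                            "dimension": d,
                            "trial": trial,
                            "seed": trial_seed,
                            "igd": igd(objs, front),
                            "hypervolume": hypervolume_2d(objs),
                        }
                    )
    df = pd.DataFrame(rows)
    med = df.groupby(["algorithm", "problem", "dimension"])["igd"].transform("median")
    df["front_attained"] = med < FRONT_ATTAINED_IGD
    return df
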