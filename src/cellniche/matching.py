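"""Cross-subtype niche matching via chi-squared distances and partial
optimal transport.

Two independently derived niche sets (e.g., the ten LUAD and ten LUSC
niches) are compared on their phenotype distributions with the symmetric
chi-squared distance

    d(x, y) = sum_i (x_i - y_i)^2 / (x_i + y_i)      (terms with x_i + y_i = 0 skipped)

and matched by partial optimal transport: each niche carries uniform mass
1/k; for every n = 0..k the exact linear program transporting total mass n/k
at minimum chi-squared cost is solved. Because moving additional mass can
only add cost, the cost sequence is nondecreasing in n, and the number of
genuinely analogous pairs shows up as an elbow in the log-cost curve: the
selected n* maximizes the discrete second difference of log(cost + eps).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

ELBOW_EPS = 1e-12
#: A plan entry counts as a matched pair when it carries at least half of a
#: full niche mass unit.
PAIR_MASS_FRACTION = 0.5


def chi2_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Symmetric chi-squared distance between nonnegative distributions.

    Zero iff x == y; symmetric; does not satisfy the triangle inequality.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("distributions must share support")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("distributions must be nonnegative")
    s = x + y
    mask = s > 0
    return float((((x - y) ** 2)[mask] / s[mask]).sum())


def chi2_distance_matrix(profiles_a: np.ndarray, profiles_b: np.ndarray) -> np.ndarray:
    a = np.atleast_2d(np.asarray(profiles_a, dtype=float))
    b = np.atleast_2d(np.asarray(profiles_b, dtype=float))
    out = np.zeros((a.shape[0], b.shape[0]))
    for i in range(a.shape[0]):
        for j in range(b.shape[0]):
            out[i, j] = chi2_distance(a[i], b[j])
    return out


@dataclass
class MatchResult:
    distance_matrix: np.ndarray  # (k_a, k_b)
    costs: np.ndarray  # transport cost for n = 0..min(k_a, k_b)
    log_costs: np.ndarray  # log(cost + ELBOW_EPS)
    n_matched: int  # elbow-selected n*
    pairs: list[tuple[int, int, float]]  # (niche_a, niche_b, mass), 1-based ids
    plans: list[np.ndarray] | None = None


def partial_transport(cost: np.ndarray, mass: float) -> tuple[float, np.ndarray]:
    """Exact partial OT between uniform marginals, transporting ``mass`` total.

    Marginals are 1/k_a per source niche and 1/k_b per target niche; the plan
    gamma >= 0 satisfies row sums <= 1/k_a, column sums <= 1/k_b and
    sum(gamma) == mass. Solved as an LP (HiGHS), hence deterministic.
    """
    ka, kb = cost.shape
    if mass < -1e-12 or mass > min(1.0, 1.0) + 1e-12:
        raise ValueError("mass must lie in [0, 1]")
    if mass <= 0:
        return 0.0, np.zeros_like(cost)
    c = cost.ravel()
    # row-sum constraints
    a_ub = np.zeros((ka + kb, ka * kb))
    for i in range(ka):
        a_ub[i, i * kb : (i + 1) * kb] = 1.0
    for j in range(kb):
        a_ub[ka + j, j::kb] = 1.0
    b_ub = np.concatenate([np.full(ka, 1.0 / ka), np.full(kb, 1.0 / kb)])
    a_eq = np.ones((1, ka * kb))
    b_eq = np.array([mass])
    res = linprog(c, A_ub=a_ub, b_ub=b_ub, A_eq=a_eq, b_eq=b_eq, bounds=(0, None), method="highs")
    if not res.success:  # pragma: no cover - LP is always feasible for mass <= 1
        raise RuntimeError(f"partial OT LP failed: {res.message}")
    return float(res.fun), res.x.reshape(ka, kb)


def match_niches(
    profiles_a: np.ndarray,
    profiles_b: np.ndarray,
    return_plans: bool = False,
) -> MatchResult:
    """Match niche sets by partial OT over all candidate pair counts.

    ``profiles_a``/``profiles_b``: rows are per-niche phenotype distributions
    (nonnegative, summing to 1). Row order defines 1-based niche ids.
    """
    a = np.atleast_2d(np.asarray(profiles_a, dtype=float))
    b = np.atleast_2d(np.asarray(profiles_b, dtype=float))
    if a.shape[0] < 1 or b.shape[0] < 1:
        raise ValueError("need at least one profile per side")
    dist = chi2_distance_matrix(a, b)
    ka, kb = dist.shape
    n_max = min(ka, kb)

    costs = np.zeros(n_max + 1)
    plans: list[np.ndarray] = [np.zeros_like(dist)]
    for n in range(1, n_max + 1):
        cost_n, plan = partial_transport(dist, n / n_max)
        costs[n] = cost_n
        plans.append(plan)
    log_costs = np.log(costs + ELBOW_EPS)

    if n_max == 1:
        n_star = 1
    elif np.allclose(costs, 0.0):
        # degenerate: everything matches at zero cost
        n_star = n_max
    else:
        second_diff = log_costs[2:] - 2 * log_costs[1:-1] + log_costs[:-2]
        n_star = int(np.argmax(second_diff)) + 1  # candidates n = 1..n_max-1

    plan = plans[n_star]
    unit = min(1.0 / ka, 1.0 / kb)
    pairs = [
        (i + 1, j + 1, float(plan[i, j]))
        for i, j in zip(*np.nonzero(plan >= PAIR_MASS_FRACTION * unit))
    ]
    pairs.sort()
    return MatchResult(
        distance_matrix=dist,
        costs=costs,
        log_costs=log_costs,
        n_matched=n_star,
        pairs=pairs,
        plans=plans if return_plans else None,
    )
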