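"""Incremental association Markov blanket (IAMB) discovery.

The blanket of a target variable — its parents, children, and spouses in
the generating Bayesian network — is recovered in two phases: a growing
phase that repeatedly admits the candidate with the strongest association
with the target conditional on the current blanket (if the conditional-
independence test rejects), and a shrinking phase that removes any member
that is independent of the target given the rest of the blanket.

Conditional independence is tested with the Fisher z-transform of the
Gaussian partial correlation: ``z = atanh(rho)``, statistic
``sqrt(n - |Z| - 3) * z`` against the standard normal.  Role tagging
separates spouses from direct neighbors by searching for a d-separating
subset inside the blanket, and orients children via collider checks;
directions that collider logic cannot settle stay "undetermined".
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class CITestResult:
    x: str
    y: str
    conditioning_set: frozenset[str]
    partial_corr: float
    z_stat: float
    p_value: float


@dataclass
class MarkovBlanketResult:
    target: str
    blanket: set[str]
    roles: dict[str, str] = field(default_factory=dict)
    alpha: float = 0.05

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "blanket": sorted(self.blanket),
            "roles": dict(sorted(self.roles.items())),
            "alpha": self.alpha,
        }


class SingularConditioningError(ValueError):
    """The conditioning variables are collinear; the test is undefined."""


def partial_correlation(
    x: str, y: str, Z: set[str] | frozenset[str], data: pd.DataFrame
) -> float:
    """Partial correlation of x and y given Z, by linear residualization."""
    if x == y:
        return 1.0
    Z = sorted(set(Z) - {x, y})
    xv = data[x].to_numpy(dtype=float)
    yv = data[y].to_numpy(dtype=float)
    n = len(xv)
    if n <= len(Z) + 3:
        raise ValueError(
            f"partial correlation needs n > |Z| + 3 (n={n}, |Z|={len(Z)})"
        )
    if not Z:
        rx, ry = xv - xv.mean(), yv - yv.mean()
    else:
        design = np.column_stack(
            [np.ones(n)] + [data[z].to_numpy(dtype=float) for z in Z]
        )
        rank = np.linalg.matrix_rank(design)
        if rank < design.shape[1]:
            raise SingularConditioningError(
                f"collinear conditioning set {Z}"
            )
        coef_x, *_ = np.linalg.lstsq(design, xv, rcond=None)
        coef_y, *_ = np.linalg.lstsq(design, yv, rcond=None)
        rx = xv - design @ coef_x
        ry = yv - design @ coef_y
    sx = math.sqrt(float(rx @ rx))
    sy = math.sqrt(float(ry @ ry))
    if sx == 0.0 or sy == 0.0:
        raise SingularConditioningError("zero residual variance")
    rho = float(rx @ ry) / (sx * sy)
    return float(min(1.0, max(-1.0, rho)))


def fisher_z_test(
    partial_corr: float, n_obs: int, z_size: int,
    x: str = "x", y: str = "y", Z: frozenset[str] = frozenset(),
) -> CITestResult:
    """Fisher z conditional-independence test of a partial correlation."""
    df = n_obs - z_size - 3
    if df <= 0:
        raise ValueError(
            f"Fisher z test needs n - |Z| - 3 > 0 (n={n_obs}, |Z|={z_size})"
        )
    rho = min(1.0, max(-1.0, partial_corr))
    if abs(rho) >= 1.0:
        return CITestResult(x, y, Z, rho, math.copysign(math.inf, rho), 0.0)
    z = 0.5 * math.log((1.0 + rho) / (1.0 - rho))
    stat = math.sqrt(df) * z
    p = 2.0 * float(stats.norm.sf(abs(stat)))
    return CITestResult(x, y, Z, rho, stat, min(1.0, p))


def ci_test(
    x: str, y: str, Z: set[str] | frozenset[str], data: pd.DataFrame
) -> CITestResult:
    Z = frozenset(set(Z) - {x, y})
    rho = partial_correlation(x, y, Z, data)
    return fisher_z_test(rho, len(data), len(Z), x=x, y=y, Z=Z)


def _max_valid_z(n_obs: int) -> int:
    # test validity: n - |Z| - 3 > 0 for the z statistic and n > |Z| + 3
    return n_obs - 4


def iamb(target: str, data: pd.DataFrame, alpha: float = 0.05) -> MarkovBlanketResult:
    """Grow-then-shrink Markov blanket recovery for one target variable.

    Ties in the growing phase break lexicographically on the variable ID,
    so the result is deterministic for a given column set.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if data.shape[1] < 2:
        raise ValueError("data needs at least 2 variables")
    if len(data) < 8:
        raise ValueError("IAMB needs at least 8 observations")
    if target not in data.columns:
        raise KeyError(f"target {target!r} not in data")
    variables = sorted(c for c in data.columns if c != target)
    mb: set[str] = set()
    max_z = _max_valid_z(len(data))

    changed = True
    while changed:
        changed = False
        if len(mb) > max_z:
            break
        best: tuple[float, str] | None = None
        best_p = 1.0
        for cand in variables:
            if cand in mb:
                continue
            try:
                res = ci_test(target, cand, mb, data)
            except SingularConditioningError:
                logger.warning("skipping %s: singular conditioning", cand)
                continue
            key = (-abs(res.partial_corr), cand)
            if best is None or key < best:
                best, best_p = key, res.p_value
        if best is not None and best_p <= alpha:
            mb.add(best[1])
            changed = True

    mb = _shrink(target, mb, data, alpha)
    return MarkovBlanketResult(target=target, blanket=mb, alpha=alpha)


def _shrink(
    target: str, mb: set[str], data: pd.DataFrame, alpha: float
) -> set[str]:
    """Backward phase: drop members independent of the target given the rest."""
    mb = set(mb)
    changed = True
    while changed:
        changed = False
        for member in sorted(mb):
            rest = mb - {member}
            if len(rest) > _max_valid_z(len(data)):
                continue
            try:
                res = ci_test(target, member, rest, data)
            except SingularConditioningError:
                continue
            if res.p_value > alpha:
                mb.discard(member)
                changed = True
                break
    return mb


def tag_roles(
    mb: MarkovBlanketResult,
    data: pd.DataFrame,
    alpha: float | None = None,
    max_sepset: int = 3,
) -> MarkovBlanketResult:
    """Separate spouses from direct neighbors; orient children via colliders.

    A member b is a spouse if some subset of the remaining blanket
    d-separates it from the target (its link is explained away through a
    common child).  For each spouse, the neighbor that re-couples it to the
    target when conditioned on is marked a child (collider evidence).
    Everything else stays "undetermined"; blanket membership alone cannot
    orient a chain.
    """
    alpha = mb.alpha if alpha is None else alpha
    blanket = sorted(mb.blanket)
    max_z = min(_max_valid_z(len(data)), max_sepset)
    roles: dict[str, str] = {}
    sepsets: dict[str, frozenset[str]] = {}
    for member in blanket:
        rest = [b for b in blanket if b != member]
        separated = False
        for size in range(0, min(len(rest), max_z) + 1):
            for subset in itertools.combinations(rest, size):
                try:
                    res = ci_test(mb.target, member, set(subset), data)
                except (SingularConditioningError, ValueError):
                    continue
                if res.p_value > alpha:
                    separated = True
                    sepsets[member] = frozenset(subset)
                    break
            if separated:
                break
        roles[member] = "spouse" if separated else "undetermined"

    # collider check: conditioning on a child re-couples target and spouse
    for spouse, sepset in sepsets.items():
        for cand in blanket:
            if cand == spouse or roles[cand] == "spouse" or cand in sepset:
                continue
            cond = set(sepset) | {cand}
            if len(cond) > _max_valid_z(len(data)):
                continue
            try:
                res = ci_test(mb.target, spouse, cond, data)
            except SingularConditioningError:
                continue
            if res.p_value <= alpha:
                roles[cand] = "child"
    return MarkovBlanketResult(
        target=mb.target, blanket=set(mb.blanket), roles=roles, alpha=alpha
    )


def causal_network(
    data: pd.DataFrame,
    targets: list[str],
    alpha: float = 0.05,
    bonferroni: bool = False,
    and_rule: bool = True,
    with_roles: bool = True,
) -> tuple[nx.DiGraph, dict[str, MarkovBlanketResult]]:
    """Union of per-target blankets as a role-tagged directed graph.

    Edges run target -> member and carry the member's role.  With the
    AND-rule, a pair of targets where X sits in MB(Y) but Y is absent from
    MB(X) is dropped (logged) as an asymmetric false positive.
    """
    missing = [t for t in targets if t not in data.columns]
    if missing:
        raise KeyError(f"targets not in data: {missing[:5]}")
    alpha_eff = alpha / len(targets) if bonferroni and targets else alpha
    results: dict[str, MarkovBlanketResult] = {}
    for target in sorted(set(targets)):
        res = iamb(target, data, alpha=alpha_eff)
        if with_roles:
            res = tag_roles(res, data)
        results[target] = res

    if and_rule:
        for t1 in results:
            for t2 in sorted(results[t1].blanket):
                if t2 in results and t1 not in results[t2].blanket:
                    logger.info(
                        "AND-rule: dropping asymmetric pair (%s, %s)", t1, t2
                    )
                    results[t1].blanket.discard(t2)
                    results[t1].roles.pop(t2, None)

    graph = nx.DiGraph(alpha=alpha_eff)
    for target, res in results.items():
        graph.add_node(target, is_target=True)
        for member in sorted(res.blanket):
            if not graph.has_node(member):
                graph.add_node(member, is_target=member in results)
            graph.add_edge(
                target, member, role=res.roles.get(member, "undetermined")
            )
    return graph, results


def count_cross_relations(
    results: dict[str, MarkovBlanketResult], radiation: set[str]
) -> int:
    """One-to-one (radiation-induced, non-radiation-induced) blanket pairs."""
    pairs = set()
    for target, res in results.items():
        for member in res.blanket:
            a, b = sorted((target, member))
            if (a in radiation) != (b in radiation):
                pairs.add((a, b))
    return len(pairs)
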