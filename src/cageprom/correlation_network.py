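"""Kendall correlation networks over promoter properties.

Pairwise associations among promoter properties are measured with
tie-corrected Kendall tau-b (rank-based, so monotone transforms and the
flagged-infinite max/median values are handled naturally).  First-order
partial correlations test whether a pairwise association survives
controlling a third property, and ``reduce_to_direct`` applies the
heuristic that an association is indirect when a third property has
strictly stronger associations with both endpoints.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "kendall_tau",
    "partial_kendall",
    "partial_kendall_pvalue",
    "CorrelationResult",
    "correlate_all",
    "Edge",
    "CorrelationNetwork",
    "reduce_to_direct",
    "mosaic_counts",
]


def _clean_pair(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    return x[ok], y[ok]


def kendall_tau(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Tie-corrected Kendall tau-b with a two-sided normal-approximation p.

    Missing values are dropped pairwise; infinities are legal and rank
    above all finite values (ties among equal infinities are tie-corrected
    like any other tie).  Requires at least 10 complete pairs.
    """
    x, y = _clean_pair(x, y)
    if len(x) < 10:
        raise ValueError(f"need >= 10 complete pairs, got {len(x)}")
    res = stats.kendalltau(x, y, variant="b", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def partial_kendall(t_xy: float, t_xz: float, t_yz: float) -> float:
    """First-order Kendall partial correlation T_xy.z.

    T_xy.z = (T_xy - T_xz * T_yz) / sqrt((1 - T_xz^2) * (1 - T_yz^2)).
    Near-zero values indicate that the x-y association is explained by z.
    """
    if abs(t_xz) >= 1.0 or abs(t_yz) >= 1.0:
        raise ValueError("control correlations must have |T| < 1")
    denom = math.sqrt((1.0 - t_xz**2) * (1.0 - t_yz**2))
    return (t_xy - t_xz * t_yz) / denom


def partial_kendall_pvalue(t_xy_z: float, n: int, n_controls: int = 1) -> float:
    """Two-sided p-value for a Kendall partial correlation.

    Normal approximation on the statistic
    z = T_xy.z / sqrt(2 * (2*(n - g) + 5) / (9 * (n - g) * (n - 1 - g)))
    with g the number of controlled variables (the same large-sample
    variance used for plain Kendall tau, with reduced effective n).
    """
    g = n_controls
    if n - 1 - g <= 0:
        raise ValueError("too few observations for a p-value")
    se = math.sqrt(2.0 * (2.0 * (n - g) + 5.0) / (9.0 * (n - g) * (n - 1.0 - g)))
    z = t_xy_z / se
    return float(2.0 * stats.norm.sf(abs(z)))


def permutation_null_band(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = 200,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Two-sided (alpha/2, 1-alpha/2) band of Kendall tau under independence.

    Estimated by permuting ``y`` relative to ``x``; an observed tau inside
    the band is indistinguishable from no association at level alpha.
    """
    rng = np.random.default_rng() if rng is None else rng
    x, y = _clean_pair(x, y)
    taus = np.empty(n_perm)
    for i in range(n_perm):
        taus[i] = stats.kendalltau(
            x, y[rng.permutation(len(y))], variant="b", method="asymptotic"
        ).statistic
    lo, hi = np.quantile(taus, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


@dataclass
class CorrelationResult:
    """All pairwise Kendall correlations over a property table."""

    tau: pd.DataFrame
    p: pd.DataFrame
    significant: pd.DataFrame
    alpha: float
    n_pairs: int
    n_obs: pd.DataFrame

    @property
    def properties(self) -> list[str]:
        return list(self.tau.columns)


def correlate_all(
    properties: pd.DataFrame, alpha: float = 0.05, bonferroni: bool = True
) -> CorrelationResult:
    """Kendall tau-b and p-value for every pair of property columns.

    Observations are pairwise-complete (NaN dropped per pair); infinities
    rank extreme.  Significance flags use ``alpha``, Bonferroni-adjusted
    over the number of property pairs by default.
    """
    cols = list(properties.columns)
    k = len(cols)
    n_pairs = k * (k - 1) // 2
    tau = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    nobs = pd.DataFrame(np.zeros((k, k), dtype=int), index=cols, columns=cols)
    threshold = alpha / n_pairs if (bonferroni and n_pairs) else alpha
    for a, b in itertools.combinations(cols, 2):
        x, y = _clean_pair(properties[a].to_numpy(), properties[b].to_numpy())
        t, pv = kendall_tau(x, y)
        tau.loc[a, b] = tau.loc[b, a] = t
        p.loc[a, b] = p.loc[b, a] = pv
        nobs.loc[a, b] = nobs.loc[b, a] = len(x)
    sig = (p <= threshold) & ~np.eye(k, dtype=bool)
    return CorrelationResult(
        tau=tau, p=p, significant=sig, alpha=alpha, n_pairs=n_pairs, n_obs=nobs
    )


@dataclass(frozen=True)
class Edge:
    x: str
    y: str
    tau: float
    p: float
    status: str  # direct | indirect | nonsignificant

    @property
    def sign(self) -> int:
        return int(np.sign(self.tau))


@dataclass
class CorrelationNetwork:
    nodes: list[str]
    edges: list[Edge] = field(default_factory=list)

    def direct_edges(self) -> list[Edge]:
        return [e for e in self.edges if e.status == "direct"]

    def edge(self, x: str, y: str) -> Edge | None:
        for e in self.edges:
            if {e.x, e.y} == {x, y}:
                return e
        return None

    def to_json(self) -> str:
        return json.dumps(
            {
                "nodes": self.nodes,
                "edges": [
                    {"x": e.x, "y": e.y, "tau": e.tau, "p": e.p, "status": e.status}
                    for e in self.edges
                ],
            },
            indent=2,
        )


def _triangle_reduce(
    pairs: list[tuple[str, str]],
    strength: dict[tuple[str, str], float],
    nodes: list[str],
    covers_must_be_direct: bool = False,
) -> set[tuple[str, str]]:
    """Triangle rule: discard associations explainable by stronger ones.

    An edge (x, y) is indirect when some third node z has significant
    edges to both x and y that are both strictly stronger than (x, y) -
    the pair of stronger associations "potentially explains" the weaker
    one.  With ``covers_must_be_direct`` the two covering edges must
    additionally have been decided direct themselves; edges are decided
    in decreasing |tau| (covers are strictly stronger, so every cover is
    decided before the edges it covers, and one pass reaches the fixed
    point).  The conservative variant prunes less on long causal chains,
    where the intermediate links of a shortcut association are themselves
    explained away.
    """
    indirect: set[tuple[str, str]] = set()

    def key_of(a: str, b: str) -> tuple[str, str] | None:
        if (a, b) in strength:
            return (a, b)
        if (b, a) in strength:
            return (b, a)
        return None

    for x, y in sorted(pairs, key=lambda k: abs(strength[k]), reverse=True):
        for z in nodes:
            if z in (x, y):
                continue
            kxz = key_of(x, z)
            kyz = key_of(y, z)
            if kxz is None or kyz is None:
                continue
            if covers_must_be_direct and (kxz in indirect or kyz in indirect):
                continue
            if (
                abs(strength[kxz]) > abs(strength[(x, y)])
                and abs(strength[kyz]) > abs(strength[(x, y)])
            ):
                indirect.add((x, y))
                break
    return indirect


def _widest_path_bottleneck(
    nodes: list[str],
    strength: dict[tuple[str, str], float],
    src: str,
    dst: str,
    exclude: tuple[str, str],
) -> float:
    """Maximum over paths src->dst of the minimum |tau| along the path,
    excluding the direct edge itself."""
    best = {n: 0.0 for n in nodes}
    best[src] = float("inf")
    visited: set[str] = set()
    while True:
        cand = [(v, n) for n, v in best.items() if n not in visited and v > 0]
        if not cand:
            return 0.0
        v, n = max(cand)
        if n == dst:
            return v
        visited.add(n)
        for (a, b), t in strength.items():
            if {a, b} == set(exclude):
                continue
            if a == n or b == n:
                other = b if a == n else a
                bott = min(v, abs(t))
                if bott > best[other]:
                    best[other] = bott


def reduce_to_direct(
    result: CorrelationResult,
    rule: str = "triangle",
) -> CorrelationNetwork:
    """Classify significant associations as direct or indirect.

    ``triangle`` (default): an edge (x, y) is marked indirect when some
    third property z has |T_xz| > |T_xy| and |T_yz| > |T_xy| with both of
    those stronger edges significant - every association that can
    potentially be explained by a pair of strictly stronger associations
    through a third property is discarded.  ``triangle_direct`` is the
    conservative variant requiring the two covering edges to be direct
    themselves.  ``strongest_path`` instead marks (x, y) indirect when
    some other path between x and y has a bottleneck |tau| exceeding
    |T_xy|.  The globally strongest edge can never be marked indirect
    under any rule.  Nonsignificant pairs are carried through with status
    "nonsignificant".
    """
    nodes = result.properties
    sig_pairs = [
        (x, y)
        for x, y in itertools.combinations(nodes, 2)
        if result.significant.loc[x, y]
    ]
    strength = {(x, y): float(result.tau.loc[x, y]) for x, y in sig_pairs}

    if rule == "triangle":
        indirect = _triangle_reduce(sig_pairs, strength, nodes)
    elif rule == "triangle_direct":
        indirect = _triangle_reduce(
            sig_pairs, strength, nodes, covers_must_be_direct=True
        )
    elif rule == "strongest_path":
        indirect = set()
        for x, y in sig_pairs:
            bott = _widest_path_bottleneck(nodes, strength, x, y, (x, y))
            if bott > abs(strength[(x, y)]):
                indirect.add((x, y))
    else:
        raise ValueError(f"unknown reduction rule {rule!r}")

    edges = []
    for x, y in itertools.combinations(nodes, 2):
        t = float(result.tau.loc[x, y])
        pv = float(result.p.loc[x, y])
        if (x, y) in strength:
            status = "indirect" if (x, y) in indirect else "direct"
        else:
            status = "nonsignificant"
        edges.append(Edge(x=x, y=y, tau=t, p=pv, status=status))
    return CorrelationNetwork(nodes=nodes, edges=edges)


def mosaic_counts(
    properties: pd.DataFrame,
    iqr_threshold: float = 7.0,
    cpg_threshold: float = 0.5,
    iqr_col: str = "iqr",
    cpg_col: str = "cpg_oe",
) -> tuple[pd.DataFrame, float, float]:
    """2x2 counts of promoters by TSS-spread class and CpG class.

    Rows split promoters at ``iqr_threshold`` (narrow: IQR < threshold),
    columns at ``cpg_threshold`` (low: cpg_oe < threshold).  Also returns
    Kendall tau and p for the association between the two underlying
    continuous properties.  Promoters with a missing value in either
    property are excluded; counts sum to the number of complete rows.
    """
    sub = properties[[iqr_col, cpg_col]].dropna()
    narrow = sub[iqr_col] < iqr_threshold
    low = sub[cpg_col] < cpg_threshold
    table = pd.DataFrame(
        {
            "low_cpg": [int((narrow & low).sum()), int((~narrow & low).sum())],
            "high_cpg": [int((narrow & ~low).sum()), int((~narrow & ~low).sum())],
        },
        index=["narrow", "wide"],
    )
    t, p = kendall_tau(sub[iqr_col].to_numpy(), sub[cpg_col].to_numpy())
    return table, t, p
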