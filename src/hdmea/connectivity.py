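"""Cross-correlation functional connectivity between sorted units.

Spike-time differences between ordered pairs of trains are histogrammed
over a symmetric +-30 ms window in 3 ms bins; the correlogram peak,
normalised by the geometric mean of the two spike counts, gives a
"correlation value" in [0, 1] whose peak lag carries the link direction.
Links are called against jitter surrogates (each spike displaced uniformly
by +-50 ms, which destroys millisecond-scale coincidences while preserving
slow rate structure).  The correlation index (CI) of a graph is the number
of called links divided by the number of units.

Link calling controls the family-wise error over all ordered pairs at level
``alpha``: a pair's observed value must exceed both the empirical
(1 - alpha) surrogate quantile and a Gaussian tail bound at level
alpha / n_pairs fitted to the surrogate values.  Without the correction the
expected number of chance links (alpha x n_pairs) would swamp the handful
of genuine connections in a sparse network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
from scipy import stats

__all__ = [
    "Link",
    "ConnectivityGraph",
    "cross_correlogram",
    "correlation_value",
    "call_links",
    "correlation_index",
    "sample_correlation_values",
]

WINDOW_MS = 30.0
BIN_MS = 3.0


def _bin_edges_s(window_ms: float, bin_ms: float) -> np.ndarray:
    n_bins = int(round(2 * window_ms / bin_ms))
    return (np.arange(n_bins + 1) * bin_ms - window_ms) * 1e-3


def cross_correlogram(
    train_a: np.ndarray,
    train_b: np.ndarray,
    window_ms: float = WINDOW_MS,
    bin_ms: float = BIN_MS,
) -> Tuple[np.ndarray, np.ndarray]:
    """Counts of spike-time differences t_b - t_a over lag bins.

    Bins are right-open ([edge, edge + bin)), covering [-window, +window);
    a zero-lag difference (identical spike copies) falls in the bin whose
    left edge is 0.  Returns (counts, bin_edges_s).
    """
    edges = _bin_edges_s(window_ms, bin_ms)
    a = np.sort(np.asarray(train_a, float))
    b = np.sort(np.asarray(train_b, float))
    n_bins = edges.size - 1
    if a.size == 0 or b.size == 0:
        return np.zeros(n_bins, dtype=np.int64), edges
    # gather only the differences inside the window, then bin them
    lo = np.searchsorted(b, a + edges[0], side="left")
    hi = np.searchsorted(b, a + edges[-1], side="left")
    per_a = hi - lo
    total = int(per_a.sum())
    if total == 0:
        return np.zeros(n_bins, dtype=np.int64), edges
    offsets = np.cumsum(per_a) - per_a
    idx = np.arange(total) - np.repeat(offsets, per_a) + np.repeat(lo, per_a)
    diffs = b[idx] - np.repeat(a, per_a)
    bins = np.searchsorted(edges, diffs, side="right") - 1
    counts = np.bincount(bins[(bins >= 0) & (bins < n_bins)], minlength=n_bins)
    return counts.astype(np.int64), edges


def correlation_value(
    train_a: np.ndarray,
    train_b: np.ndarray,
    window_ms: float = WINDOW_MS,
    bin_ms: float = BIN_MS,
) -> Tuple[float, float]:
    """Normalised cross-correlation statistic in [0, 1] and its peak lag (ms).

    The correlogram peak count is divided by the geometric mean of the two
    spike counts and clipped to [0, 1]; identical trains give 1, trains with
    no differences inside the window give 0.  Empty trains return 0.
    """
    a = np.asarray(train_a, float)
    b = np.asarray(train_b, float)
    if a.size == 0 or b.size == 0:
        return 0.0, 0.0
    counts, edges = cross_correlogram(a, b, window_ms, bin_ms)
    peak = int(np.argmax(counts))
    value = float(counts[peak]) / float(np.sqrt(a.size * b.size))
    lag_ms = float((edges[peak] + edges[peak + 1]) / 2.0 * 1e3)
    return float(np.clip(value, 0.0, 1.0)), lag_ms


@dataclass(frozen=True)
class Link:
    source: int
    target: int
    correlation_value: float
    lag_ms: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.correlation_value <= 1.0:
            raise ValueError("correlation value must lie in [0, 1]")
        if abs(self.lag_ms) > WINDOW_MS:
            raise ValueError("lag exceeds the correlation window")


@dataclass
class ConnectivityGraph:
    """Directed functional-connectivity graph for one condition epoch."""

    nodes: List[int]
    links: List[Link]
    positions_um: Dict[int, Tuple[float, float]] = field(default_factory=dict)
    condition_label: str = ""

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_links(self) -> int:
        return len(self.links)

    @property
    def correlation_index(self) -> float:
        if self.n_nodes == 0:
            raise ZeroDivisionError("correlation index undefined for zero units")
        return self.n_links / self.n_nodes

    def node_roles(self) -> Dict[int, str]:
        """'incoming', 'outgoing' or 'both' per node with at least one link."""
        incoming = {l.target for l in self.links}
        outgoing = {l.source for l in self.links}
        roles = {}
        for node in self.nodes:
            if node in incoming and node in outgoing:
                roles[node] = "both"
            elif node in incoming:
                roles[node] = "incoming"
            elif node in outgoing:
                roles[node] = "outgoing"
        return roles

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph(condition=self.condition_label)
        for node in self.nodes:
            pos = self.positions_um.get(node)
            if pos is None:
                g.add_node(node)
            else:
                g.add_node(node, x_um=float(pos[0]), y_um=float(pos[1]))
        for l in self.links:
            g.add_edge(l.source, l.target, value=l.correlation_value, lag_ms=l.lag_ms)
        return g

    def write_graphml(self, path: str) -> None:
        nx.write_graphml(self.to_networkx(), path)


def call_links(
    trains: Sequence[np.ndarray],
    alpha: float = 0.05,
    n_surrogates: int = 100,
    jitter_ms: float = 50.0,
    window_ms: float = WINDOW_MS,
    bin_ms: float = BIN_MS,
    positions_um: Optional[Dict[int, Tuple[float, float]]] = None,
    condition_label: str = "",
    seed: int = 0,
    family_wise: bool = True,
    require_positive_lag: bool = True,
) -> ConnectivityGraph:
    """Call directed links between units against jitter surrogates.

    For each ordered pair the observed correlation value is compared with
    the values obtained after jittering the target train ``n_surrogates``
    times by +-``jitter_ms``.  A link is called when the observed value
    exceeds the empirical (1 - alpha) surrogate quantile and, with
    ``family_wise=True`` (default), a normal tail bound at level
    alpha / n_pairs on the surrogate distribution, keeping the expected
    number of chance links across the whole network near alpha.

    With ``require_positive_lag`` (default) a link i -> j is only called
    when the correlogram peak sits at positive lag (target fires after
    source); the reverse pair then carries the peak at negative lag and is
    not double-reported.
    """
    n = len(trains)
    if n < 2:
        return ConnectivityGraph(
            nodes=list(range(n)),
            links=[],
            positions_um=positions_um or {},
            condition_label=condition_label,
        )
    if n_surrogates < int(np.ceil(1.0 / alpha)) - 1:
        raise ValueError(
            f"n_surrogates={n_surrogates} cannot resolve the (1 - {alpha}) quantile"
        )
    rng = np.random.default_rng(seed)
    trains = [np.sort(np.asarray(t, float)) for t in trains]
    jitter = jitter_ms * 1e-3
    surrogates: List[List[np.ndarray]] = []
    for t in trains:
        surrogates.append(
            [
                np.sort(t + rng.uniform(-jitter, jitter, size=t.size))
                for _ in range(n_surrogates)
            ]
        )
    n_pairs = n * (n - 1)
    z = stats.norm.ppf(1.0 - alpha / n_pairs) if family_wise else None
    links: List[Link] = []
    for i in range(n):
        for j in range(n):
            if i == j or trains[i].size == 0 or trains[j].size == 0:
                continue
            obs, lag = correlation_value(trains[i], trains[j], window_ms, bin_ms)
            if require_positive_lag and lag <= 0:
                continue
            surr = np.array(
                [
                    correlation_value(trains[i], s, window_ms, bin_ms)[0]
                    for s in surrogates[j]
                ]
            )
            threshold = np.quantile(surr, 1.0 - alpha)
            if family_wise:
                threshold = max(threshold, surr.mean() + z * surr.std(ddof=1))
            if obs > threshold:
                links.append(Link(i, j, obs, lag))
    return ConnectivityGraph(
        nodes=list(range(n)),
        links=links,
        positions_um=positions_um or {},
        condition_label=condition_label,
    )


def correlation_index(graph: ConnectivityGraph) -> float:
    """Number of called links divided by the number of units."""
    return graph.correlation_index


def sample_correlation_values(
    values: Sequence[float], n: int = 100, seed: int = 0
) -> np.ndarray:
    """Uniform sample of ``n`` correlation values without replacement.

    When fewer than ``n`` values are available the full set is returned and
    a warning is emitted (the statistical comparison then simply uses all
    values).
    """
    values = np.asarray(values, float)
    if n >= values.size:
        if n > values.size:
            import warnings

            warnings.warn(
                f"requested {n} values but only {values.size} available; "
                "returning all",
                stacklevel=2,
            )
        return values.copy()
    rng = np.random.default_rng(seed)
    return rng.choice(values, size=n, replace=False)
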