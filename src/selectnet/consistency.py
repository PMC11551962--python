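"""Cross-validation diagnostics for free-energy networks.

Alchemical estimates of the same quantity obtained along different routes
(direct vs. composed from other legs) should agree within their statistical
uncertainty.  This module implements the standard diagnostics: direct-vs-
indirect comparisons with a two-sided significance test, RMSD aggregation,
cycle-closure sums, and forward/reverse hysteresis.

The significance test is a two-sided z test on the normal distribution —
the large-sample limit of a t test on uncertainties that are themselves
estimated from long time series.  Comparisons between quantities that share
inputs ignore their covariance (plain quadrature), a deliberate and
documented simplification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import networkx as nx
from scipy.stats import norm

from .network import Edge, Network, Node
from .thermo import Measurement, difference

__all__ = [
    "ComparisonRecord",
    "ConsistencyReport",
    "CycleClosure",
    "rmsd",
    "compare",
    "compare_many",
    "hysteresis",
    "cycle_closure",
]


@dataclass(frozen=True)
class ComparisonRecord:
    """A direct estimate against an indirect (composed) one.

    ``delta = direct - indirect``; ``combined_sigma`` is the 1-sigma
    quadrature of the two errors; ``z = |delta| / combined_sigma``;
    ``p_value`` is the two-sided normal tail; ``significant`` at the
    stated alpha.
    """

    label: str
    direct: Measurement
    indirect: Measurement
    delta: float
    combined_sigma: float
    z: float
    p_value: float
    significant: bool
    alpha: float = 0.05


@dataclass(frozen=True)
class ConsistencyReport:
    records: List[ComparisonRecord]
    rmsd: float
    n: int

    @property
    def flagged(self) -> List[ComparisonRecord]:
        return [r for r in self.records if r.significant]


@dataclass(frozen=True)
class CycleClosure:
    """Signed sum of edge values around one independent undirected cycle."""

    nodes: Tuple[Node, ...]
    closure: float
    uncertainty: Optional[float]  # 2-sigma quadrature, None if any edge lacks one


def rmsd(pairs: Sequence[Tuple[float, float]]) -> float:
    """Root-mean-square deviation ``sqrt(mean((a - b)**2))`` over pairs."""
    if len(pairs) == 0:
        raise ValueError("rmsd of an empty list is undefined")
    return math.sqrt(sum((a - b) ** 2 for a, b in pairs) / len(pairs))


def compare(
    direct: Measurement,
    indirect: Measurement,
    alpha: float = 0.05,
    label: str = "",
) -> ComparisonRecord:
    """Two-sided z test of a direct estimate against an indirect one.

    Both measurements must carry uncertainties (2-sigma convention); the
    combined error is their 1-sigma quadrature.  ``significant`` means the
    discrepancy had probability < alpha of arising by chance under the
    Gaussian error model.
    """
    if direct.uncertainty is None or indirect.uncertainty is None:
        raise ValueError("cannot test significance without both uncertainties")
    if direct.uncertainty == 0 and indirect.uncertainty == 0:
        raise ValueError("cannot test significance with two exact values")
    delta = direct.value - indirect.value
    combined_sigma = math.hypot(direct.sigma, indirect.sigma)
    z = abs(delta) / combined_sigma
    p = 2.0 * norm.sf(z)
    return ComparisonRecord(
        label=label,
        direct=direct,
        indirect=indirect,
        delta=delta,
        combined_sigma=combined_sigma,
        z=z,
        p_value=float(p),
        significant=bool(p < alpha),
        alpha=alpha,
    )


def compare_many(
    items: Iterable[Tuple[str, Measurement, Measurement]],
    alpha: float = 0.05,
) -> ConsistencyReport:
    """Compare labelled (direct, indirect) pairs and aggregate their RMSD."""
    records = [compare(d, i, alpha=alpha, label=lab) for lab, d, i in items]
    agg = rmsd([(r.direct.value, r.indirect.value) for r in records])
    return ConsistencyReport(records=records, rmsd=agg, n=len(records))


def hysteresis(forward: Measurement, reverse: Measurement) -> Measurement:
    """Forward/reverse convergence check for a swap computed both ways.

    A transformation run forward and then in reverse forms a closed cycle,
    so the two free energies must sum to zero; the deviation
    ``|forward + reverse|`` (uncertainty by quadrature) measures hysteresis.
    """
    s = difference(forward, -reverse)  # forward - (-reverse) = forward + reverse
    return Measurement(abs(s.value), s.uncertainty)


def cycle_closure(network: Network) -> List[CycleClosure]:
    """Signed closure sums over an independent cycle basis of the network.

    Each cycle's closure is the sum of edge values traversed head-ward minus
    those traversed tail-ward; thermodynamically consistent data close to
    zero within the quadrature uncertainty.  Parallel edges between the same
    node pair form two-node cycles and are included.
    """
    g = network.as_undirected()
    closures: List[CycleClosure] = []

    # cycle_basis works on simple graphs; handle parallel edges separately,
    # then compute the basis on the collapsed simple graph using one
    # representative edge per node pair.
    rep: dict[frozenset, Edge] = {}
    for e in network.edges:
        key = frozenset((e.tail, e.head))
        if key in rep:
            first = rep[key]
            # two-edge cycle: traverse first forward, e backward (or aligned)
            if (first.tail, first.head) == (e.tail, e.head):
                val = first.measurement.value - e.measurement.value
            else:
                val = first.measurement.value + e.measurement.value
            unc = _quad2(first, e)
            closures.append(CycleClosure((e.tail, e.head), val, unc))
        else:
            rep[key] = e

    simple = nx.Graph()
    simple.add_nodes_from(g.nodes)
    for key, e in rep.items():
        a, b = tuple(key)
        simple.add_edge(a, b, edge=e)
    for cyc in nx.cycle_basis(simple):
        total = 0.0
        var = 0.0
        missing = False
        for a, b in zip(cyc, cyc[1:] + cyc[:1]):
            e: Edge = simple.edges[a, b]["edge"]
            sign = 1.0 if (e.tail, e.head) == (a, b) else -1.0
            total += sign * e.measurement.value
            if e.measurement.uncertainty is None:
                missing = True
            else:
                var += e.measurement.uncertainty**2
        closures.append(
            CycleClosure(tuple(cyc), total, None if missing else math.sqrt(var))
        )
    return closures


def _quad2(a: Edge, b: Edge) -> Optional[float]:
    ua, ub = a.measurement.uncertainty, b.measurement.uncertainty
    if ua is None or ub is None:
        return None
    return math.hypot(ua, ub)
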