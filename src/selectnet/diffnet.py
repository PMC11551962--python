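"""Generalized DiffNet: maximum-likelihood node estimates from difference edges.

Given a network of measured free-energy differences d_e with standard
deviations sigma_e and one or more anchored nodes, the estimates x minimize

    F(x) = sum_e (x_head - x_tail - d_e)**2 / sigma_e**2

with anchored nodes held fixed (hard anchors, the default) or restrained
(soft anchors).  For RBFE/RHFE networks the nodes are absolute binding free
energies of receptor–ligand complexes; for RSFE networks they are per-ligand
binding selectivity free energies.  The two cases share one solver: only the
meaning of the nodes differs.

The minimizer solves the reduced weighted-Laplacian normal equations
``L x = b`` over the free (non-anchored) nodes with edge weights
``w_e = 1/sigma_e**2``; node variances are the diagonal of ``L^-1``.
Edge uncertainties are supplied on the reported 2-sigma scale and halved
for the weights.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .network import Anchor, Edge, Network, Node
from .thermo import Measurement

__all__ = [
    "SolveResult",
    "DegenerateWeightError",
    "UnsolvableNetworkError",
    "objective",
    "solve",
    "solve_selectivity",
    "uncertainties",
]

logger = logging.getLogger(__name__)

#: condition number above which the reduced system is reported as ill-conditioned
CONDITION_WARN_THRESHOLD = 1e12


class DegenerateWeightError(ValueError):
    """An edge has zero or missing uncertainty and cannot be weighted."""


class UnsolvableNetworkError(ValueError):
    """The reduced system is singular (a component lacks an anchor)."""


@dataclass(frozen=True)
class SolveResult:
    """Solution of a difference network.

    ``estimates`` and ``uncertainties`` (2-sigma) are per node;
    ``residuals[i]`` is ``x_head - x_tail - d_e`` for the i-th edge of the
    input network; ``objective`` is the minimized weighted sum of squares.
    """

    estimates: Dict[Node, float]
    uncertainties: Dict[Node, float]
    residuals: List[float]
    objective: float

    def estimate(self, node: Node) -> Measurement:
        """The solved value of ``node`` as a Measurement (2-sigma error)."""
        return Measurement(self.estimates[node], self.uncertainties[node])


def _edge_weight(e: Edge) -> float:
    u = e.measurement.uncertainty
    if u is None or u == 0:
        raise DegenerateWeightError(
            f"edge {e.tail} -> {e.head} has uncertainty {u!r}; exact constraints "
            "must be expressed as anchors, not zero-variance edges"
        )
    sigma = u / 2.0  # reported uncertainties are 2-sigma
    return 1.0 / (sigma * sigma)


def objective(network: Network, assignment: Mapping[Node, float]) -> float:
    """Weighted sum of squared edge discrepancies for a full assignment.

    Anchored nodes contribute no term (they are hard constraints); the
    assignment must cover every node in the network.
    """
    missing = [n for n in network.nodes if n not in assignment]
    if missing:
        raise KeyError(f"assignment missing {len(missing)} node(s), e.g. {missing[0]}")
    total = 0.0
    for e in network.edges:
        w = _edge_weight(e)
        r = assignment[e.head] - assignment[e.tail] - e.measurement.value
        total += w * r * r
    return total


def _anchor_values(network: Network, hard: bool) -> Dict[Node, Anchor]:
    by_node: Dict[Node, Anchor] = {}
    for a in network.anchors:
        prev = by_node.get(a.node)
        if prev is not None and hard and prev.value.value != a.value.value:
            raise UnsolvableNetworkError(
                f"conflicting hard anchors on {a.node}: "
                f"{prev.value.value} vs {a.value.value}"
            )
        by_node[a.node] = a
    return by_node


def solve(network: Network, *, soft_anchors: bool = False) -> SolveResult:
    """Maximum-likelihood node estimates for a difference network.

    Parameters
    ----------
    network
        The network to solve.  Every connected component must contain at
        least one anchor.
    soft_anchors
        If True, anchors enter the objective as Gaussian prior terms
        weighted by their own reported uncertainty (2-sigma; anchors
        without an uncertainty are restrained with sigma = 1e-6 kcal/mol,
        effectively hard).  Useful for fusing several absolute references.
        Default is hard anchoring: anchored nodes are eliminated from the
        linear system and reproduce their anchor values exactly.

    Returns
    -------
    SolveResult
        Estimates, 2-sigma uncertainties, per-edge residuals, and the
        minimized objective.

    Raises
    ------
    UnsolvableNetworkError
        If some connected component has no anchor (the system is singular
        there; this is detected structurally before factorization).
    DegenerateWeightError
        If any edge has a zero or missing uncertainty.
    """
    findings = network.validate()
    errors = [f for f in findings if f.level == "error"]
    if errors:
        raise UnsolvableNetworkError("; ".join(f.message for f in errors))

    nodes = network.nodes
    anchors = _anchor_values(network, hard=not soft_anchors)
    if soft_anchors:
        free = list(nodes)
    else:
        free = [n for n in nodes if n not in anchors]
    index = {n: i for i, n in enumerate(free)}
    nfree = len(free)

    est: Dict[Node, float] = {n: a.value.value for n, a in anchors.items()}
    if nfree == 0:
        residuals = [
            est[e.head] - est[e.tail] - e.measurement.value for e in network.edges
        ]
        obj = objective(network, est) if network.edges else 0.0
        unc = {n: (anchors[n].value.uncertainty or 0.0) for n in nodes}
        return SolveResult(est, unc, residuals, obj)

    lap = np.zeros((nfree, nfree))
    rhs = np.zeros(nfree)
    for e in network.edges:
        w = _edge_weight(e)
        d = e.measurement.value
        it = index.get(e.tail)
        ih = index.get(e.head)
        if it is not None and ih is not None:
            lap[it, it] += w
            lap[ih, ih] += w
            lap[it, ih] -= w
            lap[ih, it] -= w
            rhs[ih] += w * d
            rhs[it] -= w * d
        elif ih is not None:  # tail anchored
            lap[ih, ih] += w
            rhs[ih] += w * (d + est[e.tail])
        elif it is not None:  # head anchored
            lap[it, it] += w
            rhs[it] += w * (est[e.head] - d)
        # both anchored: constant term, no influence on the minimizer

    if soft_anchors:
        for n, a in anchors.items():
            u = a.value.uncertainty
            sigma = (u / 2.0) if u else 1e-6
            w = 1.0 / (sigma * sigma)
            i = index[n]
            lap[i, i] += w
            rhs[i] += w * a.value.value

    try:
        factor = cho_factor(lap)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by validate()
        raise UnsolvableNetworkError(f"singular reduced system: {exc}") from exc
    x = cho_solve(factor, rhs)
    cov = cho_solve(factor, np.eye(nfree))

    cond = np.linalg.cond(lap)
    if cond > CONDITION_WARN_THRESHOLD:
        msg = f"reduced system condition number {cond:.2e} exceeds 1e12"
        logger.warning(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)
    else:
        logger.debug("reduced system condition number %.3e", cond)

    for n, i in index.items():
        est[n] = float(x[i])
    unc: Dict[Node, float] = {}
    for n in nodes:
        if n in index:
            unc[n] = 2.0 * float(np.sqrt(cov[index[n], index[n]]))
        else:
            unc[n] = anchors[n].value.uncertainty or 0.0
    residuals = [
        est[e.head] - est[e.tail] - e.measurement.value for e in network.edges
    ]
    obj = float(sum(_edge_weight(e) * r * r for e, r in zip(network.edges, residuals)))
    return SolveResult(est, unc, residuals, obj)


def solve_selectivity(network: Network, *, soft_anchors: bool = False) -> SolveResult:
    """Solve a selectivity (BSFE/RSFE) network.

    The same estimator as :func:`solve`; provided as a named entry point for
    the selectivity workflow, with a mode check.
    """
    from .network import NetworkMode

    if network.mode is not NetworkMode.SELECTIVITY:
        raise UnsolvableNetworkError(
            "solve_selectivity expects a selectivity-mode network"
        )
    return solve(network, soft_anchors=soft_anchors)


def uncertainties(network: Network, result: SolveResult) -> Dict[Node, float]:
    """Per-node 2-sigma uncertainties of a solved network.

    These are computed during :func:`solve` (diagonal of the inverse reduced
    precision matrix); exposed separately for symmetry with the objective.
    """
    return dict(result.uncertainties)
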