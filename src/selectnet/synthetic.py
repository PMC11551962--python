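"""Synthetic ground-truth affinity tables and noised difference networks.

The generator emulates the statistical structure the network solver assumes:
a fixed (receptor x ligand) table of true absolute binding free energies,
from which every pairwise difference (RBFE, BSFE/RHFE, RSFE) follows exactly,
plus independent Gaussian noise added per edge.  Because the true table
satisfies all thermodynamic identities by construction, every derived cycle
closes exactly, and parameter-recovery experiments isolate the estimator's
statistical behaviour from any model error.

Noise is applied to edges, not nodes, matching the error model implicit in
per-calculation uncertainties.  A fixed seed gives byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Literal, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .diffnet import SolveResult, solve
from .network import ComplexNode, Network, NetworkMode, SelectivityNode
from .thermo import Measurement

__all__ = [
    "GroundTruth",
    "NoiseSpec",
    "RecoverySummary",
    "generate_truth",
    "sample_network",
    "recovery_experiment",
]

Topology = Literal["all_pairs", "star", "chain"]

# nominal 1-sigma recorded on noiseless edges so the network stays weightable;
# with exact data the WLS solution is weight-independent
_NOMINAL_SIGMA = 1e-6


@dataclass(frozen=True)
class GroundTruth:
    """True affinities: receptors x ligands -> ABFE (kcal/mol).

    All difference quantities are derived from this table through the
    thermodynamic identities, so they are mutually consistent to machine
    precision.
    """

    receptors: Tuple[str, ...]
    ligands: Tuple[str, ...]
    abfe: pd.DataFrame  # index = receptors, columns = ligands

    def abfe_value(self, receptor: str, ligand: str) -> float:
        return float(self.abfe.at[receptor, ligand])

    def rbfe(self, receptor: str, ligand_from: str, ligand_to: str) -> float:
        return self.abfe_value(receptor, ligand_to) - self.abfe_value(
            receptor, ligand_from
        )

    def bsfe(self, ligand: str, receptor_from: str, receptor_to: str) -> float:
        return self.abfe_value(receptor_to, ligand) - self.abfe_value(
            receptor_from, ligand
        )

    def rsfe(
        self,
        ligand_1: str,
        ligand_2: str,
        receptor_from: str,
        receptor_to: str,
    ) -> float:
        """Swap free energy for (L1 at receptor_from, L2 at receptor_to)."""
        return self.bsfe(ligand_1, receptor_from, receptor_to) - self.bsfe(
            ligand_2, receptor_from, receptor_to
        )


@dataclass(frozen=True)
class NoiseSpec:
    """How to corrupt and wire a sampled network.

    ``edge_sigma`` is the 1-sigma of the Gaussian noise added to each edge;
    the edge's reported uncertainty is recorded as ``2 * edge_sigma``.
    ``topology`` wires the ligand pairs within each receptor (and the
    selectivity-node pairs in selectivity mode); ``n_hop_edges`` is how many
    ligands carry an RHFE edge between consecutive receptors.
    """

    edge_sigma: float = 0.2
    seed: int = 0
    topology: Topology = "all_pairs"
    n_hop_edges: int = 1
    custom_pairs: Optional[Sequence[Tuple[str, str]]] = None

    def __post_init__(self) -> None:
        if self.edge_sigma < 0:
            raise ValueError(f"edge_sigma must be >= 0, got {self.edge_sigma}")
        if self.n_hop_edges < 1:
            raise ValueError("need at least one hop edge per receptor pair")


def generate_truth(
    n_receptors: int,
    n_ligands: int,
    value_range: Tuple[float, float] = (-12.0, 0.0),
    seed: int = 0,
) -> GroundTruth:
    """Draw a ground-truth ABFE table uniformly over ``value_range``.

    Receptors are named R1..Rn and ligands L1..Ln; the same seed always
    yields the same table.
    """
    if n_receptors < 1 or n_ligands < 1:
        raise ValueError("need at least one receptor and one ligand")
    lo, hi = value_range
    if not (hi > lo):
        raise ValueError(f"empty value range: {value_range}")
    rng = np.random.default_rng(seed)
    receptors = tuple(f"R{i + 1}" for i in range(n_receptors))
    ligands = tuple(f"L{i + 1}" for i in range(n_ligands))
    table = pd.DataFrame(
        rng.uniform(lo, hi, size=(n_receptors, n_ligands)),
        index=receptors,
        columns=ligands,
    )
    return GroundTruth(receptors, ligands, table)


def _ligand_pairs(
    ligands: Sequence[str], noise: NoiseSpec
) -> List[Tuple[str, str]]:
    if noise.custom_pairs is not None:
        return list(noise.custom_pairs)
    if noise.topology == "all_pairs":
        return [
            (ligands[i], ligands[j])
            for i in range(len(ligands))
            for j in range(i + 1, len(ligands))
        ]
    if noise.topology == "star":
        hub = ligands[0]
        return [(hub, l) for l in ligands[1:]]
    if noise.topology == "chain":
        return list(zip(ligands[:-1], ligands[1:]))
    raise ValueError(f"unknown topology {noise.topology!r}")


def sample_network(
    truth: GroundTruth,
    noise: NoiseSpec,
    mode: NetworkMode | str = NetworkMode.COMPLEX,
) -> Network:
    """Sample a solvable noised network from the ground truth.

    Complex mode: an RBFE subnetwork per receptor over the chosen ligand-pair
    topology, RHFE edges for the first ``n_hop_edges`` ligands between each
    consecutive receptor pair, and one hard anchor at the true value of the
    first receptor's first ligand.

    Selectivity mode: BSFE nodes for the first two receptors over all
    ligands, RSFE edges over the same ligand-pair topology, anchored at the
    first ligand's true BSFE.

    Edge values are true differences plus ``N(0, edge_sigma**2)``; recorded
    edge uncertainties are ``2 * edge_sigma`` (a nominal tiny sigma when
    ``edge_sigma == 0``, so that a noiseless network remains solvable).
    """
    mode = NetworkMode(mode)
    rng = np.random.default_rng([noise.seed, 0xD1FF])
    sig = noise.edge_sigma
    reported = 2.0 * (sig if sig > 0 else _NOMINAL_SIGMA)

    def noisy(true_value: float) -> Measurement:
        if sig > 0:
            true_value = true_value + rng.normal(0.0, sig)
        return Measurement(true_value, reported)

    pairs = _ligand_pairs(truth.ligands, noise)
    if mode is NetworkMode.COMPLEX:
        net = Network(NetworkMode.COMPLEX)
        for receptor in truth.receptors:
            for la, lb in pairs:
                net.add_rbfe(receptor, la, lb, noisy(truth.rbfe(receptor, la, lb)))
        for ra, rb in zip(truth.receptors[:-1], truth.receptors[1:]):
            for ligand in truth.ligands[: noise.n_hop_edges]:
                net.add_rhfe(ligand, ra, rb, noisy(truth.bsfe(ligand, ra, rb)))
        anchor = ComplexNode(truth.receptors[0], truth.ligands[0])
        net.add_anchor(
            anchor,
            Measurement(truth.abfe_value(anchor.receptor_id, anchor.ligand_id)),
        )
        return net

    if len(truth.receptors) < 2:
        raise ValueError("selectivity mode needs at least two receptors")
    ra, rb = truth.receptors[:2]
    net = Network(NetworkMode.SELECTIVITY, receptor_pair=(ra, rb))
    for l1, l2 in pairs:
        net.add_rsfe(l1, l2, noisy(truth.rsfe(l1, l2, ra, rb)))
    ref = truth.ligands[0]
    net.add_anchor(SelectivityNode(ref, ra, rb), Measurement(truth.bsfe(ref, ra, rb)))
    return net


def _true_value(truth: GroundTruth, node) -> float:
    if isinstance(node, ComplexNode):
        return truth.abfe_value(node.receptor_id, node.ligand_id)
    return truth.bsfe(node.ligand_id, node.receptor_from, node.receptor_to)


@dataclass(frozen=True)
class RecoverySummary:
    """Aggregate recovery statistics over replicate noised networks.

    ``bias``/``rmse`` pool every non-anchored node over all replicates;
    ``per_class`` breaks them down by receptor (complex mode) or by the
    receptor pair (selectivity mode).  ``coverage`` is the fraction of
    node-replicates whose 2-sigma interval contains the truth.
    """

    n_replicates: int
    bias: float
    rmse: float
    per_class: Dict[str, Tuple[float, float]]
    coverage: float
    n_node_replicates: int


def recovery_experiment(
    truth: GroundTruth,
    noise: NoiseSpec,
    n_replicates: int,
    mode: NetworkMode | str = NetworkMode.COMPLEX,
) -> RecoverySummary:
    """Repeatedly sample and solve; measure bias, RMSE and 2-sigma coverage.

    Replicate r reseeds the generator deterministically from
    ``(noise.seed, r)``, so the whole experiment is reproducible from the
    spec alone.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    mode = NetworkMode(mode)
    errors: Dict[str, List[float]] = {}
    pooled: List[float] = []
    covered = 0
    total = 0
    anchored_ok = True
    for r in range(n_replicates):
        spec_r = replace(noise, seed=int(np.random.default_rng(
            [noise.seed, r]).integers(0, 2**31 - 1)))
        net = sample_network(truth, spec_r, mode)
        result = solve(net)
        anchored = {a.node for a in net.anchors}
        for node, est in result.estimates.items():
            if node in anchored:
                continue
            tv = _true_value(truth, node)
            err = est - tv
            pooled.append(err)
            cls = (
                node.receptor_id
                if isinstance(node, ComplexNode)
                else f"{node.receptor_from}->{node.receptor_to}"
            )
            errors.setdefault(cls, []).append(err)
            if abs(err) <= result.uncertainties[node]:
                covered += 1
            total += 1
    arr = np.asarray(pooled)
    per_class = {
        cls: (float(np.mean(v)), float(np.sqrt(np.mean(np.square(v)))))
        for cls, v in errors.items()
    }
    return RecoverySummary(
        n_replicates=n_replicates,
        bias=float(arr.mean()),
        rmse=float(np.sqrt(np.mean(np.square(arr)))),
        per_class=per_class,
        coverage=covered / total if total else float("nan"),
        n_node_replicates=total,
    )
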