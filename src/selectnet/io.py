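"""Edge-list / anchor file I/O, report serialization, and packaged fixtures.

File formats (all delimiter-separated text with a header row):

Edge list::

    kind,receptor_a,ligand_a,receptor_b,ligand_b,value_kcal_mol,uncertainty_2sigma

* ``RBFE`` rows require ``receptor_a == receptor_b``; the edge runs
  ligand_a -> ligand_b on that receptor.
* ``RHFE`` rows require ``ligand_a == ligand_b``; the edge runs
  receptor_a -> receptor_b for that ligand.
* ``RSFE`` rows describe a swap starting from (ligand_a bound to receptor_a,
  ligand_b bound to receptor_b); the edge constrains
  ``BSFE(ligand_a) - BSFE(ligand_b)`` for the hop receptor_a -> receptor_b.

Anchor list::

    receptor_a,receptor_b,ligand,value_kcal_mol,uncertainty_2sigma

Complex-mode anchors leave ``receptor_b`` empty (the node is
receptor_a·ligand); selectivity anchors fill both receptors (the node is the
ligand's BSFE for receptor_a -> receptor_b).  Direction is always explicit —
no sign conventions are inferred from file order.

Packaged fixtures transcribe published two-host (TEMOA/TEETOA, SAMPL8
guests) and trypsin/thrombin free-energy tables; each is verified against a
recorded SHA-256 checksum at load time.
"""

from __future__ import annotations

import csv
import hashlib
import json
import math
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple, Union

import pandas as pd

from .network import (
    Anchor,
    ComplexNode,
    Edge,
    EdgeKind,
    Network,
    NetworkMode,
    SelectivityNode,
)
from .thermo import Measurement

__all__ = [
    "EDGE_COLUMNS",
    "ANCHOR_COLUMNS",
    "EdgeListParseError",
    "read_edge_list",
    "write_edge_list",
    "read_anchor_list",
    "write_anchor_list",
    "build_network",
    "write_report",
    "read_report",
    "FIXTURE_NAMES",
    "fixtures",
    "fixture_frame",
    "sampl8_complex_network",
    "sampl8_selectivity_network",
    "TRYPSIN_THROMBIN_PKI",
    "TEXT_HYSTERESIS_PAIR",
]

EDGE_COLUMNS = [
    "kind",
    "receptor_a",
    "ligand_a",
    "receptor_b",
    "ligand_b",
    "value_kcal_mol",
    "uncertainty_2sigma",
]
ANCHOR_COLUMNS = ["receptor_a", "receptor_b", "ligand", "value_kcal_mol",
                  "uncertainty_2sigma"]


class EdgeListParseError(ValueError):
    """A row of an edge/anchor file could not be interpreted."""

    def __init__(self, path, line: int, message: str) -> None:
        super().__init__(f"{path}:{line}: {message}")
        self.path = path
        self.line = line


def _parse_float(raw: str, path, line: int, column: str,
                 optional: bool = False) -> Optional[float]:
    raw = (raw or "").strip()
    if raw == "":
        if optional:
            return None
        raise EdgeListParseError(path, line, f"missing value in column {column!r}")
    try:
        value = float(raw)
    except ValueError:
        raise EdgeListParseError(
            path, line, f"non-numeric value {raw!r} in column {column!r}"
        ) from None
    if not math.isfinite(value):
        raise EdgeListParseError(path, line, f"non-finite value in column {column!r}")
    return value


def _edge_from_row(row: dict, path, line: int) -> Edge:
    kind_raw = (row.get("kind") or "").strip().upper()
    try:
        kind = EdgeKind(kind_raw)
    except ValueError:
        raise EdgeListParseError(
            path, line, f"unknown edge kind {row.get('kind')!r}"
        ) from None
    ra, la = (row["receptor_a"] or "").strip(), (row["ligand_a"] or "").strip()
    rb, lb = (row["receptor_b"] or "").strip(), (row["ligand_b"] or "").strip()
    if not all([ra, la, rb, lb]):
        raise EdgeListParseError(path, line, "empty endpoint field")
    value = _parse_float(row["value_kcal_mol"], path, line, "value_kcal_mol")
    unc = _parse_float(
        row["uncertainty_2sigma"], path, line, "uncertainty_2sigma", optional=True
    )
    m = Measurement(value, unc)
    if kind is EdgeKind.RBFE:
        if ra != rb:
            raise EdgeListParseError(
                path, line, f"RBFE row must keep one receptor, got {ra!r} and {rb!r}"
            )
        return Edge(kind, ComplexNode(ra, la), ComplexNode(rb, lb), m)
    if kind is EdgeKind.RHFE:
        if la != lb:
            raise EdgeListParseError(
                path, line, f"RHFE row must keep one ligand, got {la!r} and {lb!r}"
            )
        return Edge(kind, ComplexNode(ra, la), ComplexNode(rb, lb), m)
    # RSFE: swap starts at (ligand_a @ receptor_a, ligand_b @ receptor_b);
    # nodes are BSFEs for the hop receptor_a -> receptor_b.
    if ra == rb:
        raise EdgeListParseError(path, line, "RSFE row needs two distinct receptors")
    return Edge(
        kind,
        SelectivityNode(lb, ra, rb),
        SelectivityNode(la, ra, rb),
        m,
    )


def read_edge_list(path: Union[str, Path]) -> List[Edge]:
    """Parse an edge-list file; malformed rows raise with their line number."""
    path = Path(path)
    edges: List[Edge] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in EDGE_COLUMNS if c not in header]
        if missing:
            raise EdgeListParseError(path, 1, f"missing columns {missing}")
        for row in reader:
            try:
                edges.append(_edge_from_row(row, path, reader.line_num))
            except EdgeListParseError:
                raise
            except ValueError as exc:
                raise EdgeListParseError(path, reader.line_num, str(exc)) from exc
    return edges


def write_edge_list(path: Union[str, Path], edges: Iterable[Edge]) -> None:
    """Write edges in the canonical edge-list format (full float precision)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(EDGE_COLUMNS)
        for e in edges:
            if e.kind is EdgeKind.RSFE:
                head: SelectivityNode = e.head  # type: ignore[assignment]
                tail: SelectivityNode = e.tail  # type: ignore[assignment]
                row = [e.kind.value, head.receptor_from, head.ligand_id,
                       head.receptor_to, tail.ligand_id]
            else:
                row = [e.kind.value, e.tail.receptor_id, e.tail.ligand_id,  # type: ignore[union-attr]
                       e.head.receptor_id, e.head.ligand_id]  # type: ignore[union-attr]
            u = e.measurement.uncertainty
            row += [repr(e.measurement.value), "" if u is None else repr(u)]
            writer.writerow(row)


def read_anchor_list(path: Union[str, Path]) -> List[Anchor]:
    """Parse an anchor file (see module docstring for the schema)."""
    path = Path(path)
    anchors: List[Anchor] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in ANCHOR_COLUMNS if c not in header]
        if missing:
            raise EdgeListParseError(path, 1, f"missing columns {missing}")
        for row in reader:
            line = reader.line_num
            ra = (row["receptor_a"] or "").strip()
            rb = (row["receptor_b"] or "").strip()
            ligand = (row["ligand"] or "").strip()
            if not ra or not ligand:
                raise EdgeListParseError(path, line, "anchor needs receptor_a and ligand")
            value = _parse_float(row["value_kcal_mol"], path, line, "value_kcal_mol")
            unc = _parse_float(row["uncertainty_2sigma"], path, line,
                               "uncertainty_2sigma", optional=True)
            node = SelectivityNode(ligand, ra, rb) if rb else ComplexNode(ra, ligand)
            anchors.append(Anchor(node, Measurement(value, unc)))
    return anchors


def write_anchor_list(path: Union[str, Path], anchors: Iterable[Anchor]) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(ANCHOR_COLUMNS)
        for a in anchors:
            if isinstance(a.node, SelectivityNode):
                row = [a.node.receptor_from, a.node.receptor_to, a.node.ligand_id]
            else:
                row = [a.node.receptor_id, "", a.node.ligand_id]
            u = a.value.uncertainty
            row += [repr(a.value.value), "" if u is None else repr(u)]
            writer.writerow(row)


def build_network(edges: Iterable[Edge], anchors: Iterable[Anchor] = ()) -> Network:
    """Assemble a network from parsed edges and anchors, inferring the mode.

    A network is selectivity-mode iff it contains RSFE edges; RSFE edges
    must all share one ordered receptor pair.
    """
    edges = list(edges)
    anchors = list(anchors)
    selectivity = any(e.kind is EdgeKind.RSFE for e in edges) or any(
        isinstance(a.node, SelectivityNode) for a in anchors
    )
    if selectivity:
        pairs = {
            (n.receptor_from, n.receptor_to)
            for e in edges
            for n in (e.tail, e.head)
            if isinstance(n, SelectivityNode)
        } | {
            (a.node.receptor_from, a.node.receptor_to)
            for a in anchors
            if isinstance(a.node, SelectivityNode)
        }
        if len(pairs) != 1:
            raise ValueError(
                f"selectivity network must use exactly one ordered receptor "
                f"pair, got {sorted(pairs)}"
            )
        net = Network(NetworkMode.SELECTIVITY, receptor_pair=next(iter(pairs)))
    else:
        net = Network(NetworkMode.COMPLEX)
    for e in edges:
        net.add_edge(e)
    for a in anchors:
        net.add_anchor(a.node, a.value)
    return net


# -- reports ---------------------------------------------------------------


def write_report(path: Union[str, Path], payload: dict) -> None:
    """Serialize a report as JSON (full float precision; lossless round trip)."""
    path = Path(path)
    with path.open("w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path: Union[str, Path]) -> dict:
    with Path(path).open() as fh:
        return json.load(fh)


def display_round(value: float, ndigits: int = 2) -> float:
    """Display rounding (half-to-even) at 0.01 kcal/mol, table precision."""
    return round(value, ndigits)


# -- packaged fixtures -----------------------------------------------------

_FIXTURE_SHA256 = {
    "sampl8_abfe": "8130db6d83b4e803b326d102a860d68eac00d435a8c211edf071d8306c915bdc",
    "sampl8_rhfe": "e027d7190edbac88b2c489cf2ac324ba1660beb129a544d460ac6fb68f61e2c4",
    "sampl8_rbfe": "0e9d135baed238f215e4b401d56f2825bcd66b1ebcf2082f994b6b68469052dd",
    "sampl8_rsfe": "6b92381aa36deccc9bbdc406433c31514f60f9dc750a36bd1331b148aad4bc7f",
    "trypsin_thrombin_rbfe": "912b51b94fdd626795cb0ad281bf5a795864f270281ba9601f995079b211eeda",
    "trypsin_thrombin_rsfe": "3d554229d173f2a77b517d26fd74b3c3868846d7b80da7e65eb085264338dcd8",
}

FIXTURE_NAMES = tuple(_FIXTURE_SHA256)

#: measured inhibition constants (as pKi) for the serine-protease example
TRYPSIN_THROMBIN_PKI = {
    ("trypsin", "Bz"): 7.51,
    ("thrombin", "Bz"): 6.44,
    ("trypsin", "Am"): 6.44,
    ("thrombin", "Am"): 6.82,
}

#: forward/reverse swap pair quoted in running text for the hysteresis check
#: (the corresponding table rows are 2.37 / -2.88; both are genuine outputs
#: of the same calculations at different stages of convergence)
TEXT_HYSTERESIS_PAIR = (Measurement(2.05, 0.30), Measurement(-2.32, 0.30))


def _fixture_path(name: str):
    if name not in _FIXTURE_SHA256:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        )
    return resources.files("selectnet.data").joinpath(f"{name}.csv")


def fixture_frame(name: str) -> pd.DataFrame:
    """Raw fixture table as a DataFrame, after checksum verification."""
    ref = _fixture_path(name)
    data = ref.read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _FIXTURE_SHA256[name]:
        raise ValueError(f"fixture {name!r} failed its checksum ({digest})")
    with resources.as_file(ref) as p:
        return pd.read_csv(p, dtype={"kind": str}, keep_default_na=False)


def fixtures(name: str):
    """Load a packaged fixture.

    ``sampl8_abfe`` returns a dict ``(receptor, ligand) -> Measurement``;
    every other name returns a list of parsed edges.
    """
    ref = _fixture_path(name)
    fixture_frame(name)  # checksum verification
    if name == "sampl8_abfe":
        df = fixture_frame(name)
        return {
            (r.receptor, r.ligand): Measurement(
                float(r.value_kcal_mol), float(r.uncertainty_2sigma)
            )
            for r in df.itertuples()
        }
    with resources.as_file(ref) as p:
        return read_edge_list(p)


def sampl8_complex_network(
    rhfe_ligands: Optional[Iterable[str]] = None,
) -> Network:
    """The two-host network: all RBFE edges plus RHFE hops, anchored at the
    first host's first guest (TEMOA·G1) at its absolute value.

    ``rhfe_ligands`` restricts which guests' hopping edges are included
    (default: all five).
    """
    edges = list(fixtures("sampl8_rbfe"))
    keep = None if rhfe_ligands is None else set(rhfe_ligands)
    for e in fixtures("sampl8_rhfe"):
        if keep is None or e.tail.ligand_id in keep:  # type: ignore[union-attr]
            edges.append(e)
    abfe = fixtures("sampl8_abfe")
    anchor = Anchor(ComplexNode("TEMOA", "G1"), abfe[("TEMOA", "G1")])
    return build_network(edges, [anchor])


def sampl8_selectivity_network() -> Network:
    """The swap network over the ten guest pairs, anchored at G1's directly
    calculated hopping free energy."""
    edges = fixtures("sampl8_rsfe")
    rhfe = {e.tail.ligand_id: e.measurement for e in fixtures("sampl8_rhfe")}  # type: ignore[union-attr]
    anchor = Anchor(SelectivityNode("G1", "TEMOA", "TEETOA"), rhfe["G1"])
    return build_network(edges, [anchor])
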