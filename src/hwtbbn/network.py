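"""Discrete Bayesian network structure: nodes, states, edges, CPTs.

The default shipped network is the three-layer mediation structure for
household water treatment: eight socio-economic root nodes, each a parent of
all five RANAS psychosocial nodes, which in turn are the only parents of the
behaviour outcome node (no direct SEC -> outcome edge).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import yaml

PROB_TOL = 1e-9

SEC_NODES = {
    "water_health_problem": ("No", "Yes"),
    "information_access": ("Difficult", "Medium", "Easy"),
    "mother_education": ("None", "Primary", "Secondary", "Higher"),
    "father_education": ("None", "Primary", "Secondary", "Higher"),
    "wealth": ("Poor", "Middle", "Rich"),
    "religion": ("Christian", "Islam"),
    "accessibility": ("Difficult", "Easy"),
    "access_water": ("Far", "Medium", "Close"),
}
RANAS_NODES = ("risk", "attitude", "norm", "ability", "self_regulation")
RANAS_NODE_STATES = ("Low", "Moderate", "High")
HWT_NODE = "hwt_behaviour"
HWT_NODE_STATES = ("non-user", "irregular user", "regular user")


class NetworkError(ValueError):
    pass


@dataclass
class NetworkSpec:
    """DAG over named nodes with ordered state lists."""

    nodes: dict[str, tuple[str, ...]]           # name -> ordered states
    edges: list[tuple[str, str]]                # (parent, child)
    layers: dict[str, str] = field(default_factory=dict)  # optional layer tags

    def __post_init__(self) -> None:
        self.nodes = {n: tuple(s) for n, s in self.nodes.items()}
        self.edges = [tuple(e) for e in self.edges]

    def parents(self, node: str) -> tuple[str, ...]:
        return tuple(p for p, c in self.edges if c == node)

    def card(self, node: str) -> int:
        return len(self.nodes[node])

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def topological_order(self) -> list[str]:
        return list(nx.lexicographical_topological_sort(self.graph()))

    def joint_size(self) -> int:
        size = 1
        for states in self.nodes.values():
            size *= len(states)
        return size

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        out = {
            "nodes": [{"name": n, "states": list(s)} for n, s in self.nodes.items()],
            "edges": [list(e) for e in self.edges],
        }
        if self.layers:
            out["layers"] = dict(self.layers)
        return out

    @classmethod
    def from_dict(cls, payload: dict) -> "NetworkSpec":
        nodes = {str(e["name"]): tuple(str(s) for s in e["states"])
                 for e in payload["nodes"]}
        edges = [(str(p), str(c)) for p, c in payload.get("edges", [])]
        return cls(nodes=nodes, edges=edges,
                   layers=dict(payload.get("layers", {})))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "NetworkSpec":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def validate_spec(spec: NetworkSpec) -> list[str]:
    """Check acyclicity, state sanity and (when tagged) layer conformance.

    Returns a list of diagnostics; raises :class:`NetworkError` on a hard
    violation such as a cycle.
    """
    diagnostics: list[str] = []
    for node, states in spec.nodes.items():
        if len(states) < 2:
            raise NetworkError(f"node {node!r} needs at least 2 states")
        if len(set(states)) != len(states):
            raise NetworkError(f"node {node!r} has duplicate states")
    for p, c in spec.edges:
        if p not in spec.nodes or c not in spec.nodes:
            raise NetworkError(f"edge ({p!r}, {c!r}) references unknown node")
    g = spec.graph()
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise NetworkError(f"network contains a cycle: {cycle}")
    if spec.layers:
        order = {"sec": 0, "ranas": 1, "outcome": 2}
        for p, c in spec.edges:
            lp, lc = spec.layers.get(p), spec.layers.get(c)
            if lp in order and lc in order and order[lc] - order[lp] != 1:
                diagnostics.append(f"edge {p}->{c} skips or inverts layers")
    return diagnostics


def default_network() -> NetworkSpec:
    """The 14-node three-layer mediation network."""
    nodes: dict[str, tuple[str, ...]] = dict(SEC_NODES)
    for r in RANAS_NODES:
        nodes[r] = RANAS_NODE_STATES
    nodes[HWT_NODE] = HWT_NODE_STATES
    edges = [(s, r) for r in RANAS_NODES for s in SEC_NODES]
    edges += [(r, HWT_NODE) for r in RANAS_NODES]
    layers = {**{s: "sec" for s in SEC_NODES},
              **{r: "ranas" for r in RANAS_NODES},
              HWT_NODE: "outcome"}
    spec = NetworkSpec(nodes=nodes, edges=edges, layers=layers)
    validate_spec(spec)
    return spec


@dataclass
class Cpt:
    """Conditional probability table: shape (*parent_cards, card(node))."""

    node: str
    parents: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.parents = tuple(self.parents)
        self.values = np.asarray(self.values, dtype=float)

    def validate(self, spec: NetworkSpec) -> None:
        want = tuple(spec.card(p) for p in self.parents) + (spec.card(self.node),)
        if self.values.shape != want:
            raise NetworkError(
                f"CPT for {self.node!r} has shape {self.values.shape}, expected {want}")
        if (self.values < -PROB_TOL).any():
            raise NetworkError(f"CPT for {self.node!r} has negative entries")
        sums = self.values.sum(axis=-1)
        if not np.allclose(sums, 1.0, atol=PROB_TOL):
            raise NetworkError(f"CPT rows for {self.node!r} do not sum to 1")


@dataclass
class BbnModel:
    """A network spec plus one CPT per node and learning metadata."""

    spec: NetworkSpec
    cpts: dict[str, Cpt]
    metadata: dict = field(default_factory=dict)

    def validate(self) -> None:
        if set(self.cpts) != set(self.spec.nodes):
            raise NetworkError("CPTs do not cover exactly the spec's nodes")
        for node, cpt in self.cpts.items():
            if cpt.node != node:
                raise NetworkError(f"CPT key {node!r} names node {cpt.node!r}")
            if cpt.parents != self.spec.parents(node):
                raise NetworkError(f"CPT parents for {node!r} disagree with spec")
            cpt.validate(self.spec)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "cpts": [
                {
                    "node": c.node,
                    "parents": list(c.parents),
                    "table": np.round(c.values, 12).reshape(
                        -1, c.values.shape[-1]).tolist(),
                }
                for c in self.cpts.values()
            ],
            "metadata": _plain(self.metadata),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "BbnModel":
        spec = NetworkSpec.from_dict(payload["spec"])
        cpts = {}
        for entry in payload["cpts"]:
            node = str(entry["node"])
            parents = tuple(str(p) for p in entry["parents"])
            shape = tuple(spec.card(p) for p in parents) + (spec.card(node),)
            values = np.asarray(entry["table"], dtype=float).reshape(shape)
            cpts[node] = Cpt(node=node, parents=parents, values=values)
        model = cls(spec=spec, cpts=cpts, metadata=dict(payload.get("metadata", {})))
        model.validate()
        return model

    @classmethod
    def from_yaml(cls, path: str | Path) -> "BbnModel":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False,
                           default_flow_style=None)

    def cpts_to_csv(self, path: str | Path) -> None:
        """One row per parent configuration, columns = node states."""
        import csv
        import itertools

        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["node", "parent_config", "state", "probability"])
            for cpt in self.cpts.values():
                parent_states = [self.spec.nodes[p] for p in cpt.parents]
                flat = cpt.values.reshape(-1, cpt.values.shape[-1])
                for i, config in enumerate(itertools.product(*parent_states) if
                                           cpt.parents else [()]):
                    label = "|".join(f"{p}={s}" for p, s in zip(cpt.parents, config))
                    for j, state in enumerate(self.spec.nodes[cpt.node]):
                        writer.writerow([cpt.node, label, state, f"{flat[i, j]:.10g}"])


def _plain(obj):
    """Recursively convert numpy scalars/arrays for YAML serialization."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


Evidence = dict[str, str]


def validate_evidence(spec: NetworkSpec, evidence: Evidence) -> None:
    for node, state in evidence.items():
        if node not in spec.nodes:
            raise NetworkError(f"evidence names unknown node {node!r}")
        if state not in spec.nodes[node]:
            raise NetworkError(
                f"evidence state {state!r} invalid for node {node!r}")
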