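"""Exact inference in discrete Bayesian networks.

Two routes are provided: brute-force enumeration of the factored joint
(:func:`infer_enumeration`), intended as an oracle on desk-scale networks,
and variable elimination with a min-degree ordering (:func:`infer_ve`), the
production path.  Both return identical posteriors up to numerical noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import BbnModel, Evidence, NetworkError, validate_evidence

ENUMERATION_LIMIT = 10**7


class ImpossibleEvidenceError(NetworkError):
    """The supplied evidence has probability zero under the model."""


@dataclass
class Factor:
    """A non-negative table over an ordered tuple of variables."""

    variables: tuple[str, ...]
    values: np.ndarray

    def reduce(self, var: str, index: int) -> "Factor":
        """Condition on var = index (drops the axis)."""
        axis = self.variables.index(var)
        values = np.take(self.values, index, axis=axis)
        variables = self.variables[:axis] + self.variables[axis + 1:]
        return Factor(variables, values)

    def marginalize(self, var: str) -> "Factor":
        axis = self.variables.index(var)
        return Factor(self.variables[:axis] + self.variables[axis + 1:],
                      self.values.sum(axis=axis))

    def multiply(self, other: "Factor") -> "Factor":
        """Pointwise product over the union of the two scopes."""
        union = list(self.variables)
        union += [v for v in other.variables if v not in self.variables]
        a = _expand(self, union)
        b = _expand(other, union)
        return Factor(tuple(union), a * b)


def _expand(factor: Factor, union: list[str]) -> np.ndarray:
    """Broadcastable view of factor.values aligned to the union scope."""
    present = [v for v in union if v in factor.variables]
    perm = [factor.variables.index(v) for v in present]
    arr = np.transpose(factor.values, perm) if perm else np.asarray(factor.values)
    shape = [arr.shape[present.index(v)] if v in factor.variables else 1
             for v in union]
    return arr.reshape(shape)


def model_factors(model: BbnModel, evidence: Evidence) -> list[Factor]:
    """CPT factors with evidence variables sliced out."""
    validate_evidence(model.spec, evidence)
    state_index = {n: {s: i for i, s in enumerate(states)}
                   for n, states in model.spec.nodes.items()}
    factors = []
    for node, cpt in model.cpts.items():
        f = Factor(cpt.parents + (node,), cpt.values)
        for var in f.variables:
            if var in evidence:
                f = f.reduce(var, state_index[var][evidence[var]])
        factors.append(f)
    return factors


def _posterior_from_joint(joint: Factor, query: str, states: tuple[str, ...]) -> np.ndarray:
    for var in joint.variables:
        if var != query:
            joint = joint.marginalize(var)
    values = joint.values if joint.variables else np.asarray(joint.values)
    total = float(np.sum(values))
    if not np.isfinite(total) or total <= 0:
        raise ImpossibleEvidenceError("impossible evidence: normalizer is zero")
    post = np.asarray(values, dtype=float).reshape(len(states)) / total
    return post


def infer_enumeration(model: BbnModel, evidence: Evidence, query: str) -> np.ndarray:
    """Exact posterior P(query | evidence) by full joint enumeration."""
    if query in evidence:
        return _degenerate(model, evidence, query)
    if model.spec.joint_size() > ENUMERATION_LIMIT:
        raise NetworkError("joint state space too large for enumeration")
    factors = model_factors(model, evidence)
    joint = factors[0]
    for f in factors[1:]:
        joint = joint.multiply(f)
    return _posterior_from_joint(joint, query, model.spec.nodes[query])


def _degenerate(model: BbnModel, evidence: Evidence, query: str) -> np.ndarray:
    """Posterior of a node that is itself observed (after a consistency check)."""
    if evidence_log_likelihood(model, evidence) == -np.inf:
        raise ImpossibleEvidenceError("impossible evidence: normalizer is zero")
    states = model.spec.nodes[query]
    post = np.zeros(len(states))
    post[states.index(evidence[query])] = 1.0
    return post


def _min_degree_order(factors: list[Factor], keep: set[str]) -> list[str]:
    """Min-degree elimination order over the factors' interaction graph.

    Deterministic: ties broken by node name.
    """
    neighbors: dict[str, set[str]] = {}
    for f in factors:
        for v in f.variables:
            neighbors.setdefault(v, set()).update(f.variables)
    for v in neighbors:
        neighbors[v].discard(v)
    order = []
    remaining = {v for v in neighbors if v not in keep}
    while remaining:
        v = min(remaining, key=lambda x: (len(neighbors[x] & (remaining | keep)), x))
        order.append(v)
        nbrs = neighbors[v] & (remaining | keep)
        for a in nbrs:
            neighbors[a].update(nbrs)
            neighbors[a].discard(a)
            neighbors[a].discard(v)
        remaining.discard(v)
    return order


def _eliminate(factors: list[Factor], keep: set[str]) -> Factor:
    """Sum out everything outside `keep`; return the single remaining factor."""
    factors = list(factors)
    for var in _min_degree_order(factors, keep):
        touching = [f for f in factors if var in f.variables]
        rest = [f for f in factors if var not in f.variables]
        if not touching:
            continue
        prod = touching[0]
        for f in touching[1:]:
            prod = prod.multiply(f)
        factors = rest + [prod.marginalize(var)]
    result = Factor((), np.asarray(1.0))
    for f in factors:
        result = result.multiply(f)
    return result


def infer_joint(model: BbnModel, evidence: Evidence,
                query_vars: list[str], *, normalize: bool = True) -> Factor:
    """Joint (posterior) factor over query_vars by variable elimination."""
    free = [q for q in query_vars if q not in evidence]
    factors = model_factors(model, evidence)
    joint = _eliminate(factors, set(free))
    # put axes into query order
    present = [v for v in query_vars if v in joint.variables]
    perm = [joint.variables.index(v) for v in present]
    joint = Factor(tuple(present), np.transpose(joint.values, perm))
    if normalize:
        total = float(joint.values.sum())
        if not np.isfinite(total) or total <= 0:
            raise ImpossibleEvidenceError("impossible evidence: normalizer is zero")
        joint = Factor(joint.variables, joint.values / total)
    return joint


def infer_ve(model: BbnModel, evidence: Evidence, query: str) -> np.ndarray:
    """Exact posterior P(query | evidence) by variable elimination."""
    if query in evidence:
        return _degenerate(model, evidence, query)
    joint = infer_joint(model, evidence, [query])
    return joint.values.reshape(model.spec.card(query))


def evidence_log_likelihood(model: BbnModel, evidence: Evidence) -> float:
    """log P(evidence) under the model (-inf for impossible evidence)."""
    factors = model_factors(model, evidence)
    result = _eliminate(factors, set())
    total = float(np.asarray(result.values))
    if total <= 0:
        return -np.inf
    return float(np.log(total))
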