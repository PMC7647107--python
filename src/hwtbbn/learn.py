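"""CPT estimation: Dirichlet-smoothed counting and EM under missing data.

Both learners share the same M-step: cell = (count + prior_ess/k) /
(config_total + prior_ess), where k is the node's state count and prior_ess
is the total pseudo-count spread uniformly over a CPT row (a symmetric
Dirichlet prior).  With complete data EM reproduces the counting estimate
after a single iteration.  With prior_ess > 0 the quantity EM maximizes —
and the one asserted monotone — is the Dirichlet log posterior; with
prior_ess = 0 it is the raw log-likelihood.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .inference import evidence_log_likelihood, infer_joint
from .network import BbnModel, Cpt, NetworkSpec

MONOTONE_SLACK = 1e-8


class LearnError(ValueError):
    pass


def encode_dataset(data: pd.DataFrame, spec: NetworkSpec) -> np.ndarray:
    """Node states -> integer codes (missing -> -1); unseen tokens raise."""
    missing = [n for n in spec.nodes if n not in data.columns]
    if missing:
        raise LearnError(f"dataset lacks columns for nodes: {missing}")
    n = len(data)
    codes = np.full((n, len(spec.nodes)), -1, dtype=np.int64)
    for j, (node, states) in enumerate(spec.nodes.items()):
        col = data[node]
        lookup = {s: i for i, s in enumerate(states)}
        present = col.notna().to_numpy()
        tokens = col[present].astype(str)
        unseen = sorted(set(tokens) - set(states))
        if unseen:
            raise LearnError(f"unseen state token(s) {unseen} for node {node!r}")
        codes[present, j] = tokens.map(lookup).to_numpy(dtype=np.int64)
    return codes


def _m_step(counts: dict[str, np.ndarray], spec: NetworkSpec,
            prior_ess: float) -> dict[str, Cpt]:
    cpts = {}
    for node, c in counts.items():
        k = spec.card(node)
        totals = c.sum(axis=-1, keepdims=True)
        if prior_ess > 0:
            table = (c + prior_ess / k) / (totals + prior_ess)
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                table = c / totals
            table[np.broadcast_to(totals == 0, table.shape)] = 1.0 / k
        cpts[node] = Cpt(node=node, parents=spec.parents(node), values=table)
    return cpts


def _zero_counts(spec: NetworkSpec) -> dict[str, np.ndarray]:
    out = {}
    for node in spec.nodes:
        shape = tuple(spec.card(p) for p in spec.parents(node)) + (spec.card(node),)
        out[node] = np.zeros(shape)
    return out


def count_estimate(data: pd.DataFrame, spec: NetworkSpec,
                   prior_ess: float = 0.0) -> BbnModel:
    """Closed-form (available-case) counting estimate of all CPTs.

    Rows missing any member of a node's family are excluded from that
    family's counts; CPT rows with zero data and zero prior become uniform.
    """
    codes = encode_dataset(data, spec)
    cols = {n: j for j, n in enumerate(spec.nodes)}
    counts = _zero_counts(spec)
    for node in spec.nodes:
        family = list(spec.parents(node)) + [node]
        fam_codes = codes[:, [cols[f] for f in family]]
        ok = (fam_codes >= 0).all(axis=1)
        if ok.any():
            shape = counts[node].shape
            flat = np.ravel_multi_index(fam_codes[ok].T, shape)
            np.add.at(counts[node].reshape(-1), flat, 1.0)
    model = BbnModel(spec=spec, cpts=_m_step(counts, spec, prior_ess),
                     metadata={"method": "count_estimate", "prior_ess": prior_ess,
                               "n_rows": int(len(data))})
    model.validate()
    return model


def _init_cpts(spec: NetworkSpec, init: str, seed: int | None) -> dict[str, Cpt]:
    cpts = {}
    rng = np.random.default_rng(seed)
    for node in spec.nodes:
        shape = tuple(spec.card(p) for p in spec.parents(node)) + (spec.card(node),)
        if init == "uniform":
            table = np.full(shape, 1.0 / shape[-1])
        elif init == "random":
            table = rng.dirichlet(np.ones(shape[-1]), size=shape[:-1])
        else:
            raise LearnError(f"unknown init {init!r}")
        cpts[node] = Cpt(node=node, parents=spec.parents(node), values=table)
    return cpts


def _log_prior(cpts: dict[str, Cpt], prior_ess: float) -> float:
    if prior_ess <= 0:
        return 0.0
    total = 0.0
    for cpt in cpts.values():
        k = cpt.values.shape[-1]
        total += (prior_ess / k) * np.log(np.clip(cpt.values, 1e-300, None)).sum()
    return float(total)


def em_learn(data: pd.DataFrame, spec: NetworkSpec, *,
             prior_ess: float = 1.0, tol: float = 1e-6, max_iter: int = 500,
             init: str = "uniform", seed: int | None = None) -> BbnModel:
    """EM estimation of all CPTs under arbitrarily missing node states.

    E-step: each household's posterior over the missing members of each
    node family, by exact variable-elimination inference given its observed
    nodes.  M-step: Dirichlet-smoothed re-estimation from expected counts.
    Iterates until the relative change of the (penalized) log-likelihood
    falls below ``tol`` or ``max_iter`` is reached.
    """
    codes = encode_dataset(data, spec)
    if len(codes) == 0:
        raise LearnError("empty dataset")
    all_missing = (codes < 0).all(axis=1)
    if all_missing.any():
        # rows with no observed node carry no information (their posterior is
        # the current marginal, an EM fixed-point contribution)
        import warnings
        warnings.warn(f"dropping {int(all_missing.sum())} household row(s) "
                      "with no observed node")
        codes = codes[~all_missing]
        if len(codes) == 0:
            raise LearnError("no household has any observed node")
    node_names = list(spec.nodes)
    cols = {n: j for j, n in enumerate(node_names)}
    families = {n: list(spec.parents(n)) + [n] for n in node_names}

    # unique row patterns, with multiplicities, to avoid repeated inference
    uniq, inverse, weights = np.unique(codes, axis=0,
                                       return_inverse=True, return_counts=True)
    complete = (uniq >= 0).all(axis=1)

    cpts = _init_cpts(spec, init, seed)
    objective_trace: list[float] = []
    loglik_trace: list[float] = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        model = BbnModel(spec=spec, cpts=cpts)
        counts = _zero_counts(spec)
        loglik = 0.0

        # complete rows: plain weighted counting + direct likelihood lookup
        if complete.any():
            crows, cw = uniq[complete], weights[complete]
            for node in node_names:
                fam = [cols[f] for f in families[node]]
                shape = counts[node].shape
                flat = np.ravel_multi_index(crows[:, fam].T, shape)
                np.add.at(counts[node].reshape(-1), flat, cw)
                probs = cpts[node].values.reshape(-1)[flat]
                if (probs <= 0).any():
                    bad = int(np.where(probs <= 0)[0][0])
                    raise LearnError(
                        f"zero-probability configuration for node {node!r} "
                        f"(household pattern {crows[bad].tolist()})")
                loglik += float(cw @ np.log(probs))

        # incomplete rows: exact posterior over each family's missing members
        for u in np.where(~complete)[0]:
            row, w = uniq[u], weights[u]
            evidence = {node_names[j]: spec.nodes[node_names[j]][row[j]]
                        for j in range(len(node_names)) if row[j] >= 0}
            ll = evidence_log_likelihood(model, evidence)
            if not np.isfinite(ll):
                raise LearnError(
                    f"non-finite likelihood for household pattern {row.tolist()}")
            loglik += w * ll
            for node in node_names:
                fam = families[node]
                hidden = [f for f in fam if row[cols[f]] < 0]
                if not hidden:
                    idx = tuple(row[cols[f]] for f in fam)
                    counts[node][idx] += w
                    continue
                post = infer_joint(model, evidence, hidden)
                # posterior axes follow `hidden` order; align to family axes
                expected = np.transpose(
                    post.values, [post.variables.index(h) for h in hidden])
                index: list = []
                for f in fam:
                    index.append(slice(None) if row[cols[f]] < 0
                                 else int(row[cols[f]]))
                counts[node][tuple(index)] += w * expected

        objective = loglik + _log_prior(cpts, prior_ess)
        if objective_trace and objective < objective_trace[-1] - \
                MONOTONE_SLACK * (1 + abs(objective_trace[-1])):
            raise LearnError("EM objective decreased — numerical failure")
        objective_trace.append(objective)
        loglik_trace.append(loglik)

        cpts = _m_step(counts, spec, prior_ess)

        if len(objective_trace) >= 2:
            prev, cur = objective_trace[-2], objective_trace[-1]
            if abs(cur - prev) <= tol * (1 + abs(prev)):
                break

    model = BbnModel(spec=spec, cpts=cpts, metadata={
        "method": "em", "prior_ess": prior_ess, "tol": tol,
        "max_iter": max_iter, "init": init, "seed": seed,
        "iterations": n_iter, "loglik_trace": [float(x) for x in loglik_trace],
        "objective_trace": [float(x) for x in objective_trace],
        "converged": len(objective_trace) >= 2 and abs(
            objective_trace[-1] - objective_trace[-2])
            <= tol * (1 + abs(objective_trace[-2])),
        "n_rows": int(len(data)),
    })
    model.validate()
    return model
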