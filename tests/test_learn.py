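import numpy as np
import pandas as pd
import pytest

from hwtbbn import NetworkSpec, count_estimate, em_learn
from hwtbbn.learn import LearnError


def single_node_spec():
    return NetworkSpec(nodes={"X": ("A", "B")}, edges=[])


def chain_spec():
    return NetworkSpec(nodes={"A": ("0", "1"), "B": ("0", "1", "2")},
                       edges=[("A", "B")])


def test_ml_proportions():
    data = pd.DataFrame({"X": ["A"] * 60 + ["B"] * 40})
    model = count_estimate(data, single_node_spec(), prior_ess=0)
    np.testing.assert_allclose(model.cpts["X"].values, [0.6, 0.4])


def test_laplace_smoothing_by_hand():
    """prior_ess=1, k=2: P = (60.5/101, 40.5/101)."""
    data = pd.DataFrame({"X": ["A"] * 60 + ["B"] * 40})
    model = count_estimate(data, single_node_spec(), prior_ess=1)
    np.testing.assert_allclose(model.cpts["X"].values,
                               [60.5 / 101, 40.5 / 101], atol=1e-12)


def test_unseen_state_token_rejected():
    data = pd.DataFrame({"X": ["A", "C"]})
    with pytest.raises(LearnError, match="unseen"):
        count_estimate(data, single_node_spec())


def test_zero_count_rows_uniform():
    data = pd.DataFrame({"A": ["0", "0"], "B": ["1", "2"]})
    model = count_estimate(data, chain_spec(), prior_ess=0)
    np.testing.assert_allclose(model.cpts["B"].values[1], [1 / 3] * 3)


def test_em_equals_counting_on_complete_data():
    rng = np.random.default_rng(2)
    data = pd.DataFrame({
        "A": rng.choice(["0", "1"], size=200),
        "B": rng.choice(["0", "1", "2"], size=200),
    })
    spec = chain_spec()
    for prior in (0.0, 1.0):
        counted = count_estimate(data, spec, prior_ess=prior)
        em = em_learn(data, spec, prior_ess=prior, max_iter=1)
        for node in spec.nodes:
            np.testing.assert_allclose(em.cpts[node].values,
                                       counted.cpts[node].values, atol=1e-12)


def test_em_symmetric_missing_closed_form():
    """Single binary node: 50 A, 50 B, 100 missing -> P = (1/2, 1/2)."""
    data = pd.DataFrame({"X": ["A"] * 50 + ["B"] * 50 + [None] * 100})
    model = em_learn(data, single_node_spec(), prior_ess=0)
    np.testing.assert_allclose(model.cpts["X"].values, [0.5, 0.5], atol=1e-9)


def test_em_objective_monotone_with_missing_data():
    rng = np.random.default_rng(4)
    n = 300
    a = rng.choice(["0", "1"], size=n, p=[0.3, 0.7])
    b = np.where(a == "0",
                 rng.choice(["0", "1", "2"], size=n, p=[0.7, 0.2, 0.1]),
                 rng.choice(["0", "1", "2"], size=n, p=[0.1, 0.3, 0.6]))
    data = pd.DataFrame({"A": a, "B": b})
    mask = rng.random((n, 2)) < 0.25
    data = data.mask(pd.DataFrame(mask, columns=data.columns))
    for prior in (0.0, 1.0):
        model = em_learn(data, chain_spec(), prior_ess=prior)
        trace = np.array(model.metadata["objective_trace"])
        assert (np.diff(trace) >= -1e-8 * (1 + np.abs(trace[:-1]))).all()
        assert model.metadata["converged"]


def test_em_estimates_generating_cpts():
    """With 25% MCAR masking EM still recovers the generating tables."""
    rng = np.random.default_rng(8)
    n = 4000
    a = rng.choice(["0", "1"], size=n, p=[0.4, 0.6])
    p_b = {"0": [0.7, 0.2, 0.1], "1": [0.1, 0.3, 0.6]}
    b = np.array([rng.choice(["0", "1", "2"], p=p_b[x]) for x in a])
    data = pd.DataFrame({"A": a, "B": b})
    data = data.mask(pd.DataFrame(rng.random((n, 2)) < 0.25,
                                  columns=data.columns))
    model = em_learn(data, chain_spec(), prior_ess=0)
    np.testing.assert_allclose(model.cpts["A"].values, [0.4, 0.6], atol=0.04)
    np.testing.assert_allclose(model.cpts["B"].values[0], p_b["0"], atol=0.05)
    np.testing.assert_allclose(model.cpts["B"].values[1], p_b["1"], atol=0.05)


def test_all_missing_rows_dropped_with_warning():
    data = pd.DataFrame({"X": ["A", "B", None, None]})
    with pytest.warns(UserWarning, match="no observed node"):
        model = em_learn(data, single_node_spec(), prior_ess=0)
    np.testing.assert_allclose(model.cpts["X"].values, [0.5, 0.5], atol=1e-9)
    data_all_missing = pd.DataFrame({"X": [None, None]})
    with pytest.warns(UserWarning):
        with pytest.raises(LearnError):
            em_learn(data_all_missing, single_node_spec())


def test_marginal_invariance_on_complete_data():
    """Summing a learned CPT against the parents' empirical joint reproduces
    the node's empirical marginal (prior 0, complete data)."""
    rng = np.random.default_rng(12)
    n = 500
    a = rng.choice(["0", "1"], size=n)
    b = np.where(a == "0", rng.choice(["0", "1", "2"], size=n),
                 rng.choice(["0", "1", "2"], size=n, p=[0.6, 0.3, 0.1]))
    data = pd.DataFrame({"A": a, "B": b})
    model = count_estimate(data, chain_spec(), prior_ess=0)
    parent_marg = model.cpts["A"].values
    implied = parent_marg @ model.cpts["B"].values
    empirical = np.array([(b == s).mean() for s in ("0", "1", "2")])
    np.testing.assert_allclose(implied, empirical, atol=1e-12)


def test_count_estimate_recovers_exact_frequencies():
    """Data enumerating each parent configuration equally recovers the
    generating frequencies exactly (prior 0)."""
    rows = []
    table = {"0": [2, 1, 1], "1": [1, 1, 2]}  # counts per B state
    for a, counts in table.items():
        for state, c in zip(("0", "1", "2"), counts):
            rows += [{"A": a, "B": state}] * c
    model = count_estimate(pd.DataFrame(rows), chain_spec(), prior_ess=0)
    np.testing.assert_allclose(model.cpts["B"].values,
                               [[0.5, 0.25, 0.25], [0.25, 0.25, 0.5]])
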