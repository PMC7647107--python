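import numpy as np
import pandas as pd
import pytest

from hwtbbn import (BbnModel, Cpt, NetworkSpec, cross_validate, delta_p,
                    infer_enumeration, parameter_sensitivity_3point, scenario,
                    sensitivity)

from conftest import make_random_model


def toy_chain():
    """A -> B -> C, all binary."""
    spec = NetworkSpec(nodes={"A": ("0", "1"), "B": ("0", "1"),
                              "C": ("0", "1")},
                       edges=[("A", "B"), ("B", "C")])
    cpts = {
        "A": Cpt("A", (), np.array([0.3, 0.7])),
        "B": Cpt("B", ("A",), np.array([[0.8, 0.2], [0.3, 0.7]])),
        "C": Cpt("C", ("B",), np.array([[0.9, 0.1], [0.4, 0.6]])),
    }
    return BbnModel(spec=spec, cpts=cpts)


def disconnected_model():
    spec = NetworkSpec(nodes={"A": ("0", "1"), "T": ("0", "1")}, edges=[])
    return BbnModel(spec=spec, cpts={
        "A": Cpt("A", (), np.array([0.6, 0.4])),
        "T": Cpt("T", (), np.array([0.25, 0.75])),
    })


# --------------------------------------------------------------------------
# ΔP
# --------------------------------------------------------------------------

def test_delta_p_zero_for_dseparated_node():
    report = delta_p(disconnected_model(), "T", "1", precision=4)
    assert report.delta_p["A"] == 0.0
    np.testing.assert_allclose(report.table["updated_pct"],
                               report.baseline_pct, atol=1e-9)


def test_delta_p_matches_enumeration_oracle():
    model = toy_chain()
    report = delta_p(model, "C", "1", precision=6)
    for _, row in report.table.iterrows():
        oracle = infer_enumeration(model, {row["node"]: row["state"]}, "C")[1]
        assert row["updated_pct"] == pytest.approx(oracle * 100, abs=1e-9)
    spread = report.table.groupby("node")["updated_pct"].agg(lambda s: s.max() - s.min())
    for node, d in report.delta_p.items():
        assert d == pytest.approx(spread[node], abs=1e-6)


def test_delta_p_rounds_after_differencing():
    model = toy_chain()
    fine = delta_p(model, "C", "1", precision=6)
    coarse = delta_p(model, "C", "1", precision=0)
    for node in fine.delta_p:
        assert coarse.delta_p[node] == round(fine.delta_p[node], 0)


# --------------------------------------------------------------------------
# scenario propagation
# --------------------------------------------------------------------------

def test_scenario_degenerate_equals_hard_evidence():
    model = toy_chain()
    post = scenario(model, "B", np.array([1.0, 0.0]), target="C")
    np.testing.assert_allclose(post, infer_enumeration(model, {"B": "0"}, "C"),
                               atol=1e-12)


def test_scenario_at_marginal_is_no_op():
    model = toy_chain()
    marginal = infer_enumeration(model, {}, "B")
    post = scenario(model, "B", marginal, target="C")
    np.testing.assert_allclose(post, infer_enumeration(model, {}, "C"),
                               atol=1e-12)


def test_scenario_hand_computed_bayes_update():
    model = toy_chain()
    # P(C=1 | B=0) = 0.1, P(C=1 | B=1) = 0.6; mixture 0.5/0.5 -> 0.35
    post = scenario(model, "B", np.array([0.5, 0.5]), target="C")
    assert post[1] == pytest.approx(0.35)


# --------------------------------------------------------------------------
# sensitivity
# --------------------------------------------------------------------------

def test_sensitivity_single_node_identity():
    """One-node network, P(T=t) = θ: derivative 1 under co-variation."""
    spec = NetworkSpec(nodes={"T": ("0", "1")}, edges=[])
    model = BbnModel(spec=spec,
                     cpts={"T": Cpt("T", (), np.array([0.3, 0.7]))})
    report = sensitivity(model, "T", "1")
    row = report.table[(report.table["node"] == "T") &
                       (report.table["state"] == 1)]
    assert row["derivative"].iloc[0] == pytest.approx(1.0)
    d3 = parameter_sensitivity_3point(model, "T", "1", "T", (), 1)
    assert d3 == pytest.approx(1.0, abs=1e-9)


def test_sensitivity_zero_for_dseparated_parameter():
    report = sensitivity(disconnected_model(), "T", "1")
    a_rows = report.table[report.table["node"] == "A"]
    np.testing.assert_allclose(a_rows["derivative"], 0.0, atol=1e-12)


def _finite_difference(model, target, tstate, node, config, state, h=1e-5):
    """Independent central-difference oracle via enumeration inference."""
    cpt = model.cpts[node]
    t_idx = model.spec.nodes[target].index(tstate)
    original = cpt.values.copy()
    row = original[config]
    theta0 = row[state]

    def covary(theta):
        out = row.copy()
        out[state] = theta
        others = np.arange(len(row)) != state
        out[others] = row[others] * (1 - theta) / (1 - theta0)
        return out

    vals = []
    for theta in (theta0 - h, theta0 + h):
        cpt.values = original.copy()
        cpt.values[config] = covary(theta)
        vals.append(infer_enumeration(model, {}, target)[t_idx])
    cpt.values = original
    return (vals[1] - vals[0]) / (2 * h)


def test_sensitivity_matches_finite_difference_and_3point():
    rng = np.random.default_rng(21)
    model = make_random_model(rng, 5, edge_p=0.5)
    target = "n4"
    tstate = model.spec.nodes[target][0]
    report = sensitivity(model, target, tstate)
    checked = 0
    for _, row in report.table.iterrows():
        node, config, state = row["node"], row["parent_config"], row["state"]
        theta = row["theta"]
        if theta < 1e-3 or theta > 1 - 1e-3:
            continue
        fd = _finite_difference(model, target, tstate, node, tuple(config),
                                int(state))
        assert row["derivative"] == pytest.approx(fd, abs=1e-6)
        checked += 1
    assert checked > 10
    # 3-point fit agrees with the analytic path on a sample of parameters
    sample = report.table.sample(5, random_state=0)
    for _, row in sample.iterrows():
        d3 = parameter_sensitivity_3point(model, target, tstate, row["node"],
                                          tuple(row["parent_config"]),
                                          int(row["state"]))
        assert d3 == pytest.approx(row["derivative"], abs=1e-7)


# --------------------------------------------------------------------------
# cross-validation
# --------------------------------------------------------------------------

def separable_dataset(n=200, seed=0):
    """Outcome a deterministic function of one ternary parent."""
    rng = np.random.default_rng(seed)
    x = rng.choice(["a", "b", "c"], size=n)
    y = np.select([x == "a", x == "b"], ["L", "M"], default="H")
    return pd.DataFrame({"X": x, "Y": y}), NetworkSpec(
        nodes={"X": ("a", "b", "c"), "Y": ("L", "M", "H")},
        edges=[("X", "Y")])


def test_cv_perfectly_separable_auc_one():
    data, spec = separable_dataset()
    result = cross_validate(data, spec, outcome="Y", k=10, seed=0)
    assert result.macro_auc == 1.0
    assert result.accuracy == 1.0
    assert all(v == 1.0 for v in result.per_class_auc.values())


def test_cv_requires_enough_rows_per_state():
    data, spec = separable_dataset(n=20)
    with pytest.raises(ValueError):
        cross_validate(data, spec, outcome="Y", k=15)


def test_auc_rank_identities():
    """Mann–Whitney identities: separated scores -> 1, identical -> 1/2."""
    from sklearn.metrics import roc_auc_score
    assert roc_auc_score([1, 1, 0, 0], [0.9, 0.8, 0.1, 0.2]) == 1.0
    assert roc_auc_score([1, 1, 0, 0], [0.5, 0.5, 0.5, 0.5]) == 0.5


def test_cv_deterministic_given_seed():
    data, spec = separable_dataset(n=120, seed=3)
    r1 = cross_validate(data, spec, outcome="Y", k=5, seed=42)
    r2 = cross_validate(data, spec, outcome="Y", k=5, seed=42)
    np.testing.assert_array_equal(r1.fold_assignments, r2.fold_assignments)
    pd.testing.assert_frame_equal(r1.predictions, r2.predictions)
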