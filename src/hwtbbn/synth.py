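"""Synthetic survey generator with a known ground-truth network.

The generator emulates the statistical structure the pipeline assumes: a
14-node ground-truth Bayesian network (eight socio-economic roots, five
RANAS psychosocial nodes, one behaviour outcome) sampled ancestrally per
household, Likert items emitted from the psychosocial latents as rounded
clamped Gaussians, binary assets driven by the wealth latent, behaviour
items driven by the outcome latent, and MCAR cell masking.

Ground-truth CPTs use a monotone softmax parameterization: each parent state
maps to a centred level in [-1, 1]; a weighted sum of parent levels (the
"drive") shifts the child's state distribution up or down through a
per-state slope.  The default weights and offsets were calibrated once, by
running exact inference on the resulting model, so that the true model's
no-evidence baseline P(outcome = regular) and the per-node ΔP spreads sit at
the values the study design assumes (baseline ≈ 31%; ΔP ≈ 19/16/11/10/6 for
self-regulation/ability/attitude/norm/risk and ≈ 10 for mother's education).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codebook import Codebook, default_codebook
from .learn import em_learn
from .network import (BbnModel, Cpt, HWT_NODE, NetworkSpec, RANAS_NODES,
                      SEC_NODES, default_network)
from .inference import infer_joint
from .survey import SurveyTable, validate_frame

# --------------------------------------------------------------------------
# default ground-truth parameters (study conditions)
# --------------------------------------------------------------------------

#: marginals of the socio-economic root nodes.  Where the study reports a
#: figure it is used (55% households with recent child diarrhea; 16.8% of
#: mothers and 25.7% of household heads without formal education; 45.5% with
#: an in-dwelling tap; wealth 40/40/20 by construction of the index); the
#: rest are realistic for a suburban Indonesian setting.
DEFAULT_SEC_MARGINALS: dict[str, tuple[float, ...]] = {
    "water_health_problem": (0.45, 0.55),
    "information_access": (0.25, 0.40, 0.35),
    "mother_education": (0.17, 0.40, 0.32, 0.11),
    "father_education": (0.26, 0.37, 0.27, 0.10),
    "wealth": (0.40, 0.40, 0.20),
    "religion": (0.40, 0.60),
    "accessibility": (0.54, 0.46),
    "access_water": (0.25, 0.30, 0.45),
}

#: SEC -> RANAS drive weights.  Mother's education dominates (through
#: attitude and ability); child diarrhea and distance to the water point
#: carry no effect; wealth and religion act weakly negatively.
DEFAULT_SEC_WEIGHTS: dict[tuple[str, str], float] = {}
for _r in RANAS_NODES:
    for _s in SEC_NODES:
        DEFAULT_SEC_WEIGHTS[(_s, _r)] = 0.0583
    DEFAULT_SEC_WEIGHTS[("water_health_problem", _r)] = 0.0
    DEFAULT_SEC_WEIGHTS[("access_water", _r)] = 0.0
    DEFAULT_SEC_WEIGHTS[("wealth", _r)] = -0.0729
    DEFAULT_SEC_WEIGHTS[("religion", _r)] = -0.0729
DEFAULT_SEC_WEIGHTS[("mother_education", "attitude")] = 0.6268
DEFAULT_SEC_WEIGHTS[("mother_education", "ability")] = 0.6268

#: per-state softmax offsets of the RANAS nodes (Low, Moderate, High);
#: calibrated for marginals near (0.40, 0.35, 0.25)
DEFAULT_RANAS_ALPHA: dict[str, tuple[float, float, float]] = {
    r: (0.0755, 0.0, -0.3453) for r in RANAS_NODES
}

#: RANAS -> outcome drive weights; calibrated so the true-model ΔP spreads
#: match the study conditions (self-reg 19, ability 16, attitude 11,
#: norm 10, risk 6)
DEFAULT_HWT_WEIGHTS: dict[str, float] = {
    "risk": 0.0886,
    "attitude": 0.1516,
    "norm": 0.1547,
    "ability": 0.2390,
    "self_regulation": 0.2996,
}

#: per-state softmax offsets of the outcome node (non-user, irregular,
#: regular); calibrated for a marginal near (0.36, 0.33, 0.31)
DEFAULT_HWT_ALPHA: tuple[float, float, float] = (-0.1116, 0.0, 0.0091)

#: Likert emission means per latent state (Low, Moderate, High) and the
#: common emission noise SD
DEFAULT_LIKERT_MU: tuple[float, float, float] = (2.0, 3.0, 4.0)
DEFAULT_LIKERT_SIGMA: float = 0.8

#: binary psychosocial item (barrier planning) success probability per state
DEFAULT_BINARY_ITEM_P: tuple[float, float, float] = (0.10, 0.30, 0.55)

#: asset ownership probability per wealth state (Poor, Middle, Rich); one
#: row per asset of the default codebook, cheap assets common, dear ones rare
DEFAULT_ASSET_P: dict[str, tuple[float, float, float]] = {
    "asset_radio": (0.30, 0.50, 0.70),
    "asset_tv": (0.45, 0.75, 0.92),
    "asset_fridge": (0.10, 0.35, 0.75),
    "asset_mobile_phone": (0.55, 0.80, 0.95),
    "asset_motorcycle": (0.30, 0.60, 0.85),
    "asset_bicycle": (0.25, 0.40, 0.55),
    "asset_electricity": (0.70, 0.90, 0.99),
    "asset_improved_floor": (0.30, 0.60, 0.90),
    "asset_own_toilet": (0.05, 0.12, 0.45),
    "asset_bank_account": (0.08, 0.25, 0.65),
}

#: behaviour item emissions per outcome state (non-user, irregular, regular)
DEFAULT_BEHAVIOUR_BINARY_P: dict[str, tuple[float, float, float]] = {
    "self_report_treat": (0.05, 0.35, 0.80),
}
DEFAULT_BEHAVIOUR_LIKERT_MU: dict[str, tuple[float, float, float]] = {
    "raw_water_frequency": (4.2, 3.0, 1.6),   # reverse-coded item
    "pct_water_treated": (1.6, 3.0, 4.3),
    "hwt_habit": (1.8, 3.0, 4.2),
    "hwt_intention": (2.2, 3.2, 4.3),
}

DEFAULT_MISSING_RATE = 0.015


class SynthError(ValueError):
    pass


def _levels(card: int) -> np.ndarray:
    """Centred, ordered parent-state levels in [-1, 1]."""
    if card == 1:
        return np.zeros(1)
    return np.linspace(-1.0, 1.0, card)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def build_truth_model(spec: NetworkSpec | None = None,
                      sec_marginals: dict | None = None,
                      sec_weights: dict | None = None,
                      ranas_alpha: dict | None = None,
                      hwt_weights: dict | None = None,
                      hwt_alpha: tuple | None = None) -> BbnModel:
    """Assemble the ground-truth model from the softmax parameterization."""
    spec = spec or default_network()
    sec_marginals = sec_marginals or DEFAULT_SEC_MARGINALS
    sec_weights = sec_weights or DEFAULT_SEC_WEIGHTS
    ranas_alpha = ranas_alpha or DEFAULT_RANAS_ALPHA
    hwt_weights = hwt_weights or DEFAULT_HWT_WEIGHTS
    hwt_alpha = hwt_alpha or DEFAULT_HWT_ALPHA

    cpts: dict[str, Cpt] = {}
    for node, probs in sec_marginals.items():
        p = np.asarray(probs, dtype=float)
        if not np.isclose(p.sum(), 1.0):
            raise SynthError(f"marginal for {node!r} does not sum to 1")
        cpts[node] = Cpt(node=node, parents=(), values=p)

    child_levels = _levels(3)
    for r in RANAS_NODES:
        parents = spec.parents(r)
        cards = [spec.card(p) for p in parents]
        drive = np.zeros(cards)
        for axis, p in enumerate(parents):
            lv = sec_weights.get((p, r), 0.0) * _levels(spec.card(p))
            shape = [1] * len(cards)
            shape[axis] = -1
            drive = drive + lv.reshape(shape)
        logits = np.asarray(ranas_alpha[r]) + drive[..., None] * child_levels
        cpts[r] = Cpt(node=r, parents=parents, values=_softmax(logits))

    parents = spec.parents(HWT_NODE)
    cards = [spec.card(p) for p in parents]
    drive = np.zeros(cards)
    for axis, p in enumerate(parents):
        lv = hwt_weights[p] * _levels(spec.card(p))
        shape = [1] * len(cards)
        shape[axis] = -1
        drive = drive + lv.reshape(shape)
    logits = np.asarray(hwt_alpha) + drive[..., None] * child_levels
    cpts[HWT_NODE] = Cpt(node=HWT_NODE, parents=parents, values=_softmax(logits))

    model = BbnModel(spec=spec, cpts=cpts,
                     metadata={"method": "synthetic_ground_truth"})
    model.validate()
    return model


@dataclass
class GroundTruth:
    """Everything needed to generate one synthetic survey."""

    model: BbnModel
    codebook: Codebook
    likert_mu: dict[str, tuple[float, float, float]]
    likert_sigma: float
    binary_item_p: dict[str, tuple[float, float, float]]
    asset_p: dict[str, tuple[float, float, float]]
    behaviour_binary_p: dict[str, tuple[float, float, float]]
    behaviour_likert_mu: dict[str, tuple[float, float, float]]
    missing_rate: float = DEFAULT_MISSING_RATE

    def validate(self) -> None:
        self.model.validate()
        if not 0 <= self.missing_rate < 1:
            raise SynthError("missing_rate must be in [0, 1)")
        for name, p in {**self.binary_item_p, **self.asset_p,
                        **self.behaviour_binary_p}.items():
            if not all(0 <= x <= 1 for x in p):
                raise SynthError(f"probabilities for {name!r} outside [0, 1]")
        for name, mu in self.likert_mu.items():
            var = self.codebook[name]
            lo, hi = (mu[0], mu[-1]) if var.polarity == "positive" else \
                     (mu[-1], mu[0])
            if not lo < hi:
                raise SynthError(f"emission means for {name!r} must be "
                                 "monotone in the latent state")


def default_ground_truth(missing_rate: float = DEFAULT_MISSING_RATE,
                         likert_sigma: float = DEFAULT_LIKERT_SIGMA,
                         model: BbnModel | None = None) -> GroundTruth:
    """The shipped study-condition ground truth."""
    cb = default_codebook()
    likert_mu = {}
    for v in cb.by_role("ranas_item"):
        if v.scale != "likert_1_5":
            continue
        mu = DEFAULT_LIKERT_MU
        if v.polarity == "reverse":
            mu = tuple(reversed(mu))
        likert_mu[v.name] = mu
    truth = GroundTruth(
        model=model or build_truth_model(),
        codebook=cb,
        likert_mu=likert_mu,
        likert_sigma=likert_sigma,
        binary_item_p={"barrier_planning": DEFAULT_BINARY_ITEM_P},
        asset_p=dict(DEFAULT_ASSET_P),
        behaviour_binary_p=dict(DEFAULT_BEHAVIOUR_BINARY_P),
        behaviour_likert_mu=dict(DEFAULT_BEHAVIOUR_LIKERT_MU),
        missing_rate=missing_rate,
    )
    truth.validate()
    return truth


@dataclass
class SynthOutput:
    survey: SurveyTable
    truth_states: pd.DataFrame
    ground_truth: GroundTruth


def _sample_categorical(rng: np.random.Generator, probs: np.ndarray) -> np.ndarray:
    """Row-wise categorical draw; probs shape (n, k)."""
    u = rng.random(probs.shape[0])
    return (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)


def generate(truth: GroundTruth, n: int, seed: int) -> SynthOutput:
    """Ancestral sampling of n households plus item emission and masking."""
    truth.validate()
    if n < 1:
        raise SynthError("need n >= 1 households")
    rng = np.random.default_rng(seed)
    spec = truth.model.spec
    cb = truth.codebook

    # --- latent node states ------------------------------------------------
    states: dict[str, np.ndarray] = {}
    for node in spec.topological_order():
        cpt = truth.model.cpts[node]
        if not cpt.parents:
            probs = np.broadcast_to(cpt.values, (n, spec.card(node)))
        else:
            idx = tuple(states[p] for p in cpt.parents)
            probs = cpt.values[idx]
        states[node] = _sample_categorical(rng, probs)

    factor_of = {"Risk": "risk", "Attitude": "attitude", "Norm": "norm",
                 "Ability": "ability", "Self-regulation": "self_regulation"}

    # --- item emission -----------------------------------------------------
    columns: dict[str, np.ndarray | list] = {
        cb.id_variable: np.arange(1, n + 1)}
    for node in SEC_NODES:
        if node == "wealth":
            continue
        columns[node] = np.array(spec.nodes[node], dtype=object)[states[node]]

    def emit_likert(latent: np.ndarray, mu: tuple) -> np.ndarray:
        vals = rng.normal(np.asarray(mu)[latent], truth.likert_sigma)
        return np.clip(np.round(vals), 1, 5)

    def emit_binary(latent: np.ndarray, p: tuple) -> np.ndarray:
        return (rng.random(n) < np.asarray(p)[latent]).astype(float)

    for v in cb.by_role("ranas_item"):
        latent = states[factor_of[v.factor]]
        if v.scale == "likert_1_5":
            columns[v.name] = emit_likert(latent, truth.likert_mu[v.name])
        else:
            columns[v.name] = emit_binary(latent, truth.binary_item_p[v.name])

    for name, p in truth.asset_p.items():
        columns[name] = emit_binary(states["wealth"], p)

    hwt = states[HWT_NODE]
    for name, p in truth.behaviour_binary_p.items():
        columns[name] = emit_binary(hwt, p)
    for name, mu in truth.behaviour_likert_mu.items():
        columns[name] = emit_likert(hwt, mu)

    frame = pd.DataFrame(columns)

    # --- MCAR masking ------------------------------------------------------
    if truth.missing_rate > 0:
        maskable = [c for c in frame.columns if c != cb.id_variable]
        mask = rng.random((n, len(maskable))) < truth.missing_rate
        for j, c in enumerate(maskable):
            col = frame[c].astype(object)
            col[mask[:, j]] = np.nan
            frame[c] = col

    survey = validate_frame(frame, cb)
    truth_states = pd.DataFrame(
        {cb.id_variable: np.arange(1, n + 1),
         **{node: np.array(spec.nodes[node], dtype=object)[states[node]]
            for node in spec.nodes}})
    return SynthOutput(survey=survey, truth_states=truth_states,
                       ground_truth=truth)


# --------------------------------------------------------------------------
# recovery experiment
# --------------------------------------------------------------------------

def reach_weights(model: BbnModel, node: str) -> np.ndarray:
    """Probability of each parent configuration under the model."""
    parents = model.cpts[node].parents
    if not parents:
        return np.asarray(1.0)
    joint = infer_joint(model, {}, list(parents))
    perm = [joint.variables.index(p) for p in parents]
    return np.transpose(joint.values, perm)


def weighted_cpt_l1(truth_model: BbnModel, learned: BbnModel,
                    node: str) -> float:
    """Reach-weighted mean L1 distance between true and learned CPT rows."""
    w = reach_weights(truth_model, node)
    diff = np.abs(truth_model.cpts[node].values - learned.cpts[node].values)
    return float((w[..., None] * diff).sum())


def delta_p_ranking_agreement(truth_deltas: dict[str, float],
                              learned_deltas: dict[str, float],
                              min_gap: float = 5.0) -> bool:
    """True when every node pair with a true ΔP gap >= min_gap is ordered
    the same way by the learned model's ΔP."""
    nodes = list(truth_deltas)
    for a, b in itertools.combinations(nodes, 2):
        gap = truth_deltas[a] - truth_deltas[b]
        if abs(gap) >= min_gap:
            if np.sign(learned_deltas[a] - learned_deltas[b]) != np.sign(gap):
                return False
    return True


def recovery_experiment(truth: GroundTruth, n: int, seeds: list[int], *,
                        prior_ess: float = 0.0, target_state: str =
                        "regular user") -> pd.DataFrame:
    """Generate -> full pipeline -> EM -> compare against the ground truth.

    One row per seed with the per-CPT reach-weighted L1 distances (and their
    median), the learned and true baseline outcome probabilities, and
    whether the learned ΔP ranking agrees with the truth for node pairs at
    least 5 points apart.

    The default prior here is 0 (maximum likelihood): a consistency
    experiment measures the estimator's convergence to the generating CPTs,
    which a fixed Dirichlet prior would bias at any finite n.  The analysis
    pipeline's own default for small surveys remains prior_ess = 1.
    """
    from .analysis import delta_p
    from .scores import discretize_scores, score_survey

    spec = truth.model.spec
    # fine precision: ranking comparisons must not be blurred by rounding
    true_report = delta_p(truth.model, HWT_NODE, target_state, precision=4)
    rows = []
    for seed in seeds:
        out = generate(truth, n, seed)
        scores = score_survey(out.survey)
        discrete = discretize_scores(scores, out.survey)
        learned = em_learn(discrete, spec, prior_ess=prior_ess)
        l1 = {node: weighted_cpt_l1(truth.model, learned, node)
              for node in spec.nodes}
        learned_report = delta_p(learned, HWT_NODE, target_state, precision=4)
        rows.append({
            "seed": seed, "n": n,
            "median_cpt_l1": float(np.median(list(l1.values()))),
            **{f"l1_{node}": v for node, v in l1.items()},
            "true_baseline_pct": true_report.baseline_pct,
            "learned_baseline_pct": learned_report.baseline_pct,
            "ranking_agrees": delta_p_ranking_agreement(
                true_report.delta_p, learned_report.delta_p),
            **{f"true_dp_{k}": v for k, v in true_report.delta_p.items()},
            **{f"learned_dp_{k}": v for k, v in learned_report.delta_p.items()},
        })
    return pd.DataFrame(rows)
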