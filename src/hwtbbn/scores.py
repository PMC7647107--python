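"""First-principal-component indices and their discretization.

Each construct (relative wealth, the five RANAS factors, HWT behaviour) is
summarized by the score on the first principal component of its standardized
item matrix — the DHS wealth-index construction applied uniformly.  PC1 sign
is ambiguous, so scores are oriented to correlate non-negatively with the
unweighted item mean.  Continuous scores are then cut into the categorical
node states of the network: 40/40/20 for wealth (poor/middle/rich), tertiles
for the psychosocial factors (Low/Moderate/High) and the behaviour outcome
(non-user / irregular user / regular user).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .codebook import RANAS_FACTORS
from .survey import SurveyTable

logger = logging.getLogger(__name__)

#: factor name -> score column
FACTOR_SCORE_COLUMNS = {
    "Risk": "risk_score",
    "Attitude": "attitude_score",
    "Norm": "norm_score",
    "Ability": "ability_score",
    "Self-regulation": "selfreg_score",
}

SCHEMES = {
    "tertile": (1 / 3, 1 / 3, 1 / 3),
    "forty_forty_twenty": (0.4, 0.4, 0.2),
}

#: node -> ordered states used for discretized scores
WEALTH_STATES = ("Poor", "Middle", "Rich")
RANAS_STATES = ("Low", "Moderate", "High")
HWT_STATES = ("non-user", "irregular user", "regular user")


@dataclass
class Pc1Result:
    scores: np.ndarray          # per-row score, NaN where the row was unusable
    loadings: np.ndarray        # per retained item
    variance_explained: float
    kept_items: list[int]       # indices of items kept (zero-variance dropped)


def _standardize(matrix: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Z-score columns (ddof=1); drop zero-variance columns with a warning."""
    sd = np.nanstd(matrix, axis=0, ddof=1)
    keep = [j for j in range(matrix.shape[1]) if sd[j] > 0]
    if len(keep) < matrix.shape[1]:
        dropped = sorted(set(range(matrix.shape[1])) - set(keep))
        warnings.warn(f"dropping zero-variance item column(s) {dropped}")
    if not keep:
        raise ValueError("all items have zero variance; PC1 undefined")
    sub = matrix[:, keep]
    mean = np.nanmean(sub, axis=0)
    return (sub - mean) / sd[keep], keep


def pc1_scores(items: np.ndarray, orientation_anchor: str = "mean") -> Pc1Result:
    """Scores on the first principal component of the standardized items.

    PCA is performed on the correlation matrix (items are z-scored first).
    Rows containing NaN receive a NaN score; impute beforehand with
    :func:`impute_items` if partial responses should still be scored.

    Parameters
    ----------
    items : array of shape (n_households, n_items)
    orientation_anchor : ``"mean"`` flips the component sign when the score
        correlates negatively with the unweighted mean of the (standardized)
        items; ``"none"`` keeps the eigensolver's sign.
    """
    items = np.asarray(items, dtype=float)
    if items.ndim != 2 or items.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 items")
    z, keep = _standardize(items)
    complete = ~np.isnan(z).any(axis=1)
    if complete.sum() < 3:
        raise ValueError("need at least 3 complete rows for PCA")

    pca = PCA(n_components=1, svd_solver="full")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        pca.fit(z[complete])
    loadings = pca.components_[0]
    scores = np.full(len(items), np.nan)
    scores[complete] = z[complete] @ loadings

    if orientation_anchor == "mean":
        anchor = z[complete].mean(axis=1)
        r = np.corrcoef(scores[complete], anchor)[0, 1] if anchor.std() > 0 else 1.0
        if np.isnan(r):
            r = float(np.sign(loadings.sum()) or 1.0)
        if r < 0:
            loadings = -loadings
            scores = -scores
    elif orientation_anchor != "none":
        raise ValueError(f"unknown orientation_anchor {orientation_anchor!r}")

    # recentre on the scored rows (PCA centred on its own fit sample)
    scores[complete] -= scores[complete].mean()
    return Pc1Result(scores=scores, loadings=loadings,
                     variance_explained=float(pca.explained_variance_ratio_[0]),
                     kept_items=keep)


def impute_items(items: np.ndarray) -> np.ndarray:
    """Mean-impute sparse gaps; blank out rows missing half or more items.

    A household keeps its row when more than half of the construct's items
    are present: remaining gaps are filled with the item's sample mean.
    Otherwise the whole row is set to NaN so the downstream factor score (and
    the network state) is missing and left to the EM learner.
    """
    items = np.asarray(items, dtype=float).copy()
    n_items = items.shape[1]
    item_means = np.nanmean(items, axis=0)
    n_present = (~np.isnan(items)).sum(axis=1)
    for i in range(items.shape[0]):
        if n_present[i] == n_items:
            continue
        if n_present[i] >= n_items / 2 and n_present[i] > 0:
            gaps = np.isnan(items[i])
            items[i, gaps] = item_means[gaps]
        else:
            items[i, :] = np.nan
    return items


def wealth_index(assets: np.ndarray) -> Pc1Result:
    """Relative wealth: PC1 of the binary asset-indicator matrix."""
    return pc1_scores(np.asarray(assets, dtype=float), orientation_anchor="mean")


def hwt_behaviour_score(answers: np.ndarray,
                        reverse: list[int] | None = None,
                        scale_max: np.ndarray | None = None,
                        scale_min: np.ndarray | None = None) -> Pc1Result:
    """HWT behaviour index: PC1 of the five behaviour items.

    ``reverse`` lists column indices of reverse-coded items; they are flipped
    (x -> min+max-x) before scoring so that larger always means more/safer
    treatment.
    """
    answers = np.asarray(answers, dtype=float).copy()
    if reverse:
        if scale_max is None:
            scale_max = np.nanmax(answers, axis=0)
        if scale_min is None:
            scale_min = np.nanmin(answers, axis=0)
        for j in reverse:
            answers[:, j] = scale_min[j] + scale_max[j] - answers[:, j]
    return pc1_scores(answers, orientation_anchor="mean")


def discretize(scores: np.ndarray, scheme: str,
               states: tuple[str, ...] | None = None) -> np.ndarray:
    """Cut continuous scores into ordered states by rank-based quantiles.

    Cutpoints sit at ranks ceil(q1*m) and ceil((q1+q2)*m) of the m
    non-missing scores; a household enters the lowest state whose cutpoint
    value is >= its score.  Ties at a cutpoint therefore all take the lower
    state (with every score identical, everyone is in the lowest state), and
    category counts deviate from the quantile targets by at most the number
    of tied boundary values.  Missing scores yield missing states (None).
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown discretization scheme {scheme!r}")
    q = SCHEMES[scheme]
    if states is None:
        states = RANAS_STATES
    if len(states) != len(q):
        raise ValueError("state list length must match the scheme")

    scores = np.asarray(scores, dtype=float)
    present = ~np.isnan(scores)
    m = int(present.sum())
    if m < 3:
        raise ValueError("need at least 3 non-missing scores to discretize")
    ordered = np.sort(scores[present])
    b1 = int(np.ceil(q[0] * m))
    b2 = int(np.ceil((q[0] + q[1]) * m))
    cut1, cut2 = ordered[b1 - 1], ordered[b2 - 1]

    out = np.full(len(scores), None, dtype=object)
    out[present & (scores <= cut1)] = states[0]
    out[present & (scores > cut1) & (scores <= cut2)] = states[1]
    out[present & (scores > cut2)] = states[2]
    logger.debug("discretize %s: cutpoints %.4f / %.4f", scheme, cut1, cut2)
    return out


# --------------------------------------------------------------------------
# survey-level drivers
# --------------------------------------------------------------------------

def score_survey(table: SurveyTable) -> pd.DataFrame:
    """Build the full ScoreTable (wealth, five RANAS factors, HWT behaviour).

    Items with partial missingness are mean-imputed per construct via
    :func:`impute_items`; households missing half or more of a construct's
    items get a missing score.
    """
    cb = table.codebook
    out = pd.DataFrame({cb.id_variable: table.ids})

    asset_cols = [v.name for v in cb.by_role("asset")]
    assets = impute_items(table.data[asset_cols].to_numpy(dtype=float))
    out["wealth_score"] = wealth_index(assets).scores

    for factor in RANAS_FACTORS:
        defs = cb.items_for_factor(factor)
        mat = table.data[[v.name for v in defs]].to_numpy(dtype=float).copy()
        for j, v in enumerate(defs):
            if v.polarity == "reverse":
                lo, hi = (1, 5) if v.scale == "likert_1_5" else (0, 1)
                mat[:, j] = lo + hi - mat[:, j]
        out[FACTOR_SCORE_COLUMNS[factor]] = pc1_scores(impute_items(mat)).scores

    beh = cb.by_role("behaviour_item")
    mat = table.data[[v.name for v in beh]].to_numpy(dtype=float)
    reverse = [j for j, v in enumerate(beh) if v.polarity == "reverse"]
    lo = np.array([1 if v.scale == "likert_1_5" else 0 for v in beh], dtype=float)
    hi = np.array([5 if v.scale == "likert_1_5" else 1 for v in beh], dtype=float)
    out["hwt_score"] = hwt_behaviour_score(
        impute_items(mat), reverse=reverse, scale_min=lo, scale_max=hi).scores
    return out


def discretize_scores(score_table: pd.DataFrame, survey: SurveyTable) -> pd.DataFrame:
    """Build the 14-node DiscreteDataset from scores + raw SEC answers.

    SEC answers pass through unchanged; wealth uses the 40/40/20 cut; RANAS
    factors and the behaviour outcome use tertiles.  Missing stays missing.
    """
    cb = survey.codebook
    out = pd.DataFrame({cb.id_variable: survey.ids})
    for v in cb.by_role("sec"):
        if not v.derived:
            out[v.name] = survey.data[v.name]
    out["wealth"] = discretize(score_table["wealth_score"].to_numpy(),
                               "forty_forty_twenty", WEALTH_STATES)
    node_names = {"Risk": "risk", "Attitude": "attitude", "Norm": "norm",
                  "Ability": "ability", "Self-regulation": "self_regulation"}
    for factor, node in node_names.items():
        col = FACTOR_SCORE_COLUMNS[factor]
        out[node] = discretize(score_table[col].to_numpy(), "tertile", RANAS_STATES)
    out["hwt_behaviour"] = discretize(score_table["hwt_score"].to_numpy(),
                                      "tertile", HWT_STATES)
    return out
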