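"""End-to-end drivers tying the stages together.

survey -> PCA score table -> discrete 14-node dataset -> EM-learned network
-> ΔP / sensitivity / cross-validation, plus the supporting regression and
chi-square tests.  The CLI is a thin wrapper around these functions.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .analysis import (CvResult, DeltaPReport, SensitivityReport,
                       cross_validate, delta_p, sensitivity)
from .learn import em_learn
from .network import BbnModel, HWT_NODE, NetworkSpec, default_network
from .scores import discretize_scores, score_survey
from .stats import ChiSquareResult, RegressionResult, chi_square, ols_forced_entry
from .survey import SurveyTable

TARGET_STATE = "regular user"


def regression_from_survey(survey: SurveyTable,
                           scores: pd.DataFrame) -> RegressionResult:
    """Forced-entry OLS of the HWT behaviour score on all 16 RANAS items."""
    items = [v.name for v in survey.codebook.by_role("ranas_item")]
    return ols_forced_entry(scores["hwt_score"], survey.data[items])


@dataclass
class PipelineResult:
    scores: pd.DataFrame
    discrete: pd.DataFrame
    model: BbnModel
    delta_p: DeltaPReport
    sensitivity: SensitivityReport
    cv: CvResult
    regression: RegressionResult
    chi_square_religion: ChiSquareResult


def run_pipeline(survey: SurveyTable, *, spec: NetworkSpec | None = None,
                 prior_ess: float = 1.0, tol: float = 1e-6,
                 max_iter: int = 500, cv_folds: int = 10,
                 cv_seed: int = 0) -> PipelineResult:
    """Run every analysis stage on one survey table."""
    spec = spec or default_network()
    scores = score_survey(survey)
    discrete = discretize_scores(scores, survey)
    model = em_learn(discrete, spec, prior_ess=prior_ess, tol=tol,
                     max_iter=max_iter)
    dp = delta_p(model, HWT_NODE, TARGET_STATE)
    sens = sensitivity(model, HWT_NODE, TARGET_STATE)
    cv = cross_validate(discrete, spec, k=cv_folds, seed=cv_seed,
                        prior_ess=prior_ess, tol=tol, max_iter=max_iter)
    reg = regression_from_survey(survey, scores)
    chi = chi_square(discrete["religion"], discrete[HWT_NODE])
    return PipelineResult(scores=scores, discrete=discrete, model=model,
                          delta_p=dp, sensitivity=sens, cv=cv, regression=reg,
                          chi_square_religion=chi)
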