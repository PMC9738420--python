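"""Study-level analyses: descriptives and ordinal mixed-model comparisons.

Ties the packaged study table to the cumulative-link mixed models: single-
and multi-term fits of perceived control and frustration on the game
variables, likelihood-ratio tests against the subject-only null, and the
forward-stepwise comparison tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .clmm import (CumulativeLinkMixedModel, build_design, forward_stepwise,
                   lr_test)
from .data import StudyTable

__all__ = ["fit_study_model", "descriptives_table", "model_comparison_table",
           "STUDY_CANDIDATES"]

# covariates available per cell in the packaged table
STUDY_CANDIDATES = ["fish_lost", "fish_caught", "positive_feedback",
                    "mi_conversion_rate", "condition"]


def fit_study_model(table: StudyTable, response: str, terms: list[str],
                    seed: int = 0) -> CumulativeLinkMixedModel:
    """Fit ``response`` (ordinal 1-7) on ``terms`` with participant random
    intercepts over the 71 complete participant-condition rows."""
    df = table.complete
    X = build_design(df, terms)
    model = CumulativeLinkMixedModel(seed=seed)
    model.fit(X.to_numpy(), df[f"{response}_level"].to_numpy(),
              df["participant"].to_numpy())
    model.term_names_ = list(X.columns)
    return model


def descriptives_table(table: StudyTable) -> pd.DataFrame:
    """Min/max/mean/SD of the response and explanatory variables over the
    complete rows (ratings on their normalized 0-1 display scale)."""
    df = table.complete
    cols = {"perceived_control": df["perceived_control"],
            "frustration": df["frustration"],
            "mi_conversion_rate": df["mi_conversion_rate"],
            "positive_feedback": df["positive_feedback"],
            "fish_caught": df["fish_caught"],
            "fish_lost": df["fish_lost"]}
    out = pd.DataFrame({k: [v.min(), v.max(), v.mean(), v.std()] for k, v in cols.items()},
                       index=["min", "max", "mean", "sd"]).T
    return out.round(3)


def model_comparison_table(table: StudyTable, response: str, seed: int = 0
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Forward-stepwise comparison of the in-table candidate terms.

    Returns (comparison table with AIC / ML / LR / p per evaluated model,
    estimates table for the final selected model).
    """
    df = table.complete
    trace = forward_stepwise(df, f"{response}_level", "participant",
                             STUDY_CANDIDATES, seed=seed)
    comp = trace.to_frame().rename(columns={"loglik": "ML"})
    comp["aic"] = comp["aic"].round(2)
    comp["ML"] = comp["ML"].round(2)
    final_label = " + ".join(trace.selected) if trace.selected else "<null>"
    final = trace.fits[final_label]
    est = final.summary_frame(getattr(final, "term_names_", None))
    return comp, est.round(3)
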