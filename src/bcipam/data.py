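"""Packaged study table: loading, validation, and analysis datasets.

The package ships the per-participant, per-condition scores of the 18-person
within-subject game study as a tidy CSV (one row per participant-condition):
normalized 7-point ratings of perceived control and frustration, the MI
conversion rate and positive-feedback rate (whole percent, multiples of 5 as
implied by 20-trial conditions), and fish caught/lost counts.  One cell
(participant 14, mitigated failure) is missing and kept as an explicit
empty-row marker; participant 2 is absent entirely (excluded at source for
missing data).  :func:`simulate_cohort` replays the full game + scheduler
pipeline to produce a table of the same shape from per-participant success
rates.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .clmm import OrdinalDataset, build_design  # noqa: F401  (re-export convenience)
from .metrics import recode_rating

__all__ = ["StudyTable", "load_study_table", "to_ordinal_dataset", "simulate_cohort"]

CONDITIONS = ["normal", "augmented_success", "input_override", "mitigated_failure"]

_RATING_COLS = ["perceived_control", "frustration"]
_PCT_COLS = ["mi_conversion_pct", "positive_feedback_pct"]
_COUNT_COLS = ["fish_caught", "fish_lost"]


@dataclass
class StudyTable:
    """Validated study table: all rows plus the complete-case analysis frame."""

    frame: pd.DataFrame          # 72 rows incl. the missing-cell marker row
    complete: pd.DataFrame       # 71 complete rows with ordinal levels added
    missing_cells: list[tuple[int, str]]

    @property
    def n_participants(self) -> int:
        return self.frame["participant"].nunique()

    def save(self, path: str | Path) -> None:
        """Write the raw table back out (round-trips through the loader)."""
        self.frame.to_csv(path, index=False)


def _default_path() -> Path:
    return Path(str(importlib.resources.files("bcipam") / "data" / "study_table.csv"))


def load_study_table(path: str | Path | None = None) -> StudyTable:
    """Load and validate the packaged (or an equally-shaped) study table.

    Validation enforces the structural facts of the study: 18 participants x
    4 conditions with exactly one missing cell, ratings on the 1/6 grid of a
    normalized 7-point scale, percentage columns in whole multiples of 5,
    and reference-condition positive feedback equal to the MI conversion
    rate.  Violations raise ``ValueError`` listing the offending cells.
    """
    path = Path(path) if path is not None else _default_path()
    raw = pd.read_csv(path, dtype={"participant": int})
    # normalize unicode minus / stray percent signs in numeric columns
    for col in _RATING_COLS + _PCT_COLS + _COUNT_COLS:
        if raw[col].dtype == object:
            raw[col] = (raw[col].astype(str)
                        .str.replace("−", "-", regex=False)
                        .str.replace("%", "", regex=False)
                        .replace({"": np.nan, "nan": np.nan}))
        raw[col] = pd.to_numeric(raw[col], errors="raise")

    problems: list[str] = []
    if set(raw["condition"]) != set(CONDITIONS):
        problems.append(f"unexpected condition labels: {sorted(set(raw['condition']))}")
    counts = raw.groupby("participant").size()
    if not (counts == 4).all():
        problems.append("each participant must have 4 condition rows")

    value_cols = _RATING_COLS + _PCT_COLS + _COUNT_COLS
    miss_mask = raw[value_cols].isna().any(axis=1)
    missing_cells = [(int(r.participant), str(r.condition))
                     for r in raw[miss_mask].itertuples()]
    if not raw[miss_mask][value_cols].isna().all(axis=None):
        problems.append("partially missing cells are not allowed")

    ok = raw[~miss_mask]
    for col in _RATING_COLS:
        off = ok.loc[np.abs(ok[col] * 6 - np.round(ok[col] * 6)) > 0.03]
        for r in off.itertuples():
            problems.append(f"off-grid rating {getattr(r, col)} in {col} "
                            f"(P{r.participant}, {r.condition})")
    for col in _PCT_COLS:
        off = ok.loc[(ok[col] % 5 != 0) | (ok[col] < 0) | (ok[col] > 100)]
        for r in off.itertuples():
            problems.append(f"off-grid percentage {getattr(r, col)} in {col} "
                            f"(P{r.participant}, {r.condition})")
    ref = ok[ok["condition"] == "normal"]
    bad_ref = ref[ref["mi_conversion_pct"] != ref["positive_feedback_pct"]]
    for r in bad_ref.itertuples():
        problems.append(f"reference condition P{r.participant}: positive feedback "
                        "must equal MI conversion rate")
    if (ok[_COUNT_COLS] < 0).any(axis=None):
        problems.append("negative fish counts")
    if problems:
        raise ValueError("study table validation failed:\n  " + "\n  ".join(problems))

    complete = ok.copy()
    complete["mi_conversion_rate"] = complete.pop("mi_conversion_pct") / 100.0
    complete["positive_feedback"] = complete.pop("positive_feedback_pct") / 100.0
    complete["perceived_control_level"] = recode_rating(complete["perceived_control"])
    complete["frustration_level"] = recode_rating(complete["frustration"])
    complete[_COUNT_COLS] = complete[_COUNT_COLS].astype(int)
    return StudyTable(frame=raw, complete=complete.reset_index(drop=True),
                      missing_cells=missing_cells)


def to_ordinal_dataset(table: StudyTable | pd.DataFrame, response: str,
                       terms: list[str]) -> OrdinalDataset:
    """Build the ordinal dataset (levels 1-7, participant grouping) for a fit.

    ``response`` is ``"perceived_control"`` or ``"frustration"``; ``terms``
    are covariate names (``condition`` expands to helped-vs-normal contrasts).
    """
    df = table.complete if isinstance(table, StudyTable) else table
    y = df[f"{response}_level"].to_numpy()
    X = build_design(df, terms)
    return OrdinalDataset(response=y, covariates=X,
                          group=df["participant"].to_numpy())


def simulate_cohort(conversion_rates: dict[int, float] | None = None,
                    seed: int = 0, mode: str = "experiment") -> pd.DataFrame:
    """Replay the full scheduler + game pipeline for a simulated cohort.

    Each participant plays the four conditions in their Latin-square order
    with a Bernoulli(rate) attempt model; rates default to the packaged
    reference-condition MI conversion rates.  Returns a study-table-shaped
    frame (ratings absent: there is no human-rating model).
    """
    from .scheduler import PamKind, condition_order, run_condition
    from .metrics import summarize_condition

    if conversion_rates is None:
        table = load_study_table()
        ref = table.complete[table.complete["condition"] == "normal"]
        conversion_rates = dict(zip(ref["participant"], ref["mi_conversion_rate"]))
    bad = {p: r for p, r in conversion_rates.items() if not 0.0 <= r <= 1.0}
    if bad:
        raise ValueError(f"conversion rates outside [0, 1]: {bad}")

    cond_name = {PamKind.NONE: "normal", PamKind.AUGMENTED_SUCCESS: "augmented_success",
                 PamKind.INPUT_OVERRIDE: "input_override",
                 PamKind.MITIGATED_FAILURE: "mitigated_failure"}
    rng = np.random.default_rng(seed)
    rows = []
    for idx, (pid, rate) in enumerate(sorted(conversion_rates.items())):
        for pam in condition_order(idx):
            sub_seed = int(rng.integers(0, 2**31 - 1))
            result = run_condition(pam, attempt_rate=rate, seed=sub_seed, mode=mode)
            rec = summarize_condition(result.trials, result.encounters)
            rows.append({"participant": pid, "condition": cond_name[pam],
                         "mi_conversion_rate": rec.mi_conversion_rate,
                         "positive_feedback": rec.positive_feedback,
                         "pam_rate": rec.pam_rate,
                         "fish_caught": rec.fish_caught, "fish_lost": rec.fish_lost,
                         "fish_reel": rec.fish_reel, "fish_unreel": rec.fish_unreel,
                         "seed": sub_seed})
    return pd.DataFrame(rows)
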