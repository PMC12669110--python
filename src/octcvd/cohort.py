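"""Cohort construction: event window, exclusions, 1:3 propensity matching.

Cases are subjects with a first MI/stroke inside the half-open window
(0, 5] years after imaging; subjects with diabetes or cardiomyopathy are
excluded as confounders. Controls are matched 1:3 to cases on a logistic
propensity score built from age and sex, with exact sex stratification,
greedy nearest-neighbour selection without replacement, and an age caliper.
Every inclusion/exclusion step is recorded in a STROBE-style ledger whose
counts must chain exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from octcvd.errors import ConfigurationError, MatchingError
from octcvd.phantom import EVENT_WINDOW_YEARS


@dataclass
class LedgerStep:
    step_name: str
    n_before: int
    n_excluded: int
    n_after: int
    reason: str


@dataclass
class StrobeLedger:
    """Ordered inclusion/exclusion record; counts must chain exactly."""

    steps: List[LedgerStep] = field(default_factory=list)

    def add_step(self, step_name: str, n_before: int, n_excluded: int, reason: str):
        n_after = n_before - n_excluded
        if n_after < 0:
            raise ConfigurationError("cannot exclude more records than present")
        if self.steps and self.steps[-1].n_after != n_before:
            raise ConfigurationError(
                f"ledger does not chain: step {step_name!r} starts at "
                f"{n_before} but previous step ended at {self.steps[-1].n_after}"
            )
        self.steps.append(LedgerStep(step_name, n_before, n_excluded, n_after, reason))

    def validate(self) -> None:
        for s in self.steps:
            assert s.n_after == s.n_before - s.n_excluded
        for a, b in zip(self.steps, self.steps[1:]):
            assert a.n_after == b.n_before

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.steps])

    def to_text(self) -> str:
        """Render as a text STROBE flow diagram."""
        if not self.steps:
            return "(empty ledger)"
        lines = [f"[ n = {self.steps[0].n_before} ]"]
        for s in self.steps:
            lines.append(f"  |-- excluded {s.n_excluded}: {s.reason}")
            lines.append(f"[ n = {s.n_after} ]  ({s.step_name})")
        return "\n".join(lines)


@dataclass
class MatchedCohort:
    """Result of case-control matching.

    ``pairing`` maps each case id to its matched control ids; every control
    appears at most once and shares its case's sex exactly.
    """

    cases: List[str]
    controls: List[str]
    pairing: Dict[str, List[str]]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"case_id": c, "control_id": k}
            for c, ctrls in self.pairing.items()
            for k in ctrls
        ]
        return pd.DataFrame(rows)


def event_in_window(event_offset: float, window: float = EVENT_WINDOW_YEARS) -> bool:
    """True iff the first event falls strictly after imaging and within the
    window: 0 < offset <= window. Pre-imaging events and missing offsets
    are out of window."""
    if event_offset is None or not np.isfinite(event_offset):
        return False
    return 0.0 < event_offset <= window


def apply_exclusions(
    records: pd.DataFrame,
    exclusion_flags: Sequence[str] = ("diabetes", "cardiomyopathy"),
    ledger: Optional[StrobeLedger] = None,
) -> Tuple[pd.DataFrame, StrobeLedger]:
    """Drop records with any exclusion flag set, one ledger step per flag."""
    if ledger is None:
        ledger = StrobeLedger()
    kept = records
    for flag in exclusion_flags:
        if flag not in records.columns:
            raise ConfigurationError(f"unknown exclusion flag {flag!r}")
        n_before = len(kept)
        mask = kept[flag].astype(bool)
        kept = kept.loc[~mask]
        ledger.add_step(
            f"exclude_{flag}", n_before, int(mask.sum()), f"{flag} present"
        )
    return kept.copy(), ledger


def select_cases(
    records: pd.DataFrame,
    window: float = EVENT_WINDOW_YEARS,
    ledger: Optional[StrobeLedger] = None,
) -> Tuple[pd.DataFrame, StrobeLedger]:
    """Label eligibility: CVD+ subjects must have their event in (0, window].

    CVD+ records whose event falls outside the window are excluded; CVD-
    records pass through (they are the control pool).
    """
    if ledger is None:
        ledger = StrobeLedger()
    in_window = records.apply(
        lambda r: r["cvd_label"] != "CVD+" or event_in_window(r["event_offset"], window),
        axis=1,
    )
    n_before = len(records)
    kept = records.loc[in_window]
    ledger.add_step(
        "event_window", n_before, int((~in_window).sum()),
        f"CVD+ event outside (0, {window}] years",
    )
    return kept.copy(), ledger


def _propensity_scores(records: pd.DataFrame, covariates: Sequence[str]) -> pd.Series:
    X = pd.DataFrame(index=records.index)
    for cov in covariates:
        if cov == "sex":
            X["sex"] = (records["sex"] == "M").astype(float)
        else:
            X[cov] = records[cov].astype(float)
    y = (records["cvd_label"] == "CVD+").astype(int)
    model = LogisticRegression(max_iter=1000)
    model.fit(X.values, y.values)
    return pd.Series(model.predict_proba(X.values)[:, 1], index=records.index)


def propensity_match(
    records: pd.DataFrame,
    ratio: int = 3,
    covariates: Sequence[str] = ("age", "sex"),
    caliper: float = 2.0,
    seed: int = 0,
) -> MatchedCohort:
    """1:ratio greedy propensity matching with exact sex strata.

    A logistic propensity model is fit on the covariates; within each sex
    stratum, cases (in seeded random order) greedily take the ``ratio``
    nearest unused controls by propensity score, subject to an absolute age
    caliper in years. If any case cannot be fully matched a
    :class:`~octcvd.errors.MatchingError` is raised listing every such case
    -- there is no silent partial matching.
    """
    if ratio < 1:
        raise ConfigurationError("ratio must be >= 1")
    ps = _propensity_scores(records, covariates)
    cases = records.loc[records["cvd_label"] == "CVD+"]
    controls = records.loc[records["cvd_label"] == "CVD-"]

    rng = np.random.default_rng(seed)
    case_order = cases.index.to_numpy()[rng.permutation(len(cases))]

    used: set = set()
    pairing: Dict[str, List[str]] = {}
    unmatched: List[str] = []
    for ci in case_order:
        case = records.loc[ci]
        pool = controls.loc[
            (controls["sex"] == case["sex"])
            & ((controls["age"] - case["age"]).abs() <= caliper)
        ]
        pool = pool.loc[[i for i in pool.index if i not in used]]
        if len(pool) < ratio:
            unmatched.append(str(case["subject_id"]))
            continue
        dist = (ps.loc[pool.index] - ps.loc[ci]).abs()
        chosen = dist.sort_values(kind="stable").index[:ratio]
        used.update(chosen)
        pairing[str(case["subject_id"])] = [
            str(records.loc[i, "subject_id"]) for i in chosen
        ]
    if unmatched:
        raise MatchingError(sorted(unmatched))

    case_ids = [str(records.loc[i, "subject_id"]) for i in sorted(cases.index)]
    control_ids = [c for case_id in sorted(pairing) for c in pairing[case_id]]
    return MatchedCohort(cases=case_ids, controls=control_ids, pairing=pairing)


def standardized_mean_difference(a: np.ndarray, b: np.ndarray) -> float:
    """Covariate-balance SMD: |mean(a)-mean(b)| / pooled SD."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
    if pooled == 0:
        return 0.0
    return float(abs(a.mean() - b.mean()) / pooled)
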