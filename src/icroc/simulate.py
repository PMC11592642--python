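"""Monte Carlo recovery harness for Bi-distributional ROC model selection.

Each run draws a negative- and a positive-class sample from a pseudo-true
distribution pair, fits all seven candidate families to each class by
maximum likelihood (candidates whose support excludes the data are dropped
for that run), scores every candidate pair with AUC, AIC-ROC and
ICOMP-ROC, and records which pair each criterion selects.  Selection
frequencies over many runs measure each criterion's ability to recover the
generating pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .criteria import CriterionConfig, CriterionReport, DEFAULT_CONFIG, score_candidate
from .families import Family, FitInfeasibleError, ParamVector, fit_mle, sample
from .roc import BiDistributionPair

__all__ = [
    "CANDIDATE_PAIRS",
    "ScenarioSpec",
    "FrequencyTable",
    "normal_normal_scenario",
    "weibull_gamma_scenario",
    "run_once",
    "select_winner",
    "run_monte_carlo",
]

#: The sixteen candidate (positive family, negative family) pairs, in
#: canonical order: the seven matched pairs followed by the nine mixed ones.
CANDIDATE_PAIRS: tuple[tuple[Family, Family], ...] = tuple(
    [(fam, fam) for fam in Family]
    + [
        (Family.EXPONENTIAL, Family.NORMAL),
        (Family.GAMMA, Family.NORMAL),
        (Family.WEIBULL, Family.NORMAL),
        (Family.EV, Family.NORMAL),
        (Family.GEV, Family.NORMAL),
        (Family.GP, Family.NORMAL),
        (Family.WEIBULL, Family.GAMMA),
        (Family.WEIBULL, Family.EXPONENTIAL),
        (Family.GAMMA, Family.EXPONENTIAL),
    ]
)

CRITERIA = ("AUC", "AIC-ROC", "ICOMP-ROC")


def pair_label(pos: Family, neg: Family) -> str:
    return f"{pos.value}-{neg.value}"


@dataclass
class ScenarioSpec:
    """One Monte Carlo study: a pseudo-true pair plus the candidate portfolio."""

    true_pos: ParamVector
    true_neg: ParamVector
    n_neg: int = 200
    n_pos: int = 300
    candidate_pairs: tuple = CANDIDATE_PAIRS
    n_runs: int = 100
    master_seed: int = 0
    config: CriterionConfig = DEFAULT_CONFIG

    def __post_init__(self) -> None:
        if not self.candidate_pairs:
            raise ValueError("candidate pair list must be nonempty")
        if self.n_neg < 2 or self.n_pos < 2:
            raise ValueError("class sample sizes must be >= 2")

    @property
    def prevalence_neg(self) -> float:
        return self.n_neg / (self.n_neg + self.n_pos)

    @property
    def prevalence_pos(self) -> float:
        return 1.0 - self.prevalence_neg


def normal_normal_scenario(**overrides) -> ScenarioSpec:
    """Case 1: both classes Gaussian with nearly equal means, unequal spreads."""
    defaults = dict(
        true_pos=ParamVector(Family.NORMAL, {"mu": 1.0, "sigma": 1.87}),
        true_neg=ParamVector(Family.NORMAL, {"mu": 0.99, "sigma": 0.71}),
    )
    defaults.update(overrides)
    return ScenarioSpec(**defaults)


def weibull_gamma_scenario(**overrides) -> ScenarioSpec:
    """Case 2: Weibull positive class versus Gamma negative class."""
    defaults = dict(
        true_pos=ParamVector(Family.WEIBULL, {"alpha": 2.0, "beta": 1.0}),
        true_neg=ParamVector(Family.GAMMA, {"alpha": 2.0, "beta": 2.0}),
    )
    defaults.update(overrides)
    return ScenarioSpec(**defaults)


def run_once(scenario: ScenarioSpec, run_seed: int) -> list[CriterionReport]:
    """One Monte Carlo run: sample, fit all families per class, score all pairs.

    Families whose support excludes the drawn data (e.g. positive-support
    families on samples with negative values) yield excluded reports rather
    than aborting the run.  Each family is fitted once per class and reused
    across candidate pairs.
    """
    neg = sample(scenario.true_neg, scenario.n_neg, 2 * run_seed + 1)
    pos = sample(scenario.true_pos, scenario.n_pos, 2 * run_seed + 2)
    pooled = np.concatenate([neg, pos])
    n_total = scenario.n_neg + scenario.n_pos

    fits: dict[tuple[str, Family], object] = {}
    notes: dict[tuple[str, Family], str] = {}
    needed_pos = {p for p, _ in scenario.candidate_pairs}
    needed_neg = {q for _, q in scenario.candidate_pairs}
    for cls, data, needed in (("pos", pos, needed_pos), ("neg", neg, needed_neg)):
        for fam in needed:
            try:
                fits[(cls, fam)] = fit_mle(fam, data)
            except FitInfeasibleError as exc:
                fits[(cls, fam)] = None
                notes[(cls, fam)] = str(exc)

    reports: list[CriterionReport] = []
    for pos_fam, neg_fam in scenario.candidate_pairs:
        label = pair_label(pos_fam, neg_fam)
        fit_pos = fits[("pos", pos_fam)]
        fit_neg = fits[("neg", neg_fam)]
        if fit_pos is None or fit_neg is None:
            why = notes.get(("pos", pos_fam)) or notes.get(("neg", neg_fam)) or "fit infeasible"
            reports.append(CriterionReport.excluded_report(label, n_total, why))
            continue
        pair = BiDistributionPair(pos=fit_pos, neg=fit_neg, label=label)
        reports.append(
            score_candidate(pair, n_total, pooled=pooled, config=scenario.config)
        )
    if all(rep.excluded for rep in reports):
        warnings.warn(f"run with seed {run_seed}: every candidate was excluded", stacklevel=2)
    return reports


def select_winner(reports: list[CriterionReport], criterion: str) -> tuple[str, bool]:
    """The winning candidate label under one criterion, plus a tie flag.

    AUC is maximized; AIC-ROC and ICOMP-ROC are minimized.  Exact ties are
    broken by candidate order (the earlier candidate wins) and flagged.
    """
    if criterion not in CRITERIA:
        raise ValueError(f"criterion must be one of {CRITERIA}")
    valid = [rep for rep in reports if not rep.excluded]
    if not valid:
        raise ValueError("no non-excluded reports to select from")
    key = {"AUC": lambda rep: -rep.auc,
           "AIC-ROC": lambda rep: rep.aic_roc,
           "ICOMP-ROC": lambda rep: rep.icomp_roc}[criterion]
    values = [key(rep) for rep in valid]
    best = min(values)
    winners = [rep for rep, v in zip(valid, values) if v == best]
    return winners[0].candidate, len(winners) > 1


@dataclass
class FrequencyTable:
    """Per-candidate selection counts for each criterion over a Monte Carlo study."""

    counts: pd.DataFrame  # index: candidate labels; columns: CRITERIA
    n_runs: int
    n_excluded: pd.Series  # per-candidate number of runs it was excluded
    ties: int = 0

    def to_frame(self) -> pd.DataFrame:
        out = self.counts.copy()
        out["n_excluded"] = self.n_excluded
        return out

    def selection_rate(self, candidate: str, criterion: str) -> float:
        """Selection frequency as a percentage of valid runs."""
        return 100.0 * self.counts.loc[candidate, criterion] / self.n_runs


def run_monte_carlo(scenario: ScenarioSpec, progress: bool = False) -> FrequencyTable:
    """Repeat :func:`run_once` and tabulate selection frequencies.

    Child run seeds are ``master_seed + run_index`` so the full table is
    reproducible from the scenario alone.
    """
    if scenario.n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    labels = [pair_label(p, q) for p, q in scenario.candidate_pairs]
    counts = pd.DataFrame(0, index=labels, columns=list(CRITERIA))
    excluded = pd.Series(0, index=labels)
    ties = 0
    valid_runs = 0
    for i in range(scenario.n_runs):
        reports = run_once(scenario, scenario.master_seed + i)
        if all(rep.excluded for rep in reports):
            continue
        valid_runs += 1
        for rep in reports:
            if rep.excluded:
                excluded[rep.candidate] += 1
        for crit in CRITERIA:
            winner, tied = select_winner(reports, crit)
            counts.loc[winner, crit] += 1
            ties += int(tied)
        if progress:  # pragma: no cover - cosmetic
            print(f"run {i + 1}/{scenario.n_runs}", end="\r")
    if valid_runs < scenario.n_runs:
        warnings.warn(
            f"{scenario.n_runs - valid_runs} runs had no valid candidate and "
            "were dropped from the denominators",
            stacklevel=2,
        )
    return FrequencyTable(counts=counts, n_runs=valid_runs, n_excluded=excluded, ties=ties)
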