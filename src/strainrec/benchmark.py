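"""Retrospective validation against curated strain-pair background effects.

Each curated record names two strains and which one was experimentally
observed to be more vulnerable for a phenotype.  A pair is scored only when
both strains' recommendation FPRs pass a threshold (default 0.05); the
strain with the higher vulnerability score is predicted more vulnerable, and
exact score ties abstain.  Per-disease sensitivity is correct / (correct +
incorrect); abstentions never enter denominators.  Disease-level summaries
report the macro-average (unweighted mean across diseases) with a Normal
95% confidence interval, the fraction of diseases above 50% sensitivity,
and counts in fixed categories: high >= 90%, moderate 70-90%, low
50-70%, poor <= 50%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import (EmptySummaryError, UndefinedSensitivityError,
                     UnknownSampleError)

log = logging.getLogger(__name__)

DEFAULT_FPR_MAX = 0.05
DEFAULT_SWEEP = (0.05, 0.10, 0.15, 0.20)
Z_95 = 1.959963984540054  # two-sided Normal 95% quantile


@dataclass(frozen=True)
class ValidationRecord:
    """One curated strain-pair observation from the literature."""

    study_id: str
    strain_a: str
    strain_b: str
    observed_vulnerable: str
    phenotype_term: str
    disease_ids: tuple = ()
    rare_flags: tuple = ()

    def __post_init__(self) -> None:
        if self.strain_a == self.strain_b:
            raise ValueError("strain_a and strain_b must differ")
        if self.observed_vulnerable not in (self.strain_a, self.strain_b):
            raise ValueError("observed_vulnerable must be one of the two strains")


@dataclass(frozen=True)
class ComparisonOutcome:
    """A scored (or abstained) strain-pair prediction.

    ``status`` is 1 (correct), 0 (incorrect) or None (abstained).
    """

    record: ValidationRecord
    gene_set_id: str = ""
    status: int | None = None


@dataclass(frozen=True)
class DiseaseSummary:
    disease_id: str
    sensitivity: float
    n_cases: int
    category: str


@dataclass
class BenchmarkSummary:
    mean_sensitivity: float
    ci_low: float | None
    ci_high: float | None
    frac_above_half: float
    category_counts: dict
    n_diseases: int


# ---------------------------------------------------------------------------
# pair prediction and scoring


def _recs_lookup(recs: pd.DataFrame) -> pd.DataFrame:
    table = recs.set_index("strain_id")
    return table


def predict_pair(recs: pd.DataFrame, a: str, b: str,
                 fpr_max: float = DEFAULT_FPR_MAX) -> str | None:
    """Predicted more-vulnerable strain of a pair, or None to abstain.

    Abstains when either strain's FPR exceeds ``fpr_max`` or the two scores
    are exactly tied.
    """
    table = _recs_lookup(recs)
    for s in (a, b):
        if s not in table.index:
            raise UnknownSampleError(s)
    ra, rb = table.loc[a], table.loc[b]
    if ra["fpr"] > fpr_max or rb["fpr"] > fpr_max:
        return None
    if ra["score"] == rb["score"]:
        return None
    return a if ra["score"] > rb["score"] else b


def score_comparison(prediction: str | None, record: ValidationRecord,
                     gene_set_id: str = "") -> ComparisonOutcome:
    """Correct (1) iff the prediction matches the observed vulnerable strain."""
    if prediction is None:
        return ComparisonOutcome(record, gene_set_id, None)
    return ComparisonOutcome(record, gene_set_id,
                             int(prediction == record.observed_vulnerable))


def score_records(recs: pd.DataFrame, records, fpr_max: float = DEFAULT_FPR_MAX,
                  gene_set_id: str = "",
                  drop_insufficient: bool = False) -> list[ComparisonOutcome]:
    """Score every record's pair against one recommendation table.

    With ``drop_insufficient`` a whole (gene set, study) block abstains when
    the top-ranked strain among that study's strains fails the FPR
    threshold (the gene set is deemed insufficient for that study).
    """
    records = list(records)
    insufficient_studies: set = set()
    if drop_insufficient:
        table = _recs_lookup(recs)
        by_study: dict = {}
        for r in records:
            by_study.setdefault(r.study_id, set()).update((r.strain_a, r.strain_b))
        for study, strains in by_study.items():
            sub = table.loc[sorted(strains)]  # sorted: deterministic idxmax ties
            top = sub.loc[sub["score"].idxmax()]
            if top["fpr"] > fpr_max:
                insufficient_studies.add(study)
        if insufficient_studies:
            log.info("gene set %r insufficient for %d studies", gene_set_id,
                     len(insufficient_studies))
    out = []
    for r in records:
        if r.study_id in insufficient_studies:
            out.append(ComparisonOutcome(r, gene_set_id, None))
            continue
        pred = predict_pair(recs, r.strain_a, r.strain_b, fpr_max)
        out.append(score_comparison(pred, r, gene_set_id))
    return out


# ---------------------------------------------------------------------------
# disease-level aggregation


def sensitivity_category(s: float) -> str:
    """Category bands: >=0.90 high, [0.70,0.90) moderate,
    (0.50,0.70) low, <=0.50 poor."""
    if s >= 0.90:
        return "high"
    if s >= 0.70:
        return "moderate"
    if s > 0.50:
        return "low"
    return "poor"


def outcomes_by_disease(outcomes) -> dict:
    """Fan outcomes out over each record's mapped diseases.

    A record mapped to two diseases contributes to both denominators;
    records with no mapped disease are excluded (logged).
    """
    grouped: dict = {}
    unmapped = 0
    for o in outcomes:
        if not o.record.disease_ids:
            unmapped += 1
            continue
        for d in o.record.disease_ids:
            grouped.setdefault(d, []).append(o)
    if unmapped:
        log.info("%d outcomes had no mapped disease and were excluded", unmapped)
    return grouped


def disease_sensitivity(outcomes, disease_id: str = "") -> DiseaseSummary:
    """Sensitivity = correct / (correct + incorrect) for one disease."""
    statuses = [o.status for o in outcomes if o.status is not None]
    if not statuses:
        raise UndefinedSensitivityError(
            f"disease {disease_id!r} has no scored comparisons")
    s = float(np.mean(statuses))
    return DiseaseSummary(disease_id, s, len(statuses), sensitivity_category(s))


def summarize(summaries) -> BenchmarkSummary:
    """Macro-average sensitivity with a Normal 95% CI and category counts."""
    summaries = list(summaries)
    if not summaries:
        raise EmptySummaryError("no disease summaries to aggregate")
    sens = np.array([d.sensitivity for d in summaries], dtype=float)
    mean = float(sens.mean())
    if len(sens) >= 2:
        half = Z_95 * float(sens.std(ddof=1)) / np.sqrt(len(sens))
        ci_low, ci_high = mean - half, mean + half
    else:
        ci_low = ci_high = None
    counts = {c: 0 for c in ("high", "moderate", "low", "poor")}
    for d in summaries:
        counts[d.category] += 1
    return BenchmarkSummary(mean, ci_low, ci_high,
                            float((sens > 0.5).mean()), counts, len(sens))


def evaluate(recs: pd.DataFrame, records, fpr_max: float = DEFAULT_FPR_MAX,
             gene_set_id: str = "", drop_insufficient: bool = False
             ) -> tuple[list[DiseaseSummary], BenchmarkSummary]:
    """Score records, group by disease, and aggregate.

    Diseases whose comparisons all abstained are excluded with a log line.
    """
    outcomes = score_records(recs, records, fpr_max, gene_set_id,
                             drop_insufficient)
    return aggregate_outcomes(outcomes)


def aggregate_outcomes(outcomes) -> tuple[list[DiseaseSummary], BenchmarkSummary]:
    grouped = outcomes_by_disease(outcomes)
    summaries, excluded = [], 0
    for disease_id in grouped:
        try:
            summaries.append(disease_sensitivity(grouped[disease_id], disease_id))
        except UndefinedSensitivityError:
            excluded += 1
    if excluded:
        log.info("%d diseases had only abstained comparisons and were excluded",
                 excluded)
    return summaries, summarize(summaries)


def sweep_fpr_thresholds(recs: pd.DataFrame, records,
                         thresholds=DEFAULT_SWEEP,
                         drop_insufficient: bool = False) -> pd.DataFrame:
    """Recompute abstentions, sensitivities and disease coverage per threshold.

    Coverage (diseases with at least one scored comparison) is
    non-decreasing in the threshold.
    """
    rows = []
    for t in thresholds:
        if not 0 < t <= 1:
            raise ValueError("thresholds must lie in (0, 1]")
        outcomes = score_records(recs, records, fpr_max=t,
                                 drop_insufficient=drop_insufficient)
        scored = sum(o.status is not None for o in outcomes)
        grouped = outcomes_by_disease(outcomes)
        summaries = []
        for disease_id in grouped:
            try:
                summaries.append(disease_sensitivity(grouped[disease_id], disease_id))
            except UndefinedSensitivityError:
                pass
        if summaries:
            summary = summarize(summaries)
            mean, lo, hi = (summary.mean_sensitivity, summary.ci_low,
                            summary.ci_high)
        else:
            mean = lo = hi = np.nan
        rows.append({"threshold": t, "mean_sensitivity": mean,
                     "ci_low": lo, "ci_high": hi,
                     "coverage": len(summaries), "n_scored": scored,
                     "n_abstained": len(outcomes) - scored})
    return pd.DataFrame(rows)


def deduplicate_diseases(outcomes) -> list:
    """Representative diseases with unique comparison sets.

    Comparisons are keyed by (gene set, study, phenotype term, strain pair);
    the first-listed disease of each identical comparison set is retained.
    """
    keysets: dict = {}
    order: list = []
    for o in outcomes:
        r = o.record
        key = (o.gene_set_id, r.study_id, r.phenotype_term, r.strain_a, r.strain_b)
        for d in r.disease_ids:
            if d not in keysets:
                keysets[d] = set()
                order.append(d)
            keysets[d].add(key)
    seen: dict = {}
    reps = []
    for d in order:
        fs = frozenset(keysets[d])
        if fs not in seen:
            seen[fs] = d
            reps.append(d)
    return reps


def join_disease_labels(records, mapping: pd.DataFrame,
                        rare_ids=frozenset()) -> list:
    """Annotate records with mapped diseases and rare-disease flags.

    ``mapping`` has columns ``phenotype_term, disease_id``; a phenotype term
    mapped to several diseases fans out to all of them.  Unmapped terms
    leave the record without diseases (logged; such records drop out of
    disease-level summaries).
    """
    rare_ids = set(rare_ids)
    by_term: dict = {}
    for row in mapping.itertuples(index=False):
        by_term.setdefault(str(row.phenotype_term), []).append(str(row.disease_id))
    out, unmapped = [], 0
    for r in records:
        diseases = by_term.get(r.phenotype_term, [])
        if not diseases:
            unmapped += 1
        out.append(replace(r, disease_ids=tuple(diseases),
                           rare_flags=tuple(d in rare_ids for d in diseases)))
    if unmapped:
        log.info("%d records had unmapped phenotype terms", unmapped)
    return out


# ---------------------------------------------------------------------------
# I/O


def read_validation_records(path) -> list:
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["study_id", "strain_a", "strain_b", "observed_vulnerable",
                "phenotype_term"]
    if list(df.columns[:5]) != expected:
        raise ValueError(f"validation records must have columns {expected}")
    return [ValidationRecord(r.study_id, r.strain_a, r.strain_b,
                             r.observed_vulnerable, r.phenotype_term)
            for r in df.itertuples(index=False)]


def write_validation_records(records, path) -> None:
    rows = [{"study_id": r.study_id, "strain_a": r.strain_a,
             "strain_b": r.strain_b,
             "observed_vulnerable": r.observed_vulnerable,
             "phenotype_term": r.phenotype_term} for r in records]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_phenotype_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["phenotype_term", "disease_id"]:
        raise ValueError("mapping must have columns phenotype_term, disease_id")
    return df


def read_rare_ids(path) -> set:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}
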