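"""Phenotype coding: questionnaire items and flags -> binary trait status.

The speech-and/or-language-difficulties (SaLD) phenotype is coded from a
parent-reported late-talking item on a 0/1/2 scale: any positive response
(1 = "yes, to a certain degree", 2 = "yes") counts as affected.  Exclusion
flags take precedence over the questionnaire response, so an excluded
individual is never counted affected:

* Model 1 excludes hearing impairment, acquired language disorder and
  chromosomal abnormalities (conditions that could cause differential
  misclassification of the phenotype).
* Model 2 (sensitivity analysis) additionally excludes autism and
  intellectual disability.  The autism flag is a single merged variable:
  register-diagnosed autism or a parental "autism" answer to the follow-up
  cause question.

Individuals with no questionnaire response and no exclusion flag are coded
missing-phenotype, distinct from unaffected, and dropped from denominators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import CAUSE_CATEGORIES, NO_RESPONSE, TwinPairRecord

__all__ = [
    "SaldStatus",
    "CauseTally",
    "AnalysisSet",
    "code_sald",
    "code_cohort",
    "pair_analysis_set",
    "tabulate_causes",
]

# exclusion precedence: misclassification-risk flags first, then (model 2)
# neurodevelopmental comorbidities
_MODEL1_EXCLUSIONS = (("hearing", "hearing"), ("acquired", "acquired"), ("chrom", "chromosomal"))
_MODEL2_EXCLUSIONS = (("autism", "autism"), ("id", "intellectual_disability"))

STATUS_AFFECTED = "affected"
STATUS_UNAFFECTED = "unaffected"
STATUS_EXCLUDED = "excluded"
STATUS_MISSING = "missing"


@dataclass
class SaldStatus:
    """Coded phenotype status for one individual."""

    status: str
    exclusion_reason: str | None = None

    def __post_init__(self) -> None:
        if (self.status == STATUS_EXCLUDED) != (self.exclusion_reason is not None):
            raise ValueError("exclusion_reason must be present iff status is excluded")


def _check_model(model: int) -> None:
    if model not in (1, 2):
        raise ValueError(f"model must be 1 or 2, got {model!r}")


def code_sald(record: TwinPairRecord, twin_index: int, model: int = 1) -> SaldStatus:
    """Code one twin's phenotype status under exclusion model 1 or 2."""
    _check_model(model)
    if twin_index not in (1, 2):
        raise ValueError(f"twin_index must be 1 or 2, got {twin_index!r}")
    sfx = str(twin_index)
    rules = _MODEL1_EXCLUSIONS + (_MODEL2_EXCLUSIONS if model == 2 else ())
    for col, reason in rules:
        if getattr(record, f"{col}{sfx}"):
            return SaldStatus(STATUS_EXCLUDED, reason)
    atac = getattr(record, f"atac{sfx}")
    if atac is None or (isinstance(atac, float) and np.isnan(atac)):
        return SaldStatus(STATUS_MISSING)
    return SaldStatus(STATUS_AFFECTED if atac in (1, 2) else STATUS_UNAFFECTED)


def code_cohort(frame: pd.DataFrame, model: int = 1) -> pd.DataFrame:
    """Vectorized coding of a cohort table.

    Adds, for each twin slot i: ``sald{i}`` (affected/unaffected/excluded/
    missing) and ``reason{i}`` (exclusion reason or empty).  The row-level
    :func:`code_sald` defines the semantics; this is the same logic applied
    columnwise.
    """
    _check_model(model)
    out = frame.copy()
    rules = _MODEL1_EXCLUSIONS + (_MODEL2_EXCLUSIONS if model == 2 else ())
    for i in (1, 2):
        atac = pd.to_numeric(out[f"atac{i}"], errors="coerce")
        status = np.where(atac.isna(), STATUS_MISSING,
                          np.where(atac.isin((1, 2)), STATUS_AFFECTED, STATUS_UNAFFECTED))
        reason = np.full(len(out), "", dtype=object)
        excluded = np.zeros(len(out), dtype=bool)
        for col, label in rules:
            flag = out[f"{col}{i}"].astype(bool).to_numpy() & ~excluded
            reason[flag] = label
            excluded |= flag
        status = np.where(excluded, STATUS_EXCLUDED, status)
        out[f"sald{i}"] = status
        out[f"reason{i}"] = reason
    return out


@dataclass
class AnalysisSet:
    """Individuals for prevalence and complete pairs for twin analyses."""

    individuals: pd.DataFrame  # columns: pair_id, zygosity_group, sex, affected
    pairs: pd.DataFrame        # coded rows where both twins are analysable
    flow: dict                 # counts removed at each step

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def pair_analysis_set(frame: pd.DataFrame, model: int = 1) -> AnalysisSet:
    """Split a cohort into prevalence individuals and twin-analysis pairs.

    Prevalence denominators keep every non-excluded individual with a coded
    phenotype; correlation / model-fit tables keep only pairs where both
    twins are non-excluded with phenotypes.  A flow of removed counts
    (excluded by reason, missing, incomplete pairs) is recorded.
    """
    coded = code_cohort(frame, model=model)
    if coded.empty:
        raise ValueError("empty cohort: nothing to analyse")

    people = []
    for i in (1, 2):
        part = coded[["pair_id", "zygosity_group", f"sex{i}", f"sald{i}", f"reason{i}"]].copy()
        part.columns = ["pair_id", "zygosity_group", "sex", "sald", "reason"]
        part["twin"] = i
        people.append(part)
    people = pd.concat(people, ignore_index=True)

    excluded = people[people["sald"] == STATUS_EXCLUDED]
    missing = people[people["sald"] == STATUS_MISSING]
    keep = people[people["sald"].isin((STATUS_AFFECTED, STATUS_UNAFFECTED))].copy()
    keep["affected"] = keep["sald"] == STATUS_AFFECTED
    individuals = keep[["pair_id", "twin", "zygosity_group", "sex", "affected"]].reset_index(drop=True)
    if individuals.empty:
        raise ValueError("all individuals excluded or missing: empty analysis set")

    ok1 = coded["sald1"].isin((STATUS_AFFECTED, STATUS_UNAFFECTED))
    ok2 = coded["sald2"].isin((STATUS_AFFECTED, STATUS_UNAFFECTED))
    pairs = coded[ok1 & ok2].copy()
    pairs["aff1"] = pairs["sald1"] == STATUS_AFFECTED
    pairs["aff2"] = pairs["sald2"] == STATUS_AFFECTED

    flow = {
        "model": model,
        "n_pairs_input": int(len(coded)),
        "n_individuals_input": int(2 * len(coded)),
        "excluded_individuals": int(len(excluded)),
        "excluded_by_reason": excluded["reason"].value_counts().to_dict(),
        "missing_phenotype_individuals": int(len(missing)),
        "individuals_for_prevalence": int(len(individuals)),
        "pairs_removed_incomplete": int(len(coded) - len(pairs)),
        "pairs_for_twin_analyses": int(len(pairs)),
    }
    return AnalysisSet(individuals=individuals, pairs=pairs.reset_index(drop=True), flow=flow)


@dataclass
class CauseTally:
    """Tally of parent-reported causes behind the phenotype.

    ``n_indicated`` counts individuals whose parents indicated a known cause
    or diagnosis; ``n_responded`` those who also answered the open-ended
    follow-up (the remainder carry the ``no_response`` label).  Percentages
    are computed among responders.
    """

    counts: pd.DataFrame       # rows: categories; columns: total, male, female
    n_indicated: int
    n_responded: int
    percentages: pd.DataFrame | None = None
    responded_share: float | None = None
    empty: bool = False

    def to_frame(self) -> pd.DataFrame:
        out = self.counts.copy()
        if self.percentages is not None:
            for col in out.columns:
                out[f"{col}_pct"] = self.percentages[col]
        return out


def tabulate_causes(frame: pd.DataFrame) -> CauseTally:
    """Tabulate follow-up cause labels overall and by sex.

    Unknown labels raise a ``ValueError`` naming the offending values; an
    empty input yields zero counts with percentages flagged undefined.
    """
    records = []
    for i in (1, 2):
        sub = frame[["pair_id", f"sex{i}", f"cause{i}"]].copy()
        sub.columns = ["pair_id", "sex", "cause"]
        records.append(sub)
    people = pd.concat(records, ignore_index=True)
    people["cause"] = people["cause"].fillna("").astype(str)
    people = people[people["cause"] != ""]

    allowed = set(CAUSE_CATEGORIES) | {NO_RESPONSE}
    bad = sorted(set(people["cause"]) - allowed)
    if bad:
        raise ValueError(f"unknown cause categories: {bad}")

    n_indicated = int(len(people))
    responders = people[people["cause"] != NO_RESPONSE]
    n_responded = int(len(responders))

    counts = pd.DataFrame(0, index=list(CAUSE_CATEGORIES), columns=["total", "male", "female"])
    for cat in CAUSE_CATEGORIES:
        sub = responders[responders["cause"] == cat]
        counts.loc[cat, "total"] = len(sub)
        counts.loc[cat, "male"] = int((sub["sex"] == "male").sum())
        counts.loc[cat, "female"] = int((sub["sex"] == "female").sum())

    if n_responded == 0:
        return CauseTally(counts=counts, n_indicated=n_indicated, n_responded=0, empty=True)

    pct = counts.copy().astype(float)
    pct["total"] = 100.0 * counts["total"] / n_responded
    for sex in ("male", "female"):
        sex_total = int((responders["sex"] == sex).sum())
        pct[sex] = 100.0 * counts[sex] / sex_total if sex_total else np.nan
    share = 100.0 * n_responded / n_indicated if n_indicated else None
    return CauseTally(counts=counts, n_indicated=n_indicated, n_responded=n_responded,
                      percentages=pct, responded_share=share)
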