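"""Synthetic twin-cohort generator.

Generates pair-level twin data with the statistical structure the liability
analysis assumes: five zygosity-by-sex groups (MZM, MZF, DZM, DZF, DZOS),
bivariate standard-normal liabilities whose correlation is a^2 + c^2 within
MZ pairs and 0.5 a^2 + c^2 within DZ pairs (same-sex and opposite-sex
alike), and sex-specific probit thresholds set from the configured
prevalences.  Affected twins answer the late-talking questionnaire item with
1 ("yes, to a certain degree") or 2 ("yes"); unaffected twins answer 0.
Follow-up cause labels and register-style comorbidity flags are optional
overlays drawn at configured rates.

The default configuration reproduces the structure of a large Swedish
register-based child twin sample: group sizes 2465 / 2676 / 3122 / 2739 /
5772 pairs, male prevalence 10.61%, female prevalence 5.03%, and generating
components (a^2, c^2, e^2) = (0.75, 0.22, 0.03).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GROUPS",
    "GROUP_SEXES",
    "CAUSE_CATEGORIES",
    "NO_RESPONSE",
    "COMORBIDITIES",
    "SimulationConfig",
    "TwinPairRecord",
    "simulate_cohort",
    "write_cohort_csv",
    "read_cohort_csv",
]

GROUPS = ("MZM", "MZF", "DZM", "DZF", "DZOS")
GROUP_SEXES = {
    "MZM": ("male", "male"),
    "MZF": ("female", "female"),
    "DZM": ("male", "male"),
    "DZF": ("female", "female"),
    "DZOS": ("male", "female"),
}

# controlled vocabulary for the parental follow-up cause question
CAUSE_CATEGORIES = (
    "DLD",
    "LD_due_to_ID_or_autism",
    "hearing",
    "acquired_medical",
    "SSD",
    "not_specified",
    "DLD_and_or_SSD",
)
#: cause was indicated but the open-ended follow-up was left blank
NO_RESPONSE = "no_response"

COMORBIDITIES = ("autism", "intellectual_disability", "hearing", "acquired", "chromosomal")
_FLAG_COLS = {"autism": "autism", "intellectual_disability": "id",
              "hearing": "hearing", "acquired": "acquired", "chromosomal": "chrom"}

#: study-sized cohort: pairs per zygosity-by-sex group
DEFAULT_PAIRS = {"MZM": 2465, "MZF": 2676, "DZM": 3122, "DZF": 2739, "DZOS": 5772}

COHORT_COLUMNS = [
    "pair_id", "zygosity_group", "sex1", "sex2", "atac1", "atac2",
    "cause1", "cause2", "autism1", "autism2", "id1", "id2",
    "hearing1", "hearing2", "acquired1", "acquired2", "chrom1", "chrom2",
]


@dataclass
class SimulationConfig:
    """Generating conditions for a synthetic twin cohort.

    Parameters
    ----------
    pairs_per_group
        Pair counts per zygosity-by-sex group label.
    a2, c2, e2
        Generating proportions of liability variance (must sum to 1).
    prevalence_male, prevalence_female
        Sex-specific trait prevalences in (0, 1); they set the probit
        thresholds on the liability scale.
    severe_share
        Probability that an affected twin's questionnaire response is 2
        ("yes") rather than 1 ("yes, to a certain degree"); the analysis
        collapses the two, so this split is analysis-irrelevant.
    cause_distribution
        Optional mapping of cause-category label (or ``no_response``) to
        probability; drawn independently for each affected twin.
    comorbidity_rates
        Optional mapping of comorbidity name to per-individual probability.
    comorbidity_enrichment
        Relative risk of autism / intellectual disability given affected
        (flags are otherwise independent of liability).
    seed
        Root seed; each group consumes its own documented random stream, so
        adding groups does not perturb existing draws.
    """

    pairs_per_group: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_PAIRS))
    a2: float = 0.75
    c2: float = 0.22
    e2: float = 0.03
    prevalence_male: float = 0.1061
    prevalence_female: float = 0.0503
    severe_share: float = 0.5
    cause_distribution: Mapping[str, float] | None = None
    comorbidity_rates: Mapping[str, float] | None = None
    comorbidity_enrichment: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.a2 + self.c2 + self.e2 - 1.0) > 1e-9:
            raise ValueError(
                f"a2 + c2 + e2 must equal 1, got {self.a2 + self.c2 + self.e2!r}"
            )
        for name in ("a2", "c2", "e2", "severe_share"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("prevalence_male", "prevalence_female"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name}={v} outside (0, 1)")
        for label, n in self.pairs_per_group.items():
            if label not in GROUPS:
                raise ValueError(f"unknown zygosity group {label!r}")
            if n < 0 or int(n) != n:
                raise ValueError(f"pair count for {label} must be a non-negative integer")
        if self.cause_distribution is not None:
            allowed = set(CAUSE_CATEGORIES) | {NO_RESPONSE}
            bad = set(self.cause_distribution) - allowed
            if bad:
                raise ValueError(f"unknown cause categories: {sorted(bad)}")
            tot = sum(self.cause_distribution.values())
            if tot > 1.0 + 1e-9 or any(v < 0 for v in self.cause_distribution.values()):
                raise ValueError("cause probabilities must be non-negative and sum to <= 1")
        if self.comorbidity_rates is not None:
            bad = set(self.comorbidity_rates) - set(COMORBIDITIES)
            if bad:
                raise ValueError(f"unknown comorbidities: {sorted(bad)}")
            if any(not 0 <= v <= 1 for v in self.comorbidity_rates.values()):
                raise ValueError("comorbidity rates must lie in [0, 1]")
        if self.comorbidity_enrichment < 0:
            raise ValueError("comorbidity_enrichment must be non-negative")

    @property
    def liability_correlations(self) -> dict[str, float]:
        r_mz = self.a2 + self.c2
        r_dz = 0.5 * self.a2 + self.c2
        return {g: (r_mz if g.startswith("MZ") else r_dz) for g in GROUPS}

    def threshold(self, sex: str) -> float:
        p = self.prevalence_male if sex == "male" else self.prevalence_female
        return float(stats.norm.isf(p))

    def to_json(self, path: str | Path) -> None:
        data = asdict(self)
        data["pairs_per_group"] = dict(self.pairs_per_group)
        Path(path).write_text(json.dumps(data, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class TwinPairRecord:
    """One twin pair; the row-level view of the cohort table."""

    pair_id: str
    zygosity_group: str
    sex1: str
    sex2: str
    atac1: int | None
    atac2: int | None
    cause1: str = ""
    cause2: str = ""
    autism1: bool = False
    autism2: bool = False
    id1: bool = False
    id2: bool = False
    hearing1: bool = False
    hearing2: bool = False
    acquired1: bool = False
    acquired2: bool = False
    chrom1: bool = False
    chrom2: bool = False

    def __post_init__(self) -> None:
        if self.zygosity_group not in GROUPS:
            raise ValueError(f"unknown zygosity group {self.zygosity_group!r}")
        expect = GROUP_SEXES[self.zygosity_group]
        if (self.sex1, self.sex2) != expect:
            raise ValueError(
                f"group {self.zygosity_group} requires sexes {expect}, "
                f"got {(self.sex1, self.sex2)}"
            )
        for a in (self.atac1, self.atac2):
            if a is not None and a not in (0, 1, 2):
                raise ValueError(f"questionnaire response must be 0, 1 or 2, got {a}")


def _group_rng(seed: int, group: str, purpose: int) -> np.random.Generator:
    """Deterministic stream per (group, purpose); streams are independent."""
    gi = GROUPS.index(group)
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed, spawn_key=(gi, purpose))))


def simulate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Draw a twin cohort under the liability-threshold model.

    Returns one row per pair with the documented column schema.  Liabilities
    are bivariate standard normal with the group's implied correlation; a
    twin is affected iff its liability exceeds the sex-specific probit
    threshold.  Reproducible: the same config (including seed) yields an
    identical table.
    """
    frames = []
    for group in GROUPS:
        n = int(config.pairs_per_group.get(group, 0))
        if n == 0:
            continue
        sex1, sex2 = GROUP_SEXES[group]
        r = config.liability_correlations[group]
        rng_liab = _group_rng(config.seed, group, 0)
        z = rng_liab.standard_normal((2, n))
        liab1 = z[0]
        liab2 = r * z[0] + np.sqrt(1.0 - r * r) * z[1]
        aff1 = liab1 > config.threshold(sex1)
        aff2 = liab2 > config.threshold(sex2)

        rng_resp = _group_rng(config.seed, group, 1)
        severe = rng_resp.random((2, n)) < config.severe_share
        atac1 = np.where(aff1, np.where(severe[0], 2, 1), 0)
        atac2 = np.where(aff2, np.where(severe[1], 2, 1), 0)

        cause1 = np.full(n, "", dtype=object)
        cause2 = np.full(n, "", dtype=object)
        if config.cause_distribution:
            labels = list(config.cause_distribution)
            probs = np.array([config.cause_distribution[l] for l in labels])
            labels.append("")  # no cause indicated
            probs = np.append(probs, max(0.0, 1.0 - probs.sum()))
            probs = probs / probs.sum()
            rng_cause = _group_rng(config.seed, group, 2)
            draws = rng_cause.choice(len(labels), size=(2, n), p=probs)
            lab = np.array(labels, dtype=object)
            cause1 = np.where(aff1, lab[draws[0]], "")
            cause2 = np.where(aff2, lab[draws[1]], "")

        flags = {}
        for name in COMORBIDITIES:
            col = _FLAG_COLS[name]
            rate = (config.comorbidity_rates or {}).get(name, 0.0)
            if rate == 0.0:
                flags[f"{col}1"] = np.zeros(n, dtype=int)
                flags[f"{col}2"] = np.zeros(n, dtype=int)
                continue
            rng_flag = _group_rng(config.seed, group, 3 + COMORBIDITIES.index(name))
            u = rng_flag.random((2, n))
            if name in ("autism", "intellectual_disability") and config.comorbidity_enrichment != 1.0:
                p_aff = min(1.0, rate * config.comorbidity_enrichment)
                flags[f"{col}1"] = (u[0] < np.where(aff1, p_aff, rate)).astype(int)
                flags[f"{col}2"] = (u[1] < np.where(aff2, p_aff, rate)).astype(int)
            else:
                flags[f"{col}1"] = (u[0] < rate).astype(int)
                flags[f"{col}2"] = (u[1] < rate).astype(int)

        frames.append(pd.DataFrame({
            "pair_id": [f"{group}-{i:06d}" for i in range(n)],
            "zygosity_group": group,
            "sex1": sex1,
            "sex2": sex2,
            "atac1": atac1.astype(int),
            "atac2": atac2.astype(int),
            "cause1": cause1,
            "cause2": cause2,
            **flags,
        }))
    if not frames:
        raise ValueError("configuration generates an empty cohort")
    out = pd.concat(frames, ignore_index=True)
    return out[COHORT_COLUMNS]


def write_cohort_csv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype={"cause1": str, "cause2": str}, keep_default_na=False)
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"cohort CSV is missing columns: {missing}")
    return frame[COHORT_COLUMNS]
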