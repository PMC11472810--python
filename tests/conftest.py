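import numpy as np
import pytest
from hypothesis import settings

from twinace import (
    SimulationConfig,
    build_group_tables,
    fit_variance_model,
    pair_analysis_set,
    profile_ci,
    simulate_cohort,
)
from twinace.liability import GroupTable, bvn_upper_orthant

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

#: study-sized generating conditions: group sizes, components and prevalences
#: of the emulated register cohort
STUDY_CONFIG = dict(
    pairs_per_group={"MZM": 2465, "MZF": 2676, "DZM": 3122, "DZF": 2739, "DZOS": 5772},
    a2=0.75, c2=0.22, e2=0.03,
    prevalence_male=0.1061, prevalence_female=0.0503,
)

#: printed 95% CIs the recovery experiments are judged against
PRINTED_CI = {"a2": (0.67, 0.83), "c2": (0.14, 0.30), "e2": (0.02, 0.04)}


def exact_group_tables(a2, c2, tau_m, tau_f=None, n=100_000):
    """Probability-exact MZ/DZ concordance tables (no sampling noise)."""
    if tau_f is None:
        tau_f = tau_m
    tables = {}
    specs = {"MZM": (tau_m, tau_m, a2 + c2), "MZF": (tau_f, tau_f, a2 + c2),
             "DZM": (tau_m, tau_m, 0.5 * a2 + c2), "DZF": (tau_f, tau_f, 0.5 * a2 + c2),
             "DZOS": (tau_m, tau_f, 0.5 * a2 + c2)}
    from scipy.special import ndtr
    for label, (t1, t2, r) in specs.items():
        p11 = bvn_upper_orthant(t1, t2, r)
        p10 = ndtr(-t1) - p11
        p01 = ndtr(-t2) - p11
        p00 = 1.0 - p11 - p10 - p01
        tables[label] = GroupTable(label, n * p00, n * p01, n * p10, n * p11,
                                   symmetrized=(label != "DZOS"))
    return tables


@pytest.fixture(scope="session")
def study_cohort():
    """One simulated cohort at the study conditions (fixed seed)."""
    return simulate_cohort(SimulationConfig(**STUDY_CONFIG, seed=20260923))


@pytest.fixture(scope="session")
def study_analysis(study_cohort):
    return pair_analysis_set(study_cohort, model=1)


@pytest.fixture(scope="session")
def recovery_replicates():
    """100 simulate-and-fit replicates at the study conditions.

    Each replicate records the fitted ACE components and the profile CI of
    each component; consumed by the bias, coverage and acceptance checks.
    """
    reps = []
    for i in range(100):
        cfg = SimulationConfig(**STUDY_CONFIG, seed=2026_000 + i)
        analysis = pair_analysis_set(simulate_cohort(cfg), model=1)
        comp, fit = fit_variance_model(build_group_tables(analysis.pairs), model="ACE")
        cis = {name: profile_ci(fit, name)[:2] for name in ("a2", "c2", "e2")}
        reps.append({"a2": comp.a2, "c2": comp.c2, "e2": comp.e2,
                     "ci": cis, "converged": fit.converged})
    return reps
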