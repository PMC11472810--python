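"""Liability-threshold twin models for binary phenotypes.

The classical twin design decomposes variance in a latent, standard-normal
liability into additive-genetic (A), shared-environment (C) and non-shared
environment (E) components.  A binary trait is observed when liability
exceeds a threshold tau, so the population prevalence p fixes
tau = Phi^-1(1 - p).  Twin resemblance enters through the correlation of the
pair's bivariate-normal liabilities:

    r_MZ  = a^2 + c^2
    r_DZ  = 0.5 * a^2 + c^2          (same-sex DZ and opposite-sex DZ alike)

Each zygosity group contributes a 2x2 concordance table whose multinomial
cell probabilities are bivariate-normal orthant probabilities; all models
here are fitted by maximizing that joint multinomial likelihood, and nested
models are compared by likelihood-ratio chi-square tests on -2 log L.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import ndtr, owens_t

__all__ = [
    "GroupTable",
    "VarianceComponents",
    "ModelFit",
    "LRTResult",
    "TetrachoricResult",
    "bvn_cdf",
    "bvn_upper_orthant",
    "implied_correlations",
    "tetrachoric_ml",
    "fit_saturated",
    "fit_variance_model",
    "likelihood_ratio_test",
    "profile_ci",
    "fit_model_ladder",
]

# zygosity-by-sex groups and the sex of (twin 1, twin 2); DZOS is ordered
# male-first by convention, same-sex groups are unordered
GROUP_SEXES = {
    "MZM": ("male", "male"),
    "MZF": ("female", "female"),
    "DZM": ("male", "male"),
    "DZF": ("female", "female"),
    "DZOS": ("male", "female"),
}

_TINY = 1e-300
_LRT_CLIP = 1e-6


# ---------------------------------------------------------------------------
# bivariate-normal kernel
# ---------------------------------------------------------------------------

def bvn_cdf(h: float, k: float, r: float) -> float:
    """P(X <= h, Y <= k) for a standard bivariate normal with correlation r.

    Uses Owen's T function, which is accurate to close to machine precision;
    the degenerate cases |r| = 1 and h = k = 0 have closed forms.
    """
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"correlation must lie in [-1, 1], got {r}")
    if r >= 1.0 - 1e-14:
        return float(ndtr(min(h, k)))
    if r <= -1.0 + 1e-14:
        return float(max(0.0, ndtr(h) + ndtr(k) - 1.0))
    eps = 1e-12
    if abs(h) < eps and abs(k) < eps:
        return 0.25 + math.asin(r) / (2.0 * math.pi)
    # nudge an exactly-zero threshold off zero; the induced error is O(1e-12)
    if abs(h) < eps:
        h = eps
    if abs(k) < eps:
        k = eps
    s = math.sqrt(1.0 - r * r)
    ah = (k - r * h) / (h * s)
    ak = (h - r * k) / (k * s)
    beta = 0.0 if h * k > 0.0 else 0.5
    val = (
        0.5 * (ndtr(h) + ndtr(k))
        - owens_t(h, ah)
        - owens_t(k, ak)
        - beta
    )
    return float(min(1.0, max(0.0, val)))


def bvn_upper_orthant(h: float, k: float, r: float) -> float:
    """P(X > h, Y > k) for a standard bivariate normal with correlation r."""
    return float(
        min(1.0, max(0.0, 1.0 - ndtr(h) - ndtr(k) + bvn_cdf(h, k, r)))
    )


def _cell_probs(tau1: float, tau2: float, r: float) -> np.ndarray:
    """Multinomial cell probabilities (p00, p01, p10, p11) of a concordance table."""
    p11 = bvn_upper_orthant(tau1, tau2, r)
    s1 = float(ndtr(-tau1))
    s2 = float(ndtr(-tau2))
    p10 = max(s1 - p11, 0.0)
    p01 = max(s2 - p11, 0.0)
    p00 = max(1.0 - p11 - p10 - p01, 0.0)
    return np.array([p00, p01, p10, p11])


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class GroupTable:
    """2x2 pair-concordance counts for one zygosity group.

    Cells are counts of pairs by (twin1 affected, twin2 affected):
    n00, n01, n10, n11.  Same-sex pairs have no natural within-pair order, so
    they are double-entered: each pair contributes both orderings at half
    weight, making n01 == n10 and within-pair threshold equality automatic.
    Counts may therefore be half-integers.
    """

    label: str
    n00: float
    n01: float
    n10: float
    n11: float
    symmetrized: bool = False

    def __post_init__(self) -> None:
        counts = (self.n00, self.n01, self.n10, self.n11)
        if any(c < 0 for c in counts):
            raise ValueError(f"negative cell count in group {self.label}: {counts}")
        if self.total <= 0:
            raise ValueError(f"group {self.label} has no pairs")

    @property
    def counts(self) -> np.ndarray:
        return np.array([self.n00, self.n01, self.n10, self.n11], dtype=float)

    @property
    def total(self) -> float:
        return self.n00 + self.n01 + self.n10 + self.n11

    @property
    def proportions(self) -> np.ndarray:
        return self.counts / self.total

    @property
    def margins(self) -> tuple[float, float]:
        """Affected fractions of twin 1 and twin 2."""
        n = self.total
        return (self.n10 + self.n11) / n, (self.n01 + self.n11) / n

    @property
    def sexes(self) -> tuple[str | None, str | None]:
        return GROUP_SEXES.get(self.label, (None, None))

    @property
    def is_mz(self) -> bool:
        return self.label.upper().startswith("MZ")

    def symmetrize(self) -> "GroupTable":
        """Double-enter an unordered same-sex table (half weight per ordering)."""
        off = 0.5 * (self.n01 + self.n10)
        return GroupTable(self.label, self.n00, off, off, self.n11, symmetrized=True)

    @classmethod
    def from_pairs(cls, label: str, aff1, aff2, symmetrize: bool | None = None) -> "GroupTable":
        """Tabulate a concordance table from per-pair affected indicators."""
        a1 = np.asarray(aff1, dtype=bool)
        a2 = np.asarray(aff2, dtype=bool)
        if a1.shape != a2.shape:
            raise ValueError("aff1 and aff2 must have equal length")
        t = cls(
            label,
            float(np.sum(~a1 & ~a2)),
            float(np.sum(~a1 & a2)),
            float(np.sum(a1 & ~a2)),
            float(np.sum(a1 & a2)),
        )
        if symmetrize is None:
            symmetrize = label.upper() != "DZOS"
        return t.symmetrize() if symmetrize else t


@dataclass
class VarianceComponents:
    """ACE decomposition of liability variance (proportions on [0, 1])."""

    a2: float
    c2: float
    e2: float
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    boundary: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = self.a2 + self.c2 + self.e2
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"variance components must sum to 1, got {total}")
        for name in ("a2", "c2", "e2"):
            v = getattr(self, name)
            if not -1e-9 <= v <= 1.0 + 1e-9:
                raise ValueError(f"{name}={v} outside [0, 1]")

    @property
    def r_mz(self) -> float:
        return self.a2 + self.c2

    @property
    def r_dz(self) -> float:
        return 0.5 * self.a2 + self.c2

    def as_dict(self) -> dict:
        out = {"a2": self.a2, "c2": self.c2, "e2": self.e2,
               "r_mz": self.r_mz, "r_dz": self.r_dz}
        if self.ci:
            out["ci"] = {k: list(v) for k, v in self.ci.items()}
        if self.boundary:
            out["boundary"] = dict(self.boundary)
        return out


def implied_correlations(components: VarianceComponents | tuple) -> tuple[float, float]:
    """(r_MZ, r_DZ) implied by an ACE decomposition.

    MZ pairs share all additive genetic variance and all shared environment;
    DZ pairs (same-sex or opposite-sex) share half of A and all of C.
    """
    if isinstance(components, VarianceComponents):
        a2, c2 = components.a2, components.c2
    else:
        a2, c2 = components[0], components[1]
    return a2 + c2, 0.5 * a2 + c2


@dataclass
class ModelFit:
    """One fitted liability model: estimates, -2 log L and bookkeeping."""

    model: str
    minus2ll: float
    n_parameters: int
    df: int
    params: dict
    converged: bool
    diagnostics: dict = field(default_factory=dict)
    _context: dict = field(default_factory=dict, repr=False)

    def as_dict(self) -> dict:
        return {
            "model": self.model,
            "minus2ll": self.minus2ll,
            "n_parameters": self.n_parameters,
            "df": self.df,
            "params": {k: (dict(v) if isinstance(v, dict) else v) for k, v in self.params.items()},
            "converged": self.converged,
        }


@dataclass
class LRTResult:
    """Likelihood-ratio comparison of nested models."""

    delta_chi2: float
    delta_df: int
    p: float


@dataclass
class TetrachoricResult:
    """Maximum-likelihood tetrachoric correlation with profile-likelihood CI."""

    r: float
    ci_low: float | None
    ci_high: float | None
    tau1: float
    tau2: float
    minus2ll: float
    boundary: bool = False


# ---------------------------------------------------------------------------
# likelihood machinery
# ---------------------------------------------------------------------------

def _m2ll_table(counts: np.ndarray, probs: np.ndarray) -> float:
    mask = counts > 0
    return float(-2.0 * np.sum(counts[mask] * np.log(np.maximum(probs[mask], _TINY))))


def _saturated_m2ll(table: GroupTable) -> float:
    """-2 sum n_ij log(n_ij / N): the multinomial saturated log-likelihood."""
    return _m2ll_table(table.counts, table.proportions)


def _solve_r_for_p11(tau1: float, tau2: float, p11: float) -> tuple[float, bool]:
    """Correlation whose upper orthant at (tau1, tau2) equals p11.

    Returns (r, at_boundary).  p11 outside the Frechet bounds is clipped to
    the nearest attainable orthant probability (r = +/-1) with a flag.
    """
    lo = bvn_upper_orthant(tau1, tau2, -1.0)
    hi = bvn_upper_orthant(tau1, tau2, 1.0)
    if p11 >= hi - 1e-12:
        return 1.0, True
    if p11 <= lo + 1e-12:
        return -1.0, True
    r = optimize.brentq(
        lambda rr: bvn_upper_orthant(tau1, tau2, rr) - p11, -1.0 + 1e-12, 1.0 - 1e-12,
        xtol=1e-12,
    )
    return float(r), False


# ---------------------------------------------------------------------------
# tetrachoric correlation
# ---------------------------------------------------------------------------

def tetrachoric_ml(table: GroupTable, ci: bool = True, level: float = 0.95) -> TetrachoricResult:
    """Joint maximum-likelihood tetrachoric correlation from a 2x2 table.

    The three parameters (tau1, tau2, r) exactly saturate the multinomial
    table, so the MLE reproduces the observed margins (thresholds at the
    margin probits) and matches the concordant-cell proportion through the
    orthant probability.  The 95% CI is a profile-likelihood interval: the
    set of r whose -2 log L, profiled over the thresholds, lies within the
    chi-square(1) critical value of the minimum.
    """
    counts = table.counts
    if np.count_nonzero(counts) < 2:
        raise ValueError("tetrachoric correlation needs at least two non-empty cells")
    n = table.total
    m1, m2 = table.margins
    if not (0 < m1 < 1 and 0 < m2 < 1):
        raise ValueError("tetrachoric correlation undefined for empty margins")
    tau1 = float(stats.norm.isf(m1))
    tau2 = float(stats.norm.isf(m2))
    r_hat, at_boundary = _solve_r_for_p11(tau1, tau2, table.n11 / n)
    m2ll = _m2ll_table(counts, _cell_probs(tau1, tau2, r_hat))

    lo = hi = None
    if ci:
        crit = stats.chi2.ppf(level, 1)

        def profiled(r: float) -> float:
            def obj(taus):
                return _m2ll_table(counts, _cell_probs(taus[0], taus[1], r))
            res = optimize.minimize(obj, [tau1, tau2], method="Nelder-Mead",
                                    options={"xatol": 1e-8, "fatol": 1e-10})
            return float(res.fun)

        def excess(r: float) -> float:
            return profiled(r) - m2ll - crit

        lo = _bisect_down(excess, r_hat, -1.0)
        hi = _bisect_up(excess, r_hat, 1.0)
    return TetrachoricResult(r_hat, lo, hi, tau1, tau2, m2ll, boundary=at_boundary)


def _bisect_down(excess, start: float, floor: float) -> float:
    """Lower endpoint where the profiled -2LL crosses the critical excess."""
    if excess(floor + 1e-9) <= 0:
        return floor
    return float(optimize.brentq(excess, floor + 1e-9, start, xtol=1e-5))


def _bisect_up(excess, start: float, ceil: float) -> float:
    if excess(ceil - 1e-9) <= 0:
        return ceil
    return float(optimize.brentq(excess, start, ceil - 1e-9, xtol=1e-5))


# ---------------------------------------------------------------------------
# saturated model
# ---------------------------------------------------------------------------

def _independent_cells(table: GroupTable) -> int:
    # a symmetrized table has 3 distinct cells -> 2 free proportions;
    # an ordered table has 4 cells -> 3 free proportions
    return 2 if table.symmetrized else 3


def fit_saturated(
    tables: dict[str, GroupTable],
    threshold_pattern: str = "by_group",
    correlation_pattern: str = "by_group",
) -> ModelFit:
    """Saturated (reference) model: per-group thresholds and correlations.

    The unconstrained default ("by_group"/"by_group") is solved analytically:
    thresholds at the margin probits and each correlation matched to the
    concordant cell, which reproduces the observed (symmetrized) proportions
    exactly; its -2 log L equals the multinomial saturated value.  Equality
    constraints across groups ("by_sex" thresholds, "by_zygosity" or
    "pooled_dz" correlations) are fitted numerically.
    """
    if not tables:
        raise ValueError("at least one group table is required")
    if threshold_pattern == "by_group" and correlation_pattern == "by_group":
        return _fit_saturated_unconstrained(tables)
    return _fit_saturated_constrained(tables, threshold_pattern, correlation_pattern)


def _fit_saturated_unconstrained(tables: dict[str, GroupTable]) -> ModelFit:
    params: dict = {"thresholds": {}, "correlations": {}}
    m2ll = 0.0
    n_par = 0
    cells = 0
    boundary = {}
    for label, t in tables.items():
        m1, m2 = t.margins
        tau1 = float(stats.norm.isf(np.clip(m1, 1e-12, 1 - 1e-12)))
        tau2 = float(stats.norm.isf(np.clip(m2, 1e-12, 1 - 1e-12)))
        r, at_bound = _solve_r_for_p11(tau1, tau2, t.n11 / t.total)
        params["thresholds"][label] = (tau1, tau2)
        params["correlations"][label] = r
        boundary[label] = at_bound
        m2ll += _m2ll_table(t.counts, _cell_probs(tau1, tau2, r))
        n_par += (2 if t.symmetrized else 3)
        cells += _independent_cells(t)
    return ModelFit(
        model="saturated",
        minus2ll=m2ll,
        n_parameters=n_par,
        df=cells - n_par,
        params=params,
        converged=True,
        diagnostics={"analytic": True, "boundary": boundary},
        _context={"tables": tables},
    )


def _threshold_index(tables: dict[str, GroupTable], pattern: str):
    """Map each (group, twin slot) to an index into the threshold vector."""
    if pattern == "by_sex":
        names = []
        idx = {}
        for label, t in tables.items():
            sexes = t.sexes
            if sexes[0] is None:
                raise ValueError(
                    f"threshold pattern 'by_sex' needs sex-resolvable group labels, got {label}"
                )
            for slot, sex in enumerate(sexes):
                if sex not in names:
                    names.append(sex)
                idx[(label, slot)] = names.index(sex)
        return names, idx
    if pattern == "single":
        idx = {(label, slot): 0 for label in tables for slot in (0, 1)}
        return ["all"], idx
    if pattern == "by_group":
        names, idx = [], {}
        for label, t in tables.items():
            if t.symmetrized:
                names.append(f"{label}")
                idx[(label, 0)] = idx[(label, 1)] = len(names) - 1
            else:
                names.append(f"{label}:1")
                idx[(label, 0)] = len(names) - 1
                names.append(f"{label}:2")
                idx[(label, 1)] = len(names) - 1
        return names, idx
    raise ValueError(f"unknown threshold pattern {pattern!r}")


def _correlation_index(tables: dict[str, GroupTable], pattern: str):
    if pattern == "by_group":
        names = list(tables)
        return names, {label: i for i, label in enumerate(names)}
    if pattern == "pooled_dz":
        names, idx = [], {}
        for label, t in tables.items():
            key = "MZ" if t.is_mz else "DZ"
            if key not in names:
                names.append(key)
            idx[label] = names.index(key)
        return names, idx
    if pattern == "by_zygosity":
        names, idx = [], {}
        for label, t in tables.items():
            if t.is_mz:
                key = "MZ"
            elif label.upper() == "DZOS":
                key = "DZOS"
            else:
                key = "DZSS"
            if key not in names:
                names.append(key)
            idx[label] = names.index(key)
        return names, idx
    raise ValueError(f"unknown correlation pattern {pattern!r}")


def _fit_saturated_constrained(tables, threshold_pattern, correlation_pattern) -> ModelFit:
    tnames, tidx = _threshold_index(tables, threshold_pattern)
    rnames, ridx = _correlation_index(tables, correlation_pattern)
    nt, nr = len(tnames), len(rnames)

    # start: thresholds from pooled margins per threshold class, r from pooled z
    tau0 = np.zeros(nt)
    weight = np.zeros(nt)
    for label, t in tables.items():
        for slot, m in enumerate(t.margins):
            j = tidx[(label, slot)]
            tau0[j] += m * t.total
            weight[j] += t.total
    tau0 = stats.norm.isf(np.clip(tau0 / np.maximum(weight, 1), 1e-6, 1 - 1e-6))

    def unpack(x):
        taus = x[:nt]
        rs = np.tanh(x[nt:])
        return taus, rs

    def obj(x):
        taus, rs = unpack(x)
        total = 0.0
        for label, t in tables.items():
            p = _cell_probs(taus[tidx[(label, 0)]], taus[tidx[(label, 1)]], rs[ridx[label]])
            total += _m2ll_table(t.counts, p)
        return total

    x0 = np.concatenate([tau0, np.arctanh(np.full(nr, 0.5))])
    best = None
    for r_start in (0.1, 0.3, 0.5, 0.7, 0.9):
        x0[nt:] = np.arctanh(r_start)
        res = optimize.minimize(obj, x0, method="Nelder-Mead",
                                options={"xatol": 1e-9, "fatol": 1e-10, "maxiter": 20000,
                                         "maxfev": 20000})
        if best is None or res.fun < best.fun - 1e-10:
            best = res
    taus, rs = unpack(best.x)
    cells = sum(_independent_cells(t) for t in tables.values())
    n_par = nt + nr
    return ModelFit(
        model="saturated",
        minus2ll=float(best.fun),
        n_parameters=n_par,
        df=cells - n_par,
        params={
            "thresholds": dict(zip(tnames, map(float, taus))),
            "correlations": dict(zip(rnames, map(float, rs))),
        },
        converged=bool(best.success),
        diagnostics={"optimizer": "Nelder-Mead", "nfev": int(best.nfev)},
        _context={"tables": tables, "threshold_pattern": threshold_pattern,
                  "correlation_pattern": correlation_pattern},
    )


# ---------------------------------------------------------------------------
# ACE-family variance models
# ---------------------------------------------------------------------------

_MODEL_COMPONENTS = {"ACE": ("a", "c"), "AE": ("a",), "CE": ("c",), "E": ()}


def _group_correlation(table: GroupTable, a2: float, c2: float) -> float:
    return a2 + c2 if table.is_mz else 0.5 * a2 + c2


def _variance_m2ll(tables, tidx, taus, a2, c2) -> float:
    total = 0.0
    for label, t in tables.items():
        r = min(_group_correlation(t, a2, c2), 1.0)
        p = _cell_probs(taus[tidx[(label, 0)]], taus[tidx[(label, 1)]], r)
        total += _m2ll_table(t.counts, p)
    return total


def fit_variance_model(
    tables: dict[str, GroupTable],
    model: str = "ACE",
    threshold_pattern: str = "by_sex",
) -> tuple[VarianceComponents, ModelFit]:
    """Fit an ACE / AE / CE / E liability-threshold model across twin groups.

    Path coefficients (a, c) are optimized on the constrained simplex
    a^2 + c^2 <= 1 with e^2 = 1 - a^2 - c^2; group liability correlations are
    structured as r_MZ = a^2 + c^2 and r_DZ = r_DZOS = 0.5 a^2 + c^2, with
    thresholds shared across zygosity (default: one per sex).  Five starting
    points spread over the feasible range guard against local optima.
    """
    model = model.upper()
    if model not in _MODEL_COMPONENTS:
        raise ValueError(f"model must be one of {sorted(_MODEL_COMPONENTS)}, got {model!r}")
    if not any(t.is_mz for t in tables.values()) or not any(not t.is_mz for t in tables.values()):
        raise ValueError("variance models need at least one MZ and one DZ group")
    comps = _MODEL_COMPONENTS[model]
    tnames, tidx = _threshold_index(tables, threshold_pattern)
    nt = len(tnames)

    tau0 = np.zeros(nt)
    weight = np.zeros(nt)
    for label, t in tables.items():
        for slot, m in enumerate(t.margins):
            j = tidx[(label, slot)]
            tau0[j] += m * t.total
            weight[j] += t.total
    tau0 = stats.norm.isf(np.clip(tau0 / np.maximum(weight, 1), 1e-6, 1 - 1e-6))

    def split(x):
        taus = x[:nt]
        a = c = 0.0
        i = nt
        if "a" in comps:
            a = x[i]
            i += 1
        if "c" in comps:
            c = x[i]
        return taus, a, c

    def obj(x):
        taus, a, c = split(x)
        a2, c2 = a * a, c * c
        if a2 + c2 > 1.0:  # infeasible corner during line search
            over = a2 + c2 - 1.0
            scale = 1.0 / math.sqrt(a2 + c2)
            a2, c2 = a2 * scale * scale, c2 * scale * scale
            return _variance_m2ll(tables, tidx, taus, a2, c2) + 1e4 * over
        return _variance_m2ll(tables, tidx, taus, a2, c2)

    bounds = [(-6.0, 6.0)] * nt + [(0.0, 1.0)] * len(comps)
    constraints = []
    if len(comps) == 2:
        constraints = [{"type": "ineq", "fun": lambda x: 1.0 - x[nt] ** 2 - x[nt + 1] ** 2}]

    best = None
    n_starts = 0
    for s in (0.1, 0.3, 0.5, 0.7, 0.9):
        x0 = list(tau0)
        if model == "ACE":
            x0 += [math.sqrt(2.0 * s / 3.0), math.sqrt(s / 3.0)]
        elif model == "AE":
            x0 += [math.sqrt(s)]
        elif model == "CE":
            x0 += [math.sqrt(s)]
        res = optimize.minimize(
            obj, np.array(x0), method="SLSQP", bounds=bounds, constraints=constraints,
            options={"ftol": 1e-12, "maxiter": 500},
        )
        n_starts += 1
        if best is None or res.fun < best.fun - 1e-9:
            best = res
        if model == "E":
            break  # objective has no component parameters; one start suffices

    taus, a, c = split(best.x)
    a2 = float(a * a)
    c2 = float(c * c)
    if a2 + c2 > 1.0:
        norm = a2 + c2
        a2, c2 = a2 / norm, c2 / norm
    e2 = max(0.0, 1.0 - a2 - c2)
    m2ll = float(_variance_m2ll(tables, tidx, taus, a2, c2))
    components = VarianceComponents(a2=a2, c2=c2, e2=e2)
    components.boundary = {
        "a2": model in ("ACE", "AE") and a2 < 1e-8,
        "c2": model in ("ACE", "CE") and c2 < 1e-8,
        "e2": e2 < 1e-8,
    }
    cells = sum(_independent_cells(t) for t in tables.values())
    n_par = nt + len(comps)
    fit = ModelFit(
        model=model,
        minus2ll=m2ll,
        n_parameters=n_par,
        df=cells - n_par,
        params={
            "thresholds": dict(zip(tnames, map(float, taus))),
            "a2": a2, "c2": c2, "e2": e2,
        },
        converged=bool(best.success),
        diagnostics={"optimizer": "SLSQP", "n_starts": n_starts, "nit": int(best.nit),
                     "boundary": dict(components.boundary)},
        _context={"tables": tables, "threshold_pattern": threshold_pattern, "model": model},
    )
    if not fit.converged:
        fit.diagnostics["message"] = str(best.message)
    return components, fit


# ---------------------------------------------------------------------------
# likelihood-ratio tests and profile CIs
# ---------------------------------------------------------------------------

_NESTING = {
    "E": {"CE", "AE", "ACE", "saturated"},
    "CE": {"ACE", "saturated"},
    "AE": {"ACE", "saturated"},
    "ACE": {"saturated"},
    "saturated": set(),
}


def likelihood_ratio_test(restricted: ModelFit, general: ModelFit) -> LRTResult:
    """Compare nested fits: delta -2LL is asymptotically chi-square.

    Degrees of freedom equal the difference in free parameters.  For tests
    that pin a variance component to its boundary at zero the naive
    chi-square reference is conservative (the asymptotic null is a 50:50
    mixture of chi-square distributions); the naive reference is reported.
    """
    if restricted.model == general.model:
        pass  # self-comparison is allowed and yields delta = 0
    elif general.model not in _NESTING.get(restricted.model, set()):
        raise ValueError(f"model {restricted.model!r} is not nested in {general.model!r}")
    if restricted.n_parameters > general.n_parameters:
        raise ValueError("restricted model has more parameters than the general model")
    delta = restricted.minus2ll - general.minus2ll
    if delta < -_LRT_CLIP:
        raise ValueError(
            f"restricted model fits better than the general model (delta={delta:.3g}); "
            "check convergence"
        )
    delta = max(delta, 0.0)
    ddf = general.n_parameters - restricted.n_parameters
    p = 1.0 if ddf == 0 else float(stats.chi2.sf(delta, ddf))
    if ddf == 0 and delta > _LRT_CLIP:
        p = 0.0
    return LRTResult(delta_chi2=float(delta), delta_df=int(ddf), p=p)


def _profiled_m2ll(tables, tidx, nt, tau0, model, component, value) -> float:
    """Minimum -2LL with one variance component fixed at `value`."""
    comps = _MODEL_COMPONENTS[model]

    if component == "e2":
        s = 1.0 - value  # a2 + c2 fixed at s
        if "a" in comps and "c" in comps:
            def obj(x):
                taus = x[:nt]
                frac = x[nt]
                return _variance_m2ll(tables, tidx, taus, frac * s, (1 - frac) * s)
            bounds = [(-6, 6)] * nt + [(0.0, 1.0)]
            x0 = np.concatenate([tau0, [0.7]])
        elif "a" in comps:
            def obj(x):
                return _variance_m2ll(tables, tidx, x[:nt], s, 0.0)
            bounds = [(-6, 6)] * nt
            x0 = tau0
        elif "c" in comps:
            def obj(x):
                return _variance_m2ll(tables, tidx, x[:nt], 0.0, s)
            bounds = [(-6, 6)] * nt
            x0 = tau0
        else:
            if abs(value - 1.0) > 1e-12:
                return math.inf
            def obj(x):
                return _variance_m2ll(tables, tidx, x[:nt], 0.0, 0.0)
            bounds = [(-6, 6)] * nt
            x0 = tau0
    else:
        fixed_a = component == "a2"
        other = "c" if fixed_a else "a"
        if (fixed_a and "a" not in comps) or (not fixed_a and "c" not in comps):
            return math.inf if value > 1e-12 else _profiled_m2ll(
                tables, tidx, nt, tau0, model, "e2", 1.0 - value)
        free_other = other in comps
        cap = math.sqrt(max(0.0, 1.0 - value))
        if free_other:
            def obj(x):
                taus = x[:nt]
                o2 = x[nt] ** 2
                a2 = value if fixed_a else o2
                c2 = o2 if fixed_a else value
                return _variance_m2ll(tables, tidx, taus, a2, c2)
            bounds = [(-6, 6)] * nt + [(0.0, cap)]
            x0 = np.concatenate([tau0, [min(0.4, cap / 2)]])
        else:
            def obj(x):
                a2 = value if fixed_a else 0.0
                c2 = 0.0 if fixed_a else value
                return _variance_m2ll(tables, tidx, x[:nt], a2, c2)
            bounds = [(-6, 6)] * nt
            x0 = tau0

    res = optimize.minimize(obj, x0, method="L-BFGS-B", bounds=bounds,
                            options={"ftol": 1e-13, "gtol": 1e-10})
    return float(res.fun)


def profile_ci(fit: ModelFit, component: str, level: float = 0.95) -> tuple[float, float, dict]:
    """Profile-likelihood CI for a variance component of a fitted model.

    Returns (low, high, flags): the set of component values whose profiled
    -2 log L lies within the chi-square(1) critical value of the minimum,
    found by bisection and truncated at [0, 1] with boundary flags.
    """
    if component not in ("a2", "c2", "e2"):
        raise ValueError(f"component must be a2, c2 or e2, got {component!r}")
    if not fit.converged:
        raise ValueError("profile CI requires a converged fit")
    ctx = fit._context
    tables = ctx["tables"]
    model = ctx.get("model", fit.model)
    tnames, tidx = _threshold_index(tables, ctx.get("threshold_pattern", "by_sex"))
    nt = len(tnames)
    tau0 = np.array([fit.params["thresholds"][n] for n in tnames])
    hat = fit.params[component]
    crit = stats.chi2.ppf(level, 1)
    target = fit.minus2ll + crit

    def excess(v):
        return _profiled_m2ll(tables, tidx, nt, tau0, model, component, v) - target

    flags = {"lower_at_boundary": False, "upper_at_boundary": False}
    # lower endpoint
    if hat <= 1e-10 or excess(0.0) <= 0:
        lo = 0.0
        flags["lower_at_boundary"] = True
    else:
        lo = float(optimize.brentq(excess, 0.0, hat, xtol=1e-5))
    # upper endpoint
    if hat >= 1.0 - 1e-10 or excess(1.0) <= 0:
        hi = 1.0
        flags["upper_at_boundary"] = True
    else:
        hi = float(optimize.brentq(excess, hat, 1.0, xtol=1e-5))
    return lo, hi, flags


# ---------------------------------------------------------------------------
# model ladder
# ---------------------------------------------------------------------------

def fit_model_ladder(
    tables: dict[str, GroupTable],
    threshold_pattern: str = "by_sex",
    ci: bool = True,
    level: float = 0.95,
) -> dict:
    """Fit saturated / ACE / AE / CE / E and compare along the nested ladder.

    Returns a dict with the fits, the ACE variance components (with profile
    CIs when requested), and a comparison table: ACE against the saturated
    reference, then each submodel against ACE.
    """
    fits: dict[str, ModelFit] = {"saturated": fit_saturated(tables)}
    components: dict[str, VarianceComponents] = {}
    for model in ("ACE", "AE", "CE", "E"):
        comp, fit = fit_variance_model(tables, model=model, threshold_pattern=threshold_pattern)
        fits[model] = fit
        components[model] = comp
    if ci:
        ace = components["ACE"]
        for name in ("a2", "c2", "e2"):
            lo, hi, flags = profile_ci(fits["ACE"], name, level=level)
            ace.ci[name] = (lo, hi)
            ace.boundary[name] = flags["lower_at_boundary"] and ace.ci[name][0] == 0.0
    comparisons = []
    for model, reference in (("ACE", "saturated"), ("AE", "ACE"), ("CE", "ACE"), ("E", "ACE")):
        lrt = likelihood_ratio_test(fits[model], fits[reference])
        comparisons.append({"model": model, "reference": reference,
                            "minus2ll": fits[model].minus2ll,
                            "n_parameters": fits[model].n_parameters,
                            "df": fits[model].df,
                            "delta_chi2": lrt.delta_chi2,
                            "delta_df": lrt.delta_df, "p": lrt.p})
    return {"fits": fits, "components": components, "comparisons": comparisons}
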