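"""Univariate statistics for factorial endpoint data.

Implements the gatekept decision tree commonly used for genotoxicity
endpoints: Lilliefors (Monte Carlo) normality and Bartlett homogeneity
checks, an optional natural-log transform, one-way ANOVA with Tukey HSD
post-hoc and a compact letter display, and a Kruskal–Wallis fallback for
data that cannot be normalized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, ValidationError

__all__ = [
    "TestResult",
    "PolicyRecord",
    "summarize_groups",
    "lilliefors_test",
    "bartlett_test",
    "apply_transform_policy",
    "one_way_anova",
    "tukey_hsd",
    "compact_letter_display",
    "kruskal_wallis",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single hypothesis test."""

    statistic: float
    pvalue: float
    method: str
    df: tuple | int | None = None
    n: int | None = None
    transform: str = "none"

    def __post_init__(self):
        if not 0 <= self.pvalue <= 1:
            raise ValidationError(f"p-value out of [0, 1]: {self.pvalue}")


def _groups_from_table(table: pd.DataFrame) -> dict[str, np.ndarray]:
    _require_columns(table)
    return {
        str(g): sub["value"].to_numpy(dtype=float)
        for g, sub in table.groupby("group", sort=False)
    }


def _require_columns(table: pd.DataFrame):
    missing = {"group", "value"} - set(table.columns)
    if missing:
        raise ValidationError(f"endpoint table missing column(s): {sorted(missing)}")
    vals = table["value"].to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValidationError("endpoint values must be finite")


def summarize_groups(table: pd.DataFrame) -> pd.DataFrame:
    """Per-group mean, standard error of the mean and n.

    Group means feed the interaction-factor analysis: the control mean plays
    the role of C, treated means the role of G.  SEM = SD/sqrt(n) with the
    n-1 denominator for SD.
    """
    groups = _groups_from_table(table)
    rows = []
    for g, v in groups.items():
        if len(v) < 2:
            raise ValidationError(f"group '{g}' has n < 2; cannot estimate SEM")
        sd = float(np.std(v, ddof=1))
        rows.append((g, float(np.mean(v)), sd / np.sqrt(len(v)), len(v)))
    return pd.DataFrame(rows, columns=["group", "mean", "sem", "n"])


# ---------------------------------------------------------------------------
# Normality / homogeneity gates


def _ks_stat_normal(x: np.ndarray) -> np.ndarray:
    """Kolmogorov–Smirnov distance to N(mean, sd) with estimated parameters.

    Accepts a 1-D sample or a 2-D array of samples in rows; vectorized so the
    Monte Carlo null needs one call.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    m = x.mean(axis=1, keepdims=True)
    s = x.std(axis=1, ddof=1, keepdims=True)
    z = np.sort((x - m) / s, axis=1)
    n = x.shape[1]
    cdf = stats.norm.cdf(z)
    grid = np.arange(1, n + 1) / n
    d_plus = (grid - cdf).max(axis=1)
    d_minus = (cdf - (np.arange(n) / n)).max(axis=1)
    return np.maximum(d_plus, d_minus)


def lilliefors_test(values, n_mc: int = 10_000, seed: int = 0) -> TestResult:
    """Lilliefors test of composite normality with a Monte Carlo p-value.

    The null distribution of the KS statistic (normal with estimated mean
    and SD) is simulated at the observed n with parameters re-estimated per
    resample; the p-value uses the add-one estimator (k+1)/(n_mc+1).  The
    statistic is location-scale invariant by construction.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 4:
        raise ValidationError("lilliefors_test requires a 1-D sample with n >= 4")
    if np.std(x, ddof=1) == 0:
        raise DegenerateDataError("degenerate sample: zero variance")
    d = float(_ks_stat_normal(x)[0])
    rng = np.random.default_rng(seed)
    null = _ks_stat_normal(rng.standard_normal((int(n_mc), len(x))))
    p = (1 + int(np.sum(null >= d - 1e-12))) / (n_mc + 1)
    return TestResult(d, float(p), "lilliefors-mc", n=len(x))


def bartlett_test(groups: list) -> TestResult:
    """Bartlett's test of variance homogeneity across groups."""
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValidationError("bartlett_test requires >= 2 groups")
    for i, a in enumerate(arrs):
        if len(a) < 2:
            raise ValidationError(f"group {i} has n < 2")
        if np.var(a, ddof=1) == 0:
            raise DegenerateDataError(f"group {i} has zero variance")
    stat, p = stats.bartlett(*arrs)
    return TestResult(float(stat), float(p), "bartlett", df=len(arrs) - 1)


@dataclass
class PolicyRecord:
    """Audit record of the transform/branch decision."""

    branch: str  # raw-ANOVA | ln-ANOVA | nonparametric
    transform: str  # none | ln
    normality_p: dict[str, float] = field(default_factory=dict)
    normality_p_after: dict[str, float] = field(default_factory=dict)
    bartlett_p: float | None = None
    warnings: list[str] = field(default_factory=list)


def apply_transform_policy(
    table: pd.DataFrame,
    alpha_gate: float = 0.05,
    n_mc: int = 2_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, PolicyRecord]:
    """Decide the analysis branch for an endpoint table.

    Branch logic: if every group passes the Lilliefors gate on the raw scale
    (and Bartlett passes), use raw-scale ANOVA; otherwise, when all values
    are positive, apply the natural-log transform and retest — if normality
    is then achieved (and Bartlett passes on the log scale) use ln-ANOVA,
    else fall back to Kruskal–Wallis.  Nonpositive values make the ln branch
    unavailable and route directly to the nonparametric branch.  Bartlett
    failure with normality intact also routes nonparametric (homogeneity is
    an ANOVA assumption too).  Groups with n < 4 or zero variance are not
    testable for normality and are skipped with a warning.
    """
    groups = _groups_from_table(table)
    rec = PolicyRecord(branch="raw-ANOVA", transform="none")
    rng = np.random.default_rng(seed)

    def gate(gs: dict[str, np.ndarray], store: dict[str, float]) -> bool:
        ok = True
        for g, v in gs.items():
            if len(v) < 4 or np.std(v, ddof=1) == 0:
                rec.warnings.append(f"group '{g}' not testable for normality; skipped")
                continue
            res = lilliefors_test(v, n_mc=n_mc, seed=int(rng.integers(2**31)))
            store[g] = res.pvalue
            ok &= res.pvalue > alpha_gate
        return ok

    def bartlett_ok(gs) -> bool:
        try:
            res = bartlett_test(list(gs.values()))
        except DegenerateDataError:
            rec.warnings.append("zero-variance group; Bartlett skipped")
            return True
        rec.bartlett_p = res.pvalue
        return res.pvalue > alpha_gate

    if gate(groups, rec.normality_p):
        if bartlett_ok(groups):
            return table, rec
        rec.branch = "nonparametric"
        rec.warnings.append("variance homogeneity failed with normality intact")
        return table, rec

    if any((v <= 0).any() for v in groups.values()):
        rec.branch = "nonparametric"
        rec.warnings.append("nonpositive values: ln transform unavailable")
        return table, rec

    ln_table = table.copy()
    ln_table["value"] = np.log(ln_table["value"].to_numpy(dtype=float))
    ln_groups = _groups_from_table(ln_table)
    if gate(ln_groups, rec.normality_p_after) and bartlett_ok(ln_groups):
        rec.branch = "ln-ANOVA"
        rec.transform = "ln"
        return ln_table, rec
    rec.branch = "nonparametric"
    return table, rec


# ---------------------------------------------------------------------------
# Omnibus tests and post-hoc


def one_way_anova(groups: list) -> TestResult:
    """One-way fixed-effects ANOVA; F on (k-1, N-k) df."""
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2 or any(len(a) < 2 for a in arrs):
        raise ValidationError("one_way_anova requires >= 2 groups with n >= 2 each")
    allv = np.concatenate(arrs)
    if np.ptp(allv) == 0:
        raise DegenerateDataError("all values identical; ANOVA undefined")
    stat, p = stats.f_oneway(*arrs)
    k, n_tot = len(arrs), len(allv)
    return TestResult(float(stat), float(p), "one-way-anova", df=(k - 1, n_tot - k))


def tukey_hsd(groups: list, alpha: float = 0.05) -> pd.DataFrame:
    """All-pairs Tukey HSD on the studentized-range distribution.

    Returns one row per unordered pair: indices, mean difference i-j,
    p-value and significance at ``alpha``.  p-values are symmetric in pair
    order by construction.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2 or any(len(a) < 2 for a in arrs):
        raise ValidationError("tukey_hsd requires >= 2 groups with n >= 2 each")
    if np.ptp(np.concatenate(arrs)) == 0:
        raise DegenerateDataError("all values identical; Tukey HSD undefined")
    res = stats.tukey_hsd(*arrs)
    rows = []
    k = len(arrs)
    for i in range(k):
        for j in range(i + 1, k):
            p = float(res.pvalue[i, j])
            rows.append((i, j, float(res.statistic[i, j]), p, p < alpha))
    return pd.DataFrame(rows, columns=["i", "j", "diff", "pvalue", "significant"])


def compact_letter_display(pairwise: pd.DataFrame, labels: list[str] | None = None) -> dict[str, str]:
    """Letter coding of a pairwise significance pattern (insert-and-absorb).

    Groups that are *not* significantly different share at least one letter;
    significantly different groups share none.  Non-transitive patterns are
    permitted — letters follow the insertion algorithm: start with one
    letter covering all groups; for each significant pair, split every
    letter-set containing both members; absorb letter-sets contained in
    another; assign letters in order of each set's smallest member.
    """
    need = {"i", "j", "significant"}
    if not need <= set(pairwise.columns):
        raise ValidationError(f"pairwise frame must have columns {sorted(need)}")
    idx = sorted(set(pairwise["i"]) | set(pairwise["j"]))
    cols: list[set] = [set(idx)]
    for _, row in pairwise[pairwise["significant"]].iterrows():
        i, j = row["i"], row["j"]
        new_cols = []
        for col in cols:
            if i in col and j in col:
                new_cols.extend([col - {i}, col - {j}])
            else:
                new_cols.append(col)
        # absorb: drop empty sets, exact duplicates, and strict subsets
        cols = []
        for col in new_cols:
            if not col or col in cols:
                continue
            if any(col < other for other in new_cols):
                continue
            cols.append(col)
    cols.sort(key=lambda c: min(c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in idx}
    for letter, col in zip(alphabet, cols):
        for g in sorted(col):
            letters[g] += letter
    if labels is not None:
        return {labels[g]: letters[g] for g in idx}
    return {g: letters[g] for g in idx}


def kruskal_wallis(groups: list) -> TestResult:
    """Kruskal–Wallis H test with the standard tie correction."""
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValidationError("kruskal_wallis requires >= 2 groups")
    if np.ptp(np.concatenate(arrs)) == 0:
        raise DegenerateDataError("all values tied; Kruskal-Wallis undefined")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stat, p = stats.kruskal(*arrs)
    return TestResult(float(stat), float(p), "kruskal-wallis", df=len(arrs) - 1)
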