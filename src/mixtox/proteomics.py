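"""Label-free spectral-count proteomics workflow.

Order of operations is fixed and meaningful:

1. :func:`filter_min_peptides` — drop proteins identified by fewer than
   three distinct peptides (false-positive control at identification).
2. :func:`aggregate_peptides` — sum peptide counts per protein, scaled by
   the number of peptides actually summed per cell.
3. :func:`filter_replicate_presence` — keep proteins observed in at least
   ``min_bioreps`` biological replicates of at least one condition.
4. :func:`vsn_normalize` — per-sample scale calibration + generalized-log
   (arcsinh) transform for variance stabilization (reporting/imputation
   scale only).
5. :func:`impute_mixed` — KNN for cells missing in some replicates of a
   condition where the protein is otherwise seen; QRILC (left-censored
   draws) for proteins entirely absent from a condition.
6. :func:`de_test` — per-protein quasi-Poisson GLM on the *aggregated
   counts* (missing = zero) with library-size offset, BH q-values.
7. :func:`spectral_index` / :func:`overlap_analysis` — normalized abundance
   and Venn-style comparison of candidate sets.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .synthetic import PeptideCountMatrix

__all__ = [
    "ProteinMatrix",
    "filter_min_peptides",
    "aggregate_peptides",
    "filter_replicate_presence",
    "vsn_normalize",
    "impute_mixed",
    "spectral_index",
    "de_test",
    "bh_adjust",
    "overlap_analysis",
]

OBSERVED = "observed"
MISSING = "missing"
IMPUTED_KNN = "imputed-KNN"
IMPUTED_QRILC = "imputed-QRILC"


@dataclass
class ProteinMatrix:
    """Protein-level matrix with per-cell provenance flags.

    ``values``: proteins x samples (NaN = missing); ``n_peptides``: distinct
    peptides behind each protein; ``provenance``: per-cell flag in
    {observed, missing, imputed-KNN, imputed-QRILC}; ``design``: sample,
    condition, biorep.  ``scale`` records whether values are raw aggregated
    counts or the variance-stabilized (glog) scale.
    """

    values: pd.DataFrame
    n_peptides: pd.Series
    design: pd.DataFrame
    provenance: pd.DataFrame | None = None
    scale: str = "counts"
    n_observed: pd.DataFrame | None = None  # peptides summed per cell

    def __post_init__(self):
        if self.provenance is None:
            flags = np.where(np.isnan(self.values.to_numpy(dtype=float)), MISSING, OBSERVED)
            self.provenance = pd.DataFrame(
                flags, index=self.values.index, columns=self.values.columns
            )

    def copy(self) -> "ProteinMatrix":
        return ProteinMatrix(
            self.values.copy(),
            self.n_peptides.copy(),
            self.design.copy(),
            self.provenance.copy(),
            self.scale,
            None if self.n_observed is None else self.n_observed.copy(),
        )

    def samples_for(self, condition: str) -> list[str]:
        d = self.design
        return list(d.loc[d["condition"] == condition, "sample"])

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.design["condition"]))


# ---------------------------------------------------------------------------
# Filters and aggregation


def filter_min_peptides(
    matrix: PeptideCountMatrix, min_peptides: int = 3
) -> tuple[PeptideCountMatrix, pd.DataFrame]:
    """Drop proteins with fewer than ``min_peptides`` distinct peptides.

    Returns the filtered matrix and an audit frame (protein, n_peptides,
    kept).
    """
    counts_per_protein = matrix.protein_map.groupby(matrix.protein_map).size()
    kept_proteins = set(counts_per_protein[counts_per_protein >= min_peptides].index)
    audit = pd.DataFrame(
        {
            "protein": counts_per_protein.index,
            "n_peptides": counts_per_protein.to_numpy(),
            "kept": [p in kept_proteins for p in counts_per_protein.index],
        }
    )
    keep_mask = matrix.protein_map.isin(kept_proteins)
    peptides = matrix.protein_map.index[keep_mask]
    if len(peptides) == 0:
        warnings.warn("no protein passed the peptide filter; result is empty")
    out = PeptideCountMatrix(
        matrix.counts.loc[peptides],
        matrix.protein_map.loc[peptides],
        matrix.design.copy(),
        None if matrix.latent is None else matrix.latent.loc[peptides],
    )
    return out, audit


def aggregate_peptides(matrix: PeptideCountMatrix) -> ProteinMatrix:
    """Sum peptide counts per protein, scaled by the peptides summed.

    Per cell: value = sum of the protein's *observed* peptide counts divided
    by the number of observed peptides in that cell; a protein cell is
    missing only when every constituent peptide cell is missing.  The
    scaling makes proteins with different peptide coverage comparable while
    conserving total counts (value x peptides summed = summed counts).
    """
    counts = matrix.counts
    grouper = matrix.protein_map.reindex(counts.index)
    sums = counts.groupby(grouper).sum(min_count=1)
    n_obs = counts.notna().groupby(grouper).sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        values = sums / n_obs.replace(0, np.nan)
    n_peptides = grouper.groupby(grouper).size()
    n_peptides = n_peptides.reindex(values.index)
    return ProteinMatrix(
        values, n_peptides, matrix.design.copy(), n_observed=n_obs.reindex(values.index)
    )


def filter_replicate_presence(
    matrix: ProteinMatrix, min_bioreps: int = 3
) -> ProteinMatrix:
    """Keep proteins observed (non-missing, nonzero) in >= ``min_bioreps``
    biological replicates of at least one condition."""
    vals = matrix.values
    present = vals.notna() & (vals != 0)
    keep = pd.Series(False, index=vals.index)
    sample_to_rep = matrix.design.set_index("sample")["biorep"]
    for cond in matrix.conditions:
        cols = matrix.samples_for(cond)
        # count distinct biological replicates in which the protein is present
        rep_present = present[cols].T.groupby(sample_to_rep.loc[cols]).any().T
        keep |= rep_present.sum(axis=1) >= min_bioreps
    if not keep.any():
        warnings.warn("no protein passed the replicate-presence filter")
    out = matrix.copy()
    out.values = out.values.loc[keep]
    out.n_peptides = out.n_peptides.loc[keep]
    out.provenance = out.provenance.loc[keep]
    if out.n_observed is not None:
        out.n_observed = out.n_observed.loc[keep]
    return out


# ---------------------------------------------------------------------------
# Normalization and imputation


def vsn_normalize(matrix: ProteinMatrix) -> ProteinMatrix:
    """Variance-stabilizing normalization: scale calibration + glog.

    Each sample is calibrated by its median ratio to the row-median
    reference profile (an affine map with zero offset), then transformed by
    the generalized log ``arcsinh(y / c)`` with ``c`` the global median of
    calibrated values.  The transform is strictly increasing within each
    sample, leaves missing cells untouched, and makes the per-protein SD
    approximately independent of the mean when noise is multiplicative at
    high abundance and additive near zero.
    """
    vals = matrix.values.to_numpy(dtype=float)
    if vals.shape[1] < 2:
        raise ValidationError("vsn_normalize requires >= 2 samples")
    if np.all(np.isnan(vals), axis=0).any():
        raise ValidationError("sample with all values missing")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ref = np.nanmedian(vals, axis=1, keepdims=True)
        ratio = np.where(ref > 0, vals / ref, np.nan)
        scale = np.nanmedian(ratio, axis=0)
    scale = np.where((scale > 0) & np.isfinite(scale), scale, 1.0)
    calibrated = vals / scale
    c = np.nanmedian(calibrated)
    if not np.isfinite(c) or c <= 0:
        c = 1.0
    out = matrix.copy()
    out.values = pd.DataFrame(
        np.arcsinh(calibrated / c), index=matrix.values.index, columns=matrix.values.columns
    )
    out.scale = "glog"
    return out


def _qrilc_fit(observed: np.ndarray) -> tuple[float, float]:
    """Fit a normal to a left-censored sample by regressing order statistics
    on standard-normal quantiles (least squares over all plotting positions)."""
    v = np.sort(observed)
    m = len(v)
    pp = (np.arange(1, m + 1) - 0.5) / m
    q = stats.norm.ppf(pp)
    slope, intercept = np.polyfit(q, v, 1)
    if slope <= 0:
        slope = max(np.std(v, ddof=1), 1e-8)
    return float(intercept), float(slope)


def impute_mixed(
    matrix: ProteinMatrix,
    k: int = 10,
    qrilc_quantile: float = 0.01,
    seed: int = 0,
) -> ProteinMatrix:
    """Mixed KNN + QRILC imputation on a normalized matrix.

    Cells missing in *some* replicates of a condition where the protein is
    otherwise observed are treated as randomly missing and imputed by KNN:
    the k nearest proteins (Euclidean distance over co-observed samples,
    normalized per shared sample) that are observed in the target sample,
    averaged.  Cells of proteins entirely missing within a condition are
    treated as left-censored and imputed by QRILC: per sample, a normal is
    fitted to the observed values by quantile regression and draws are taken
    from its left tail truncated at the censoring quantile (never above the
    sample's empirical ``qrilc_quantile`` quantile).  Observed cells are
    never altered; every imputed cell is flagged with its method.
    """
    if not 0 < qrilc_quantile < 1:
        raise ValidationError("qrilc_quantile must be in (0, 1)")
    rng = np.random.default_rng(seed)
    out = matrix.copy()
    vals = out.values.to_numpy(dtype=float)
    prov = out.provenance.to_numpy(dtype=object)
    n_prot, n_samp = vals.shape
    sample_idx = {s: j for j, s in enumerate(out.values.columns)}

    # classify missing cells
    knn_cells: list[tuple[int, int]] = []
    qrilc_cells: list[tuple[int, int]] = []
    for cond in out.conditions:
        cols = [sample_idx[s] for s in out.samples_for(cond)]
        block = vals[:, cols]
        any_obs = ~np.all(np.isnan(block), axis=1)
        for local_j, j in enumerate(cols):
            miss = np.isnan(block[:, local_j])
            for i in np.where(miss & any_obs)[0]:
                knn_cells.append((i, j))
            for i in np.where(miss & ~any_obs)[0]:
                qrilc_cells.append((i, j))

    obs_mask = ~np.isnan(vals)

    # ---- KNN on co-observed profiles
    if knn_cells:
        # pairwise distances computed lazily per target protein
        target_rows = sorted({i for i, _ in knn_cells})
        dist_cache: dict[int, np.ndarray] = {}
        for i in target_rows:
            shared = obs_mask[i] & obs_mask  # (n_prot, n_samp) co-observed
            diff = vals[i] - vals
            with np.errstate(invalid="ignore"):
                sq = np.where(shared, diff**2, 0.0)
            n_shared = shared.sum(axis=1)
            d = np.sqrt(sq.sum(axis=1) / np.maximum(n_shared, 1))
            d[n_shared == 0] = np.inf
            d[i] = np.inf
            dist_cache[i] = d
        for i, j in knn_cells:
            d = dist_cache[i].copy()
            d[~obs_mask[:, j]] = np.inf  # neighbour must be observed at sample j
            order = np.argsort(d)
            finite = order[np.isfinite(d[order])]
            if len(finite) == 0:
                qrilc_cells.append((i, j))
                continue
            kk = min(k, len(finite))
            if kk < k:
                warnings.warn(f"KNN: only {kk} neighbours available (k={k})")
            vals[i, j] = float(np.mean(vals[finite[:kk], j]))
            prov[i, j] = IMPUTED_KNN

    # ---- QRILC per sample
    by_sample: dict[int, list[int]] = {}
    for i, j in qrilc_cells:
        by_sample.setdefault(j, []).append(i)
    z_q = stats.norm.ppf(qrilc_quantile)
    for j, rows in sorted(by_sample.items()):
        observed = vals[obs_mask[:, j], j]
        if len(observed) < 4:
            raise ValidationError(
                f"sample column {j}: too few observed values for QRILC"
            )
        mu, sigma = _qrilc_fit(observed)
        emp_q = float(np.quantile(observed, qrilc_quantile))
        upper = min(mu + sigma * z_q, emp_q)
        b = (upper - mu) / sigma
        draws = stats.truncnorm.rvs(
            a=-38.0, b=b, loc=mu, scale=sigma, size=len(rows),
            random_state=np.random.RandomState(int(rng.integers(2**31))),
        )
        for i, v in zip(rows, np.atleast_1d(draws)):
            vals[i, j] = float(v)
            prov[i, j] = IMPUTED_QRILC

    out.values = pd.DataFrame(vals, index=out.values.index, columns=out.values.columns)
    out.provenance = pd.DataFrame(
        prov, index=out.values.index, columns=out.values.columns
    )
    return out


# ---------------------------------------------------------------------------
# Quantification, differential expression, overlaps


def spectral_index(matrix: ProteinMatrix) -> pd.DataFrame:
    """Sample-normalized spectral index: SI_N = value / sample total.

    Missing cells contribute zero.  Columns sum to one; the index is
    invariant to rescaling a sample's counts.
    """
    vals = matrix.values.fillna(0.0)
    totals = vals.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero) > 0:
        raise ValidationError(f"zero-total sample(s): {list(zero.index)}")
    return vals / totals


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _poisson_deviance(y: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Rowwise Poisson deviance; valid for non-integer y (quasi-likelihood)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return 2.0 * np.sum(term - (y - mu), axis=1)


def de_test(
    matrix: ProteinMatrix,
    contrast: tuple[str, str],
    alpha: float = 0.05,
    fdr: float = 0.01,
    prior_df: float = 4.0,
) -> pd.DataFrame:
    """Per-protein quasi-Poisson GLM differential-expression test.

    ``contrast`` is (reference condition, treatment condition).  The model
    is a log-link GLM of aggregated counts on condition with an offset of
    log(sample total counts); for the two-group design the grouped MLE has
    the closed form rate_g = sum(counts_g) / sum(totals_g).  Dispersion is
    estimated per protein from the residual deviance, squeezed toward the
    proteome-wide median with ``prior_df`` pseudo-df, and the condition
    effect tested with a deviance F statistic on (1, n-2+prior_df) df.
    Missing cells count as zero (a missing spectral count is a
    non-observation).

    Returns one row per protein: log2fc (treatment vs reference), F
    statistic, p, BH q, direction, and tier flags ``candidate`` (p < alpha)
    and ``confirmed`` (q < fdr).  Proteins with all-zero counts in both
    groups are excluded and flagged in the ``tested`` column.
    """
    ref, treat = contrast
    for cond in contrast:
        if cond not in matrix.conditions:
            raise ValidationError(f"condition '{cond}' not in design")
    cols_ref = matrix.samples_for(ref)
    cols_treat = matrix.samples_for(treat)
    if len(cols_ref) < 2 or len(cols_treat) < 2:
        raise ValidationError("de_test requires >= 2 replicates per condition")
    cols = cols_ref + cols_treat
    # test the actual summed spectral counts: undo the per-cell peptide
    # scaling where the peptide tally is available (the Poisson variance
    # model applies to the sums, not the scaled averages)
    if matrix.n_observed is not None:
        y = (matrix.values[cols] * matrix.n_observed[cols]).fillna(0.0).to_numpy(dtype=float)
    else:
        y = matrix.values[cols].fillna(0.0).to_numpy(dtype=float)
    group = np.array([0] * len(cols_ref) + [1] * len(cols_treat))
    totals = y.sum(axis=0)
    if np.any(totals <= 0):
        raise ValidationError("sample with zero total counts in contrast")
    n = y.shape[1]

    y_ref, y_treat = y[:, group == 0], y[:, group == 1]
    n_ref, n_treat = totals[group == 0].sum(), totals[group == 1].sum()
    s_ref, s_treat = y_ref.sum(axis=1), y_treat.sum(axis=1)
    tested = (s_ref + s_treat) > 0

    rate_ref = s_ref / n_ref
    rate_treat = s_treat / n_treat
    rate_null = (s_ref + s_treat) / (n_ref + n_treat)

    mu_full = np.where(group == 0, rate_ref[:, None], rate_treat[:, None]) * totals
    mu_null = rate_null[:, None] * totals
    with np.errstate(invalid="ignore"):
        d_full = _poisson_deviance(y, np.maximum(mu_full, 1e-300))
        d_null = _poisson_deviance(y, np.maximum(mu_null, 1e-300))

    df_resid = n - 2
    eps = 1e-12
    delta = np.maximum(d_null - d_full, 0.0)
    # deviance-based dispersion, squeezed toward the proteome-wide median
    # with `prior_df` pseudo-degrees of freedom: per-protein estimates on a
    # handful of residual df are too noisy for far-tail inference, so the
    # quasi-F denominator borrows strength across proteins and the test df
    # gain the prior df
    phi = d_full / df_resid
    usable = tested & (phi > 0)
    phi0 = float(np.median(phi[usable])) if usable.any() else 0.0
    phi_sq = (prior_df * phi0 + df_resid * phi) / (prior_df + df_resid)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = delta / np.maximum(phi_sq, eps)
    pvals = stats.f.sf(f_stat, 1, df_resid + prior_df)
    pvals = np.where(tested, pvals, np.nan)

    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(rate_treat / rate_ref)
    qvals = np.full_like(pvals, np.nan)
    qvals[tested] = bh_adjust(pvals[tested])

    res = pd.DataFrame(
        {
            "protein": matrix.values.index,
            "log2fc": log2fc,
            "statistic": f_stat,
            "pvalue": pvals,
            "qvalue": qvals,
            "direction": np.where(log2fc > 0, "up", np.where(log2fc < 0, "down", "none")),
            "tested": tested,
            "candidate": (pvals < alpha) & tested,
            "confirmed": (qvals < fdr) & tested,
            "contrast": f"{treat} vs {ref}",
        }
    )
    return res


def overlap_analysis(de_sets: dict[str, set]) -> dict:
    """Venn-partition cardinalities and overlap percentages for named sets.

    Returns ``regions`` (each nonempty combination of set names, mapped to
    the count of elements in exactly those sets), ``pairwise_percent``
    (Jaccard |intersection|/|union| x 100 per pair), ``mean_pairwise_percent``
    and ``all_sets_percent``.
    """
    if len(de_sets) < 2:
        raise ValidationError("overlap_analysis requires >= 2 sets")
    names = list(de_sets)
    universe = set().union(*de_sets.values())
    regions: dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set(universe)
            for nm in combo:
                inside &= de_sets[nm]
            for nm in names:
                if nm not in combo:
                    inside -= de_sets[nm]
            regions["&".join(combo)] = len(inside)
    pairwise = {}
    for a, b in itertools.combinations(names, 2):
        union = de_sets[a] | de_sets[b]
        inter = de_sets[a] & de_sets[b]
        pairwise[f"{a}&{b}"] = 100.0 * len(inter) / len(union) if union else 0.0
    inter_all = set.intersection(*map(set, de_sets.values()))
    all_pct = 100.0 * len(inter_all) / len(universe) if universe else 0.0
    return {
        "regions": regions,
        "pairwise_percent": pairwise,
        "mean_pairwise_percent": float(np.mean(list(pairwise.values()))) if pairwise else 0.0,
        "all_sets_percent": all_pct,
        "union_size": len(universe),
    }
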