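"""Term over-representation testing for candidate protein sets.

Two correction styles are provided, matching the two conventions of the
field's GO and pathway tools: permutation-based family-wise error control
(min-p resampling of random candidate sets) and Benjamini–Hochberg q-values.
Annotation maps are flat term -> protein sets (any ontology propagation is
assumed done upstream); the enrichment universe should be the population
the candidates were selected from, e.g. all proteins surviving the
presence filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = [
    "AnnotationMap",
    "hypergeom_enrich",
    "fwer_adjust",
    "bh_enrich",
    "enrich",
]


@dataclass(frozen=True)
class AnnotationMap:
    """Flat term -> protein-set annotation over a fixed universe."""

    terms: dict
    universe: frozenset
    names: dict = field(default_factory=dict)

    def __post_init__(self):
        for t, members in self.terms.items():
            if not members:
                raise ValidationError(f"term '{t}' has an empty member set")
            stray = set(members) - set(self.universe)
            if stray:
                raise ValidationError(
                    f"term '{t}' annotates proteins outside the universe: "
                    f"{sorted(stray)[:5]}"
                )

    def restricted_to(self, universe) -> "AnnotationMap":
        """Intersect every term with a new universe, dropping emptied terms."""
        uni = frozenset(universe)
        terms = {}
        for t, members in self.terms.items():
            kept = frozenset(members) & uni
            if kept:
                terms[t] = kept
        return AnnotationMap(terms=terms, universe=uni, names=dict(self.names))


def hypergeom_enrich(
    candidates,
    annotation: AnnotationMap,
    min_term_size: int = 3,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation p per term.

    With N = universe size, K = proteins annotated to the term, n =
    candidate-set size and k = annotated candidates, p = P(X >= k) for
    X ~ Hypergeometric(N, K, n).  Terms with K < ``min_term_size`` are
    skipped (their upper tails are untestable).
    """
    cand = set(candidates)
    stray = cand - set(annotation.universe)
    if stray:
        raise ValidationError(
            f"candidates outside the universe: {sorted(stray)[:10]}"
        )
    n_univ = len(annotation.universe)
    n_cand = len(cand)
    rows = []
    for term, members in annotation.terms.items():
        big_k = len(members)
        if big_k < min_term_size:
            continue
        k = len(cand & set(members))
        p = float(stats.hypergeom.sf(k - 1, n_univ, big_k, n_cand))
        rows.append(
            {
                "term": term,
                "name": annotation.names.get(term, ""),
                "k": k,
                "K": big_k,
                "n": n_cand,
                "N": n_univ,
                "pvalue": min(p, 1.0),
            }
        )
    return pd.DataFrame(rows, columns=["term", "name", "k", "K", "n", "N", "pvalue"])


def fwer_adjust(
    results: pd.DataFrame,
    candidates,
    annotation: AnnotationMap,
    n_perm: int = 1000,
    seed: int = 0,
    min_term_size: int = 3,
) -> pd.DataFrame:
    """Min-p permutation FWER adjustment.

    Random candidate sets of the same size are drawn uniformly without
    replacement from the universe (annotation held fixed); the adjusted p of
    a term is the fraction of permutations whose *minimum* raw p across all
    tested terms is <= the term's raw p (add-one estimator).  This is
    monotone in the raw p by construction and controls the FWER in the weak
    sense.
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    if results.empty:
        out = results.copy()
        out["p_fwer"] = pd.Series(dtype=float)
        return out
    cand = set(candidates)
    n_cand = len(cand)
    universe = np.array(sorted(annotation.universe))
    terms = [t for t in annotation.terms if len(annotation.terms[t]) >= min_term_size]
    term_index = {p: i for i, p in enumerate(universe)}
    indicator = np.zeros((len(terms), len(universe)), dtype=bool)
    for ti, t in enumerate(terms):
        for p in annotation.terms[t]:
            indicator[ti, term_index[p]] = True
    big_k = indicator.sum(axis=1)
    n_univ = len(universe)

    rng = np.random.default_rng(seed)
    min_p = np.empty(n_perm)
    # per-term p as a function of k is monotone decreasing; precompute sf tables
    sf_tables = {}
    for ti, kk in enumerate(big_k):
        kmax = min(kk, n_cand)
        sf_tables[ti] = stats.hypergeom.sf(np.arange(0, kmax + 1) - 1, n_univ, kk, n_cand)
    for b in range(n_perm):
        idx = rng.choice(n_univ, size=n_cand, replace=False)
        ks = indicator[:, idx].sum(axis=1)
        p_min = 1.0
        for ti in range(len(terms)):
            p_min = min(p_min, sf_tables[ti][ks[ti]])
        min_p[b] = p_min

    raw = results["pvalue"].to_numpy(dtype=float)
    adj = np.array(
        [(1 + np.sum(min_p <= p + 1e-15)) / (n_perm + 1) for p in raw]
    )
    out = results.copy()
    out["p_fwer"] = np.maximum(adj, raw)  # adjusted p can never undercut raw p
    return out


def bh_enrich(results: pd.DataFrame) -> pd.DataFrame:
    """Append Benjamini–Hochberg q-values over all tested terms."""
    from .proteomics import bh_adjust

    out = results.copy()
    out["qvalue"] = bh_adjust(out["pvalue"].to_numpy(dtype=float)) if len(out) else pd.Series(dtype=float)
    return out


def enrich(
    candidates,
    annotation: AnnotationMap,
    n_perm: int = 1000,
    min_term_size: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Hypergeometric enrichment with both FWER and BH corrections,
    sorted by q-value then raw p."""
    res = hypergeom_enrich(candidates, annotation, min_term_size=min_term_size)
    res = fwer_adjust(res, candidates, annotation, n_perm=n_perm, seed=seed,
                      min_term_size=min_term_size)
    res = bh_enrich(res)
    if len(res):
        res = res.sort_values(["qvalue", "pvalue"], kind="mergesort").reset_index(drop=True)
    return res
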