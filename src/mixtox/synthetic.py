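"""Synthetic data generators for a two-agent factorial exposure study.

The generators emulate the structure of a mussel co-exposure experiment: a
genotoxic organic agent (agent A, e.g. B[a]P at three doses), a nanomaterial
(agent B, e.g. aqueous fullerene at three doses), and mixture groups pairing
each A dose with one fixed B dose.  Downstream consumers are the endpoint
statistics, the interaction-factor analysis, the spectral-count proteomics
workflow, and term enrichment — each generator therefore emits a *truth*
record alongside its data so recovery can be scored, but the truth is never
embedded in the data tables themselves.

All generators are deterministic in (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError

__all__ = [
    "ExposureDesign",
    "EndpointSimConfig",
    "ProteomeSimConfig",
    "PeptideCountMatrix",
    "generate_endpoint_data",
    "generate_spectral_counts",
    "inject_missingness",
    "generate_annotation",
]


def _fmt_dose(d: float) -> str:
    return f"{d:g}"


@dataclass(frozen=True)
class ExposureDesign:
    """Factorial exposure design: control, two single agents, mixtures.

    Mixture groups pair every dose in ``mix_a_doses`` (default: all A doses)
    with the single fixed B dose ``mix_b_dose``, mirroring the common
    co-exposure layout where the nanomaterial is held at one concentration.
    """

    a_name: str = "BaP"
    b_name: str = "C60"
    a_doses: tuple[float, ...] = (5.0, 50.0, 100.0)
    b_doses: tuple[float, ...] = (0.01, 0.1, 1.0)
    mix_b_dose: float = 1.0
    mix_a_doses: tuple[float, ...] | None = None
    n_per_group: int = 10
    control_label: str = "control"
    endpoint: str = "percent_tail_DNA"

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ConfigError("n_per_group: all sample sizes must be >= 2")
        if self.mix_b_dose not in self.b_doses:
            raise ConfigError(
                "mix_b_dose: mixture B dose must exist as a single-agent group"
            )
        for d in self.mix_a_doses or ():
            if d not in self.a_doses:
                raise ConfigError(
                    f"mix_a_doses: dose {d!r} must exist as a single-agent A group"
                )

    def single_label(self, agent: str, dose: float) -> str:
        return f"{agent}_{_fmt_dose(dose)}"

    def mix_label(self, a_dose: float) -> str:
        return (
            f"{self.single_label(self.a_name, a_dose)}"
            f"+{self.single_label(self.b_name, self.mix_b_dose)}"
        )

    @property
    def single_groups(self) -> list[str]:
        return [self.single_label(self.a_name, d) for d in self.a_doses] + [
            self.single_label(self.b_name, d) for d in self.b_doses
        ]

    @property
    def mixtures(self) -> list[tuple[str, str, str]]:
        """(mixture label, constituent A label, constituent B label) triples."""
        doses = self.mix_a_doses if self.mix_a_doses is not None else self.a_doses
        b_lab = self.single_label(self.b_name, self.mix_b_dose)
        return [
            (self.mix_label(d), self.single_label(self.a_name, d), b_lab)
            for d in doses
        ]

    @property
    def groups(self) -> list[str]:
        return [self.control_label] + self.single_groups + [m for m, _, _ in self.mixtures]


@dataclass(frozen=True)
class EndpointSimConfig:
    """Configuration for per-individual endpoint simulation.

    ``effects`` maps single-agent group labels to additive mean shifts above
    control (endpoint units).  ``interaction_shift`` (scalar, or map keyed by
    mixture label) perturbs the additive expectation of each mixture group:
    0 = additive, negative = antagonistic, positive = synergistic.

    Defaults emulate a comet-assay endpoint (% tail DNA): control mean 8 with
    SD 5, dose-increasing genotoxic effects for agent A and mild effects for
    agent B, n = 10 individuals per group.
    """

    design: ExposureDesign = field(default_factory=ExposureDesign)
    control_mean: float = 8.0
    control_sd: float = 5.0
    effects: Mapping[str, float] | None = None
    interaction_shift: float | Mapping[str, float] = 0.0
    noise: str = "normal"
    seed: int = 0

    def __post_init__(self):
        if self.control_sd <= 0:
            raise ConfigError("control_sd: SDs must be > 0")
        if self.noise not in ("normal", "lognormal"):
            raise ConfigError("noise: noise family must be 'normal' or 'lognormal'")
        if self.effects is not None:
            unknown = set(self.effects) - set(self.design.single_groups)
            if unknown:
                raise ConfigError(f"effects: unknown group labels {sorted(unknown)}")
        if isinstance(self.interaction_shift, Mapping):
            mix = {m for m, _, _ in self.design.mixtures}
            unknown = set(self.interaction_shift) - mix
            if unknown:
                raise ConfigError(
                    f"interaction_shift: unknown mixture labels {sorted(unknown)}"
                )

    def resolved_effects(self) -> dict[str, float]:
        """Per single-agent-group additive effect, defaulting to a graded
        dose–response: A doses shift the mean by (4, 7, 10) units across its
        dose ranks, B doses by (1, 2, 3)."""
        if self.effects is not None:
            eff = dict.fromkeys(self.design.single_groups, 0.0)
            eff.update(self.effects)
            return eff
        d = self.design
        a_grid = np.linspace(4.0, 10.0, num=len(d.a_doses)) if d.a_doses else []
        b_grid = np.linspace(1.0, 3.0, num=len(d.b_doses)) if d.b_doses else []
        eff = {d.single_label(d.a_name, dose): float(v) for dose, v in zip(d.a_doses, a_grid)}
        eff.update(
            {d.single_label(d.b_name, dose): float(v) for dose, v in zip(d.b_doses, b_grid)}
        )
        return eff

    def shift_for(self, mixture_label: str) -> float:
        if isinstance(self.interaction_shift, Mapping):
            return float(self.interaction_shift.get(mixture_label, 0.0))
        return float(self.interaction_shift)

    def expected_means(self) -> dict[str, float]:
        """Ground-truth expected mean per group under the additivity model."""
        eff = self.resolved_effects()
        means = {self.design.control_label: self.control_mean}
        for g in self.design.single_groups:
            means[g] = self.control_mean + eff[g]
        for mix, a_lab, b_lab in self.design.mixtures:
            means[mix] = (
                self.control_mean + eff[a_lab] + eff[b_lab] + self.shift_for(mix)
            )
        return means


def generate_endpoint_data(
    config: EndpointSimConfig,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Simulate one factorial endpoint experiment.

    Returns a tidy table with columns ``subject``, ``group``, ``value`` (one
    row per individual) and the truth record of per-group expected means.

    Under ``noise='normal'`` values are ``mean + control_sd * z``; under
    ``'lognormal'`` the group mean is the median and ``control_sd`` is the SD
    of log-values (multiplicative noise).
    """
    rng = np.random.default_rng(config.seed)
    means = config.expected_means()
    n = config.design.n_per_group
    rows = []
    for g in config.design.groups:
        if config.noise == "normal":
            vals = means[g] + config.control_sd * rng.standard_normal(n)
        else:
            vals = means[g] * np.exp(config.control_sd * rng.standard_normal(n))
        for i, v in enumerate(vals):
            rows.append((f"{g}~{i + 1:02d}", g, float(v)))
    table = pd.DataFrame(rows, columns=["subject", "group", "value"])
    return table, means


# ---------------------------------------------------------------------------
# Spectral-count proteome simulation


@dataclass
class PeptideCountMatrix:
    """Peptide-level spectral counts with protein map and sample design.

    ``counts`` is peptides x samples (float; NaN marks a missing cell),
    ``protein_map`` maps each peptide id to exactly one protein id, and
    ``design`` has one row per sample with columns ``sample``, ``condition``,
    ``biorep``.  ``latent`` (optional) holds the pre-integer expected
    abundance used by intensity-dependent censoring.
    """

    counts: pd.DataFrame
    protein_map: pd.Series
    design: pd.DataFrame
    latent: pd.DataFrame | None = None

    def __post_init__(self):
        from .errors import ValidationError

        missing = set(self.counts.index) - set(self.protein_map.index)
        if missing:
            raise ValidationError(
                f"peptides without protein mapping: {sorted(missing)[:5]}"
            )
        extra = set(self.counts.columns) - set(self.design["sample"])
        if extra:
            raise ValidationError(f"samples absent from design: {sorted(extra)[:5]}")
        observed = self.counts.to_numpy()
        if np.nanmin(observed, initial=0.0) < 0:
            raise ValidationError("counts must be nonnegative where observed")

    def copy(self) -> "PeptideCountMatrix":
        return PeptideCountMatrix(
            self.counts.copy(),
            self.protein_map.copy(),
            self.design.copy(),
            None if self.latent is None else self.latent.copy(),
        )

    def samples_for(self, condition: str) -> list[str]:
        d = self.design
        return list(d.loc[d["condition"] == condition, "sample"])

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.design["condition"]))


@dataclass(frozen=True)
class ProteomeSimConfig:
    """Configuration for the spectral-count generator.

    Defaults emulate a pooled-replicate label-free shotgun experiment:
    3 biological replicates per condition, peptide counts drawn from a
    negative binomial (gamma–Poisson) with moderate overdispersion, protein
    baselines lognormal across the proteome, and a shifted-geometric number
    of peptides per protein so a realistic mass of proteins sits at 1–2
    peptides (exercising the three-peptide identification rule).
    """

    n_proteins: int = 500
    peptide_geometric_p: float = 0.35
    max_peptides: int = 12
    conditions: tuple[str, ...] = ("control", "treated")
    n_reps: int = 3
    baseline_mean: float = 8.0
    baseline_log_sd: float = 1.0
    dispersion: float = 0.1
    frac_de: float = 0.0
    log2fc: float = 2.0
    mnar_quantile: float = 0.0
    mcar_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_proteins < 1:
            raise ConfigError("n_proteins: must be >= 1")
        if not 0 < self.peptide_geometric_p <= 1:
            raise ConfigError("peptide_geometric_p: must be in (0, 1]")
        if self.dispersion < 0:
            raise ConfigError("dispersion: overdispersion must be >= 0")
        for name in ("frac_de", "mnar_quantile", "mcar_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name}: proportion must be in [0, 1]")
        if self.mnar_quantile + self.mcar_rate * (1 - self.mnar_quantile) >= 1:
            raise ConfigError(
                "mnar_quantile/mcar_rate: joint missingness must be < 1"
            )
        if len(self.conditions) < 1 or self.n_reps < 1:
            raise ConfigError("conditions/n_reps: need >= 1 condition and replicate")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma–Poisson negative binomial with Var = mu + dispersion * mu^2."""
    if dispersion == 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def generate_spectral_counts(
    config: ProteomeSimConfig,
) -> tuple[PeptideCountMatrix, pd.DataFrame]:
    """Simulate a peptide x sample spectral-count matrix with DE truth.

    A random subset (``frac_de``) of proteins carries a ``log2fc`` fold
    change (random sign) in every non-control condition; all peptides of a
    protein share its fold change.  Returns the matrix and a truth table
    (``protein``, ``is_de``, ``log2fc``, ``direction``).
    """
    rng = np.random.default_rng(config.seed)
    n_prot = config.n_proteins
    proteins = np.array([f"PROT{i:05d}" for i in range(n_prot)])

    n_pep = rng.geometric(config.peptide_geometric_p, size=n_prot)
    n_pep = np.minimum(n_pep, config.max_peptides)
    pep_protein = np.repeat(proteins, n_pep)
    peptides = np.array([f"PEP{i:06d}" for i in range(len(pep_protein))])

    # protein baseline abundance, split across peptides by lognormal weights
    prot_base = config.baseline_mean * np.exp(
        config.baseline_log_sd * rng.standard_normal(n_prot)
    )
    pep_weight = np.exp(0.5 * rng.standard_normal(len(peptides)))
    pep_mean = np.repeat(prot_base, n_pep) * pep_weight

    n_de = int(round(config.frac_de * n_prot))
    de_idx = rng.choice(n_prot, size=n_de, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    prot_lfc = np.zeros(n_prot)
    prot_lfc[de_idx] = signs * config.log2fc

    samples, conds, reps = [], [], []
    for c in config.conditions:
        for r in range(1, config.n_reps + 1):
            samples.append(f"{c}_r{r}")
            conds.append(c)
            reps.append(r)
    design = pd.DataFrame({"sample": samples, "condition": conds, "biorep": reps})

    control = config.conditions[0]
    pep_lfc = np.repeat(prot_lfc, n_pep)
    latent = np.empty((len(peptides), len(samples)))
    counts = np.empty_like(latent)
    for j, cond in enumerate(conds):
        mu = pep_mean * (2.0 ** pep_lfc if cond != control else 1.0)
        # latent carries a small per-run wobble so left-censoring varies across
        # replicates; counts are drawn from the clean mean so dispersion=0
        # yields exact Poisson sampling
        latent[:, j] = mu * np.exp(0.1 * rng.standard_normal(len(peptides)))
        counts[:, j] = _nb_draw(rng, mu, config.dispersion)

    counts_df = pd.DataFrame(counts, index=peptides, columns=samples)
    latent_df = pd.DataFrame(latent, index=peptides, columns=samples)
    pmap = pd.Series(pep_protein, index=peptides, name="protein")
    matrix = PeptideCountMatrix(counts_df, pmap, design, latent_df)

    truth = pd.DataFrame(
        {
            "protein": proteins,
            "is_de": prot_lfc != 0,
            "log2fc": prot_lfc,
            "direction": np.where(prot_lfc > 0, "up", np.where(prot_lfc < 0, "down", "null")),
        }
    )
    if config.mnar_quantile > 0 or config.mcar_rate > 0:
        matrix = inject_missingness(
            matrix, config.mnar_quantile, config.mcar_rate, seed=int(rng.integers(2**31))
        )
    return matrix, truth


def inject_missingness(
    matrix: PeptideCountMatrix,
    mnar_quantile: float,
    mcar_rate: float,
    seed: int,
) -> PeptideCountMatrix:
    """Apply intensity-dependent left-censoring (MNAR) then random dropout.

    MNAR: within each sample, cells whose *latent* abundance falls strictly
    below that sample's ``mnar_quantile`` quantile of latent abundance are
    set missing (the latent, pre-integer scale keeps the threshold
    well-defined when counts are tied; when no latent matrix is attached the
    observed counts are used with an infinitesimal random tie-break).
    MCAR: each surviving cell is additionally dropped with probability
    ``mcar_rate``.  Observed cells are never altered.
    """
    for name, v in (("mnar_quantile", mnar_quantile), ("mcar_rate", mcar_rate)):
        if not 0 <= v <= 1:
            raise ConfigError(f"{name}: must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = matrix.copy()
    vals = out.counts.to_numpy(dtype=float)
    if out.latent is not None:
        latent = out.latent.to_numpy(dtype=float)
    else:
        latent = vals + rng.uniform(0, 1e-9, size=vals.shape)
    mask = np.zeros(vals.shape, dtype=bool)
    if mnar_quantile > 0:
        thresh = np.nanquantile(latent, mnar_quantile, axis=0, keepdims=True)
        mask |= latent < thresh
    if mcar_rate > 0:
        mask |= rng.random(vals.shape) < mcar_rate
    vals[mask] = np.nan
    out.counts = pd.DataFrame(vals, index=out.counts.index, columns=out.counts.columns)
    return out


def generate_annotation(
    n_proteins: int | Sequence[str],
    n_terms: int,
    term_size_range: tuple[int, int] = (5, 50),
    enriched_term_spec: Mapping | None = None,
    seed: int = 0,
):
    """Random flat term -> protein-set annotation map with optional planting.

    ``enriched_term_spec`` plants one extra term overrepresented in a
    candidate set: keys ``candidates`` (protein ids), ``frac_candidates``
    (annotation probability inside the set, default 0.8) and
    ``frac_background`` (outside, default 0.1).
    """
    from .enrichment import AnnotationMap

    if isinstance(n_proteins, int):
        universe = [f"PROT{i:05d}" for i in range(n_proteins)]
    else:
        universe = list(n_proteins)
    lo, hi = term_size_range
    if lo < 1 or hi < lo:
        raise ConfigError("term_size_range: need 1 <= lo <= hi")
    if hi > len(universe):
        raise ConfigError("term_size_range: term sizes cannot exceed the universe")
    rng = np.random.default_rng(seed)
    arr = np.array(universe)
    terms: dict[str, frozenset] = {}
    names: dict[str, str] = {}
    for t in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        tid = f"TERM:{t:04d}"
        terms[tid] = frozenset(rng.choice(arr, size=size, replace=False))
        names[tid] = f"random term {t}"
    if enriched_term_spec is not None:
        cand = set(enriched_term_spec["candidates"])
        bad = cand - set(universe)
        if bad:
            raise ConfigError(f"enriched_term_spec: candidates outside universe {sorted(bad)[:5]}")
        p_in = float(enriched_term_spec.get("frac_candidates", 0.8))
        p_out = float(enriched_term_spec.get("frac_background", 0.1))
        members = {
            p
            for p in universe
            if rng.random() < (p_in if p in cand else p_out)
        }
        if not members:
            members = set(rng.choice(sorted(cand), size=1))
        tid = enriched_term_spec.get("term_id", "TERM:PLANTED")
        terms[tid] = frozenset(members)
        names[tid] = "planted enriched term"
    return AnnotationMap(terms=terms, names=names, universe=frozenset(universe))
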