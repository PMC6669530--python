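"""End-to-end pipeline driver: configuration, seeding, orchestration.

A single global seed determines every random stream; each stage derives an
independent substream from (seed, stage name), so toggling one stage never
shifts another stage's randomness.  Identical (config, inputs) produce
byte-identical outputs, recorded in a run manifest with input checksums.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .endpoint_stats import (
    apply_transform_policy,
    compact_letter_display,
    kruskal_wallis,
    one_way_anova,
    summarize_groups,
    tukey_hsd,
)
from .enrichment import enrich
from .errors import ConfigError, StageError, ValidationError
from .interaction import interaction_table
from .io import (
    read_count_matrix,
    read_endpoint_table,
    read_gmt,
    write_count_matrix,
    write_endpoint_table,
)
from .proteomics import (
    aggregate_peptides,
    de_test,
    filter_min_peptides,
    filter_replicate_presence,
    impute_mixed,
    overlap_analysis,
    spectral_index,
    vsn_normalize,
)
from .synthetic import (
    EndpointSimConfig,
    ExposureDesign,
    ProteomeSimConfig,
    generate_annotation,
    generate_endpoint_data,
    generate_spectral_counts,
)

__all__ = ["PipelineConfig", "derive_seed", "run_pipeline"]


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage substream seed (< 2^31) from the global seed."""
    digest = hashlib.blake2b(f"{global_seed}:{stage}".encode(), digest_size=8).digest()
    return int.from_bytes(digest, "big") % (2**31)


@dataclass
class PipelineConfig:
    """Serializable pipeline configuration.

    Stage parameter dicts accept either simulation parameters (the default)
    or input paths (``table`` for the endpoint stage; ``matrix``, ``map``,
    ``design`` for proteomics; ``gmt`` for enrichment).
    """

    seed: int = 0
    outdir: str = "mixtox_out"
    stages: dict = field(
        default_factory=lambda: {"endpoint": True, "proteomics": True, "enrichment": True}
    )
    endpoint: dict = field(default_factory=dict)
    proteomics: dict = field(default_factory=dict)
    enrichment: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**d)

    def save(self, path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
        return cls.from_dict(data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _endpoint_stage(cfg: PipelineConfig, outdir: Path, manifest: dict) -> dict:
    params = dict(cfg.endpoint)
    seed = derive_seed(cfg.seed, "endpoint")
    alpha = float(params.pop("alpha", 0.05))
    gate_alpha = float(params.pop("gate_alpha", 0.05))
    n_mc = int(params.pop("n_mc", 2000))
    design_params = params.pop("design", {})
    design = ExposureDesign(**design_params)
    if "table" in params:
        src = Path(params.pop("table"))
        manifest["inputs"][str(src)] = _sha256(src)
        table = read_endpoint_table(src, known_groups=design.groups)
        truth = None
    else:
        sim = EndpointSimConfig(design=design, seed=seed, **params)
        table, truth = generate_endpoint_data(sim)
        write_endpoint_table(table, outdir / "endpoint_table.tsv")
        (outdir / "endpoint_truth.json").write_text(json.dumps(truth, indent=2))

    summary = summarize_groups(table)
    summary.to_csv(outdir / "group_summary.tsv", sep="\t", index=False)

    work_table, record = apply_transform_policy(
        table, alpha_gate=gate_alpha, n_mc=n_mc, seed=derive_seed(cfg.seed, "endpoint-gate")
    )
    labels = list(dict.fromkeys(work_table["group"]))
    groups = [work_table.loc[work_table["group"] == g, "value"].to_numpy() for g in labels]
    tests: dict = {
        "branch": record.branch,
        "transform": record.transform,
        "normality_p": record.normality_p,
        "bartlett_p": record.bartlett_p,
        "warnings": record.warnings,
    }
    if record.branch in ("raw-ANOVA", "ln-ANOVA"):
        omni = one_way_anova(groups)
        tests["anova"] = {"F": omni.statistic, "p": omni.pvalue, "df": omni.df}
        if omni.pvalue < alpha:
            pairs = tukey_hsd(groups, alpha=alpha)
            pairs.to_csv(outdir / "tukey_pairs.tsv", sep="\t", index=False)
            tests["letters"] = compact_letter_display(pairs, labels=labels)
    else:
        omni = kruskal_wallis(groups)
        tests["kruskal"] = {"H": omni.statistic, "p": omni.pvalue, "df": omni.df}
    (outdir / "endpoint_tests.json").write_text(json.dumps(tests, indent=2, default=float))

    itable = interaction_table(summary, design, alpha=alpha)
    itable.to_csv(outdir / "interaction_table.tsv", sep="\t", index=False)
    return {"summary": summary, "tests": tests, "interaction": itable, "truth": truth}


def _proteomics_stage(cfg: PipelineConfig, outdir: Path, manifest: dict) -> dict:
    params = dict(cfg.proteomics)
    seed = derive_seed(cfg.seed, "proteomics")
    min_peptides = int(params.pop("min_peptides", 3))
    min_bioreps = int(params.pop("min_bioreps", 3))
    alpha = float(params.pop("alpha", 0.05))
    fdr = float(params.pop("fdr", 0.01))
    knn_k = int(params.pop("knn_k", 10))
    qrilc_q = float(params.pop("qrilc_q", 0.01))
    if "matrix" in params:
        paths = [Path(params.pop(k)) for k in ("matrix", "map", "design")]
        for p in paths:
            manifest["inputs"][str(p)] = _sha256(p)
        matrix = read_count_matrix(*paths)
        truth = None
    else:
        sim = ProteomeSimConfig(seed=seed, **params)
        matrix, truth = generate_spectral_counts(sim)
        write_count_matrix(
            matrix,
            outdir / "peptide_counts.tsv",
            outdir / "peptide_map.tsv",
            outdir / "sample_design.tsv",
        )
        truth.to_csv(outdir / "proteome_truth.tsv", sep="\t", index=False)

    filtered, audit = filter_min_peptides(matrix, min_peptides=min_peptides)
    audit.to_csv(outdir / "peptide_filter_audit.tsv", sep="\t", index=False)
    protein = aggregate_peptides(filtered)
    protein = filter_replicate_presence(protein, min_bioreps=min_bioreps)
    normalized = vsn_normalize(protein)
    imputed = impute_mixed(
        normalized, k=knn_k, qrilc_quantile=qrilc_q,
        seed=derive_seed(cfg.seed, "proteomics-impute"),
    )
    imputed.values.to_csv(outdir / "protein_matrix_glog.tsv", sep="\t", na_rep="NA")
    imputed.provenance.to_csv(outdir / "protein_provenance.tsv", sep="\t")
    si = spectral_index(protein)
    si.to_csv(outdir / "spectral_index.tsv", sep="\t")

    control = protein.conditions[0]
    de_results = {}
    candidate_sets = {}
    for cond in protein.conditions[1:]:
        res = de_test(protein, (control, cond), alpha=alpha, fdr=fdr)
        safe = cond.replace("/", "_")
        res.to_csv(outdir / f"de_{safe}.tsv", sep="\t", index=False)
        de_results[cond] = res
        candidate_sets[cond] = set(res.loc[res["candidate"], "protein"])
    overlap = overlap_analysis(candidate_sets) if len(candidate_sets) >= 2 else None
    if overlap is not None:
        (outdir / "overlap.json").write_text(json.dumps(overlap, indent=2))
    return {
        "matrix": protein,
        "imputed": imputed,
        "de": de_results,
        "candidates": candidate_sets,
        "overlap": overlap,
        "truth": truth,
    }


def _enrichment_stage(
    cfg: PipelineConfig, outdir: Path, manifest: dict, proteomics_out: dict | None
) -> dict:
    params = dict(cfg.enrichment)
    n_perm = int(params.pop("n_perm", 1000))
    min_term_size = int(params.pop("min_term_size", 3))
    if proteomics_out is None:
        raise ValidationError("enrichment stage requires the proteomics stage")
    universe = list(proteomics_out["matrix"].values.index)
    if "gmt" in params:
        src = Path(params.pop("gmt"))
        manifest["inputs"][str(src)] = _sha256(src)
        annotation = read_gmt(src).restricted_to(universe)
    else:
        annotation = generate_annotation(
            universe,
            n_terms=int(params.pop("n_terms", 50)),
            term_size_range=tuple(params.pop("term_size_range", (5, 50))),
            seed=derive_seed(cfg.seed, "enrichment-annotation"),
        )
    results = {}
    for cond, candidates in proteomics_out["candidates"].items():
        if not candidates:
            continue
        res = enrich(
            candidates,
            annotation,
            n_perm=n_perm,
            min_term_size=min_term_size,
            seed=derive_seed(cfg.seed, f"enrichment-{cond}"),
        )
        res.to_csv(outdir / f"enrichment_{cond.replace('/', '_')}.tsv", sep="\t", index=False)
        results[cond] = res
    return {"annotation": annotation, "results": results}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages in fixed order and write a report bundle.

    Returns a dict of in-memory stage outputs; all artifacts (tables,
    manifest, summary) land under ``config.outdir``.  A stage failure
    raises :class:`StageError` naming the stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "mixtox",
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": {},
        "config": config.to_dict(),
        "inputs": {},
        "outputs": [],
    }
    bundle: dict = {}
    stage_fns = [
        ("endpoint", lambda: _endpoint_stage(config, outdir, manifest)),
        ("proteomics", lambda: _proteomics_stage(config, outdir, manifest)),
        (
            "enrichment",
            lambda: _enrichment_stage(config, outdir, manifest, bundle.get("proteomics")),
        ),
    ]
    for name, fn in stage_fns:
        if not config.stages.get(name, False):
            continue
        manifest["stage_seeds"][name] = derive_seed(config.seed, name)
        try:
            bundle[name] = fn()
        except (ConfigError, ValidationError):
            raise
        except Exception as exc:
            raise StageError(name, str(exc)) from exc

    manifest["outputs"] = sorted(
        str(p.relative_to(outdir)) for p in outdir.glob("*") if p.name != "manifest.json"
    )
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    _write_summary(outdir, bundle)
    return bundle


def _write_summary(outdir: Path, bundle: dict) -> None:
    lines = ["mixtox run summary", "=================="]
    if "endpoint" in bundle:
        ep = bundle["endpoint"]
        lines.append(f"endpoint branch: {ep['tests']['branch']}")
        for _, row in ep["interaction"].iterrows():
            star = " *" if row["significant"] else ""
            lines.append(
                f"  {row['treatment']}: IF = {row['IF']:.2f} ± {row['halfwidth']:.2f}{star}"
                f" -> {row['label']}"
            )
    if "proteomics" in bundle:
        pr = bundle["proteomics"]
        for cond, res in pr["de"].items():
            lines.append(
                f"proteomics {cond}: {int(res['candidate'].sum())} candidate (p<0.05), "
                f"{int(res['confirmed'].sum())} confirmed (q<0.01) of {int(res['tested'].sum())} tested"
            )
        if pr["overlap"] is not None:
            lines.append(
                f"mean pairwise DE overlap: {pr['overlap']['mean_pairwise_percent']:.1f}%"
            )
    if "enrichment" in bundle:
        for cond, res in bundle["enrichment"]["results"].items():
            n_sig = int((res["qvalue"] < 0.05).sum()) if len(res) else 0
            lines.append(f"enrichment {cond}: {n_sig} terms at q < 0.05")
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")
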