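"""One reproducible run: simulate (or load) -> methylation -> expression ->
integrate -> enrich, with a flat config, stage logging, and a summary.

A single pipeline-level seed fans out to the per-stage generators by fixed
offsets (universe +0, planted effects +1, male/female methylation arrays
+2/+3, male/female expression arrays +4/+5, annotations +6), so one integer
reproduces the whole run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import expression as expr_mod
from . import integration, methylation, synthgen
from .enrichment import run_enrichment
from .errors import ValidationError
from .io_formats import (
    read_expression,
    read_gene2go,
    read_mesh_table,
    read_probe_signals,
    write_annotation,
    write_expression,
    write_probe_signals,
)
from .synthgen import NoiseModel, write_truth

logger = logging.getLogger(__name__)

COUPLED_CLASSES = ("up_demethylated", "down_methylated")


@dataclass
class RunConfig:
    """Flat configuration of one pipeline run (thresholds, simulation, paths)."""

    # flagging thresholds
    up: float = 1.5
    down: float = 0.67
    probe_p: float = 0.05
    # extraction filters for over-representation
    min_ef: float = 2.0
    min_nf: int = 5
    max_p: float = 0.05
    # reproducibility and scale
    seed: int = 0
    sexes: tuple[str, ...] = ("male", "female")
    # simulation parameters (used when no input paths are given)
    n_genes: int = 1000
    max_probes_per_island: int = 6
    frac_coupled: float = 0.1
    frac_meth_only: float = 0.05
    frac_expr_only: float = 0.05
    effect_fold: float = 2.0
    log_sigma: float = 0.1
    p_detect_fail: float = 0.02
    n_categories: int = 50
    n_enriched: int = 5
    # optional pre-existing inputs: {sex: path}
    meth_paths: dict = field(default_factory=dict)
    expr_paths: dict = field(default_factory=dict)
    annotation_path: str | None = None
    annotation_vocab: str = "GO"
    outdir: str | None = None

    def __post_init__(self) -> None:
        if not (self.up > 1 > self.down > 0):
            raise ValidationError(f"need up > 1 > down > 0, got {self.up}, {self.down}")
        for name in ("probe_p", "min_ef", "min_nf", "max_p"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"filter value {name} must be positive")
        self.sexes = tuple(self.sexes)
        unknown = set(self.sexes) - set(synthgen.SEXES)
        if unknown:
            raise ValidationError(f"unknown sex label(s): {sorted(unknown)}")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load a flat key-value YAML config; unknown keys are rejected."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sexes"] = list(self.sexes)
        return d


def _simulate_inputs(config: RunConfig):
    universe = synthgen.generate_universe(
        config.n_genes, config.max_probes_per_island, seed=config.seed
    )
    truth = synthgen.plant_effects(
        universe,
        frac_coupled=config.frac_coupled,
        frac_meth_only=config.frac_meth_only,
        frac_expr_only=config.frac_expr_only,
        effect_fold=config.effect_fold,
        n_categories=config.n_categories,
        n_enriched=config.n_enriched,
        seed=config.seed + 1,
    )
    noise = NoiseModel(log_sigma_signal=config.log_sigma, p_detect_fail=config.p_detect_fail)
    meth, expr = {}, {}
    for i, sex in enumerate(synthgen.SEXES):
        if sex not in config.sexes:
            continue
        meth[sex] = synthgen.simulate_methylation_array(
            universe, truth, noise, seed=config.seed + 2 + i, sex=sex
        )
        expr[sex] = synthgen.simulate_expression_array(
            universe, truth, noise, seed=config.seed + 4 + i, sex=sex
        )
    annotation = synthgen.generate_annotations(universe, truth, seed=config.seed + 6)
    return universe, truth, meth, expr, annotation


def _load_inputs(config: RunConfig):
    meth = {sex: read_probe_signals(config.meth_paths[sex]) for sex in config.sexes}
    expr = {sex: read_expression(config.expr_paths[sex]) for sex in config.sexes}
    if config.annotation_path is None:
        annotation = None
    elif config.annotation_vocab == "MeSH":
        annotation = read_mesh_table(config.annotation_path)
    else:
        annotation = read_gene2go(config.annotation_path)
    return meth, expr, annotation


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the summary dict.

    When ``config.outdir`` is set, all stage outputs (tables, truth,
    annotation, enrichment, resolved config, summary) are written there.
    """
    simulate = not config.meth_paths
    truth = None
    if simulate:
        universe, truth, meth_tables, expr_tables, annotation = _simulate_inputs(config)
        array_genes = universe.accessions
    else:
        if set(config.meth_paths) != set(config.sexes) or set(config.expr_paths) != set(
            config.sexes
        ):
            raise ValidationError("meth_paths and expr_paths must cover every configured sex")
        meth_tables, expr_tables, annotation = _load_inputs(config)
        array_genes = set()
        for t in meth_tables.values():
            array_genes |= set(t["accession"])
        for t in expr_tables.values():
            array_genes |= set(t["accession"])

    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
        if simulate:
            write_truth(truth, outdir / "truth.tsv")
            write_annotation(annotation, outdir / "annotation.tsv")

    summary: dict = {"seed": config.seed, "sexes": {}}
    integrated_by_sex = {}
    for sex in config.sexes:
        probes = meth_tables[sex]
        logger.info("[%s] methylation probes in: %d", sex, len(probes))
        kept = methylation.filter_probes(probes, config.probe_p)
        logger.info("[%s] probes after detection/background filter: %d", sex, len(kept))
        probe_results = methylation.methylation_fold_ratio(kept, config.up, config.down)
        calls = methylation.collapse_to_genes(probe_results)
        tally = methylation.tally_by_chromosome(calls)

        expr_probes = expr_mod.expression_fold_change(expr_tables[sex], config.up, config.down)
        expr_genes = expr_mod.collapse_expression_to_genes(expr_probes)
        logger.info(
            "[%s] expression probes: %d -> genes: %d", sex, len(expr_probes), len(expr_genes)
        )

        integrated = integration.join_and_classify(calls, expr_genes, sex)
        venn = integration.venn_counts(integrated)
        integrated_by_sex[sex] = integrated

        flagged = set(
            integrated.loc[
                integrated["integration_class"].isin(COUPLED_CLASSES), "accession"
            ]
        )
        enrich = None
        if annotation is not None:
            enrich = run_enrichment(
                flagged & array_genes,
                annotation,
                array_genes,
                min_ef=config.min_ef,
                min_nf=config.min_nf,
                max_p=config.max_p,
            )

        summary["sexes"][sex] = {
            "probes_total": int(len(probes)),
            "probes_filtered": int(len(kept)),
            "probes_increased": int((probe_results["direction"] == "increased").sum()),
            "probes_decreased": int((probe_results["direction"] == "decreased").sum()),
            "genes_meth_increased": int(calls["call"].isin(["increased", "both"]).sum()),
            "genes_meth_decreased": int(calls["call"].isin(["decreased", "both"]).sum()),
            "genes_expr_up": int(expr_genes["regulation"].isin(["up", "both"]).sum()),
            "genes_expr_down": int(expr_genes["regulation"].isin(["down", "both"]).sum()),
            "venn": venn,
            "n_flagged_coupled": len(flagged),
            "categories_passing": int(enrich["passes"].sum()) if enrich is not None else None,
        }

        if outdir:
            write_probe_signals(probes, outdir / f"probes_{sex}.tsv")
            write_expression(expr_tables[sex], outdir / f"expression_{sex}.tsv")
            calls.to_csv(outdir / f"meth_calls_{sex}.tsv", sep="\t", index=False)
            tally.to_csv(outdir / f"chrom_tally_{sex}.tsv", sep="\t", index=False)
            expr_genes.to_csv(outdir / f"expr_genes_{sex}.tsv", sep="\t", index=False)
            integrated.to_csv(outdir / f"integrated_{sex}.tsv", sep="\t", index=False)
            if enrich is not None:
                enrich.to_csv(outdir / f"enrichment_{sex}.tsv", sep="\t", index=False)

    if len(config.sexes) == 2:
        summary["cross_sex"] = {
            cls: integration.cross_sex_overlap(
                integrated_by_sex["male"], integrated_by_sex["female"], cls
            )
            for cls in COUPLED_CLASSES
        }

    if outdir:
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
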