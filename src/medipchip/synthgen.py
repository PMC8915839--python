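"""Seeded simulator for CpG-island methylation and expression arrays.

The generator emulates the statistical structure the downstream analysis
assumes, at desk scale: a universe of genes (CpG islands) spread over the 21
mouse chromosome labels, several methylation probes per island mapping
many-to-one onto genes via accessions, a one-color expression array with one
or two probes per gene, planted multiplicative effects per gene and sex, and
a category annotation whose "enriched" categories preferentially contain the
coupled genes.

The effect classes mirror the coupling the integrated analysis looks for:
*coupled-up* genes are demethylated and upregulated, *coupled-down* genes are
methylated and downregulated; *meth-only* and *expr-only* genes perturb one
layer; the rest are null.

Signal model (per probe and group): the input channel is log-normal around a
baseline intensity; the IP channel is the input times a per-gene baseline
methylation level (log-uniform in [0.2, 5], so both directions of change are
observable), times the planted effect in the exposed group, times
independent log-normal noise.  With ``log_sigma_signal = 0`` the fold ratio
of every probe equals the planted effect exactly, which is what makes the
noiseless-faithfulness tests possible.  The default universe is 1,000 genes
(~4,000 methylation probes), a scaled-down stand-in for a 15,342-island /
~88,000-probe array.

Not modelled: sequence-level chemistry, dye bias, spatial artifacts, and
litter structure.  One pooled signal per group and sex is generated,
matching a pooled-sample design with no biological replication.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import CHROMOSOMES, CategoryAnnotation

SEXES = ("male", "female")

#: Per-gene baseline methylation (IP/input ratio) is log-uniform over this range.
BASELINE_METH_RANGE = (0.2, 5.0)

EFFECT_CLASSES = ("coupled_up", "coupled_down", "meth_only", "expr_only", "null")

TRUTH_COLUMNS = ["accession", "sex", "effect_class", "meth_effect", "expr_effect", "coupled"]


@dataclass(frozen=True)
class NoiseModel:
    """Noise and detection parameters of the simulated arrays.

    log_sigma_signal: SD of multiplicative log-normal intensity noise (natural log).
    baseline_mu: location of log-normal baseline intensities (log fluorescence units).
    background_level: intensity at or below which a channel is "at background".
    p_detect_fail: probability that a probe's detection p-value exceeds 0.05.
    """

    log_sigma_signal: float = 0.1
    baseline_mu: float = math.log(1000.0)
    background_level: float = 100.0
    p_detect_fail: float = 0.02

    def __post_init__(self) -> None:
        for name in ("log_sigma_signal", "baseline_mu", "background_level", "p_detect_fail"):
            if getattr(self, name) < 0:
                raise ValidationError(f"NoiseModel.{name} must be non-negative")
        if not 0 <= self.p_detect_fail <= 1:
            raise ValidationError("p_detect_fail must be a probability")
        if self.background_level >= math.exp(self.baseline_mu):
            raise ValidationError("background_level must lie below the baseline intensity")


@dataclass(frozen=True)
class GeneUniverse:
    """The simulated array design: one row per gene/CpG island."""

    genes: pd.DataFrame  # accession, symbol, chromosome, island_start, island_end,
    #                      n_meth_probes, n_expr_probes

    def __post_init__(self) -> None:
        g = self.genes
        if g["accession"].duplicated().any() or g["symbol"].duplicated().any():
            raise ValidationError("accessions and symbols must be unique in a universe")
        if (g["island_end"] <= g["island_start"]).any():
            raise ValidationError("island_end must exceed island_start")
        if (g["n_meth_probes"] < 1).any() or (g["n_expr_probes"] < 1).any():
            raise ValidationError("every gene needs >= 1 probe on each array")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def accessions(self) -> set[str]:
        return set(self.genes["accession"])

    @property
    def total_meth_probes(self) -> int:
        return int(self.genes["n_meth_probes"].sum())


@dataclass(frozen=True)
class TruthRecord:
    """Planted ground truth: per-gene, per-sex effects plus category structure.

    ``category_cores`` maps each enriched category id to the member genes
    that were over-sampled into the coupled classes (in both sexes), so the
    downstream annotation can realise the planted enrichment.
    """

    effects: pd.DataFrame  # TRUTH_COLUMNS
    category_ids: tuple[str, ...]
    enriched_categories: frozenset[str] = field(default_factory=frozenset)
    category_cores: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        e = self.effects
        if (e["meth_effect"] <= 0).any() or (e["expr_effect"] <= 0).any():
            raise ValidationError("planted effects must be strictly positive")
        coupled = e[e["coupled"]]
        ok = ((coupled["meth_effect"] < 1) & (coupled["expr_effect"] > 1)) | (
            (coupled["meth_effect"] > 1) & (coupled["expr_effect"] < 1)
        )
        if not ok.all():
            raise ValidationError("coupled genes must perturb the two layers in opposition")

    def for_sex(self, sex: str) -> pd.DataFrame:
        if sex not in SEXES:
            raise ValidationError(f"sex must be one of {SEXES}, got {sex!r}")
        return self.effects[self.effects["sex"] == sex].set_index("accession")


def generate_universe(
    n_genes: int, max_probes_per_island: int = 6, seed: int = 0
) -> GeneUniverse:
    """Build a deterministic universe of ``n_genes`` genes.

    Chromosome labels cycle through chr1..chr19, chrX, chrY so every label is
    populated once ``n_genes >= 21``; methylation probe counts per island are
    uniform on [1, max_probes_per_island]; expression probe counts are 1 or 2.
    """
    if n_genes < 1:
        raise ValidationError(f"n_genes must be positive, got {n_genes}")
    if max_probes_per_island < 1:
        raise ValidationError("max_probes_per_island must be positive")
    rng = np.random.default_rng(seed)
    idx = np.arange(n_genes)
    starts = rng.integers(10_000, 100_000_000, size=n_genes)
    lengths = rng.integers(200, 2_000, size=n_genes)
    genes = pd.DataFrame(
        {
            "accession": [f"NM_{100000 + i:06d}" for i in idx],
            "symbol": [f"Syng{i:04d}" for i in idx],
            "chromosome": [CHROMOSOMES[i % len(CHROMOSOMES)] for i in idx],
            "island_start": starts,
            "island_end": starts + lengths,
            "n_meth_probes": rng.integers(1, max_probes_per_island + 1, size=n_genes),
            "n_expr_probes": rng.integers(1, 3, size=n_genes),
        }
    )
    return GeneUniverse(genes)


def plant_effects(
    universe: GeneUniverse,
    frac_coupled: float = 0.1,
    frac_meth_only: float = 0.05,
    frac_expr_only: float = 0.05,
    effect_fold: float = 2.0,
    n_categories: int = 50,
    n_enriched: int = 5,
    seed: int = 0,
    enriched_core_size: int = 12,
    core_coupled_prob: float = 0.9,
) -> TruthRecord:
    """Assign each gene, per sex, to exactly one effect class and plant folds.

    Coupled genes split evenly between coupled-up (meth 1/fold, expr fold)
    and coupled-down (meth fold, expr 1/fold); single-layer genes get the
    fold or its reciprocal with equal probability; null genes get 1.0 on
    both layers.

    Each of the first ``n_enriched`` of ``n_categories`` category ids owns a
    disjoint core of ``enriched_core_size`` genes; core genes enter the
    coupled classes with probability ``core_coupled_prob`` in *each* sex (up
    to the per-sex coupled budget ``round(frac_coupled * n_genes)``), with
    the remaining coupled slots drawn from non-core genes.  This is what
    makes the enriched categories recoverable per sex downstream.
    """
    fracs = (frac_coupled, frac_meth_only, frac_expr_only)
    if any(f < 0 for f in fracs) or sum(fracs) > 1 + 1e-12:
        raise ValidationError(f"class fractions must be non-negative and sum <= 1, got {fracs}")
    if effect_fold <= 1:
        raise ValidationError(f"effect_fold must exceed 1, got {effect_fold}")
    if n_categories < 1 or n_enriched < 0 or n_enriched > n_categories:
        raise ValidationError("need n_categories >= 1 and 0 <= n_enriched <= n_categories")

    rng = np.random.default_rng(seed)
    n = universe.n_genes
    accessions = universe.genes["accession"].to_numpy()
    n_coupled = int(round(frac_coupled * n))
    n_meth = int(round(frac_meth_only * n))
    n_expr = int(round(frac_expr_only * n))

    category_ids = tuple(f"SYN:{i:04d}" for i in range(n_categories))
    enriched = category_ids[:n_enriched]
    core_size = min(enriched_core_size, n // max(n_enriched, 1))
    core_pool = (
        rng.choice(accessions, size=n_enriched * core_size, replace=False)
        if n_enriched and core_size
        else np.array([], dtype=object)
    )
    cores = {
        cid: tuple(core_pool[i * core_size : (i + 1) * core_size])
        for i, cid in enumerate(enriched)
    }
    acc_index = {a: i for i, a in enumerate(accessions)}
    core_idx = np.array([acc_index[a] for a in core_pool], dtype=int)

    rows = []
    for sex in SEXES:
        # core genes enter the coupled class first, then fill from the rest
        core_hit = core_idx[rng.random(len(core_idx)) < core_coupled_prob]
        core_hit = rng.permutation(core_hit)[:n_coupled]
        rest = np.setdiff1d(np.arange(n), core_idx, assume_unique=False)
        missed_core = np.setdiff1d(core_idx, core_hit, assume_unique=False)
        fill_pool = np.concatenate([rng.permutation(rest), rng.permutation(missed_core)])
        n_fill = n_coupled - len(core_hit)
        coupled_idx = np.concatenate([core_hit, fill_pool[:n_fill]]).astype(int)
        remaining = rng.permutation(fill_pool[n_fill:]).astype(int)
        meth_idx = remaining[:n_meth]
        expr_idx = remaining[n_meth : n_meth + n_expr]
        klass = np.full(n, "null", dtype=object)
        # alternate coupled directions so cores mix demethylated and methylated genes
        klass[coupled_idx[0::2]] = "coupled_up"
        klass[coupled_idx[1::2]] = "coupled_down"
        klass[meth_idx] = "meth_only"
        klass[expr_idx] = "expr_only"
        meth = np.ones(n)
        expr = np.ones(n)
        meth[klass == "coupled_up"] = 1.0 / effect_fold
        expr[klass == "coupled_up"] = effect_fold
        meth[klass == "coupled_down"] = effect_fold
        expr[klass == "coupled_down"] = 1.0 / effect_fold
        signs = rng.random(n) < 0.5
        meth[klass == "meth_only"] = np.where(signs, effect_fold, 1.0 / effect_fold)[
            klass == "meth_only"
        ]
        expr[klass == "expr_only"] = np.where(signs, effect_fold, 1.0 / effect_fold)[
            klass == "expr_only"
        ]
        for i in range(n):
            rows.append(
                (
                    accessions[i],
                    sex,
                    klass[i],
                    float(meth[i]),
                    float(expr[i]),
                    klass[i] in ("coupled_up", "coupled_down"),
                )
            )
    effects = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    return TruthRecord(
        effects=effects,
        category_ids=category_ids,
        enriched_categories=frozenset(enriched),
        category_cores=cores,
    )


def _check_coverage(universe: GeneUniverse, truth: TruthRecord) -> None:
    missing = universe.accessions - set(truth.effects["accession"])
    if missing:
        raise ValidationError(f"truth does not cover gene(s): {sorted(missing)[:5]}")


def simulate_methylation_array(
    universe: GeneUniverse,
    truth: TruthRecord,
    noise: NoiseModel,
    seed: int = 0,
    sex: str = "male",
) -> pd.DataFrame:
    """Simulate the two-color probe-signal table for one sex.

    Each probe gets independent log-normal input (Cy3) draws per group; the
    IP channel (Cy5) is input x per-gene baseline methylation x planted
    effect (exposed group only) x log-normal noise.  Detection p-values fall
    below 0.05 except with probability ``p_detect_fail``; above-background
    flags require both channels of a group to exceed ``background_level``.
    """
    _check_coverage(universe, truth)
    per_sex = truth.for_sex(sex)
    rng = np.random.default_rng(seed)
    sigma = noise.log_sigma_signal
    genes = universe.genes
    baseline_meth = np.exp(
        rng.uniform(
            math.log(BASELINE_METH_RANGE[0]), math.log(BASELINE_METH_RANGE[1]), universe.n_genes
        )
    )
    rows = []
    for gi, gene in enumerate(genes.itertuples(index=False)):
        effect = float(per_sex.loc[gene.accession, "meth_effect"])
        n_probes = int(gene.n_meth_probes)
        span = max(int(gene.island_end - gene.island_start) - 45, 1)
        offsets = np.sort(rng.integers(0, span, size=n_probes))
        for j in range(n_probes):
            start = int(gene.island_start) + int(offsets[j])
            locus = f"{gene.chromosome}:{start}-{start + 44}"
            channels = {}
            for group, grp_effect in (("sham", 1.0), ("exposed", effect)):
                cy3 = math.exp(rng.normal(noise.baseline_mu, sigma))
                cy5 = cy3 * baseline_meth[gi] * grp_effect * math.exp(rng.normal(0.0, sigma))
                channels[group] = (cy3, cy5)
            fail = rng.random() < noise.p_detect_fail
            detect_p = rng.uniform(0.05, 1.0) if fail else rng.uniform(0.0, 0.05)
            rows.append(
                (
                    f"{gene.accession}_M{j:02d}",
                    gene.accession,
                    gene.symbol,
                    locus,
                    channels["sham"][0],
                    channels["sham"][1],
                    channels["exposed"][0],
                    channels["exposed"][1],
                    detect_p,
                    min(channels["sham"]) > noise.background_level,
                    min(channels["exposed"]) > noise.background_level,
                )
            )
    from .io_formats import PROBE_SIGNAL_COLUMNS

    return pd.DataFrame(rows, columns=PROBE_SIGNAL_COLUMNS)


def simulate_expression_array(
    universe: GeneUniverse,
    truth: TruthRecord,
    noise: NoiseModel,
    seed: int = 0,
    sex: str = "male",
) -> pd.DataFrame:
    """Simulate the one-color expression table for one sex.

    Each probe draws one baseline intensity shared by the two groups, then
    multiplies in the planted expression effect (exposed group) and
    independent log-normal noise per group — so at zero noise the per-probe
    fold change equals the planted effect exactly.
    """
    _check_coverage(universe, truth)
    per_sex = truth.for_sex(sex)
    rng = np.random.default_rng(seed)
    sigma = noise.log_sigma_signal
    rows = []
    for gene in universe.genes.itertuples(index=False):
        effect = float(per_sex.loc[gene.accession, "expr_effect"])
        for j in range(int(gene.n_expr_probes)):
            base = math.exp(rng.normal(noise.baseline_mu, sigma))
            i_sham = base * math.exp(rng.normal(0.0, sigma))
            i_exposed = base * effect * math.exp(rng.normal(0.0, sigma))
            rows.append(
                (f"{gene.accession}_E{j:02d}", gene.accession, gene.symbol, i_sham, i_exposed)
            )
    from .io_formats import EXPRESSION_COLUMNS

    return pd.DataFrame(rows, columns=EXPRESSION_COLUMNS)


def generate_annotations(
    universe: GeneUniverse,
    truth: TruthRecord,
    genes_per_category_range: tuple[int, int] = (10, 40),
    seed: int = 0,
) -> CategoryAnnotation:
    """Assign genes to the truth's categories, concentrating coupled genes
    in the enriched ones.

    Every category receives at least one member.  Non-enriched categories
    sample members uniformly from the universe; an enriched category
    consists of its coupled core (see :func:`plant_effects`) topped up with
    uniform draws to the drawn size.
    """
    _check_coverage(universe, truth)
    lo, hi = genes_per_category_range
    if lo < 1 or hi < lo:
        raise ValidationError(f"invalid genes_per_category_range {genes_per_category_range}")
    rng = np.random.default_rng(seed)
    accessions = universe.genes["accession"].to_numpy()
    records: dict[str, set[tuple[str, str]]] = {}
    for cid in truth.category_ids:
        size = min(int(rng.integers(lo, hi + 1)), len(accessions))
        term = f"synthetic category {cid}"
        core = set(truth.category_cores.get(cid, ()))
        if core:
            chosen = set(core)
            rest_pool = np.array([a for a in accessions if a not in chosen], dtype=object)
            n_rest = min(max(size - len(chosen), 0), len(rest_pool))
            if n_rest > 0:
                chosen |= set(rng.choice(rest_pool, size=n_rest, replace=False))
        else:
            chosen = set(rng.choice(accessions, size=size, replace=False))
        for gene in chosen:
            records.setdefault(str(gene), set()).add((cid, term))
    return CategoryAnnotation(vocabulary="GO", records=records)


def write_truth(truth: TruthRecord, path) -> None:
    """Write the planted ground truth as a sorted TSV (plus enriched ids as comments)."""
    with open(path, "w", encoding="utf-8") as fh:
        for cid in sorted(truth.enriched_categories):
            fh.write(f"# enriched_category\t{cid}\n")
        truth.effects.sort_values(["sex", "accession"], kind="stable").to_csv(
            fh, sep="\t", index=False
        )
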