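"""Probe filtering, relative-methylation fold ratios, and gene-level calls.

The CpG-island array is a two-color competitive design: each probe carries a
Cy3 input-DNA signal and a Cy5 methylated-DNA (MeDIP) signal per group.
Relative methylation of a probe in one group is Cy5/Cy3; the effect of
exposure is the ratio of relative methylation between the exposed and sham
groups ("fold ratio").  A probe is flagged *increased* at fold ratio >= 1.5
and *decreased* at <= 0.67 (both thresholds inclusive and configurable; note
0.67 is the conventional printed cutoff, not exactly 1/1.5).

Genes are flagged by the any-probe rule: a single qualifying probe flags its
gene (probes map many-to-one onto genes via GenBank accessions).  A gene with
probes flagged in both directions receives the call ``both`` and contributes
to both per-direction tallies.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConsistencyError, ValidationError
from .io_formats import CHROMOSOMES, parse_locus

#: Default inclusive thresholds on the exposed/sham fold ratio.
UP_THRESHOLD = 1.5
DOWN_THRESHOLD = 0.67

#: Intensities are floored at this many fluorescence units before any ratio,
#: so near-zero background-subtracted signals cannot blow up a quotient.
INTENSITY_FLOOR = 1.0

GENE_CALL_COLUMNS = [
    "accession",
    "symbol",
    "chromosome",
    "n_probes_tested",
    "n_probes_increased",
    "n_probes_decreased",
    "call",
    "extreme_fold",
]


def filter_probes(probes: pd.DataFrame, p_cutoff: float = 0.05) -> pd.DataFrame:
    """Keep probes detected at ``detect_p < p_cutoff`` (strict) that are above
    background in at least one of the two groups.  Row order is preserved."""
    if not 0 < p_cutoff <= 1:
        raise ValidationError(f"p_cutoff must be in (0, 1], got {p_cutoff}")
    keep = (probes["detect_p"] < p_cutoff) & (
        probes["above_bg_sham"] | probes["above_bg_exposed"]
    )
    return probes.loc[keep].reset_index(drop=True)


def relative_methylation(cy5, cy3, floor: float = INTENSITY_FLOOR):
    """Relative methylation of a probe in one group: IP (Cy5) over input (Cy3).

    Inputs are floored at ``floor`` fluorescence units before division.
    Accepts scalars or arrays; raises ValidationError on non-finite input.
    """
    cy5 = np.asarray(cy5, dtype=float)
    cy3 = np.asarray(cy3, dtype=float)
    if not (np.isfinite(cy5).all() and np.isfinite(cy3).all()):
        raise ValidationError("non-finite intensity passed to relative_methylation")
    out = np.maximum(cy5, floor) / np.maximum(cy3, floor)
    return float(out) if out.ndim == 0 else out


def _direction(fold: np.ndarray, up: float, down: float) -> np.ndarray:
    direction = np.full(fold.shape, "none", dtype=object)
    direction[fold >= up] = "increased"
    direction[fold <= down] = "decreased"
    return direction


def methylation_fold_ratio(
    probes: pd.DataFrame,
    up_threshold: float = UP_THRESHOLD,
    down_threshold: float = DOWN_THRESHOLD,
    floor: float = INTENSITY_FLOOR,
) -> pd.DataFrame:
    """Per-probe fold ratios and direction flags for filtered probe signals.

    ``fold_ratio = (cy5_exposed/cy3_exposed) / (cy5_sham/cy3_sham)``; the
    direction is *increased* at ``fold_ratio >= up_threshold`` and
    *decreased* at ``<= down_threshold`` (inclusive).
    """
    if not (up_threshold > 1 > down_threshold > 0):
        raise ValidationError(
            f"need up_threshold > 1 > down_threshold > 0, got {up_threshold}, {down_threshold}"
        )
    rel_sham = relative_methylation(probes["cy5_sham"], probes["cy3_sham"], floor)
    rel_exposed = relative_methylation(probes["cy5_exposed"], probes["cy3_exposed"], floor)
    fold = np.asarray(rel_exposed) / np.asarray(rel_sham)
    if not np.isfinite(fold).all() or (fold <= 0).any():
        raise ValidationError("non-positive or non-finite fold ratio after flooring")
    out = probes[["probe_id", "accession", "symbol", "locus"]].copy()
    out["rel_meth_sham"] = np.asarray(rel_sham)
    out["rel_meth_exposed"] = np.asarray(rel_exposed)
    out["fold_ratio"] = fold
    out["direction"] = _direction(fold, up_threshold, down_threshold)
    return out


def _extreme(folds: pd.Series) -> float:
    """Fold of the probe with maximal |log fold| (most extreme change)."""
    return float(folds.iloc[np.argmax(np.abs(np.log(folds.to_numpy(dtype=float))))])


def collapse_to_genes(results: pd.DataFrame) -> pd.DataFrame:
    """Collapse probe-level direction flags to one call per gene (accession).

    A gene is *increased* if >= 1 probe is increased, *decreased* if >= 1
    probe is decreased, *both* if both, else *none*.  ``extreme_fold`` is the
    fold ratio of the gene's most extreme probe.  Probes of one gene must
    agree on the chromosome; a conflict raises ConsistencyError.
    """
    if results.empty:
        raise ValidationError("collapse_to_genes requires a non-empty probe result table")
    work = results.copy()
    work["chromosome"] = [parse_locus(s).chromosome for s in work["locus"]]
    rows = []
    for accession, grp in work.groupby("accession", sort=True):
        chroms = grp["chromosome"].unique()
        if len(chroms) > 1:
            raise ConsistencyError(
                f"gene {accession}: probes on multiple chromosomes {sorted(chroms)}"
            )
        n_up = int((grp["direction"] == "increased").sum())
        n_down = int((grp["direction"] == "decreased").sum())
        if n_up and n_down:
            call = "both"
        elif n_up:
            call = "increased"
        elif n_down:
            call = "decreased"
        else:
            call = "none"
        rows.append(
            (
                accession,
                grp["symbol"].iloc[0],
                chroms[0],
                len(grp),
                n_up,
                n_down,
                call,
                _extreme(grp["fold_ratio"]),
            )
        )
    return pd.DataFrame(rows, columns=GENE_CALL_COLUMNS)


def tally_by_chromosome(calls: pd.DataFrame) -> pd.DataFrame:
    """Count flagged genes per chromosome.

    ``n_increased`` counts calls in {increased, both}; ``n_decreased`` counts
    {decreased, both} — a gene called *both* appears in both columns, so the
    column sums equal the total genes flagged in each direction.
    """
    if calls.empty:
        return pd.DataFrame(columns=["chromosome", "n_increased", "n_decreased"])
    rows = []
    for chrom in CHROMOSOMES:
        grp = calls[calls["chromosome"] == chrom]
        if grp.empty:
            continue
        rows.append(
            (
                chrom,
                int(grp["call"].isin(["increased", "both"]).sum()),
                int(grp["call"].isin(["decreased", "both"]).sum()),
            )
        )
    return pd.DataFrame(rows, columns=["chromosome", "n_increased", "n_decreased"])
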