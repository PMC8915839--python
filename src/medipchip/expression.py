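"""Fold-change flagging for the one-color expression array.

The study design pools all offspring RNA into one sample per group and sex,
so there is no replicate variance: differential expression is declared by
fold change alone, exposed/sham >= 1.5 (up) or <= 0.67 (down), thresholds
inclusive.  Probes collapse to genes by GenBank accession; the gene-level
fold is taken from the probe with the largest |log fold|.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ValidationError
from .methylation import DOWN_THRESHOLD, INTENSITY_FLOOR, UP_THRESHOLD

logger = logging.getLogger(__name__)

GENE_EXPRESSION_COLUMNS = ["accession", "symbol", "gene_fold", "regulation"]


def expression_fold_change(
    records: pd.DataFrame,
    up_threshold: float = UP_THRESHOLD,
    down_threshold: float = DOWN_THRESHOLD,
    floor: float = INTENSITY_FLOOR,
) -> pd.DataFrame:
    """Per-probe fold change (exposed/sham) and regulation flag.

    Intensities are floored at ``floor`` before the quotient; regulation is
    ``up`` at fold >= up_threshold, ``down`` at fold <= down_threshold
    (both inclusive), else ``none``.
    """
    if not (up_threshold > 1 > down_threshold > 0):
        raise ValidationError(
            f"need up_threshold > 1 > down_threshold > 0, got {up_threshold}, {down_threshold}"
        )
    sham = records["intensity_sham"].to_numpy(dtype=float)
    exposed = records["intensity_exposed"].to_numpy(dtype=float)
    if not (np.isfinite(sham).all() and np.isfinite(exposed).all()):
        raise ValidationError("non-finite expression intensity")
    fold = np.maximum(exposed, floor) / np.maximum(sham, floor)
    out = records[["probe_id", "accession", "symbol"]].copy()
    out["intensity_sham"] = sham
    out["intensity_exposed"] = exposed
    out["fold_change"] = fold
    regulation = np.full(fold.shape, "none", dtype=object)
    regulation[fold >= up_threshold] = "up"
    regulation[fold <= down_threshold] = "down"
    out["regulation"] = regulation
    return out


def collapse_expression_to_genes(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse probe-level folds to one record per gene (accession).

    ``gene_fold`` is the fold of the probe with maximal |log fold|.  The
    regulation flag follows the union rule: ``up`` if any probe is up,
    ``down`` if any is down; a gene with probes flagged in both directions
    is marked ``both`` and logged.
    """
    if records.empty:
        raise ValidationError("collapse_expression_to_genes requires a non-empty table")
    rows = []
    for accession, grp in records.groupby("accession", sort=True):
        folds = grp["fold_change"].to_numpy(dtype=float)
        gene_fold = float(folds[np.argmax(np.abs(np.log(folds)))])
        any_up = (grp["regulation"] == "up").any()
        any_down = (grp["regulation"] == "down").any()
        if any_up and any_down:
            regulation = "both"
            logger.warning("gene %s has probes flagged in both directions", accession)
        elif any_up:
            regulation = "up"
        elif any_down:
            regulation = "down"
        else:
            regulation = "none"
        rows.append((accession, grp["symbol"].iloc[0], gene_fold, regulation))
    return pd.DataFrame(rows, columns=GENE_EXPRESSION_COLUMNS)
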