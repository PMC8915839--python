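"""Join gene-level methylation and expression calls and classify the result.

The biologically interpreted classes couple the two layers in the repressive
direction expected for CpG-island methylation near transcription start
sites: *up_demethylated* (mRNA up, island demethylated) and
*down_methylated* (mRNA down, island methylated).  Genes flagged on only one
array — including genes absent from the other array entirely — fall into the
single-layer classes, so an expression hit whose gene has no CpG-island
probes remains classifiable.
"""

from __future__ import annotations

import math
from collections import Counter

import pandas as pd

from .errors import ConsistencyError

INTEGRATION_CLASSES = (
    "up_demethylated",
    "down_methylated",
    "expr_only_up",
    "expr_only_down",
    "meth_only_increased",
    "meth_only_decreased",
    "none",
)

#: Methylation calls counted as flagged, and as "decreased"/"increased" evidence.
_METH_DOWN = ("decreased", "both")
_METH_UP = ("increased", "both")


def _classify(regulation: str, call: str, gene_fold: float, extreme_fold: float) -> str:
    up = regulation in ("up", "both")
    down = regulation in ("down", "both")
    if regulation == "both":
        # a both-direction expression gene acts in the direction of its most
        # extreme probe when only one coupled class is reachable
        up = math.isnan(gene_fold) or gene_fold >= 1
        down = not up
    if up and call in _METH_DOWN:
        return "up_demethylated"
    if down and call in _METH_UP:
        return "down_methylated"
    if up:
        return "expr_only_up"
    if down:
        return "expr_only_down"
    if call == "both":
        # methylation-only conflict: side of the most extreme probe wins
        return "meth_only_increased" if extreme_fold >= 1 else "meth_only_decreased"
    if call == "increased":
        return "meth_only_increased"
    if call == "decreased":
        return "meth_only_decreased"
    return "none"


def join_and_classify(
    meth_calls: pd.DataFrame, expr_genes: pd.DataFrame, sex: str
) -> pd.DataFrame:
    """Outer-join methylation calls with expression genes on accession and
    assign each gene exactly one integration class.

    Genes present on only one array are classified from that layer alone.
    Duplicate accessions within either input raise ConsistencyError.
    """
    for name, table in (("methylation", meth_calls), ("expression", expr_genes)):
        dups = table["accession"][table["accession"].duplicated()]
        if not dups.empty:
            raise ConsistencyError(f"duplicate accession in {name} table: {dups.iloc[0]}")
    meth = meth_calls[["accession", "symbol", "call", "extreme_fold"]].rename(
        columns={"extreme_fold": "extreme_fold_meth", "symbol": "symbol_meth"}
    )
    expr = expr_genes[["accession", "symbol", "gene_fold", "regulation"]].rename(
        columns={"gene_fold": "gene_fold_expr", "symbol": "symbol_expr"}
    )
    joined = meth.merge(expr, on="accession", how="outer", sort=True)
    joined["symbol"] = joined["symbol_expr"].fillna(joined["symbol_meth"])
    joined["call"] = joined["call"].fillna("none")
    joined["regulation"] = joined["regulation"].fillna("none")
    joined["integration_class"] = [
        _classify(reg, call, gf, ef)
        for reg, call, gf, ef in zip(
            joined["regulation"],
            joined["call"],
            joined["gene_fold_expr"].astype(float),
            joined["extreme_fold_meth"].astype(float),
        )
    ]
    joined["sex"] = sex
    cols = [
        "accession",
        "symbol",
        "sex",
        "gene_fold_expr",
        "extreme_fold_meth",
        "call",
        "regulation",
        "integration_class",
    ]
    return joined[cols].sort_values("accession", kind="stable").reset_index(drop=True)


def venn_counts(integrated: pd.DataFrame) -> dict:
    """Marginal and intersection counts for the two flagged-gene sets.

    Returns ``n_expr_flagged`` (regulation in {up, down, both}),
    ``n_meth_flagged`` (call in {increased, decreased, both}), ``n_both``
    (flagged on both layers), and the per-class counts of the join.
    """
    expr_flagged = integrated["regulation"].isin(("up", "down", "both"))
    meth_flagged = integrated["call"].isin(("increased", "decreased", "both"))
    per_class = Counter(integrated["integration_class"])
    return {
        "n_expr_flagged": int(expr_flagged.sum()),
        "n_meth_flagged": int(meth_flagged.sum()),
        "n_both": int((expr_flagged & meth_flagged).sum()),
        "classes": {c: int(per_class.get(c, 0)) for c in INTEGRATION_CLASSES},
    }


def cross_sex_overlap(
    male: pd.DataFrame, female: pd.DataFrame, class_filter: str
) -> list[str]:
    """Symbols assigned to ``class_filter`` in both sexes, sorted.

    The comparison key is the gene symbol (the human-readable identifier the
    per-sex reports carry).
    """
    m = set(male.loc[male["integration_class"] == class_filter, "symbol"])
    f = set(female.loc[female["integration_class"] == class_filter, "symbol"])
    return sorted(m & f)
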