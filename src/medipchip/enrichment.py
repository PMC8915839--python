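"""Over-representation analysis with the enrichment-factor statistic.

For a flagged gene set against a category, with the 2x2 margins

    nf  flagged genes in the category
    n   flagged genes in the universe
    Nf  universe genes in the category
    N   universe genes,

the enrichment factor is EF = (nf/n)/(Nf/N): the flagged-gene fraction of
the category relative to the universe-wide flagged fraction (EF = 1 means no
enrichment).  Significance is the one-sided hypergeometric
over-representation tail P(X >= nf), X ~ Hypergeometric(N, Nf, n) — the
one-sided Fisher exact test.  A category is extracted when EF >= 2, nf >= 5
and p < 0.05 (the defaults; all configurable).

Only over-representation is tested: extraction requires EF >= 2, so the
depletion tail is out of scope.  Annotations are used as given — no
ontology-graph propagation.  Raw p-values gate extraction; a
Benjamini-Hochberg column is emitted for reference and participates in
``passes`` only on request.
"""

from __future__ import annotations

from fractions import Fraction

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import UndefinedEnrichmentError, ValidationError
from .io_formats import CategoryAnnotation

ENRICHMENT_COLUMNS = [
    "category_id",
    "term",
    "nf",
    "n",
    "Nf",
    "N",
    "enrichment_factor",
    "p_value",
    "p_bh",
    "passes",
]

MIN_EF = 2.0
MIN_NF = 5
MAX_P = 0.05


def _check_margins(nf: int, n: int, Nf: int, N: int) -> None:
    for name, v in (("nf", nf), ("n", n), ("Nf", Nf), ("N", N)):
        if not isinstance(v, (int,)) or isinstance(v, bool):
            raise ValidationError(f"{name} must be an integer count, got {v!r}")
        if v < 0:
            raise ValidationError(f"{name} must be non-negative, got {v}")
    if nf > n or nf > Nf or n > N or Nf > N:
        raise ValidationError(
            f"inconsistent contingency margins nf={nf}, n={n}, Nf={Nf}, N={N}"
        )


def enrichment_factor(nf: int, n: int, Nf: int, N: int) -> float:
    """EF = (nf/n)/(Nf/N), evaluated in exact rational arithmetic.

    Raises UndefinedEnrichmentError when n = 0 or Nf = 0 (the statistic has
    no value), and ValidationError on inconsistent margins.
    """
    _check_margins(nf, n, Nf, N)
    if n == 0 or Nf == 0:
        raise UndefinedEnrichmentError(f"EF undefined for n={n}, Nf={Nf}")
    return float(Fraction(nf, n) / Fraction(Nf, N))


def hypergeom_pvalue(nf: int, n: int, Nf: int, N: int) -> float:
    """One-sided over-representation tail P(X >= nf), X ~ Hypergeom(N, Nf, n)."""
    _check_margins(nf, n, Nf, N)
    # sf(k) = P(X > k), so the inclusive upper tail is sf(nf - 1)
    return float(min(1.0, hypergeom.sf(nf - 1, N, Nf, n)))


def run_enrichment(
    flagged_genes: set,
    annotation: CategoryAnnotation,
    array_genes: set,
    min_ef: float = MIN_EF,
    min_nf: int = MIN_NF,
    max_p: float = MAX_P,
    universe: str = "annotated",
    use_bh: bool = False,
) -> pd.DataFrame:
    """Test every annotated category for over-representation of the flagged set.

    Parameters
    ----------
    flagged_genes
        Gene identifiers flagged by the upstream analysis; must all be on
        the array.
    annotation
        Gene-to-category annotation for one vocabulary (GO or MeSH).
    array_genes
        All gene identifiers printed on the array.
    universe
        ``"annotated"`` (default) restricts the background N to array genes
        carrying at least one annotation in this vocabulary — unannotated
        genes cannot contribute to any category; ``"array"`` uses all array
        genes.
    use_bh
        When true, ``passes`` additionally requires the Benjamini-Hochberg
        adjusted p to clear ``max_p``.

    Returns one row per category with >= 1 annotated array gene, sorted by
    descending enrichment factor, then ascending p, then category id.
    """
    flagged_genes = set(flagged_genes)
    array_genes = set(array_genes)
    stray = flagged_genes - array_genes
    if stray:
        raise ValidationError(f"flagged gene(s) not on the array: {sorted(stray)[:5]}")
    if universe not in ("annotated", "array"):
        raise ValidationError(f"universe must be 'annotated' or 'array', got {universe!r}")

    annotated_on_array = annotation.genes() & array_genes
    universe_genes = annotated_on_array if universe == "annotated" else array_genes
    N = len(universe_genes)
    flagged_in_universe = flagged_genes & universe_genes
    n = len(flagged_in_universe)

    rows = []
    for cid, (term, members) in annotation.categories().items():
        members_u = members & universe_genes
        Nf = len(members_u)
        if Nf == 0:
            continue
        nf = len(members_u & flagged_in_universe)
        if n == 0:
            ef = float("nan")
            p = 1.0
        else:
            ef = float(Fraction(nf, n) / Fraction(Nf, N))
            p = hypergeom_pvalue(nf, n, Nf, N)
        rows.append((cid, term, nf, n, Nf, N, ef, p))
    out = pd.DataFrame(
        rows,
        columns=["category_id", "term", "nf", "n", "Nf", "N", "enrichment_factor", "p_value"],
    )
    if out.empty:
        out["p_bh"] = pd.Series(dtype=float)
        out["passes"] = pd.Series(dtype=bool)
        return out[ENRICHMENT_COLUMNS]
    out["p_bh"] = multipletests(out["p_value"].to_numpy(), method="fdr_bh")[1]
    out["passes"] = (
        (out["enrichment_factor"] >= min_ef)
        & (out["nf"] >= min_nf)
        & (out["p_value"] < max_p)
    )
    if use_bh:
        out["passes"] &= out["p_bh"] < max_p
    out = out.sort_values(
        ["enrichment_factor", "p_value", "category_id"],
        ascending=[False, True, True],
        kind="stable",
    ).reset_index(drop=True)
    return out[ENRICHMENT_COLUMNS]
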