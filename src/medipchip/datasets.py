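"""Bundled reference fixtures from the published neonatal mouse brain study.

Three small tables ship with the package:

* the probe-level worked example of male genes downregulated with increased
  CpG-island methylation (16 probe rows over 13 genes), and
* the extracted GO and MeSH enrichment tables for the male coupled gene set
  (category id, term, enrichment factor, printed p-value).

p-values below the reporting limit are printed as ``"<0.001"``; loaders
expose a numeric ``p_upper`` column holding the printed value or that upper
bound, so filter-consistency checks can compare against cutoffs.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io_formats import parse_locus


def _data_path(name: str):
    return resources.files("medipchip.data").joinpath(name)


def load_downregulated_methylated_male() -> pd.DataFrame:
    """Probe-level worked example: accession, symbol, locus, expr_fold, meth_fold.

    Multiple probes may map to one gene (the Zfp775 island carries four), so
    gene-level counts require collapsing by accession or symbol.
    """
    with _data_path("downregulated_methylated_male.tsv").open("r") as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    df["locus"].map(parse_locus)  # validate
    return df


def _load_enrichment(name: str) -> pd.DataFrame:
    with _data_path(name).open("r") as fh:
        df = pd.read_csv(fh, sep="\t", comment="#", dtype={"category_id": str})
    df["p_upper"] = [
        float(str(p).lstrip("<")) for p in df["p_value"]
    ]
    df["p_is_bound"] = [str(p).startswith("<") for p in df["p_value"]]
    return df


def load_go_enrichment_male() -> pd.DataFrame:
    """Extracted GO categories for the male coupled gene set."""
    return _load_enrichment("go_enrichment_male.tsv")


def load_mesh_enrichment_male() -> pd.DataFrame:
    """Extracted MeSH descriptors for the male coupled gene set."""
    return _load_enrichment("mesh_enrichment_male.tsv")
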