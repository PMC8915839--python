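"""Readers and writers for the tabular dialects the pipeline exchanges.

All files are UTF-8, tab-separated, with ``#``-prefixed comment lines
permitted.  Writers emit deterministic row order (sorted by probe id, gene,
or category id) so outputs are diffable across runs.

Genomic loci follow the UCSC-style ``chrN:start-end`` convention used on
CpG-island arrays: coordinates are 1-based inclusive and carry no strand
(island probes are unstranded by design).  The parser accepts both the
typographic en-dash and the ASCII hyphen as the coordinate separator; the
formatter always emits the ASCII hyphen.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd

from .errors import LocusParseError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

#: Chromosome labels of the mouse karyotype as printed on array annotations.
CHROMOSOMES: tuple[str, ...] = tuple(f"chr{i}" for i in range(1, 20)) + ("chrX", "chrY")

_LOCUS_RE = re.compile(r"^(?P<chrom>chr[0-9XY]+):(?P<start>\d+)[–-](?P<end>\d+)$")

PROBE_SIGNAL_COLUMNS = [
    "probe_id",
    "accession",
    "symbol",
    "locus",
    "cy3_sham",
    "cy5_sham",
    "cy3_exposed",
    "cy5_exposed",
    "detect_p",
    "above_bg_sham",
    "above_bg_exposed",
]

EXPRESSION_COLUMNS = [
    "probe_id",
    "accession",
    "symbol",
    "intensity_sham",
    "intensity_exposed",
]

_INTENSITY_COLUMNS = ["cy3_sham", "cy5_sham", "cy3_exposed", "cy5_exposed"]
_FLAG_COLUMNS = ["above_bg_sham", "above_bg_exposed"]


@dataclass(frozen=True, order=True)
class Locus:
    """A 1-based inclusive genomic interval on a named chromosome."""

    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.chromosome not in CHROMOSOMES:
            raise LocusParseError(
                f"chromosome: {self.chromosome!r} not in the allowed set chr1..chr19, chrX, chrY"
            )
        if self.start < 1:
            raise LocusParseError(f"start: {self.start} must be a positive 1-based coordinate")
        if self.end < self.start:
            raise LocusParseError(f"end: {self.end} precedes start {self.start}")

    def __str__(self) -> str:
        return f"{self.chromosome}:{self.start}-{self.end}"


def parse_locus(text: str) -> Locus:
    """Parse a ``chrN:start-end`` locus string (en-dash or hyphen separator).

    Raises
    ------
    LocusParseError
        If the string is empty, lacks the colon, has non-numeric bounds, an
        unknown chromosome label, or ``end < start``.  The message names the
        offending field.
    """
    if not isinstance(text, str) or not text.strip():
        raise LocusParseError("locus: empty string")
    m = _LOCUS_RE.match(text.strip())
    if m is None:
        if ":" not in text:
            raise LocusParseError(f"locus: missing ':' separator in {text!r}")
        raise LocusParseError(f"locus: malformed coordinates in {text!r}")
    return Locus(m.group("chrom"), int(m.group("start")), int(m.group("end")))


def format_locus(locus: Locus) -> str:
    """Render a locus with the ASCII hyphen separator (normalizes the dash)."""
    return str(locus)


@dataclass
class CategoryAnnotation:
    """Gene-to-category annotation for one controlled vocabulary (GO or MeSH).

    ``records`` maps a gene identifier to the set of ``(category_id, term)``
    pairs annotated on it; genes with no annotation are simply absent.
    """

    vocabulary: str
    records: dict[str, set[tuple[str, str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.vocabulary not in ("GO", "MeSH"):
            raise ValidationError(f"vocabulary must be 'GO' or 'MeSH', got {self.vocabulary!r}")

    def genes(self) -> set[str]:
        return set(self.records)

    def categories(self) -> dict[str, tuple[str, frozenset[str]]]:
        """Invert the mapping: category id -> (term, member genes)."""
        members: dict[str, set[str]] = {}
        terms: dict[str, str] = {}
        for gene, pairs in self.records.items():
            for cid, term in pairs:
                members.setdefault(cid, set()).add(gene)
                terms.setdefault(cid, term)
        return {cid: (terms[cid], frozenset(members[cid])) for cid in members}

    def __len__(self) -> int:
        return len(self.records)


def _require_columns(df: pd.DataFrame, required: list[str], path: object) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def _parse_flags(series: pd.Series) -> pd.Series:
    mapping = {"true": True, "false": False, "1": True, "0": False}
    out = series.astype(str).str.strip().str.lower().map(mapping)
    if out.isna().any():
        bad = series[out.isna()].iloc[0]
        raise ValidationError(f"unparseable boolean flag value {bad!r}")
    return out.astype(bool)


def read_probe_signals(path) -> pd.DataFrame:
    """Read a probe-signal TSV for the two-color CpG-island array.

    Columns: probe_id, accession, symbol, locus, cy3_sham, cy5_sham,
    cy3_exposed, cy5_exposed, detect_p, above_bg_sham, above_bg_exposed.
    Every locus string is validated on read; intensities must be
    non-negative and detection p-values must lie in [0, 1].
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"probe_id": str})
    _require_columns(df, PROBE_SIGNAL_COLUMNS, path)
    df = df[PROBE_SIGNAL_COLUMNS].copy()
    for col in _INTENSITY_COLUMNS + ["detect_p"]:
        df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
        if (df[col] < 0).any():
            raise ValidationError(f"{path}: negative value in column {col}")
    if ((df["detect_p"] < 0) | (df["detect_p"] > 1)).any():
        raise ValidationError(f"{path}: detect_p outside [0, 1]")
    for col in _FLAG_COLUMNS:
        df[col] = _parse_flags(df[col])
    df["locus"].map(parse_locus)  # validate; stored as string
    return df.reset_index(drop=True)


def write_probe_signals(table: pd.DataFrame, path) -> None:
    _require_columns(table, PROBE_SIGNAL_COLUMNS, "probe-signal table")
    out = table[PROBE_SIGNAL_COLUMNS].sort_values("probe_id", kind="stable")
    out.to_csv(path, sep="\t", index=False)


def read_expression(path) -> pd.DataFrame:
    """Read a one-color expression TSV (probe_id, accession, symbol, intensity per group)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"probe_id": str})
    _require_columns(df, EXPRESSION_COLUMNS, path)
    df = df[EXPRESSION_COLUMNS].copy()
    for col in ("intensity_sham", "intensity_exposed"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
        if (df[col] < 0).any():
            raise ValidationError(f"{path}: negative value in column {col}")
    return df.reset_index(drop=True)


def write_expression(table: pd.DataFrame, path) -> None:
    _require_columns(table, EXPRESSION_COLUMNS, "expression table")
    out = table[EXPRESSION_COLUMNS].sort_values("probe_id", kind="stable")
    out.to_csv(path, sep="\t", index=False)


_GENE2GO_COLUMNS = ["tax_id", "GeneID", "GO_ID", "Evidence", "Qualifier", "GO_term"]


def read_gene2go(path, taxon: int = 10090) -> CategoryAnnotation:
    """Read an NCBI ``gene2go``-layout annotation file, keeping one taxon.

    The file is tab-separated with columns beginning
    ``tax_id  GeneID  GO_ID  Evidence  Qualifier  GO_term``; lines starting
    with ``#`` are comments (the real file's header is such a line).  Rows of
    other taxa are dropped and duplicate (gene, GO id) pairs collapse to one.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    if df.shape[1] < 6:
        raise SchemaError(f"{path}: expected >= 6 tab-separated columns, found {df.shape[1]}")
    df = df.iloc[:, :6]
    df.columns = _GENE2GO_COLUMNS
    kept = df[pd.to_numeric(df["tax_id"], errors="coerce") == taxon]
    records: dict[str, set[tuple[str, str]]] = {}
    for gene, go_id, term in zip(kept["GeneID"], kept["GO_ID"], kept["GO_term"]):
        records.setdefault(str(gene), set()).add((str(go_id), str(term)))
    if not records:
        logger.warning("no gene2go rows for taxon %s in %s", taxon, path)
    return CategoryAnnotation(vocabulary="GO", records=records)


_MESH_COLUMNS = ["GeneID", "MeSH_ID", "MeSH_term"]


def read_mesh_table(path) -> CategoryAnnotation:
    """Read a gene-to-MeSH correspondence TSV (GeneID, MeSH_ID, MeSH_term)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    _require_columns(df, _MESH_COLUMNS, path)
    records: dict[str, set[tuple[str, str]]] = {}
    for gene, mesh_id, term in zip(df["GeneID"], df["MeSH_ID"], df["MeSH_term"]):
        records.setdefault(str(gene), set()).add((str(mesh_id), str(term)))
    if not records:
        logger.warning("no annotation rows in %s", path)
    return CategoryAnnotation(vocabulary="MeSH", records=records)


def write_annotation(annotation: CategoryAnnotation, path, taxon: int = 10090) -> None:
    """Write an annotation in the gene2go column layout, sorted by gene then category."""
    rows = []
    for gene in sorted(annotation.records):
        for cid, term in sorted(annotation.records[gene]):
            rows.append((taxon, gene, cid, "IEA", "-", term))
    pd.DataFrame(rows, columns=_GENE2GO_COLUMNS).to_csv(path, sep="\t", index=False, header=False)
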