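"""Matrisome and integrin-adhesome catalogs and proteome filtering.

The matrisome is an in-silico compilation of ECM and ECM-associated genes,
split into a core matrisome (collagens, glycoproteins, proteoglycans) and
matrisome-associated classes (ECM regulators, secreted factors,
ECM-affiliated proteins).  The adhesome is a literature-curated catalog of
integrin adhesion-complex components.  This module represents such catalogs
and filters/classifies abundance matrices against them.

A gene listed in both catalogs is assigned the matrisome division
(precedence matrisome > adhesome) so that divisions partition the catalog
and reported counts are disjoint; adhesome membership is retained as a
boolean flag so adhesome composition breakdowns remain possible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .cohort_io import AbundanceMatrix, FormatError, as_frame

logger = logging.getLogger(__name__)

DIVISIONS = ("core_matrisome", "matrisome_associated", "adhesome")
CORE_MATRISOME_CATEGORIES = ("collagens", "glycoproteins", "proteoglycans")

# matrisome divisions outrank adhesome when a gene sits in both catalogs
_DIVISION_PRECEDENCE = {"core_matrisome": 0, "matrisome_associated": 1, "adhesome": 2}


@dataclass(frozen=True)
class AnnotationRecord:
    gene_symbol: str
    division: str
    category: str
    adhesome_overlap: bool = False

    def __post_init__(self):
        if not self.gene_symbol:
            raise ValueError("gene_symbol must be non-empty")
        if self.division not in DIVISIONS:
            raise ValueError(f"unknown division {self.division!r}")
        if (
            self.division == "core_matrisome"
            and self.category not in CORE_MATRISOME_CATEGORIES
        ):
            raise ValueError(
                f"core matrisome category must be one of {CORE_MATRISOME_CATEGORIES}, "
                f"got {self.category!r} for {self.gene_symbol}"
            )


@dataclass
class AnnotationDB:
    """Catalog of annotation records with total gene-symbol lookup."""

    records: list[AnnotationRecord]
    source_version: str = "unversioned"
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        index = {}
        for rec in self.records:
            if rec.gene_symbol in index:
                raise ValueError(f"duplicate gene {rec.gene_symbol!r} in catalog")
            index[rec.gene_symbol] = rec
        self._index = index

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def get(self, gene: str) -> AnnotationRecord | None:
        return self._index.get(gene)

    @property
    def genes(self) -> list[str]:
        return [r.gene_symbol for r in self.records]

    def by_division(self, division: str) -> list[AnnotationRecord]:
        if division not in DIVISIONS:
            raise ValueError(f"unknown division {division!r}")
        return [r for r in self.records if r.division == division]


def load_annotation_db(path, source_version: str | None = None) -> AnnotationDB:
    """Load a catalog from a delimited table with columns gene, division, category.

    Delimiter is inferred from the extension (.tsv -> tab, else comma).
    Duplicate rows for one gene are resolved by division precedence
    (core_matrisome > matrisome_associated > adhesome); a gene carried by
    both a matrisome and the adhesome catalog keeps the matrisome division
    with ``adhesome_overlap=True``.  An empty file yields an empty catalog
    with a warning.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"gene", "division", "category"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: annotation table needs columns gene, division, category")
    if len(df) == 0:
        logger.warning("%s: empty annotation catalog", path)
        return AnnotationDB([], source_version or path.name)

    chosen: dict[str, dict] = {}
    for _, row in df.iterrows():
        gene, division, category = row["gene"].strip(), row["division"].strip(), row["category"].strip()
        if division not in DIVISIONS:
            raise FormatError(f"{path}: unknown division {division!r} for gene {gene!r}")
        if gene not in chosen:
            chosen[gene] = {"division": division, "category": category,
                            "adhesome_overlap": division == "adhesome"}
            continue
        prev = chosen[gene]
        if division == "adhesome" or prev["division"] == "adhesome":
            chosen[gene]["adhesome_overlap"] = True
        if _DIVISION_PRECEDENCE[division] < _DIVISION_PRECEDENCE[prev["division"]]:
            logger.warning(
                "gene %s listed with divisions %s and %s; keeping %s",
                gene, prev["division"], division, division,
            )
            chosen[gene]["division"] = division
            chosen[gene]["category"] = category
        elif division != prev["division"]:
            logger.warning(
                "gene %s listed with divisions %s and %s; keeping %s",
                gene, prev["division"], division, prev["division"],
            )
    records = [
        AnnotationRecord(g, info["division"], info["category"], info["adhesome_overlap"])
        for g, info in chosen.items()
    ]
    logger.info("%s: loaded %d annotation records", path, len(records))
    return AnnotationDB(records, source_version or path.name)


def load_packaged_catalog() -> AnnotationDB:
    """Load the small synthetic matrisome/adhesome snapshot shipped in-package."""
    ref = resources.files("ecmnet.data") / "synthetic_matrisome_adhesome.csv"
    with resources.as_file(ref) as path:
        return load_annotation_db(path, source_version="synthetic-snapshot-0.1")


def filter_matrix(matrix, db: AnnotationDB, case_insensitive: bool = False) -> AbundanceMatrix:
    """Restrict an abundance matrix to catalog proteins.

    Row order and the sample set are preserved.  Matching is exact and
    case-sensitive unless ``case_insensitive`` is set (no alias expansion).
    """
    df = as_frame(matrix)
    if case_insensitive:
        lookup = {g.upper() for g in db.genes}
        keep = [g for g in df.index if str(g).upper() in lookup]
    else:
        keep = [g for g in df.index if g in db]
    if not keep:
        logger.warning("no overlap between matrix rows and annotation catalog")
    return AbundanceMatrix(df.loc[keep])


def coverage_stats(matrix, db: AnnotationDB, case_insensitive: bool = False) -> pd.DataFrame:
    """Detection coverage of the catalog per division and category.

    Returns a table with rows ("division", d, "") and ("category", d, c)
    carrying n_detected, n_catalog and fraction = detected / catalog size.
    The catalog is deduplicated by construction, so fractions match plain
    set arithmetic.
    """
    df = as_frame(matrix)
    if case_insensitive:
        detected = {str(g).upper() for g in df.index}
        def seen(gene): return gene.upper() in detected
    else:
        detected = set(df.index)
        def seen(gene): return gene in detected

    rows = []
    for division in DIVISIONS:
        recs = db.by_division(division)
        n_detected = sum(seen(r.gene_symbol) for r in recs)
        rows.append({
            "level": "division", "division": division, "category": "",
            "n_detected": n_detected, "n_catalog": len(recs),
            "fraction": n_detected / len(recs) if recs else 0.0,
        })
        for category in sorted({r.category for r in recs}):
            sub = [r for r in recs if r.category == category]
            n_det = sum(seen(r.gene_symbol) for r in sub)
            rows.append({
                "level": "category", "division": division, "category": category,
                "n_detected": n_det, "n_catalog": len(sub),
                "fraction": n_det / len(sub) if sub else 0.0,
            })
    return pd.DataFrame(rows)
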