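"""Readers, writers and cohort operations for expression panels.

File conventions
----------------
* Expression: TSV, genes in rows, first column ``gene``, one column per sample.
* Sample metadata: sidecar TSV with columns ``sample_id``, ``patient_id``,
  ``tissue_class`` (primary/recurrent), ``cohort`` (study/augmentation) and
  ``histology_label``.
* Gene sets: standard GMT (term id, description, genes...).
* Protein interaction network: TSV edge list ``gene_a<TAB>gene_b[<TAB>score]``.

Gene identifiers are matched by exact string equality after whitespace
trimming; no alias resolution is attempted, and genes dropped during a merge
are counted in the log rather than silently discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SCALE_TAGS = ("raw_counts", "normalized", "log2")
TISSUE_CLASSES = ("primary", "recurrent")
COHORTS = ("study", "augmentation")

METADATA_COLUMNS = ["sample_id", "patient_id", "tissue_class", "cohort", "histology_label"]


class ExpressionIOError(ValueError):
    """Malformed expression/metadata/gene-set input."""


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with a declared measurement scale.

    ``values`` is a pandas DataFrame indexed by gene id with sample ids as
    columns. ``scale_tag`` records whether values are raw counts, normalized
    counts, or log2-transformed.
    """

    values: pd.DataFrame
    scale_tag: str = "raw_counts"

    def __post_init__(self) -> None:
        if self.scale_tag not in SCALE_TAGS:
            raise ExpressionIOError(f"unknown scale_tag {self.scale_tag!r}; expected one of {SCALE_TAGS}")
        idx = self.values.index.astype(str).str.strip()
        cols = self.values.columns.astype(str).str.strip()
        self.values = self.values.copy()
        self.values.index = idx
        self.values.columns = cols
        _check_unique(idx, "gene")
        _check_unique(cols, "sample")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ExpressionIOError(
                f"non-finite value at gene {idx[bad[0]]!r}, sample {cols[bad[1]]!r}"
            )
        if self.scale_tag == "raw_counts" and (arr < 0).any():
            bad = np.argwhere(arr < 0)[0]
            raise ExpressionIOError(
                f"negative raw count at gene {idx[bad[0]]!r}, sample {cols[bad[1]]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        present = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(self.values.loc[present], self.scale_tag)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, list(samples)], self.scale_tag)

    def to_log2(self, offset: float = 1.0) -> "ExpressionMatrix":
        """Log2-transform counts with a pseudocount offset (recorded in log)."""
        if self.scale_tag == "log2":
            return self
        logger.info("log2 transform with offset +%g", offset)
        return ExpressionMatrix(np.log2(self.values + offset), "log2")


@dataclass
class GeneSet:
    term_id: str
    term_name: str
    category: str  # "pathway" | "go_bp"
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        seen: dict[str, None] = {}
        for g in self.genes:
            g = str(g).strip()
            if g and g not in seen:
                seen[g] = None
        self.genes = tuple(seen)
        if not self.genes:
            raise ExpressionIOError(f"gene set {self.term_id!r} is empty")


@dataclass
class GeneSetCollection:
    entries: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_unique([e.term_id for e in self.entries], "term")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def get(self, term_id: str) -> GeneSet:
        for e in self.entries:
            if e.term_id == term_id:
                return e
        raise KeyError(term_id)

    def by_category(self, category: str) -> "GeneSetCollection":
        return GeneSetCollection([e for e in self.entries if e.category == category])


def _check_unique(ids: Iterable[str], kind: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ExpressionIOError(f"duplicate {kind} id {i!r}")
        seen.add(i)


# ---------------------------------------------------------------------------
# expression TSV
# ---------------------------------------------------------------------------

def read_expression(path: str | Path, scale_tag: str = "raw_counts") -> ExpressionMatrix:
    """Read a genes-in-rows TSV with a header of sample ids.

    Raises a hard error naming the offending gene/sample on duplicate ids and
    the offending cell on non-numeric values.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str).str.strip()
    _check_unique(df.index, "gene")
    _check_unique(df.columns, "sample")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        mask = numeric.isna()
        gene = mask.index[mask.any(axis=1)][0]
        sample = mask.columns[mask.loc[gene]][0]
        raise ExpressionIOError(
            f"non-numeric value {df.loc[gene, sample]!r} at gene {gene!r}, sample {sample!r} in {path}"
        )
    return ExpressionMatrix(numeric.astype(float), scale_tag)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return validate_metadata(meta)


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ExpressionIOError(f"metadata missing columns {missing}")
    _check_unique(meta["sample_id"], "sample")
    bad_tc = set(meta["tissue_class"]) - set(TISSUE_CLASSES)
    if bad_tc:
        raise ExpressionIOError(f"unknown tissue_class values {sorted(bad_tc)}")
    bad_cohort = set(meta["cohort"]) - set(COHORTS)
    if bad_cohort:
        raise ExpressionIOError(f"unknown cohort values {sorted(bad_cohort)}")
    # paired design: every study recurrent sample needs a study primary partner
    study = meta[meta["cohort"] == "study"]
    primaries = set(study.loc[study["tissue_class"] == "primary", "patient_id"])
    for _, row in study[study["tissue_class"] == "recurrent"].iterrows():
        if row["patient_id"] not in primaries:
            raise ExpressionIOError(
                f"recurrent sample {row['sample_id']!r} has no paired primary for patient {row['patient_id']!r}"
            )
    return meta.reset_index(drop=True)


def study_pairing(meta: pd.DataFrame) -> dict[str, tuple[str, str]]:
    """patient_id -> (primary sample, recurrent sample) for the paired study cohort."""
    study = meta[meta["cohort"] == "study"]
    pairing: dict[str, tuple[str, str]] = {}
    for pid, grp in study.groupby("patient_id", sort=True):
        prim = grp.loc[grp["tissue_class"] == "primary", "sample_id"].tolist()
        rec = grp.loc[grp["tissue_class"] == "recurrent", "sample_id"].tolist()
        if len(prim) == 1 and len(rec) == 1:
            pairing[pid] = (prim[0], rec[0])
        elif rec:
            raise ExpressionIOError(f"patient {pid!r} is not a clean primary/recurrent pair")
    if not pairing:
        raise ExpressionIOError("no complete primary/recurrent pairs in metadata")
    return pairing


def filter_cohort(meta: pd.DataFrame, exclude_labels: set[str]) -> list[str]:
    """Sample ids whose histology label is not excluded, in metadata order."""
    if len(meta) == 0:
        raise ExpressionIOError("empty metadata")
    keep = meta.loc[~meta["histology_label"].isin(set(exclude_labels)), "sample_id"]
    return keep.tolist()


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path, category: str = "pathway") -> GeneSetCollection:
    """Parse a GMT file: term id, description, then one gene per field."""
    entries = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ExpressionIOError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3")
            entries.append(GeneSet(fields[0].strip(), fields[1].strip(), category, tuple(fields[2:])))
    return GeneSetCollection(entries)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for e in collection:
            fh.write("\t".join([e.term_id, e.term_name, *e.genes]) + "\n")


# ---------------------------------------------------------------------------
# PPI edge list
# ---------------------------------------------------------------------------

def read_edge_list(path: str | Path) -> nx.Graph:
    """TSV edge list (gene_a, gene_b, optional score in [0,1]) -> simple graph."""
    g = nx.Graph()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        has_score = len(header) > 2
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise ExpressionIOError(f"{path}:{lineno}: edge line needs >= 2 fields")
            a, b = fields[0].strip(), fields[1].strip()
            if a == b:
                raise ExpressionIOError(f"{path}:{lineno}: self-loop on {a!r}")
            if has_score and len(fields) > 2 and fields[2]:
                g.add_edge(a, b, score=float(fields[2]))
            else:
                g.add_edge(a, b)
    return g


def write_edge_list(g: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tscore\n")
        for a, b, data in sorted(g.edges(data=True)):
            score = data.get("score", "")
            fh.write(f"{a}\t{b}\t{score}\n")


# ---------------------------------------------------------------------------
# cohort merge
# ---------------------------------------------------------------------------

def merge_cohorts(study: ExpressionMatrix, augmentation: ExpressionMatrix) -> ExpressionMatrix:
    """Join two cohorts on their shared genes.

    The merged matrix is restricted to the gene intersection (in study order);
    unmatched genes are counted in the log. Sample id collisions are an error.
    """
    shared = [g for g in study.gene_ids if g in set(augmentation.gene_ids)]
    if not shared:
        raise ExpressionIOError("no shared genes between cohorts")
    collisions = set(study.sample_ids) & set(augmentation.sample_ids)
    if collisions:
        raise ExpressionIOError(f"sample id collision between cohorts: {sorted(collisions)}")
    dropped_study = len(study.gene_ids) - len(shared)
    dropped_aug = len(augmentation.gene_ids) - len(shared)
    logger.info(
        "merge_cohorts: %d shared genes; dropped %d study-only and %d augmentation-only genes",
        len(shared), dropped_study, dropped_aug,
    )
    if study.scale_tag != augmentation.scale_tag:
        raise ExpressionIOError(
            f"scale mismatch: {study.scale_tag} vs {augmentation.scale_tag}"
        )
    merged = pd.concat(
        [study.values.loc[shared], augmentation.values.loc[shared]], axis=1
    )
    return ExpressionMatrix(merged, study.scale_tag)
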