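"""Readers, writers and validated domain containers for every pipeline table.

All tabular formats are TSV with a header row, UTF-8, no quoting (featureCounts
/ GEO matrix conventions); gene sets are flat GMT. Gene identity is matched
case-sensitively on ``gene_id`` throughout; symbols are display-only.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NAMESPACES = ("BP", "CC", "MF")
CONDITIONS = ("embryonic", "postnatal")


class FormatError(ValueError):
    """A file does not conform to its expected layout."""


class ValidationError(ValueError):
    """A file parses but violates a content invariant."""


_TIMEPOINT_RE = re.compile(r"^([EP])(\d+(?:\.\d+)?)$")


def timepoint_sort_key(tp: str):
    """Developmental ordering for E##/P## names: embryonic days before
    postnatal days, numeric within stage. Non-conforming names sort last,
    lexicographically (callers fall back to file order for those)."""
    m = _TIMEPOINT_RE.match(tp)
    if m is None:
        return (2, 0.0, tp)
    stage = 0 if m.group(1) == "E" else 1
    return (stage, float(m.group(2)), tp)


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Gene x sample matrix of non-negative integer counts."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # (n_genes, n_samples) int64

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise ValidationError("counts must be integer-valued")
            self.counts = self.counts.astype(np.int64)
        else:
            self.counts = self.counts.astype(np.int64)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if (self.counts < 0).any():
            raise ValidationError("counts must be non-negative")
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene_ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample_ids")
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )

    @property
    def shape(self):
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy())


@dataclass
class SampleMetadata:
    """Per-sample design: batch, developmental timepoint, stage condition."""

    table: pd.DataFrame  # columns sample_id, batch, timepoint, condition, replicate

    REQUIRED = ("sample_id", "batch", "timepoint", "condition", "replicate")

    def __post_init__(self):
        t = self.table
        missing = [c for c in self.REQUIRED if c not in t.columns]
        if missing:
            raise FormatError(f"metadata missing columns: {missing}")
        if t["sample_id"].duplicated().any():
            dup = t.loc[t["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValidationError(f"duplicate sample_id {dup!r}")
        if t[list(self.REQUIRED)].isna().any().any() or (
            t[list(self.REQUIRED)].astype(str).apply(lambda c: c.str.strip() == "").any().any()
        ):
            raise ValidationError("metadata contains missing values")
        bad = set(t["condition"]) - set(CONDITIONS)
        if bad:
            raise ValidationError(f"unknown condition labels: {sorted(bad)}")
        tp_cond = t.groupby("timepoint", sort=False)["condition"].nunique()
        if (tp_cond > 1).any():
            tp = tp_cond.index[tp_cond > 1][0]
            raise ValidationError(f"timepoint {tp!r} mapped to more than one condition")
        self.table = t.reset_index(drop=True)
        self.table["replicate"] = self.table["replicate"].astype(int)
        self.table["batch"] = self.table["batch"].astype(str)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def timepoints(self) -> list[str]:
        """Timepoints in developmental order (E then P, numeric), falling back
        to first-appearance order for non-conforming names."""
        seen = list(dict.fromkeys(self.table["timepoint"]))
        if all(_TIMEPOINT_RE.match(tp) for tp in seen):
            return sorted(seen, key=timepoint_sort_key)
        return seen

    @property
    def batches(self) -> list[str]:
        return sorted(set(self.table["batch"]))

    def condition_of_timepoint(self) -> dict[str, str]:
        return dict(zip(self.table["timepoint"], self.table["condition"]))

    def condition_of_sample(self) -> dict[str, str]:
        return dict(zip(self.table["sample_id"], self.table["condition"]))

    def batch_of_sample(self) -> dict[str, str]:
        return dict(zip(self.table["sample_id"], self.table["batch"]))

    def samples_at(self, timepoint: str) -> list[str]:
        return list(self.table.loc[self.table["timepoint"] == timepoint, "sample_id"])

    def samples_in_condition(self, condition: str) -> list[str]:
        return list(self.table.loc[self.table["condition"] == condition, "sample_id"])

    def check_against(self, counts: CountMatrix) -> None:
        if set(self.sample_ids) != set(counts.sample_ids):
            raise ValidationError("metadata samples do not match count matrix samples")


@dataclass
class GeneAnnotation:
    """gene_id -> (symbol, union-exon length in bp) used for TPM."""

    table: pd.DataFrame  # columns gene_id, symbol, length_bp

    def __post_init__(self):
        t = self.table
        for c in ("gene_id", "symbol", "length_bp"):
            if c not in t.columns:
                raise FormatError(f"annotation missing column {c!r}")
        if t["gene_id"].duplicated().any():
            raise ValidationError("duplicate gene_id in annotation")
        t["length_bp"] = t["length_bp"].astype(int)
        if (t["length_bp"] < 1).any():
            raise ValidationError("length_bp must be >= 1")
        self.table = t.reset_index(drop=True)

    def lengths_for(self, gene_ids: list[str]) -> np.ndarray:
        lut = dict(zip(self.table["gene_id"], self.table["length_bp"]))
        missing = [g for g in gene_ids if g not in lut]
        if missing:
            raise ValidationError(f"genes missing from annotation: {missing[:10]}"
                                  + ("..." if len(missing) > 10 else ""))
        return np.array([lut[g] for g in gene_ids], dtype=float)


@dataclass(frozen=True)
class GeneSet:
    term_id: str
    name: str
    namespace: str  # BP | CC | MF
    genes: frozenset


@dataclass
class GeneSetCollection:
    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __post_init__(self):
        for term_id, gs in self.sets.items():
            if not gs.genes:
                raise ValidationError(f"gene set {term_id!r} is empty")
            if gs.namespace not in NAMESPACES:
                raise ValidationError(f"gene set {term_id!r} has namespace "
                                      f"{gs.namespace!r}, expected one of {NAMESPACES}")

    def __len__(self):
        return len(self.sets)

    def __contains__(self, term_id):
        return term_id in self.sets

    def __getitem__(self, term_id) -> GeneSet:
        return self.sets[term_id]

    def values(self):
        return self.sets.values()

    def annotated_genes(self) -> set:
        out: set = set()
        for gs in self.sets.values():
            out |= gs.genes
        return out


@dataclass
class KnownGeneList:
    genes: frozenset
    provenance: str = ""

    def __post_init__(self):
        if not self.genes:
            raise ValidationError("known-gene list is empty")
        self.genes = frozenset(self.genes)

    def __len__(self):
        return len(self.genes)

    def __contains__(self, g):
        return g in self.genes


@dataclass
class EvidenceTable:
    """Local literature/expression evidence; genes absent from the table are
    treated as documented (never candidates) so missing evidence can only
    suppress, not fabricate, discoveries."""

    table: pd.DataFrame  # columns gene_id, literature_hits, expression_evidence

    def __post_init__(self):
        t = self.table
        for c in ("gene_id", "literature_hits", "expression_evidence"):
            if c not in t.columns:
                raise FormatError(f"evidence table missing column {c!r}")
        if t["gene_id"].duplicated().any():
            raise ValidationError("duplicate gene_id in evidence table")
        t["literature_hits"] = t["literature_hits"].astype(int)
        if (t["literature_hits"] < 0).any():
            raise ValidationError("literature_hits must be >= 0")
        t["expression_evidence"] = t["expression_evidence"].astype(bool)
        self.table = t.reset_index(drop=True)
        self._hits = dict(zip(t["gene_id"], t["literature_hits"]))
        self._expr = dict(zip(t["gene_id"], t["expression_evidence"]))

    def __contains__(self, gene_id):
        return gene_id in self._hits

    def literature_hits(self, gene_id):
        return self._hits.get(gene_id)

    def expression_evidence(self, gene_id):
        return self._expr.get(gene_id)

    def is_candidate_evidence(self, gene_id) -> bool:
        """Zero curated literature hits AND positive tissue expression; a gene
        with no evidence row is conservatively treated as documented."""
        if gene_id not in self._hits:
            return False
        return self._hits[gene_id] == 0 and bool(self._expr[gene_id])


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _parse_bool(v, where: str) -> bool:
    s = str(v).strip().lower()
    if s in ("true", "1", "yes", "t"):
        return True
    if s in ("false", "0", "no", "f"):
        return False
    raise FormatError(f"cannot parse boolean {v!r} in {where}")


def read_count_matrix(path) -> CountMatrix:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValidationError(f"{path.name}: duplicate sample IDs in header")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    gene_ids = list(df.index.astype(str))
    if len(set(gene_ids)) != len(gene_ids):
        dup = pd.Index(gene_ids)
        dup = dup[dup.duplicated()][0]
        raise ValidationError(f"{path.name}: duplicate gene ID {dup!r}")
    counts = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            g = df.index[vals.isna()][0]
            raise FormatError(f"{path.name}: non-numeric count at gene {g!r}, sample {col!r}")
        arr = vals.to_numpy(dtype=float)
        if not np.all(arr == np.floor(arr)):
            g = df.index[arr != np.floor(arr)][0]
            raise FormatError(f"{path.name}: non-integer count at gene {g!r}, sample {col!r}")
        if (arr < 0).any():
            g = df.index[arr < 0][0]
            raise ValidationError(f"{path.name}: negative count at gene {g!r}, sample {col!r}")
        counts[:, j] = arr.astype(np.int64)
    return CountMatrix(gene_ids, list(df.columns), counts)


def read_sample_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "replicate" in df.columns:
        try:
            df["replicate"] = pd.to_numeric(df["replicate"])
        except (ValueError, TypeError) as e:
            raise FormatError(f"non-numeric replicate column: {e}") from e
    return SampleMetadata(df)


def read_gene_annotation(path) -> GeneAnnotation:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "symbol": str})
    return GeneAnnotation(df)


def read_gene_sets(path) -> GeneSetCollection:
    """Flat GMT: term_id <TAB> description <TAB> gene... . The namespace is
    encoded in the description, either as a bare 'BP'/'CC'/'MF' or as
    'NS|human-readable name'; anything else defaults to BP with a warning."""
    sets: dict[str, GeneSet] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{Path(path).name}:{lineno}: GMT line has "
                                  f"{len(fields)} field(s), expected >= 2")
            term_id, desc = fields[0], fields[1]
            genes = frozenset(g for g in fields[2:] if g.strip())
            if term_id in sets:
                raise ValidationError(f"duplicate term_id {term_id!r} (line {lineno})")
            if not genes:
                logger.warning("dropping empty gene set %r (line %d)", term_id, lineno)
                continue
            if "|" in desc:
                ns, name = desc.split("|", 1)
            else:
                ns, name = desc, desc
            ns = ns.strip()
            if ns not in NAMESPACES:
                logger.warning("term %r: unrecognized namespace %r, defaulting to BP",
                               term_id, ns)
                ns, name = "BP", desc
            sets[term_id] = GeneSet(term_id, name.strip(), ns, genes)
    return GeneSetCollection(sets)


def read_known_genes(path, provenance: str = "") -> KnownGeneList:
    genes = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            g = line.strip()
            if g and not g.startswith("#"):
                genes.append(g)
    if not genes:
        raise ValidationError(f"{Path(path).name}: known-gene list is empty")
    return KnownGeneList(frozenset(genes), provenance or str(path))


def read_evidence(path) -> EvidenceTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for c in ("gene_id", "literature_hits", "expression_evidence"):
        if c not in df.columns:
            raise FormatError(f"evidence table missing column {c!r}")
    try:
        df["literature_hits"] = df["literature_hits"].astype(int)
    except (ValueError, TypeError) as e:
        raise FormatError(f"non-integer literature_hits: {e}") from e
    df["expression_evidence"] = [
        _parse_bool(v, f"evidence row {g}") for g, v in
        zip(df["gene_id"], df["expression_evidence"])
    ]
    return EvidenceTable(df)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_count_matrix(cm: CountMatrix, path) -> None:
    cm.to_frame().to_csv(path, sep="\t", index_label="gene_id")


def write_sample_metadata(meta: SampleMetadata, path) -> None:
    meta.table.to_csv(path, sep="\t", index=False)


def write_gene_annotation(ann: GeneAnnotation, path) -> None:
    ann.table.to_csv(path, sep="\t", index=False)


def write_gene_sets(coll: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term_id in coll.sets:
            gs = coll.sets[term_id]
            genes = "\t".join(sorted(gs.genes))
            fh.write(f"{gs.term_id}\t{gs.namespace}|{gs.name}\t{genes}\n")


def write_known_genes(known: KnownGeneList, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in sorted(known.genes):
            fh.write(g + "\n")


def write_evidence(ev: EvidenceTable, path) -> None:
    out = ev.table.copy()
    out["expression_evidence"] = out["expression_evidence"].map({True: "true", False: "false"})
    out.to_csv(path, sep="\t", index=False)
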