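"""Readers and writers for the tabular formats the pipeline consumes.

Dialects
--------
* Count matrix: TSV, first column ``contig_id``, remaining columns one per
  life-cycle stage, cells are non-negative integer read counts.
* BLAST hits: tab-separated, the 12 standard tabular columns (qseqid sseqid
  pident length mismatch gapopen qstart qend sstart send evalue bitscore)
  with ``qlen`` and ``slen`` appended (14 columns, no header).  Subject
  coordinates are 1-based inclusive; hits on the minus strand arrive with
  ``sstart > send`` and are normalised to ``sstart <= send`` with a
  ``reverse`` flag.  Interval arithmetic elsewhere converts to half-open.
* Annotations: TSV of ``contig_id  go_id  namespace`` with namespace one of
  P (biological process), F (molecular function), C (cellular component).

All parsers reject malformed input with an error naming the offending line;
nothing is silently coerced.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_STAGES = ("pre-competent larva", "post-larva", "adult")

BLAST_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    "qlen", "slen",
]

_GO_RE = re.compile(r"^GO:\d{7}$")
_NAMESPACES = frozenset({"P", "F", "C"})


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


@dataclass
class StageCountMatrix:
    """Read counts per contig per life-cycle stage.

    ``counts`` is indexed by contig id with one integer column per stage,
    in life-cycle order.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.shape[1] < 2:
            raise FormatError("count matrix needs at least 2 stages")
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate contig ids: {dupes[:5]}")
        if not all(np.issubdtype(dt, np.integer) for dt in df.dtypes):
            raise FormatError("counts must be integers")
        if (df.to_numpy() < 0).any():
            raise FormatError("counts must be non-negative")

    @property
    def contig_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def stage_labels(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_contigs(self) -> int:
        return self.counts.shape[0]

    def subset(self, contig_ids) -> "StageCountMatrix":
        """Row subset preserving this matrix's row order."""
        keep = self.counts.index.isin(set(contig_ids))
        return StageCountMatrix(self.counts.loc[keep].copy())


@dataclass
class BlastHitTable:
    """Top-hit BLAST records, one row per query contig.

    ``records`` carries the 14 dialect columns plus a boolean ``reverse``
    marking hits whose subject coordinates were flipped to start <= end.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in BLAST_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"blast table missing columns: {missing}")
        if "reverse" not in df.columns:
            df["reverse"] = False
        if (df["evalue"] < 0).any():
            raise FormatError("negative e-value")
        if (df["sstart"] > df["send"]).any():
            raise FormatError("subject coordinates not normalised")
        if df["qseqid"].duplicated().any():
            raise FormatError("multiple records per query; table must be top-hit deduplicated")

    @property
    def n_hits(self) -> int:
        return len(self.records)


@dataclass
class AnnotationTable:
    """Mapping contig id -> set of (GO id, namespace) pairs."""

    terms: dict[str, frozenset[tuple[str, str]]] = field(default_factory=dict)

    def contigs_with_term(self, go_id: str) -> set[str]:
        return {c for c, ts in self.terms.items() if any(g == go_id for g, _ in ts)}

    @property
    def annotated_contigs(self) -> set[str]:
        return set(self.terms)

    def all_terms(self) -> set[tuple[str, str]]:
        out: set[tuple[str, str]] = set()
        for ts in self.terms.values():
            out |= ts
        return out


# ---------------------------------------------------------------------------
# parsers


def parse_count_table(path, expected_stages=None) -> StageCountMatrix:
    """Parse a TSV count matrix; every cell must be a non-negative integer.

    Raises :class:`FormatError` naming the first offending line.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 3:
            raise FormatError("header must list a contig-id column and >=2 stages")
        stages = header[1:]
        if expected_stages is not None and list(expected_stages) != stages:
            raise FormatError(
                f"stage labels {stages} do not match expected {list(expected_stages)}"
            )
        ids: list[str] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise FormatError(f"line {lineno}: expected {len(header)} columns, got {len(parts)}")
            row = []
            for val in parts[1:]:
                try:
                    iv = int(val)
                except ValueError:
                    raise FormatError(f"line {lineno}: non-integer count {val!r}") from None
                if iv < 0:
                    raise FormatError(f"line {lineno}: negative count {iv}")
                row.append(iv)
            ids.append(parts[0])
            rows.append(row)
    df = pd.DataFrame(rows, index=pd.Index(ids, name="contig_id"), columns=stages, dtype=np.int64)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"duplicate contig id {dup!r}")
    return StageCountMatrix(df)


def write_count_table(matrix: StageCountMatrix, path) -> None:
    matrix.counts.to_csv(path, sep="\t", index_label="contig_id")


def parse_blast_tabular(path, evalue_cutoff: float = 1e-5) -> BlastHitTable:
    """Parse extended tabular BLAST output and keep one top hit per query.

    Records with e-value above ``evalue_cutoff`` are dropped.  The top hit
    is the record with the lowest e-value; ties are broken by the highest
    bit score, then by lexicographic subject id.  Reversed subject
    coordinates are normalised to start <= end and flagged ``reverse``.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(BLAST_COLUMNS):
                raise FormatError(
                    f"line {lineno}: expected {len(BLAST_COLUMNS)} columns, got {len(parts)}"
                )
            try:
                rec = {
                    "qseqid": parts[0],
                    "sseqid": parts[1],
                    "pident": float(parts[2]),
                    "length": int(parts[3]),
                    "mismatch": int(parts[4]),
                    "gapopen": int(parts[5]),
                    "qstart": int(parts[6]),
                    "qend": int(parts[7]),
                    "sstart": int(parts[8]),
                    "send": int(parts[9]),
                    "evalue": float(parts[10]),
                    "bitscore": float(parts[11]),
                    "qlen": int(parts[12]),
                    "slen": int(parts[13]),
                }
            except ValueError as exc:
                raise FormatError(f"line {lineno}: {exc}") from None
            if rec["evalue"] < 0:
                raise FormatError(f"line {lineno}: negative e-value")
            rows.append(rec)
    df = pd.DataFrame(rows, columns=BLAST_COLUMNS)
    df = df[df["evalue"] <= evalue_cutoff].copy()
    rev = df["sstart"] > df["send"]
    df["reverse"] = rev
    lo = df[["sstart", "send"]].min(axis=1)
    hi = df[["sstart", "send"]].max(axis=1)
    df["sstart"], df["send"] = lo, hi
    # top hit per query: lowest e-value, then highest bit score, then subject id
    df = df.sort_values(
        ["qseqid", "evalue", "bitscore", "sseqid"],
        ascending=[True, True, False, True],
        kind="mergesort",
    ).drop_duplicates("qseqid", keep="first")
    return BlastHitTable(df.reset_index(drop=True))


def write_blast_tabular(table: BlastHitTable, path) -> None:
    """Write records back out in the 14-column dialect (no header).

    Reverse-flagged hits are re-emitted with swapped subject coordinates so
    a write -> parse round trip is an identity.
    """
    df = table.records.copy()
    rev = df["reverse"].to_numpy(dtype=bool)
    s, e = df["sstart"].to_numpy().copy(), df["send"].to_numpy().copy()
    s[rev], e[rev] = e[rev], s[rev]
    df["sstart"], df["send"] = s, e
    df[BLAST_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def parse_annotation_table(path) -> AnnotationTable:
    """Parse the contig -> GO-term TSV; duplicates collapse to one entry."""
    mapping: dict[str, set[tuple[str, str]]] = {}
    n = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise FormatError(f"line {lineno}: expected 3 columns, got {len(parts)}")
            contig, go_id, ns = parts
            if not _GO_RE.match(go_id):
                raise FormatError(f"line {lineno}: invalid GO id {go_id!r}")
            if ns not in _NAMESPACES:
                raise FormatError(f"line {lineno}: namespace {ns!r} not in P/F/C")
            mapping.setdefault(contig, set()).add((go_id, ns))
            n += 1
    if n == 0:
        logger.warning("annotation table %s is empty", path)
    return AnnotationTable({c: frozenset(ts) for c, ts in mapping.items()})


def write_annotation_table(annotations: AnnotationTable, path) -> None:
    with open(path, "w") as fh:
        for contig in sorted(annotations.terms):
            for go_id, ns in sorted(annotations.terms[contig]):
                fh.write(f"{contig}\t{go_id}\t{ns}\n")


# ---------------------------------------------------------------------------
# Newick


def _quote(name: str) -> str:
    if re.search(r"[\s()\[\]:;,']", name):
        return "'" + name.replace("'", "''") + "'"
    return name


def newick_string(tree) -> str:
    """Serialise an ultrametric dendrogram to Newick with branch lengths.

    Branch length of a node is its parent's height minus its own height
    (leaves sit at height 0).  Children are written larger cluster first;
    equal sizes keep merge order, which follows the input label order.
    """

    def render(node, parent_height: float) -> str:
        bl = parent_height - node.height
        if node.is_leaf:
            return f"{_quote(node.label)}:{bl:g}"
        kids = sorted(node.children, key=lambda c: -c.n_leaves)
        inner = ",".join(render(k, node.height) for k in kids)
        return f"({inner}):{bl:g}"

    root = tree.root
    if root.is_leaf:
        return f"{_quote(root.label)}:0;"
    kids = sorted(root.children, key=lambda c: -c.n_leaves)
    inner = ",".join(render(k, root.height) for k in kids)
    return f"({inner});"


def write_newick(tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(newick_string(tree) + "\n")


def read_fasta_lengths(path) -> dict[str, int]:
    """Contig lengths from a FASTA file, as an alternative to the qlen column."""
    from Bio import SeqIO

    return {rec.id: len(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
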