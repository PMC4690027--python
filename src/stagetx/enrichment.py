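"""GO-term enrichment for transition-selected contigs.

For each life-cycle transition, the up- and down-regulated annotated contig
sets are tested separately against the annotated reference set.  For every
GO term annotating at least one test-set contig, a 2x2 table is built::

                        with term   without term
        test set            a            b
        reference \\ test    c            d

(test-set contigs are excluded from the reference column, the standard
term-enrichment convention).  Two-tailed Fisher exact p-values are
corrected with Benjamini-Hochberg within each (transition, direction)
family and a term is significant when q <= alpha.  GO ancestor propagation
is not performed; terms are tested exactly as annotated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .filters import TransitionSelection
from .formats import AnnotationTable

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentRecord:
    go_id: str
    namespace: str
    transition: tuple[str, str]
    direction: str  # "up" | "down"
    a: int  # test-set contigs with term
    b: int  # test-set contigs without
    c: int  # reference (minus test set) contigs with term
    d: int  # reference (minus test set) contigs without
    p: float
    q: float = float("nan")
    significant: bool = False


@dataclass
class TransitionComparison:
    """Up/down counts of significant terms for two transitions."""

    transition_a: tuple[str, str]
    transition_b: tuple[str, str]
    up_a: int
    down_a: int
    up_b: int
    down_b: int
    p: float
    degenerate: bool = False

    @property
    def percent_up_a(self) -> int:
        return round(100 * self.up_a / (self.up_a + self.down_a)) if self.up_a + self.down_a else 0

    @property
    def percent_up_b(self) -> int:
        return round(100 * self.up_b / (self.up_b + self.down_b)) if self.up_b + self.down_b else 0


def fisher_exact_two_tailed(table) -> float:
    """Two-tailed Fisher exact p for a 2x2 table of non-negative integers.

    The p-value sums the hypergeometric probabilities of every table with
    the observed margins whose probability is <= that of the observed
    table.  A table with any zero margin is degenerate and returns p = 1.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        raise ValueError("table entries must be non-negative integers")
    if 0 in t.sum(axis=0) or 0 in t.sum(axis=1):
        logger.warning("degenerate 2x2 table with a zero margin: %s", t.tolist())
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided").pvalue)


def bh_adjust(pvalues, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: q-values and significance flags at alpha."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, reject


def enrich_transition(
    selection: TransitionSelection,
    annotations: AnnotationTable,
    reference: set[str],
    alpha: float = 0.05,
) -> list[EnrichmentRecord]:
    """Per-term enrichment records for one transition, both directions.

    ``reference`` is the annotated contig-id universe (the non-redundant
    all-stages set intersected with the annotation table).  Contigs without
    any annotation never enter the 2x2 counts.  A term significant in both
    directions keeps only its smaller-q record (with a warning).  Records
    are sorted by q.
    """
    annotated = annotations.annotated_contigs
    universe = reference & annotated
    records: list[EnrichmentRecord] = []
    by_term_dir: dict[tuple[str, str], EnrichmentRecord] = {}

    for direction, contigs in (("up", selection.up), ("down", selection.down)):
        test = contigs & universe
        if not test:
            logger.warning(
                "transition %s: empty annotated %s-regulated set", selection.transition, direction
            )
            continue
        rest = universe - test
        # term -> test-set count
        term_ns: dict[str, str] = {}
        counts_test: dict[str, int] = {}
        for cid in test:
            for go_id, ns in annotations.terms[cid]:
                counts_test[go_id] = counts_test.get(go_id, 0) + 1
                term_ns[go_id] = ns
        counts_rest: dict[str, int] = {g: 0 for g in counts_test}
        for cid in rest:
            for go_id, _ns in annotations.terms[cid]:
                if go_id in counts_rest:
                    counts_rest[go_id] += 1
        dir_records = []
        for go_id in sorted(counts_test):
            a = counts_test[go_id]
            b = len(test) - a
            c = counts_rest[go_id]
            d = len(rest) - c
            p = fisher_exact_two_tailed(np.array([[a, b], [c, d]]))
            dir_records.append(
                EnrichmentRecord(
                    go_id=go_id, namespace=term_ns[go_id], transition=selection.transition,
                    direction=direction, a=a, b=b, c=c, d=d, p=p,
                )
            )
        q, sig = bh_adjust([r.p for r in dir_records], alpha=alpha)
        for rec, qi, si in zip(dir_records, q, sig):
            rec.q = float(qi)
            rec.significant = bool(si)
            by_term_dir[(rec.go_id, rec.direction)] = rec
        records.extend(dir_records)

    # resolve terms significant in both directions of the same transition
    resolved = []
    dropped: set[int] = set()
    for rec in records:
        other = by_term_dir.get((rec.go_id, "down" if rec.direction == "up" else "up"))
        if other is not None and rec.significant and other.significant:
            if (rec.q, rec.direction) > (other.q, other.direction):
                logger.warning(
                    "term %s significant in both directions of %s; keeping %s (q=%.3g)",
                    rec.go_id, rec.transition, other.direction, other.q,
                )
                dropped.add(id(rec))
    resolved = [r for r in records if id(r) not in dropped]
    resolved.sort(key=lambda r: (r.q, r.p, r.go_id))
    return resolved


def compare_transitions(
    records_a: list[EnrichmentRecord], records_b: list[EnrichmentRecord]
) -> TransitionComparison:
    """Compare significant-term direction frequencies between two transitions."""

    def count(records, direction):
        return sum(1 for r in records if r.significant and r.direction == direction)

    ta = records_a[0].transition if records_a else ("A", "?")
    tb = records_b[0].transition if records_b else ("B", "?")
    up_a, down_a = count(records_a, "up"), count(records_a, "down")
    up_b, down_b = count(records_b, "up"), count(records_b, "down")
    degenerate = (up_a + down_a == 0) or (up_b + down_b == 0)
    if degenerate:
        logger.warning("transition comparison degenerate: no significant terms on one side")
    p = fisher_exact_two_tailed(np.array([[up_a, down_a], [up_b, down_b]]))
    return TransitionComparison(ta, tb, up_a, down_a, up_b, down_b, p, degenerate)


def write_enrichment_table(records: list[EnrichmentRecord], path) -> None:
    rows = [
        (
            r.go_id, r.namespace, f"{r.transition[0]}/{r.transition[1]}", r.direction,
            r.a, r.b, r.c, r.d, r.p, r.q, r.significant,
        )
        for r in records
    ]
    pd.DataFrame(
        rows,
        columns=["go_id", "namespace", "transition", "direction",
                 "a", "b", "c", "d", "p", "q", "significant"],
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_comparison_table(cmp: TransitionComparison, path) -> None:
    with open(path, "w") as fh:
        fh.write("transition\tup\tdown\tpercent_up\n")
        fh.write(f"{cmp.transition_a[0]}/{cmp.transition_a[1]}\t{cmp.up_a}\t{cmp.down_a}\t{cmp.percent_up_a}\n")
        fh.write(f"{cmp.transition_b[0]}/{cmp.transition_b[1]}\t{cmp.up_b}\t{cmp.down_b}\t{cmp.percent_up_b}\n")
        fh.write(f"# two-tailed Fisher exact p = {cmp.p:.6g}\n")
        if cmp.degenerate:
            fh.write("# WARNING: degenerate comparison (no significant terms on one side)\n")
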