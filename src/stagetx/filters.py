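"""Transcript detection and fold-change selection rules.

Three rules drive the expression analyses:

1. *Detection*: a contig is counted only if it has at least ``min_reads``
   reads (default 64) in at least one life-cycle stage.
2. *Stage-specific*: a contig is selected if, for some stage, the
   pseudocounted count ratio between that stage and the arithmetic mean of
   the other two stages reaches ``fold_threshold`` (default 4) in either
   direction.
3. *Transition*: for an ordered stage pair, a contig is up-regulated if the
   pseudocounted later/earlier ratio is >= the threshold and down-regulated
   if it is <= its reciprocal.

Counts are log2-transformed after adding a pseudocount of 1 for the
correlation profiles; the fold rules operate on pseudocounted raw counts
(fold is a ratio of expression levels, not of logs).  Threshold boundaries
are inclusive: a ratio of exactly 4 counts as a >=4-fold change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats import StageCountMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterConfig:
    min_reads: int = 64
    fold_threshold: float = 4.0
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.min_reads < 0:
            raise ValueError("min_reads must be >= 0")
        if self.fold_threshold < 1:
            raise ValueError("fold_threshold must be >= 1")


@dataclass
class ExpressionProfile:
    """log2(count + pseudocount) values, contigs x stages."""

    values: pd.DataFrame
    pseudocount: float = 1.0

    @property
    def contig_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def stage_labels(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class TransitionSelection:
    """Contigs with a >=fold change across one ordered stage transition."""

    transition: tuple[str, str]
    up: set[str] = field(default_factory=set)
    down: set[str] = field(default_factory=set)
    fold: dict[str, float] = field(default_factory=dict)  # realised later/earlier ratio

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("up and down selections must be disjoint")

    @property
    def selected(self) -> set[str]:
        return self.up | self.down


def apply_detection_filter(matrix: StageCountMatrix, cfg: FilterConfig) -> StageCountMatrix:
    """Keep contigs with >= ``cfg.min_reads`` reads in at least one stage."""
    keep = matrix.counts.max(axis=1) >= cfg.min_reads
    out = StageCountMatrix(matrix.counts.loc[keep].copy())
    logger.info(
        "detection filter (>=%d reads in >=1 stage): %d -> %d contigs",
        cfg.min_reads, matrix.n_contigs, out.n_contigs,
    )
    return out


def log_transform(matrix: StageCountMatrix, cfg: FilterConfig) -> ExpressionProfile:
    """log2(count + pseudocount) per cell."""
    if cfg.pseudocount <= 0 and (matrix.counts.to_numpy() == 0).any():
        raise ValueError("pseudocount must be positive when zero counts are present")
    vals = np.log2(matrix.counts.astype(float) + cfg.pseudocount)
    return ExpressionProfile(vals, pseudocount=cfg.pseudocount)


def select_stage_specific(matrix: StageCountMatrix, cfg: FilterConfig) -> set[str]:
    """Contigs with a >=fold difference between one stage and the mean of the
    other two (pseudocounted, either direction, boundary inclusive)."""
    if len(matrix.stage_labels) != 3:
        raise ValueError("stage-specific selection requires exactly 3 stages")
    c = matrix.counts.to_numpy(dtype=float) + cfg.pseudocount
    selected = np.zeros(len(c), dtype=bool)
    for s in range(3):
        a = c[:, s]
        m = c[:, [j for j in range(3) if j != s]].mean(axis=1)
        ratio = np.maximum(a / m, m / a)
        selected |= ratio >= cfg.fold_threshold
    ids = {cid for cid, sel in zip(matrix.contig_ids, selected) if sel}
    logger.info("stage-specific >=%g-fold rule: %d of %d contigs selected",
                cfg.fold_threshold, len(ids), matrix.n_contigs)
    return ids


def select_transition_changed(
    matrix: StageCountMatrix, transition: tuple[str, str], cfg: FilterConfig
) -> TransitionSelection:
    """Contigs with a >=fold change across an ordered (earlier, later) pair."""
    earlier, later = transition
    for stage in transition:
        if stage not in matrix.stage_labels:
            raise ValueError(f"stage {stage!r} not in matrix")
    num = matrix.counts[later].to_numpy(dtype=float) + cfg.pseudocount
    den = matrix.counts[earlier].to_numpy(dtype=float) + cfg.pseudocount
    rho = num / den
    ids = np.asarray(matrix.contig_ids)
    up = set(ids[rho >= cfg.fold_threshold])
    down = set(ids[rho <= 1.0 / cfg.fold_threshold])
    fold = dict(zip(ids, rho))
    logger.info("transition %s -> %s: %d up, %d down of %d contigs",
                earlier, later, len(up), len(down), matrix.n_contigs)
    return TransitionSelection(transition=(earlier, later), up=up, down=down, fold=fold)


def write_selection_table(
    path,
    stage_specific: set[str] | None = None,
    transitions: list[TransitionSelection] | None = None,
) -> None:
    """Export selections as TSV: contig, rule, stage/transition, direction, fold."""
    rows = []
    for cid in sorted(stage_specific or ()):
        rows.append((cid, "stage_specific", "", "", ""))
    for sel in transitions or ():
        label = f"{sel.transition[0]}/{sel.transition[1]}"
        for cid in sorted(sel.up):
            rows.append((cid, "transition", label, "up", f"{sel.fold[cid]:.4g}"))
        for cid in sorted(sel.down):
            rows.append((cid, "transition", label, "down", f"{sel.fold[cid]:.4g}"))
    pd.DataFrame(rows, columns=["contig_id", "rule", "scope", "direction", "fold"]).to_csv(
        path, sep="\t", index=False
    )
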