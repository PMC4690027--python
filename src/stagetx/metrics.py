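"""Assembly quality metrics: N50, ortholog hit ratio, redundancy,
saturation, non-redundant reference construction, and read normalization.

Ortholog hit ratio (OHR) is the length of a contig with a significant
BLAST hit divided by the length of its top match; OHR = 1 means the
transcript was assembled to its full length, OHR > 1 suggests an insertion
in the transcript (or a deletion in the match).

Redundancy comes in two senses.  *Broad*: the fraction of BLAST-hit
contigs whose top-hit subject is shared with at least one other contig.
*Narrow*: per subject, contigs whose subject intervals overlap (by at
least one base, configurable) are grouped into connected components,
interpreted as distinct duplicate genes; each component beyond the first
per subject counts one redundant contig — the fragments-of-one-gene
signal.  Narrow-sense redundancy never exceeds broad-sense.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .formats import BlastHitTable, StageCountMatrix

logger = logging.getLogger(__name__)

DEFAULT_FRACTIONS = (0.125, 0.25, 0.375, 0.5, 0.625, 0.75, 0.875)

OHR_PERCENTILES = (5, 10, 25, 50, 75, 90, 95)


@dataclass
class AssemblySummary:
    n_contigs: int
    total_bp: int
    mean_length: float
    max_length: int
    n50: int


@dataclass
class OhrDistribution:
    values: np.ndarray
    mean: float
    sd: float  # corrected (n-1) sample standard deviation
    percentiles: dict[int, float]


@dataclass
class SaturationCurve:
    fractions: list[float]
    n_hit_contigs: list[int]
    n50: list[int]
    seed: int


@dataclass
class RedundancyEstimate:
    broad_percent: float
    narrow_percent: float
    n_hit_contigs: int
    # per shared subject: contig count and number of overlap components
    subjects: dict[str, tuple[int, int]] = field(default_factory=dict)


def compute_n50(lengths: Sequence[int]) -> int:
    """Length at which the cumulative bp of descending-sorted contigs first
    reaches half the total assembled bases."""
    arr = np.asarray(lengths)
    if arr.size == 0:
        raise ValueError("empty length list")
    if (arr <= 0).any():
        raise ValueError("lengths must be positive")
    srt = np.sort(arr)[::-1]
    csum = np.cumsum(srt)
    idx = int(np.searchsorted(csum, csum[-1] / 2.0))
    return int(srt[idx])


def summarize_assembly(lengths: Sequence[int]) -> AssemblySummary:
    arr = np.asarray(lengths)
    return AssemblySummary(
        n_contigs=int(arr.size),
        total_bp=int(arr.sum()),
        mean_length=float(arr.mean()),
        max_length=int(arr.max()),
        n50=compute_n50(arr),
    )


def compute_ohr(record) -> float:
    """OHR of one top-hit record: contig length / top-match length."""
    qlen, slen = int(record["qlen"]), int(record["slen"])
    if qlen <= 0 or slen <= 0:
        raise ValueError("query and subject lengths must be positive")
    return qlen / slen


def summarize_ohr(hits: BlastHitTable) -> OhrDistribution:
    """Mean, corrected sample SD, and box-plot percentiles of per-contig OHR.

    Percentiles use linear interpolation between order statistics.
    """
    if hits.n_hits < 2:
        raise ValueError("need >=2 hits for a corrected sample SD")
    vals = (hits.records["qlen"] / hits.records["slen"]).to_numpy(dtype=float)
    if (vals <= 0).any():
        raise ValueError("OHR values must be positive")
    pct = {p: float(np.percentile(vals, p)) for p in OHR_PERCENTILES}
    return OhrDistribution(
        values=vals, mean=float(vals.mean()), sd=float(vals.std(ddof=1)), percentiles=pct
    )


def _overlap_components(intervals: list[tuple[int, int, str]], min_overlap: int = 1):
    """Connected components of 1-based inclusive intervals overlapping by
    >= min_overlap bases.  Returns a list of contig-id lists.

    Intervals are swept in start order; for intervals, transitive overlap
    chains are exactly the clusters produced by extending the running end.
    """
    comps: list[list[str]] = []
    cur: list[str] = []
    cur_end = -np.inf
    for start, end, cid in sorted(intervals):
        # shared bases with the running cluster: cur_end - start + 1
        if cur and cur_end - start + 1 >= min_overlap:
            cur.append(cid)
            cur_end = max(cur_end, end)
        else:
            if cur:
                comps.append(cur)
            cur = [cid]
            cur_end = end
    if cur:
        comps.append(cur)
    return comps


def estimate_redundancy(hits: BlastHitTable, min_overlap: int = 1) -> RedundancyEstimate:
    """Broad- and narrow-sense redundancy of a top-hit table.

    broad % = contigs sharing their subject with another contig / all hit
    contigs.  narrow % = sum over subjects of (overlap components - 1) /
    all hit contigs.
    """
    df = hits.records
    total = len(df)
    if total == 0:
        return RedundancyEstimate(0.0, 0.0, 0)
    broad = 0
    narrow = 0
    subjects: dict[str, tuple[int, int]] = {}
    for sid, grp in df.groupby("sseqid"):
        k = len(grp)
        if k < 2:
            continue
        broad += k
        ivals = list(zip(grp["sstart"], grp["send"], grp["qseqid"]))
        comps = _overlap_components(ivals, min_overlap)
        narrow += len(comps) - 1
        subjects[sid] = (k, len(comps))
    return RedundancyEstimate(
        broad_percent=100.0 * broad / total,
        narrow_percent=100.0 * narrow / total,
        n_hit_contigs=total,
        subjects=subjects,
    )


def build_nonredundant_reference(
    hits: BlastHitTable, all_contigs: set[str], min_overlap: int = 1
) -> set[str]:
    """Non-redundant contig set: per subject, keep only the overlap
    component containing the longest contig; other components are treated
    as extra fragments of the same gene and removed.  Contigs without hits
    are retained."""
    df = hits.records
    qlen = dict(zip(df["qseqid"], df["qlen"]))
    removed: set[str] = set()
    for _sid, grp in df.groupby("sseqid"):
        if len(grp) < 2:
            continue
        ivals = list(zip(grp["sstart"], grp["send"], grp["qseqid"]))
        comps = _overlap_components(ivals, min_overlap)
        if len(comps) < 2:
            continue
        # component holding the longest contig wins; ties by contig id
        best = max(comps, key=lambda comp: (max(qlen[c] for c in comp), min(comp)))
        for comp in comps:
            if comp is not best:
                removed.update(comp)
    return set(all_contigs) - removed


def saturation_assessment(
    read_pool: pd.Series,
    evaluator: Callable[[pd.Series], tuple[int, int]],
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    seed: int = 0,
) -> SaturationCurve:
    """Random-subsampling saturation curve.

    ``read_pool`` assigns each contig its read count; each fraction draws
    its own independent without-replacement subsample of the pooled reads
    (the draws are not nested), and ``evaluator`` maps the subsampled
    counts to (number of contigs with significant hits, N50).  Production
    users may wire a real assembly+search pipeline as the evaluator.
    """
    fr = list(fractions)
    if any(not 0 < f <= 1 for f in fr):
        raise ValueError("fractions must lie in (0, 1]")
    if sorted(fr) != fr or len(set(fr)) != len(fr):
        raise ValueError("fractions must be strictly increasing")
    rng = np.random.default_rng(seed)
    counts = read_pool.to_numpy(dtype=np.int64)
    total = int(counts.sum())
    n_hits, n50s = [], []
    for f in fr:
        if f == 1.0:
            sub = counts
        else:
            size = int(round(f * total))
            sub = rng.multivariate_hypergeometric(counts, size, method="marginals")
        h, n50 = evaluator(pd.Series(sub, index=read_pool.index))
        n_hits.append(int(h))
        n50s.append(int(n50))
    return SaturationCurve(fractions=fr, n_hit_contigs=n_hits, n50=n50s, seed=seed)


def normalize_by_subsampling(matrix: StageCountMatrix, seed: int = 0) -> StageCountMatrix:
    """Downsample every stage column to the smallest stage total.

    Uses exact without-replacement draws (multivariate hypergeometric) so
    column totals match the smallest stage exactly; the smallest stage is
    left untouched.  Per-contig expected proportions are preserved.
    """
    rng = np.random.default_rng(seed)
    totals = matrix.counts.sum(axis=0)
    target = int(totals.min())
    out = {}
    for stage in matrix.stage_labels:
        col = matrix.counts[stage].to_numpy(dtype=np.int64)
        if int(totals[stage]) == target:
            out[stage] = col
        else:
            out[stage] = rng.multivariate_hypergeometric(col, target, method="marginals")
        logger.info("normalization: stage %r total %d -> %d", stage, int(totals[stage]), target)
    return StageCountMatrix(
        pd.DataFrame(out, index=matrix.counts.index, dtype=np.int64)[matrix.stage_labels]
    )


def filter_short_contigs(lengths: dict[str, int], min_length: int = 300) -> set[str]:
    """Contig ids passing the minimum assembled-length cutoff (default 300 bp)."""
    return {cid for cid, ln in lengths.items() if ln >= min_length}


def write_redundancy_report(est: RedundancyEstimate, path) -> None:
    with open(path, "w") as fh:
        fh.write("metric\tvalue\n")
        fh.write(f"n_hit_contigs\t{est.n_hit_contigs}\n")
        fh.write(f"broad_percent\t{est.broad_percent:.4g}\n")
        fh.write(f"narrow_percent\t{est.narrow_percent:.4g}\n")


def write_saturation_curve(curve: SaturationCurve, path) -> None:
    pd.DataFrame(
        {"fraction": curve.fractions, "n_hit_contigs": curve.n_hit_contigs, "n50": curve.n50}
    ).to_csv(path, sep="\t", index=False)


def write_ohr_summary(dist: OhrDistribution, path) -> None:
    with open(path, "w") as fh:
        fh.write("statistic\tvalue\n")
        fh.write(f"n\t{len(dist.values)}\n")
        fh.write(f"mean\t{dist.mean:.4g}\n")
        fh.write(f"sd\t{dist.sd:.4g}\n")
        for p in OHR_PERCENTILES:
            fh.write(f"p{p}\t{dist.percentiles[p]:.4g}\n")
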