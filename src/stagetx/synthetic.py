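"""Synthetic data with planted ground truth for the whole pipeline.

The generator emulates the statistical structure the analysis assumes for
a three-stage life-cycle transcriptome:

* a per-contig read-count matrix with per-gene lognormal baselines and
  negative-binomial counts (the standard overdispersed count model; the
  Poisson limit is reached as dispersion -> infinity), with planted
  stage-specific and transition fold effects acting on (mean+1) ratios so
  the pseudocounted fold rules detect them by construction;
* a top-hit BLAST table with one subject per gene, subject lengths sized
  from a Beta-distributed target OHR, and extra per-gene fragment contigs
  whose subject intervals overlap or not exactly as the fragmentation
  plan states — exercising both redundancy definitions analytically;
* a GO annotation table where planted terms annotate their target contigs
  at ``enrichment_ratio`` times the background rate.

Effects are step functions in life-cycle order: a transition-up gene is
elevated in every stage after the transition, a transition-down gene in
every stage before it, so each planted effect is confined to its own
transition.  All randomness flows through explicit seeds; identical seeds
give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats import (
    DEFAULT_STAGES,
    AnnotationTable,
    BlastHitTable,
    StageCountMatrix,
    BLAST_COLUMNS,
)

_NS_CYCLE = ("P", "F", "C")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic life-cycle transcriptome.

    Defaults model a modest de novo assembly: a few thousand expressed
    contigs, median depth around the detection cutoff, strong (8-fold)
    planted effects, contig lengths centred near 700 bp and a mean target
    OHR near 0.35.
    """

    n_genes: int = 3000
    stage_labels: tuple[str, ...] = DEFAULT_STAGES
    base_mean: float = 64.0          # median expected reads per contig
    log2_spread: float = 2.5         # per-gene baseline spread, log2 units
    dispersion: float = 8.0          # NB size parameter; inf = Poisson
    frac_stage_specific: float = 0.15
    # planted per-transition change: scalar (same for every transition) or
    # one value per transition.  Defaults put more change, and more of it
    # up-regulated, on the settlement/metamorphosis transition, and mostly
    # down-regulated change on the post-larva/adult transition.
    frac_transition_up: float | tuple[float, ...] = (0.10, 0.025)
    frac_transition_down: float | tuple[float, ...] = (0.05, 0.06)
    effect_fold: float = 8.0         # planted (mean+1) fold
    # per-stage library-depth multipliers (~10-15% inequality, as typical
    # of real stage libraries); applied when counts are drawn
    depth_factors: tuple[float, ...] = (1.0, 0.85, 1.05)
    # annotations
    n_planted_terms: int = 6
    n_background_terms: int = 40
    background_prob: float = 0.05
    enrichment_ratio: float = 10.0
    min_term_contigs: int = 10
    # fragmentation / BLAST structure
    frac_fragmented: float = 0.10
    extra_fragments: int = 1
    overlap_prob: float = 0.5
    mean_contig_len: float = 700.0
    len_log2_sd: float = 0.6
    min_contig_len: int = 300


@dataclass(frozen=True)
class PlantedTerm:
    go_id: str
    namespace: str
    direction: str            # "up" | "down"
    transition: int           # 0-based transition index
    gene_ids: tuple[str, ...]


@dataclass
class SyntheticTruth:
    """Planted per-contig effects plus the generator settings that made them."""

    config: GeneratorConfig
    seed: int
    gene_ids: list[str]
    baselines: np.ndarray                 # per-gene baseline expected reads
    mu: pd.DataFrame                      # expected reads, genes x stages
    roles: pd.DataFrame                   # role / scope / direction per gene
    planted_terms: list[PlantedTerm]
    fragmentation_plan: dict[str, tuple[int, bool]]  # gene -> (n_extra, overlap?)

    @property
    def stage_labels(self) -> list[str]:
        return list(self.config.stage_labels)

    def genes_with_role(self, role: str, scope=None, direction=None) -> list[str]:
        df = self.roles
        m = df["role"] == role
        if scope is not None:
            m &= df["scope"] == str(scope)
        if direction is not None:
            m &= df["direction"] == direction
        return list(df.index[m])

    def expected_redundancy(self) -> tuple[float, float]:
        """Analytic broad/narrow redundancy percentages of the BLAST table."""
        total = len(self.gene_ids) + sum(k for k, _ in self.fragmentation_plan.values())
        broad = sum(k + 1 for k, _ in self.fragmentation_plan.values())
        narrow = sum(k for k, ov in self.fragmentation_plan.values() if not ov)
        return 100.0 * broad / total, 100.0 * narrow / total


def _per_transition(value, n_transitions: int) -> tuple[float, ...]:
    if np.isscalar(value):
        return (float(value),) * n_transitions
    out = tuple(float(v) for v in value)
    if len(out) != n_transitions:
        raise ValueError(f"expected {n_transitions} per-transition values, got {len(out)}")
    return out


def _validate(cfg: GeneratorConfig) -> None:
    if cfg.n_genes < 10:
        raise ValueError("need n_genes >= 10")
    if len(cfg.stage_labels) != 3:
        raise ValueError("need exactly 3 stage labels")
    n_transitions = len(cfg.stage_labels) - 1
    ups = _per_transition(cfg.frac_transition_up, n_transitions)
    downs = _per_transition(cfg.frac_transition_down, n_transitions)
    for name in ("frac_stage_specific", "frac_fragmented", "background_prob",
                 "overlap_prob"):
        v = getattr(cfg, name)
        if not 0 <= v <= 1:
            raise ValueError(f"{name}={v} outside [0, 1]")
    for v in ups + downs:
        if not 0 <= v <= 1:
            raise ValueError(f"transition fraction {v} outside [0, 1]")
    for u, d in zip(ups, downs):
        if u + d > 1:
            raise ValueError("frac_transition_up + frac_transition_down exceeds 1")
    budget = cfg.frac_stage_specific + sum(ups) + sum(downs)
    if budget > 1:
        raise ValueError(f"planted fractions sum to {budget:.3g} > 1; assignments must be disjoint")
    if cfg.effect_fold < 1:
        raise ValueError("effect_fold must be >= 1")
    if len(cfg.depth_factors) != len(cfg.stage_labels) or any(
        f <= 0 for f in cfg.depth_factors
    ):
        raise ValueError("depth_factors must be positive, one per stage")


def generate_truth(config: GeneratorConfig, seed: int) -> SyntheticTruth:
    """Assign disjoint planted roles, baselines, expected means and terms."""
    _validate(config)
    cfg = config
    rng = np.random.default_rng(seed)
    n = cfg.n_genes
    gene_ids = [f"c{i:06d}" for i in range(1, n + 1)]
    baselines = cfg.base_mean * np.exp2(rng.normal(0.0, cfg.log2_spread, n))

    n_transitions = len(cfg.stage_labels) - 1
    ups = _per_transition(cfg.frac_transition_up, n_transitions)
    downs = _per_transition(cfg.frac_transition_down, n_transitions)
    order = rng.permutation(n)
    n_ss = int(round(cfg.frac_stage_specific * n))

    roles = pd.DataFrame(
        {"role": "null", "scope": "", "direction": ""},
        index=pd.Index(gene_ids, name="gene_id"),
    )
    pos = 0
    ss_idx = order[pos:pos + n_ss]; pos += n_ss
    ss_stage = rng.integers(0, 3, size=n_ss)
    roles.iloc[ss_idx, 0] = "stage_specific"
    roles.iloc[ss_idx, 1] = [str(s) for s in ss_stage]
    tr_sets: dict[tuple[int, str], np.ndarray] = {}
    for t in range(n_transitions):
        for direction, frac in (("up", ups[t]), ("down", downs[t])):
            count = int(round(frac * n))
            idx = order[pos:pos + count]; pos += count
            tr_sets[(t, direction)] = idx
            roles.iloc[idx, 0] = "transition"
            roles.iloc[idx, 1] = str(t)
            roles.iloc[idx, 2] = direction

    # expected means: step effects on (mean+1) so pseudocounted folds hold
    f = cfg.effect_fold
    mu = np.tile(baselines[:, None], (1, 3)).astype(float)
    elevated = f * (baselines + 1.0) - 1.0
    for j, (i, s) in enumerate(zip(ss_idx, ss_stage)):
        mu[i, s] = elevated[i]
    for (t, direction), idx in tr_sets.items():
        stages = range(t + 1, 3) if direction == "up" else range(0, t + 1)
        for s in stages:
            mu[idx, s] = elevated[idx]

    planted_terms: list[PlantedTerm] = []
    combos = [(t, d) for t in range(len(cfg.stage_labels) - 1) for d in ("up", "down")]
    for i in range(cfg.n_planted_terms):
        t, d = combos[i % len(combos)]
        pool = [gene_ids[g] for g in tr_sets[(t, d)]]
        if len(pool) < cfg.min_term_contigs:
            raise ValueError(
                f"planted term pool for transition {t} {d} has {len(pool)} genes "
                f"< min_term_contigs={cfg.min_term_contigs}"
            )
        planted_terms.append(
            PlantedTerm(
                go_id=f"GO:{i + 1:07d}",
                namespace=_NS_CYCLE[i % 3],
                direction=d,
                transition=t,
                gene_ids=tuple(pool),
            )
        )

    n_frag = int(round(cfg.frac_fragmented * n))
    frag_idx = rng.choice(n, size=n_frag, replace=False)
    overlaps = rng.random(n_frag) < cfg.overlap_prob
    plan = {
        gene_ids[g]: (cfg.extra_fragments, bool(ov))
        for g, ov in zip(sorted(frag_idx), overlaps)
    }

    return SyntheticTruth(
        config=cfg, seed=seed, gene_ids=gene_ids, baselines=baselines,
        mu=pd.DataFrame(mu, index=pd.Index(gene_ids, name="gene_id"),
                        columns=list(cfg.stage_labels)),
        roles=roles, planted_terms=planted_terms, fragmentation_plan=plan,
    )


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, size_param: float) -> np.ndarray:
    if np.isinf(size_param):
        return rng.poisson(mu)
    p = size_param / (size_param + mu)
    return rng.negative_binomial(size_param, p)


def generate_counts(truth: SyntheticTruth, seed: int) -> StageCountMatrix:
    """Negative-binomial counts around the truth's expected means.

    Expected means are scaled by the per-stage ``depth_factors`` first, so
    stage library sizes are realistically unequal; ``truth.mu`` itself
    stays on the biological (depth-free) scale.
    """
    rng = np.random.default_rng(seed)
    mu = truth.mu.to_numpy() * np.asarray(truth.config.depth_factors)
    counts = np.empty_like(mu, dtype=np.int64)
    for s in range(mu.shape[1]):
        counts[:, s] = _nb_draw(rng, mu[:, s], truth.config.dispersion)
    return StageCountMatrix(
        pd.DataFrame(counts, index=truth.mu.index.rename("contig_id"),
                     columns=truth.stage_labels, dtype=np.int64)
    )


def generate_blast_table(truth: SyntheticTruth, seed: int) -> BlastHitTable:
    """Top-hit table: one subject per gene, fragments per the plan.

    For a gene with k extra fragments the subject is split into k+1
    equal-length slots.  Non-overlapping fragments occupy their own slots
    (disjoint intervals); overlapping fragments are shifted within the
    primary slot so they share at least one subject coordinate.
    """
    cfg = truth.config
    rng = np.random.default_rng(seed)
    n = len(truth.gene_ids)
    qlens = np.maximum(
        cfg.min_contig_len,
        np.round(cfg.mean_contig_len * np.exp2(rng.normal(0.0, cfg.len_log2_sd, n))),
    ).astype(int)
    # Beta-distributed target OHR, mean ~0.35 as typical of de novo assemblies
    ohr = np.clip(rng.beta(1.4, 2.6, n), 0.05, 1.0)
    rows = []
    for i, gid in enumerate(truth.gene_ids):
        qlen = int(qlens[i])
        sid = f"SUBJ_{gid}"
        k, overlap = truth.fragmentation_plan.get(gid, (0, False))
        if k == 0:
            slen = max(qlen, int(round(qlen / ohr[i])))
            alen = qlen
            sstart = int(rng.integers(1, slen - alen + 2))
            rows.append(_hit(rng, gid, sid, sstart, sstart + alen - 1, qlen, slen))
        else:
            alen = qlen
            slen = (k + 1) * alen
            # primary in slot 0
            rows.append(_hit(rng, gid, sid, 1, alen, qlen, slen))
            for j in range(1, k + 1):
                fid = f"{gid}_f{j}"
                flen = max(cfg.min_contig_len, alen // 2)
                if overlap:
                    start = max(1, alen - flen + 1)  # shares the primary's tail
                else:
                    start = j * alen + 1            # its own slot
                rows.append(_hit(rng, fid, sid, start, start + flen - 1, flen, slen))
    df = pd.DataFrame(rows, columns=BLAST_COLUMNS)
    df["reverse"] = False
    return BlastHitTable(df)


def _hit(rng, qid, sid, sstart, send, qlen, slen):
    alen = send - sstart + 1
    pident = float(np.round(rng.uniform(40.0, 95.0), 1))
    evalue = float(10.0 ** -rng.uniform(6.0, 60.0))
    return {
        "qseqid": qid, "sseqid": sid, "pident": pident, "length": alen,
        "mismatch": int(round(alen * (100 - pident) / 100)), "gapopen": 0,
        "qstart": 1, "qend": alen, "sstart": sstart, "send": send,
        "evalue": evalue, "bitscore": float(np.round(2.0 * alen * pident / 100, 1)),
        "qlen": qlen, "slen": slen,
    }


def generate_annotations(truth: SyntheticTruth, seed: int) -> AnnotationTable:
    """GO annotations: uniform background plus elevated planted terms.

    Background terms annotate every gene with probability
    ``background_prob``; each planted term annotates its target genes with
    probability ``enrichment_ratio * background_prob`` (capped at 1) and
    other genes at the background rate.  Planted terms falling below
    ``min_term_contigs`` annotations are topped up from their target pool.
    Only primary contigs carry annotations (fragments share their gene's
    subject and would be collapsed by the non-redundant reference anyway).
    """
    cfg = truth.config
    rng = np.random.default_rng(seed)
    genes = truth.gene_ids
    n = len(genes)
    mapping: dict[str, set[tuple[str, str]]] = {g: set() for g in genes}

    for j in range(cfg.n_background_terms):
        go_id = f"GO:{1000000 + j + 1:07d}"
        ns = _NS_CYCLE[j % 3]
        hits = rng.random(n) < cfg.background_prob
        for g, h in zip(genes, hits):
            if h:
                mapping[g].add((go_id, ns))

    p1 = min(1.0, cfg.enrichment_ratio * cfg.background_prob)
    for term in truth.planted_terms:
        target = set(term.gene_ids)
        draws = rng.random(n)
        annotated = []
        for g, u in zip(genes, draws):
            prob = p1 if g in target else cfg.background_prob
            if u < prob:
                mapping[g].add((term.go_id, term.namespace))
                annotated.append(g)
        short = cfg.min_term_contigs - len(annotated)
        if short > 0:
            for g in term.gene_ids:
                if (term.go_id, term.namespace) not in mapping[g]:
                    mapping[g].add((term.go_id, term.namespace))
                    short -= 1
                    if short == 0:
                        break

    return AnnotationTable(
        {g: frozenset(ts) for g, ts in mapping.items() if ts}
    )


def make_saturation_evaluator(contig_lengths: dict[str, int], min_reads: int = 5,
                              half_saturation: float = 20.0):
    """Emulated assembly+search step for saturation curves.

    A contig is recovered with a significant hit when its subsampled read
    count reaches ``min_reads``; its recovered length grows with depth as
    ``full_length * c / (c + half_saturation)``, saturating at the full
    length — recovery and N50 both increase with sequencing effort.
    """
    from .metrics import compute_n50

    def evaluate(counts: pd.Series) -> tuple[int, int]:
        rec = counts[counts >= min_reads]
        if rec.empty:
            return 0, 0
        lens = [
            max(1, int(round(contig_lengths[c] * k / (k + half_saturation))))
            for c, k in rec.items()
        ]
        return len(rec), compute_n50(lens)

    return evaluate


def write_truth_table(truth: SyntheticTruth, path) -> None:
    """Sidecar TSV of planted assignments, for tests and reports."""
    df = truth.roles.copy()
    df["baseline"] = np.round(truth.baselines, 4)
    plan = truth.fragmentation_plan
    df["extra_fragments"] = [plan.get(g, (0, False))[0] for g in df.index]
    df["fragments_overlap"] = [int(plan.get(g, (0, False))[1]) for g in df.index]
    df.to_csv(path, sep="\t")


def generate_bundle(config: GeneratorConfig, seed: int):
    """Truth + counts + BLAST table + annotations from one master seed.

    Sub-seeds are derived deterministically (and kept below 2**31) so the
    four artifacts are independent draws but jointly reproducible.
    """
    ss = np.random.SeedSequence(seed).spawn(4)
    sub = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    truth = generate_truth(config, sub[0])
    counts = generate_counts(truth, sub[1])
    blast = generate_blast_table(truth, sub[2])
    annotations = generate_annotations(truth, sub[3])
    return truth, counts, blast, annotations
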