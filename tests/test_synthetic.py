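import io

import numpy as np
import pytest

from stagetx.filters import FilterConfig, apply_detection_filter, log_transform
from stagetx.correlation import pearson_r
from stagetx.metrics import estimate_redundancy
from stagetx.synthetic import (
    GeneratorConfig,
    generate_annotations,
    generate_blast_table,
    generate_bundle,
    generate_counts,
    generate_truth,
    write_truth_table,
)
from stagetx.formats import write_count_table


class TestTruth:
    def test_planted_fraction_forced_by_parameters(self):
        cfg = GeneratorConfig(n_genes=1000, frac_stage_specific=0.2)
        truth = generate_truth(cfg, seed=1)
        assert len(truth.genes_with_role("stage_specific")) == 200

    def test_determinism_same_seed(self):
        cfg = GeneratorConfig(n_genes=600)
        a, b = generate_truth(cfg, 1), generate_truth(cfg, 1)
        assert a.roles.equals(b.roles)
        assert np.array_equal(a.baselines, b.baselines)
        assert a.fragmentation_plan == b.fragmentation_plan
        assert a.planted_terms == b.planted_terms

    def test_conflicting_direction_fractions_rejected(self):
        with pytest.raises(ValueError, match="exceeds 1"):
            generate_truth(
                GeneratorConfig(frac_transition_up=0.9, frac_transition_down=0.9), 0
            )

    def test_small_gene_count_rejected(self):
        with pytest.raises(ValueError):
            generate_truth(GeneratorConfig(n_genes=5), 0)

    def test_planted_roles_disjoint(self):
        truth = generate_truth(GeneratorConfig(n_genes=500), 3)
        roles = truth.roles
        planted = roles[roles["role"] != "null"]
        assert planted.index.is_unique  # one role per gene by construction
        up = set(truth.genes_with_role("transition", scope=0, direction="up"))
        down = set(truth.genes_with_role("transition", scope=0, direction="down"))
        assert not up & down


class TestCounts:
    def test_planted_fold_construction(self):
        """8-fold up in one stage at base_mean=32 gives means near (263, 32, 32)."""
        cfg = GeneratorConfig(
            n_genes=10, base_mean=32, log2_spread=0.0, frac_stage_specific=1.0,
            frac_transition_up=0.0, frac_transition_down=0.0, effect_fold=8.0,
            n_planted_terms=0,
        )
        truth = generate_truth(cfg, 0)
        for gid in truth.gene_ids:
            mu = truth.mu.loc[gid]
            target = int(truth.roles.loc[gid, "scope"])
            others = [mu.iloc[s] for s in range(3) if s != target]
            assert others == [32.0, 32.0]
            # (mean+1) ratio is exactly the planted fold
            assert (mu.iloc[target] + 1) / (others[0] + 1) == pytest.approx(8.0)

    def test_transition_fold_in_stated_direction(self):
        cfg = GeneratorConfig(
            n_genes=100, log2_spread=0.0, frac_stage_specific=0.0,
            frac_transition_up=0.2, frac_transition_down=0.2, n_planted_terms=0,
        )
        truth = generate_truth(cfg, 1)
        mu1 = truth.mu.to_numpy() + 1.0
        for t in range(2):
            for gid in truth.genes_with_role("transition", scope=t, direction="up"):
                i = truth.gene_ids.index(gid)
                assert mu1[i, t + 1] / mu1[i, t] == pytest.approx(cfg.effect_fold)
            for gid in truth.genes_with_role("transition", scope=t, direction="down"):
                i = truth.gene_ids.index(gid)
                assert mu1[i, t] / mu1[i, t + 1] == pytest.approx(cfg.effect_fold)

    def test_fixed_seed_identical_matrix(self):
        truth = generate_truth(GeneratorConfig(n_genes=600), 2)
        a, b = generate_counts(truth, 5), generate_counts(truth, 5)
        assert a.counts.equals(b.counts)

    def test_mean_within_three_standard_errors(self):
        cfg = GeneratorConfig(
            n_genes=5000, base_mean=50, log2_spread=0.0, dispersion=8.0,
            frac_stage_specific=0.0, frac_transition_up=0.0,
            frac_transition_down=0.0, n_planted_terms=0,
        )
        truth = generate_truth(cfg, 0)
        counts = generate_counts(truth, 0).counts.to_numpy()[:, 0]
        se = np.sqrt((50 + 50**2 / 8.0) / 5000)  # NB variance mu + mu^2/size
        assert abs(counts.mean() - 50) < 3 * se

    def test_poisson_limit_variance_equals_mean(self):
        cfg = GeneratorConfig(
            n_genes=10000, base_mean=40, log2_spread=0.0, dispersion=np.inf,
            frac_stage_specific=0.0, frac_transition_up=0.0,
            frac_transition_down=0.0, n_planted_terms=0,
        )
        truth = generate_truth(cfg, 0)
        col = generate_counts(truth, 1).counts.to_numpy()[:, 0]
        assert col.var() == pytest.approx(col.mean(), rel=0.1)


class TestBlastTable:
    def test_fragment_plans_respected(self):
        cfg = GeneratorConfig(n_genes=50, frac_fragmented=0.4, n_planted_terms=0)
        truth = generate_truth(cfg, 4)
        table = generate_blast_table(truth, 5)
        df = table.records.set_index("qseqid")
        for gid, (k, overlap) in truth.fragmentation_plan.items():
            frags = [f"{gid}_f{j}" for j in range(1, k + 1)]
            prim = df.loc[gid]
            for fid in frags:
                frag = df.loc[fid]
                assert frag["sseqid"] == prim["sseqid"]
                shared = min(prim["send"], frag["send"]) - max(prim["sstart"], frag["sstart"]) + 1
                if overlap:
                    assert shared >= 1
                else:
                    assert shared <= 0

    def test_full_length_record_ohr_is_length_ratio(self):
        truth = generate_truth(GeneratorConfig(n_genes=20, frac_fragmented=0.0,
                                               n_planted_terms=0), 0)
        rec = generate_blast_table(truth, 1).records.iloc[0]
        assert rec["qlen"] / rec["slen"] <= 1.0

    def test_realized_redundancy_matches_plan_analytics(self):
        cfg = GeneratorConfig(n_genes=10, frac_fragmented=0.5, n_planted_terms=0)
        truth = generate_truth(cfg, 7)
        est = estimate_redundancy(generate_blast_table(truth, 8))
        broad, narrow = truth.expected_redundancy()
        assert est.broad_percent == pytest.approx(broad)
        assert est.narrow_percent == pytest.approx(narrow)

    def test_deterministic(self):
        truth = generate_truth(GeneratorConfig(n_genes=50, n_planted_terms=0), 1)
        a, b = generate_blast_table(truth, 2), generate_blast_table(truth, 2)
        assert a.records.equals(b.records)


class TestAnnotations:
    def test_planted_term_frequency_elevated_tenfold(self):
        cfg = GeneratorConfig(
            n_genes=3000, n_planted_terms=4, n_background_terms=10,
            background_prob=0.05, enrichment_ratio=10.0,
        )
        truth = generate_truth(cfg, 0)
        anno = generate_annotations(truth, 1)
        term = truth.planted_terms[0]
        target = set(term.gene_ids)
        inside = sum(
            1 for g in target if (term.go_id, term.namespace) in anno.terms.get(g, ())
        ) / len(target)
        outside_pool = [g for g in truth.gene_ids if g not in target]
        outside = sum(
            1 for g in outside_pool if (term.go_id, term.namespace) in anno.terms.get(g, ())
        ) / len(outside_pool)
        assert inside == pytest.approx(0.5, abs=0.1)   # 10 x 0.05
        assert outside == pytest.approx(0.05, abs=0.03)

    def test_no_planted_terms_homogeneous(self):
        cfg = GeneratorConfig(n_genes=2000, n_planted_terms=0, n_background_terms=5,
                              background_prob=0.1)
        truth = generate_truth(cfg, 0)
        anno = generate_annotations(truth, 1)
        up = set(truth.genes_with_role("transition", scope=0, direction="up"))
        term = next(iter(anno.all_terms()))
        with_term = anno.contigs_with_term(term[0])
        f_up = len(with_term & up) / len(up)
        f_all = len(with_term) / cfg.n_genes
        assert f_up == pytest.approx(f_all, abs=0.05)

    def test_minimum_annotation_count_enforced(self):
        cfg = GeneratorConfig(
            n_genes=200, frac_transition_up=0.1, frac_transition_down=0.1,
            n_planted_terms=4, background_prob=0.001, enrichment_ratio=1.0,
            min_term_contigs=10,
        )
        truth = generate_truth(cfg, 0)
        anno = generate_annotations(truth, 1)
        for term in truth.planted_terms:
            assert len(anno.contigs_with_term(term.go_id)) >= cfg.min_term_contigs


class TestDeterminismAndRecovery:
    def test_bundle_byte_identical_for_fixed_seed(self):
        cfg = GeneratorConfig(n_genes=600)
        outs = []
        for _ in range(2):
            _, counts, _, _ = generate_bundle(cfg, 9)
            buf = io.StringIO()
            write_count_table(counts, buf)
            outs.append(buf.getvalue())
        assert outs[0] == outs[1]

    def test_truth_sidecar_roundtrips(self, tmp_path, small_bundle):
        _, truth, _, _, _ = small_bundle
        p = tmp_path / "truth.tsv"
        write_truth_table(truth, p)
        import pandas as pd
        df = pd.read_csv(p, sep="\t", index_col=0, keep_default_na=False)
        assert len(df) == len(truth.gene_ids)
        assert (df["role"] == "null").sum() == len(truth.genes_with_role("null"))

    def test_no_planted_effects_high_stage_correlation(self):
        cfg = GeneratorConfig(
            n_genes=2000, frac_stage_specific=0.0, frac_transition_up=0.0,
            frac_transition_down=0.0, n_planted_terms=0,
        )
        truth = generate_truth(cfg, 0)
        counts = generate_counts(truth, 1)
        prof = log_transform(counts, FilterConfig())
        r = pearson_r(prof.values.iloc[:, 0], prof.values.iloc[:, 1])
        assert r >= 0.9

    def test_correlation_decreases_with_planted_fraction(self):
        rs = []
        for frac in (0.0, 0.2, 0.4):
            cfg = GeneratorConfig(
                n_genes=2000, frac_stage_specific=frac, frac_transition_up=0.0,
                frac_transition_down=0.0, n_planted_terms=0,
            )
            truth = generate_truth(cfg, 0)
            counts = generate_counts(truth, 1)
            prof = log_transform(counts, FilterConfig())
            rs.append(pearson_r(prof.values.iloc[:, 0], prof.values.iloc[:, 1]))
        assert rs[0] > rs[1] > rs[2]
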