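"""Codon-usage indices against hand-evaluated and brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genefam import codon_usage as cu
from genefam import synthetic
from genefam._codons import AA_OF, DEGENERATE_AAS, FAMILIES, SENSE_CODONS

from conftest import random_cds


def brute_force_counts(cds: str) -> dict[str, int]:
    out = {}
    for i in range(0, len(cds) - 2, 3):
        c = cds[i : i + 3]
        out[c] = out.get(c, 0) + 1
    return out


class TestCountCodons:
    def test_direct_count(self):
        c = cu.count_codons("ATGATG")
        assert c.counts == {"ATG": 2} and c.total_codons == 2

    def test_trailing_stop_tracked_separately(self):
        c = cu.count_codons("ATGTTTTAA")
        assert c.counts == {"ATG": 1, "TTT": 1}
        assert c.stop_counts == {"TAA": 1}
        assert c.total_codons == 2

    def test_matches_striding_oracle(self):
        cds = random_cds(300, seed=3)
        c = cu.count_codons(cds)
        oracle = brute_force_counts(cds)
        oracle = {k: v for k, v in oracle.items() if k in SENSE_CODONS}
        assert c.counts == oracle

    def test_ambiguous_codon_skipped(self):
        c = cu.count_codons("ATGANGTTT")
        assert c.skipped_ambiguous == 1
        assert c.counts == {"ATG": 1, "TTT": 1}


class TestRSCU:
    def test_two_codon_family(self):
        counts = cu.CodonCounts("g", {"GAT": 3, "GAC": 1}, 4)
        r = cu.rscu(counts)
        assert r["GAT"] == pytest.approx(1.5) and r["GAC"] == pytest.approx(0.5)

    def test_uniform_usage_is_one(self):
        counts = cu.CodonCounts("g", {c: 2 for c in FAMILIES["L"]}, 12)
        r = cu.rscu(counts)
        assert all(r[c] == pytest.approx(1.0) for c in FAMILIES["L"])

    def test_single_codon_six_fold_family(self):
        counts = cu.CodonCounts("g", {"CTG": 7}, 7)
        r = cu.rscu(counts)
        assert r["CTG"] == pytest.approx(6.0)
        assert all(r[c] == 0.0 for c in FAMILIES["L"] if c != "CTG")

    def test_unobserved_family_undefined(self):
        counts = cu.CodonCounts("g", {"ATG": 1}, 1)
        r = cu.rscu(counts)
        assert all(r[c] is None for c in FAMILIES["L"])

    def test_family_sums_equal_family_size(self):
        cds = random_cds(400, seed=9)
        r = cu.rscu(cu.count_codons(cds))
        for aa, codons in FAMILIES.items():
            vals = [r[c] for c in codons]
            if any(v is not None for v in vals):
                assert sum(vals) == pytest.approx(len(codons), abs=1e-9)


class TestGC3s:
    def test_no_synonymous_sites_is_undefined(self):
        assert cu.gc3s("ATGTGG" * 5) is None

    def test_saturation(self):
        cds = synthetic.generate_cds(1, (100, 100), 1.0, seed=1)["G001"]
        assert cu.gc3s(cds) == pytest.approx(1.0)

    def test_matches_positional_oracle(self):
        cds = random_cds(200, seed=4)
        num = den = 0
        for i in range(0, len(cds), 3):
            codon = cds[i : i + 3]
            if AA_OF.get(codon) in DEGENERATE_AAS:
                den += 1
                num += codon[2] in "GC"
        assert cu.gc3s(cds) == pytest.approx(num / den)


class TestENC:
    def test_single_codon_per_family_gives_20(self):
        counts = {fam[0]: 5 for fam in FAMILIES.values()}
        c = cu.CodonCounts("g", counts, sum(counts.values()))
        assert cu.enc_observed(c) == pytest.approx(20.0)

    def test_uniform_usage_near_61(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            counts: dict[str, int] = {}
            for _ in range(1000):
                aa = list(FAMILIES)[rng.integers(len(FAMILIES))]
                fam = FAMILIES[aa]
                c = fam[rng.integers(len(fam))]
                counts[c] = counts.get(c, 0) + 1
            enc = cu.enc_observed(cu.CodonCounts("g", counts, 1000))
            assert 58.0 <= enc <= 61.0

    def test_range_contract(self):
        for seed in range(10):
            cds = random_cds(60, seed=seed)
            assert 20.0 <= cu.enc_observed(cu.count_codons(cds)) <= 61.0

    def test_permutation_invariance(self, rng):
        cds = random_cds(120, seed=2)
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        shuffled = "".join(np.array(codons)[rng.permutation(len(codons))])
        a = cu.enc_observed(cu.count_codons(cds))
        b = cu.enc_observed(cu.count_codons(shuffled))
        assert a == pytest.approx(b)


class TestENCExpected:
    def test_midpoint_value(self):
        assert cu.enc_expected(0.5) == pytest.approx(60.5)

    def test_limit_toward_one(self):
        assert cu.enc_expected(1 - 1e-12) == pytest.approx(32.0, abs=1e-6)

    def test_near_symmetry_and_maximum(self):
        # the curve's rational part is symmetric about 0.5; the linear +s
        # term shifts mirrored values by exactly (1 - 2s)
        for s in (0.1, 0.25, 0.4):
            assert cu.enc_expected(1 - s) - cu.enc_expected(s) == pytest.approx(1 - 2 * s)
        grid = np.linspace(0.01, 0.99, 981)
        values = [cu.enc_expected(s) for s in grid]
        assert max(values) == pytest.approx(60.5, abs=0.01)
        assert grid[int(np.argmax(values))] == pytest.approx(0.5, abs=0.01)

    @pytest.mark.parametrize("s", [0.0, 1.0, -0.2, 1.5])
    def test_domain_errors(self, s):
        with pytest.raises(ValueError):
            cu.enc_expected(s)


class TestReferenceIndices:
    @pytest.fixture()
    def optimal_gene(self):
        # a gene using one fixed codon per degenerate family
        counts = {sorted(FAMILIES[aa])[0]: 10 for aa in DEGENERATE_AAS}
        cc = cu.CodonCounts("opt", counts, sum(counts.values()))
        ref = cu.reference_weights_from_counts(cc)
        return cc, ref

    def test_all_optimal_upper_bounds(self, optimal_gene):
        cc, ref = optimal_gene
        assert cu.fop(cc, ref) == pytest.approx(1.0)
        assert cu.cbi(cc, ref) == pytest.approx(1.0)
        assert cu.cai(cc, ref) == pytest.approx(1.0)

    def test_cai_log_domain_oracle(self):
        cds = random_cds(250, seed=8)
        cc = cu.count_codons(cds)
        ref = cu.reference_weights_from_counts(cc)
        logs = []
        for codon, n in cc.counts.items():
            if AA_OF[codon] in DEGENERATE_AAS:
                logs.extend([math.log(ref.w[codon])] * n)
        assert cu.cai(cc, ref) == pytest.approx(math.exp(np.mean(logs)))

    def test_met_codon_leaves_cai_unchanged(self):
        cds = random_cds(120, seed=5)
        cc1 = cu.count_codons(cds)
        cc2 = cu.count_codons(cds + "ATG")
        ref = cu.reference_weights_from_counts(cc1)
        assert cu.cai(cc1, ref) == pytest.approx(cu.cai(cc2, ref))

    def test_uniform_usage_cbi_near_zero(self):
        rng = np.random.default_rng(0)
        counts: dict[str, int] = {}
        for _ in range(1000):
            aa = sorted(DEGENERATE_AAS)[rng.integers(len(DEGENERATE_AAS))]
            fam = FAMILIES[aa]
            c = fam[rng.integers(len(fam))]
            counts[c] = counts.get(c, 0) + 1
        cc = cu.CodonCounts("g", counts, 1000)
        ref = cu.ReferenceWeights(
            w={c: 1.0 for c in SENSE_CODONS},
            optimal_set=frozenset(sorted(FAMILIES[aa])[0] for aa in DEGENERATE_AAS),
        )
        assert abs(cu.cbi(cc, ref)) < 0.1

    def test_zero_optimal_codons(self):
        # gene uses only the last codon of each family, reference prefers the first
        counts = {sorted(FAMILIES[aa])[-1]: 5 for aa in DEGENERATE_AAS}
        cc = cu.CodonCounts("g", counts, sum(counts.values()))
        ref = cu.ReferenceWeights(
            w={c: 1.0 for c in SENSE_CODONS},
            optimal_set=frozenset(sorted(FAMILIES[aa])[0] for aa in DEGENERATE_AAS),
        )
        assert cu.fop(cc, ref) == 0.0
        assert cu.cbi(cc, ref) < 0.0

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_optimal_swap_monotonicity(self, seed):
        """Replacing a non-optimal codon by its family's optimal codon never
        decreases FOP, CBI or CAI."""
        cds = random_cds(80, seed=seed % 50)
        cc = cu.count_codons(cds)
        ref = cu.reference_weights_from_counts(cu.count_codons(random_cds(200, seed=seed % 7)))
        rng = np.random.default_rng(seed)
        non_opt = [
            c
            for c, n in cc.counts.items()
            if n > 0 and c not in ref.optimal_set and AA_OF[c] in DEGENERATE_AAS
        ]
        if not non_opt:
            return
        victim = non_opt[rng.integers(len(non_opt))]
        target = next(c for c in ref.optimal_set if AA_OF[c] == AA_OF[victim])
        improved = dict(cc.counts)
        improved[victim] -= 1
        improved[target] = improved.get(target, 0) + 1
        cc2 = cu.CodonCounts("g2", improved, cc.total_codons)
        assert cu.fop(cc2, ref) >= cu.fop(cc, ref) - 1e-12
        assert cu.cbi(cc2, ref) >= cu.cbi(cc, ref) - 1e-12
        assert cu.cai(cc2, ref) >= cu.cai(cc, ref) - 1e-12


class TestCorrelations:
    def test_perfect_linear_relationship(self):
        import pandas as pd

        rng = np.random.default_rng(1)
        gc3 = rng.uniform(0.3, 0.7, 30)
        table = pd.DataFrame(
            {"gc3s": gc3, "fop": 0.5 * gc3 + 0.1, "gc": gc3, "length_nt": rng.integers(300, 3000, 30),
             "exon_length_mean": rng.uniform(100, 500, 30), "cbi": rng.normal(size=30), "cai": rng.normal(size=30)}
        )
        out = cu.correlate_features(table)
        row = out[(out.feature == "gc3s") & (out["index"] == "fop")].iloc[0]
        assert row.r == pytest.approx(1.0)
        assert row.significant

    def test_type_one_error_calibration(self):
        import pandas as pd

        flags = 0
        total = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            table = pd.DataFrame(
                {col: rng.normal(size=100) for col in
                 ("gc", "gc3s", "length_nt", "exon_length_mean", "fop", "cbi", "cai")}
            )
            out = cu.correlate_features(table)
            flags += int(out.significant.sum())
            total += len(out)
        rate = flags / total
        assert 0.0 <= rate <= 0.03  # 1% nominal, +/- 2 points

    def test_constant_column_flagged_nan(self):
        import pandas as pd

        rng = np.random.default_rng(2)
        table = pd.DataFrame(
            {"gc": np.ones(20), "gc3s": rng.normal(size=20), "length_nt": rng.normal(size=20),
             "exon_length_mean": rng.normal(size=20), "fop": rng.normal(size=20),
             "cbi": rng.normal(size=20), "cai": rng.normal(size=20)}
        )
        out = cu.correlate_features(table)
        assert out[(out.feature == "gc") & (out["index"] == "fop")].r.isna().all()


class TestENCPlot:
    def test_uniform_gene_residual_near_zero(self):
        rng = np.random.default_rng(3)
        stats = []
        for seed in range(5):
            counts: dict[str, int] = {}
            for _ in range(1000):
                aa = list(FAMILIES)[rng.integers(len(FAMILIES))]
                fam = FAMILIES[aa]
                c = fam[rng.integers(len(fam))]
                counts[c] = counts.get(c, 0) + 1
            cc = cu.CodonCounts(f"g{seed}", counts, 1000)
            s = cu.gc3s(cc)
            stats.append(
                cu.CodonUsageStats(
                    gene_id=f"g{seed}", gc=0.5, gc3s=s, rscu={}, enc_obs=cu.enc_observed(cc),
                    enc_exp=None, fop=None, cbi=None, cai=None, length_nt=3000,
                )
            )
        table = cu.enc_plot_table(stats)
        assert (table.residual.abs() < 3.0).all()

    def test_undefined_gc3s_excluded(self):
        stats = [
            cu.CodonUsageStats("a", 0.5, None, {}, 55.0, None, None, None, None, 300),
            cu.CodonUsageStats("b", 0.5, 0.5, {}, 55.0, None, None, None, None, 300),
        ]
        table = cu.enc_plot_table(stats)
        assert list(table.gene_id) == ["b"]
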