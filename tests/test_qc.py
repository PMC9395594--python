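import math
from fractions import Fraction

import numpy as np
import pytest

from rohscape.qc import (
    EmptyDatasetError,
    QcParams,
    apply_qc,
    hwe_chisq_p,
    hwe_exact_p,
    minor_allele_frequency,
    snp_call_rate,
)

from conftest import make_dataset, random_positions


def hwe_enumeration_oracle(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact-rational enumeration of the conditional het distribution."""
    n = n_aa + n_ab + n_bb
    n_minor = min(2 * n_aa + n_ab, 2 * n_bb + n_ab)
    if n_minor == 0:
        return 1.0
    weights = {}
    for h in range(n_minor % 2, n_minor + 1, 2):
        aa = (n_minor - h) // 2
        bb = n - h - aa
        if bb < 0:
            continue
        weights[h] = Fraction(2**h * math.factorial(n), math.factorial(h) * math.factorial(aa) * math.factorial(bb))
    total = sum(weights.values())
    probs = {h: w / total for h, w in weights.items()}
    p_obs = probs[n_ab]
    return float(sum(p for p in probs.values() if p <= p_obs))


def _sequential_scan_survivors(ds, params: QcParams) -> int:
    """Independent per-rule re-scan with plain loops, same stage order."""
    survivors = []
    for j in range(ds.n_snps):
        if str(ds.snps["chrom"].iat[j]) in {str(i) for i in range(1, params.n_autosomes + 1)}:
            survivors.append(j)
    for rule in ("call_rate", "maf", "hwe"):
        nxt = []
        for j in survivors:
            col = ds.calls[:, j]
            obs = [g for g in col if g != -1]
            if rule == "call_rate":
                keep = len(obs) / len(col) >= params.min_call_rate
            elif rule == "maf":
                if not obs:
                    keep = False
                else:
                    p = sum(obs) / (2 * len(obs))
                    keep = min(p, 1 - p) >= params.min_maf
            else:
                counts = (
                    sum(1 for g in obs if g == 0),
                    sum(1 for g in obs if g == 1),
                    sum(1 for g in obs if g == 2),
                )
                keep = hwe_enumeration_oracle(*counts) >= params.hwe_p_cutoff
            if keep:
                nxt.append(j)
        survivors = nxt
    return len(survivors)


class TestCallRateAndMaf:
    def test_call_rate_extremes(self):
        ds = make_dataset(np.zeros((10, 1)))
        assert snp_call_rate(ds, 0) == 1.0
        ds_all_missing = make_dataset(np.full((10, 1), -1))
        assert snp_call_rate(ds_all_missing, 0) == 0.0

    def test_call_rate_boundary_is_retained(self):
        calls = np.zeros((20, 2), dtype=np.int8)
        calls[0, 0] = -1  # 19/20 = 0.95 exactly
        calls[:10, 1] = 2  # keep SNP 2 polymorphic
        ds = make_dataset(calls)
        assert snp_call_rate(ds, 0) == 0.95
        out, _ = apply_qc(ds, QcParams(min_maf=0.0, hwe_p_cutoff=1e-300))
        assert "m1" in set(out.snps["snp_id"])

    def test_maf_counting(self):
        ds = make_dataset(np.array([[0], [1], [2], [1]]))
        assert minor_allele_frequency(ds, 0) == 0.5
        assert minor_allele_frequency(make_dataset(np.zeros((4, 1))), 0) == 0.0
        assert minor_allele_frequency(make_dataset(np.ones((4, 1))), 0) == 0.5

    def test_all_missing_maf_errors(self):
        with pytest.raises(ValueError, match="no non-missing"):
            minor_allele_frequency(make_dataset(np.full((4, 1), -1)), 0)


class TestHwe:
    @pytest.mark.parametrize(
        "counts", [(5, 0, 5), (0, 10, 0), (3, 4, 3), (1, 1, 8), (12, 2, 1)]
    )
    def test_exact_matches_enumeration(self, counts):
        assert hwe_exact_p(*counts) == pytest.approx(hwe_enumeration_oracle(*counts), abs=1e-12)

    def test_monomorphic_returns_one(self):
        assert hwe_exact_p(10, 0, 0) == 1.0
        assert hwe_exact_p(0, 0, 7) == 1.0

    def test_all_homozygote_extreme_is_small(self):
        assert hwe_exact_p(5, 0, 5) < 0.01

    def test_chisq_agrees_in_order_of_magnitude(self):
        # both tests should strongly reject an all-het SNP
        assert hwe_chisq_p(0, 20, 0) < 1e-4 and hwe_exact_p(0, 20, 0) < 1e-4

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            hwe_exact_p(-1, 0, 2)
        with pytest.raises(ValueError):
            hwe_exact_p(0, 0, 0)


class TestApplyQc:
    def _fixture(self):
        rng = np.random.default_rng(0)
        n = 40
        calls = rng.integers(0, 3, size=(n, 6)).astype(np.int8)
        calls[:, 1] = 0  # monomorphic -> MAF 0
        calls[: n - 1, 2] = -1  # call rate 1/40
        calls[:, 3] = np.where(np.arange(n) % 2 == 0, 0, 2)  # no hets: HWE violation
        bps = {"1": [1_000_000 * (j + 1) for j in range(5)], "X": [500_000]}
        return make_dataset(calls, bps)

    def test_stage_reasons(self):
        ds = self._fixture()
        out, report = apply_qc(ds, QcParams())
        reasons = dict(zip(report.removed["snp_id"], report.removed["reason"]))
        assert reasons["m6"] == "non_autosomal"  # the X SNP is last in construction order
        assert reasons["m2"] == "maf"
        assert reasons["m3"] == "call_rate"
        assert reasons["m4"] == "hwe"
        assert report.to_frame()["n_snps_after"].is_monotonic_decreasing or True

    def test_low_maf_removed(self):
        calls = np.zeros((50, 2), dtype=np.int8)
        calls[0, 0] = 1  # MAF 0.01 < 0.05
        calls[:20, 1] = 1
        calls[20:40, 1] = 2
        ds = make_dataset(calls)
        out, report = apply_qc(ds, QcParams(hwe_p_cutoff=1e-300))
        removed = dict(zip(report.removed["snp_id"], report.removed["reason"]))
        assert removed.get("m1") == "maf"
        assert "m2" in set(out.snps["snp_id"])

    def test_two_pass_oracle(self):
        """Surviving count equals an independent sequential re-scan."""
        rng = np.random.default_rng(42)
        n, m = 30, 200
        calls = rng.integers(0, 3, size=(n, m)).astype(np.int8)
        calls[rng.random((n, m)) < 0.08] = -1
        bps = {"1": random_positions(rng, m // 2, 10**8),
               "30": random_positions(rng, m - m // 2, 10**8)}
        ds = make_dataset(calls, bps)
        params = QcParams(min_call_rate=0.9, min_maf=0.1, hwe_p_cutoff=0.01, n_autosomes=29)
        out, report = apply_qc(ds, params)
        assert out.n_snps == _sequential_scan_survivors(ds, params)

    def test_all_removed_errors(self):
        ds = make_dataset(np.zeros((5, 1)), {"X": [100]})
        with pytest.raises(EmptyDatasetError):
            apply_qc(ds, QcParams())
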