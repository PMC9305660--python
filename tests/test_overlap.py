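"""CNV/SNV overlap scenario engine: closed forms, feasibility, oracles."""

import numpy as np
import pytest

from clonefish.overlap import CnvType, NoFeasibleCaseError, OverlapCase, \
    enumerate_overlap_cases, predict_vaf, resolve_overlap


def mk_case(w, x, y, z, cnv_type=CnvType.DELETION, cnv_value=1):
    return OverlapCase(scenario=1, cnv_value=cnv_value, cnv_type=cnv_type,
                       w=w, x=x, y=y, z=z, ccf_cnv=w + x, vaf=0.0,
                       ccf_snv=w + y, feasible=True, violation=0.0)


class TestPredictVaf:
    def test_deletion_direct_substitution(self):
        case = mk_case(0.375, 0.125, 0.0, 0.5)
        assert predict_vaf(case) == pytest.approx(0.25)

    def test_no_mutant_allele_anywhere(self):
        for ct in CnvType:
            assert predict_vaf(mk_case(0.0, 0.5, 0.0, 0.5, ct,
                                       cnv_value=0)) == 0.0

    def test_duplication_two_mutant_copies(self):
        case = mk_case(0.5, 0.0, 0.0, 0.5, CnvType.DUPLICATION, cnv_value=2)
        assert predict_vaf(case) == pytest.approx(0.4)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            predict_vaf(mk_case(0.0, 0.0, 0.0, 0.0))


class TestEnumerateCases:
    def test_deletion_worked_example(self):
        cases = enumerate_overlap_cases(0.25, 0.5, CnvType.DELETION)
        by = {(c.scenario, c.cnv_value): c for c in cases}
        assert len(cases) == 4
        assert by[(1, 1)].feasible and by[(1, 1)].ccf_snv \
            == pytest.approx(0.375)
        assert by[(2, 0)].feasible and by[(2, 0)].ccf_snv \
            == pytest.approx(0.875)
        assert not by[(2, 1)].feasible and by[(2, 1)].y < 0
        assert by[(3, 1)].feasible and by[(3, 1)].ccf_snv \
            == pytest.approx(0.375)

    def test_duplication_worked_example(self):
        cases = enumerate_overlap_cases(0.4, 0.5, CnvType.DUPLICATION)
        by = {(c.scenario, c.cnv_value): c for c in cases}
        assert by[(2, 2)].feasible and by[(2, 2)].ccf_snv \
            == pytest.approx(0.5) and by[(2, 2)].y == pytest.approx(0.0)
        assert by[(2, 1)].feasible and by[(2, 1)].ccf_snv \
            == pytest.approx(1.0)
        assert not by[(1, 1)].feasible
        assert not by[(3, 1)].feasible

    @pytest.mark.parametrize("cnv_type", list(CnvType))
    def test_zero_vaf_gives_zero_ccf_everywhere(self, cnv_type):
        for c in enumerate_overlap_cases(0.0, 0.4, cnv_type):
            assert c.ccf_snv == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("cnv_type", list(CnvType))
    @pytest.mark.parametrize("vaf", [0.0, 0.1, 0.25, 0.4, 0.5])
    def test_absent_cnv_collapses_to_heterozygous_rule(self, cnv_type, vaf):
        for c in enumerate_overlap_cases(vaf, 0.0, cnv_type):
            assert c.ccf_snv == pytest.approx(2 * vaf, abs=1e-12)

    def test_roundtrip_feasible_cases_reproduce_vaf(self):
        rng = np.random.default_rng(1)
        for _ in range(10_000):
            vaf = rng.uniform(0, 1)
            ccf_cnv = rng.uniform(0, 1)
            ct = CnvType.DELETION if rng.integers(2) else CnvType.DUPLICATION
            for case in enumerate_overlap_cases(vaf, ccf_cnv, ct):
                if case.feasible:
                    assert predict_vaf(case) == pytest.approx(vaf, abs=1e-9)

    def test_exclusion_agrees_with_lattice_search(self):
        # whenever the closed form leaves [0,1], no exactly-valid
        # population on a 0.001 lattice reproduces the target VAF; when
        # it is exactly feasible, one does.
        rng = np.random.default_rng(7)
        grid = np.arange(0.0, 1.0 + 1e-12, 0.001)
        for _ in range(60):
            vaf = float(rng.uniform(0, 1))
            C = float(rng.uniform(0, 1))
            ct = CnvType.DELETION if rng.integers(2) else CnvType.DUPLICATION
            n = 1 if ct == CnvType.DELETION else 3
            for case in enumerate_overlap_cases(vaf, C, ct, eps=0.0):
                if case.scenario == 1:
                    w = grid[grid <= C + 1e-12]
                    x, y, z = C - w, 0.0, 1.0 - C
                elif case.scenario == 2:
                    y = grid[grid <= 1.0 - C + 1e-12]
                    w, x, z = C, 0.0, 1.0 - C - y
                else:
                    y = grid[grid <= 1.0 - C + 1e-12]
                    w, x, z = 0.0, C, 1.0 - C - y
                denom = n * (w + x) + 2 * (y + z)
                vafs = (case.cnv_value * w + y) / denom
                best = np.min(np.abs(vafs - vaf)) if np.size(vafs) else np.inf
                if case.violation > 2e-3:
                    assert best > 1e-12
                else:
                    assert best <= 3e-3

    def test_continuity_away_from_boundaries(self):
        for ct in CnvType:
            a = enumerate_overlap_cases(0.2, 0.3, ct)
            b = enumerate_overlap_cases(0.2 + 1e-7, 0.3 + 1e-7, ct)
            for ca, cb in zip(a, b):
                assert abs(ca.ccf_snv - cb.ccf_snv) < 1e-5


class TestResolveOverlap:
    def test_ambiguous_duplication(self):
        estimates, cases = resolve_overlap(0.4, 0.5, CnvType.DUPLICATION)
        assert len(estimates) == 2
        assert all("ambiguous" in e.flags for e in estimates)

    def test_ambiguous_deletion(self):
        estimates, _ = resolve_overlap(0.25, 0.5, CnvType.DELETION)
        assert len(estimates) == 3

    def test_degenerate_no_cnv_single_estimate(self):
        estimates, _ = resolve_overlap(0.25, 0.0, CnvType.DELETION)
        assert len(estimates) == 1
        assert estimates[0].ccf == pytest.approx(0.5)
        assert "ambiguous" not in estimates[0].flags

    def test_inconsistent_inputs_raise(self):
        with pytest.raises(NoFeasibleCaseError, match="eps"):
            resolve_overlap(0.9, 0.1, CnvType.DELETION)

    def test_unique_case_not_flagged(self):
        # high-CCF deletion: only the CNV-first ordering survives
        estimates, cases = resolve_overlap(0.20, 0.95, CnvType.DELETION)
        assert len(estimates) == 1
        assert cases[0].scenario == 1
        assert "ambiguous" not in estimates[0].flags
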