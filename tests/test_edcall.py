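"""The contrast caller: worked filter examples, lattice oracle, spectrum, nulls."""
from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pytest

from adarcall.edcall import (
    CallerConfig,
    CallerError,
    SampleSheet,
    call_sites,
    detection_power,
    mismatch_frequencies,
    spectrum,
)
from adarcall.evaluate import evaluate_recovery, run_in_memory
from adarcall.simdata import SimConfig

from conftest import make_consensus, make_pileup, make_reference

REF = make_reference({"t1": "CCCCCACCCC"})  # site at pos 5, ref A
SITE = 5


def sheet4() -> SampleSheet:
    return SampleSheet(
        controls=[f"c{i}" for i in range(1, 5)],
        knockdowns={"adar2": [f"k{i}" for i in range(1, 5)]},
    )


def site_pileups(ctrl, kd):
    """Per-sample pileups from (alt_count, depth) pairs at the test site."""
    tables = {}
    for sid, (alt, depth) in {**ctrl, **kd}.items():
        tables[sid] = make_pileup(
            REF, {"t1": {SITE: {"A": depth - alt, "G": alt}}}
        )
    return tables


class TestWorkedExamples:
    def test_support_below_four_not_called(self):
        tables = site_pileups(
            {f"c{i}": (2, 20) for i in range(1, 5)},
            {f"k{i}": (0, 10) for i in range(1, 5)},
        )
        calls = call_sites(tables, sheet4(), "adar2", make_consensus(REF))
        assert calls == []

    def test_clean_contrast_called_with_full_reduction(self):
        tables = site_pileups(
            {f"c{i}": (4, 40) for i in range(1, 5)},
            {f"k{i}": (0, 10) for i in range(1, 5)},
        )
        (call,) = call_sites(tables, sheet4(), "adar2", make_consensus(REF))
        assert (call.transcript_id, call.pos, call.ref, call.alt) == ("t1", SITE, "A", "G")
        assert call.mean_control_freq == pytest.approx(0.10)
        assert call.reduction == pytest.approx(1.0)
        assert call.mismatch_class == "A>G"

    def test_one_knockdown_replicate_above_half_mean_blocks_call(self):
        kd = {f"k{i}": (0, 50) for i in range(1, 4)}
        kd["k4"] = (3, 50)  # freq 0.06 > 0.5 * 0.10
        tables = site_pileups({f"c{i}": (4, 40) for i in range(1, 5)}, kd)
        assert call_sites(tables, sheet4(), "adar2", make_consensus(REF)) == []

    def test_masked_position_never_called(self):
        tables = site_pileups(
            {f"c{i}": (4, 40) for i in range(1, 5)},
            {f"k{i}": (0, 10) for i in range(1, 5)},
        )
        cons = make_consensus(REF, masked_positions={"t1": [SITE]})
        assert call_sites(tables, sheet4(), "adar2", cons) == []

    def test_low_knockdown_coverage_blocks_call(self):
        tables = site_pileups(
            {f"c{i}": (4, 40) for i in range(1, 5)},
            {f"k{i}": (0, 3) for i in range(1, 5)},  # depth < 4
        )
        assert call_sites(tables, sheet4(), "adar2", make_consensus(REF)) == []

    def test_empty_replicate_list_raises(self):
        sheet = SampleSheet(controls=[], knockdowns={"adar2": ["k1"]})
        with pytest.raises(CallerError):
            call_sites({}, sheet, "adar2", make_consensus(REF))

    def test_unknown_condition_raises(self):
        with pytest.raises(CallerError, match="adar1"):
            call_sites(site_pileups({f"c{i}": (4, 40) for i in range(1, 5)},
                                    {f"k{i}": (0, 10) for i in range(1, 5)}),
                       sheet4(), "adar1", make_consensus(REF))


def brute_force_called(ctrl, kd, cfg: CallerConfig) -> bool:
    """Independent re-statement of the filter cascade on explicit numbers."""
    freqs = [a / d if d else 0.0 for a, d in ctrl]
    if not all(d >= cfg.control_min_cov for _, d in ctrl):
        return False
    if not all(f >= cfg.control_min_freq for f in freqs):
        return False
    if not all(a >= cfg.min_support_reads for a, _ in ctrl):
        return False
    mean_ctrl = sum(freqs) / len(freqs)
    for a, d in kd:
        if d < cfg.kd_min_cov:
            return False
        if (a / d if d else 0.0) > cfg.max_kd_to_control_ratio * mean_ctrl:
            return False
    return True


class TestLatticeOracle:
    def test_caller_equals_brute_force_on_lattice(self):
        """Exhaustive grid of per-replicate (alt, depth) values, symmetric reps."""
        cfg = CallerConfig()
        cons = make_consensus(REF)
        for c_alt, c_depth, k_alt, k_depth in itertools.product(
            (0, 1, 2, 4, 6), (8, 10, 20, 40), (0, 1, 2, 3), (3, 4, 20, 60)
        ):
            if c_alt > c_depth or k_alt > k_depth:
                continue
            ctrl = {f"c{i}": (c_alt, c_depth) for i in range(1, 5)}
            kd = {f"k{i}": (k_alt, k_depth) for i in range(1, 5)}
            called = bool(call_sites(site_pileups(ctrl, kd), sheet4(), "adar2", cons, cfg))
            expected = brute_force_called(
                [(c_alt, c_depth)] * 4, [(k_alt, k_depth)] * 4, cfg
            )
            assert called == expected, (c_alt, c_depth, k_alt, k_depth)

    def test_caller_equals_brute_force_asymmetric_replicates(self):
        cfg = CallerConfig()
        cons = make_consensus(REF)
        rng = np.random.default_rng(8)
        for _ in range(300):
            ctrl_vals = [(int(rng.integers(0, 8)), int(rng.integers(8, 60))) for _ in range(4)]
            kd_vals = [(int(rng.integers(0, 4)), int(rng.integers(2, 40))) for _ in range(4)]
            ctrl = {f"c{i+1}": v for i, v in enumerate(ctrl_vals)}
            kd = {f"k{i+1}": v for i, v in enumerate(kd_vals)}
            called = bool(call_sites(site_pileups(ctrl, kd), sheet4(), "adar2", cons, cfg))
            assert called == brute_force_called(ctrl_vals, kd_vals, cfg)

    def test_threshold_monotonicity(self, clean_experiment):
        data = clean_experiment
        base = CallerConfig()
        baseline = {
            (c.transcript_id, c.pos, c.alt)
            for c in call_sites(data.pileups, data.sheet, "adar2", data.consensus, base)
        }
        stricter = [
            dataclasses.replace(base, control_min_freq=0.10),
            dataclasses.replace(base, control_min_cov=25),
            dataclasses.replace(base, min_support_reads=8),
            dataclasses.replace(base, max_kd_to_control_ratio=0.2),
        ]
        for cfg in stricter:
            calls = call_sites(data.pileups, data.sheet, "adar2", data.consensus, cfg)
            assert {(c.transcript_id, c.pos, c.alt) for c in calls} <= baseline


class TestMismatchFrequencies:
    def test_arithmetic_and_mask_omission(self):
        tables = {"s1": make_pileup(REF, {"t1": {SITE: {"A": 18, "G": 2},
                                                 7: {"C": 10, "T": 5}}})}
        cons = make_consensus(REF, masked_positions={"t1": [7]})
        df = mismatch_frequencies(tables, cons)
        assert len(df) == 1  # masked pos 7 omitted
        row = df.iloc[0]
        assert (row.pos, row.alt, row.alt_count, row.depth) == (SITE, "G", 2, 20)
        assert row.freq == pytest.approx(0.10)

    def test_frequencies_match_per_read_recount(self, clean_experiment):
        data = clean_experiment
        df = mismatch_frequencies({"control_1": data.pileups["control_1"]}, data.consensus)
        table = data.pileups["control_1"]
        sub = df.sample(n=min(30, len(df)), random_state=0)
        for _, row in sub.iterrows():
            mat = table.count_matrix(row.transcript_id)
            assert row.alt_count == mat[row.pos, "ACGT".index(row.alt)]
            assert row.depth == mat[row.pos, :4].sum()
            assert row.unique_support == table.unique_support(
                row.transcript_id, row.pos, row.alt
            )


class TestSpectrum:
    def test_empty_calls(self):
        spec = spectrum([])
        assert spec.total == 0 and all(v == 0 for v in spec.counts.values())
        assert spec.signature_fraction == 0.0

    def test_clean_simulation_spectrum_is_pure_signature(self, clean_experiment, clean_calls):
        spec = spectrum(clean_calls)
        assert spec.total == len(clean_calls) > 0
        assert spec.signature_count == spec.total
        assert set(k for k, v in spec.counts.items() if v) <= {"A>G", "T>C"}
        anti = clean_experiment.truth.antisense
        expected_tc = sum(
            1 for c in clean_calls if c.transcript_id in anti
        )
        assert spec.counts["T>C"] == expected_tc


class TestNullAndRecovery:
    def test_permutation_null_yields_near_zero_calls(self):
        """kd_reduction = 0: knockdowns behave as controls, contrast finds ~nothing."""
        cfg = SimConfig(n_transcripts=6, length_range=(600, 800), n_edit_sites=15,
                        control_freq_range=(0.2, 0.6), kd_reduction=0.0,
                        coverage_rna=50, error_rate=0.0, seed=33)
        data = run_in_memory(cfg, conditions=("adar2",))
        calls = call_sites(data.pileups, data.sheet, "adar2", data.consensus)
        assert len(calls) <= 1

    def test_recall_matches_analytic_detection_power(self):
        """Empirical recall tracks the binomial power prediction at 30x."""
        cfg = SimConfig(n_transcripts=20, length_range=(800, 1000), n_edit_sites=40,
                        control_freq_range=(0.05, 0.60), kd_reduction=1.0,
                        coverage_rna=30, error_rate=0.0, antisense_fraction=0.0,
                        seed=55)
        data = run_in_memory(cfg, conditions=("adar2",))
        calls = call_sites(data.pileups, data.sheet, "adar2", data.consensus)
        stats = evaluate_recovery(data.truth, calls, "adar2")
        predicted = float(np.mean([
            detection_power(s.control_freq, cfg.coverage_rna)
            for s in data.truth.edit_sites
        ]))
        assert stats.precision == 1.0
        assert abs(stats.recall - predicted) < 0.15

    def test_every_site_with_passing_evidence_is_recovered(self, clean_experiment, clean_calls):
        """Conditional on realized evidence meeting the thresholds, recall is 1."""
        data = clean_experiment
        cfg = CallerConfig()
        called = {(c.transcript_id, c.pos, c.alt) for c in clean_calls}
        for s in data.truth.edit_sites:
            ctrl = []
            for sid in data.sheet.controls:
                mat = data.pileups[sid].count_matrix(s.transcript_id)
                ctrl.append((int(mat[s.pos, "ACGT".index(s.alt)]), int(mat[s.pos, :4].sum())))
            kd = []
            for sid in data.sheet.knockdowns["adar2"]:
                mat = data.pileups[sid].count_matrix(s.transcript_id)
                kd.append((int(mat[s.pos, "ACGT".index(s.alt)]), int(mat[s.pos, :4].sum())))
            evidence_ok = brute_force_called(ctrl, kd, cfg) and not data.consensus.is_masked(
                s.transcript_id, s.pos
            )
            assert ((s.transcript_id, s.pos, s.alt) in called) == evidence_ok
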