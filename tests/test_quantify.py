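"""Quantification chain: depth normalization, baseline, ratios, exon pooling."""

import math

import numpy as np
import pytest

from mlpaseq.probe_design import Mix
from mlpaseq.quantify import (
    DepthNormalized,
    QuantifyError,
    build_baseline,
    compute_ratios,
    depth_normalize,
    load_baseline,
    summarize_exons,
    write_baseline,
)
from mlpaseq.read_counting import LibraryCounts
from mlpaseq.simulate import (
    CNEvent,
    SimulationConfig,
    TruthSet,
    simulate_counts,
    simulate_efficiencies,
)


def lib_for(design, counts, mix=Mix.detection, sample_id="s"):
    full = {p.probe_id: 0 for p in design.probes_in_mix(mix)}
    full.update(counts)
    return LibraryCounts(sample_id=sample_id, mix=mix, counts=full)


def uniform_lib(design, c, mix=Mix.detection, **kw):
    return lib_for(
        design, {p.probe_id: c for p in design.probes_in_mix(mix)}, mix, **kw
    )


class TestDepthNormalize:
    def test_uniform_counts_normalize_to_one(self, small_design):
        norm = depth_normalize(uniform_lib(small_design, 500), small_design)
        assert norm.normalizer == 500
        assert all(abs(v - 1) < 1e-12 for v in norm.values.values())

    def test_hand_arithmetic(self, small_design):
        probes = small_design.probes_in_mix(Mix.detection)[:4]
        design_subset = type(small_design)(
            [p for p in small_design.probes if p in probes]
        )
        counts = dict(zip([p.probe_id for p in probes], [100, 200, 300, 400]))
        norm = depth_normalize(lib_for(design_subset, counts), design_subset)
        assert norm.normalizer == 250
        got = [norm.values[p.probe_id] for p in probes]
        assert got == pytest.approx([0.4, 0.8, 1.2, 1.6])

    def test_scale_invariance(self, small_design):
        lib = lib_for(
            small_design,
            {p.probe_id: 100 + 13 * i for i, p in
             enumerate(small_design.probes_in_mix(Mix.detection))},
        )
        scaled = lib_for(
            small_design, {pid: 7 * c for pid, c in lib.counts.items()}
        )
        a = depth_normalize(lib, small_design).values
        b = depth_normalize(scaled, small_design).values
        assert all(abs(a[k] - b[k]) < 1e-12 for k in a)

    def test_amplification_probes_excluded_from_normalizer(self, amp_design):
        base = uniform_lib(amp_design, 1000)
        amp_probe = next(
            p for p in amp_design.probes_in_mix(Mix.detection)
            if p.gene in amp_design.amplification_genes
        )
        boosted_counts = dict(base.counts)
        boosted_counts[amp_probe.probe_id] = 100_000
        boosted = lib_for(amp_design, boosted_counts)
        a = depth_normalize(base, amp_design)
        b = depth_normalize(boosted, amp_design)
        assert a.normalizer == b.normalizer
        for pid in a.values:
            if pid != amp_probe.probe_id:
                assert a.values[pid] == b.values[pid]
        assert b.values[amp_probe.probe_id] == pytest.approx(100.0)

    def test_zero_coverage_is_an_error(self, small_design):
        with pytest.raises(QuantifyError, match="zero mean coverage"):
            depth_normalize(uniform_lib(small_design, 0), small_design)

    def test_idempotence(self, small_design):
        lib = lib_for(
            small_design,
            {p.probe_id: 900 + 31 * i for i, p in
             enumerate(small_design.probes_in_mix(Mix.detection))},
        )
        once = depth_normalize(lib, small_design)
        again = depth_normalize(
            LibraryCounts(sample_id="s", mix=Mix.detection, counts=once.values),
            small_design,
        )
        assert all(
            abs(once.values[k] - again.values[k]) < 1e-9 for k in once.values
        )


class TestBaseline:
    def test_identical_controls_have_zero_cv(self, small_design):
        lib = uniform_lib(small_design, 800)
        norms = [depth_normalize(lib, small_design) for _ in range(3)]
        base = build_baseline(norms, small_design)
        assert all(cv == 0 for cv in base.per_probe_cv.values())
        assert base.per_probe_mean == pytest.approx(norms[0].values)

    def test_mean_of_symmetric_controls(self, small_design):
        pid = small_design.probes_in_mix(Mix.detection)[0].probe_id
        norms = []
        for scale in (0.9, 1.1):
            values = {
                p.probe_id: 1.0 for p in small_design.probes_in_mix(Mix.detection)
            }
            values[pid] = scale
            norms.append(
                DepthNormalized("c", Mix.detection, values, normalizer=1000.0)
            )
        base = build_baseline(norms, small_design, min_controls=2)
        assert base.per_probe_mean[pid] == pytest.approx(1.0)

    def test_too_few_controls(self, small_design):
        norm = depth_normalize(uniform_lib(small_design, 800), small_design)
        with pytest.raises(QuantifyError, match="at least 3"):
            build_baseline([norm, norm], small_design)

    def test_mixed_mixes_rejected(self, small_design):
        det = depth_normalize(uniform_lib(small_design, 800), small_design)
        conf = depth_normalize(
            uniform_lib(small_design, 800, mix=Mix.confirmation), small_design
        )
        with pytest.raises(QuantifyError, match="one baseline per mix"):
            build_baseline([det, conf, det], small_design)

    def test_high_cv_probe_marked_unusable(self, small_design):
        pid = small_design.probes_in_mix(Mix.detection)[0].probe_id
        norms = []
        for scale in (0.3, 1.7, 0.4, 1.6):
            values = {
                p.probe_id: 1.0 for p in small_design.probes_in_mix(Mix.detection)
            }
            values[pid] = scale
            norms.append(
                DepthNormalized("c", Mix.detection, values, normalizer=1000.0)
            )
        base = build_baseline(norms, small_design)
        assert pid in base.unusable

    def test_control_noise_recovered_as_cv(self, small_design):
        """8 controls at ratio-scale noise SD 0.103: the mean per-probe CV
        across controls recovers the generator's noise (plus a small Poisson
        term), within sampling error."""
        cfg = SimulationConfig(seed=31, probe_noise_sd=0.103)
        rng = np.random.default_rng(cfg.seed)
        eff = simulate_efficiencies(small_design, cfg, rng)
        norms = [
            depth_normalize(
                simulate_counts(
                    small_design, TruthSet(), cfg, Mix.detection, rng, eff,
                    sample_id=f"c{i}", is_control=True,
                ),
                small_design,
            )
            for i in range(8)
        ]
        base = build_baseline(norms, small_design)
        mean_cv = float(np.mean(list(base.per_probe_cv.values())))
        assert mean_cv == pytest.approx(0.103, abs=0.015)

    def test_round_trip_and_checksum_guard(self, tmp_path, small_design, amp_design):
        norm = depth_normalize(uniform_lib(small_design, 800), small_design)
        base = build_baseline([norm] * 3, small_design)
        path = tmp_path / "baseline.tsv"
        write_baseline(base, path)
        reloaded = load_baseline(path, small_design)
        assert reloaded.per_probe_mean == pytest.approx(base.per_probe_mean)
        assert reloaded.n_controls == 3
        with pytest.raises(QuantifyError, match="design"):
            load_baseline(path, amp_design)


class TestRatios:
    def _baseline(self, design, mix=Mix.detection):
        norm = depth_normalize(uniform_lib(design, 1000, mix=mix), design)
        return build_baseline([norm] * 3, design)

    def test_sample_identical_to_baseline_gives_unity(self, small_design):
        base = self._baseline(small_design)
        sample = depth_normalize(uniform_lib(small_design, 1000), small_design)
        ratios = compute_ratios(sample, base)
        assert all(r == pytest.approx(1.0) for r in ratios.ratios.values())

    def test_halved_values_give_half_ratios(self, small_design):
        base = self._baseline(small_design)
        sample = depth_normalize(uniform_lib(small_design, 1000), small_design)
        halved = DepthNormalized(
            "s", Mix.detection,
            {k: v / 2 for k, v in sample.values.items()}, sample.normalizer,
        )
        ratios = compute_ratios(halved, base)
        assert all(r == pytest.approx(0.5) for r in ratios.ratios.values())

    def test_unusable_probes_excluded_with_reason(self, small_design):
        base = self._baseline(small_design)
        pid = next(iter(base.per_probe_mean))
        base.unusable[pid] = "below 500x floor in control c1"
        sample = depth_normalize(uniform_lib(small_design, 1000), small_design)
        ratios = compute_ratios(sample, base)
        assert pid not in ratios.ratios
        assert "floor" in ratios.excluded[pid]

    def test_mix_mismatch_rejected(self, small_design):
        base = self._baseline(small_design)
        conf = depth_normalize(
            uniform_lib(small_design, 1000, mix=Mix.confirmation), small_design
        )
        with pytest.raises(QuantifyError, match="mix"):
            compute_ratios(conf, base)

    def test_simulated_het_deletion_ratios(self, small_design, noiseless_config):
        gene = "GENE1"
        exons = small_design.exon_order(gene)[:2]
        truth = TruthSet(events=[CNEvent(gene, tuple(exons), copies=1)])
        rng = np.random.default_rng(0)
        lib = simulate_counts(
            small_design, truth, noiseless_config, Mix.detection, rng
        )
        base = self._baseline(small_design)
        ratios = compute_ratios(depth_normalize(lib, small_design), base)
        for p in small_design.probes_in_mix(Mix.detection):
            expected = 0.5 if (p.gene == gene and p.exon_label in exons) else 1.0
            # normalizer shifts slightly because deleted probes sit in it
            assert ratios.ratios[p.probe_id] == pytest.approx(expected, rel=0.08)


class TestExonSummaries:
    def test_two_probe_exon_pooled_mean_and_sd(self, small_design):
        exon = small_design.exon_labels()[0]
        det_probe = small_design.probes_for_exon(exon, Mix.detection)[0]
        conf_probe = small_design.probes_for_exon(exon, Mix.confirmation)[0]
        det = _ratio_matrix(small_design, Mix.detection, {det_probe.probe_id: 0.9})
        conf = _ratio_matrix(
            small_design, Mix.confirmation, {conf_probe.probe_id: 1.1}
        )
        summary = next(
            s for s in summarize_exons(det, conf, small_design)
            if s.exon_label == exon
        )
        assert summary.mean_ratio == pytest.approx(1.0)
        assert summary.sd_ratio == pytest.approx(0.14142, abs=1e-4)
        assert summary.n_probes == 2

    def test_single_probe_exon_has_zero_sd(self, small_design):
        exon = small_design.exon_labels()[0]
        det_probe = small_design.probes_for_exon(exon, Mix.detection)[0]
        det = _ratio_matrix(small_design, Mix.detection, {det_probe.probe_id: 1.6})
        summary = next(
            s for s in summarize_exons(det, None, small_design)
            if s.exon_label == exon
        )
        assert summary.mean_ratio == pytest.approx(1.6)
        assert summary.sd_ratio == 0.0
        assert summary.n_probes == 1

    def test_exon_without_usable_probes_flagged_missing(self, small_design):
        exon = small_design.exon_labels()[0]
        det = _ratio_matrix(small_design, Mix.detection, {}, exclude_exon=exon)
        conf = _ratio_matrix(small_design, Mix.confirmation, {}, exclude_exon=exon)
        summary = next(
            s for s in summarize_exons(det, conf, small_design)
            if s.exon_label == exon
        )
        assert summary.missing and summary.n_probes == 0
        # every design exon is emitted exactly once
        labels = [s.exon_label for s in summarize_exons(det, conf, small_design)]
        assert labels == small_design.exon_labels()


def _ratio_matrix(design, mix, overrides, exclude_exon=None):
    from mlpaseq.quantify import RatioMatrix

    ratios = {}
    for p in design.probes_in_mix(mix):
        if p.exon_label == exclude_exon:
            continue
        ratios[p.probe_id] = overrides.get(p.probe_id, 1.0)
    return RatioMatrix(sample_id="s", mix=mix, ratios=ratios)


class TestNoisePropagation:
    def test_exon_pooling_reduces_sd_like_sqrt_k(self):
        from mlpaseq.simulate import pooled_noise_sd

        for k in (2, 3, 4):
            sd = pooled_noise_sd(
                n_exons=50_000, probes_per_exon=k, probe_sd=0.103, seed=k
            )
            assert sd == pytest.approx(0.103 / math.sqrt(k), abs=0.004)

    def test_deletion_skew_inflates_other_ratios(self, small_design, noiseless_config):
        """A large heterozygous deletion spanning many normalization probes
        deflates the normalizer and inflates every other probe's ratio —
        the assay's known false-positive mechanism, reproduced, not
        corrected."""
        gene = "GENE1"
        truth = TruthSet(
            events=[CNEvent(gene, tuple(small_design.exon_order(gene)), copies=1)]
        )
        rng = np.random.default_rng(0)
        control = simulate_counts(
            small_design, TruthSet(), noiseless_config, Mix.detection, rng
        )
        base = build_baseline(
            [depth_normalize(control, small_design)] * 3, small_design
        )
        case = simulate_counts(
            small_design, truth, noiseless_config, Mix.detection, rng
        )
        ratios = compute_ratios(depth_normalize(case, small_design), base)
        unaffected = [
            r for pid, r in ratios.ratios.items()
            if small_design[pid].gene != gene
        ]
        assert all(r > 1.0 for r in unaffected)
        assert np.mean(unaffected) > 1.05
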