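"""Read classification, filters, rate computation and heat maps."""

import numpy as np
import pandas as pd
import pytest

from zfrec._seq import revcomp
from zfrec import design as dz
from zfrec import screen as sz
from zfrec.io import build_manifest
from zfrec.simulate import ErrorModel, ScreenTruth, simulate_screen_reads


@pytest.fixture(scope="module")
def index(small_screen):
    return sz.ReferenceIndex.from_amplicons(small_screen["amplicons"])


def _read(seq, q=None, rid="r1"):
    quals = None if q is None else np.full(len(seq), float(q))
    return sz.Read(id=rid, sequence=seq, qualities=quals)


class TestQualityFilter:
    def test_boundary_inclusive_at_10(self):
        reads = [_read("ACGT" * 10, q=9, rid="low"), _read("ACGT" * 10, q=10, rid="edge")]
        kept = [r.id for r in sz.filter_reads_by_quality(reads)]
        assert kept == ["edge"]

    def test_empty_input(self):
        assert sz.filter_reads_by_quality([]) == []

    def test_reads_without_qualities_pass(self):
        reads = [_read("ACGTACGT")]
        assert sz.filter_reads_by_quality(reads) == reads

    def test_mean_phred_is_error_probability_mean(self):
        # Q10 and Q30 mix: mean error prob (0.1 + 0.001)/2 -> ~12.97, not 20
        q = np.array([10.0, 30.0])
        assert sz.mean_phred(q) == pytest.approx(-10 * np.log10(0.0505), abs=1e-6)
        assert sz.mean_phred(q, stat="median") == 20.0

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            sz.filter_reads_by_quality([], min_phred=-1)


class TestClassify:
    def test_exact_read_assigned_with_positive_margin(self, small_screen, index):
        vid = sorted(small_screen["pairs"])[0]
        unrec, rec = small_screen["pairs"][vid]
        a = sz.classify_read(_read(rec.sequence), index)
        assert (a.variant_id, a.state) == (vid, dz.RecombinationState.REC)
        assert a.margin > 0
        assert a.score == 0.0  # perfect match, edit distance 0

    def test_reverse_complement_invariance(self, small_screen, index):
        vid = sorted(small_screen["pairs"])[2]
        unrec, _ = small_screen["pairs"][vid]
        fwd = sz.classify_read(_read(unrec.sequence), index)
        rev = sz.classify_read(_read(revcomp(unrec.sequence)), index)
        assert (fwd.variant_id, fwd.state) == (rev.variant_id, rev.state)
        assert fwd.margin == rev.margin
        assert {fwd.strand, rev.strand} == {"+", "-"}

    def test_synthetic_tie_is_ambiguous(self):
        # two references identical except far beyond the read: a read matching
        # the shared prefix ties and must be left unassigned
        seqs = {"A|REC": "ACGTACGTAC" * 10 + "AAAA", "B|REC": "ACGTACGTAC" * 10 + "CCCC"}
        amps = [
            dz.ReferenceAmplicon(k.split("|")[0], dz.RecombinationState.REC, v,
                                 {"target_site": [(0, 4)]})
            for k, v in seqs.items()
        ]
        idx = sz.ReferenceIndex.from_amplicons(amps)
        a = sz.classify_read(_read("ACGTACGTAC" * 10), idx)
        assert not a.assigned
        assert "ambiguous" in a.flags

    def test_empty_read_rejected(self, index):
        with pytest.raises(ValueError):
            sz.classify_read(_read(""), index)

    def test_simulated_reads_assigned_to_truth(self, small_screen, index):
        pairs = small_screen["pairs"]
        truth = ScreenTruth(
            rates={v: 0.5 for v in pairs}, reads_per_variant=30
        )
        model = ErrorModel(0.025, 0.0125, 0.0125)  # 5% total error
        reads, table = simulate_screen_reads(pairs, truth, model, seed=2, mean_q=30, sd_q=0)
        truth_map = {r.read_id: (r.variant_id, r.state) for r in table.itertuples()}
        n_correct = 0
        n_assigned = 0
        for r in reads:
            a = sz.classify_read(r, index)
            if a.assigned:
                n_assigned += 1
                if (a.variant_id, a.state.value) == truth_map[r.id]:
                    n_correct += 1
        assert n_assigned / len(reads) >= 0.99
        assert n_correct / n_assigned >= 0.99


class TestCoverage:
    ANN = {"target_site": [(10, 30)], "fusion_diagnostic": [(50, 90)]}

    def _assignment(self, span):
        return sz.Assignment(
            read_id="r", variant_id="v", state=dz.RecombinationState.REC, ref_span=span
        )

    def test_full_span_passes(self):
        assert sz.coverage_filter(self._assignment((0, 100)), self.ANN)

    def test_missing_diagnostic_region_fails(self):
        assert not sz.coverage_filter(self._assignment((0, 60)), self.ANN)

    def test_partial_overlap_fails_in_containment_mode(self):
        assert not sz.coverage_filter(self._assignment((15, 100)), self.ANN)

    def test_overlap_mode_accepts_fractional(self):
        assert sz.coverage_filter(
            self._assignment((12, 100)), self.ANN, mode="overlap", min_overlap_fraction=0.9
        )

    def test_unassigned_rejected(self):
        a = sz.Assignment(read_id="r", variant_id=None, state=None, flags={"ambiguous"})
        with pytest.raises(ValueError):
            sz.coverage_filter(a, self.ANN)


class TestRates:
    def test_rate_arithmetic(self):
        r = sz.RateRecord("v", n_rec=10, n_unrec=30)
        assert r.rate == 0.25
        assert r.odds == pytest.approx(1 / 3)

    def test_empty_cell_is_na(self):
        r = sz.RateRecord("v", 0, 0)
        assert r.rate is None

    def test_undetermined_state_excluded(self):
        a_ok = sz.Assignment("r1", "v", dz.RecombinationState.REC)
        a_und = sz.Assignment("r2", "v", None)
        recs = sz.compute_rates([a_ok, a_und])
        assert recs[0].n_rec == 1 and recs[0].n_unrec == 0

    def test_band_intensity(self):
        assert sz.band_intensity_rate(1, 3) == 0.25
        assert sz.band_intensity_rate(0, 5) == 0.0
        assert sz.band_intensity_rate(5, 0) == 1.0
        assert sz.band_intensity_rate(0, 0) is None
        with pytest.raises(ValueError):
            sz.band_intensity_rate(-1, 1)

    def test_conservation_through_pipeline(self, small_screen, index):
        pairs = small_screen["pairs"]
        truth = ScreenTruth(rates={v: 0.5 for v in pairs}, reads_per_variant=10)
        reads, _ = simulate_screen_reads(pairs, truth, ErrorModel(0.02, 0.01, 0.01), seed=3)
        assignments, stats = sz.classify_reads(reads, index)
        stats.check_conservation()
        assert stats.n_input == len(reads)
        assert stats.n_assigned == len(assignments)


class TestHeatmap:
    def _records(self, rows):
        return [
            sz.RateRecord(
                f"v{i}",
                n_rec,
                n_unrec,
                key={
                    "mode": mode,
                    "linker_left": ll,
                    "linker_right": lr,
                    "spacing": sp,
                    "orientation": orient,
                },
            )
            for i, (mode, ll, lr, sp, orient, n_rec, n_unrec) in enumerate(rows)
        ]

    def test_summed_left_right_pools_counts(self):
        recs = self._records(
            [
                ("ins", 3, 5, 5, "A", 10, 10),
                ("ins", 4, 4, 5, "A", 30, 10),
            ]
        )
        (hm,) = sz.build_heatmap(recs, "summed_left_right")
        assert list(hm.rates.index) == [8]
        assert hm.n_rec.loc[8, 5] == 40
        assert hm.rates.loc[8, 5] == pytest.approx(40 / 60)
        assert hm.total_counts == 60

    def test_summed_rows_span_2_to_16(self):
        rows = [
            ("ins", l, r, 0, "B", 1, 1)
            for l in range(1, 9)
            for r in range(1, 9)
        ]
        (hm,) = sz.build_heatmap(self._records(rows), "summed_left_right")
        assert list(hm.rates.index) == list(range(2, 17))

    def test_terminal_grid_shape(self):
        rows = [
            ("N", l, 0, s, o, 1, 1)
            for l in (2, 4, 6, 8, 10, 12)
            for s in range(11)
            for o in ("A", "B")
        ]
        maps = {h.orientation: h for h in sz.build_heatmap(self._records(rows))}
        assert set(maps) == {"A", "B"}
        assert maps["A"].rates.shape == (6, 11)

    def test_pooling_conserves_counts(self):
        rows = [("ins", l, r, 3, "A", l, r) for l in range(1, 5) for r in range(1, 5)]
        recs = self._records(rows)
        (per,) = sz.build_heatmap(recs, "per_linker")
        (summed,) = sz.build_heatmap(recs, "summed_left_right")
        assert per.total_counts == summed.total_counts == sum(l + r for l in range(1, 5) for r in range(1, 5))

    def test_mixed_modes_rejected(self):
        recs = self._records(
            [("N", 2, 0, 1, "A", 1, 1), ("ins", 1, 1, 1, "A", 1, 1)]
        )
        with pytest.raises(ValueError, match="mix"):
            sz.build_heatmap(recs)


@pytest.fixture(scope="module")
def demux_setup():
    rng = np.random.default_rng(21)
    from zfrec.simulate import random_cds, random_sequence

    backbones = {}
    libraries = {}
    pairs = {}
    for name in ("vikaA", "vikaB", "vikaC"):
        rec_cds = random_cds(150, rng)
        site = random_sequence(40, rng)
        inter = random_sequence(150, rng)
        head = random_sequence(40, rng)
        tail = random_sequence(40, rng)
        unrec_seq = head + site + inter + site + rec_cds + tail
        rec_seq = head + site + rec_cds + tail
        backbones[name] = (unrec_seq, rec_seq)
        # insertion variants: 15-nt inserts at three junctions of the ORF
        lib = {}
        for j in (30, 70, 110):
            ins = random_sequence(15, rng)
            cds_var = rec_cds[: 3 * j] + ins + rec_cds[3 * j :]
            lib[f"{name}-ins{j}"] = head + site + cds_var + tail
        libraries[name] = lib
    amps = []
    for name, (u, r) in backbones.items():
        amps.append(
            dz.ReferenceAmplicon(name, dz.RecombinationState.UNREC, u,
                                 {"target_site": [(40, 80), (40 + 40 + 150, 40 + 40 + 150 + 40)],
                                  "intersite": [(80, 230)]})
        )
        amps.append(
            dz.ReferenceAmplicon(name, dz.RecombinationState.REC, r,
                                 {"target_site": [(40, 80)]})
        )
    backbone_index = sz.ReferenceIndex.from_amplicons(amps)
    lib_indexes = {
        name: sz.ReferenceIndex.from_sequences(lib) for name, lib in libraries.items()
    }
    return backbones, libraries, backbone_index, lib_indexes


class TestTwoPhase:
    def test_six_phase1_references(self, demux_setup):
        _, _, backbone_index, _ = demux_setup
        assert len(backbone_index) == 6

    def test_error_free_read_counted_for_its_variant(self, demux_setup):
        backbones, libraries, backbone_index, lib_indexes = demux_setup
        # build a REC read for one specific insertion variant
        name = "vikaB"
        var = f"{name}-ins70"
        # recombined version of the variant amplicon: library seqs are
        # unrecombined-agnostic; use library sequence directly (single site)
        seq = libraries[name][var]
        reads = [sz.Read(id="r0", sequence=seq)]
        records = sz.two_phase_demultiplex(reads, backbone_index, lib_indexes)
        assert len(records) == 1
        rec = records[0]
        assert rec.variant_id == f"{name}::{var}"
        assert rec.n_rec == 1 and rec.n_unrec == 0

    def test_mixed_pool_rates_recovered(self, demux_setup):
        backbones, libraries, backbone_index, lib_indexes = demux_setup
        rng = np.random.default_rng(22)
        from zfrec.simulate import ErrorModel, mutate_sequence

        true_rates = {"vikaA-ins30": 0.0, "vikaB-ins70": 0.5, "vikaC-ins110": 1.0}
        model = ErrorModel(0.015, 0.0075, 0.0075)
        reads = []
        n_per = 60
        planted = {}
        for k, (var, rate) in enumerate(true_rates.items()):
            name = var.split("-")[0]
            lib_seq = libraries[name][var]
            # unrecombined template: insert the variant ORF into the two-site backbone
            u, r = backbones[name]
            head_site = u[: 80]
            rec_read = lib_seq
            unrec_read = u[:230] + lib_seq[40:]  # head+site+inter then site+cds+tail
            for i in range(n_per):
                is_rec = rng.random() < rate
                template = rec_read if is_rec else unrec_read
                reads.append(
                    sz.Read(id=f"{var}-{i}", sequence=mutate_sequence(template, model, rng))
                )
            planted[f"{name}::{var}"] = rate
        records = sz.two_phase_demultiplex(reads, backbone_index, lib_indexes)
        got = {r.variant_id: r for r in records}
        for key, rate in planted.items():
            rec = got[key]
            n = rec.n_rec + rec.n_unrec
            se = np.sqrt(rate * (1 - rate) / n) if n else 0.0
            assert abs(rec.rate - rate) <= max(3 * se, 1e-9)

    def test_backbone_missing_state_rejected(self, demux_setup):
        _, _, _, lib_indexes = demux_setup
        amp = dz.ReferenceAmplicon("solo", dz.RecombinationState.REC, "ACGT" * 30,
                                   {"target_site": [(0, 10)]})
        idx = sz.ReferenceIndex.from_amplicons([amp])
        with pytest.raises(ValueError, match="state"):
            sz.two_phase_demultiplex([], idx, {"solo": lib_indexes["vikaA"]})
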