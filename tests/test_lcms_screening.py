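"""Semitargeted screen: matching, confirmation, filtering, normalization."""

import numpy as np
import pandas as pd
import pytest

from pcbscreen.chem_core import enumerate_suspects
from pcbscreen.isotope_patterns import envelope
from pcbscreen.lcms_screening import (DetectionRecord, PeakList, SampleMeta,
                                      confirm_fragments, confirm_isotopes,
                                      frequency_filter, match_candidates,
                                      read_peaklists, relative_abundance,
                                      screen, write_peaklists)


@pytest.fixture(scope="module")
def oh_pcb95(suspects):
    return next(c for c in suspects if c.class_id == "1.1")


def _peaklist(sample_id, rows, level="MS1", precursor=None):
    return PeakList(sample_id=sample_id, level=level, precursor_mz=precursor,
                    peaks=pd.DataFrame(rows, columns=["rt_min", "mz", "intensity"]))


class TestIO:
    def test_tsv_round_trip(self, tmp_path, small_study):
        _, study = small_study
        path = tmp_path / "peaks.tsv"
        write_peaklists(study.peaklists, path)
        back = read_peaklists(path)

        def content(peaklists):
            # scans with the same (sample, level, precursor) may merge on read
            agg = {}
            for p in peaklists:
                key = (p.sample_id, p.level,
                       None if p.precursor_mz is None else round(p.precursor_mz, 4))
                rows = [(r.rt_min, r.mz, r.intensity) for r in p.peaks.itertuples()]
                agg.setdefault(key, []).extend(rows)
            return {k: np.array(sorted(v)) for k, v in agg.items()}

        orig, got = content(study.peaklists), content(back)
        assert got.keys() == orig.keys()
        for key in orig:  # TSV carries 6 decimal places
            np.testing.assert_allclose(got[key], orig[key], atol=1e-5, rtol=1e-9)

    def test_small_fixture_parses(self, tmp_path):
        path = tmp_path / "tiny.tsv"
        path.write_text(
            "sample_id\tlevel\tprecursor_mz\trt_min\tmz\tintensity\n"
            "s1\tMS1\t\t1.0\t338.87103\t1000\n"
            "s1\tMS1\t\t1.1\t338.87110\t900\n"
            "s1\tMS1\t\t5.0\t200.0\t100\n")
        (pl,) = read_peaklists(path)
        assert len(pl) == 3 and pl.sample_id == "s1"

    def test_empty_file_warns(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        with pytest.warns(UserWarning):
            assert read_peaklists(path) == []

    def test_malformed_row_reports_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "sample_id\tlevel\tprecursor_mz\trt_min\tmz\tintensity\n"
            "s1\tMS1\t\t1.0\tnot-a-number\t1000\n")
        with pytest.raises(ValueError, match="line 2"):
            read_peaklists(path)


class TestMatching:
    def test_two_ppm_offset_is_matched(self, oh_pcb95):
        mz = oh_pcb95.theoretical_mz * (1 + 2e-6)
        pl = _peaklist("s1", [(7.7, mz, 1e6)])
        (rec,) = match_candidates([pl], [oh_pcb95])
        assert rec.delta_ppm == pytest.approx(2.0, abs=1e-6)

    def test_eight_ppm_offset_is_not_matched(self, oh_pcb95):
        mz = oh_pcb95.theoretical_mz * (1 + 8e-6)
        pl = _peaklist("s1", [(7.7, mz, 1e6)])
        assert match_candidates([pl], [oh_pcb95]) == []

    def test_colliding_candidates_both_flagged(self, suspects, oh_pcb95):
        import dataclasses
        near = dataclasses.replace(
            oh_pcb95, class_id="x", name="near-isobar",
            theoretical_mz=oh_pcb95.theoretical_mz * (1 + 3e-6))
        pl = _peaklist("s1", [(7.7, oh_pcb95.theoretical_mz, 1e6)])
        recs = match_candidates([pl], [oh_pcb95, near])
        assert len(recs) == 2 and all(r.ambiguous for r in recs)

    def test_rt_gap_splits_features(self, oh_pcb95):
        mz = oh_pcb95.theoretical_mz
        pl = _peaklist("s1", [(7.0, mz, 1e6), (7.1, mz, 2e6), (8.5, mz, 3e6)])
        recs = match_candidates([pl], [oh_pcb95], rt_gap=0.2)
        assert [r.rt for r in recs] == [7.1, 8.5]  # apex of each feature

    def test_order_invariance(self, suspects, small_study):
        _, study = small_study
        fwd = match_candidates(study.peaklists, study.suspects)
        rev = match_candidates(list(reversed(study.peaklists)),
                               list(reversed(study.suspects)))
        key = lambda r: (r.sample_id, str(r.candidate.class_id), r.rt, r.measured_mz)
        assert sorted(map(key, fwd)) == sorted(map(key, rev))

    def test_nonpositive_tolerance_rejected(self, oh_pcb95):
        with pytest.raises(ValueError):
            match_candidates([], [oh_pcb95], tolerance_ppm=0)


class TestIsotopeConfirmation:
    def test_planted_envelope_retained(self, oh_pcb95):
        env = envelope(oh_pcb95.ion)
        top = env.top(5)
        pl = _peaklist("s1", [(7.7, mz, 1e4 * rel)
                              for mz, rel in zip(top.mz, top.rel_intensity)])
        (rec,) = match_candidates([pl], [oh_pcb95])
        rec = confirm_isotopes(rec, pl, env)
        assert rec.isotope_score >= 0.99
        assert "isotope-pattern-rejected" not in rec.flags

    def test_monoisotopic_only_decoy_dropped(self, oh_pcb95):
        env = envelope(oh_pcb95.ion)
        pl = _peaklist("s1", [(7.7, oh_pcb95.theoretical_mz, 1e6)])
        (rec,) = match_candidates([pl], [oh_pcb95])
        rec = confirm_isotopes(rec, pl, env)
        assert rec.isotope_score < 0.95
        assert "isotope-pattern-rejected" in rec.flags

    def test_chlorine_free_interference_dropped(self, oh_pcb95):
        # a decoy at the right m/z with a C-only M+1 pattern, no Cl M+2
        env = envelope(oh_pcb95.ion)
        mono = oh_pcb95.theoretical_mz
        pl = _peaklist("s1", [(7.7, mono, 1e6), (7.7, mono + 1.0034, 1.3e5)])
        (rec,) = match_candidates([pl], [oh_pcb95])
        rec = confirm_isotopes(rec, pl, env)
        assert "isotope-pattern-rejected" in rec.flags


class TestFragmentConfirmation:
    def test_hcl_loss_upgrades_to_level_2(self, oh_pcb95):
        pl = _peaklist("s1", [(7.7, oh_pcb95.theoretical_mz, 1e6)])
        (rec,) = match_candidates([pl], [oh_pcb95])
        ms2 = _peaklist("s1", [(7.7, 302.89435, 5e4)], level="MS2",
                        precursor=oh_pcb95.theoretical_mz)
        rec = confirm_fragments(rec, [ms2])
        assert rec.fragments_confirmed == {"HCl": True}
        assert rec.confidence_level == 2

    def test_no_ms2_stays_level_3(self, suspects):
        sulfonate = next(c for c in suspects if c.class_id == "5")
        pl = _peaklist("s1", [(5.9, sulfonate.theoretical_mz, 1e6)])
        (rec,) = match_candidates([pl], [sulfonate])
        rec = confirm_fragments(rec, [])
        assert rec.confidence_level == 3

    def test_fragment_20_ppm_off_not_confirmed(self, oh_pcb95):
        pl = _peaklist("s1", [(7.7, oh_pcb95.theoretical_mz, 1e6)])
        (rec,) = match_candidates([pl], [oh_pcb95])
        frag = (oh_pcb95.theoretical_mz - 35.97668) * (1 + 20e-6)
        ms2 = _peaklist("s1", [(7.7, frag, 5e4)], level="MS2",
                        precursor=oh_pcb95.theoretical_mz)
        rec = confirm_fragments(rec, [ms2])
        assert rec.fragments_confirmed == {"HCl": False}
        assert rec.confidence_level == 3


class TestFrequencyAndNormalization:
    def _records(self, cand, n):
        return [DetectionRecord(candidate=cand, sample_id=f"s{i}", rt=7.7,
                                measured_mz=cand.theoretical_mz,
                                raw_intensity=1e6, delta_ppm=0.0,
                                confidence_level=3)
                for i in range(n)]

    @pytest.mark.parametrize("n_detected,retained", [(16, True), (15, False),
                                                     (0, False)])
    def test_majority_rule_is_strict(self, oh_pcb95, n_detected, retained):
        report = frequency_filter(self._records(oh_pcb95, n_detected), 30)
        if n_detected == 0:
            assert report.candidates.empty
        else:
            assert bool(report.candidates["retained"].iloc[0]) is retained

    def test_relative_abundance_arithmetic(self, oh_pcb95):
        meta = SampleMeta("s0", "M", "WT", sample_mass=0.025, pfos_intensity=1e6)
        rec = self._records(oh_pcb95, 1)[0]
        rec.raw_intensity = 2e6
        assert relative_abundance(rec, meta).relative_abundance == pytest.approx(80.0)
        meta2 = SampleMeta("s0", "M", "WT", sample_mass=0.025, pfos_intensity=2e6)
        assert relative_abundance(rec, meta2).relative_abundance == pytest.approx(40.0)


class TestFullScreen:
    def test_confirmed_records_satisfy_contract(self, small_study):
        _, study = small_study
        res = screen(study.peaklists, study.suspects, study.metas)
        assert res.confirmed
        for rec in res.confirmed:
            assert abs(rec.delta_ppm) <= 5.0
            assert rec.isotope_score >= 0.95
            assert rec.confidence_level in (2, 3)
            assert rec.relative_abundance > 0
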