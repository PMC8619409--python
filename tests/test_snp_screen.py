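import numpy as np
import pytest

from copycall import synthetic as syn
from copycall.snp_screen import (
    AssayDefinition,
    locate_assay_sites,
    scan_panel_for_snps,
    uniformity_verdict,
)


def _rc(seq):
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def make_assay(amplicon, f=(0, 20), p=(40, 62), r=(80, 100)):
    return AssayDefinition(
        name="toy",
        forward_primer=amplicon[f[0]:f[1]],
        probe=amplicon[p[0]:p[1]],
        reverse_primer=_rc(amplicon[r[0]:r[1]]),
        reference_amplicon=amplicon,
    )


@pytest.fixture(scope="module")
def toy_amplicon():
    rng = np.random.default_rng(123)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=100)])


class TestLocateSites:
    def test_forward_at_amplicon_start(self, toy_amplicon):
        sites = locate_assay_sites(make_assay(toy_amplicon))
        assert sites["forward"].span_1based == (1, 20)
        assert sites["forward"].strand == "+"

    def test_reverse_spans_3prime_end(self, toy_amplicon):
        sites = locate_assay_sites(make_assay(toy_amplicon))
        assert sites["reverse"].span_1based == (81, 100)
        assert sites["reverse"].strand == "-"

    def test_probe_mismatch_is_not_found(self, toy_amplicon):
        assay = make_assay(toy_amplicon)
        probe = list(assay.probe)
        probe[10] = {"A": "C", "C": "A", "G": "T", "T": "G"}[probe[10]]
        bad = AssayDefinition("toy", assay.forward_primer, assay.reverse_primer,
                              "".join(probe), assay.reference_amplicon)
        with pytest.raises(ValueError, match="not found"):
            locate_assay_sites(bad)

    def test_multiple_matches_rejected(self):
        amp = "ACGTACGTAA" * 10
        assay = AssayDefinition("dup", amp[:8], _rc(amp[-20:]), amp[20:40], amp)
        with pytest.raises(ValueError, match="more than one"):
            locate_assay_sites(assay)

    def test_offset_roundtrip_all_positions(self, toy_amplicon):
        sites = locate_assay_sites(make_assay(toy_amplicon))
        for site in sites.values():
            for offset in range(1, site.end - site.start + 1):
                pos = site.offset_to_amplicon(offset)
                assert site.amplicon_to_offset(pos) == offset


class TestScanPanel:
    def test_identical_panel_has_no_hits(self, assay):
        panel = {f"L{i}": assay.reference_amplicon for i in range(10)}
        assert scan_panel_for_snps(panel, assay) == []

    def test_planted_cohort_recovered(self, assay):
        cfg = syn.SimulationConfig(seed=2)
        panel, truth = syn.simulate_amplicon_panel(cfg, assay)
        hits = scan_panel_for_snps(panel, assay)
        assert len(hits) == 2
        by_oligo = {h.oligo: h for h in hits}
        fwd = by_oligo["forward"]
        assert (fwd.offset_from_5prime, fwd.ref_base, fwd.alt_base) == (1, "T", "A")
        assert fwd.carrier_count == 112
        assert fwd.frequency_percent == pytest.approx(100 * 112 / 633)
        rev = by_oligo["reverse"]
        assert (rev.offset_from_5prime, rev.ref_base, rev.alt_base) == (2, "G", "T")
        assert rev.carrier_count == 3
        assert rev.frequency_percent == pytest.approx(100 * 3 / 633)

    def test_length_mismatch_rejected(self, assay):
        with pytest.raises(ValueError, match="length"):
            scan_panel_for_snps({"L1": assay.reference_amplicon[:-1]}, assay)

    def test_non_iupac_rejected(self, assay):
        seq = "X" + assay.reference_amplicon[1:]
        with pytest.raises(ValueError, match="non-IUPAC"):
            scan_panel_for_snps({"L1": seq}, assay)

    def test_iupac_ambiguity_flagged_separately(self, assay):
        sites = locate_assay_sites(assay)
        pos0 = sites["probe"].start + 3
        seq = list(assay.reference_amplicon)
        seq[pos0] = "N"
        hits = scan_panel_for_snps({"L1": "".join(seq)}, assay)
        assert len(hits) == 1 and hits[0].is_iupac_ambiguity

    def test_agrees_with_bruteforce_diff_oracle(self, assay):
        """Random 50-line panels: the scan must match an independent
        whole-sequence diff restricted to the oligo sites."""
        rng = np.random.default_rng(77)
        ref = assay.reference_amplicon
        sites = locate_assay_sites(assay)
        bases = "ACGT"
        panel = {}
        for i in range(50):
            seq = list(ref)
            for _ in range(rng.integers(0, 4)):
                j = int(rng.integers(0, len(ref)))
                seq[j] = bases[(bases.index(seq[j]) + int(rng.integers(1, 4))) % 4]
            panel[f"L{i:02d}"] = "".join(seq)
        # oracle: per line, position-by-position diff, then map into sites
        expected = {}
        for lid, seq in panel.items():
            for j, (a, b) in enumerate(zip(ref, seq)):
                if a == b:
                    continue
                for site in sites.values():
                    if site.start <= j < site.end:
                        off = site.amplicon_to_offset(j + 1)
                        if site.strand == "+":
                            key = (site.oligo, off, a, b)
                        else:
                            key = (site.oligo, off, _rc(a), _rc(b))
                        expected.setdefault(key, set()).add(lid)
        hits = scan_panel_for_snps(panel, assay)
        got = {
            (h.oligo, h.offset_from_5prime, h.ref_base, h.alt_base): set(h.line_ids)
            for h in hits
        }
        assert got == expected

    def test_frequencies_sum_to_panel_fraction(self, assay):
        cfg = syn.SimulationConfig(seed=9, panel_size=50,
                                   variant_specs=(("forward", 1, "T", "A", 20),))
        panel, _ = syn.simulate_amplicon_panel(cfg, assay)
        hits = scan_panel_for_snps(panel, assay)
        at_pos = [h for h in hits if h.oligo == "forward" and h.offset_from_5prime == 1]
        variant_total = sum(h.frequency_percent for h in at_pos)
        ref_fraction = 100.0 * (50 - sum(h.carrier_count for h in at_pos)) / 50
        assert variant_total + ref_fraction == pytest.approx(100.0)


class TestUniformityVerdict:
    def test_clean_and_flagged_oligos(self, assay):
        cfg = syn.SimulationConfig(seed=2)
        panel, _ = syn.simulate_amplicon_panel(cfg, assay)
        verdict = uniformity_verdict(scan_panel_for_snps(panel, assay), assay)
        assert verdict["oligos"] == {
            "forward": "variant_detected",
            "reverse": "variant_detected",
            "probe": "clean",
        }
        assert verdict["redesign_recommended"]

    def test_empty_hits_clean_assay(self, assay):
        verdict = uniformity_verdict([], assay)
        assert verdict["assay_clean"] and not verdict["redesign_recommended"]
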