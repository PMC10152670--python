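"""Unit and property tests for the DAP/ampDAP methylation analysis."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methylsense import dap_methyl as dm
from methylsense import synthetic_data as sd


# ---------------------------------------------------------------------------
# log-ratio
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("dap, amp, pc, expected", [
    (100, 100, 1.0, 0.0),
    (200, 100, 0.0, math.log10(2)),
    (0, 99, 1.0, -2.0),
])
def test_log_ratio_closed_forms(dap, amp, pc, expected):
    assert dm.log_ratio(dap, amp, 1e6, 1e6, pc) == pytest.approx(expected)

def test_log_ratio_normalizes_by_library_size():
    # same counts, DAP library twice as deep -> normalized DAP coverage halves
    assert dm.log_ratio(100, 100, 2e6, 1e6, 0.0) == pytest.approx(-math.log10(2))

def test_log_ratio_rejects_bad_libsize():
    with pytest.raises(ValueError):
        dm.log_ratio(1, 1, 0.0, 1e6)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(dap=st.integers(0, 10000), amp=st.integers(0, 10000),
       pc=st.floats(0.1, 10))
def test_log_ratio_antisymmetric(dap, amp, pc):
    a = dm.log_ratio(dap, amp, 1e6, 1e6, pc)
    b = dm.log_ratio(amp, dap, 1e6, 1e6, pc)
    assert a == pytest.approx(-b, abs=1e-12)


# ---------------------------------------------------------------------------
# PWM construction
# ---------------------------------------------------------------------------

def test_build_pwm_unanimous_column():
    pwm = dm.build_pwm(["GGTCAA"] * 4, pseudocount=0.0)
    assert pwm.probs[3, dm._CODE["C"]] == pytest.approx(1.0)
    assert pwm.consensus == "GGTCAA"

def test_build_pwm_uniform_sites_give_zero_log_odds():
    pwm = dm.build_pwm(["AA", "CC", "GG", "TT"], pseudocount=0.0)
    assert np.allclose(pwm.probs, 0.25)
    assert np.allclose(pwm.log_odds(), 0.0)

def test_build_pwm_matches_frequency_count_oracle():
    rng = np.random.default_rng(7)
    sites = ["".join(rng.choice(list("ACGT"), 6)) for _ in range(20)]
    pwm = dm.build_pwm(sites, pseudocount=1.0)
    for j in range(6):
        for b, base in enumerate("ACGT"):
            count = sum(s[j] == base for s in sites)
            assert pwm.probs[j, b] == pytest.approx(
                (count + 0.25) / (len(sites) + 1.0))

@pytest.mark.parametrize("sites", [[], ["ACG", "AC"], ["ACX"]])
def test_build_pwm_rejects_bad_input(sites):
    with pytest.raises(ValueError):
        dm.build_pwm(sites)

def test_meme_round_trip(wbox):
    text = dm.write_meme_pwm(wbox, "WBOX")
    back = dm.read_meme_pwm(text)
    assert np.allclose(back.probs, wbox.probs, atol=1e-5)
    assert np.allclose(back.background, wbox.background, atol=1e-5)


# ---------------------------------------------------------------------------
# best-site scanning
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def consensus_pwm():
    return dm.build_pwm(["GGTCAA"] * 10, pseudocount=0.4)

def test_scan_finds_exact_forward_match(consensus_pwm):
    hit = dm.scan_best_site("TTTGGTCAATT", consensus_pwm)
    assert (hit.offset, hit.strand, hit.site) == (3, "+", "GGTCAA")

def test_scan_reports_reverse_hit_in_pwm_orientation(consensus_pwm):
    hit = dm.scan_best_site("TTTTGACCTTT", consensus_pwm)
    assert hit.strand == "-"
    assert hit.site == "GGTCAA"

def test_scan_strand_invariance_of_maximum(consensus_pwm):
    rng = np.random.default_rng(3)
    for _ in range(20):
        seq = "".join(rng.choice(list("ACGT"), 50))
        fwd = dm.scan_best_site(seq, consensus_pwm)
        rev = dm.scan_best_site(dm.revcomp(seq), consensus_pwm)
        assert fwd.score == pytest.approx(rev.score, abs=1e-9)

def test_scan_matches_exhaustive_enumeration(consensus_pwm):
    """The vectorized scanner must agree with a brute-force window walk
    (including the smaller-offset-then-forward tie-break) on random 50-mers."""
    rng = np.random.default_rng(11)
    for _ in range(50):
        seq = "".join(rng.choice(list("ACGT"), 50))
        candidates = []
        for offset in range(50 - consensus_pwm.length + 1):
            window = seq[offset:offset + consensus_pwm.length]
            for strand, site in (("+", window), ("-", dm.revcomp(window))):
                candidates.append((offset, strand, consensus_pwm.score(site)))
        top = max(s for _, _, s in candidates)
        # same tie semantics as the scanner: scores equal up to float
        # round-off count as tied; smaller offset wins, then forward strand
        tied = [(o, st) for o, st, s in candidates if s >= top - 1e-9]
        expected = min(tied, key=lambda c: (c[0], c[1] == "-"))
        hit = dm.scan_best_site(seq, consensus_pwm)
        assert (hit.offset, hit.strand) == expected
        assert hit.score == pytest.approx(top, abs=1e-9)

def test_scan_scores_n_as_background(consensus_pwm):
    hit = dm.scan_best_site("GGNCAA", consensus_pwm)
    lo = consensus_pwm.log_odds()
    expected = sum(lo[j, dm._CODE[b]] for j, b in enumerate("GGTCAA")
                   if j != 2)
    assert hit.score == pytest.approx(expected)

def test_scan_rejects_short_sequence(consensus_pwm):
    with pytest.raises(ValueError):
        dm.scan_best_site("GGT", consensus_pwm)


# ---------------------------------------------------------------------------
# methylation density and site counts
# ---------------------------------------------------------------------------

def _region(seq_start=0, length=10):
    return dm.BoundRegion("r1", "chr1", seq_start, seq_start + length,
                          10, 10, 1e6, 1e6)

def test_methylation_density_counts_strictly_above_threshold():
    genome = {"chr1": "CACACACAGT"}  # Cs at 0,2,4,6; G at 8 (reverse C)
    track = dm.MethylationTrack([
        ("chr1", 0, "+", "CHH", 0.9), ("chr1", 2, "+", "CHH", 0.6),
        ("chr1", 4, "+", "CHH", 0.4), ("chr1", 6, "+", "CHH", 0.1),
        ("chr1", 8, "-", "CHH", 0.0),
    ])
    assert dm.methylation_density(_region(), genome, track) == pytest.approx(2 / 5)

def test_methylation_density_threshold_is_strict():
    genome = {"chr1": "CCCCAAAAAA"}
    track = dm.MethylationTrack(
        [("chr1", i, "+", "CHH", 0.5) for i in range(4)])
    assert dm.methylation_density(_region(), genome, track) == 0.0

def test_methylation_density_no_cytosines_warns():
    genome = {"chr1": "ATATATATAT"}
    track = dm.MethylationTrack([])
    with pytest.warns(UserWarning, match="no cytosines"):
        assert dm.methylation_density(_region(), genome, track) == 0.0

def test_count_methylated_tfbs_both_strands():
    # site GGTCAA at offset 2: C on + at site pos 4, reverse-strand Cs under
    # the two leading Gs
    genome = {"chr1": "TTGGTCAATT"}
    region = _region()
    hit = dm.TFBSHit("r1", 2, "+", 0.0, "GGTCAA")
    track = dm.MethylationTrack([
        ("chr1", 5, "+", "CHH", 0.9),   # site C4, methylated
        ("chr1", 2, "-", "CHH", 0.2),   # site C1' on reverse, unmethylated
    ])
    assert dm.count_methylated_tfbs(hit, region, genome, track) == 1

def test_count_methylated_tfbs_no_records():
    genome = {"chr1": "TTGGTCAATT"}
    hit = dm.TFBSHit("r1", 2, "+", 0.0, "GGTCAA")
    assert dm.count_methylated_tfbs(hit, _region(), genome,
                                    dm.MethylationTrack([])) == 0

def test_count_methylated_tfbs_matches_per_base_scan():
    rng = np.random.default_rng(5)
    for _ in range(20):
        seq = "".join(rng.choice(list("ACGT"), 30))
        genome = {"chr1": seq}
        region = dm.BoundRegion("r", "chr1", 0, 30, 5, 5, 1e6, 1e6)
        offset = int(rng.integers(0, 24))
        hit = dm.TFBSHit("r", offset, "+", 0.0, seq[offset:offset + 6])
        records = []
        for i, base in enumerate(seq):
            if base == "C":
                records.append(("chr1", i, "+", "CHH", float(rng.random())))
            elif base == "G":
                records.append(("chr1", i, "-", "CHH", float(rng.random())))
        track = dm.MethylationTrack(records)
        expected = 0
        for i in range(offset, offset + 6):
            if seq[i] == "C" and track.probability("chr1", i, "+") > 0.5:
                expected += 1
            if seq[i] == "G" and track.probability("chr1", i, "-") > 0.5:
                expected += 1
        assert dm.count_methylated_tfbs(hit, region, genome, track) == expected

def test_count_methylated_never_exceeds_site_cytosines(planted_bundle):
    bundle = planted_bundle
    genome, track = bundle.genome, bundle.track
    regions = bundle.to_regions()[:50]
    for region in regions:
        hit = dm.scan_best_site(region.sequence(genome), bundle.pwm,
                                region.region_id)
        n = dm.count_methylated_tfbs(hit, region, genome, track)
        n_cyt = sum(b in "CG" for b in
                    region.sequence(genome)[hit.offset:hit.offset + 6])
        assert 0 <= n <= n_cyt


def test_methylation_track_validation():
    with pytest.raises(ValueError, match="duplicate"):
        dm.MethylationTrack([("chr1", 1, "+", "CG", 0.5),
                             ("chr1", 1, "+", "CHH", 0.6)])
    with pytest.raises(ValueError):
        dm.MethylationTrack([("chr1", 1, "+", "CG", 1.5)])
    with pytest.raises(ValueError):
        dm.MethylationTrack([("chr1", 1, "+", "XX", 0.5)])


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------

def test_bh_closed_form_triplet():
    assert dm.bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

def test_bh_single_p_is_identity():
    assert dm.bh_adjust([0.4]) == pytest.approx([0.4])

def test_bh_matches_statsmodels_on_random_vectors():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(13)
    for _ in range(100):
        p = rng.random(rng.integers(2, 40))
        ours = dm.bh_adjust(p)
        theirs = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, theirs, atol=1e-12)

@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
def test_bh_invariants(pvals):
    q = dm.bh_adjust(pvals)
    p = np.asarray(pvals)
    assert np.all(q >= p - 1e-12) and np.all(q <= 1.0)
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= -1e-12)

def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        dm.bh_adjust([0.5, 1.2])


# ---------------------------------------------------------------------------
# per-position correlation and masking
# ---------------------------------------------------------------------------

def _perfect_linear_setup():
    """Regions whose log-ratio is exactly -m4: r at position 4 must be -1."""
    rng = np.random.default_rng(2)
    genome_parts, regions, hits, records = [], [], [], []
    cursor = 0
    for i in range(12):
        m4 = (i + 1) / 13.0
        seq = "AT" + "GGTCAA" + "TA"
        genome_parts.append(seq)
        start = cursor
        cursor += len(seq)
        # pick counts to realize log_ratio == -m4 exactly (pseudocount 0)
        amp = 1000.0
        dap = amp * 10 ** (-m4)
        region = dm.BoundRegion(f"r{i}", "chr1", start, cursor, dap, amp,
                                1e6, 1e6, pseudocount=0.0)
        regions.append(region)
        hits.append(dm.TFBSHit(f"r{i}", 2, "+", 0.0, "GGTCAA"))
        records.append(("chr1", start + 5, "+", "CHH", m4))
    genome = {"chr1": "".join(genome_parts)}
    return regions, hits, genome, dm.MethylationTrack(records)

def test_perfect_linear_dependence_gives_r_minus_one():
    regions, hits, genome, track = _perfect_linear_setup()
    table = dm.per_position_correlation(hits, regions, genome, track)
    row = table.query("position == 4 and strand == '+'").iloc[0]
    assert row["r"] == pytest.approx(-1.0)
    assert row["n_cytosines"] == 12

def test_constant_methylation_flagged_zero_variance():
    regions, hits, genome, _ = _perfect_linear_setup()
    # every position-1 reverse-strand cytosine at the same probability
    records = [("chr1", r.start + 2, "-", "CHH", 0.7) for r in regions]
    table = dm.per_position_correlation(hits, regions, genome,
                                        dm.MethylationTrack(records),
                                        min_n=10)
    row = table.query("position == 1 and strand == '-'").iloc[0]
    assert row["status"] == dm.STATUS_ZERO_VARIANCE
    assert not np.isfinite(row["r"])

def test_minus_strand_hits_are_motif_normalized():
    """A region hit on the minus strand must contribute its C4 methylation
    to motif position 4 exactly like a plus-strand hit."""
    regions, hits, genome, track = _perfect_linear_setup()
    # rebuild genome with every site reverse-complemented
    parts, new_hits, records = [], [], []
    for i, region in enumerate(regions):
        m4 = (i + 1) / 13.0
        parts.append("AT" + dm.revcomp("GGTCAA") + "TA")
        new_hits.append(dm.TFBSHit(region.region_id, 2, "-", 0.0, "GGTCAA"))
        # C4 now sits on the genomic minus strand under the forward G
        records.append(("chr1", region.start + 4, "-", "CHH", m4))
    genome2 = {"chr1": "".join(parts)}
    table = dm.per_position_correlation(new_hits, regions, genome2,
                                        dm.MethylationTrack(records))
    row = table.query("position == 4 and strand == '+'").iloc[0]
    assert row["r"] == pytest.approx(-1.0)
    assert row["n_cytosines"] == 12

@pytest.mark.parametrize("n, q, expected", [
    (9, 0.001, dm.STATUS_INSUFFICIENT),
    (50, 0.2, dm.STATUS_BLANK_FDR),
    (50, 0.01, dm.STATUS_TESTED),
])
def test_masking_rules(n, q, expected):
    table = pd.DataFrame([{"position": 4, "strand": "+", "r": -0.5,
                           "p": q / 2, "q": q, "n_cytosines": n,
                           "status": "tested"}])
    out = dm.mask_positions(table)
    assert out.iloc[0]["status"] == expected
    assert out.iloc[0]["r"] == -0.5  # masking never alters values

def test_masking_is_pure_relabeling(planted_bundle):
    bundle = planted_bundle
    regions = bundle.to_regions()
    genome, track = bundle.genome, bundle.track
    hits = [dm.scan_best_site(r.sequence(genome), bundle.pwm, r.region_id)
            for r in regions]
    table = dm.per_position_correlation(hits, regions, genome, track)
    remasked = dm.mask_positions(table, min_n=100, fdr=0.001)
    for col in ("r", "p", "q", "n_cytosines"):
        pd.testing.assert_series_equal(table[col], remasked[col])


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def test_run_pipeline_end_to_end(tmp_path, planted_bundle):
    paths = planted_bundle.write(tmp_path / "data")
    config = dm.RunConfig(
        peaks=paths["peaks"], genome=paths["genome"], counts=paths["counts"],
        methylome=paths["methylome"], pwm=paths["pwm"],
        out_dir=tmp_path / "out")
    result = dm.run_methylation_sensitivity(config)
    assert len(result.regions) == 500
    assert (tmp_path / "out" / "position_effects.tsv").exists()
    assert (tmp_path / "out" / "run.yaml").exists()
    # the planted repression shows up as ratio decreasing with density
    corr = result.regions["methylation_density"].corr(
        result.regions["log_ratio"])
    assert corr < 0
    # minimum ratio at the most-methylated TFBS bin
    bins = result.count_bins.set_index("n_methylated_tfbs")["mean"]
    assert bins.iloc[-1] < bins.iloc[0]

def test_run_pipeline_empty_peaks_is_clean_error(tmp_path, planted_bundle):
    paths = planted_bundle.write(tmp_path / "data")
    empty = tmp_path / "empty.bed"
    empty.write_text("")
    config = dm.RunConfig(
        peaks=empty, genome=paths["genome"], counts=paths["counts"],
        methylome=paths["methylome"], pwm=paths["pwm"],
        out_dir=tmp_path / "out")
    with pytest.raises(Exception, match="empty.bed|empty"):
        dm.run_methylation_sensitivity(config)

def test_run_pipeline_mismatched_region_ids(tmp_path, planted_bundle):
    paths = planted_bundle.write(tmp_path / "data")
    counts = pd.read_csv(paths["counts"], sep="\t").iloc[:100]
    bad = tmp_path / "bad_counts.tsv"
    counts.to_csv(bad, sep="\t", index=False)
    config = dm.RunConfig(
        peaks=paths["peaks"], genome=paths["genome"], counts=bad,
        methylome=paths["methylome"], pwm=paths["pwm"],
        out_dir=tmp_path / "out")
    with pytest.raises(ValueError, match="missing"):
        dm.run_methylation_sensitivity(config)
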