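"""Hairpin discovery: excision, folding, filter, arms, scoring, control."""

import copy
import subprocess

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gutmir import (
    CollapsedRead,
    ContigRecord,
    DiscoveryConfig,
    HairpinCandidate,
    ScoreBreakdown,
    assign_arms,
    compute_snr,
    estimate_false_positives,
    excise_candidates,
    fold_sequence,
    hairpin_filter,
    score_candidate,
    select_candidates,
)
from gutmir._seq import revcomp, to_dna, to_rna
from gutmir.conservation import CatalogEntry
from gutmir.discovery import catalog_seed_set
from gutmir.reads import ReadStack


def _stack(start, end, strand="+", contig="c"):
    return ReadStack(contig_id=contig, strand=strand, start=start, end=end, hits=[])


# ---------------------------------------------------------------- excision
def test_excision_arithmetic():
    contig = ContigRecord(id="c", seq="A" * 10_000)
    wins = excise_candidates(_stack(100, 122), contig)
    assert [(w.start, w.end) for w in wins] == [(30, 142), (80, 192)]


def test_excision_clipped_at_contig_start():
    contig = ContigRecord(id="c", seq="A" * 10_000)
    wins = excise_candidates(_stack(0, 22), contig)
    assert (0, 42) in [(w.start, w.end) for w in wins]


def test_excision_minus_strand_read_oriented():
    seq = "".join("ACGT"[i % 4] for i in range(400))
    contig = ContigRecord(id="c", seq=seq)
    wins = excise_candidates(_stack(100, 122, strand="-"), contig)
    # read-oriented upstream (70) extends to higher contig coordinates
    assert [(w.start, w.end) for w in wins] == [(80, 192), (30, 142)]
    for w in wins:
        assert w.seq == revcomp(seq[w.start : w.end])


def test_excision_duplicates_removed():
    # symmetric config makes the two windows identical
    contig = ContigRecord(id="c", seq="A" * 1000)
    cfg = DiscoveryConfig(excise_up=30, excise_down=30)
    assert len(excise_candidates(_stack(100, 122), contig, cfg)) == 1


def test_window_contains_full_truth_precursor(sim, pipeline):
    found = set()
    for w in pipeline["windows"]:
        for hp in sim["truth"].hairpins:
            if (
                w.contig_id == hp.contig
                and w.strand == hp.strand
                and w.start <= hp.start
                and hp.end <= w.end
            ):
                found.add(hp.hairpin_id)
    assert len(found) == len(sim["truth"].hairpins)


# ---------------------------------------------------------------- folding
def test_fold_homopolymer_no_pairs():
    fold = fold_sequence("A" * 20)
    assert fold.mfe == 0.0
    assert set(fold.dotbracket) == {"."}


def test_fold_matches_rnafold_cli_oracle():
    seq = "GGGGGAAAAAACCCCC"
    out = subprocess.run(
        ["RNAfold", "--noPS"], input=to_rna(seq), capture_output=True, text=True
    ).stdout.splitlines()[1]
    db_cli, mfe_cli = out.split(None, 1)
    fold = fold_sequence(seq)
    assert fold.dotbracket == db_cli
    assert fold.mfe == pytest.approx(float(mfe_cli.strip("() ")), abs=0.01)


def test_fold_mfe_nonpositive_and_deterministic(pipeline):
    for w in pipeline["windows"][:20]:
        assert w.fold.mfe <= 0.0
        assert fold_sequence(w.seq) == w.fold


def test_fold_rejects_short_and_invalid():
    with pytest.raises(ValueError):
        fold_sequence("ACGUACGU")  # < 10
    with pytest.raises(ValueError):
        fold_sequence("ACGUACGUXX")
    with pytest.raises(ValueError):
        fold_sequence("N" * 8 + "ACGUACGUACGUACGUACGUACGUACGU"[:20])


def test_fold_tolerates_sparse_n():
    fold = fold_sequence("GGGGGAAAAAACCCCCAAAN")
    assert fold.mfe <= 0.0


# ------------------------------------------------------- filter and arms
MATURE = "TGAGGTAGTAGGTTGTATAGTT"  # 22 nt


def _perfect_candidate(n_mature=90, n_shifted=10, with_star=True):
    """A perfect stem-loop window with a coherent read stack on the 5p arm."""
    loop = "GGAAGAGAGGTAGTA"[:14]
    precursor = MATURE + loop + revcomp(MATURE)
    flank5, flank3 = "ATTGCGA", "TCGGATC"
    window = flank5 + precursor + flank3
    cand = HairpinCandidate(
        contig_id="c", start=0, end=len(window), strand="+", seq=window
    )
    moff = len(flank5)
    reads = [(moff, CollapsedRead(id="seq_1", seq=MATURE, count=n_mature))]
    if n_shifted:
        reads.append(
            (moff + 1, CollapsedRead(id="seq_2", seq=MATURE[1:] + "G", count=n_shifted))
        )
    if with_star:
        star = revcomp(MATURE)[2:]  # 2-nt 3' overhang geometry
        soff = moff + len(MATURE) + len(loop) + 2
        reads.append((soff, CollapsedRead(id="seq_3", seq=star, count=8)))
    cand.reads = sorted(reads, key=lambda t: t[0])
    cand.fold = fold_sequence(window)
    return cand


def test_filter_passes_perfect_stemloop():
    ok, reason = hairpin_filter(_perfect_candidate())
    assert ok, reason


def test_filter_rejects_mature_in_loop():
    cand = _perfect_candidate(with_star=False)
    # move the 'mature' read onto the loop center
    loop_mid = 7 + 22 + 5
    cand.reads = [(loop_mid, CollapsedRead(id="seq_1", seq=cand.seq[loop_mid : loop_mid + 20], count=50))]
    ok, reason = hairpin_filter(cand)
    assert not ok and reason in {"mature-in-loop", "mature-underpaired", "no-hairpin"}


def test_filter_rejects_unstructured():
    cand = HairpinCandidate(contig_id="c", start=0, end=40, strand="+", seq="A" * 40)
    cand.reads = [(5, CollapsedRead(id="seq_1", seq="A" * 20, count=5))]
    ok, reason = hairpin_filter(cand)
    assert not ok and reason == "no-hairpin"


def test_filter_no_reads():
    cand = _perfect_candidate()
    cand.reads = []
    assert hairpin_filter(cand) == (False, "no-reads")


def test_assign_arms_max_count_rule():
    cand = _perfect_candidate(n_mature=90, n_shifted=10)
    assert hairpin_filter(cand)[0]
    assign_arms(cand)
    assert cand.mature_seq == MATURE


def test_assign_arms_tie_breaks_lexicographic():
    cand = _perfect_candidate(n_mature=50, n_shifted=0, with_star=False)
    other = MATURE[1:] + "G"
    cand.reads.append((8, CollapsedRead(id="seq_9", seq=other, count=50)))
    assign_arms(cand)
    assert cand.mature_seq == min(MATURE, other)


def test_assign_arms_star_overhang_geometry():
    cand = _perfect_candidate()
    assign_arms(cand)
    truth_star_start = 7 + 22 + 14 + 2  # flank + mature + loop + 2-nt overhang
    assert abs(cand.star_start - truth_star_start) <= 1


# ---------------------------------------------------------------- scoring
def _seed_set(*seqs):
    return {to_dna(s)[1:8] for s in seqs}


def test_score_closed_form_12_54():
    cand = _perfect_candidate(n_mature=90, n_shifted=1, with_star=True)
    cand.reads = [
        (7, CollapsedRead(id="seq_1", seq=MATURE, count=99)),
        (7 + 22 + 14 + 2, CollapsedRead(id="seq_2", seq=revcomp(MATURE)[2:], count=1)),
    ]
    assert hairpin_filter(cand)[0]
    assign_arms(cand)
    score = score_candidate(cand, _seed_set(MATURE), DiscoveryConfig())
    # both reads anchor on arm 5' ends -> C = 99 + 1 + 1 (pseudocount), I = 1
    assert score.s_str == 1.3
    assert score.s_star == 1.6
    assert score.s_seed == 3.0
    assert score.s_sig == pytest.approx(np.log2(101), abs=1e-9)


def test_score_component_example_arithmetic():
    # worked example: log2(100) + 1.3 + 1.6 + 3.0 = 12.54
    s = ScoreBreakdown(
        s_sig=float(np.log2(100)), s_str=1.3, s_star=1.6, s_seed=3.0
    )
    assert round(s.total, 2) == 12.54


def test_score_empty_signature_minus_1_9():
    s = ScoreBreakdown(s_sig=0.0, s_str=-1.3, s_star=0.0, s_seed=-0.6)
    assert s.total == pytest.approx(-1.9)


def test_score_additivity(pipeline):
    for c in pipeline["passing"]:
        assert c.score.total == pytest.approx(
            c.score.s_str + c.score.s_sig + c.score.s_star + c.score.s_seed
        )


@given(st.integers(1, 200))
def test_score_monotone_in_consistent_reads(extra):
    base = _perfect_candidate(n_mature=30, n_shifted=0, with_star=True)
    assign_arms(base)
    more = copy.deepcopy(base)
    more.reads[0] = (more.reads[0][0], CollapsedRead(id="seq_1", seq=MATURE, count=30 + extra))
    assign_arms(more)
    cfg = DiscoveryConfig()
    seeds = _seed_set(MATURE)
    assert (
        score_candidate(more, seeds, cfg).total
        >= score_candidate(base, seeds, cfg).total
    )


def test_seed_bonus_and_penalty():
    cand = _perfect_candidate()
    assign_arms(cand)
    cfg = DiscoveryConfig()
    hit = score_candidate(cand, _seed_set(MATURE), cfg)
    miss = score_candidate(cand, _seed_set("ACGTACGTACGTACGTACGTAC"), cfg)
    assert hit.s_seed == 3.0 and miss.s_seed == -0.6


# ---------------------------------------------------------------- selection
def _scored(total, start=0, end=100, contig="c", strand="+", mfe=-30.0):
    c = HairpinCandidate(
        contig_id=contig, start=start, end=end, strand=strand, seq="A" * (end - start)
    )
    c.fold = fold_sequence("G" * 12 + "AAAA" + "C" * 12) if False else None
    from gutmir.discovery import StructureFold

    c.fold = StructureFold(dotbracket="." * (end - start), mfe=mfe)
    c.mature_start, c.mature_end = 10, 32
    c.seq = "TGAGGTAGTAGGTTGTATAGTT".join(["A" * 10, "A" * (end - start - 32)])
    c.score = ScoreBreakdown(s_sig=total)  # total == s_sig
    return c


def test_select_boundary_minus_3_kept():
    kept = select_candidates([_scored(-3.0)], [], DiscoveryConfig())
    assert len(kept["known"] + kept["novel"]) == 1


def test_select_below_cutoff_rejected():
    kept = select_candidates([_scored(-3.01)], [], DiscoveryConfig())
    assert kept["known"] == [] and kept["novel"] == []
    assert kept["rejected"][0].reject_reason == "below-cutoff"


def test_select_overlap_dedup_best_wins():
    a, b = _scored(5.0, 0, 100), _scored(2.0, 50, 150)
    kept = select_candidates([a, b], [], DiscoveryConfig())
    sel = kept["known"] + kept["novel"]
    assert len(sel) == 1 and sel[0].score.total == 5.0


def test_select_known_labeling():
    cand = _scored(5.0)
    entry = CatalogEntry(name="mir-x", species="hsa", mature=cand.mature_seq)
    kept = select_candidates([cand], [entry], DiscoveryConfig())
    assert len(kept["known"]) == 1 and kept["novel"] == []


# ---------------------------------------------------------------- snr / control
def test_compute_snr_published_values():
    assert compute_snr(354, 140) == 2.5
    assert compute_snr(399, 95) == 4.2
    assert compute_snr(100, 100) == 1.0


def test_compute_snr_rounds_half_away_from_zero():
    assert compute_snr(105, 100) == 1.1  # 1.05 rounds up, not banker's
    with pytest.raises(ValueError):
        compute_snr(10, 0)


def test_control_determinism(pipeline):
    seeds = catalog_seed_set([])
    a = estimate_false_positives(
        pipeline["passing"], pipeline["windows"], seeds, DiscoveryConfig()
    )
    b = estimate_false_positives(
        pipeline["passing"], pipeline["windows"], seeds, DiscoveryConfig()
    )
    assert a == b


def test_control_identical_windows_symmetry():
    """All windows identical -> permutation changes nothing; snr = 1.0."""
    wins = []
    for k in range(6):
        c = _perfect_candidate()
        c.contig_id = f"c{k}"  # non-overlapping loci
        wins.append(c)
        assign_arms(c)
        c.score = score_candidate(c, set(), DiscoveryConfig())
    passing = [c for c in wins if c.score.total >= -3]
    assert passing
    est = estimate_false_positives(passing, wins, set(), DiscoveryConfig())
    assert est.fp_mean == len(passing)
    assert est.snr == 1.0


def test_control_needs_two_windows():
    with pytest.raises(ValueError):
        estimate_false_positives([], [_perfect_candidate()], set(), DiscoveryConfig())


def test_config_validation():
    with pytest.raises(ValueError):
        DiscoveryConfig(control_rounds=0)
    with pytest.raises(ValueError):
        DiscoveryConfig(cutoff=float("nan"))
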