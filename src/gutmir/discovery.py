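"""Read-guided hairpin discovery with log-odds scoring and permuted-control
false-positive estimation.

Candidate precursor windows are excised around read stacks (asymmetric
70/20-nt flanks on either side, so whichever arm the reads sit on, one
window contains the full hairpin), folded to their minimum-free-energy
structure, filtered on stem-loop topology, and scored by four additive
log2-odds components:

* ``s_str``  — structure stability: bonus if the window MFE is at or below a
  stability threshold, penalty otherwise;
* ``s_sig`` — read signature: log2 odds of count-weighted reads whose 5'
  ends are consistent with the mature/star arms versus inconsistent reads;
* ``s_star`` — direct star-strand evidence (a read at the predicted star 5'
  end, the Dicer 2-nt 3'-overhang signature);
* ``s_seed`` — seed conservation against a catalog of known mammalian
  matures.

The false-positive rate of the score cut-off is estimated by permuting the
read signatures across candidate windows (each structure scored against
another window's reads) and counting how many permuted candidates still
pass; the signal-to-noise ratio is the real pass count over that mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import RNA

from ._seq import revcomp, to_dna, to_rna
from .conservation import CatalogEntry, edit_distance
from .reads import CollapsedRead, ContigRecord, GenomeHit, ReadStack


@dataclass(frozen=True)
class StructureFold:
    dotbracket: str
    mfe: float  # kcal/mol

    def pair_table(self) -> list[int]:
        """Partner index per position, -1 if unpaired."""
        pt = [-1] * len(self.dotbracket)
        stack: list[int] = []
        for i, ch in enumerate(self.dotbracket):
            if ch == "(":
                stack.append(i)
            elif ch == ")":
                j = stack.pop()
                pt[i], pt[j] = j, i
        return pt


@dataclass
class ScoreBreakdown:
    s_str: float = 0.0
    s_sig: float = 0.0
    s_star: float = 0.0
    s_seed: float = 0.0

    @property
    def total(self) -> float:
        return self.s_str + self.s_sig + self.s_star + self.s_seed


@dataclass
class DiscoveryConfig:
    cutoff: float = -3.0
    excise_up: int = 70
    excise_down: int = 20
    seed_match_bonus: float = 3.0
    seed_miss_penalty: float = -0.6
    star_bonus: float = 1.6
    stable_bonus: float = 1.3
    unstable_penalty: float = -1.3
    mfe_stable_threshold: float = -25.0  # kcal/mol
    sig_jitter: int = 2
    star_jitter: int = 1
    min_mature_paired: float = 0.60
    control_rounds: int = 10
    rng_seed: int = 42

    def __post_init__(self) -> None:
        if not math.isfinite(self.cutoff):
            raise ValueError("cutoff must be finite")
        if self.control_rounds < 1:
            raise ValueError("control_rounds must be >= 1")


@dataclass
class HairpinCandidate:
    """An excised window with fold, arm assignment and score."""

    contig_id: str
    start: int  # window interval, contig coordinates, 0-based half-open
    end: int
    strand: str
    seq: str  # read-oriented window sequence
    reads: list[tuple[int, CollapsedRead]] = field(default_factory=list)  # (offset, read)
    fold: StructureFold | None = None
    mature_start: int = -1
    mature_end: int = -1
    star_start: int = -1
    star_end: int = -1
    loop_start: int = -1
    loop_end: int = -1
    score: ScoreBreakdown | None = None
    status: str = "candidate"  # candidate | known | novel | rejected
    reject_reason: str | None = None

    @property
    def mature_seq(self) -> str:
        return self.seq[self.mature_start : self.mature_end]

    @property
    def star_seq(self) -> str:
        return self.seq[self.star_start : self.star_end]


@dataclass
class ControlEstimate:
    n_pass_real: int
    fp_mean: float
    snr: float
    per_round: list[int] = field(default_factory=list)


def compute_snr(n_pass: int, fp: float) -> float:
    """Signal-to-noise ratio, rounded half-away-from-zero to one decimal."""
    if fp <= 0:
        raise ValueError("undefined signal-to-noise: false-positive estimate <= 0")
    x = n_pass / fp
    return math.floor(x * 10 + 0.5) / 10 if x >= 0 else -math.floor(-x * 10 + 0.5) / 10


def fold_sequence(seq: str) -> StructureFold:
    """Minimum-free-energy fold at 37 degC, Turner nearest-neighbor parameters.

    Deterministic for a fixed parameter set; N is left unpaired, but a
    sequence with more than 20% N is refused.
    """
    s = to_rna(seq)
    if len(s) < 10:
        raise ValueError("sequence too short to fold (< 10 nt)")
    if set(s) - set("ACGUN"):
        raise ValueError(f"invalid alphabet in {seq[:20]!r}...")
    if s.count("N") > 0.2 * len(s):
        raise ValueError("sequence has more than 20% uncalled nucleotides")
    structure, mfe = RNA.fold(s)
    return StructureFold(dotbracket=structure, mfe=round(float(mfe), 2))


def excise_candidates(
    stack: ReadStack, contig: ContigRecord, config: DiscoveryConfig | None = None
) -> list[HairpinCandidate]:
    """Excise up to two asymmetric windows around a read stack.

    In read orientation the windows are [start-70, end+20) and
    [start-20, end+70), clipped to the contig; minus-strand stacks are excised
    from the reverse complement. Duplicate windows are deduplicated.
    """
    config = config or DiscoveryConfig()
    up, down = config.excise_up, config.excise_down
    n = contig.length
    if stack.strand == "+":
        intervals = [
            (stack.start - up, stack.end + down),
            (stack.start - down, stack.end + up),
        ]
    else:  # read-oriented upstream is contig-downstream
        intervals = [
            (stack.start - down, stack.end + up),
            (stack.start - up, stack.end + down),
        ]
    out: list[HairpinCandidate] = []
    seen: set[tuple[int, int]] = set()
    for a, b in intervals:
        a, b = max(0, a), min(n, b)
        if b - a < 10 or (a, b) in seen:
            continue
        seen.add((a, b))
        seq = to_dna(contig.seq[a:b])
        if stack.strand == "-":
            seq = revcomp(seq)
        out.append(
            HairpinCandidate(
                contig_id=contig.id, start=a, end=b, strand=stack.strand, seq=seq
            )
        )
    return out


def attach_reads(
    candidate: HairpinCandidate,
    hits: list[GenomeHit],
    reads_by_id: dict[str, CollapsedRead],
) -> HairpinCandidate:
    """Attach all same-strand hits overlapping the window, as window offsets."""
    for h in hits:
        if h.contig_id != candidate.contig_id or h.strand != candidate.strand:
            continue
        if h.end <= candidate.start or h.start >= candidate.end:
            continue
        if candidate.strand == "+":
            off = h.start - candidate.start
        else:
            off = candidate.end - h.end
        candidate.reads.append((off, reads_by_id[h.read_id]))
    candidate.reads.sort(key=lambda t: (t[0], t[1].seq))
    return candidate


def _most_abundant(reads: list[tuple[int, CollapsedRead]]) -> tuple[int, CollapsedRead]:
    """Max-count read; ties break to the lexicographically smaller sequence."""
    return min(reads, key=lambda t: (-t[1].count, t[1].seq, t[0]))


def _terminal_loops(fold: StructureFold) -> list[tuple[int, int]]:
    """Half-open intervals of hairpin (terminal) loops in the structure."""
    db = fold.dotbracket
    loops = []
    last_open = -1
    for i, ch in enumerate(db):
        if ch == "(":
            last_open = i
        elif ch == ")":
            if last_open >= 0:
                loops.append((last_open + 1, i))
                last_open = -1
    return loops


def hairpin_filter(
    candidate: HairpinCandidate, config: DiscoveryConfig | None = None
) -> tuple[bool, str | None]:
    """Stem-loop topology filter.

    Pass iff the structure has exactly one terminal loop over the read-stack
    region, the mature (most abundant read) lies on one stem arm with at most
    1 nt overlapping that loop, and at least 60% of mature positions are
    paired.
    """
    config = config or DiscoveryConfig()
    if candidate.fold is None:
        candidate.fold = fold_sequence(candidate.seq)
    if not candidate.reads:
        return False, "no-reads"
    stack_lo = min(off for off, _ in candidate.reads)
    stack_hi = max(off + len(r.seq) for off, r in candidate.reads)
    loops = [
        (a, b)
        for a, b in _terminal_loops(candidate.fold)
        if a < stack_hi and b > stack_lo
    ]
    if len(loops) != 1:
        return False, "multi-loop" if len(loops) > 1 else "no-hairpin"
    la, lb = loops[0]
    moff, mread = _most_abundant(candidate.reads)
    mlen = len(mread.seq)
    mend = min(moff + mlen, len(candidate.seq))
    overlap = max(0, min(mend, lb) - max(moff, la))
    if overlap > 1:
        return False, "mature-in-loop"
    pt = candidate.fold.pair_table()
    lo, hi = max(0, moff), mend
    if hi <= lo:
        return False, "mature-outside-window"
    paired = sum(1 for i in range(lo, hi) if pt[i] >= 0)
    if paired < config.min_mature_paired * (hi - lo):
        return False, "mature-underpaired"
    return True, None


def assign_arms(
    candidate: HairpinCandidate, config: DiscoveryConfig | None = None
) -> HairpinCandidate:
    """Set mature, star and loop from the reads and the fold.

    Mature is the most abundant overlapping read. The star is the sequence
    pairing with the mature, shifted so each strand of the duplex keeps a
    2-nt 3' overhang (the Dicer signature), derived from the pair table.
    """
    if not candidate.reads:
        raise ValueError("cannot assign arms: no reads overlap the window")
    if candidate.fold is None:
        candidate.fold = fold_sequence(candidate.seq)
    wlen = len(candidate.seq)
    moff, mread = _most_abundant(candidate.reads)
    mstart = max(0, moff)
    mend = min(moff + len(mread.seq), wlen)
    pt = candidate.fold.pair_table()

    # innermost paired mature position near the 3' end, minus the 2-nt shift
    i1 = mend - 3
    while i1 >= mstart and pt[i1] < 0:
        i1 -= 1
    i0 = mstart
    while i0 < mend and pt[i0] < 0:
        i0 += 1
    if i1 < mstart or i0 >= mend:
        raise ValueError("mature unpaired; cannot derive star")
    p1 = pt[i1] - ((mend - 3) - i1)  # star 5' end
    p0 = pt[i0] + 2 + (i0 - mstart)  # star 3' end (inclusive)
    star_start, star_end = min(p1, p0), max(p1, p0) + 1
    star_start = max(0, star_start)
    star_end = min(wlen, star_end)
    if star_end <= star_start:
        raise ValueError("degenerate star interval")

    candidate.mature_start, candidate.mature_end = mstart, mend
    candidate.star_start, candidate.star_end = star_start, star_end
    if star_start >= mend:
        candidate.loop_start, candidate.loop_end = mend, star_start
    else:
        candidate.loop_start, candidate.loop_end = star_end, mstart
    return candidate


def score_candidate(
    candidate: HairpinCandidate,
    seed_set: set[str],
    config: DiscoveryConfig | None = None,
) -> ScoreBreakdown:
    """Four-component additive log2-odds score (see module docstring)."""
    config = config or DiscoveryConfig()
    assert candidate.fold is not None and candidate.mature_start >= 0
    br = ScoreBreakdown()
    br.s_str = (
        config.stable_bonus
        if candidate.fold.mfe <= config.mfe_stable_threshold
        else config.unstable_penalty
    )
    c_weight = 0
    i_weight = 0
    star_read = False
    for off, read in candidate.reads:
        near_mature = abs(off - candidate.mature_start) <= config.sig_jitter
        near_star = abs(off - candidate.star_start) <= config.sig_jitter
        if near_mature or near_star:
            c_weight += read.count
        else:
            i_weight += read.count
        if abs(off - candidate.star_start) <= config.star_jitter and (
            off != candidate.mature_start or len(read.seq) != candidate.mature_end - candidate.mature_start
        ):
            star_read = True
    br.s_sig = float(
        np.clip(math.log2((c_weight + 1) / (i_weight + 1)), -10.0, 10.0)
    )
    br.s_star = config.star_bonus if star_read else 0.0
    seed = to_dna(candidate.mature_seq)[1:8]
    br.s_seed = (
        config.seed_match_bonus if seed in seed_set else config.seed_miss_penalty
    )
    candidate.score = br
    return br


def catalog_seed_set(catalog: list[CatalogEntry]) -> set[str]:
    return {to_dna(e.mature)[1:8] for e in catalog}


def select_candidates(
    scored: list[HairpinCandidate],
    catalog: list[CatalogEntry],
    config: DiscoveryConfig | None = None,
) -> dict[str, list[HairpinCandidate]]:
    """Apply the score cut-off, deduplicate overlapping windows, label known/novel.

    Candidates with total >= cutoff are kept; among overlapping windows on the
    same contig strand only the best-scoring one survives (ties: lower mfe,
    then leftmost). A kept candidate is 'known' iff its mature lies within
    <=2 edits of a catalog mature, else 'novel'.
    """
    config = config or DiscoveryConfig()
    passing = [
        c
        for c in scored
        if c.status != "rejected" and c.score is not None and c.score.total >= config.cutoff
    ]
    order = sorted(
        passing,
        key=lambda c: (-c.score.total, c.fold.mfe if c.fold else 0.0, c.contig_id, c.start),
    )
    kept: list[HairpinCandidate] = []
    for c in order:
        clash = any(
            k.contig_id == c.contig_id
            and k.strand == c.strand
            and c.start < k.end
            and k.start < c.end
            for k in kept
        )
        if clash:
            c.status = "rejected"
            c.reject_reason = "overlaps-better-window"
        else:
            kept.append(c)

    result: dict[str, list[HairpinCandidate]] = {"known": [], "novel": [], "rejected": []}
    matures = [e.mature for e in catalog]
    kept_ids = {id(k) for k in kept}
    for c in scored:
        if id(c) in kept_ids:
            known = any(
                edit_distance(c.mature_seq, m, max_edits=2) >= 0 for m in matures
            )
            c.status = "known" if known else "novel"
            result[c.status].append(c)
        else:
            if c.status != "rejected":
                c.status = "rejected"
                c.reject_reason = c.reject_reason or "below-cutoff"
            result["rejected"].append(c)
    return result


def _rescore_with_signature(
    window: HairpinCandidate,
    signature: list[tuple[int, CollapsedRead]],
    seed_set: set[str],
    config: DiscoveryConfig,
) -> float | None:
    """Score a window against a foreign read signature; None if it is rejected.

    Donor reads are kept under the same rule used when attaching real reads:
    any read overlapping the window stays (clipped at the bounds), so a dense
    incoherent signature stays dense when transplanted.
    """
    donor_reads = [
        (off, r) for off, r in signature if off < len(window.seq) and off + len(r.seq) > 0
    ]
    if not donor_reads:
        return None
    shadow = HairpinCandidate(
        contig_id=window.contig_id,
        start=window.start,
        end=window.end,
        strand=window.strand,
        seq=window.seq,
        reads=donor_reads,
        fold=window.fold,
    )
    ok, _ = hairpin_filter(shadow, config)
    if not ok:
        return None
    try:
        assign_arms(shadow, config)
    except ValueError:
        return None
    return score_candidate(shadow, seed_set, config).total


def estimate_false_positives(
    passing: list[HairpinCandidate],
    all_windows: list[HairpinCandidate],
    seed_set: set[str],
    config: DiscoveryConfig | None = None,
) -> ControlEstimate:
    """Estimate false positives by permuting read signatures across windows.

    For each control round a seeded random permutation (a derangement when
    possible) reassigns window j's reads to window i; the permuted candidates
    are re-filtered and re-scored and those still passing the cut-off are
    counted. The mean count over rounds estimates the number of score-passing
    candidates expected from structure alone.
    """
    config = config or DiscoveryConfig()
    windows = [w for w in all_windows if w.reads]
    if len(windows) < 2:
        raise ValueError("false-positive control needs at least 2 read-bearing windows")
    rng = np.random.default_rng(config.rng_seed)
    per_round: list[int] = []
    n = len(windows)
    for _ in range(config.control_rounds):
        perm = _derangement(n, rng)
        passing_round: list[tuple[HairpinCandidate, float]] = []
        for i, w in enumerate(windows):
            total = _rescore_with_signature(
                w, windows[perm[i]].reads, seed_set, config
            )
            if total is not None and total >= config.cutoff:
                passing_round.append((w, total))
        # the same overlap deduplication applied to the real candidate list
        passing_round.sort(
            key=lambda wt: (-wt[1], wt[0].fold.mfe, wt[0].contig_id, wt[0].start)
        )
        kept: list[HairpinCandidate] = []
        for w, _total in passing_round:
            if not any(
                k.contig_id == w.contig_id
                and k.strand == w.strand
                and w.start < k.end
                and k.start < w.end
                for k in kept
            ):
                kept.append(w)
        per_round.append(len(kept))
    fp_mean = float(np.mean(per_round))
    snr = compute_snr(len(passing), fp_mean) if fp_mean > 0 else float("inf")
    return ControlEstimate(
        n_pass_real=len(passing), fp_mean=fp_mean, snr=snr, per_round=per_round
    )


def _derangement(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random permutation without fixed points when n > 1 (best effort)."""
    for _ in range(100):
        perm = rng.permutation(n)
        if n == 1 or not np.any(perm == np.arange(n)):
            return perm
    return np.roll(np.arange(n), 1)


def discover(
    contigs: list[ContigRecord],
    stacks: list[ReadStack],
    hits: list[GenomeHit],
    reads_by_id: dict[str, CollapsedRead],
    catalog: list[CatalogEntry],
    config: DiscoveryConfig | None = None,
) -> tuple[dict[str, list[HairpinCandidate]], ControlEstimate | None, list[HairpinCandidate]]:
    """Run the full discovery stage: excise, fold, filter, score, select, control.

    Returns (partition, control estimate or None, all excised windows).
    """
    config = config or DiscoveryConfig()
    contig_by_id = {c.id: c for c in contigs}
    seed_set = catalog_seed_set(catalog)

    all_windows: list[HairpinCandidate] = []
    for stack in stacks:
        contig = contig_by_id.get(stack.contig_id)
        if contig is None:
            continue
        for cand in excise_candidates(stack, contig, config):
            attach_reads(cand, hits, reads_by_id)
            all_windows.append(cand)

    scored: list[HairpinCandidate] = []
    for cand in all_windows:
        try:
            cand.fold = fold_sequence(cand.seq)
        except ValueError:
            cand.status, cand.reject_reason = "rejected", "unfoldable"
            scored.append(cand)
            continue
        ok, reason = hairpin_filter(cand, config)
        if not ok:
            cand.status, cand.reject_reason = "rejected", reason
            scored.append(cand)
            continue
        try:
            assign_arms(cand, config)
        except ValueError as exc:
            cand.status, cand.reject_reason = "rejected", str(exc)
            scored.append(cand)
            continue
        score_candidate(cand, seed_set, config)
        scored.append(cand)

    partition = select_candidates(scored, catalog, config)
    passing = partition["known"] + partition["novel"]
    control = None
    readful = [w for w in all_windows if w.reads]
    if len(readful) >= 2:
        control = estimate_false_positives(passing, all_windows, seed_set, config)
    return partition, control, all_windows
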