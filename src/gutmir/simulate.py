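"""Synthetic data generator: genomes with planted miRNA hairpins, Dicer-signature
small-RNA reads, miRBase-like catalogs, and two-channel-free microarray
intensities across six intestinal loci plus a pooled common reference.

The generator emulates the statistical structure the analysis assumes:

* contigs carrying stem-loop precursors whose mature/star duplex has the
  canonical 2-nt 3' overhangs, plus repeat families (>=5 perfect copies),
  QC-failing contigs, and decoy loci;
* read stacks dominated by the mature arm, a star minority, rare loop reads,
  5' jitter of +/-1 nt and up to 2 nt of 3' heterogeneity, uniform degradation
  background, and every read carrying the 3' sequencing adapter;
* a catalog whose ortholog baits sit within <=2 edits of planted matures,
  whose primate-specific entries match nothing, and whose seed baits share
  only the 7-nt seed;
* array intensities following the additive-background + multiplicative-noise
  model that variance-stabilizing transforms assume, with the common
  reference equal to the mean of the locus signals before noise.

Decoy loci are short inverted repeats that receive no reads at all: they
exist so that structure alone (a foldable stem in the genome) is never
sufficient to produce a candidate, and so that windows constructed over them
in tests are rejected on topology grounds.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import revcomp, to_rna
from .conservation import CatalogEntry, edit_distance
from .reads import ContigRecord

LOCI = (
    "duodenum",
    "proximal_jejunum",
    "distal_jejunum",
    "ileum",
    "ascending_colon",
    "transverse_colon",
)
COMMON_REFERENCE = "common_reference"

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic genome, reads, catalog and arrays."""

    seed: int = 42
    n_contigs: int = 12
    contig_length: int = 4000
    n_hairpins: int = 20
    n_decoys: int = 50
    n_repeat_families: int = 2
    repeat_copies: int = 5
    read_depth: int = 100  # mean reads per mature
    star_fraction: float = 0.08
    loop_fraction: float = 0.02
    background_reads: int = 300
    repeat_depth: int = 12  # reads sampled from each repeat family consensus
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    catalog_size: int = 40
    ortholog_edit_rate: float = 0.5  # per-allowed-edit probability for baits
    n_orthologs: int | None = None  # default: half the planted hairpins
    n_primate: int = 3
    n_seed_baits: int = 3
    n_loci: int = 7  # six intestinal loci + common reference
    expression_profiles: dict[str, np.ndarray] | None = None
    n_star_dominant: int = 0
    n_silent: int = 0  # hairpins with no array expression anywhere
    # array noise model: signal * lognormal + additive Gaussian background
    array_baseline: float = 16.0
    array_background_mean: float = 64.0  # 2**6
    array_background_sd: float = 8.0
    array_noise_sigma: float = 0.10  # lognormal sigma, natural-log units
    array_replicates: int = 7

    def __post_init__(self) -> None:
        if self.star_fraction + self.loop_fraction >= 1:
            raise ValueError("star_fraction + loop_fraction must be < 1")
        if self.repeat_copies < 5:
            raise ValueError("repeat_copies must be >= 5")


@dataclass
class TruthRecord:
    """Ground truth for one planted hairpin."""

    hairpin_id: str
    contig: str
    start: int  # 0-based half-open, contig coordinates
    end: int
    strand: str
    precursor: str  # read-oriented (equals contig slice on '+', revcomp on '-')
    mature: str
    mature_arm: str  # '5p' or '3p'
    mature_offset: int  # within precursor
    star: str
    star_offset: int
    expression: dict[str, float] = field(default_factory=dict)  # sample -> log2


@dataclass
class DecoyRecord:
    decoy_id: str
    contig: str
    start: int  # inverted-repeat interval
    end: int
    region_start: int  # degradation scatter window
    region_end: int


@dataclass
class RepeatRecord:
    family_id: str
    seq: str
    placements: list[tuple[str, int]]  # (contig, start)


@dataclass
class TruthTable:
    hairpins: list[TruthRecord]
    decoys: list[DecoyRecord]
    repeats: list[RepeatRecord]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def _mismatched_arm(mature: str, rng: np.random.Generator, n_mismatch: int = 3) -> str:
    """Complementary arm with interior mismatches, as in real Dicer duplexes.

    Mismatches keep the duplex from being a perfect palindrome (so arm reads
    map uniquely) while leaving >=60% of mature positions paired; arm ends
    stay intact so the 2-nt-overhang geometry is preserved.
    """
    arm = list(revcomp(mature))
    interior = np.arange(4, len(arm) - 4)
    pos = rng.choice(interior, size=min(n_mismatch, len(interior)), replace=False)
    for p in pos:
        choices = [b for b in "ACGT" if b != arm[p]]
        arm[p] = choices[int(rng.integers(0, 3))]
    return "".join(arm)


def _make_hairpin(rng: np.random.Generator) -> tuple[str, str, str, str, int, int]:
    """Build a precursor whose mature/star duplex has 2-nt 3' overhangs.

    Returns (precursor, mature, star, arm, mature_offset, star_offset).
    """
    m = int(rng.integers(21, 24))
    loop_len = int(rng.integers(12, 17))
    mature = _random_seq(rng, m)
    arm2 = _mismatched_arm(mature, rng)
    loop = _random_seq(rng, loop_len)
    tail = _random_seq(rng, 2)
    if rng.random() < 0.5:
        # mature on the 5p arm
        precursor = mature + loop + arm2 + tail
        star = precursor[m + loop_len + 2 : 2 * m + loop_len + 2]
        return precursor, mature, star, "5p", 0, m + loop_len + 2
    # mature on the 3p arm
    precursor = tail + arm2 + loop + mature
    star = precursor[2 : m + 2]
    return precursor, mature, star, "3p", 2 + m + loop_len, 2


def _make_inverted_repeat(rng: np.random.Generator) -> str:
    """A short, weak stem-loop: a decoy that folds but carries no read signature."""
    stem = _random_seq(rng, 12)
    loop = _random_seq(rng, 8)
    return stem + loop + revcomp(stem)


def build_genome(config: SimulationConfig) -> tuple[list[ContigRecord], TruthTable]:
    """Generate contigs with planted hairpins, repeats, decoys and QC failures.

    Each precursor occurs exactly once in the genome at its truth interval;
    each repeat family occurs exactly ``repeat_copies`` times; two QC-failing
    contigs (one shorter than 200 nt, one with >=20% N) are always appended to
    exercise contig filtering.
    """
    rng = np.random.default_rng(config.seed)

    hairpins = []
    for i in range(config.n_hairpins):
        precursor, mature, star, arm, moff, soff = _make_hairpin(rng)
        hairpins.append((f"HP{i + 1:03d}", precursor, mature, star, arm, moff, soff))

    decoy_seqs = [_make_inverted_repeat(rng) for _ in range(config.n_decoys)]
    repeat_seqs = [_random_seq(rng, 80) for _ in range(config.n_repeat_families)]

    # count feature slots per contig
    features: list[tuple[str, int, str]] = []  # (kind, index, seq)
    features += [("hairpin", i, hp[1]) for i, hp in enumerate(hairpins)]
    features += [("decoy", i, s) for i, s in enumerate(decoy_seqs)]
    for i, s in enumerate(repeat_seqs):
        features += [("repeat", i, s)] * config.repeat_copies
    rng.shuffle(features)

    margin = 200  # room for decoy scatter windows and excision flanks
    slot = max(len(f[2]) for f in features) + margin if features else margin
    per_contig = max(1, (config.contig_length - margin) // slot)
    needed = -(-len(features) // per_contig) if features else 0
    if needed > config.n_contigs:
        raise ValueError(
            f"contig_length {config.contig_length} too small to host "
            f"{len(features)} features on {config.n_contigs} contigs"
        )

    contigs: list[ContigRecord] = []
    truth = TruthTable(hairpins=[], decoys=[], repeats=[])
    repeat_place: dict[int, list[tuple[str, int]]] = {
        i: [] for i in range(len(repeat_seqs))
    }
    fi = 0
    for ci in range(config.n_contigs):
        name = f"contig_{ci + 1:03d} chr={ci % 18 + 1}"
        cid = name.split()[0]
        seq = list(_random_seq(rng, config.contig_length))
        pos = margin // 2
        while fi < len(features) and pos + slot <= config.contig_length - margin // 2:
            kind, idx, fseq = features[fi]
            planted = fseq
            strand = "+"
            if kind == "hairpin" and rng.random() < 0.25:
                strand = "-"
                planted = revcomp(fseq)
            seq[pos : pos + len(planted)] = list(planted)
            if kind == "hairpin":
                hid, precursor, mature, star, arm, moff, soff = hairpins[idx]
                truth.hairpins.append(
                    TruthRecord(
                        hairpin_id=hid,
                        contig=cid,
                        start=pos,
                        end=pos + len(precursor),
                        strand=strand,
                        precursor=precursor,
                        mature=mature,
                        mature_arm=arm,
                        mature_offset=moff,
                        star=star,
                        star_offset=soff,
                    )
                )
            elif kind == "decoy":
                half = 60  # bookkeeping margin for overlap checks in tests
                truth.decoys.append(
                    DecoyRecord(
                        decoy_id=f"DEC{idx + 1:03d}",
                        contig=cid,
                        start=pos,
                        end=pos + len(fseq),
                        region_start=max(0, pos - half),
                        region_end=min(config.contig_length, pos + len(fseq) + half),
                    )
                )
            else:
                repeat_place[idx].append((cid, pos))
            fi += 1
            pos += slot
        contigs.append(ContigRecord(id=cid, seq="".join(seq)))
    if fi < len(features):
        raise ValueError("could not place all features; increase contig_length")

    for i, seq in enumerate(repeat_seqs):
        truth.repeats.append(
            RepeatRecord(family_id=f"REP{i + 1}", seq=seq, placements=repeat_place[i])
        )

    # QC-failing contigs: too short, and too many uncalled bases
    contigs.append(ContigRecord(id="contig_short", seq=_random_seq(rng, 150)))
    n_heavy = list(_random_seq(rng, 300))
    n_pos = rng.choice(300, size=90, replace=False)  # 30% N
    for p in n_pos:
        n_heavy[p] = "N"
    contigs.append(ContigRecord(id="contig_nheavy", seq="".join(n_heavy)))

    _attach_expression(config, truth.hairpins, rng)
    return contigs, truth


def _attach_expression(
    config: SimulationConfig, hairpins: list[TruthRecord], rng: np.random.Generator
) -> None:
    """Assign per-locus log2 expression offsets with designed spatial blocks.

    Hairpins 1-2 are high only in the proximal loci (duodenum, proximal
    jejunum); the next four are expressed everywhere but elevated in the two
    colonic loci, so they stay in the everywhere-detected set used for
    clustering and make the colonic samples cluster as siblings; remaining
    expressed hairpins are ubiquitous with mild locus jitter. The common
    reference is the mean of the locus signals on the raw intensity scale.
    """
    n = len(hairpins)
    if config.expression_profiles is not None:
        for i, hp in enumerate(hairpins):
            for locus in LOCI:
                hp.expression[locus] = float(config.expression_profiles[locus][i])
    else:
        silent = set(range(n - config.n_silent, n))
        for i, hp in enumerate(hairpins):
            if i in silent:
                for locus in LOCI:
                    hp.expression[locus] = 0.0
                continue
            base = float(rng.uniform(7.0, 10.0))
            jitter = {locus: float(rng.normal(0, 0.3)) for locus in LOCI}
            for locus in LOCI:
                if i in (0, 1):  # proximal-only block (off elsewhere)
                    hp.expression[locus] = (
                        base + jitter[locus]
                        if locus in ("duodenum", "proximal_jejunum")
                        else 0.0
                    )
                elif 2 <= i <= 5 and n > 6:  # colon-elevated, detected everywhere
                    lift = 2.5 if locus in ("ascending_colon", "transverse_colon") else 0.0
                    hp.expression[locus] = base + jitter[locus] + lift
                else:
                    hp.expression[locus] = base + jitter[locus]
    # common reference: mean of expected locus intensities, before noise
    for hp in hairpins:
        raw = [config.array_baseline * 2 ** hp.expression[locus] for locus in LOCI]
        mean_raw = float(np.mean(raw))
        hp.expression[COMMON_REFERENCE] = float(
            np.log2(mean_raw / config.array_baseline)
        )


def simulate_reads(
    contigs: list[ContigRecord], truth: TruthTable, config: SimulationConfig
) -> list[str]:
    """Emit adapter-bearing raw reads with the Dicer signature.

    Mature reads dominate each hairpin, star reads are the configured
    minority, loop reads rare; 5' ends jitter by +/-1 nt with probabilities
    (0.7, 0.15, 0.15) and 3' ends by up to 2 nt. Background reads are uniform
    18-30-mers from the contigs; decoy loci receive no reads.
    Every read is emitted with the 3' adapter appended (36-cycle emulation).
    """
    rng = np.random.default_rng(config.seed + 1)
    contig_by_id = {c.id: c.seq for c in contigs}
    reads: list[str] = []

    def emit(insert: str) -> None:
        raw = insert + config.adapter
        reads.append(raw[:36] if len(raw) > 36 else raw)

    def oriented_context(hp: TruthRecord) -> tuple[str, int]:
        """Precursor +/-5 nt of flank, read-oriented; returns (ctx, pre_offset)."""
        cseq = contig_by_id[hp.contig]
        a, b = max(0, hp.start - 5), min(len(cseq), hp.end + 5)
        ctx = cseq[a:b]
        if hp.strand == "-":
            return revcomp(ctx), b - hp.end
        return ctx, hp.start - a

    for hp in truth.hairpins:
        ctx, pre = oriented_context(hp)
        n_star = rng.binomial(config.read_depth, config.star_fraction)
        n_loop = rng.binomial(config.read_depth, config.loop_fraction)
        n_mature = config.read_depth - n_star - n_loop
        for anchor, count in ((hp.mature_offset, n_mature), (hp.star_offset, n_star)):
            ref_len = len(hp.mature) if anchor == hp.mature_offset else len(hp.star)
            for _ in range(count):
                j5 = int(rng.choice([-1, 0, 1], p=[0.15, 0.70, 0.15]))
                j3 = int(rng.choice([0, 1, 2], p=[0.60, 0.30, 0.10]))
                s = pre + anchor + j5
                e = pre + anchor + ref_len - j3
                if 0 <= s < e <= len(ctx):
                    emit(ctx[s:e])
        # loop reads: short fragments from between the arms
        lo = min(hp.mature_offset, hp.star_offset) + len(hp.mature)
        hi = max(hp.mature_offset, hp.star_offset)
        if hi - lo >= 18:
            for _ in range(n_loop):
                ln = int(rng.integers(18, min(25, hi - lo + 1)))
                s = pre + lo + int(rng.integers(0, hi - lo - ln + 1))
                emit(ctx[s : s + ln])

    for rep in truth.repeats:
        for _ in range(config.repeat_depth):
            ln = int(rng.integers(18, 27))
            s = int(rng.integers(0, len(rep.seq) - ln + 1))
            emit(rep.seq[s : s + ln])

    usable = [c for c in contigs if c.length >= 40]
    for _ in range(config.background_reads):
        c = usable[int(rng.integers(0, len(usable)))]
        ln = int(rng.integers(18, 31))
        s = int(rng.integers(0, c.length - ln + 1))
        frag = c.seq[s : s + ln]
        emit(frag if rng.random() < 0.5 else revcomp(frag))
    return reads


def simulate_catalog(
    truth: TruthTable, config: SimulationConfig
) -> list[CatalogEntry]:
    """Build a miRBase-like catalog with ortholog, primate and seed baits.

    Ortholog baits lie within <=2 edits of planted matures (the number of
    edits per bait is Binomial(2, ortholog_edit_rate)); primate-specific
    entries are verified to match nothing within 2 edits; seed baits share
    only the 7-nt seed with a planted mature.
    """
    rng = np.random.default_rng(config.seed + 2)
    hairpins = truth.hairpins
    n_orth = (
        config.n_orthologs if config.n_orthologs is not None else len(hairpins) // 2
    )
    n_orth = min(n_orth, len(hairpins))
    entries: list[CatalogEntry] = []

    for i in range(n_orth):
        mature = hairpins[i].mature
        n_edits = int(rng.binomial(2, config.ortholog_edit_rate))
        bait = _apply_edits(mature, n_edits, rng)
        entries.append(
            CatalogEntry(name=f"hsa-miR-{9000 + i}", species="hsa", mature=to_rna(bait))
        )

    matures = [hp.mature for hp in hairpins]
    for i in range(config.n_primate):
        while True:
            seq = _random_seq(rng, 22)
            if all(edit_distance(seq, m, max_edits=2) < 0 for m in matures):
                break
        entries.append(
            CatalogEntry(
                name=f"ptr-miR-{9500 + i}",
                species="ptr",
                mature=to_rna(seq),
                primate_specific=True,
            )
        )

    for i in range(min(config.n_seed_baits, len(hairpins))):
        hp = hairpins[-(i + 1)]
        while True:
            seq = hp.mature[0] + hp.mature[1:8] + _random_seq(rng, 14)
            if all(edit_distance(seq, m, max_edits=2) < 0 for m in matures):
                break
        entries.append(
            CatalogEntry(name=f"mmu-miR-{9700 + i}", species="mmu", mature=to_rna(seq))
        )

    while len(entries) < config.catalog_size:
        seq = _random_seq(rng, int(rng.integers(20, 24)))
        entries.append(
            CatalogEntry(
                name=f"bta-miR-{9800 + len(entries)}", species="bta", mature=to_rna(seq)
            )
        )
    return entries


def _apply_edits(seq: str, n_edits: int, rng: np.random.Generator) -> str:
    out = list(seq)
    for _ in range(n_edits):
        pos = int(rng.integers(0, len(out)))
        op = rng.random()
        if op < 0.6:  # substitution
            choices = [b for b in "ACGT" if b != out[pos]]
            out[pos] = choices[int(rng.integers(0, 3))]
        elif op < 0.8 and len(out) > 18:  # deletion
            del out[pos]
        else:  # insertion
            out.insert(pos, "ACGT"[int(rng.integers(0, 4))])
    return "".join(out)


def simulate_array(truth: TruthTable, config: SimulationConfig):
    """Generate raw probe intensities for six loci plus the common reference.

    intensity = baseline * 2**expression * lognormal(sigma) + Gaussian
    background. Mature and star probes are laid out in ``array_replicates``
    replicates per sample. Star probes sit ``star_offset`` log2 units below
    the mature except for the first ``n_star_dominant`` hairpins, whose star
    exceeds the mature in every sample.

    Returns a pandas DataFrame (probe_id, target_id, kind, sample, replicate,
    intensity).
    """
    rng = np.random.default_rng(config.seed + 3)
    samples = list(LOCI) + [COMMON_REFERENCE]
    rows = []
    star_drop = 3.0
    for i, hp in enumerate(truth.hairpins):
        star_dominant = i < config.n_star_dominant
        for sample in samples:
            expr = hp.expression.get(sample, 0.0)
            if star_dominant:
                kinds = {"mature": expr - star_drop, "star": expr}
            else:
                kinds = {"mature": expr, "star": expr - star_drop}
            for kind, e in kinds.items():
                signal = config.array_baseline * 2**e
                for rep in range(config.array_replicates):
                    noise = (
                        float(np.exp(rng.normal(0.0, config.array_noise_sigma)))
                        if config.array_noise_sigma > 0
                        else 1.0
                    )
                    bg = config.array_background_mean + (
                        float(rng.normal(0.0, config.array_background_sd))
                        if config.array_background_sd > 0
                        else 0.0
                    )
                    rows.append(
                        {
                            "probe_id": f"{hp.hairpin_id}_{kind}_{rep + 1}",
                            "target_id": hp.hairpin_id,
                            "kind": kind,
                            "sample": sample,
                            "replicate": rep + 1,
                            "intensity": signal * noise + max(bg, 0.0),
                        }
                    )
    return pd.DataFrame(rows)


def truth_to_tsv(truth: TruthTable, path) -> None:
    rows = [
        {
            "hairpin_id": hp.hairpin_id,
            "contig": hp.contig,
            "start": hp.start,
            "end": hp.end,
            "strand": hp.strand,
            "precursor": hp.precursor,
            "mature": hp.mature,
            "mature_arm": hp.mature_arm,
            "star": hp.star,
            **{f"expr_{k}": v for k, v in hp.expression.items()},
        }
        for hp in truth.hairpins
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def config_from_dict(d: dict) -> SimulationConfig:
    names = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(d) - names
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return SimulationConfig(**d)
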