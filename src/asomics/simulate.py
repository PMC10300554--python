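"""Synthetic data generation with known ground truth.

Every input the pipeline consumes can be generated here: a random reference
genome with its DpnII fragment map, paired-end Capture-C libraries with
controlled artifact content, per-sample chromatin-state segmentations with
planted disease-specific states, and an "omics bundle" (gene models, ATAC
peaks, RNA read positions, chromatin loops, GWAS lead SNPs, count matrices
with negative-binomial noise, a scale-free gene interaction network and
labelled positive drug targets).  Each generator returns a
:class:`SimTruth` record of the planted signals so downstream modules can
be validated against a known answer.

Determinism: all randomness flows from ``SimConfig.seed`` through named
child streams, so an identical configuration reproduces byte-identical
outputs.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .capturec import BaitSet, ReferenceIndex, reverse_complement

#: minimum ligation-piece length emitted per fragment in a simulated read;
#: keeps every digestion product of either read orientation at or above the
#: 20-bp sub-read floor
MIN_PIECE = 25

_STREAM_REFERENCE = 0
_STREAM_CAPTURE = 1
_STREAM_STATES = 2
_STREAM_OMICS = 3


@dataclass
class SimConfig:
    """All knobs of the synthetic-data generators.

    Defaults describe the study conditions emulated throughout the test
    suite: a 2-Mb single-chromosome genome, 75-bp read pairs, 4 cases and
    4 controls for the 14-state segmentations, and 8+8 samples for count
    matrices.
    """

    seed: int = 0
    # reference
    genome_length: int = 2_000_000
    n_chromosomes: int = 1
    gc_content: float = 0.5
    # Capture-C library
    read_length: int = 75
    n_read_pairs: int = 50_000
    self_ligation_rate: float = 0.1
    re_ligation_rate: float = 0.1
    duplicate_rate: float = 0.3
    decay_exponent: float = 1.0
    decay_offset: float = 1_000.0  # d0 in the (d + d0)^-alpha contact decay
    planted_interactions: list = field(default_factory=list)  # (bait_id, fragment_id, multiplier)
    # chromatin states
    n_bins: int = 2_000
    bin_size: int = 200
    n_cases: int = 4
    n_controls: int = 4
    n_states: int = 14
    quiescent_state: int = 14
    state_dominance: float = 0.95
    planted_states: list = field(default_factory=list)  # ((lo_bin, hi_bin), state, "case"|"control")
    # omics bundle
    n_genes: int = 200
    n_peaks: int = 100
    fraction_distal: float = 0.5
    min_peak_gene_distance: int = 3_000
    n_loops: int = 40
    n_snps: int = 60
    n_positives: int = 20
    n_count_cases: int = 8
    n_count_controls: int = 8
    n_features: int = 500
    n_planted_features: int = 50
    nb_dispersion: float = 0.05
    planted_fc: float = 4.0
    network_attachment: int = 2
    erna_reads_per_peak: float = 8.0
    multi_reads_per_peak: float = 2.0

    def __post_init__(self):
        for name in ("self_ligation_rate", "re_ligation_rate", "duplicate_rate", "fraction_distal"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.self_ligation_rate + self.re_ligation_rate + self.duplicate_rate > 1.0:
            raise ValueError("artifact fractions must not sum above 1")
        for name in ("genome_length", "n_chromosomes", "read_length", "n_read_pairs",
                     "n_bins", "n_cases", "n_controls", "n_genes", "n_states"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.state_dominance < 1.0:
            raise ValueError("state_dominance must be in (0, 1)")

    def rng(self, stream: int, substream: int = 0) -> np.random.Generator:
        seq = np.random.SeedSequence(entropy=self.seed, spawn_key=(stream, substream))
        return np.random.default_rng(seq)


@dataclass
class SimTruth:
    """Ground-truth record of every planted signal."""

    interaction_counts: dict = field(default_factory=dict)  # bait_id -> {fragment_id: count}
    read_type_counts: dict = field(default_factory=dict)
    differential_bins: dict = field(default_factory=dict)  # state -> [bin indices]
    differential_features: list = field(default_factory=list)
    positive_target_genes: list = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "interaction_counts": {
                b: {str(f): n for f, n in frags.items()}
                for b, frags in self.interaction_counts.items()
            },
            "read_type_counts": self.read_type_counts,
            "differential_bins": {str(s): list(map(int, v)) for s, v in self.differential_bins.items()},
            "differential_features": list(self.differential_features),
            "positive_target_genes": list(self.positive_target_genes),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# Reference genome
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def make_reference(config: SimConfig) -> ReferenceIndex:
    """Random i.i.d. genome with its DpnII fragment tiling.

    Nucleotides are i.i.d. with the configured GC content; the fragment map
    follows the split-before-GATC convention, so fragment lengths sum
    exactly to the genome length.
    """
    if config.genome_length < 10_000:
        raise ValueError("genome_length must be at least 10 kb")
    rng = config.rng(_STREAM_REFERENCE)
    gc = config.gc_content
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seqs = {}
    per_chrom = config.genome_length // config.n_chromosomes
    for i in range(config.n_chromosomes):
        length = per_chrom if i < config.n_chromosomes - 1 else (
            config.genome_length - per_chrom * (config.n_chromosomes - 1)
        )
        draws = rng.choice(4, size=length, p=p)
        seqs[f"chr{i + 1}"] = _BASES[draws].tobytes().decode()
    ref = ReferenceIndex(seqs)
    n_sites = ref.n_fragments - config.n_chromosomes
    if n_sites < 3:
        raise ValueError(
            "genome contains fewer than 3 GATC sites; increase genome_length"
        )
    return ref


def central_bait_fragment(ref: ReferenceIndex, chrom: str = "chr1",
                          min_length: int = 100):
    """The fragment nearest the chromosome centre that is long enough to
    serve as a capture bait."""
    frags = ref.chrom_fragments(chrom)
    centre = frags[len(frags) // 2].fragment_id
    eligible = [f for f in frags if f.length >= min_length]
    if not eligible:
        raise ValueError(f"no fragment of length >= {min_length} on {chrom}")
    return min(eligible, key=lambda f: abs(f.fragment_id - centre))


def write_fasta(ref: ReferenceIndex, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom, seq in ref.sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Capture-C library
# ---------------------------------------------------------------------------


def _eligible_mask(ref: ReferenceIndex, bait_fragments: set[int]) -> np.ndarray:
    """Fragments usable as ligation partners in simulated molecules.

    Excludes bait fragments, the GATC-less first fragment of each
    chromosome, and fragments too short to donate a MIN_PIECE prefix.
    """
    firsts = ref.first_fragment_ids()
    mask = np.zeros(ref.n_fragments, dtype=bool)
    for frag in ref.fragments:
        mask[frag.fragment_id] = (
            frag.length >= MIN_PIECE
            and frag.fragment_id not in firsts
            and frag.fragment_id not in bait_fragments
        )
    return mask


def _piece_lengths(rng, total: int, caps: Sequence[int]) -> tuple[int, int, int]:
    """Split ``total`` into three pieces, each in [MIN_PIECE, cap_i]."""
    for _ in range(200):
        a = int(rng.integers(MIN_PIECE, min(caps[0], total - 2 * MIN_PIECE) + 1))
        b_hi = min(caps[1], total - a - MIN_PIECE)
        if b_hi < MIN_PIECE:
            continue
        b = int(rng.integers(MIN_PIECE, b_hi + 1))
        c = total - a - b
        if MIN_PIECE <= c <= caps[2]:
            return a, b, c
    raise RuntimeError("could not partition molecule into ligation pieces")


def simulate_capturec_library(
    ref: ReferenceIndex,
    baits: BaitSet,
    config: SimConfig,
) -> tuple[list[tuple[str, str, str]], SimTruth]:
    """Simulate a Capture-C paired-end library with known reporter counts.

    Valid reads are three-fragment ligation products: a bait piece, a
    reporter piece drawn with probability proportional to the planted
    enrichment times ``(d + d0)^-alpha`` around the bait, and a bystander
    piece drawn uniformly.  Molecule lengths are chosen so every valid pair
    overlap-merges cleanly, and the bystander is resampled whenever a
    fragment-level deduplication key would repeat, so that genuine repeated
    interactions are never mistaken for PCR duplicates downstream.
    Self-ligation reads cross a fragment's circularisation junction,
    re-ligation reads cross the boundary of two neighbouring fragments, and
    duplicates are exact sequence copies of earlier pairs.

    Returns the list of (read_id, read1, read2) tuples and the truth table
    of valid-interaction counts per (bait, fragment).
    """
    rng = config.rng(_STREAM_CAPTURE)
    R = config.read_length
    if R < 3 * MIN_PIECE // 2 + 10:
        raise ValueError("read_length too short for three-piece molecules")
    mol_lo, mol_hi = R, 2 * R - 20
    bait_frag_ids = baits.fragment_ids
    for b in baits:
        frag = ref.fragment_by_id(b.fragment_id)
        if frag.length < MIN_PIECE:
            raise ValueError(f"bait {b.bait_id} fragment too short to simulate")
    eligible = _eligible_mask(ref, bait_frag_ids)
    frag_mid = np.array([f.midpoint for f in ref.fragments])
    frag_chrom = np.array([f.chrom for f in ref.fragments])

    planted = {(b, f): m for b, f, m in config.planted_interactions}
    reporter_cands: dict[str, np.ndarray] = {}
    reporter_probs: dict[str, np.ndarray] = {}
    for b in baits:
        same_chrom = frag_chrom == b.chrom
        nonadjacent = np.abs(np.arange(ref.n_fragments) - b.fragment_id) >= 2
        cands = np.where(eligible & same_chrom & nonadjacent)[0]
        if cands.size == 0:
            raise ValueError(f"no reporter candidates for bait {b.bait_id}")
        bait_mid = ref.fragment_by_id(b.fragment_id).midpoint
        d = np.abs(frag_mid[cands] - bait_mid)
        w = (d + config.decay_offset) ** (-config.decay_exponent)
        for i, fid in enumerate(cands):
            mult = planted.get((b.bait_id, int(fid)))
            if mult is not None:
                w[i] *= mult
        reporter_cands[b.bait_id] = cands
        reporter_probs[b.bait_id] = w / w.sum()

    bystander_pool = np.where(eligible)[0]
    self_pool = [f for f in ref.fragments
                 if f.length >= 40 and f.fragment_id not in ref.first_fragment_ids()]
    relig_pool = []  # left fragment of an adjacent pair, both long enough
    for frag in ref.fragments:
        nxt = frag.fragment_id + 1
        if nxt >= ref.n_fragments:
            continue
        nxt_frag = ref.fragment_by_id(nxt)
        if (
            nxt_frag.chrom == frag.chrom
            and frag.length >= MIN_PIECE
            and nxt_frag.length >= MIN_PIECE
            and min(frag.length, 100) + min(nxt_frag.length, 100) >= mol_lo
        ):
            relig_pool.append(frag.fragment_id)
    if not self_pool or not relig_pool:
        raise ValueError("genome too fragmented to build artifact reads")

    seq_of = {c: s for c, s in ref.sequences.items()}

    def fragment_seq(fid: int) -> str:
        f = ref.fragment_by_id(fid)
        return seq_of[f.chrom][f.start : f.end]

    def emit(molecule: str) -> tuple[str, str]:
        return molecule[:R], reverse_complement(molecule[-R:])

    bait_list = list(baits)
    truth_counts: dict[str, Counter] = {b.bait_id: Counter() for b in bait_list}
    type_counts = Counter()
    used_keys: set[frozenset] = set()
    reads: list[tuple[str, str, str]] = []

    u = rng.random(config.n_read_pairs)
    d_thr = config.duplicate_rate
    s_thr = d_thr + config.self_ligation_rate
    r_thr = s_thr + config.re_ligation_rate

    for i in range(config.n_read_pairs):
        name = f"r{i:07d}"
        x = u[i]
        if x < d_thr and reads:
            _, r1, r2 = reads[int(rng.integers(0, len(reads)))]
            reads.append((name, r1, r2))
            type_counts["duplicate"] += 1
            continue
        if d_thr <= x < s_thr or (x < d_thr and not reads and s_thr > d_thr):
            frag = self_pool[int(rng.integers(0, len(self_pool)))]
            fseq = fragment_seq(frag.fragment_id)
            cap = min(frag.length, 100)
            while True:
                a = int(rng.integers(MIN_PIECE, cap + 1))
                bl = int(rng.integers(MIN_PIECE, cap + 1))
                if mol_lo <= a + bl <= mol_hi:
                    break
            molecule = fseq[-a:] + fseq[:bl]
            r1, r2 = emit(molecule)
            reads.append((name, r1, r2))
            type_counts["self_ligation"] += 1
            continue
        if s_thr <= x < r_thr:
            left = relig_pool[int(rng.integers(0, len(relig_pool)))]
            lf = ref.fragment_by_id(left)
            rf = ref.fragment_by_id(left + 1)
            while True:
                a = int(rng.integers(MIN_PIECE, min(lf.length, 100) + 1))
                bl = int(rng.integers(MIN_PIECE, min(rf.length, 100) + 1))
                if mol_lo <= a + bl <= mol_hi:
                    break
            molecule = seq_of[lf.chrom][lf.end - a : lf.end + bl]
            r1, r2 = emit(molecule)
            reads.append((name, r1, r2))
            type_counts["re_ligation"] += 1
            continue

        # valid three-fragment ligation product
        bait = bait_list[int(rng.integers(0, len(bait_list)))]
        cands = reporter_cands[bait.bait_id]
        reporter = int(rng.choice(cands, p=reporter_probs[bait.bait_id]))
        bait_frag = ref.fragment_by_id(bait.fragment_id)
        for _ in range(200):
            bys = int(bystander_pool[int(rng.integers(0, bystander_pool.size))])
            if bys == reporter:
                continue
            bf = ref.fragment_by_id(bys)
            if bf.chrom == bait_frag.chrom and abs(bys - bait.fragment_id) < 2:
                continue
            if bf.chrom == ref.fragment_by_id(reporter).chrom and abs(bys - reporter) < 2:
                continue
            key = frozenset((bait.fragment_id, reporter, bys))
            if key not in used_keys:
                break
        else:
            raise RuntimeError("could not find a collision-free bystander fragment")
        used_keys.add(key)
        rep_frag = ref.fragment_by_id(reporter)
        bys_frag = ref.fragment_by_id(bys)
        caps = (min(bait_frag.length, 100), min(rep_frag.length, 100), min(bys_frag.length, 100))
        total_hi = min(mol_hi, sum(caps))
        total = int(rng.integers(max(mol_lo, 3 * MIN_PIECE), total_hi + 1))
        a, bl, c = _piece_lengths(rng, total, caps)
        molecule = (
            fragment_seq(bait.fragment_id)[-a:]
            + fragment_seq(reporter)[:bl]
            + fragment_seq(bys)[:c]
        )
        r1, r2 = emit(molecule)
        reads.append((name, r1, r2))
        truth_counts[bait.bait_id][reporter] += 1
        truth_counts[bait.bait_id][bys] += 1
        type_counts["valid"] += 1

    truth = SimTruth(
        interaction_counts={b: dict(c) for b, c in truth_counts.items()},
        read_type_counts=dict(type_counts),
    )
    return reads, truth


def write_fastq_pair(reads: Sequence[tuple[str, str, str]], path1, path2) -> None:
    """Write the simulated pairs as two FASTQ files with constant qualities."""
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for name, r1, r2 in reads:
            f1.write(f"@{name}/1\n{r1}\n+\n{'I' * len(r1)}\n")
            f2.write(f"@{name}/2\n{r2}\n+\n{'I' * len(r2)}\n")


# ---------------------------------------------------------------------------
# Chromatin-state segmentations
# ---------------------------------------------------------------------------

#: global frequency of the per-bin dominant state, quiescent-heavy the way
#: genome-wide segmentations are (states 1..11 regulatory/transcribed,
#: 12..14 quiescent-like)
_STATE_FREQ = np.array([0.02] * 11 + [0.10, 0.10, 0.58])


def _dominant_states(config: SimConfig) -> np.ndarray:
    """Per-bin dominant state (1-based), deterministic in the seed."""
    rng = config.rng(_STREAM_STATES, 0)
    freq = _STATE_FREQ
    if config.n_states != freq.size:
        freq = np.full(config.n_states, 1.0 / config.n_states)
    return rng.choice(config.n_states, size=config.n_bins, p=freq) + 1


def state_priors(config: SimConfig) -> np.ndarray:
    """Per-bin categorical prior over states (n_bins x n_states).

    Each sample's state at a bin equals the bin's dominant state with
    probability ``state_dominance`` and is uniform over the remaining
    states otherwise.
    """
    dom = _dominant_states(config)
    S = config.n_states
    pri = np.full((config.n_bins, S), (1 - config.state_dominance) / (S - 1))
    pri[np.arange(config.n_bins), dom - 1] = config.state_dominance
    return pri


def expected_fully_separated(config: SimConfig) -> float:
    """Closed-form expected number of fully group-separated (bin, state)
    events under the null prior: for each bin and state, the probability
    that the state is present in every sample of one group and absent from
    every sample of the other."""
    pri = state_priors(config)
    nc, nh = config.n_cases, config.n_controls
    p = pri**nc * (1 - pri) ** nh + pri**nh * (1 - pri) ** nc
    return float(p.sum())


def simulate_state_matrix(config: SimConfig):
    """Per-sample chromatin-state matrix with optional planted separation.

    Returns a :class:`asomics.chromstate.StateMatrix` (4 cases + 4 controls
    by default, 200-bp bins on chr1) and the truth record of planted
    fully-separated bins per state.
    """
    from .chromstate import StateMatrix

    for (_, state, group) in config.planted_states:
        if not 1 <= state <= config.n_states:
            raise ValueError(f"planted state {state} outside 1..{config.n_states}")
        if group not in ("case", "control"):
            raise ValueError("planted group must be 'case' or 'control'")
    n = config.n_cases + config.n_controls
    dom = _dominant_states(config)
    rng = config.rng(_STREAM_STATES, 1)
    S = config.n_states
    states = np.broadcast_to(dom[:, None], (config.n_bins, n)).copy()
    noise = rng.random((config.n_bins, n)) >= config.state_dominance
    alt = rng.integers(1, S, size=(config.n_bins, n))
    alt = alt + (alt >= dom[:, None])  # uniform over the 13 non-dominant states
    states[noise] = alt[noise]

    samples = [f"AS{i + 1}" for i in range(config.n_cases)] + [
        f"HC{i + 1}" for i in range(config.n_controls)
    ]
    groups = ["case"] * config.n_cases + ["control"] * config.n_controls
    case_idx = np.arange(config.n_cases)
    ctrl_idx = np.arange(config.n_cases, n)

    # Planted bins: the chosen state fills one whole group; the other group
    # receives four distinct other states so that no displaced state can
    # itself become fully group-separated at those bins.
    plant_rng = config.rng(_STREAM_STATES, 2)
    truth_bins: dict[int, list[int]] = {}
    for (lo, hi), state, group in config.planted_states:
        present = case_idx if group == "case" else ctrl_idx
        absent = ctrl_idx if group == "case" else case_idx
        others = np.array([s for s in range(1, S + 1) if s != state])
        if len(absent) > others.size:
            raise ValueError("not enough states to scramble the absent group")
        states[lo:hi, present] = state
        for b in range(lo, hi):
            states[b, absent] = plant_rng.choice(others, size=len(absent),
                                                 replace=False)
        truth_bins.setdefault(state, []).extend(range(lo, hi))

    bins = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.arange(config.n_bins) * config.bin_size,
            "end": (np.arange(config.n_bins) + 1) * config.bin_size,
        }
    )
    sm = StateMatrix(bins, states, samples, groups, config.n_states, config.quiescent_state)
    truth = SimTruth(differential_bins=truth_bins)
    return sm, truth


# ---------------------------------------------------------------------------
# Omics bundle
# ---------------------------------------------------------------------------


def simulate_count_matrix(
    rng: np.random.Generator,
    n_features: int,
    n_cases: int,
    n_controls: int,
    dispersion: float,
    planted_idx: Sequence[int] = (),
    fold_change: float = 1.0,
    base_mean_range: tuple[float, float] = (50.0, 500.0),
    prefix: str = "feat",
) -> pd.DataFrame:
    """Negative-binomial count matrix with planted case/control fold changes.

    Counts are gamma-Poisson draws with Var = mu + dispersion * mu^2; rows
    listed in ``planted_idx`` have their case-group mean multiplied by
    ``fold_change``.
    """
    mu = rng.uniform(*base_mean_range, size=n_features)
    mu_case = mu.copy()
    mu_case[list(planted_idx)] *= fold_change
    cols = {}
    for j in range(n_cases + n_controls):
        m = mu_case if j < n_cases else mu
        if dispersion > 0:
            lam = rng.gamma(shape=1.0 / dispersion, scale=m * dispersion)
        else:
            lam = m
        name = f"AS{j + 1}" if j < n_cases else f"HC{j - n_cases + 1}"
        cols[name] = rng.poisson(lam)
    index = [f"{prefix}{i + 1}" for i in range(n_features)]
    return pd.DataFrame(cols, index=index)


def preferential_attachment_network(
    n: int, m: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Scale-free undirected network grown by preferential attachment.

    Starts from two nodes joined by one edge; every subsequent node attaches
    ``m`` edges to distinct existing nodes chosen with probability
    proportional to degree, giving ``m * (n - 2) + 1`` edges in total.
    """
    if n < 2 or m < 1:
        raise ValueError("need n >= 2 nodes and m >= 1 attachment edges")
    edges = [(0, 1)]
    degree = np.zeros(n)
    degree[0] = degree[1] = 1
    for v in range(2, n):
        k = min(m, v)
        probs = degree[:v] / degree[:v].sum()
        targets = rng.choice(v, size=k, replace=False, p=probs)
        for t in targets:
            edges.append((int(t), v))
            degree[t] += 1
            degree[v] += 1
    return edges


@dataclass
class OmicsBundle:
    """Everything the linking/enrichment/prioritisation stages consume."""

    genes: pd.DataFrame  # gene, chrom, start, end, strand, tss
    coding: pd.DataFrame  # chrom, start, end, gene
    peaks: pd.DataFrame  # peak, chrom, start, end, distal (bool)
    rna_reads: pd.DataFrame  # chrom, pos, unique (bool)
    loops: pd.DataFrame  # loop, chrom1, start1, end1, chrom2, start2, end2, gene
    snps: pd.DataFrame  # snp, chrom, pos, p
    counts_rna: pd.DataFrame  # genes x samples
    counts_atac: pd.DataFrame  # peaks x samples
    groups: dict  # sample -> case/control
    network: pd.DataFrame  # gene_a, gene_b
    eqtl_genes: pd.DataFrame  # gene, p
    positives: list
    truth: SimTruth


def simulate_omics_bundle(config: SimConfig) -> OmicsBundle:
    """Gene models, peaks, reads, loops, SNPs, counts, network and labels.

    Genes are laid out one per equal-width slot so that every slot has a
    coding-free gap wide enough to host a peak strictly more than
    ``min_peak_gene_distance`` from any coding interval; ``fraction_distal``
    of the peaks are placed there and the rest overlap gene bodies.  GWAS
    SNPs, eQTL genes, loop targets and planted differential rows are
    enriched at the labelled positive target genes, so that every predictor
    carries genuine signal about the positives.
    """
    if config.n_genes < 20:
        raise ValueError("need at least 20 genes")
    rng = config.rng(_STREAM_OMICS)
    L = config.genome_length
    slot = L // config.n_genes
    d = config.min_peak_gene_distance
    gene_max = 3_000
    if slot < gene_max + 2 * d + 1_000:
        raise ValueError(
            "genome too small for the requested distal peak placement; "
            "increase genome_length or reduce n_genes"
        )
    n_distal = round(config.fraction_distal * config.n_peaks)
    if n_distal > config.n_genes or config.n_peaks - n_distal > config.n_genes:
        raise ValueError("more peaks requested than available slots")

    # genes, one per slot, at the slot start
    starts = np.arange(config.n_genes) * slot + rng.integers(0, 100, config.n_genes)
    lengths = rng.integers(1_500, gene_max + 1, config.n_genes)
    strands = rng.choice(["+", "-"], config.n_genes)
    gene_ids = [f"G{i + 1}" for i in range(config.n_genes)]
    ends = starts + lengths
    tss = np.where(strands == "+", starts, ends - 1)
    genes = pd.DataFrame(
        {"gene": gene_ids, "chrom": "chr1", "start": starts, "end": ends,
         "strand": strands, "tss": tss}
    )
    coding = genes[["chrom", "start", "end", "gene"]].copy()

    # peaks: distal ones centred in the slot gap, proximal ones inside genes
    slot_order = rng.permutation(config.n_genes)
    peak_rows = []
    width = 400
    for k in range(config.n_peaks):
        s = int(slot_order[k % config.n_genes])
        if k < n_distal:
            centre = s * slot + gene_max + 100 + d + width // 2 + int(rng.integers(0, 200))
            lo, hi = centre - width // 2, centre + width // 2
            distal = True
        else:
            g = genes.iloc[s]
            lo = int(g.start) + int(rng.integers(0, max(1, int(g.end - g.start) - width)))
            hi = lo + width
            distal = False
        peak_rows.append((f"P{k + 1}", "chr1", lo, hi, distal))
    peaks = pd.DataFrame(peak_rows, columns=["peak", "chrom", "start", "end", "distal"])

    # RNA read positions inside peaks
    read_rows = []
    for row in peaks.itertuples(index=False):
        for flag, lam in ((True, config.erna_reads_per_peak), (False, config.multi_reads_per_peak)):
            k = rng.poisson(lam)
            for pos in rng.integers(row.start, row.end, k):
                read_rows.append(("chr1", int(pos), flag))
    rna_reads = pd.DataFrame(read_rows, columns=["chrom", "pos", "unique"])

    # positive targets, degree-weighted so they sit in network hubs
    edges = preferential_attachment_network(config.n_genes, config.network_attachment, rng)
    degree = np.zeros(config.n_genes)
    for a, b in edges:
        degree[a] += 1
        degree[b] += 1
    pos_idx = rng.choice(
        config.n_genes, size=config.n_positives, replace=False, p=degree / degree.sum()
    )
    positives = [gene_ids[i] for i in sorted(pos_idx)]
    network = pd.DataFrame(
        [(gene_ids[a], gene_ids[b]) for a, b in edges], columns=["gene_a", "gene_b"]
    )

    # GWAS SNPs: strong hits near a subset of positives, decoys elsewhere
    non_pos = [i for i in range(config.n_genes) if i not in set(pos_idx)]
    snp_rows = []
    strong_pos = rng.choice(pos_idx, size=min(8, len(pos_idx)), replace=False)
    strong_decoy = rng.choice(non_pos, size=7, replace=False)
    si = 0
    for idx in list(strong_pos) + list(strong_decoy):
        t = int(genes.iloc[int(idx)].tss)
        pos = t + int(rng.integers(-10_000, 10_000))
        p = 10.0 ** rng.uniform(-12, -8)
        snp_rows.append((f"rs{si + 1}", "chr1", max(0, pos), p))
        si += 1
    tier_bands = [(-7.25, -6.4), (-4.0, -1.0), (-1.0, 0.0)]
    while si < config.n_snps:
        lo, hi = tier_bands[si % len(tier_bands)]
        snp_rows.append(
            (f"rs{si + 1}", "chr1", int(rng.integers(0, L)), 10.0 ** rng.uniform(lo, hi))
        )
        si += 1
    snps = pd.DataFrame(snp_rows, columns=["snp", "chrom", "pos", "p"])

    # loops from distal peaks to promoters, positives over-represented
    distal_peaks = peaks[peaks.distal].reset_index(drop=True)
    loop_targets = list(rng.choice(pos_idx, size=min(6, len(pos_idx)), replace=False))
    loop_targets += list(rng.choice(non_pos, size=max(0, config.n_loops - len(loop_targets)), replace=True))
    loop_rows = []
    for li in range(min(config.n_loops, len(distal_peaks))):
        pk = distal_peaks.iloc[li % len(distal_peaks)]
        g = genes.iloc[int(loop_targets[li])]
        a1 = (int(pk.start) - 800, int(pk.end) + 800)
        a2 = (int(g.tss) - 1_000, int(g.tss) + 1_000)
        loop_rows.append(
            (f"L{li + 1}", "chr1", a1[0], a1[1], "chr1", a2[0], a2[1], g.gene)
        )
    loops = pd.DataFrame(
        loop_rows,
        columns=["loop", "chrom1", "start1", "end1", "chrom2", "start2", "end2", "gene"],
    )

    # eQTL gene table: positives plus decoys
    eq_idx = list(rng.choice(pos_idx, size=min(6, len(pos_idx)), replace=False))
    eq_idx += list(rng.choice(non_pos, size=6, replace=False))
    eqtl_genes = pd.DataFrame(
        {"gene": [gene_ids[int(i)] for i in eq_idx],
         "p": 10.0 ** rng.uniform(-10, -4, size=len(eq_idx))}
    )

    # count matrices with planted differential rows
    n_pl_genes = min(10, len(pos_idx))
    pl_gene_idx = list(rng.choice(pos_idx, size=n_pl_genes, replace=False))
    pl_gene_idx += list(rng.choice(non_pos, size=10, replace=False))
    counts_rna = simulate_count_matrix(
        rng, config.n_genes, config.n_count_cases, config.n_count_controls,
        config.nb_dispersion, pl_gene_idx, config.planted_fc, prefix="G",
    )
    # planted ATAC peaks: those sitting in positives' slots where possible
    pos_slots = {int(i) for i in pos_idx}
    peak_slot = [int(slot_order[k % config.n_genes]) for k in range(config.n_peaks)]
    pl_peaks = [k for k in range(config.n_peaks) if peak_slot[k] in pos_slots][:15]
    counts_atac = simulate_count_matrix(
        rng, config.n_peaks, config.n_count_cases, config.n_count_controls,
        config.nb_dispersion, pl_peaks, config.planted_fc, prefix="P",
    )
    groups = {f"AS{i + 1}": "case" for i in range(config.n_count_cases)}
    groups.update({f"HC{i + 1}": "control" for i in range(config.n_count_controls)})

    diff_truth = [gene_ids[int(i)] for i in pl_gene_idx] if config.planted_fc != 1.0 else []
    if config.planted_fc != 1.0:
        diff_truth += [f"P{k + 1}" for k in pl_peaks]
    truth = SimTruth(
        differential_features=diff_truth,
        positive_target_genes=positives,
    )
    return OmicsBundle(
        genes=genes, coding=coding, peaks=peaks, rna_reads=rna_reads, loops=loops,
        snps=snps, counts_rna=counts_rna, counts_atac=counts_atac, groups=groups,
        network=network, eqtl_genes=eqtl_genes, positives=positives, truth=truth,
    )
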