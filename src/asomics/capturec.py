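"""Capture-C read processing: digestion, ditag classification and counting.

Capture-C is a chromosome-conformation-capture (3C) assay in which chosen
"bait" restriction fragments (viewpoints, e.g. gene promoters or SNP-bearing
enhancers) are enriched by oligonucleotide capture, so that sequencing reads
report which other restriction fragments each bait was ligated to in the
nucleus.  This module implements the read-level core of that workflow:

1. paired-end reads are overlap-merged where the mates overlap
   (:func:`merge_read_pairs`);
2. merged and non-merged sequences are digested *in silico* at the DpnII
   recognition sequence ``GATC`` (:func:`digest_read`);
3. the resulting sub-reads are mapped back to the reference by exact
   substring search (:func:`map_subread`) and assigned to restriction
   fragments;
4. each read's set of fragments is classified into a valid ditag or one of
   the classical 3C artifact categories — self-ligation of a single fragment
   or re-ligation of genomic neighbours (:func:`classify_ditag`);
5. fragment-level deduplication removes PCR copies (:func:`deduplicate`);
6. valid reporters are counted per bait (:func:`count_reporters`) and
   summarised into fixed genomic bins with a median-of-top-decile region
   score (:func:`summarize_tracks`).

The digestion uses a split-before-GATC convention: every internal sub-read
starts with the recognition sequence.  Fragment assignment is by the
sub-read's leftmost mapped coordinate, so any consistent split convention
yields the same fragment-level ditag.
"""

from __future__ import annotations

import gzip
import math
from bisect import bisect_right
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd

DPNII_SITE = "GATC"
#: seed length for the exact-match index; also the default minimum sub-read
#: length retained for mapping
SEED_LENGTH = 20
MAPQ_UNIQUE = 42
MAPQ_AMBIGUOUS = 0

DITAG_CATEGORIES = (
    "valid",
    "self_ligation",
    "re_ligation",
    "uninformative",
    "low_quality",
    "short_subread",
)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def find_dpnii_sites(seq: str) -> list[int]:
    """0-based start positions of every GATC occurrence in ``seq``."""
    sites = []
    pos = seq.find(DPNII_SITE)
    while pos != -1:
        sites.append(pos)
        pos = seq.find(DPNII_SITE, pos + 1)
    return sites


def digest_read(seq: str) -> list[str]:
    """Split a read immediately before every GATC occurrence.

    The concatenation of the returned pieces reproduces the input; the
    first piece may lack a leading GATC and an occurrence at position 0
    does not produce an empty leading piece.
    """
    if not seq:
        raise ValueError("cannot digest an empty sequence")
    cuts = [p for p in find_dpnii_sites(seq) if p > 0]
    bounds = [0] + cuts + [len(seq)]
    return [seq[a:b] for a, b in zip(bounds[:-1], bounds[1:])]


# ---------------------------------------------------------------------------
# Reference index
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Fragment:
    """A DpnII restriction fragment in 0-based half-open coordinates."""

    fragment_id: int
    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


class ReferenceIndex:
    """Genome sequence plus its ordered DpnII fragment map.

    Fragments tile each chromosome exactly (non-overlapping, sorted, every
    base in exactly one fragment) under the split-before-GATC convention,
    and carry global, chromosome-contiguous integer ids.  The index also
    provides an exact-match substring search over both strands, used as the
    micro-mapper for sub-reads.
    """

    def __init__(self, sequences: dict[str, str]):
        self.sequences = {c: s.upper() for c, s in sequences.items()}
        self.fragments: list[Fragment] = []
        self._starts: dict[str, list[int]] = {}
        self._chrom_range: dict[str, tuple[int, int]] = {}
        fid = 0
        for chrom, seq in self.sequences.items():
            cuts = [p for p in find_dpnii_sites(seq) if p > 0]
            bounds = [0] + cuts + [len(seq)]
            lo = fid
            for a, b in zip(bounds[:-1], bounds[1:]):
                self.fragments.append(Fragment(fid, chrom, a, b))
                fid += 1
            self._chrom_range[chrom] = (lo, fid)
            self._starts[chrom] = bounds[:-1]
        self._seed_index: Optional[dict[str, object]] = None

    # -- fragment lookup ----------------------------------------------------

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)

    def fragment_by_id(self, fragment_id: int) -> Fragment:
        return self.fragments[fragment_id]

    def fragment_at(self, chrom: str, pos: int) -> Fragment:
        """The fragment containing genomic position ``pos`` on ``chrom``."""
        if not 0 <= pos < len(self.sequences[chrom]):
            raise ValueError(f"position {chrom}:{pos} outside the reference")
        lo, _ = self._chrom_range[chrom]
        idx = bisect_right(self._starts[chrom], pos) - 1
        return self.fragments[lo + idx]

    def chrom_fragments(self, chrom: str) -> list[Fragment]:
        lo, hi = self._chrom_range[chrom]
        return self.fragments[lo:hi]

    def first_fragment_ids(self) -> set[int]:
        """Ids of the first fragment of each chromosome (no leading GATC)."""
        return {lo for lo, _ in self._chrom_range.values()}

    # -- exact-match search --------------------------------------------------

    def _ensure_seed_index(self) -> None:
        if self._seed_index is not None:
            return
        index: dict[str, object] = {}
        chroms = list(self.sequences)
        offset = 1 << 34
        for ci, chrom in enumerate(chroms):
            seq = self.sequences[chrom]
            base = ci * offset
            for i in range(len(seq) - SEED_LENGTH + 1):
                key = seq[i : i + SEED_LENGTH]
                prev = index.get(key)
                if prev is None:
                    index[key] = base + i
                elif isinstance(prev, int):
                    index[key] = [prev, base + i]
                else:
                    prev.append(base + i)
        self._seed_index = index
        self._seed_chroms = chroms
        self._seed_offset = offset

    def _seed_hits(self, seq: str) -> list[tuple[str, int]]:
        self._ensure_seed_index()
        entry = self._seed_index.get(seq[:SEED_LENGTH])
        if entry is None:
            return []
        encoded = [entry] if isinstance(entry, int) else entry
        out = []
        for code in encoded:
            ci, pos = divmod(code, self._seed_offset)
            out.append((self._seed_chroms[ci], pos))
        return out

    def locate(self, seq: str, max_hits: int = 2) -> list[tuple[str, int, str]]:
        """Exact occurrences of ``seq`` on either strand.

        Returns up to ``max_hits`` tuples ``(chrom, leftmost_position,
        strand)``; the search stops early once ``max_hits`` are found, which
        is sufficient to decide unique vs ambiguous.
        """
        hits: list[tuple[str, int, str]] = []
        for probe, strand in ((seq, "+"), (reverse_complement(seq), "-")):
            if len(probe) >= SEED_LENGTH:
                candidates = self._seed_hits(probe)
                for chrom, pos in candidates:
                    if self.sequences[chrom][pos : pos + len(probe)] == probe:
                        hits.append((chrom, pos, strand))
                        if len(hits) >= max_hits:
                            return hits
            else:  # brute-force scan for short probes
                for chrom, ref_seq in self.sequences.items():
                    pos = ref_seq.find(probe)
                    while pos != -1:
                        hits.append((chrom, pos, strand))
                        if len(hits) >= max_hits:
                            return hits
                        pos = ref_seq.find(probe, pos + 1)
        return hits


# ---------------------------------------------------------------------------
# Pair merging
# ---------------------------------------------------------------------------


def merge_read_pairs(
    read1: str,
    read2: str,
    min_overlap: int = 10,
    max_mismatch_density: float = 0.25,
) -> Optional[str]:
    """Overlap-merge a read pair into a consensus sequence, if possible.

    The best 3' overlap between ``read1`` and the reverse complement of
    ``read2`` is chosen to maximise the number of matched bases, subject to
    a mismatch fraction of at most ``max_mismatch_density`` and an overlap
    of at least ``min_overlap`` bases.  Returns the consensus (``read1``'s
    base wins at mismatching positions) or ``None`` when no overlap
    qualifies, in which case the pair proceeds through the non-merged
    stream.
    """
    if not read1 or not read2:
        raise ValueError("both mates must be non-empty")
    rc2 = reverse_complement(read2)
    n1, n2 = len(read1), len(read2)
    max_o = min(n1, n2)
    best: Optional[tuple[int, int]] = None  # (matches, overlap)
    # exact overlaps first (cheap slice comparisons, largest wins)
    for o in range(max_o, min_overlap - 1, -1):
        if read1[n1 - o :] == rc2[:o]:
            best = (o, o)
            break
    # an inexact overlap can only win if longer than the best exact match
    lo = best[0] + 1 if best else min_overlap
    if lo <= max_o:
        a1 = np.frombuffer(read1.encode(), dtype=np.uint8)
        a2 = np.frombuffer(rc2.encode(), dtype=np.uint8)
        for o in range(lo, max_o + 1):
            mm = int((a1[n1 - o :] != a2[:o]).sum())
            if mm <= max_mismatch_density * o and (best is None or o - mm > best[0]):
                best = (o - mm, o)
    if best is None:
        return None
    o = best[1]
    return read1 + rc2[o:]


# ---------------------------------------------------------------------------
# Sub-read mapping
# ---------------------------------------------------------------------------


@dataclass
class SubRead:
    """One in-silico digestion product of a read, with its mapping."""

    sequence: str
    parent_id: str
    chrom: Optional[str] = None
    start: Optional[int] = None
    strand: Optional[str] = None
    uniqueness: str = "none"  # unique / multi / none
    mapq: int = 0
    short: bool = False
    junction_trimmed: bool = False


def map_subread(sub: SubRead, ref: ReferenceIndex, min_subread: int = 20) -> SubRead:
    """Map a sub-read by exact search on both strands.

    Exactly one hit gives a unique mapping with quality 42; more than one
    gives an ambiguous mapping with quality 0; none leaves the sub-read
    unmapped.  Sub-reads shorter than ``min_subread`` bases are flagged
    short and never searched.  If the full sequence has no hit and starts
    with GATC, the leading recognition sequence is trimmed once and the
    search repeated: under the split-before-GATC convention the junction
    GATC belongs to the downstream fragment on the forward orientation but
    to the upstream one on the reverse orientation, and the trim recovers
    those reverse-orientation junction pieces.
    """
    seq = sub.sequence
    if len(seq) < min_subread:
        return replace(sub, short=True, uniqueness="none", mapq=0)
    hits = ref.locate(seq)
    trimmed = False
    if not hits and seq.startswith(DPNII_SITE):
        hits = ref.locate(seq[len(DPNII_SITE) :])
        trimmed = bool(hits)
    if not hits:
        return replace(sub, uniqueness="none", mapq=0)
    if len(hits) > 1:
        return replace(sub, uniqueness="multi", mapq=MAPQ_AMBIGUOUS)
    chrom, pos, strand = hits[0]
    return replace(
        sub,
        chrom=chrom,
        start=pos,
        strand=strand,
        uniqueness="unique",
        mapq=MAPQ_UNIQUE,
        junction_trimmed=trimmed,
    )


# ---------------------------------------------------------------------------
# Baits and ditags
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Bait:
    """A captured viewpoint: one DpnII fragment with optional summary region."""

    bait_id: str
    fragment_id: int
    chrom: str
    start: int
    end: int
    region: Optional[tuple[str, int, int]] = None


class BaitSet:
    def __init__(self, baits: Sequence[Bait], ref: Optional[ReferenceIndex] = None):
        ids = [b.bait_id for b in baits]
        if len(set(ids)) != len(ids):
            raise ValueError("bait ids must be unique")
        if ref is not None:
            for b in baits:
                if not 0 <= b.fragment_id < ref.n_fragments:
                    raise ValueError(f"bait {b.bait_id} names a missing fragment")
        self.baits = list(baits)
        self._by_id = {b.bait_id: b for b in baits}
        self._by_fragment = {b.fragment_id: b for b in baits}

    @classmethod
    def from_fragments(
        cls, ref: ReferenceIndex, fragment_ids: Sequence[int], ids: Optional[Sequence[str]] = None
    ) -> "BaitSet":
        baits = []
        for i, fid in enumerate(fragment_ids):
            frag = ref.fragment_by_id(fid)
            name = ids[i] if ids is not None else f"bait{i + 1}"
            baits.append(Bait(name, fid, frag.chrom, frag.start, frag.end))
        return cls(baits, ref)

    @classmethod
    def from_table(cls, table: pd.DataFrame, ref: ReferenceIndex) -> "BaitSet":
        """Build baits from a table with bait_id, chrom, start, end columns."""
        baits = []
        for row in table.itertuples(index=False):
            mid = (int(row.start) + int(row.end)) // 2
            frag = ref.fragment_at(row.chrom, mid)
            region = None
            if hasattr(row, "region_chrom") and isinstance(row.region_chrom, str):
                region = (row.region_chrom, int(row.region_start), int(row.region_end))
            baits.append(Bait(str(row.bait_id), frag.fragment_id, frag.chrom, frag.start, frag.end, region))
        return cls(baits, ref)

    def __iter__(self) -> Iterator[Bait]:
        return iter(self.baits)

    def __len__(self) -> int:
        return len(self.baits)

    def get(self, bait_id: str) -> Bait:
        return self._by_id[bait_id]

    @property
    def fragment_ids(self) -> set[int]:
        return set(self._by_fragment)

    def bait_for_fragment(self, fragment_id: int) -> Optional[Bait]:
        return self._by_fragment.get(fragment_id)


@dataclass
class Ditag:
    """A classified set of mapped restriction fragments from one read."""

    parent_id: str
    fragments: tuple[tuple[str, int, str], ...]  # (chrom, fragment_id, strand)
    category: str
    bait_ids: tuple[str, ...] = ()
    duplicate: bool = False

    @property
    def fragment_ids(self) -> list[int]:
        return sorted({fid for _, fid, _ in self.fragments})


def classify_ditag(
    subreads: Sequence[SubRead],
    ref: ReferenceIndex,
    baits: BaitSet,
    mapq_min: int = 30,
) -> Ditag:
    """Assign a read's mapped sub-reads to exactly one ditag category.

    Precedence: any short sub-read makes the whole read ``short_subread``
    (pairs containing sub-reads below the length floor are discarded
    outright); any remaining sub-read below the mapping-quality floor makes
    it ``low_quality``; otherwise the fragment pattern decides — a single
    fragment seen by one sub-read is uninformative, by several sub-reads a
    self-ligation circle, exactly two neighbouring fragments on one
    chromosome a re-ligation of the original cut, and anything else a valid
    ditag.
    """
    if not subreads:
        raise ValueError("cannot classify an empty sub-read list")
    parent = subreads[0].parent_id
    if any(s.short for s in subreads):
        return Ditag(parent, (), "short_subread")
    if any(s.mapq < mapq_min for s in subreads):
        return Ditag(parent, (), "low_quality")
    triples = []
    for s in subreads:
        frag = ref.fragment_at(s.chrom, s.start)
        triples.append((s.chrom, frag.fragment_id, s.strand))
    distinct = sorted({fid for _, fid, _ in triples})
    bait_ids = tuple(
        sorted(b.bait_id for b in baits if b.fragment_id in distinct)
    )
    if len(distinct) == 1:
        category = "self_ligation" if len(subreads) >= 2 else "uninformative"
    elif len(distinct) == 2:
        (c1, f1), (c2, f2) = sorted({(c, f) for c, f, _ in triples})
        if c1 == c2 and abs(f1 - f2) == 1:
            category = "re_ligation"
        else:
            category = "valid"
    else:
        category = "valid"
    return Ditag(parent, tuple(triples), category, bait_ids)


def deduplicate(ditags: Sequence[Ditag]) -> list[Ditag]:
    """Flag repeated fragment-level ditags as duplicates.

    The key is the sorted set of (chrom, fragment_id, strand) across the
    read's sub-reads; the first occurrence is kept and later occurrences
    flagged.  Recomputing the flags from scratch makes the operation
    idempotent.
    """
    seen: set[tuple] = set()
    out = []
    for dt in ditags:
        if not dt.fragments:
            out.append(replace(dt, duplicate=False))
            continue
        key = tuple(sorted(set(dt.fragments)))
        out.append(replace(dt, duplicate=key in seen))
        seen.add(key)
    return out


# ---------------------------------------------------------------------------
# Reporter counting and summarisation
# ---------------------------------------------------------------------------


@dataclass
class ReporterTrack:
    """Per-(bait, fragment) reporter counts plus the QC partition."""

    counts: Counter = field(default_factory=Counter)
    qc: Counter = field(default_factory=Counter)

    def bait_counts(self, bait_id: str) -> dict[int, int]:
        return {fid: n for (b, fid), n in self.counts.items() if b == bait_id}

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def count_reporters(
    ditags: Sequence[Ditag],
    baits: BaitSet,
    ref: ReferenceIndex,
    exclusion_fragments: int = 1,
) -> ReporterTrack:
    """Count valid reporter fragments per bait viewpoint.

    For every deduplicated valid ditag containing exactly one bait fragment,
    each other mapped fragment increments the (bait, fragment) count, except
    fragments within ``exclusion_fragments`` of the bait (the proximity
    exclusion zone).  Reads containing two or more distinct bait fragments
    are set aside as bait-to-bait and tracked in QC only.
    """
    track = ReporterTrack()
    for dt in ditags:
        track.qc[dt.category] += 1
        if dt.category != "valid":
            continue
        if dt.duplicate:
            track.qc["duplicate"] += 1
            continue
        frag_pairs = sorted({(c, f) for c, f, _ in dt.fragments})
        hit_baits = [baits.bait_for_fragment(f) for _, f in frag_pairs]
        hit_baits = [b for b in hit_baits if b is not None]
        if not hit_baits:
            track.qc["valid_unbaited"] += 1
            continue
        if len(hit_baits) >= 2:
            track.qc["bait_to_bait"] += 1
            continue
        bait = hit_baits[0]
        for chrom, fid in frag_pairs:
            if fid == bait.fragment_id:
                continue
            if chrom == bait.chrom and abs(fid - bait.fragment_id) <= exclusion_fragments:
                track.qc["excluded_zone"] += 1
                continue
            track.counts[(bait.bait_id, fid)] += 1
    return track


def median_top_scores(scores: Sequence[float], top_fraction: float = 0.1) -> float:
    """Median of the ``ceil(top_fraction * n)`` largest scores."""
    values = np.asarray(list(scores), dtype=float)
    if values.size == 0:
        raise ValueError("empty score list")
    k = math.ceil(top_fraction * values.size)
    top = np.sort(values)[-k:]
    return float(np.median(top))


def bin_counts(
    track: ReporterTrack, ref: ReferenceIndex, bait_id: str, bin_size: int = 400
) -> Counter:
    """Aggregate a bait's fragment counts into genome-anchored fixed bins.

    Each fragment's count is assigned to the bin containing its midpoint;
    bins are half-open and anchored at coordinate 0.
    """
    binned: Counter = Counter()
    for fid, n in track.bait_counts(bait_id).items():
        frag = ref.fragment_by_id(fid)
        b = int(frag.midpoint // bin_size) * bin_size
        binned[(frag.chrom, b)] += n
    return binned


def summarize_tracks(
    tracks: dict[str, ReporterTrack],
    groups: dict[str, str],
    ref: ReferenceIndex,
    bait_id: str,
    region: tuple[str, int, int],
    bin_size: int = 400,
    top_fraction: float = 0.1,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Group-wise binned mean/SD tracks and a median-top-decile region score.

    ``region`` is (chrom, start, end) in 0-based half-open coordinates.  The
    per-bin mean and population SD are taken across each group's samples;
    the region summary is the median of the top ``top_fraction`` of the
    group's per-bin mean scores within the region.
    """
    if bin_size <= 0:
        raise ValueError("bin size must be positive")
    chrom, start, end = region
    if end <= start:
        raise ValueError("empty region")
    first = (start // bin_size) * bin_size
    bin_starts = list(range(first, end, bin_size))
    group_names = sorted(set(groups.values()))
    for g in group_names:
        if not any(v == g for v in groups.values()):
            raise ValueError(f"group {g} has no samples")
    per_sample = {}
    for sample, track in tracks.items():
        binned = bin_counts(track, ref, bait_id, bin_size)
        per_sample[sample] = np.array([binned.get((chrom, b), 0) for b in bin_starts], dtype=float)
    out = {"chrom": chrom, "start": bin_starts, "end": [b + bin_size for b in bin_starts]}
    summaries = {}
    for g in group_names:
        members = [s for s, grp in groups.items() if grp == g]
        mat = np.vstack([per_sample[s] for s in members])
        mean = mat.mean(axis=0)
        out[f"{g}_mean"] = mean
        out[f"{g}_sd"] = mat.std(axis=0, ddof=0)
        summaries[g] = median_top_scores(mean, top_fraction)
    return pd.DataFrame(out), summaries


# ---------------------------------------------------------------------------
# FASTQ handling and the end-to-end driver
# ---------------------------------------------------------------------------


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def iter_fastq(path) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) records from a (optionally gzipped) FASTQ."""
    with _open_text(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().strip()
            fh.readline()  # +
            fh.readline()  # qualities
            yield header.strip().lstrip("@").split()[0], seq


def iter_fastq_pairs(path1, path2) -> Iterator[tuple[str, str, str]]:
    for (name1, seq1), (_, seq2) in zip(iter_fastq(path1), iter_fastq(path2)):
        yield name1, seq1, seq2


def process_read_pair(
    name: str,
    read1: str,
    read2: str,
    ref: ReferenceIndex,
    baits: BaitSet,
    min_overlap: int = 10,
    max_mismatch_density: float = 0.25,
    min_subread: int = 20,
    mapq_min: int = 30,
) -> tuple[Ditag, bool]:
    """Merge, digest, map and classify a single read pair.

    Returns the ditag and whether the pair was overlap-merged.
    """
    merged = merge_read_pairs(read1, read2, min_overlap, max_mismatch_density)
    if merged is not None:
        pieces = digest_read(merged)
    else:
        pieces = digest_read(read1) + digest_read(read2)
    subs = [map_subread(SubRead(p, name), ref, min_subread) for p in pieces]
    return classify_ditag(subs, ref, baits, mapq_min), merged is not None


def process_library(
    read_pairs: Iterable[tuple[str, str, str]],
    ref: ReferenceIndex,
    baits: BaitSet,
    min_overlap: int = 10,
    max_mismatch_density: float = 0.25,
    min_subread: int = 20,
    mapq_min: int = 30,
    exclusion_fragments: int = 1,
) -> tuple[ReporterTrack, list[Ditag]]:
    """Run the full Capture-C read-processing chain over a library.

    ``read_pairs`` yields (name, read1, read2) tuples (see
    :func:`iter_fastq_pairs` for file input).  Returns the deduplicated
    reporter track (with its QC category partition) and the classified
    ditags.
    """
    ditags = []
    n_merged = 0
    for name, r1, r2 in read_pairs:
        dt, merged = process_read_pair(
            name, r1, r2, ref, baits, min_overlap, max_mismatch_density, min_subread, mapq_min
        )
        n_merged += merged
        ditags.append(dt)
    ditags = deduplicate(ditags)
    track = count_reporters(ditags, baits, ref, exclusion_fragments)
    track.qc["merged_pairs"] = n_merged
    track.qc["total_pairs"] = len(ditags)
    return track, ditags


def reporter_bedgraph(track: ReporterTrack, ref: ReferenceIndex, bait_id: str) -> pd.DataFrame:
    """Per-fragment reporter counts for one bait as a bedGraph-style table."""
    rows = []
    for fid, n in sorted(track.bait_counts(bait_id).items()):
        frag = ref.fragment_by_id(fid)
        rows.append((frag.chrom, frag.start, frag.end, n))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "count"])


def qc_table(track: ReporterTrack) -> pd.DataFrame:
    rows = sorted(track.qc.items())
    return pd.DataFrame(rows, columns=["metric", "count"])
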