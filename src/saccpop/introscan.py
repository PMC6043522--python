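"""Windowed introgression/HGT scanning against a multi-species library.

Query genomes are scanned in 1000-bp windows sliding by 500 bp.  Each
window is aligned to every reference taxon with an exact 15-mer
seed-anchored, banded edit-distance extension (edlib); identity is
matches over aligned columns.  A window with identity < 65% and seed
coverage < 30% against a reference carries no alignment signal and its
identity is set to 0 (the "deletion rule").

Candidate alien regions are maximal runs of windows whose best
conspecific identity falls below 95%, spanning at least 1 kb; the
second stage keeps fragments with mean conspecific identity < 93% and
length >= 1.5 kb, merges overlapping fragments across isolates into
cohort fragments with carrier lists, and drops short fragments private
to a single isolate.  Donors are assigned from the non-conspecific
taxa; congeneric donors imply introgression, outside-genus donors HGT,
and fragments matching no donor at >= 65% stay unknown.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import edlib
import numpy as np

SEED_K = 15
_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass(frozen=True)
class ScanParams:
    window: int = 1000
    step: int = 500
    min_tail_window: int = 200
    stage1_identity: float = 95.0
    stage1_min_len: int = 1000
    final_identity: float = 93.0
    final_min_len: int = 1500
    drop_single_isolate_short: bool = True
    deletion_identity: float = 65.0
    deletion_coverage: float = 0.30
    donor_min_identity: float = 65.0
    merge_overlap: float = 0.50


@dataclass
class WindowHit:
    contig: str
    start: int                      # 0-based half-open
    end: int
    identity: dict[str, float]      # taxon -> best identity (%)
    coverage: dict[str, float]      # taxon -> seed coverage fraction

    def best(self, taxa: Sequence[str]) -> float:
        return max((self.identity.get(t, 0.0) for t in taxa), default=0.0)


@dataclass(frozen=True)
class CandidateInterval:
    isolate: str
    contig: str
    start: int
    end: int
    mean_identity: float            # mean best-conspecific identity

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AlienFragment:
    contig: str
    start: int
    end: int
    mean_identity: float            # conspecific, over carriers
    donor_identity: dict[str, float] = field(default_factory=dict)
    donor: str | None = None
    klass: str = "unknown"          # HGT | introgression | unknown
    carriers: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start


class ReferenceLibrary:
    """Reference sequences grouped by taxon, with taxonomy tags.

    Tags: ``conspecific`` (same species; defines the identity baseline),
    ``congeneric`` (same genus; introgression donors), ``outside-genus``
    (HGT donors).
    """

    TAGS = ("conspecific", "congeneric", "outside-genus")

    def __init__(self, sequences: Mapping[str, Mapping[str, str]],
                 tags: Mapping[str, str]):
        if not sequences:
            raise ValueError("empty reference library")
        for taxon, tag in tags.items():
            if tag not in self.TAGS:
                raise ValueError(f"unknown tag {tag!r} for taxon {taxon}")
        if "conspecific" not in set(tags.values()):
            raise ValueError("library must contain a conspecific reference")
        self.sequences = {t: dict(seqs) for t, seqs in sequences.items()}
        self.tags = dict(tags)
        self._subject: dict[str, str] = {}
        self._index: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for taxon, seqs in self.sequences.items():
            # one alignment subject per taxon; N runs separate sequences so
            # no window can span two of them profitably
            subject = ("N" * 50).join(seqs.values())
            self._subject[taxon] = subject
            codes, positions = _kmer_codes(subject, with_positions=True)
            order = np.argsort(codes, kind="stable")
            self._index[taxon] = (codes[order], positions[order])

    @property
    def taxa(self) -> list[str]:
        return list(self.sequences)

    def taxa_with_tag(self, tag: str) -> list[str]:
        return [t for t in self.sequences if self.tags[t] == tag]

    def seed_matches(self, window_seq: str, taxon: str
                     ) -> tuple[float, np.ndarray]:
        """Exact shared 15-mers: (window seed coverage, match diagonals).

        A diagonal is subject position minus query position; clustered
        diagonals anchor the banded extension.
        """
        if len(window_seq) < SEED_K:
            return 0.0, np.empty(0, dtype=np.int64)
        qk, qpos = _kmer_codes(window_seq, with_positions=True)
        codes, positions = self._index[taxon]
        lo = np.searchsorted(codes, qk, side="left")
        hi = np.searchsorted(codes, qk, side="right")
        hit = hi > lo
        covered = np.zeros(len(window_seq), dtype=bool)
        diagonals = []
        for qi, l, h in zip(qpos[hit], lo[hit], hi[hit]):
            covered[qi:qi + SEED_K] = True
            for spos in positions[l:min(h, l + 4)]:  # cap repetitive kmers
                diagonals.append(int(spos) - int(qi))
        return float(covered.mean()), np.asarray(diagonals, dtype=np.int64)

    def seed_coverage(self, window_seq: str, taxon: str) -> float:
        """Fraction of the window covered by exact shared 15-mers."""
        return self.seed_matches(window_seq, taxon)[0]


_BASE_VAL = {"A": 0, "C": 1, "G": 2, "T": 3}


def _kmer_codes(seq: str, with_positions: bool = False):
    codes = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    vals = np.full(codes.size, 0, dtype=np.uint64)
    ok = np.zeros(codes.size, dtype=bool)
    for b, v in _BASE_VAL.items():
        m = codes == ord(b)
        vals[m] = v
        ok |= m
    n = codes.size - SEED_K + 1
    if n <= 0:
        empty = np.empty(0, dtype=np.uint64)
        return (empty, np.empty(0, dtype=np.int64)) if with_positions else empty
    out = np.zeros(n, dtype=np.uint64)
    valid = np.ones(n, dtype=bool)
    for j in range(SEED_K):
        out = (out << np.uint64(2)) | vals[j:j + n]
        valid &= ok[j:j + n]
    if with_positions:
        return out[valid], np.nonzero(valid)[0].astype(np.int64)
    return out[valid]


def _alignment_identity(query: str, ref: str, max_distance_frac: float = 0.6,
                        ) -> float | None:
    """Best infix-alignment identity (%) of query within ref, or None when
    no alignment exists within the distance band."""
    k = int(len(query) * max_distance_frac)
    res = edlib.align(query, ref, mode="HW", task="path", k=k)
    if res["editDistance"] < 0:
        return None
    cols = matches = 0
    for num, op in _CIGAR_RE.findall(res["cigar"] or ""):
        num = int(num)
        cols += num
        if op == "=":
            matches += num
    if cols == 0:
        return None
    return 100.0 * matches / cols


def _anchored_identity(query: str, subject: str, diagonals: np.ndarray,
                       max_distance_frac: float = 0.6) -> float | None:
    """Identity of the seed-anchored banded extension.

    The subject is sliced around the median seed diagonal with a margin,
    then aligned as an infix; falls back to the full subject when the
    anchored slice yields nothing."""
    if diagonals.size == 0:
        return None
    d = int(np.median(diagonals))
    margin = max(200, len(query) // 4)
    lo = max(0, d - margin)
    hi = min(len(subject), d + len(query) + margin)
    ident = _alignment_identity(query, subject[lo:hi], max_distance_frac)
    if ident is None:
        ident = _alignment_identity(query, subject, max_distance_frac)
    return ident


def window_identity(window_seq: str, contig: str, start: int,
                    library: ReferenceLibrary,
                    params: ScanParams = ScanParams()) -> WindowHit:
    """Best identity and seed coverage of one window against every taxon."""
    if len(window_seq) < params.min_tail_window:
        raise ValueError("window shorter than the minimum tail window")
    identity: dict[str, float] = {}
    coverage: dict[str, float] = {}
    for taxon in library.taxa:
        cov, diagonals = library.seed_matches(window_seq, taxon)
        best = _anchored_identity(window_seq, library._subject[taxon],
                                  diagonals)
        if best is None:
            best = 0.0
        if best < params.deletion_identity and cov < params.deletion_coverage:
            best = 0.0      # deletion rule: no alignment signal
        identity[taxon] = best
        coverage[taxon] = cov
    return WindowHit(contig, start, start + len(window_seq), identity, coverage)


def scan_contig(contig: str, seq: str, library: ReferenceLibrary,
                params: ScanParams = ScanParams()) -> list[WindowHit]:
    hits = []
    pos = 0
    L = len(seq)
    while pos < L:
        end = min(pos + params.window, L)
        if end - pos >= params.min_tail_window:
            hits.append(window_identity(seq[pos:end], contig, pos, library,
                                        params))
        if end == L:
            break
        pos += params.step
    return hits


def scan_candidates(hits: Sequence[WindowHit], library: ReferenceLibrary,
                    isolate: str,
                    params: ScanParams = ScanParams()) -> list[CandidateInterval]:
    """Stage 1: merge runs of low-conspecific-identity windows.

    Windows whose best conspecific identity is below the stage-1
    threshold are merged across the 500-bp step into maximal candidate
    intervals; intervals spanning less than 1 kb are dropped.
    """
    conspecific = library.taxa_with_tag("conspecific")
    runs: list[list[WindowHit]] = []
    run: list[WindowHit] = []
    for hit in hits:
        low = hit.best(conspecific) < params.stage1_identity
        if low and (not run or (hit.contig == run[-1].contig
                                and hit.start <= run[-1].end)):
            run.append(hit)
        else:
            if run:
                runs.append(run)
            run = [hit] if low else []
    if run:
        runs.append(run)

    in_run = {id(h) for r in runs for h in r}
    background = [h.best(conspecific) for h in hits if id(h) not in in_run]
    baseline = float(np.median(background)) if background else 100.0

    out: list[CandidateInterval] = []
    for run in runs:
        idents = [h.best(conspecific) for h in run]
        start = _refine_edge(run[0], idents, baseline, left=True)
        end = _refine_edge(run[-1], idents, baseline, left=False)
        if end - start >= params.stage1_min_len:
            out.append(CandidateInterval(isolate, run[0].contig, start, end,
                                         float(np.mean(idents))))
    return out


def _refine_edge(edge_hit: WindowHit, run_identities: list[float],
                 baseline: float, left: bool) -> int:
    """Sub-window boundary estimate for a partially alien edge window.

    The identity deficit of the edge window relative to the conspecific
    baseline is proportional to its alien overlap, so the boundary is
    interpolated from the interior (median) deficit of the run.  Falls
    back to the window boundary when there is no usable contrast.
    """
    interior = [v for v in run_identities if v > 0]
    edge_ident = run_identities[0] if left else run_identities[-1]
    if not interior or edge_ident <= 0:
        return edge_hit.start if left else edge_hit.end
    # the deepest window is the one most fully covered by the alien
    # segment, so it estimates the interior identity least biasedly
    depth = baseline - float(np.min(interior))
    if depth <= 1.0:    # no contrast: keep window resolution
        return edge_hit.start if left else edge_hit.end
    frac = min(max((baseline - edge_ident) / depth, 0.0), 1.0)
    span = edge_hit.end - edge_hit.start
    if left:
        return edge_hit.end - int(round(frac * span))
    return edge_hit.start + int(round(frac * span))


def _fragment_mean_identity(hits: Sequence[WindowHit], contig: str,
                            start: int, end: int,
                            taxa: Sequence[str]) -> float:
    """Mean best identity over the fragment's windows, excluding
    deletion-rule windows (identity 0), which carry no signal."""
    vals = [h.best(taxa) for h in hits
            if h.contig == contig and h.start < end and h.end > start
            and h.best(taxa) > 0]
    return float(np.mean(vals)) if vals else 0.0


def refine_fragments(candidates: Mapping[str, Sequence[CandidateInterval]],
                     hits_by_isolate: Mapping[str, Sequence[WindowHit]],
                     library: ReferenceLibrary,
                     params: ScanParams = ScanParams()) -> list[AlienFragment]:
    """Stage 2: tighten thresholds, unify carriers, assign donors."""
    conspecific = library.taxa_with_tag("conspecific")
    kept: list[CandidateInterval] = []
    for isolate, cands in candidates.items():
        for c in cands:
            if c.length < params.final_min_len:
                continue
            mean_ident = _fragment_mean_identity(
                list(hits_by_isolate[isolate]), c.contig, c.start, c.end,
                conspecific)
            if mean_ident >= params.final_identity:
                continue
            kept.append(CandidateInterval(isolate, c.contig, c.start, c.end,
                                          mean_ident))

    clusters = _cluster_candidates(kept, params.merge_overlap)
    fragments: list[AlienFragment] = []
    for members in clusters:
        start = min(c.start for c in members)
        end = max(c.end for c in members)
        carriers = sorted({c.isolate for c in members})
        if (params.drop_single_isolate_short and len(carriers) == 1
                and end - start < 2 * params.final_min_len):
            continue
        frag = AlienFragment(
            contig=members[0].contig, start=start, end=end,
            mean_identity=float(np.mean([c.mean_identity for c in members])),
            carriers=carriers)
        assign_donor(frag, hits_by_isolate, library, params)
        fragments.append(frag)
    fragments.sort(key=lambda f: (f.contig, f.start))
    return fragments


def _cluster_candidates(cands: list[CandidateInterval], min_overlap: float,
                        ) -> list[list[CandidateInterval]]:
    """Single-linkage clustering of intervals overlapping by >= min_overlap
    of the shorter interval, per contig."""
    clusters: list[list[CandidateInterval]] = []
    for c in sorted(cands, key=lambda c: (c.contig, c.start)):
        placed = False
        for cluster in clusters:
            if cluster[0].contig != c.contig:
                continue
            for other in cluster:
                ov = min(c.end, other.end) - max(c.start, other.start)
                if ov >= min_overlap * min(c.length, other.length):
                    cluster.append(c)
                    placed = True
                    break
            if placed:
                break
        if not placed:
            clusters.append([c])
    return clusters


def assign_donor(fragment: AlienFragment,
                 hits_by_isolate: Mapping[str, Sequence[WindowHit]],
                 library: ReferenceLibrary,
                 params: ScanParams = ScanParams()) -> AlienFragment:
    """Donor = non-conspecific taxon with the highest mean window identity
    over the fragment, if it reaches the 65% floor; class follows the
    donor's taxonomy tag."""
    donor_taxa = [t for t in library.taxa
                  if library.tags[t] != "conspecific"]
    per_donor: dict[str, list[float]] = {t: [] for t in donor_taxa}
    for isolate in fragment.carriers:
        for h in hits_by_isolate[isolate]:
            if (h.contig == fragment.contig and h.start < fragment.end
                    and h.end > fragment.start):
                for t in donor_taxa:
                    per_donor[t].append(h.identity.get(t, 0.0))
    fragment.donor_identity = {
        t: float(np.mean(v)) if v else 0.0 for t, v in per_donor.items()}
    if fragment.donor_identity:
        best = max(fragment.donor_identity, key=fragment.donor_identity.get)
        if fragment.donor_identity[best] >= params.donor_min_identity:
            fragment.donor = best
            tag = library.tags[best]
            fragment.klass = "HGT" if tag == "outside-genus" else "introgression"
            return fragment
    fragment.donor = None
    fragment.klass = "unknown"
    return fragment


def scan_cohort(queries: Mapping[str, Mapping[str, str]],
                library: ReferenceLibrary,
                params: ScanParams = ScanParams()) -> list[AlienFragment]:
    """Scan every isolate genome and produce the cohort fragment table."""
    hits_by_isolate: dict[str, list[WindowHit]] = {}
    candidates: dict[str, list[CandidateInterval]] = {}
    for isolate, contigs in queries.items():
        hits: list[WindowHit] = []
        cands: list[CandidateInterval] = []
        for contig, seq in contigs.items():
            chits = scan_contig(contig, seq, library, params)
            hits.extend(chits)
            cands.extend(scan_candidates(chits, library, isolate, params))
        hits_by_isolate[isolate] = hits
        candidates[isolate] = cands
    return refine_fragments(candidates, hits_by_isolate, library, params)
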