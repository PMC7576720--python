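"""Read classification by approximate k-mer matching.

Every 32-base window of a read (stride 1) is looked up in the database:

1. the window's PREFIX selects a group, implying an exact match on the
   first n bases — a linear probe walks that group's entries;
2. the QM fields are compared under the seed masks, passing iff they
   differ by at most one substitution;
3. the DP fields are compared by a banded edit distance allowing at most
   two further errors, including insertions and deletions.  Because an
   indel shifts the read frame, the query side may consume up to two read
   bases beyond the window's nominal end, and query bases beyond the
   optimal path are free.

A matched window therefore tolerates up to three errors outside the
PREFIX.  Each matched window contributes one hit to the entry's taxid
(entries are discriminative, so the probe stops at the first match); the
read is assigned to the taxid with the most hits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .codec import (
    K,
    CodecParams,
    SeedMaskSet,
    decode_bases,
    encode_bases,
    make_seed_masks,
    qm_match,
    scan_kmers,
    split_suffix,
)
from .database import KmerDatabase
from .errors import AmbiguousBaseError, ShortReadError
from .taxonomy import TaxonomyTree

INF = math.inf


@dataclass(frozen=True)
class ClassifyParams:
    """Query-time knobs: minimum hit count for a positive call and whether
    a window keeps probing its group after the first match."""

    min_hits: int = 1
    exhaustive_probe: bool = False


@dataclass(frozen=True)
class MatchResult:
    matched: bool
    taxid: int | None = None
    edit_cost: int | None = None  # tolerated errors, 0..3


@dataclass
class ReadAssignment:
    read_id: str
    status: str  # "C" or "U"
    taxid: int | None
    hit_counts: dict[int, int] = field(default_factory=dict)
    total_kmers_examined: int = 0

    @property
    def max_hits(self) -> int:
        return max(self.hit_counts.values(), default=0)


def banded_edit_cost(q: str, r: str, band_width: int = 4, max_err: int = 2) -> float:
    """Unit-cost edit distance between ``q`` and ``r`` restricted to a
    diagonal band, or infinity when it exceeds ``max_err``.

    The band spans ``band_width`` off-main diagonals (band_width // 2 on
    each side of the main diagonal), so the net length shift is limited to
    ±(band_width // 2).  Within that band the result equals the unbanded
    Levenshtein distance whenever the latter is <= max_err, since an
    optimal path of cost c never strays more than c diagonals off-center.
    """
    hw = band_width // 2
    if abs(len(q) - len(r)) > hw:
        return INF
    big = max_err + len(q) + len(r)  # safely above any reachable cost
    width = 2 * hw + 1
    # row i covers query positions j = i + o - hw for offsets o in [0, width)
    prev = [big] * width
    for o in range(width):  # i = 0: cost = number of inserted query bases
        j = o - hw
        if 0 <= j <= len(q):
            prev[o] = j
    for i in range(1, len(r) + 1):
        cur = [big] * width
        for o in range(width):
            j = i + o - hw
            if j < 0 or j > len(q):
                continue
            if j == 0:
                cur[o] = i  # leading deletions of r
                continue
            best = prev[o] + (0 if q[j - 1] == r[i - 1] else 1)  # diagonal
            if o + 1 < width:
                best = min(best, prev[o + 1] + 1)  # delete r[i-1]
            if o > 0:
                best = min(best, cur[o - 1] + 1)  # insert q[j-1]
            cur[o] = best
        prev = cur
        if min(prev) > max_err:
            return INF
    cost = prev[len(q) - len(r) + hw]
    return cost if cost <= max_err else INF


def dp_region_cost(q: str, r: str, band_width: int = 4, max_err: int = 2) -> float:
    """Banded edit cost of the reference DP field against a *prefix* of the
    (extended) query DP region — trailing query bases are free."""
    hw = band_width // 2
    lo = max(0, len(r) - hw)
    hi = min(len(q), len(r) + hw)
    best = INF
    for j in range(lo, hi + 1):
        best = min(best, banded_edit_cost(q[:j], r, band_width, max_err))
    return best


def match_kmer(
    query: str,
    entry: tuple[int, int],
    codec: CodecParams,
    masks: SeedMaskSet,
) -> MatchResult:
    """Match one query window against one database entry of its group.

    ``query`` is the 32-base window plus up to 2 trailing read bases (34
    max); the caller guarantees the window's group_id equals the entry's
    group.  ``entry`` is (suffix_code, taxid).
    """
    suffix_code, taxid = entry
    qm_q = query[16 : 16 + codec.m]
    qm_code, dp_code = split_suffix(suffix_code, codec)
    try:
        q_code = encode_bases(qm_q)
    except AmbiguousBaseError:
        return MatchResult(False)
    if not qm_match(q_code, qm_code, masks):
        return MatchResult(False)
    qm_cost = 0 if q_code == qm_code else 1
    r_dp = decode_bases(dp_code, codec.dp_len)
    q_dp = query[16 + codec.m : K + 2]
    dp_cost = dp_region_cost(q_dp, r_dp)
    if math.isinf(dp_cost):
        return MatchResult(False)
    return MatchResult(True, taxid, int(qm_cost + dp_cost))


def lookup_group(db: KmerDatabase, group_id: int) -> tuple[np.ndarray, np.ndarray]:
    """Entries of one group as parallel (suffixes, taxids) slices, in
    stored order; offsets come from the prefix sums of the group sizes."""
    off = db.offsets
    lo, hi = int(off[group_id]), int(off[group_id + 1])
    return db.suffixes[lo:hi], db.taxids[lo:hi]


def classify_read(
    read: str,
    db: KmerDatabase,
    params: ClassifyParams | None = None,
    read_id: str = "read",
    tree: TaxonomyTree | None = None,
) -> ReadAssignment:
    """Assign one read by max-hit-count over its matched k-mer windows.

    Windows containing ambiguous bases are skipped.  Ties on the hit count
    break to the deepest taxon; a residual tie reports the LCA of the tied
    taxa (smallest taxid without a taxonomy).
    """
    if params is None:
        params = ClassifyParams()
    if len(read) < K:
        raise ShortReadError(f"read {read_id!r} length {len(read)} < k={K}")
    if tree is None:
        tree = db.tree
    codec = db.params.codec
    masks = make_seed_masks(codec.m)
    read = read.upper()

    gids, sufs, valid = scan_kmers(read, codec)
    n_examined = int(valid.sum())
    hit_counts: dict[int, int] = {}
    if n_examined:
        sizes = db.group_size[gids]
        candidates = np.nonzero(valid & (sizes > 0))[0]
        off = db.offsets
        suffixes, taxids = db.suffixes, db.taxids
        for i in candidates:
            gid = int(gids[i])
            q_suffix = int(sufs[i])
            lo, hi = int(off[gid]), int(off[gid + 1])
            query = read[i : i + K + 2]
            for j in range(lo, hi):
                s = int(suffixes[j])
                if s == q_suffix:
                    res = MatchResult(True, int(taxids[j]), 0)
                else:
                    res = match_kmer(query, (s, int(taxids[j])), codec, masks)
                if res.matched:
                    hit_counts[res.taxid] = hit_counts.get(res.taxid, 0) + 1
                    if not params.exhaustive_probe:
                        break

    taxid = _pick_taxid(hit_counts, params.min_hits, tree)
    status = "C" if taxid is not None else "U"
    return ReadAssignment(read_id, status, taxid, hit_counts, n_examined)


def _pick_taxid(hit_counts: dict[int, int], min_hits: int, tree: TaxonomyTree | None) -> int | None:
    if not hit_counts:
        return None
    best = max(hit_counts.values())
    if best < min_hits:
        return None
    tied = sorted(t for t, c in hit_counts.items() if c == best)
    if len(tied) == 1:
        return tied[0]
    if tree is None:
        return tied[0]
    depths = [tree.depth(t) if t in tree else -1 for t in tied]
    dmax = max(depths)
    deepest = [t for t, d in zip(tied, depths) if d == dmax]
    if len(deepest) == 1:
        return deepest[0]
    if all(t in tree for t in deepest):
        return tree.lca_many(deepest)
    return deepest[0]


def classify_records(records, db: KmerDatabase, params: ClassifyParams | None = None):
    """Classify an iterable of (read_id, sequence); yields ReadAssignment.
    Reads shorter than k are reported unclassified with zero windows."""
    if params is None:
        params = ClassifyParams()
    for read_id, seq in records:
        if len(seq) < K:
            yield ReadAssignment(read_id, "U", None, {}, 0)
        else:
            yield classify_read(seq, db, params, read_id=read_id)


def classify_file(path: str, db: KmerDatabase, params: ClassifyParams | None = None):
    """Classify reads from a FASTA/FASTQ file (gzip transparent)."""
    from .seqio import read_sequences

    return classify_records(read_sequences(path), db, params)


def write_assignments(assignments, out_path: str) -> dict[str, int]:
    """Write Kraken-style per-read TSV; returns summary counts."""
    summary = {"classified": 0, "unclassified": 0}
    with open(out_path, "w") as fh:
        fh.write("read_id\tstatus\ttaxid\tmax_hits\tkmers_examined\n")
        for a in assignments:
            taxid = a.taxid if a.taxid is not None else 0
            fh.write(f"{a.read_id}\t{a.status}\t{taxid}\t{a.max_hits}\t{a.total_kmers_examined}\n")
            summary["classified" if a.status == "C" else "unclassified"] += 1
    return summary
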