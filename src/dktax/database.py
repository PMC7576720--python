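"""Discriminative k-mer database construction and serialization.

K-mer collisions are resolved at three levels:

1. *species* — all strains of a species are pooled and each k-mer kept once;
2. *genus* — a k-mer occurring in two or more species of one genus is
   re-assigned to the genus taxid (and is always retained, regardless of
   the subsampling proportion);
3. *whole database* — after merging all genera, any k-mer still carrying
   more than one taxid is deleted outright, leaving only discriminative
   k-mers that characterize a single taxon.

Species-unique k-mers are thinned to roughly X% by keeping window start
positions at a fixed stride (every ``round(100/X)``-th position of each
scanned sequence), which spreads the retained k-mers uniformly over each
genome without any randomness.

The serialized database is a directory holding a text header plus three
little-endian binary arrays: per-group entry counts (``size.bin``,
4 × 4^n bytes), the 16-base suffix codes (``suffix.bin``) and the parallel
taxids (``taxid.bin``).  K-mer identity throughout construction is the
stored (group_id, suffix) projection: when n < 16 the uncompared middle
bases do not distinguish k-mers, which guarantees the serialized database
can never contain a duplicate (group, suffix) pair.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .codec import CodecParams, reverse_complement, scan_kmers
from .errors import EmptyInputError, FormatError
from .taxonomy import TaxonomyTree, load_taxonomy_tsv, write_taxonomy_tsv

MAGIC = "DKTAXDB"
FORMAT_VERSION = 1

KmerKey = tuple[int, int]  # (group_id, suffix_code)


@dataclass(frozen=True)
class BuildParams:
    """Database construction parameters."""

    codec: CodecParams = field(default_factory=CodecParams)
    x_percent: float = 15.0
    include_rc: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.x_percent <= 100:
            raise ValueError(f"X must be in (0, 100], got {self.x_percent}")

    @property
    def stride(self) -> int:
        """Positional stride realizing the X% uniform selection."""
        return max(1, int(round(100.0 / self.x_percent)))


@dataclass
class KmerDatabase:
    """Grouped discriminative-k-mer index.

    ``group_size[g]`` is the number of entries whose PREFIX encodes to
    group g; ``suffixes``/``taxids`` hold the entries of all groups
    concatenated in ascending group order (insertion order within a group).
    """

    params: BuildParams
    group_size: np.ndarray
    suffixes: np.ndarray
    taxids: np.ndarray
    tree: TaxonomyTree | None = None

    _offsets: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def n_kmers(self) -> int:
        return len(self.suffixes)

    @property
    def offsets(self) -> np.ndarray:
        """Prefix sums of group sizes; group g occupies [offsets[g], offsets[g+1])."""
        if self._offsets is None:
            self._offsets = np.concatenate(
                ([0], np.cumsum(self.group_size, dtype=np.uint64))
            )
        return self._offsets

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KmerDatabase):
            return NotImplemented
        return (
            self.params == other.params
            and np.array_equal(self.group_size, other.group_size)
            and np.array_equal(self.suffixes, other.suffixes)
            and np.array_equal(self.taxids, other.taxids)
        )


def collect_species_kmers(
    records: list[tuple[str, str]], params: BuildParams
) -> dict[KmerKey, list[tuple[str, str, int]]]:
    """Pool the k-mers of all strain sequences of one species.

    Returns a mapping from k-mer key to its occurrence list of
    (sequence id, strand, window start on that strand); each k-mer is kept
    once however often it occurs.  Windows with ambiguous bases are
    skipped.  Raises :class:`EmptyInputError` when no valid window exists.
    """
    kmers: dict[KmerKey, list[tuple[str, str, int]]] = {}
    for seq_id, seq in records:
        tracks = [("+", seq)]
        if params.include_rc:
            tracks.append(("-", reverse_complement(seq)))
        for strand, s in tracks:
            gids, sufs, valid = scan_kmers(s, params.codec)
            for pos in np.nonzero(valid)[0]:
                key = (int(gids[pos]), int(sufs[pos]))
                kmers.setdefault(key, []).append((seq_id, strand, int(pos)))
    if not kmers:
        raise EmptyInputError("no valid 32-base window in any input sequence")
    return kmers


def resolve_genus(
    species_kmer_sets: dict[int, dict[KmerKey, list] | set],
    tree: TaxonomyTree,
) -> dict[KmerKey, set[int]]:
    """Assign each k-mer within every genus to a species or genus taxid.

    A k-mer present in >= 2 species of one genus maps to the genus taxid;
    a k-mer unique to one species keeps the species taxid.  Species whose
    lineage lacks a genus rank form their own singleton group.  The result
    maps each k-mer to the *set* of taxids it received across genera (a
    multi-element set marks a cross-genus collision, removed later).
    """
    by_genus: dict[int, list[int]] = {}
    for sp in sorted(species_kmer_sets):
        genus = tree.ancestor_at_rank(sp, "genus")
        by_genus.setdefault(genus if genus is not None else sp, []).append(sp)

    assigned: dict[KmerKey, set[int]] = {}
    for genus in sorted(by_genus):
        species = by_genus[genus]
        counts: dict[KmerKey, int] = {}
        first_sp: dict[KmerKey, int] = {}
        for sp in species:
            for key in species_kmer_sets[sp]:
                counts[key] = counts.get(key, 0) + 1
                if key not in first_sp:
                    first_sp[key] = sp
        for key, cnt in counts.items():
            taxid = genus if cnt >= 2 else first_sp[key]
            assigned.setdefault(key, set()).add(taxid)
    return assigned


def select_kmers(
    assigned: dict[KmerKey, int],
    positions: dict[KmerKey, list[tuple[str, str, int]]],
    tree: TaxonomyTree,
    params: BuildParams,
) -> dict[KmerKey, int]:
    """Thin species-unique k-mers to ~X% by positional stride.

    A k-mer survives when any of its source window starts is a multiple of
    the stride.  Genus-assigned (shared) k-mers are given priority and are
    always retained.
    """
    stride = params.stride
    if stride == 1:
        return dict(assigned)
    kept: dict[KmerKey, int] = {}
    for key, taxid in assigned.items():
        if tree.rank.get(taxid) == "genus":
            kept[key] = taxid
        elif any(pos % stride == 0 for (_, _, pos) in positions[key]):
            kept[key] = taxid
    return kept


def remove_cross_taxa(assigned: dict[KmerKey, set[int]]) -> dict[KmerKey, int]:
    """Delete every k-mer carrying more than one taxid after genus
    resolution; survivors map to exactly one taxon."""
    return {key: next(iter(tids)) for key, tids in assigned.items() if len(tids) == 1}


def build_database(
    genomes: dict[str, str],
    seqtax: dict[str, int],
    tree: TaxonomyTree,
    params: BuildParams | None = None,
) -> KmerDatabase:
    """Run the full construction pipeline.

    ``genomes`` maps sequence ID to sequence; ``seqtax`` maps each sequence
    ID to its species taxid.  Deterministic: species are processed in
    sorted-taxid order and k-mers retain first-insertion order within each
    group.
    """
    if params is None:
        params = BuildParams()

    by_species: dict[int, list[tuple[str, str]]] = {}
    for seq_id in sorted(genomes):
        if seq_id not in seqtax:
            raise FormatError(f"sequence {seq_id!r} missing from seqid->taxid map")
        by_species.setdefault(seqtax[seq_id], []).append((seq_id, genomes[seq_id]))

    species_kmers: dict[int, dict[KmerKey, list]] = {}
    for sp in sorted(by_species):
        try:
            species_kmers[sp] = collect_species_kmers(by_species[sp], params)
        except EmptyInputError:
            species_kmers[sp] = {}

    by_genus: dict[int, list[int]] = {}
    for sp in sorted(species_kmers):
        genus = tree.ancestor_at_rank(sp, "genus")
        by_genus.setdefault(genus if genus is not None else sp, []).append(sp)

    merged: dict[KmerKey, set[int]] = {}
    for genus in sorted(by_genus):
        subset = {sp: species_kmers[sp] for sp in by_genus[genus]}
        resolved = resolve_genus(subset, tree)
        flat = {key: next(iter(tids)) for key, tids in resolved.items()}
        positions: dict[KmerKey, list] = {}
        for sp in by_genus[genus]:
            for key, occ in species_kmers[sp].items():
                positions.setdefault(key, []).extend(occ)
        selected = select_kmers(flat, positions, tree, params)
        for key, taxid in selected.items():
            merged.setdefault(key, set()).add(taxid)

    discriminative = remove_cross_taxa(merged)
    return _assemble(discriminative, tree, params)


def _assemble(
    discriminative: dict[KmerKey, int], tree: TaxonomyTree | None, params: BuildParams
) -> KmerDatabase:
    n_groups = params.codec.n_groups
    group_size = np.zeros(n_groups, dtype=np.uint32)
    if discriminative:
        gids = np.fromiter((k[0] for k in discriminative), dtype=np.int64)
        sufs = np.fromiter((k[1] for k in discriminative), dtype=np.uint32)
        tids = np.fromiter(discriminative.values(), dtype=np.uint32)
        order = np.argsort(gids, kind="stable")  # keep insertion order in group
        gids, sufs, tids = gids[order], sufs[order], tids[order]
        uniq, counts = np.unique(gids, return_counts=True)
        group_size[uniq] = counts
    else:
        sufs = np.empty(0, dtype=np.uint32)
        tids = np.empty(0, dtype=np.uint32)
    return KmerDatabase(params, group_size, sufs, tids, tree=tree)


def write_database(db: KmerDatabase, path: str) -> None:
    """Serialize to a directory: header.json + size/suffix/taxid.bin
    (little-endian uint32) and an embedded taxonomy table."""
    os.makedirs(path, exist_ok=True)
    header = {
        "magic": MAGIC,
        "version": FORMAT_VERSION,
        "k": db.params.codec.k,
        "n": db.params.codec.n,
        "m": db.params.codec.m,
        "base_order": "ACGT",
        "x_percent": db.params.x_percent,
        "include_rc": db.params.include_rc,
        "n_kmers": int(db.n_kmers),
    }
    with open(os.path.join(path, "header.json"), "w") as fh:
        json.dump(header, fh, indent=1, sort_keys=True)
        fh.write("\n")
    db.group_size.astype("<u4").tofile(os.path.join(path, "size.bin"))
    db.suffixes.astype("<u4").tofile(os.path.join(path, "suffix.bin"))
    db.taxids.astype("<u4").tofile(os.path.join(path, "taxid.bin"))
    if db.tree is not None:
        write_taxonomy_tsv(db.tree, os.path.join(path, "taxonomy.tsv"))


def read_database(path: str) -> KmerDatabase:
    """Load and validate a serialized database directory."""
    try:
        with open(os.path.join(path, "header.json")) as fh:
            header = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot read database header under {path}: {exc}") from exc
    if header.get("magic") != MAGIC:
        raise FormatError(f"bad magic {header.get('magic')!r}, expected {MAGIC!r}")
    if header.get("version") != FORMAT_VERSION:
        raise FormatError(f"unsupported format version {header.get('version')!r}")
    if header.get("base_order", "ACGT") != "ACGT":
        raise FormatError("database built with a different base order")

    params = BuildParams(
        codec=CodecParams(n=header["n"], m=header["m"]),
        x_percent=header["x_percent"],
        include_rc=header.get("include_rc", True),
    )
    group_size = np.fromfile(os.path.join(path, "size.bin"), dtype="<u4")
    if len(group_size) != params.codec.n_groups:
        raise FormatError(
            f"size.bin holds {len(group_size)} groups, header implies "
            f"{params.codec.n_groups} (n={params.codec.n})"
        )
    suffixes = np.fromfile(os.path.join(path, "suffix.bin"), dtype="<u4")
    taxids = np.fromfile(os.path.join(path, "taxid.bin"), dtype="<u4")
    total = int(group_size.sum(dtype=np.uint64))
    if not (total == len(suffixes) == len(taxids) == header["n_kmers"]):
        raise FormatError(
            f"entry count mismatch: sizes sum to {total}, suffix.bin has "
            f"{len(suffixes)}, taxid.bin has {len(taxids)}, header says "
            f"{header['n_kmers']}"
        )
    tree = None
    taxpath = os.path.join(path, "taxonomy.tsv")
    if os.path.exists(taxpath):
        tree = load_taxonomy_tsv(taxpath)
    return KmerDatabase(params, group_size, suffixes, taxids, tree=tree)
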