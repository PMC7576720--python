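"""Synthetic communities and error-injected long reads.

The generator emulates the simulation protocol used to exercise the
classifier: fixed-length source spans drawn uniformly from reference
genomes, with per-base errors injected at a uniform total rate split among
substitutions, insertions and deletions.  It also provides the closed-form
binomial expectation for the number of error-free k-mers a read retains,
the quantity that motivates approximate (rather than exact) k-mer
matching for long-read data: at 15% per-base error a 1000-base read keeps
only ~73 exact 16-mers.

Genomes are i.i.d.-uniform over {A,C,G,T}; within a genus every species
genome carries a planted copy of a shared genus segment so that
genus-level k-mer collisions (and clade-exclusion classification of
held-out species) actually occur.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .codec import BASE_ORDER
from .taxonomy import TaxonomyTree

_BASES = np.frombuffer(BASE_ORDER.encode(), dtype=np.uint8)


@dataclass(frozen=True)
class ErrorModel:
    """Uniform per-base error model.

    ``rate`` is the total per-base error probability; ``mix`` the
    (substitution, insertion, deletion) proportions, summing to 1.
    Substitutions always change the base; insertions add a uniform random
    base after the current position; deletions drop the current base.
    """

    rate: float = 0.15
    mix: tuple[float, float, float] = (0.5, 0.25, 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.rate < 1:
            raise ValueError(f"error rate must be in [0, 1), got {self.rate}")
        if len(self.mix) != 3 or any(p < 0 for p in self.mix):
            raise ValueError(f"mix must be 3 non-negative proportions, got {self.mix}")
        if abs(sum(self.mix) - 1.0) > 1e-9:
            raise ValueError(f"mix must sum to 1, got {self.mix}")


@dataclass
class SimulatedRead:
    read_id: str
    sequence: str
    taxid: int
    genome_id: str
    start: int  # 0-based, forward strand
    end: int  # half-open; end - start == nominal length
    n_sub: int
    n_ins: int
    n_del: int


def _seq_to_arr(seq: str) -> np.ndarray:
    lut = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(BASE_ORDER):
        lut[ord(b)] = i
        lut[ord(b.lower())] = i
    arr = lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        raise ValueError("genome contains non-ACGT characters")
    return arr


def _arr_to_seq(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode("ascii")


def random_genome(length: int, rng: np.random.Generator) -> str:
    return _arr_to_seq(rng.integers(0, 4, length, dtype=np.uint8))


def inject_errors(
    span: np.ndarray, model: ErrorModel, rng: np.random.Generator
) -> tuple[np.ndarray, int, int, int]:
    """Apply the error model to one source span (codes 0-3); returns the
    read codes and the (sub, ins, del) counts."""
    L = len(span)
    err = rng.random(L) < model.rate
    out = span.copy()
    n_sub = n_ins = n_del = 0
    if err.any():
        idx = np.nonzero(err)[0]
        # inverse-CDF draw over the (sub, ins, del) mix
        cuts = np.cumsum(model.mix)
        kinds = np.searchsorted(cuts, rng.random(len(idx)), side="right")
        kinds = np.minimum(kinds, 2)
        sub_idx = idx[kinds == 0]
        ins_idx = idx[kinds == 1]
        del_idx = idx[kinds == 2]
        n_sub, n_ins, n_del = len(sub_idx), len(ins_idx), len(del_idx)
        if n_sub:
            out[sub_idx] = (span[sub_idx] + rng.integers(1, 4, n_sub)) % 4
        if n_ins or n_del:
            reps = np.ones(L, dtype=np.int64)
            reps[del_idx] = 0
            reps[ins_idx] = 2
            pick = np.repeat(np.arange(L), reps)
            out = out[pick]
            dup = np.zeros(len(pick), dtype=bool)
            dup[1:] = pick[1:] == pick[:-1]
            out[dup] = rng.integers(0, 4, int(dup.sum()), dtype=np.uint8)
    return out, n_sub, n_ins, n_del


def simulate_reads(
    genome: str,
    n_reads: int,
    read_length: int,
    error_model: ErrorModel,
    rng: np.random.Generator | None = None,
    taxid: int = 0,
    genome_id: str = "genome",
    sample_strands: bool = False,
) -> list[SimulatedRead]:
    """Draw reads of nominal ``read_length`` uniformly from ``genome`` and
    inject errors.  The nominal length is the drawn source span; the read
    itself drifts by the net indel count.  Reproducible given the model's
    seed (pass ``rng`` to share one stream across genomes)."""
    if len(genome) < read_length:
        raise ValueError(
            f"genome length {len(genome)} shorter than read length {read_length}"
        )
    if rng is None:
        rng = np.random.default_rng(error_model.seed)
    arr = _seq_to_arr(genome)
    reads: list[SimulatedRead] = []
    starts = rng.integers(0, len(genome) - read_length + 1, n_reads)
    for i in range(n_reads):
        start = int(starts[i])
        span = arr[start : start + read_length]
        if sample_strands and rng.random() < 0.5:
            span = (3 - span)[::-1]  # reverse complement in code space
        out, n_sub, n_ins, n_del = inject_errors(span, error_model, rng)
        reads.append(
            SimulatedRead(
                read_id=f"{genome_id}_r{i}",
                sequence=_arr_to_seq(out),
                taxid=taxid,
                genome_id=genome_id,
                start=start,
                end=start + read_length,
                n_sub=n_sub,
                n_ins=n_ins,
                n_del=n_del,
            )
        )
    return reads


def expected_exact_kmer_matches(read_length: int, kmer: int, error_rate: float) -> int:
    """Expected count of error-free k-mers in a read, rounded:
    round((L − k + 1) · (1 − e)^k)."""
    if kmer <= 0 or read_length < kmer:
        raise ValueError(f"need read_length >= kmer >= 1, got {read_length}, {kmer}")
    if not 0 <= error_rate < 1:
        raise ValueError(f"error rate must be in [0, 1), got {error_rate}")
    return round((read_length - kmer + 1) * (1.0 - error_rate) ** kmer)


def simulate_taxonomy_and_genomes(
    n_genera: int,
    species_per_genus: int,
    genome_length: int,
    shared_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[TaxonomyTree, dict[str, str], dict[str, int]]:
    """Build a synthetic taxonomy with matching genomes.

    Taxid scheme: root 1 ("no rank"); families 10, 11, ... (two genera per
    family); genera 100 + g; species 1000 + 10·g + s.  Each species genome
    is uniform random with a contiguous region of ``shared_fraction`` of
    its length overwritten by a genus-common segment.

    Returns (tree, genomes keyed by sequence id, seqid -> species taxid).
    """
    if not 0 <= shared_fraction < 1:
        raise ValueError(f"shared_fraction must be in [0, 1), got {shared_fraction}")
    if n_genera <= 0 or species_per_genus <= 0 or genome_length <= 0:
        raise ValueError("sizes must be positive")
    shared_len = int(round(shared_fraction * genome_length))
    if 0 < shared_len < 32:
        raise ValueError("shared segment shorter than one k-mer; raise shared_fraction")

    rng = np.random.default_rng(seed)
    parent = {1: 1}
    rank = {1: "no rank"}
    name = {1: "root"}
    genomes: dict[str, str] = {}
    seqtax: dict[str, int] = {}

    for g in range(n_genera):
        family = 10 + g // 2
        if family not in parent:
            parent[family] = 1
            rank[family] = "family"
            name[family] = f"Family_{g // 2}"
        genus = 100 + g
        parent[genus] = family
        rank[genus] = "genus"
        name[genus] = f"Genus_{g}"
        shared = rng.integers(0, 4, shared_len, dtype=np.uint8)
        for s in range(species_per_genus):
            sp = 1000 + 10 * g + s
            parent[sp] = genus
            rank[sp] = "species"
            name[sp] = f"Genus_{g} species_{s}"
            arr = rng.integers(0, 4, genome_length, dtype=np.uint8)
            if shared_len:
                at = int(rng.integers(0, genome_length - shared_len + 1))
                arr[at : at + shared_len] = shared
            seq_id = f"g{g}s{s}"
            genomes[seq_id] = _arr_to_seq(arr)
            seqtax[seq_id] = sp

    tree = TaxonomyTree(parent=parent, rank=rank, name=name, root=1)
    tree.validate()
    return tree, genomes, seqtax
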