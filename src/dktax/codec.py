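"""Bit-level encoding of 32-base DNA k-mers.

A k-mer of k = 32 bases is split into a PREFIX (the first ``n`` bases,
n <= 16) and a SUFFIX (the last 16 bases).  The PREFIX, packed 2 bits per
base, is the *group ID* used to bucket k-mers in the database; the SUFFIX is
the stored payload.  The SUFFIX is further split into a QM ("quick
mapping") field of ``m`` bases, compared with a tolerance of one
substitution via seed masks, and a DP ("dynamic programming") field of
16 − m bases, compared with a banded edit-distance allowing two further
errors including indels.

When n < 16 the middle 32 − n − 16 bases of the k-mer are neither stored
nor compared; mismatches there are invisible to the matcher.

Base order is fixed as A=0, C=1, G=2, T=3 (most significant bits leftmost)
so that serialized databases are portable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AmbiguousBaseError

K = 32
SUFFIX_LEN = 16
BASE_ORDER = "ACGT"

_BASE_CODE = {b: i for i, b in enumerate(BASE_ORDER)}
_BASE_CODE.update({b.lower(): i for i, b in enumerate(BASE_ORDER)})

# byte -> 2-bit code lookup; 255 flags anything outside {acgtACGT}
_CODE_LUT = np.full(256, 255, dtype=np.uint8)
for _b, _c in _BASE_CODE.items():
    _CODE_LUT[ord(_b)] = _c

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CodecParams:
    """Field widths of the k-mer layout.

    k is fixed at 32; ``n`` is the PREFIX length in bases (group key) and
    ``m`` the QM length in bases.  The SUFFIX is always the last 16 bases.
    """

    n: int = 14
    m: int = 6
    k: int = field(default=K, init=False)

    def __post_init__(self) -> None:
        if not 1 <= self.n <= 16:
            raise ValueError(f"PREFIX length n must be in [1, 16], got {self.n}")
        if not 1 <= self.m <= 16:
            raise ValueError(f"QM length m must be in [1, 16], got {self.m}")

    @property
    def dp_len(self) -> int:
        """DP field length in bases (16 − m)."""
        return SUFFIX_LEN - self.m

    @property
    def n_groups(self) -> int:
        return 4**self.n


def encode_bases(seq: str) -> int:
    """Pack a DNA string into an integer, 2 bits/base, leftmost base most
    significant.  Raises :class:`AmbiguousBaseError` on non-ACGT characters
    (IUPAC ambiguity codes included)."""
    code = 0
    for ch in seq:
        try:
            code = (code << 2) | _BASE_CODE[ch]
        except KeyError:
            raise AmbiguousBaseError(f"ambiguous base {ch!r} in {seq!r}") from None
    return code


def decode_bases(code: int, length: int) -> str:
    out = []
    for shift in range(2 * (length - 1), -2, -2):
        out.append(BASE_ORDER[(code >> shift) & 3])
    return "".join(out)


@dataclass(frozen=True)
class EncodedKmer:
    """A 32-mer reduced to its stored fields.

    ``group_id`` packs the first n bases, ``suffix_code`` the last 16.
    ``qm_code``/``dp_code`` are bit-slices of ``suffix_code`` that
    concatenate back to it.
    """

    group_id: int
    suffix_code: int
    params: CodecParams

    def __post_init__(self) -> None:
        assert 0 <= self.group_id < self.params.n_groups
        assert 0 <= self.suffix_code < 4**SUFFIX_LEN

    @property
    def qm_code(self) -> int:
        return self.suffix_code >> (2 * self.params.dp_len)

    @property
    def dp_code(self) -> int:
        return self.suffix_code & ((1 << (2 * self.params.dp_len)) - 1)


def encode_kmer(seq: str, params: CodecParams) -> EncodedKmer:
    """Encode a 32-base window into its (group_id, suffix_code) form.

    The middle 32 − n − 16 bases are validated (an N anywhere in the window
    rejects it) but not encoded.
    """
    if len(seq) != K:
        raise ValueError(f"k-mer must be exactly {K} bases, got {len(seq)}")
    # full validation pass, including the uncompared middle region
    for ch in seq:
        if ch not in _BASE_CODE:
            raise AmbiguousBaseError(f"ambiguous base {ch!r} in window")
    group_id = encode_bases(seq[: params.n])
    suffix_code = encode_bases(seq[K - SUFFIX_LEN:])
    return EncodedKmer(group_id, suffix_code, params)


def split_suffix(suffix_code: int, params: CodecParams) -> tuple[int, int]:
    """Split a suffix code into (qm_code, dp_code)."""
    dp_bits = 2 * params.dp_len
    return suffix_code >> dp_bits, suffix_code & ((1 << dp_bits) - 1)


@dataclass(frozen=True)
class SeedMaskSet:
    """m bit-masks over the QM field, mask i wildcarding base i.

    Two QM codes that differ at a single base compare equal under exactly
    the mask wildcarding that base, so scanning the mask list implements a
    Hamming-distance-<=1 test without decoding.
    """

    m: int
    masks: tuple[int, ...]


def make_seed_masks(m: int) -> SeedMaskSet:
    """Build the seed-mask set for a QM field of ``m`` bases."""
    if not 1 <= m <= 16:
        raise ValueError(f"QM length m must be in [1, 16], got {m}")
    full = (1 << (2 * m)) - 1
    masks = tuple(full ^ (0b11 << (2 * (m - 1 - i))) for i in range(m))
    return SeedMaskSet(m, masks)


def qm_match(a: int, b: int, masks: SeedMaskSet) -> bool:
    """True iff the two QM codes differ at no more than one base."""
    if a == b:
        return True
    for mask in masks.masks:
        if (a & mask) == (b & mask):
            return True
    return False


def scan_kmers(seq: str, params: CodecParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Encode every 32-base window of ``seq`` in one vectorized pass.

    Returns ``(group_ids, suffix_codes, valid)`` arrays of length
    ``len(seq) − 31`` (empty for shorter input).  ``valid[i]`` is False when
    window i contains a non-ACGT character; its codes are then meaningless
    (but in range).
    """
    codes = _CODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n_win = len(codes) - K + 1
    if n_win <= 0:
        empty = np.empty(0, dtype=np.uint64)
        return empty, empty.copy(), np.empty(0, dtype=bool)
    bad = codes == 255
    # window is valid iff it contains no flagged byte
    bad_cum = np.concatenate(([0], np.cumsum(bad)))
    valid = (bad_cum[K:] - bad_cum[:-K]) == 0
    safe = np.where(bad, 0, codes).astype(np.uint64)
    win = np.lib.stride_tricks.sliding_window_view(safe, K)
    pw_n = (4 ** np.arange(params.n - 1, -1, -1)).astype(np.uint64)
    pw_s = (4 ** np.arange(SUFFIX_LEN - 1, -1, -1)).astype(np.uint64)
    group_ids = win[:, : params.n] @ pw_n
    suffix_codes = win[:, K - SUFFIX_LEN:] @ pw_s
    return group_ids, suffix_codes, valid
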