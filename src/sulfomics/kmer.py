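"""Windowed tetranucleotide-frequency profiles and GC content.

Contigs are cut into fixed-size windows (default 5 kb, with a 2.5 kb floor
below which a contig is excluded entirely) and each window is summarised as
a relative-frequency vector over the 4-mer alphabet, optionally collapsed
over reverse complements (136 canonical features instead of 256).  These
profiles are the feature space in which compositional genome binning
operates: different genomes carry distinct tetranucleotide signatures, so
windows from the same genome cluster together.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

__all__ = [
    "TetraProfile",
    "count_kmers",
    "gc_content",
    "windows",
    "profile_matrix",
    "canonical_kmers",
]

_BASES = "ACGT"
# byte -> 2-bit code; anything outside ACGT (upper or lower) maps to -1
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class TetraProfile:
    """Metadata for one profile-matrix row (the k-mer window)."""

    window_id: str
    contig_id: str
    offset: int  # 0-based start of the window within its contig
    length: int
    gc: float


def _encode(sequence: str) -> np.ndarray:
    return _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def revcomp(sequence: str) -> str:
    """Reverse complement of a DNA string (ACGTN alphabet)."""
    return sequence.translate(_COMPLEMENT)[::-1]


@lru_cache(maxsize=None)
def _canonical_map(k: int) -> np.ndarray:
    """For every k-mer integer code, the code of min(kmer, revcomp(kmer))."""
    n = 4**k
    codes = np.arange(n)
    rc = np.zeros(n, dtype=np.int64)
    tmp = codes.copy()
    for _ in range(k):
        rc = rc * 4 + (3 - (tmp % 4))  # complement of the last base, reversed
        tmp //= 4
    return np.minimum(codes, rc)


@lru_cache(maxsize=None)
def canonical_kmers(k: int = 4) -> tuple[str, ...]:
    """Sorted canonical k-mers (each reverse-complement pair represented once)."""
    canon = np.unique(_canonical_map(k))
    return tuple(_decode_kmer(int(c), k) for c in canon)


def _decode_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_BASES[code % 4])
        code //= 4
    return "".join(reversed(out))


def _kmer_code_counts(sequence: str, k: int, collapse_rc: bool) -> np.ndarray:
    """Counts indexed by k-mer code; windows touching non-ACGT bases skipped."""
    arr = _encode(sequence)
    n = len(arr) - k + 1
    counts = np.zeros(4**k, dtype=np.int64)
    if n <= 0:
        return counts
    valid = arr >= 0
    codes = np.zeros(n, dtype=np.int64)
    ok = np.ones(n, dtype=bool)
    for i in range(k):
        codes = codes * 4 + np.where(valid[i : i + n], arr[i : i + n], 0)
        ok &= valid[i : i + n]
    codes = codes[ok]
    if collapse_rc:
        codes = _canonical_map(k)[codes]
    np.add.at(counts, codes, 1)
    return counts


def count_kmers(sequence: str, k: int = 4, collapse_rc: bool = False) -> dict[str, int]:
    """Count overlapping k-mers in ``sequence``.

    Any k-window containing a non-ACGT base is skipped (no imputation).
    With ``collapse_rc`` each k-mer and its reverse complement share one
    canonical key, the lexicographically smaller of the two.
    ``k`` longer than the sequence yields an empty map.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    counts = _kmer_code_counts(sequence, k, collapse_rc)
    nz = np.nonzero(counts)[0]
    return {_decode_kmer(int(c), k): int(counts[c]) for c in nz}


def gc_content(sequence: str) -> float:
    """(G+C)/(A+C+G+T); N and other ambiguity codes are excluded entirely.

    A sequence with no unambiguous base has undefined GC and returns NaN
    (never 0, which would masquerade as a real measurement).
    """
    arr = _encode(sequence)
    counted = int((arr >= 0).sum())
    if counted == 0:
        return math.nan
    gc = int(((arr == 1) | (arr == 2)).sum())
    return gc / counted


def windows(length: int, window: int = 5000, min_length: int = 2500) -> list[tuple[int, int]]:
    """Cut a contig of ``length`` bp into (offset, length) windows.

    Contigs shorter than ``min_length`` produce no windows.  Otherwise the
    contig is tiled with consecutive ``window``-bp pieces; a terminal
    remainder of at least ``min_length`` stands as its own window, while a
    shorter remainder is merged into the preceding window.
    """
    if window < min_length:
        raise ValueError("window must be >= min_length")
    if length < min_length:
        return []
    n_full, rem = divmod(length, window)
    if n_full == 0:
        return [(0, length)]
    spans = [window] * n_full
    if rem >= min_length:
        spans.append(rem)
    elif rem > 0:
        spans[-1] += rem
    out = []
    pos = 0
    for s in spans:
        out.append((pos, s))
        pos += s
    return out


def profile_matrix(
    contigs,
    k: int = 4,
    window: int = 5000,
    min_length: int = 2500,
    collapse_rc: bool = True,
    standardize: bool = False,
):
    """Tetranucleotide relative-frequency matrix over all eligible windows.

    Parameters
    ----------
    contigs
        Iterable of objects with ``contig_id`` and ``sequence`` attributes,
        or ``(contig_id, sequence)`` pairs.
    standardize
        If set, columns are z-scored after normalisation (zero-variance
        columns are left at zero).  Off by default: the binning feature is
        the plain relative frequency.

    Returns
    -------
    matrix : ndarray, shape (n_windows, n_features)
        Rows sum to 1 (before any standardisation); row order is contig
        input order, then window offset.
    meta : pandas.DataFrame
        One row of :class:`TetraProfile` fields per matrix row.
    """
    feat_dim = len(canonical_kmers(k)) if collapse_rc else 4**k
    canon_index = None
    if collapse_rc:
        canon_codes = np.unique(_canonical_map(k))
        canon_index = np.full(4**k, -1, dtype=np.int64)
        canon_index[canon_codes] = np.arange(len(canon_codes))

    rows: list[np.ndarray] = []
    meta: list[TetraProfile] = []
    for item in contigs:
        if hasattr(item, "contig_id"):
            cid, seq = item.contig_id, item.sequence
        else:
            cid, seq = item
        for offset, span in windows(len(seq), window=window, min_length=min_length):
            sub = seq[offset : offset + span]
            counts = _kmer_code_counts(sub, k, collapse_rc)
            if collapse_rc:
                full = np.zeros(feat_dim, dtype=np.float64)
                nz = np.nonzero(counts)[0]
                full[canon_index[nz]] = counts[nz]
                counts = full
            else:
                counts = counts.astype(np.float64)
            total = counts.sum()
            if total == 0:  # window of Ns only: no valid 4-mer, uninformative
                continue
            rows.append(counts / total)
            meta.append(
                TetraProfile(
                    window_id=f"{cid}:{offset}-{offset + span}",
                    contig_id=cid,
                    offset=offset,
                    length=span,
                    gc=gc_content(sub),
                )
            )
    if not rows:
        raise ValueError("no window passed the length filter; nothing to profile")
    matrix = np.vstack(rows)
    if standardize:
        mu = matrix.mean(axis=0)
        sd = matrix.std(axis=0)
        sd[sd == 0] = 1.0
        matrix = (matrix - mu) / sd
    meta_df = pd.DataFrame([m.__dict__ for m in meta])
    return matrix, meta_df


def feature_names(k: int = 4, collapse_rc: bool = True) -> list[str]:
    """Column headers matching :func:`profile_matrix` output."""
    if collapse_rc:
        return list(canonical_kmers(k))
    return [_decode_kmer(c, k) for c in range(4**k)]
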