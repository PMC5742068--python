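"""Low-level nucleotide utilities shared across modules.

Sequences are plain Python strings over the alphabet {A, C, G, T, N};
numeric work uses uint8 code arrays where A=0, C=1, G=2, T=3 and any
other symbol (N, masked base) is INVALID and never matches anything.
"""
from __future__ import annotations

import numpy as np

INVALID = 4

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_CODE_LUT = np.full(256, INVALID, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE_LUT[ord(_b)] = _i
    _CODE_LUT[ord(_b.lower())] = _i  # lowercase treated as unmasked here


def revcomp(seq: str) -> str:
    """Reverse complement; N maps to N."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str, mask: np.ndarray | None = None) -> np.ndarray:
    """Encode a sequence to uint8 codes; masked positions become INVALID.

    ``mask`` is a boolean array (True = excluded from anchoring).
    """
    codes = _CODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].copy()
    if mask is not None:
        codes[np.asarray(mask, dtype=bool)] = INVALID
    return codes


def check_alphabet(seq: str, name: str = "sequence") -> None:
    """Reject sequences with characters outside {A,C,G,T,N} (case-insensitive)."""
    allowed = set("ACGTNacgtn")
    bad = set(seq) - allowed
    if bad:
        raise ValueError(f"{name} contains non-ACGTN characters: {sorted(bad)[:5]}")


def random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    """Random nucleotide string with expected GC fraction ``gc``."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p)
    return "".join("ACGT"[c] for c in codes)


def kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Packed 2-bit k-mer value at every start position, plus validity.

    Returns ``(values, valid)`` of length ``len(codes) - k + 1``. ``k`` must
    be <= 31 so values fit an int64 exactly (no hashing collisions).
    """
    if k > 31:
        raise ValueError("k must be <= 31")
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    powers = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    # invalid codes (value 4) would collide; compute validity first and zero them
    invalid = codes >= INVALID
    bad = np.convolve(invalid.astype(np.int32), np.ones(k, dtype=np.int32), mode="valid") > 0
    safe = np.where(invalid, 0, codes).astype(np.int64)
    vals = np.lib.stride_tricks.sliding_window_view(safe, k) @ powers
    return vals, ~bad
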