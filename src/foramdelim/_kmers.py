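"""k-mer count profiles used as a cheap similarity prescreen."""

from __future__ import annotations

import numpy as np

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT string as uint8 codes (non-ACGT -> 255)."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.full(arr.shape, 255, dtype=np.uint8)
    for base, code in _CODE.items():
        out[arr == ord(base)] = code
    return out


def kmer_profile(seq: str, k: int = 4) -> np.ndarray:
    """Count vector over the 4**k canonical k-mers (k-mers with non-ACGT skipped)."""
    codes = encode(seq)
    n = len(codes) - k + 1
    if n <= 0:
        return np.zeros(4**k, dtype=np.int32)
    idx = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        c = codes[j : j + n]
        valid &= c != 255
        idx = idx * 4 + np.where(c == 255, 0, c)
    return np.bincount(idx[valid], minlength=4**k).astype(np.int32)


def profile_matrix(seqs: list[str], k: int = 4) -> np.ndarray:
    return np.stack([kmer_profile(s, k) for s in seqs]) if seqs else np.zeros((0, 4**k), dtype=np.int32)


def shared_kmers(profiles: np.ndarray, query: np.ndarray) -> np.ndarray:
    """Number of k-mers shared between each profile row and the query."""
    return np.minimum(profiles, query[None, :]).sum(axis=1)
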