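"""k-mer frequency and enrichment scoring for splicing-motif analysis.

Counts overlapping k-mers (single strand, the transcribed strand of an
RNA-side motif analysis) in an experimental and a control sequence set and
scores each k-mer by the log2 ratio of its pseudocounted, position-
normalized frequencies:

    score = log2( (c_exp + p) / (N_exp + p * 4^k)
                / ((c_ctrl + p) / (N_ctrl + p * 4^k)) )

with ``N`` the total number of counted windows in the set and ``p`` the
pseudocount (default 1). Hexamers are the standard choice; k from 5 to 8
gives concordant rankings on planted-motif data.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = ["KmerCounts", "count_kmers", "enrichment_table", "read_fasta"]

_VALID = frozenset("ACGT")


@dataclass
class KmerCounts:
    """Overlapping window counts for one sequence set."""

    k: int
    counts: Counter
    total_windows: int  # = sum over counted windows (conserves sum(len - k + 1))
    n_windows_skipped: int  # windows containing non-ACGT characters
    n_sequences: int


def _norm_seqs(sequences: Iterable) -> list[str]:
    out = []
    for s in sequences:
        if isinstance(s, tuple):
            s = s[1]
        out.append(str(s).upper())
    return out


def count_kmers(sequences: Iterable, k: int) -> KmerCounts:
    """Count overlapping k-mers on the given strand.

    ``sequences`` may be plain strings or ``(id, sequence)`` pairs (as
    returned by :func:`read_fasta`). Windows containing ambiguity codes are
    skipped and tallied. If every sequence is shorter than ``k`` the result
    is empty (total 0).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    seqs = _norm_seqs(sequences)
    counts: Counter = Counter()
    skipped = 0
    for s in seqs:
        for i in range(len(s) - k + 1):
            w = s[i : i + k]
            if set(w) <= _VALID:
                counts[w] += 1
            else:
                skipped += 1
    return KmerCounts(
        k=k,
        counts=counts,
        total_windows=sum(counts.values()),
        n_windows_skipped=skipped,
        n_sequences=len(seqs),
    )


def enrichment_table(exp: KmerCounts, ctrl: KmerCounts, pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-k-mer enrichment scores, sorted by score (descending).

    Antisymmetric under swapping the experimental and control sets; scores
    are finite for any input when ``pseudocount > 0``.
    """
    if exp.k != ctrl.k:
        raise ValueError("experimental and control counts use different k")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    import numpy as np

    k = exp.k
    kmers = sorted(set(exp.counts) | set(ctrl.counts))
    c_exp = np.array([exp.counts.get(m, 0) for m in kmers], dtype=float)
    c_ctrl = np.array([ctrl.counts.get(m, 0) for m in kmers], dtype=float)
    denom = pseudocount * 4.0**k
    f_exp = (c_exp + pseudocount) / (exp.total_windows + denom)
    f_ctrl = (c_ctrl + pseudocount) / (ctrl.total_windows + denom)
    df = pd.DataFrame(
        {
            "kmer": kmers,
            "c_exp": c_exp.astype(int),
            "c_ctrl": c_ctrl.astype(int),
            "f_exp": f_exp,
            "f_ctrl": f_ctrl,
            "score": np.log2(f_exp / f_ctrl),
        }
    )
    df = df.sort_values(["score", "kmer"], ascending=[False, True]).reset_index(drop=True)
    df.attrs["k"] = k
    df.attrs["pseudocount"] = pseudocount
    df.attrs["score_definition"] = "log2 pseudocounted position-normalized frequency ratio"
    return df


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``(id, sequence)`` pairs."""
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def reverse_complement(seq: str) -> str:
    comp = str.maketrans("ACGTacgt", "TGCAtgca")
    return seq.translate(comp)[::-1]
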