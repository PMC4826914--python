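"""Sense-codon alphabet, genetic-code bookkeeping, and codon frequency models.

The substitution machinery works on the 61 sense codons of the standard
genetic code (stop codons are excluded from the state space, following the
usual convention for codon substitution models).  Codons are indexed in
lexicographic ACGT order; all downstream arrays (rate matrices, partial
likelihoods, simulated states) use this indexing.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

NUCLEOTIDES = "ACGT"
_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")

STOP_CODONS: frozenset[str] = frozenset(standard_dna_table.stop_codons)

#: The 61 sense codons in lexicographic ACGT order.
CODONS: tuple[str, ...] = tuple(
    c
    for c in ("".join(t) for t in itertools.product(NUCLEOTIDES, repeat=3))
    if c not in STOP_CODONS
)

CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}
N_CODONS = len(CODONS)  # 61

#: Amino acid encoded by each sense codon (one-letter code), aligned with CODONS.
CODON_AA: tuple[str, ...] = tuple(standard_dna_table.forward_table[c] for c in CODONS)


def _is_transition(a: str, b: str) -> bool:
    pair = {a, b}
    return pair <= _PURINES or pair <= _PYRIMIDINES


def _build_structure() -> dict[str, np.ndarray]:
    """0/1 indicator matrices for the four single-nucleotide change classes."""
    syn_ts = np.zeros((N_CODONS, N_CODONS))
    syn_tv = np.zeros((N_CODONS, N_CODONS))
    non_ts = np.zeros((N_CODONS, N_CODONS))
    non_tv = np.zeros((N_CODONS, N_CODONS))
    for i, ci in enumerate(CODONS):
        for j, cj in enumerate(CODONS):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue  # multi-nucleotide changes have rate 0
            a, b = diffs[0]
            ts = _is_transition(a, b)
            syn = CODON_AA[i] == CODON_AA[j]
            if syn and ts:
                syn_ts[i, j] = 1
            elif syn:
                syn_tv[i, j] = 1
            elif ts:
                non_ts[i, j] = 1
            else:
                non_tv[i, j] = 1
    return {"syn_ts": syn_ts, "syn_tv": syn_tv, "non_ts": non_ts, "non_tv": non_tv}


_STRUCT = _build_structure()
SYN_TS = _STRUCT["syn_ts"]
SYN_TV = _STRUCT["syn_tv"]
NON_TS = _STRUCT["non_ts"]
NON_TV = _STRUCT["non_tv"]


def equal_frequencies() -> np.ndarray:
    """Uniform codon frequencies over the 61 sense codons."""
    return np.full(N_CODONS, 1.0 / N_CODONS)


def f3x4_frequencies(sequences, pseudocount: float = 0.0) -> np.ndarray:
    """Empirical F3x4 codon frequencies.

    Nucleotide frequencies are tabulated separately at each codon position
    over all supplied coding sequences (gap codons '---' are skipped), the
    codon frequency is the product over the three positions, stop codons are
    removed, and the result is renormalized over the sense codons.
    """
    counts = np.full((3, 4), pseudocount, dtype=float)
    nt_idx = {n: i for i, n in enumerate(NUCLEOTIDES)}
    for seq in sequences:
        s = str(seq).upper()
        if len(s) % 3:
            raise ValueError("coding sequence length not divisible by 3")
        for k in range(0, len(s), 3):
            codon = s[k : k + 3]
            if codon == "---":
                continue
            for pos, nt in enumerate(codon):
                if nt in nt_idx:
                    counts[pos, nt_idx[nt]] += 1
    if counts.sum() == 0:
        return equal_frequencies()
    freqs = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array(
        [freqs[0, nt_idx[c[0]]] * freqs[1, nt_idx[c[1]]] * freqs[2, nt_idx[c[2]]] for c in CODONS]
    )
    # Zero frequencies (a nucleotide absent at one position) would make
    # observed codons impossible; floor and renormalize instead.
    pi = np.maximum(pi, 1e-8)
    return pi / pi.sum()


def encode_codon_rows(rows) -> np.ndarray:
    """Encode nucleotide rows as codon-state indices.

    Returns an (n_rows, n_codon_columns) int array; any codon that is not
    one of the 61 sense codons (gap codon '---', ambiguity, partial gap) is
    encoded as -1 and treated as missing data by the likelihood machinery.
    """
    rows = [str(r).upper() for r in rows]
    length = len(rows[0])
    if any(len(r) != length for r in rows):
        raise ValueError("codon alignment rows differ in length")
    if length % 3:
        raise ValueError("codon alignment length not divisible by 3")
    out = np.full((len(rows), length // 3), -1, dtype=np.int64)
    for i, row in enumerate(rows):
        for j in range(length // 3):
            out[i, j] = CODON_INDEX.get(row[3 * j : 3 * j + 3], -1)
    return out


def translate_cds(cds: str) -> str:
    """Translate an ungapped CDS with the standard code (no stop allowed inside)."""
    return str(Seq(cds).translate(table="Standard"))
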