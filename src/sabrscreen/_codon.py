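"""Codon tables and usage-weighted back-translation.

Back-translation draws codons for each residue from the standard genetic code,
weighted by Mus musculus codon-usage fractions, so synthesized inserts resemble
ordinary mouse coding sequence. Draws are deterministic given a seed, and codons
overlapping a forbidden restriction motif (on either strand) are resampled.
"""

from __future__ import annotations

import numpy as np
from Bio.Seq import Seq

# Mouse codon usage fractions per amino acid (relative synonymous usage).
# Normalized per residue at import time.
MOUSE_CODON_USAGE: dict[str, dict[str, float]] = {
    "A": {"GCC": 0.38, "GCT": 0.29, "GCA": 0.23, "GCG": 0.10},
    "R": {"AGG": 0.22, "AGA": 0.21, "CGG": 0.19, "CGC": 0.18, "CGA": 0.12, "CGT": 0.08},
    "N": {"AAC": 0.57, "AAT": 0.43},
    "D": {"GAC": 0.56, "GAT": 0.44},
    "C": {"TGC": 0.52, "TGT": 0.48},
    "Q": {"CAG": 0.75, "CAA": 0.25},
    "E": {"GAG": 0.60, "GAA": 0.40},
    "G": {"GGC": 0.33, "GGA": 0.26, "GGG": 0.23, "GGT": 0.18},
    "H": {"CAC": 0.59, "CAT": 0.41},
    "I": {"ATC": 0.50, "ATT": 0.34, "ATA": 0.16},
    "L": {"CTG": 0.39, "CTC": 0.20, "CTT": 0.13, "TTG": 0.13, "CTA": 0.08, "TTA": 0.07},
    "K": {"AAG": 0.61, "AAA": 0.39},
    "M": {"ATG": 1.0},
    "F": {"TTC": 0.56, "TTT": 0.44},
    "P": {"CCC": 0.31, "CCT": 0.31, "CCA": 0.28, "CCG": 0.10},
    "S": {"AGC": 0.24, "TCC": 0.22, "TCT": 0.19, "AGT": 0.15, "TCA": 0.14, "TCG": 0.06},
    "T": {"ACC": 0.35, "ACA": 0.29, "ACT": 0.26, "ACG": 0.10},
    "W": {"TGG": 1.0},
    "Y": {"TAC": 0.57, "TAT": 0.43},
    "V": {"GTG": 0.46, "GTC": 0.25, "GTT": 0.17, "GTA": 0.12},
}

CANONICAL_AA = frozenset(MOUSE_CODON_USAGE)

_COMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(nt: str) -> str:
    return nt.translate(_COMP)[::-1]


def translate(nt: str) -> str:
    """Translate a frame-0 nucleotide string with the standard genetic code."""
    return str(Seq(nt).translate())


class CodonSampler:
    """Usage-weighted codon sampler over a codon table.

    Parameters
    ----------
    usage : mapping residue -> {codon: weight}. Defaults to mouse usage.
    """

    def __init__(self, usage: dict[str, dict[str, float]] | None = None):
        usage = usage if usage is not None else MOUSE_CODON_USAGE
        missing = CANONICAL_AA - set(usage)
        if missing:
            raise ValueError(f"codon table missing residues: {sorted(missing)}")
        self._codons: dict[str, list[str]] = {}
        self._cum: dict[str, np.ndarray] = {}
        for aa, table in usage.items():
            codons = list(table)
            w = np.asarray([table[c] for c in codons], dtype=float)
            if (w < 0).any() or w.sum() <= 0:
                raise ValueError(f"invalid codon weights for {aa!r}")
            self._codons[aa] = codons
            self._cum[aa] = np.cumsum(w / w.sum())

    def sample(self, aa: str, rng: np.random.Generator) -> str:
        i = int(np.searchsorted(self._cum[aa], rng.random(), side="right"))
        return self._codons[aa][min(i, len(self._codons[aa]) - 1)]

    def synonymous(self, codon: str, aa: str) -> list[str]:
        """Codons for `aa` other than `codon` (may be empty for M/W)."""
        return [c for c in self._codons[aa] if c != codon]


def find_motif_hits(nt: str, motifs) -> list[tuple[int, int]]:
    """All (start, end) spans where a motif or its reverse complement occurs."""
    hits: list[tuple[int, int]] = []
    for motif in motifs:
        for m in {motif.upper(), reverse_complement(motif.upper())}:
            start = nt.find(m)
            while start != -1:
                hits.append((start, start + len(m)))
                start = nt.find(m, start + 1)
    return sorted(set(hits))


def back_translate(
    peptide: str,
    codon_table: dict[str, dict[str, float]] | CodonSampler | None = None,
    forbidden_motifs=(),
    seed: int = 0,
    max_attempts: int = 200,
) -> str:
    """Back-translate a peptide into a nucleotide string.

    Codons are drawn usage-weighted and deterministically for a given seed.
    Any codon overlapping an occurrence of a forbidden motif (forward or
    reverse-complement strand) is resampled until the sequence is clean.

    Raises
    ------
    ValueError
        On non-canonical residues, or if motifs cannot be avoided within
        `max_attempts` resampling rounds.
    """
    if not peptide:
        return ""
    bad = set(peptide) - CANONICAL_AA
    if bad:
        raise ValueError(f"non-canonical residues {sorted(bad)} in peptide {peptide!r}")
    sampler = codon_table if isinstance(codon_table, CodonSampler) else CodonSampler(codon_table)
    rng = np.random.default_rng(seed)
    codons = [sampler.sample(aa, rng) for aa in peptide]
    if not forbidden_motifs:
        return "".join(codons)
    for _ in range(max_attempts):
        nt = "".join(codons)
        hits = find_motif_hits(nt, forbidden_motifs)
        if not hits:
            return nt
        for start, end in hits:
            for ci in range(start // 3, (end - 1) // 3 + 1):
                codons[ci] = sampler.sample(peptide[ci], rng)
    raise ValueError(
        f"could not avoid forbidden motifs {list(forbidden_motifs)} in back-translation "
        f"of {peptide!r} after {max_attempts} attempts"
    )


def resample_synonymous(
    nt: str,
    forbidden_motifs,
    seed: int = 0,
    max_attempts: int = 200,
    protected: tuple[int, int] | None = None,
) -> str:
    """Remove forbidden motifs from a frame-0 coding sequence by synonymous swaps.

    The translated protein is preserved exactly. `protected` is an optional
    (start, end) nucleotide span (e.g. a flank that legitimately contains the
    motif) in which hits are ignored.

    Raises ValueError if the sequence length is not a codon multiple or the
    motif cannot be removed (e.g. it sits in single-codon residues).
    """
    if len(nt) % 3 != 0:
        raise ValueError("coding sequence length must be a multiple of 3")
    sampler = CodonSampler()
    rng = np.random.default_rng(seed)
    codons = [nt[i : i + 3].upper() for i in range(0, len(nt), 3)]
    protein = translate(nt)
    for _ in range(max_attempts):
        seq = "".join(codons)
        hits = find_motif_hits(seq, forbidden_motifs)
        if protected is not None:
            hits = [h for h in hits if h[1] <= protected[0] or h[0] >= protected[1]]
        if not hits:
            return seq
        changed = False
        for start, end in hits:
            for ci in range(start // 3, (end - 1) // 3 + 1):
                aa = protein[ci]
                if aa == "*":
                    continue
                choices = sampler.synonymous(codons[ci], aa)
                if choices:
                    codons[ci] = choices[int(rng.integers(len(choices)))]
                    changed = True
        if not changed:
            break
    raise ValueError(f"could not remove forbidden motifs {list(forbidden_motifs)} synonymously")
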