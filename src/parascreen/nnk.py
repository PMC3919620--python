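"""NNK degenerate-codon model for randomized peptide libraries.

An NNK codon has any base (N) at positions 1-2 and G or T (K) at position 3,
giving 32 codons that cover all 20 amino acids.  The only stop codon reachable
under NNK is the amber codon TAG (TAA and TGA carry A at the third position);
libraries propagated in amber-suppressor *E. coli* strains (e.g. ER2738) read
TAG as glutamine, so translation here maps TAG -> Q and never emits a stop.
"""

from __future__ import annotations

from collections import Counter
from functools import reduce

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

BASES = "ACGT"
K_BASES = "GT"

#: The 32 NNK codons, lexicographic order.
NNK_CODONS: tuple[str, ...] = tuple(
    a + b + c for a in BASES for b in BASES for c in K_BASES
)

#: codon -> amino acid under amber suppression (TAG reads as Q).
CODON_TO_AA: dict[str, str] = {
    codon: ("Q" if codon == "TAG" else standard_dna_table.forward_table[codon])
    for codon in NNK_CODONS
}

#: amino acid -> number of NNK codons encoding it (values in {1, 2, 3}).
DEGENERACY: dict[str, int] = dict(Counter(CODON_TO_AA.values()))

#: amino acid -> tuple of encoding NNK codons.
AA_TO_CODONS: dict[str, tuple[str, ...]] = {
    aa: tuple(c for c in NNK_CODONS if CODON_TO_AA[c] == aa)
    for aa in DEGENERACY
}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(dna: str) -> str:
    return dna.translate(_COMPLEMENT)[::-1]


def is_nnk(dna: str) -> bool:
    """True iff ``dna`` is over ACGT, has length divisible by 3 and every
    codon ends in G or T."""
    if len(dna) % 3 != 0 or len(dna) == 0:
        return False
    if any(b not in BASES for b in dna):
        return False
    return all(dna[i] in K_BASES for i in range(2, len(dna), 3))


def translate_nnk(dna: str) -> str:
    """Translate an NNK-conforming DNA string, reading TAG as Q.

    Raises ``ValueError`` on non-NNK input.  TAA/TGA cannot occur under the
    NNK constraint, so no stop symbol is ever produced.
    """
    if not is_nnk(dna):
        raise ValueError(f"not an NNK-structured sequence: {dna!r}")
    return "".join(CODON_TO_AA[dna[i : i + 3]] for i in range(0, len(dna), 3))


def peptide_draw_probability(peptide: str) -> float:
    """Probability that one random draw of uniform NNK codons encodes
    ``peptide``: the product over residues of degeneracy(aa)/32."""
    try:
        return reduce(
            lambda acc, aa: acc * (DEGENERACY[aa] / 32.0), peptide.upper(), 1.0
        )
    except KeyError as exc:
        raise ValueError(f"unknown residue in {peptide!r}: {exc}") from None


def theoretical_diversity(length: int = 7) -> int:
    """Number of distinct peptides encodable by (NNK)_length.

    Amber reads as Q, so the peptide alphabet is exactly the 20 amino acids:
    20**length (1.28e9 for 7-mers).
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    return 20 ** length


def random_nnk_sample(
    m: int, seed: int | np.random.Generator = 0, length: int = 7
) -> list[str]:
    """Draw ``m`` i.i.d. peptides, each encoded by ``length`` uniform NNK
    codons (draws with replacement; repeats allowed)."""
    if m < 0:
        raise ValueError("m must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, 32, size=(m, length))
    codons = np.asarray(NNK_CODONS)
    aa = np.asarray([CODON_TO_AA[c] for c in codons])
    return ["".join(row) for row in aa[idx]]


def reverse_translate(peptide: str, rng: np.random.Generator) -> str:
    """One random NNK back-translation of a peptide."""
    out = []
    for aa in peptide.upper():
        choices = AA_TO_CODONS.get(aa)
        if choices is None:
            raise ValueError(f"unknown residue {aa!r}")
        out.append(choices[rng.integers(0, len(choices))])
    return "".join(out)
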