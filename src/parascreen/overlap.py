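"""Overlap statistics between candidate populations and literature lists.

The NNK codon calculus gives every peptide an exact probability of being
drawn in one random NNK library draw (product of per-residue codon
degeneracies over 32).  That probability drives the analytic null for the
overlap between a literature-derived hit list and a random in-silico
library of m clones, which the bootstrap routines check by simulation;
``subset_overlap_null`` instead draws random subsets of an observed library
(the hypergeometric null).  ``hit_rate`` is the headline quantity: the
fraction of a candidate parasite population found in the literature list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .containers import PeptideMultiset
from .nnk import (
    AMINO_ACIDS,
    DEGENERACY,
    peptide_draw_probability,
    random_nnk_sample,
    theoretical_diversity,
)

__all__ = [
    "load_peptide_list",
    "peptide_draw_probability",
    "theoretical_diversity",
    "random_nnk_sample",
    "overlap_null",
    "subset_overlap_null",
    "hit_rate",
    "OverlapNull",
]

_VALID = set(AMINO_ACIDS)


def load_peptide_list(path) -> list[str]:
    """Read a plain-text peptide list (one per line, ``#`` comments).

    Entries are uppercased and deduplicated preserving order; entries with
    letters outside the 20-residue alphabet are dropped with a warning
    (database exports often carry annotations).
    """
    seen: dict[str, None] = {}
    dropped = 0
    with open(path) as fh:
        for line in fh:
            entry = line.split("#", 1)[0].strip().upper()
            if not entry:
                continue
            if set(entry) <= _VALID:
                seen.setdefault(entry, None)
            else:
                dropped += 1
    if dropped:
        warnings.warn(f"dropped {dropped} entries with non-standard letters")
    return list(seen)


@dataclass
class OverlapNull:
    analytic_expectation: float
    bootstrap: np.ndarray

    @property
    def poisson_fit(self) -> dict[str, float]:
        """Bootstrap mean/variance summary; for a Poisson-like null the
        variance-to-mean ratio is close to 1."""
        mean = float(self.bootstrap.mean()) if self.bootstrap.size else 0.0
        var = float(self.bootstrap.var(ddof=1)) if self.bootstrap.size > 1 else 0.0
        return {
            "mean": mean,
            "var": var,
            "var_mean_ratio": var / mean if mean else float("nan"),
        }


def overlap_null(
    lit: list[str], m: int, iters: int = 100, seed: int = 0
) -> OverlapNull:
    """Null overlap between a literature list and a random NNK library of m
    clones.

    Analytic expectation: sum over unique list peptides of
    ``1 - (1 - p_i)**m`` with p_i the NNK draw probability.  The bootstrap
    repeats ``|lit ∩ set(random library of m draws)|`` and should match the
    analytic value within Monte-Carlo error (Poisson-like distribution).
    """
    if iters < 1:
        raise ValueError("iters must be >= 1")
    if m < 0:
        raise ValueError("m must be >= 0")
    unique = list(dict.fromkeys(p.upper() for p in lit))
    if not unique:
        raise ValueError("lit list is empty")
    expectation = float(
        sum(1.0 - (1.0 - peptide_draw_probability(p)) ** m for p in unique)
    )
    rng = np.random.default_rng(seed)
    lit_set = set(unique)
    draws = np.empty(iters, dtype=np.int64)
    for i in range(iters):
        if m == 0:
            draws[i] = 0
            continue
        sample = set(random_nnk_sample(m, rng))
        draws[i] = len(lit_set & sample)
    return OverlapNull(expectation, draws)


def subset_overlap_null(
    lit: list[str],
    reference: PeptideMultiset,
    subset_size: int,
    iters: int = 100,
    seed: int = 0,
) -> OverlapNull:
    """Null overlap between a literature list and random subsets of an
    observed library's unique sequences (without replacement).

    The expectation is hypergeometric:
    ``subset_size * |lit ∩ reference| / |reference|``.
    """
    if iters < 1:
        raise ValueError("iters must be >= 1")
    seqs = np.array(sorted(reference.counts))
    if subset_size > seqs.size:
        raise ValueError("subset_size exceeds unique sequences in reference")
    lit_set = {p.upper() for p in lit}
    in_lit = np.array([s in lit_set for s in seqs])
    expectation = subset_size * in_lit.sum() / seqs.size
    rng = np.random.default_rng(seed)
    draws = np.empty(iters, dtype=np.int64)
    for i in range(iters):
        idx = rng.choice(seqs.size, size=subset_size, replace=False)
        draws[i] = int(in_lit[idx].sum())
    return OverlapNull(float(expectation), draws)


def hit_rate(population, lit) -> dict[str, float]:
    """Overlap count and rate between a candidate population and a
    literature list (both deduplicated; rate = overlap / |population|)."""
    pop = {p.upper() for p in population}
    if not pop:
        raise ValueError("population is empty")
    overlap = pop & {p.upper() for p in lit}
    return {"overlap": len(overlap), "rate": len(overlap) / len(pop)}
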