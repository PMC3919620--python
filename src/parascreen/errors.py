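"""Sequencing-error analyses: Hamming profiles and point-mutant removal.

Abundant library members are surrounded by a cloud of low-count point
mutants ("MUT" reads) created by PCR and sequencing errors, typically at
1-5% of the parent's count.  ``hamming_profile`` diagnoses this (an excess
of distance-1 nearest neighbours), ``flag_mutants``/``strip_mutants``
implement greedy parent-first tagging and removal, and
``processing_variant`` composes the F/R combination with optional mutant
removal into the four labelled processing variants
(F∪R / F∩R x MUT+/- with NNM reads removed upstream).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

from .containers import PeptideMultiset
from .reads import combine_fr

__all__ = [
    "MutantFlag",
    "hamming_profile",
    "flag_mutants",
    "strip_mutants",
    "processing_variant",
    "write_flags_csv",
]


@dataclass
class MutantFlag:
    peptide: str
    parent: str
    distance: int
    child_fraction: float

    def __post_init__(self) -> None:
        if self.distance < 1:
            raise ValueError("distance must be >= 1")
        if not self.child_fraction < 1:
            raise ValueError("child_fraction must be < 1")


def _ordered(ms: PeptideMultiset) -> list[tuple[str, int]]:
    # descending count; equal counts break lexicographically (earlier = "higher")
    return ms.sorted_items()


def _encode(seqs: list[str]) -> np.ndarray:
    return np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(len(seqs), -1)


def hamming_profile(ms: PeptideMultiset, level: str = "peptide") -> dict[int, int]:
    """Histogram of each sequence's Hamming distance to its nearest
    higher-ranked neighbour.

    Sequences are ranked by descending count with lexicographic tie-break,
    so in an all-singleton library every sequence (except the first) still
    reports its distance to the nearest equal-count neighbour.  The
    top-ranked sequence has no neighbour above it and contributes nothing.
    ``level`` is informational: the multiset's own alphabet (peptide or DNA)
    sets the distance range.
    """
    if len(ms) < 2:
        return {}
    order = [p for p, _ in _ordered(ms)]
    enc = _encode(order)
    n, length = enc.shape
    hist: dict[int, int] = {}
    chunk = max(1, int(4e7) // max(n, 1))
    for lo in range(1, n, chunk):
        hi = min(lo + chunk, n)
        # distances of rows lo:hi to every row, masked to higher-ranked rows
        d = (enc[lo:hi, None, :] != enc[None, :, :]).sum(axis=2)
        for i in range(lo, hi):
            dist = int(d[i - lo, :i].min())
            hist[dist] = hist.get(dist, 0) + 1
    return dict(sorted(hist.items()))


def flag_mutants(
    ms: PeptideMultiset,
    max_child_fraction: float = 0.05,
    max_distance: int = 1,
) -> list[MutantFlag]:
    """Greedy parent-first point-mutant tagging.

    Scanning sequences in descending count order, every not-yet-flagged
    sequence within ``max_distance`` of the current (unflagged) parent whose
    count is at most ``max_child_fraction`` of the parent's count is flagged
    with that parent.  A flagged sequence is never itself used as a parent,
    so mutant clouds collapse onto the highest-count founder.
    """
    if not 0.0 < max_child_fraction < 1.0:
        raise ValueError("max_child_fraction must be in (0, 1)")
    if max_distance < 1:
        raise ValueError("max_distance must be >= 1")
    order = _ordered(ms)
    flagged: dict[str, MutantFlag] = {}
    if max_distance == 1:
        index = {p: c for p, c in order}
        alphabet = "".join(sorted({ch for s in index for ch in s}))
        for parent, pcount in order:
            if parent in flagged:
                continue
            # any candidate with count <= limit < pcount is strictly below
            # the parent in rank order, so no explicit rank check is needed
            limit = max_child_fraction * pcount
            for child, dist in _one_sub_neighbours(parent, index, alphabet):
                if child not in flagged and index[child] <= limit:
                    flagged[child] = MutantFlag(
                        child, parent, dist, index[child] / pcount
                    )
        return [flagged[p] for p, _ in order if p in flagged]

    seqs = [p for p, _ in order]
    counts = [c for _, c in order]
    enc = _encode(seqs)
    for i, (parent, pcount) in enumerate(order):
        if parent in flagged:
            continue
        limit = max_child_fraction * pcount
        d = (enc[i + 1 :] != enc[i]).sum(axis=1)
        for off in np.nonzero(d <= max_distance)[0]:
            j = i + 1 + off
            child = seqs[j]
            if child in flagged or counts[j] > limit:
                continue
            flagged[child] = MutantFlag(child, parent, int(d[off]), counts[j] / pcount)
    return [flagged[p] for p, _ in order if p in flagged]


def _one_sub_neighbours(seq: str, index: dict[str, int], alphabet: str):
    """All sequences in ``index`` at Hamming distance exactly 1 from ``seq``.

    Enumerates substitutions against the observed alphabet, so it works for
    both peptide and DNA multisets without a distance matrix.
    """
    for pos in range(len(seq)):
        prefix, base, suffix = seq[:pos], seq[pos], seq[pos + 1 :]
        for alt in alphabet:
            if alt == base:
                continue
            cand = prefix + alt + suffix
            if cand in index:
                yield cand, 1


def strip_mutants(ms: PeptideMultiset, flags: list[MutantFlag]) -> PeptideMultiset:
    """Remove flagged entries (counts dropped, not merged into parents).

    ``total_reads`` shrinks by the removed counts; the result carries the
    ``mut_filtered`` provenance flag.
    """
    counts = dict(ms.counts)
    removed = 0
    for flag in flags:
        if flag.peptide not in counts:
            raise KeyError(f"flag references unknown peptide {flag.peptide!r}")
        removed += counts.pop(flag.peptide)
    return PeptideMultiset(
        counts=counts,
        total_reads=max(ms.total_reads - removed, sum(counts.values())),
        label=ms.label,
        orientation=ms.orientation,
        mut_filtered=True,
        nnm_filtered=ms.nnm_filtered,
    )


def processing_variant(
    F: PeptideMultiset,
    R: PeptideMultiset,
    combine: str = "union",
    mut: str = "keep",
    max_child_fraction: float = 0.05,
    max_distance: int = 1,
) -> PeptideMultiset:
    """One of the four processing variants (F∪R|F∩R, MUT+|-, NNM-).

    Composes :func:`combine_fr` with optional mutant removal; NNM (non-NNK)
    reads are assumed removed upstream by the read filter, which the label
    records.  ``mut='keep'`` reproduces the standard processing
    (F∪R, MUT+, NNM-).
    """
    if mut not in ("keep", "remove"):
        raise ValueError(f"unknown mut mode {mut!r}")
    combined = combine_fr(F, R, mode=combine)
    if mut == "remove":
        combined = strip_mutants(
            combined, flag_mutants(combined, max_child_fraction, max_distance)
        )
    op = "∪" if combine == "union" else "∩"
    sign = "+" if mut == "keep" else "-"
    combined.label = f"{F.label} (F{op}R, MUT{sign}, NNM-)"
    return combined


def write_flags_csv(flags: list[MutantFlag], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["peptide", "parent", "distance", "child_fraction"])
        for f in flags:
            writer.writerow([f.peptide, f.parent, f.distance, f"{f.child_fraction:.6g}"])
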