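"""Core containers: peptide multisets and replicate count matrices.

A sequenced library is represented as a multiset (S, m): the set S of unique
peptides together with a count vector m.  ``PeptideMultiset`` stores this as
a peptide -> count mapping plus the number of reads that entered the multiset
and provenance flags (read orientation, whether point-mutant and non-NNK
reads were removed).

``ReplicateMatrix`` holds a sequences x replicates integer count table with
per-replicate library sizes, used by the replicate-based statistics
(overdispersion diagnostics, volcano test, negative-binomial exact test).
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field, replace

import numpy as np

ORIENTATIONS = ("F", "R", "F∪R", "F∩R")  # F, R, F∪R, F∩R


@dataclass
class PeptideMultiset:
    counts: dict[str, int]
    total_reads: int = 0
    label: str = "library"
    orientation: str = "F"
    mut_filtered: bool = False
    nnm_filtered: bool = False

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("label must be nonempty")
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if any(c < 1 for c in self.counts.values()):
            raise ValueError("all counts must be >= 1")
        if self.total_reads == 0:
            self.total_reads = sum(self.counts.values())

    def __len__(self) -> int:
        return len(self.counts)

    def __contains__(self, peptide: str) -> bool:
        return peptide in self.counts

    @property
    def n_reads(self) -> int:
        """Sum of stored counts (<= total_reads for F/R multisets)."""
        return sum(self.counts.values())

    def abundances(self) -> dict[str, float]:
        """Counts normalized to sum to 1."""
        total = self.n_reads
        if total == 0:
            raise ValueError("empty multiset")
        return {p: c / total for p, c in self.counts.items()}

    def sorted_items(self) -> list[tuple[str, int]]:
        """Entries by descending count, ties alphabetical."""
        return sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))

    def copy(self, **changes) -> "PeptideMultiset":
        out = replace(self, **changes)
        if "counts" not in changes:
            out.counts = dict(self.counts)
        return out

    # ------------------------------------------------------------------ IO
    def to_tsv(self, path) -> None:
        op = gzip.open if str(path).endswith(".gz") else open
        with op(path, "wt") as fh:
            fh.write(f"#label={self.label}\n")
            fh.write(f"#total_reads={self.total_reads}\n")
            fh.write(f"#orientation={self.orientation}\n")
            fh.write(f"#mut_filtered={int(self.mut_filtered)}\n")
            fh.write(f"#nnm_filtered={int(self.nnm_filtered)}\n")
            for pep, cnt in self.sorted_items():
                fh.write(f"{pep}\t{cnt}\n")

    @classmethod
    def from_tsv(cls, path) -> "PeptideMultiset":
        meta: dict[str, str] = {}
        counts: dict[str, int] = {}
        op = gzip.open if str(path).endswith(".gz") else open
        with op(path, "rt") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#"):
                    key, _, val = line[1:].partition("=")
                    meta[key] = val
                    continue
                pep, cnt = line.split("\t")
                counts[pep] = int(cnt)
        return cls(
            counts=counts,
            total_reads=int(meta.get("total_reads", 0)),
            label=meta.get("label", "library"),
            orientation=meta.get("orientation", "F"),
            mut_filtered=bool(int(meta.get("mut_filtered", 0))),
            nnm_filtered=bool(int(meta.get("nnm_filtered", 0))),
        )


@dataclass
class ReplicateMatrix:
    sequences: list[str]
    counts: np.ndarray  # (n_sequences, n_replicates) nonnegative ints
    library_sizes: np.ndarray  # (n_replicates,)
    roles: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.library_sizes = np.asarray(self.library_sizes, dtype=float)
        n, k = self.counts.shape
        if n != len(self.sequences):
            raise ValueError("sequences/counts shape mismatch")
        if k != len(self.library_sizes):
            raise ValueError("library_sizes/counts shape mismatch")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if not self.roles:
            self.roles = ["BR"] * k
        if len(self.roles) != k:
            raise ValueError("roles/counts shape mismatch")

    @property
    def n_replicates(self) -> int:
        return self.counts.shape[1]

    @classmethod
    def from_multisets(
        cls, multisets: list[PeptideMultiset], roles: list[str] | None = None
    ) -> "ReplicateMatrix":
        """Stack multisets into a count table over the union of peptides.

        Peptides absent from a replicate get count 0; library sizes are the
        multisets' total_reads.
        """
        seqs = sorted(set().union(*(ms.counts.keys() for ms in multisets)))
        idx = {s: i for i, s in enumerate(seqs)}
        counts = np.zeros((len(seqs), len(multisets)), dtype=np.int64)
        for j, ms in enumerate(multisets):
            for pep, cnt in ms.counts.items():
                counts[idx[pep], j] = cnt
        sizes = np.array([ms.total_reads for ms in multisets], dtype=float)
        return cls(seqs, counts, sizes, roles or [])


def align_matrices(
    a: ReplicateMatrix, b: ReplicateMatrix
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Align two replicate matrices on the union of their sequences.

    Missing sequences are assigned count 0 in the matrix that lacks them.
    """
    seqs = sorted(set(a.sequences) | set(b.sequences))
    idx = {s: i for i, s in enumerate(seqs)}

    def expand(m: ReplicateMatrix) -> np.ndarray:
        out = np.zeros((len(seqs), m.n_replicates), dtype=m.counts.dtype)
        rows = [idx[s] for s in m.sequences]
        out[rows, :] = m.counts
        return out

    return seqs, expand(a), expand(b)


def nan_if_empty(num: float, den: float) -> float:
    return num / den if den else math.nan
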