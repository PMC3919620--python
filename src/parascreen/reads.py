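"""FASTQ -> peptide multiset processing cascade.

Raw amplicon reads carry ``barcode + flank5 + 21-nt variable region +
flank3`` on either strand.  The cascade is: exact barcode demultiplexing
(read or its reverse complement), flank location and variable-region
extraction with a strict length check, an all-bases Phred > cut quality
filter, the NNK structure filter (third codon position G or T), amber-aware
translation, and finally combination of forward and reverse multisets by the
per-peptide max rule (union or intersection).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .containers import PeptideMultiset, nan_if_empty
from .nnk import is_nnk, reverse_complement, translate_nnk

__all__ = [
    "DemuxSpec",
    "demultiplex",
    "extract_variable",
    "quality_pass",
    "nnk_pass",
    "translate_nnk",
    "build_multisets",
    "combine_fr",
    "process_fastq",
]

REJECT_REASONS = ("no_flanks", "bad_length", "low_quality", "non_nnk")


@dataclass
class DemuxSpec:
    """Demultiplexing and extraction parameters.

    ``quality_cut`` is strict: a base passes only with Phred > cut, so the
    default 30 admits Q31 and above.
    """

    barcodes: dict[str, str]
    flank5: str
    flank3: str
    variable_length: int = 21
    quality_cut: int = 30

    def __post_init__(self) -> None:
        if not self.barcodes:
            raise ValueError("at least one barcode is required")
        if len(set(self.barcodes.values())) != len(self.barcodes):
            raise ValueError("barcodes must be pairwise distinct")
        if self.variable_length % 3 != 0:
            raise ValueError("variable_length must be divisible by 3")
        if not self.flank5 or not self.flank3:
            raise ValueError("flanks must be nonempty")


def iter_fastq(path):
    """Yield (sequence, quality_string) records from plain or gzipped FASTQ."""
    op = gzip.open if str(path).endswith(".gz") else open
    with op(path, "rt") as fh:
        for _title, seq, qual in FastqGeneralIterator(fh):
            yield seq.upper(), qual


def demultiplex(reads, spec: DemuxSpec):
    """Assign reads to samples by exact leading-barcode match.

    A read belongs to a sample iff its leading bases (or the leading bases
    of its reverse complement) equal that sample's barcode.  Returns
    ``(batches, summary)`` where ``batches`` maps sample name to a list of
    (sequence, quality) pairs and ``summary['mapped_fraction']`` is
    assigned/total (NaN for an empty stream).
    """
    batches: dict[str, list[tuple[str, str]]] = {name: [] for name in spec.barcodes}
    total = assigned = 0
    for seq, qual in reads:
        total += 1
        hit = _match_barcode(seq, spec)
        if hit is None:
            rc = reverse_complement(seq)
            hit = _match_barcode(rc, spec)
        if hit is not None:
            batches[hit].append((seq, qual))
            assigned += 1
    if total == 0:
        return {}, {"mapped_fraction": float("nan"), "total": 0, "assigned": 0}
    return batches, {
        "mapped_fraction": assigned / total,
        "total": total,
        "assigned": assigned,
    }


def _match_barcode(seq: str, spec: DemuxSpec):
    for name, bc in spec.barcodes.items():
        if seq.startswith(bc):
            return name
    return None


def extract_variable(seq: str, qual: str, spec: DemuxSpec):
    """Locate flank5...flank3 and extract the enclosed variable region.

    Searches the read (orientation F) then its reverse complement
    (orientation R, with the quality vector reversed accordingly).  Returns
    ``{'orientation', 'variable', 'qualities'}`` on success or a reason code
    string (``'no_flanks'`` or ``'bad_length'``) on rejection.
    """
    quals = [ord(c) - 33 for c in qual]
    for orientation in ("F", "R"):
        if orientation == "R":
            seq_o, quals_o = reverse_complement(seq), quals[::-1]
        else:
            seq_o, quals_o = seq, quals
        start = seq_o.find(spec.flank5)
        if start < 0:
            continue
        lo = start + len(spec.flank5)
        # prefer flank3 at the expected offset so a chance recurrence of the
        # flank bytes inside the variable region does not truncate the read
        if seq_o.startswith(spec.flank3, lo + spec.variable_length):
            hi = lo + spec.variable_length
        else:
            hi = seq_o.find(spec.flank3, lo)
            if hi < 0:
                continue
        if hi - lo != spec.variable_length:
            return "bad_length"
        return {
            "orientation": orientation,
            "variable": seq_o[lo:hi],
            "qualities": quals_o[lo:hi],
        }
    return "no_flanks"


def quality_pass(qualities, cut: int = 30) -> bool:
    """True iff every base quality is strictly greater than ``cut``."""
    if len(qualities) == 0:
        raise ValueError("empty quality vector")
    return all(q > cut for q in qualities)


def nnk_pass(dna: str) -> bool:
    """True iff the sequence is NNK-structured (third codon base G or T,
    ACGT alphabet); non-ACGT characters fail."""
    return is_nnk(dna)


def build_multisets(batch, spec: DemuxSpec, label: str = "sample"):
    """Filter and translate one demultiplexed batch.

    Applies extraction, quality and NNK filters in that order and splits
    accepted reads into forward and reverse peptide multisets.  Returns
    ``{'F': ms, 'R': ms, 'reject_counts': {reason: n}}``; every read in the
    batch lands in exactly one multiset or one reject bucket.
    """
    f_counts: dict[str, int] = {}
    r_counts: dict[str, int] = {}
    rejects = dict.fromkeys(REJECT_REASONS, 0)
    n_f = n_r = 0
    for seq, qual in batch:
        hit = extract_variable(seq, qual, spec)
        if isinstance(hit, str):
            rejects[hit] += 1
            continue
        if not quality_pass(hit["qualities"], spec.quality_cut):
            rejects["low_quality"] += 1
            continue
        if not nnk_pass(hit["variable"]):
            rejects["non_nnk"] += 1
            continue
        pep = translate_nnk(hit["variable"])
        if hit["orientation"] == "F":
            f_counts[pep] = f_counts.get(pep, 0) + 1
            n_f += 1
        else:
            r_counts[pep] = r_counts.get(pep, 0) + 1
            n_r += 1
    make = lambda counts, n, ori: PeptideMultiset(
        counts=counts, total_reads=n, label=label, orientation=ori, nnm_filtered=True
    )
    return {
        "F": make(f_counts, n_f, "F"),
        "R": make(r_counts, n_r, "R"),
        "reject_counts": rejects,
    }


def combine_fr(F: PeptideMultiset, R: PeptideMultiset, mode: str = "union") -> PeptideMultiset:
    """Combine forward and reverse multisets by the per-peptide max rule.

    ``union``: every peptide seen in F or R with count max(f, r) (absent
    counts as 0); ``intersect``: peptides seen in both, count max(f, r).
    The combined total_reads is max(total_F, total_R), the scale that
    matches max-rule counts.
    """
    if F.label != R.label:
        raise ValueError("F and R multisets must share a sample label")
    if mode == "union":
        peptides = set(F.counts) | set(R.counts)
        orientation = "F∪R"
    elif mode == "intersect":
        peptides = set(F.counts) & set(R.counts)
        orientation = "F∩R"
    else:
        raise ValueError(f"unknown combine mode {mode!r}")
    counts = {
        p: max(F.counts.get(p, 0), R.counts.get(p, 0)) for p in peptides
    }
    return PeptideMultiset(
        counts=counts,
        total_reads=max(F.total_reads, R.total_reads),
        label=F.label,
        orientation=orientation,
        mut_filtered=F.mut_filtered and R.mut_filtered,
        nnm_filtered=F.nnm_filtered and R.nnm_filtered,
    )


def process_fastq(path, spec: DemuxSpec, mode: str = "union"):
    """Full cascade on a FASTQ file: demultiplex, filter, translate, combine.

    Returns ``(multisets, summary)``: a per-sample combined multiset and a
    summary with the mapped fraction and, per sample, the rejects and the
    quality/NNK pass fractions measured on the cascade
    (quality among extracted reads, NNK among quality-passing reads).
    """
    batches, summary = demultiplex(iter_fastq(path), spec)
    multisets: dict[str, PeptideMultiset] = {}
    summary["samples"] = {}
    for name, batch in batches.items():
        if not batch:
            continue
        built = build_multisets(batch, spec, label=name)
        rej = built["reject_counts"]
        n_mapped = len(batch)
        n_extracted = n_mapped - rej["no_flanks"] - rej["bad_length"]
        n_qpass = n_extracted - rej["low_quality"]
        n_nnk = n_qpass - rej["non_nnk"]
        summary["samples"][name] = {
            "n_reads": n_mapped,
            "reject_counts": rej,
            "quality_pass_fraction": nan_if_empty(n_qpass, n_extracted),
            "nnk_pass_fraction": nan_if_empty(n_nnk, n_qpass),
        }
        multisets[name] = combine_fr(built["F"], built["R"], mode=mode)
    return multisets, summary
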