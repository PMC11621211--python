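"""Alignment-based accuracy metrics.

Reads are scored by four rates derived from a single optimal pairwise
alignment of the call (query) against its reference:

    identity  = matches    / alignment_length * 100%
    mismatch  = mismatches / alignment_length * 100%
    insertion = insertions / alignment_length * 100%   (extra bases in call)
    deletion  = deletions  / alignment_length * 100%   (reference bases absent)

The four always sum to 100%.  The aligner is an in-repo semi-global dynamic
program (match +1, mismatch −1, gap −2; end-gaps on the reference are free)
with deterministic tie-breaking: match > mismatch > deletion > insertion.
At genome scale one would map with minimap2 and keep the primary alignment;
this aligner is its desk-scale stand-in for read-length references.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from Bio import SeqIO

__all__ = ["AlignmentSummary", "RateReport", "align_read", "compute_rates",
           "evaluate_dataset", "evaluate_pairs"]

MATCH, MISMATCH, GAP = 1, -1, -2


@dataclass
class AlignmentSummary:
    matches: int
    mismatches: int
    insertions: int   # bases in query absent from reference
    deletions: int    # reference bases absent from query
    alignment_length: int

    def __post_init__(self):
        counts = (self.matches, self.mismatches, self.insertions, self.deletions)
        if any(c < 0 for c in counts):
            raise ValueError("alignment counts must be non-negative")
        if self.alignment_length != sum(counts):
            raise ValueError("alignment_length must equal the sum of counts")


@dataclass
class RateReport:
    identity_pct: float
    mismatch_pct: float
    insertion_pct: float
    deletion_pct: float

    def __post_init__(self):
        rates = (self.identity_pct, self.mismatch_pct,
                 self.insertion_pct, self.deletion_pct)
        tol = 1e-9
        if any(not -tol <= r <= 100 + tol for r in rates):
            raise ValueError("rates must lie in [0, 100]")
        if abs(sum(rates) - 100.0) > 1e-9:
            raise ValueError("rates must sum to 100%")


def _canonical(seq: str) -> str:
    return seq.upper().replace("T", "U")


def align_read(query: str, reference: str) -> AlignmentSummary:
    """Optimal semi-global alignment of call vs reference.

    Free end-gaps on the reference (unaligned reference flanks cost nothing
    and are not counted); every query base is aligned.  Deterministic
    traceback prefers match > mismatch > deletion > insertion on ties.
    """
    if not query or not reference:
        raise ValueError("query and reference must be nonempty")
    q = _canonical(query)
    r = _canonical(reference)
    nq, nr = len(q), len(r)
    D = np.empty((nq + 1, nr + 1), dtype=np.int64)
    D[0, :] = 0                      # free reference prefix
    D[:, 0] = GAP * np.arange(nq + 1)
    q_arr = np.frombuffer(q.encode(), dtype=np.uint8)
    r_arr = np.frombuffer(r.encode(), dtype=np.uint8)
    sub = np.where(q_arr[:, None] == r_arr[None, :], MATCH, MISMATCH)
    for i in range(1, nq + 1):
        diag = D[i - 1, :-1] + sub[i - 1]
        up = D[i - 1, 1:] + GAP
        row = D[i]
        prev = row[0]
        # left-dependency forces a sequential sweep within the row
        cand = np.maximum(diag, up)
        for j in range(1, nr + 1):
            prev = max(cand[j - 1], prev + GAP)
            row[j] = prev
    # free reference suffix: best score anywhere in the last row;
    # prefer the largest j (least reference skipped) on ties
    j = int(nr - np.argmax(D[nq, ::-1]))
    i = nq
    m = mm = ins = dele = 0
    while i > 0:
        if i > 0 and j > 0 and D[i, j] == D[i - 1, j - 1] + sub[i - 1, j - 1]:
            if sub[i - 1, j - 1] == MATCH:
                m += 1
            else:
                mm += 1
            i, j = i - 1, j - 1
        elif j > 0 and D[i, j] == D[i, j - 1] + GAP:
            dele += 1
            j -= 1
        else:
            ins += 1
            i -= 1
    return AlignmentSummary(matches=m, mismatches=mm, insertions=ins,
                            deletions=dele, alignment_length=m + mm + ins + dele)


def compute_rates(summary: AlignmentSummary) -> RateReport:
    """Percentages of each alignment event out of the alignment length."""
    L = summary.alignment_length
    if L < 1:
        raise ValueError("alignment_length must be >= 1")
    f = 100.0 / L
    return RateReport(identity_pct=summary.matches * f,
                      mismatch_pct=summary.mismatches * f,
                      insertion_pct=summary.insertions * f,
                      deletion_pct=summary.deletions * f)


def _read_records(path) -> dict:
    path = str(path)
    fmt = "fastq" if path.endswith(("fastq", "fq")) else "fasta"
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, fmt)}


def evaluate_pairs(calls: dict, truths: dict,
                   bins: Optional[Sequence[float]] = None) -> dict:
    """Score every call with a truth record; medians overall and per bin.

    Returns ``{"per_read": [...], "medians": {...}, "bin_medians": {...},
    "unmatched": [...]}``; reads lacking a truth are listed and excluded.
    """
    per_read = []
    unmatched = sorted(set(calls) - set(truths))
    for read_id in sorted(set(calls) & set(truths)):
        query, ref = calls[read_id], truths[read_id]
        if not query:   # empty call: nothing aligned, all reference deleted
            rates = RateReport(0.0, 0.0, 0.0, 100.0)
            length = len(ref)
        else:
            rates = compute_rates(align_read(query, ref))
            length = len(ref)
        per_read.append({"read_id": read_id, "length": length,
                         "identity": rates.identity_pct,
                         "mismatch": rates.mismatch_pct,
                         "insertion": rates.insertion_pct,
                         "deletion": rates.deletion_pct})

    def medians(rows):
        keys = ("identity", "mismatch", "insertion", "deletion")
        if not rows:
            return {k: float("nan") for k in keys}
        return {k: float(np.median([row[k] for row in rows])) for k in keys}

    result = {"per_read": per_read, "medians": medians(per_read),
              "unmatched": unmatched, "bin_medians": {}}
    if bins is not None:
        edges = list(bins)
        for lo, hi in zip(edges[:-1], edges[1:]):
            rows = [row for row in per_read if lo <= row["length"] < hi]
            result["bin_medians"][f"[{lo},{hi})"] = medians(rows)
    return result


def evaluate_dataset(calls_path, truth_path,
                     bins: Optional[Sequence[float]] = None) -> dict:
    """Evaluate a FASTA/FASTQ of calls against a FASTA of truths."""
    return evaluate_pairs(_read_records(calls_path), _read_records(truth_path),
                          bins=bins)
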