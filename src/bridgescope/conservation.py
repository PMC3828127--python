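"""Length filtering, redundancy removal and conservation ranking for
class-partitioned protein-family alignments.

Workflow mirrors a standard family analysis: ungapped sequences are kept
when their length lies between the family HMM model length L and L plus a
tolerance (default 100 residues); aligned sequences more than 98% identical
to an already-kept record are removed by a greedy scan; per-column
conservation is the modal-residue frequency over non-gap rows, ranked
descending with ties broken by column index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "Alignment",
    "FilterReport",
    "read_fasta_alignment",
    "length_filter",
    "redundancy_filter",
    "pairwise_identity",
    "conservation_rank",
]

log = logging.getLogger(__name__)

GAP_CHARS = ("-", ".")


@dataclass
class Alignment:
    """Gapped records of one chemotaxis class (e.g. F1 or F7)."""

    records: list[tuple[str, str]]
    class_label: str = ""

    def __post_init__(self):
        lengths = {len(s) for _, s in self.records}
        if len(lengths) > 1:
            raise ValueError(f"aligned sequences differ in length: {sorted(lengths)}")

    @property
    def n_columns(self) -> int:
        return len(self.records[0][1]) if self.records else 0


@dataclass
class FilterReport:
    """Accounting of a filtering pass; input = discarded + kept always."""

    n_input: int
    n_length_discarded: int
    n_redundant_discarded: int
    n_kept: int
    model_length: int = 0
    max_excess: int = 100
    identity_threshold: float = 0.98

    def __post_init__(self):
        if self.n_input != self.n_length_discarded + self.n_redundant_discarded + self.n_kept:
            raise ValueError("filter accounting identity violated")


def read_fasta_alignment(path: str | Path, class_label: str = "") -> Alignment:
    """Read a gapped FASTA alignment (Bio.SeqIO) into an :class:`Alignment`."""
    from Bio import SeqIO

    records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    return Alignment(records=records, class_label=class_label)


def _ungapped_length(seq: str) -> int:
    return sum(1 for c in seq if c not in GAP_CHARS)


def length_filter(
    records: list[tuple[str, str]], model_length: int, max_excess: int = 100
) -> tuple[list[tuple[str, str]], FilterReport]:
    """Keep sequences with model_length ≤ ungapped length ≤ model_length + max_excess."""
    if model_length <= 0:
        raise ValueError("model_length must be positive")
    kept, discarded = [], 0
    for rec in records:
        n = _ungapped_length(rec[1])
        if model_length <= n <= model_length + max_excess:
            kept.append(rec)
        else:
            discarded += 1
    report = FilterReport(
        n_input=len(records), n_length_discarded=discarded,
        n_redundant_discarded=0, n_kept=len(kept),
        model_length=model_length, max_excess=max_excess,
    )
    return kept, report


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of matching residues over columns where neither is gapped.

    Pairs with no shared ungapped column have identity 0 by convention.
    """
    both = [(x, y) for x, y in zip(a, b) if x not in GAP_CHARS and y not in GAP_CHARS]
    if not both:
        return 0.0
    return sum(x == y for x, y in both) / len(both)


def redundancy_filter(
    aln: Alignment, threshold: float = 0.98, shuffle_seed: int | None = None
) -> tuple[Alignment, FilterReport]:
    """Greedy de-duplication: drop records > threshold identical to a kept one.

    The scan runs in input order (or a seeded shuffle of it); identity is
    strict — a pair at exactly the threshold keeps both records.  All-gap
    records are removed with a warning.
    """
    records = list(aln.records)
    if shuffle_seed is not None:
        rng = np.random.default_rng(shuffle_seed)
        records = [records[i] for i in rng.permutation(len(records))]
    kept: list[tuple[str, str]] = []
    n_removed = 0
    for rec in records:
        if _ungapped_length(rec[1]) == 0:
            log.warning("record %s is all gaps; removed", rec[0])
            n_removed += 1
            continue
        if any(pairwise_identity(rec[1], k[1]) > threshold for k in kept):
            n_removed += 1
        else:
            kept.append(rec)
    report = FilterReport(
        n_input=len(records), n_length_discarded=0,
        n_redundant_discarded=n_removed, n_kept=len(kept),
        identity_threshold=threshold,
    )
    return Alignment(records=kept, class_label=aln.class_label), report


def conservation_rank(
    aln: Alignment, k: int = 5
) -> list[tuple[int, str, float]]:
    """Top-k most conserved columns as (column index, consensus residue, frequency).

    Per column, frequency of the modal residue over non-gap rows; columns
    where gaps are the majority of rows are excluded; ranking is by
    descending frequency with ties broken by ascending column index.
    """
    if not aln.records:
        raise ValueError("empty alignment")
    n_rows = len(aln.records)
    scored = []
    for col in range(aln.n_columns):
        column = [seq[col] for _, seq in aln.records]
        residues = [c for c in column if c not in GAP_CHARS]
        if len(residues) <= n_rows / 2:
            continue  # gap-majority column
        values, counts = np.unique(residues, return_counts=True)
        i = int(np.argmax(counts))
        scored.append((col, str(values[i]), counts[i] / len(residues)))
    scored.sort(key=lambda t: (-t[2], t[0]))
    return scored[:k]
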