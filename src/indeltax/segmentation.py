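"""Tandem-repeat segmentation of insertions and deletions.

An InDel at a repetitive locus can be written many ways; after left
alignment the biologically meaningful description is the shortest motif
prefix ("unit") that, read 3' from the event anchor, forms the longest
uninterrupted tandem run through the InDel motif and on into the
reference context.  The segmentation of an InDel records that unit, how
many whole copies of it lie inside the InDel, and how many more follow
in the 3' flank.  These quantities drive the channel taxonomy: run
length for homopolymer slippage, copy counts for polynucleotide repeats,
and the repeat/non-repeat split that gates the microhomology division.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import NormalizedIndel

__all__ = ["Segmentation", "segment", "homopolymer_run", "microhomology"]


@dataclass(frozen=True)
class Segmentation:
    """Chosen repeat unit of an InDel and its tandem copy counts.

    Attributes
    ----------
    unit : str
        Selected motif prefix.
    unit_len : int
        ``len(unit)``.
    copies_in_indel : int
        Whole tandem copies of ``unit`` inside the InDel motif (>= 1).
    copies_in_context : int
        Additional gap-free copies continuing into the 3' reference
        context.  Only counted when the unit tiles the motif exactly;
        a non-empty remainder breaks the tandem run.
    remainder : str
        Motif suffix not covered by whole unit copies.
    """

    unit: str
    unit_len: int
    copies_in_indel: int
    copies_in_context: int
    remainder: str

    @property
    def total_copies(self) -> int:
        return self.copies_in_indel + self.copies_in_context

    def __post_init__(self) -> None:
        if self.unit_len != len(self.unit) or self.unit_len < 1:
            raise ValueError("inconsistent unit length")
        if self.copies_in_indel < 1:
            raise ValueError("unit must occur at least once in the motif")


def _leading_copies(s: str, unit: str) -> int:
    """Whole tandem copies of ``unit`` at the start of ``s``."""
    k = len(unit)
    n = 0
    i = 0
    while s[i : i + k] == unit:
        n += 1
        i += k
    return n


def _segment_strings(motif: str, flank3: str) -> Segmentation:
    best: tuple[int, int] | None = None  # (-total, unit_len) to minimise
    best_parts: tuple[int, int] | None = None
    for k in range(1, len(motif) + 1):
        unit = motif[:k]
        j = _leading_copies(motif, unit)
        # context copies continue the tandem run only when the unit tiles
        # the motif exactly; a remainder interrupts the run at the junction
        m = _leading_copies(flank3, unit) if j * k == len(motif) else 0
        key = (-(j + m), k)
        if best is None or key < best:
            best = key
            best_parts = (j, m)
    assert best is not None and best_parts is not None
    j, m = best_parts
    k = best[1]
    return Segmentation(
        unit=motif[:k],
        unit_len=k,
        copies_in_indel=j,
        copies_in_context=m,
        remainder=motif[j * k :],
    )


def segment(indel: NormalizedIndel) -> Segmentation:
    """Segment a normalized insertion or deletion.

    Every motif prefix is scored by the number of gap-free tandem copies
    it forms reading 3' from the event anchor (through the motif, then
    into ``flank3``); the shortest prefix attaining the maximum wins.

    Raises
    ------
    ValueError
        If called on a complex InDel; complex events carry separate
        inserted/deleted motifs and are never segmented.
    """
    if indel.op_class == "complex":
        raise ValueError("complex InDels are not segmented")
    return _segment_strings(indel.motif, indel.flank3)


def homopolymer_run(indel: NormalizedIndel) -> int:
    """Reference homopolymer run length for a 1 bp InDel.

    For a deletion of base ``b`` this is the length of the uninterrupted
    run of ``b`` containing the deleted base (left alignment places the
    deleted base at the 5' end of the run, so the run is the deleted
    base plus the leading ``b``s of ``flank3``; a lone base reports 1).
    For an insertion of ``b`` it is the length of the existing reference
    run 3' of the anchor (0 when the adjacent base differs).
    """
    if indel.op_class not in ("insertion", "deletion") or len(indel.motif) != 1:
        raise ValueError("homopolymer_run is defined for 1 bp insertions/deletions only")
    b = indel.motif
    run3 = 0
    for c in indel.flank3:
        if c != b:
            break
        run3 += 1
    return run3 + (1 if indel.op_class == "deletion" else 0)


def microhomology(indel: NormalizedIndel) -> tuple[int, int]:
    """Deletion length L and junction microhomology length M.

    M is the larger of the longest proper prefix of the motif equal to
    the sequence immediately 3' of the deletion and the longest proper
    suffix equal to the sequence immediately 5'.  After left alignment
    the 5' term is always zero (a match would permit a further left
    shift), so in practice M is the 3' prefix match.  0 <= M < L.

    The caller must have established that the deletion is not in a
    repeat context (``segment(indel).total_copies == 1``).
    """
    if indel.op_class != "deletion":
        raise ValueError("microhomology is defined for deletions only")
    motif = indel.motif
    L = len(motif)
    if L < 2:
        raise ValueError("microhomology requires motif length >= 2")
    if _segment_strings(motif, indel.flank3).total_copies != 1:
        raise ValueError("deletion lies in a repeat context; microhomology does not apply")
    m3 = 0
    for k in range(L - 1, 0, -1):
        if indel.flank3[:k] == motif[:k]:
            m3 = k
            break
    m5 = 0
    for k in range(L - 1, 0, -1):
        if len(indel.flank5) >= k and indel.flank5[-k:] == motif[-k:]:
            m5 = k
            break
    return L, max(m3, m5)
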