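"""Variant, reference and catalog I/O plus InDel normalization.

Internal coordinates are 0-based half-open; conversion to and from the
1-based VCF convention happens only at the file boundary.  Variants are
reduced to a canonical left-aligned, parsimonious representation before
any downstream classification so that every VCF encoding of the same
event maps to one :class:`NormalizedIndel`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

log = logging.getLogger("indeltax")

BASES = "ACGT"
#: minimum 5' / 3' flank lengths carried by a NormalizedIndel; the 3'
#: window must exceed the longest repeat tract the schemes distinguish
FLANK5 = 10
FLANK3 = 50


class NormalizationError(ValueError):
    """Raised when a variant cannot be normalized against the reference."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RawVariant:
    """A VCF-style variant record (1-based, anchor-padded alleles)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    sample_id: str = ""
    info: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise ValueError("ref and alt are identical")


@dataclass(frozen=True)
class NormalizedIndel:
    """Left-aligned, parsimonious InDel with flanking sequence.

    ``pos0`` is the 0-based coordinate of the anchor base immediately 5'
    of the inserted/deleted motif (-1 when the event abuts the contig
    start).  ``motif`` holds the inserted or deleted sequence; complex
    events carry ``ins_motif``/``del_motif`` instead and leave ``motif``
    equal to ``del_motif`` for positional bookkeeping.
    """

    chrom: str
    pos0: int
    op_class: str  # insertion | deletion | complex
    motif: str
    ins_motif: str = ""
    del_motif: str = ""
    flank5: str = ""
    flank3: str = ""
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.op_class not in ("insertion", "deletion", "complex"):
            raise ValueError(f"bad op_class {self.op_class!r}")
        if self.op_class == "complex":
            if not self.ins_motif or not self.del_motif or self.ins_motif == self.del_motif:
                raise ValueError("complex events need distinct non-empty ins/del motifs")
        elif not self.motif:
            raise ValueError("insertion/deletion motif must be non-empty")


@dataclass
class Catalog:
    """Samples x channels non-negative integer count matrix."""

    sample_ids: list[str]
    channel_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.sample_ids), len(self.channel_ids)):
            raise ValueError("counts shape does not match sample/channel ids")
        if (self.counts < 0).any():
            raise ValueError("catalog counts must be non-negative")

    @property
    def burdens(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Channels as rows, samples as columns (the on-disk layout)."""
        return pd.DataFrame(self.counts.T, index=self.channel_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Catalog":
        return cls(
            sample_ids=list(frame.columns),
            channel_ids=list(frame.index),
            counts=frame.to_numpy().T,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Catalog):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.channel_ids == other.channel_ids
            and np.array_equal(self.counts, other.counts)
        )


@dataclass(frozen=True)
class StrandAnnotation:
    """Leading/lagging replication-strand intervals (0-based half-open)."""

    intervals: tuple[tuple[str, int, int, str], ...]

    def __post_init__(self) -> None:
        by_label: dict[tuple[str, str], list[tuple[int, int]]] = {}
        for chrom, start, end, label in self.intervals:
            if label not in ("leading", "lagging"):
                raise ValueError(f"bad strand label {label!r}")
            if not 0 <= start < end:
                raise ValueError(f"bad interval [{start}, {end})")
            by_label.setdefault((chrom, label), []).append((start, end))
        for spans in by_label.values():
            spans.sort()
            for (_, e1), (s2, _) in zip(spans, spans[1:]):
                if s2 < e1:
                    raise ValueError("overlapping intervals within one strand label")

    def label_at(self, chrom: str, pos0: int) -> str | None:
        for c, s, e, lab in self.intervals:
            if c == chrom and s <= pos0 < e:
                return lab
        return None


# ---------------------------------------------------------------------------
# reference access
# ---------------------------------------------------------------------------


def fetch(reference, chrom: str, start0: int, end0: int) -> str:
    """Reference slice [start0, end0), clipped to the contig."""
    start0 = max(start0, 0)
    if isinstance(reference, dict):
        seq = reference[chrom]
        return seq[start0 : min(end0, len(seq))].upper()
    # pyfaidx.Fasta and compatible objects
    rec = reference[chrom]
    return str(rec[start0 : min(end0, len(rec))]).upper()


def contig_length(reference, chrom: str) -> int:
    if isinstance(reference, dict):
        return len(reference[chrom])
    return len(reference[chrom])


# ---------------------------------------------------------------------------
# VCF reading and call-level filters
# ---------------------------------------------------------------------------


def read_indels(
    vcf_path,
    reference=None,
    sample_filter=None,
) -> list[RawVariant]:
    """Read InDel records from a VCF into :class:`RawVariant` objects.

    Multi-allelic records are split into one variant per alternate
    allele.  Records whose REF and ALT have equal length (SNVs/MNVs) are
    excluded and tallied; symbolic or malformed alleles are skipped with
    a logged warning.  When the VCF carries genotyped samples, one
    variant is emitted per carrier sample; otherwise the file stem is
    used as the sample id.
    """
    path = str(vcf_path)
    default_sample = Path(path).name.removesuffix(".gz").removesuffix(".vcf")
    out: list[RawVariant] = []
    n_snv = n_skipped = 0
    with pysam.VariantFile(path) as vf:
        contigs = set(vf.header.contigs)
        vcf_samples = list(vf.header.samples)
        for rec in vf:
            if reference is not None:
                try:
                    contig_length(reference, rec.chrom)
                except KeyError:
                    raise NormalizationError(
                        f"contig {rec.chrom!r} missing from reference"
                    ) from None
            elif contigs and rec.chrom not in contigs:
                raise NormalizationError(f"contig {rec.chrom!r} missing from VCF header")
            info = {}
            if rec.qual is not None:
                info["QUAL"] = float(rec.qual)
            for key in ("REP", "VAF"):
                if key in rec.info:
                    val = rec.info[key]
                    info[key] = float(val[0] if isinstance(val, tuple) else val)
            for alt_idx, alt in enumerate(rec.alts or (), start=1):
                if alt is None or not set(alt) <= set(BASES) or not set(rec.ref) <= set(BASES):
                    n_skipped += 1
                    log.warning("skipping non-ACGT allele at %s:%s", rec.chrom, rec.pos)
                    continue
                if len(rec.ref) == len(alt):
                    n_snv += 1
                    continue
                carriers = [default_sample]
                if vcf_samples:
                    carriers = [
                        s
                        for s in vcf_samples
                        if alt_idx in (rec.samples[s].get("GT") or ())
                    ]
                for sample in carriers:
                    if sample_filter is not None and sample not in sample_filter:
                        continue
                    out.append(
                        RawVariant(rec.chrom, rec.pos, rec.ref, alt, sample, dict(info))
                    )
    if n_snv or n_skipped:
        log.info("read_indels: %d SNV/MNV records excluded, %d skipped", n_snv, n_skipped)
    return out


def count_vcf_mutations(vcf_path) -> tuple[int, int]:
    """Return (n_indel, n_snv) allele counts for a VCF."""
    n_indel = n_snv = 0
    with pysam.VariantFile(str(vcf_path)) as vf:
        for rec in vf:
            for alt in rec.alts or ():
                if alt is None or not set(alt) <= set(BASES):
                    continue
                if len(rec.ref) == len(alt):
                    n_snv += 1
                else:
                    n_indel += 1
    return n_indel, n_snv


def apply_call_filters(
    variants,
    min_qual: float | None = 250.0,
    max_rep: float | None = 10.0,
    min_vaf: float | None = 0.2,
) -> list[RawVariant]:
    """Caller-quality filters (QUAL >= q, REP < r, VAF >= v).

    Thresholds set to ``None`` are not applied; variants lacking an
    annotation pass that test permissively (with a logged tally).
    """
    kept: list[RawVariant] = []
    missing = 0
    for v in variants:
        ok = True
        if min_qual is not None:
            q = v.info.get("QUAL")
            if q is None:
                missing += 1
            elif q < min_qual:
                ok = False
        if ok and max_rep is not None:
            rep = v.info.get("REP")
            if rep is None:
                missing += 1
            elif rep >= max_rep:
                ok = False
        if ok and min_vaf is not None:
            vaf = v.info.get("VAF")
            if vaf is None:
                missing += 1
            elif vaf < min_vaf:
                ok = False
        if ok:
            kept.append(v)
    if missing:
        log.warning("apply_call_filters: %d absent annotations treated as pass", missing)
    return kept


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def _trim(ref: str, alt: str, start0: int) -> tuple[str, str, int]:
    """Remove shared trailing then leading bases; returns residuals and
    the 0-based start of the residual REF segment."""
    while ref and alt and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while ref and alt and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        start0 += 1
    return ref, alt, start0


def normalize(
    variant: RawVariant,
    reference,
    flank5: int = FLANK5,
    flank3: int = FLANK3,
) -> NormalizedIndel:
    """Reduce a raw variant to its canonical left-aligned form.

    Shared trailing then leading bases are trimmed; pure insertions and
    deletions are then shifted maximally 5' (rotating the motif) while
    the represented haplotype is unchanged.  Flanks are extracted from
    the reference around the final position; the 3' window grows with
    the motif so that repeat-copy bins up to their caps never saturate
    on truncated context.
    """
    start0 = variant.pos - 1
    clen = contig_length(reference, variant.chrom)
    if start0 + len(variant.ref) > clen:
        raise NormalizationError(
            f"variant {variant.chrom}:{variant.pos} {variant.ref}>{variant.alt} "
            "extends beyond the contig"
        )
    window = fetch(reference, variant.chrom, start0, start0 + len(variant.ref))
    if window != variant.ref.upper():
        raise NormalizationError(
            f"REF mismatch at {variant.chrom}:{variant.pos}: "
            f"expected {variant.ref!r}, reference has {window!r}"
        )
    ref, alt, start0 = _trim(variant.ref.upper(), variant.alt.upper(), start0)
    if not ref and not alt:
        raise NormalizationError("variant trims to nothing")

    if ref and alt:
        op, motif = "complex", ref
        ins_motif, del_motif = alt, ref
        pos0 = start0 - 1
        event_end = start0 + len(ref)
    else:
        op = "deletion" if ref else "insertion"
        motif = ref or alt
        ins_motif = del_motif = ""
        # left-align: shift while the base 5' of the event equals the
        # last motif base (rotating the motif accordingly)
        p = start0
        while p > 0:
            prev = fetch(reference, variant.chrom, p - 1, p)
            if prev != motif[-1]:
                break
            motif = prev + motif[:-1]
            p -= 1
        pos0 = p - 1
        event_end = p + (len(motif) if op == "deletion" else 0)

    f3 = max(flank3, 9 * len(motif) + 1)
    return NormalizedIndel(
        chrom=variant.chrom,
        pos0=pos0,
        op_class=op,
        motif=motif,
        ins_motif=ins_motif,
        del_motif=del_motif,
        flank5=fetch(reference, variant.chrom, pos0 + 1 - flank5, pos0 + 1),
        flank3=fetch(reference, variant.chrom, event_end, event_end + f3),
        sample_id=variant.sample_id,
    )


def normalize_all(variants, reference, **kw) -> list[NormalizedIndel]:
    return [normalize(v, reference, **kw) for v in variants]


# ---------------------------------------------------------------------------
# catalog and annotation I/O
# ---------------------------------------------------------------------------


def write_catalog(catalog: Catalog, path) -> None:
    """TSV with channels as rows (canonical order) and samples as columns."""
    frame = catalog.to_frame()
    frame.index.name = "channel"
    frame.to_csv(path, sep="\t")


def read_catalog(path, scheme=None) -> Catalog:
    """Read a catalog TSV; rows are reordered to canonical scheme order.

    When ``scheme`` is given, its channel ordering is authoritative and
    unknown channel ids are fatal; otherwise the file order is kept.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame = frame.astype(np.int64)
    if scheme is not None:
        canonical = list(scheme.channel_ids)
        unknown = sorted(set(frame.index) - set(canonical))
        if unknown:
            raise ValueError(f"unknown channel ids in catalog: {unknown}")
        frame = frame.reindex(canonical, fill_value=0)
    return Catalog.from_frame(frame)


def read_strand_bed(path) -> StrandAnnotation:
    """BED4 with the label (leading/lagging) in column 4."""
    frame = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "label"],
        dtype={"chrom": str, "start": int, "end": int, "label": str},
    )
    return StrandAnnotation(tuple(frame.itertuples(index=False, name=None)))


def write_strand_bed(annotation: StrandAnnotation, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, label in annotation.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{label}\n")
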