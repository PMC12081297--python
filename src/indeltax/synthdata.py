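"""Synthetic references, planted InDels with channel truth, and cohorts.

Every generator is deterministic under its seed.  Planted sites are
constructed so their channel assignment is known *by construction* —
guard bases prevent accidental run extension or left-shift beyond the
planted locus, repeat units are restricted to strings whose first base
does not recur within the unit (so the unit of the planted repeat is
provably the segmentation optimum), and microhomology sites carry an
explicit breaker base that pins the homology length.  Truth channel ids
are derived from these construction parameters alone, never by calling
the classifier, so an end-to-end plant -> read -> normalize -> classify
round trip is a genuine cross-check.

The VCF emitter deliberately writes denormalized encodings (random
right-shifts within repeats, shared trailing padding) to exercise the
normalization path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    Catalog,
    NormalizedIndel,
    RawVariant,
    StrandAnnotation,
    normalize,
)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_PYR = {"A": "T", "G": "C", "C": "C", "T": "T"}
_BASES = "ACGT"


def _others(*exclude: str) -> list[str]:
    return [b for b in _BASES if b not in exclude]


def _cap(n: int, cap: int) -> str:
    return str(n) if n < cap else f"{cap}+"


def _collapse(b: str, f5: str, f3: str) -> tuple[str, str, str]:
    if b in "CT":
        return b, f5, f3
    return _COMP[b], _COMP[f3], _COMP[f5]


# ---------------------------------------------------------------------------
# planted features
# ---------------------------------------------------------------------------


@dataclass
class PlantedFeature:
    """One planted site; ``core`` includes its guard/anchor bases and
    ``start0`` (filled by :func:`make_reference`) is the core start,
    which equals the anchor position of the normalized planted event."""

    kind: str
    core: str
    meta: dict = field(default_factory=dict)
    chrom: str = ""
    start0: int = -1


@dataclass
class ReferenceSpec:
    seed: int
    features: list[PlantedFeature]
    spacing: int = 10
    contig_max_len: int = 30000
    contig_prefix: str = "chr"


class UnachievableChannelError(ValueError):
    pass


def _build_motif(rng, length: int, first_exclude=(), last_exclude=()) -> str:
    """Sequence whose first base never recurs (keeps it segmentation-
    and microhomology-inert by construction)."""
    first = rng.choice(_others(*first_exclude))
    if length == 1:
        if first in last_exclude:
            first = rng.choice(_others(*(set(first_exclude) | set(last_exclude))))
        return first
    body = [str(rng.choice(_others(first))) for _ in range(length - 2)]
    last = rng.choice(_others(first, *last_exclude))
    return first + "".join(body) + last


def _site_for(req: dict, rng) -> PlantedFeature:
    """Design the planted core for one event request."""
    op = req["op"]
    if op in ("del1", "ins1"):
        b = req.get("base") or str(rng.choice(list(_BASES)))
        run = int(req["run"])
        if op == "del1" and run < 1:
            raise UnachievableChannelError("1 bp deletion requires run >= 1")
        g5 = req.get("g5") or rng.choice(_others(b))
        g3 = req.get("g3") or rng.choice(_others(b))
        if g5 == b or g3 == b:
            raise UnachievableChannelError(f"guard base equals run base in {req}")
        if run == 0:
            return PlantedFeature("nonrepetitive", g5 + g3, {"req": req, "b": b, "g5": g5, "g3": g3})
        return PlantedFeature("homopolymer", g5 + b * run + g3,
                              {"req": req, "b": b, "run": run, "g5": g5, "g3": g3})
    if op in ("del_rep", "ins_rep"):
        unit = req["unit"].upper()
        total = int(req["total_copies"])
        k = int(req.get("event_copies", 1))
        if len(unit) > 1 and unit[0] in unit[1:]:
            raise UnachievableChannelError(
                f"repeat unit {unit!r} reuses its first base; truth not constructible")
        ref_copies = total if op == "del_rep" else total - k
        if op == "del_rep" and (k > total or total < 2):
            raise UnachievableChannelError("repeat deletion needs event_copies <= total_copies >= 2")
        if ref_copies < 0 or k < 1 or k * len(unit) < 2 or total < 2:
            raise UnachievableChannelError(f"bad repeat request {req}")
        g5 = rng.choice(_others(unit[0], unit[-1]))
        g3 = rng.choice(_others(unit[0], unit[-1]))
        kind = "homopolymer" if len(unit) == 1 else "dinucleotide_repeat" if len(unit) == 2 else "unit_repeat"
        return PlantedFeature(kind, g5 + unit * ref_copies + g3,
                              {"req": req, "unit": unit, "ref_copies": ref_copies,
                               "k": k, "total": total, "g5": g5, "g3": g3})
    if op == "del_nr":
        L = int(req["length"])
        m = _build_motif(rng, L)
        g5, g3 = rng.choice(_others(m[-1])), rng.choice(_others(m[0]))
        return PlantedFeature("nonrepetitive", g5 + m + g3, {"req": req, "m": m, "g5": g5, "g3": g3})
    if op == "ins_nr":
        L = int(req["length"])
        a = str(rng.choice(list(_BASES)))
        z = str(rng.choice(list(_BASES)))
        m = _build_motif(rng, L, first_exclude=(z,), last_exclude=(a,))
        return PlantedFeature("nonrepetitive", a + z, {"req": req, "m": m, "g5": a, "g3": z})
    if op == "del_mh":
        L, M = int(req["L"]), int(req["M"])
        if not 1 <= M < L:
            raise UnachievableChannelError(f"microhomology needs 1 <= M < L, got L={L} M={M}")
        m = _build_motif(rng, L)
        g5 = rng.choice(_others(m[-1]))
        br = rng.choice(_others(m[M], m[0]))
        return PlantedFeature("mh_site", g5 + m + m[:M] + br,
                              {"req": req, "m": m, "M": M, "g5": g5, "br": br})
    if op == "complex":
        d, i = int(req["del_len"]), int(req["ins_len"])
        if d == i:
            raise UnachievableChannelError(
                "equal-length replacements are MNVs, not InDels; they are "
                "excluded at VCF reading and cannot be planted")
        D = _build_motif(rng, d)
        a = rng.choice(_others(D[-1]))
        z = rng.choice(_others(D[0]))
        ins = _build_motif(rng, i, first_exclude=(D[0], z), last_exclude=(D[-1],))
        return PlantedFeature("nonrepetitive", a + D + z,
                              {"req": req, "D": D, "I": ins, "g5": a, "g3": z})
    raise UnachievableChannelError(f"unknown request op {op!r}")


def reference_spec_for(requests: list[dict], seed: int, **kw) -> ReferenceSpec:
    """One planted feature per requested event (``count`` expands)."""
    rng = np.random.default_rng(seed)
    features = []
    for req in requests:
        for _ in range(int(req.get("count", 1))):
            features.append(_site_for(req, rng))
    return ReferenceSpec(seed=seed, features=features, **kw)


def make_reference(spec: ReferenceSpec):
    """Lay features onto contigs with random spacers; returns the
    reference dict and the positioned feature index."""
    rng = np.random.default_rng(spec.seed)
    contigs: dict[str, str] = {}
    chrom_i = 1
    parts: list[str] = []
    length = 0

    def flush():
        nonlocal chrom_i, parts, length
        if parts:
            parts.append("".join(rng.choice(list(_BASES), size=spec.spacing)))
            contigs[f"{spec.contig_prefix}{chrom_i}"] = "".join(parts)
            chrom_i += 1
            parts, length = [], 0

    for feat in spec.features:
        spacer = "".join(rng.choice(list(_BASES), size=spec.spacing))
        if length + len(spacer) + len(feat.core) > spec.contig_max_len:
            flush()
        feat.chrom = f"{spec.contig_prefix}{chrom_i}"
        parts.append(spacer)
        length += len(spacer)
        feat.start0 = length
        parts.append(feat.core)
        length += len(feat.core)
    flush()
    for feat in spec.features:
        assert contigs[feat.chrom][feat.start0 : feat.start0 + len(feat.core)] == feat.core
    return contigs, spec.features


def write_fasta(reference: dict, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in reference.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# truth channel ids (derived from construction parameters only)
# ---------------------------------------------------------------------------


def _truth_1bp(op: str, b: str, run: int, g5: str, g3: str) -> dict:
    m, f5, f3 = _collapse(b, g5, g3)
    rb = _cap(run, 9)
    short = run <= 4
    full = f"{op}1:{m}:r{rb}:{f5}{f3}" if short else f"{op}1:{m}:r{rb}"
    if op == "ins" and run == 0:
        ind89 = f"ins1:{m}:r0:3{f3}"
    elif run == 1:
        ind89 = f"{op}1:{m}:r1:5{f5}"
    else:
        ind89 = f"{op}1:{m}:r{rb}"
    if op == "del":
        cosmic = f"1:Del:{_PYR[b]}:{min(run, 6) - 1}"
    else:
        cosmic = f"1:Ins:{_PYR[b]}:{min(run, 5)}"
    return {"full476": full, "ind89": ind89, "cosmic83": cosmic}


def _truth_repeat(op: str, unit: str, total: int, k: int) -> dict:
    u = len(unit)
    ub_full = _cap(u, 5)
    if u == 1:
        mid = f"u1:{_PYR[unit]}"
    elif u == 2:
        rc = _COMP[unit[1]] + _COMP[unit[0]]
        mid = f"u2:{min(unit, rc)}"
    else:
        mid = f"u{ub_full}"
    full = f"{op}:{mid}:c{_cap(total, 9)}"
    ind89 = f"{op}:u{_cap(min(u, 3), 3)}:c{_cap(min(total, 4), 4)}"
    motif_len = k * u
    l = min(motif_len, 5)
    if op == "del":
        ctx_units = total - k
        whole = ctx_units // k  # additional whole-motif copies 3'
        if whole >= 1:
            cosmic = f"{l}:Del:R:{min(1 + whole, 6) - 1}"
        else:
            M = min(ctx_units * u, motif_len - 1)
            cosmic = f"{l}:Del:M:{min(M, 5)}" if M >= 1 else f"{l}:Del:R:0"
    else:
        ctx_units = total - k
        cosmic = f"{l}:Ins:R:{min(ctx_units // k, 5)}"
    return {"full476": full, "ind89": ind89, "cosmic83": cosmic}


def _truth_nonrep(op: str, L: int) -> dict:
    return {
        "full476": f"{op}:nr:L{_cap(L, 10)}",
        "ind89": f"{op}:nr:L{_cap(L, 6)}",
        "cosmic83": f"{min(L, 5)}:{'Del' if op == 'del' else 'Ins'}:R:0",
    }


def _truth_mh(L: int, M: int) -> dict:
    return {
        "full476": f"mh:L{_cap(L, 12)}:M{_cap(M, 9)}",
        "ind89": f"mh:L{_cap(min(L, 5), 5)}:M{_cap(min(M, 4), 4)}",
        "cosmic83": f"{min(L, 5)}:Del:M:{min(M, 5)}",
    }


def _truth_complex(D: str, ins: str) -> dict:
    d, i = len(D), len(ins)
    if d >= i:
        cosmic = f"1:Del:{_PYR[D]}:0" if d == 1 else f"{min(d, 5)}:Del:R:0"
    else:
        cosmic = f"1:Ins:{_PYR[ins]}:0" if i == 1 else f"{min(i, 5)}:Ins:R:0"
    return {
        "full476": f"complex:T{_cap(d + i, 6)}",
        "ind89": "complex",
        "cosmic83": cosmic,
    }


# ---------------------------------------------------------------------------
# VCF emission
# ---------------------------------------------------------------------------


def _emit_event(feat: PlantedFeature, reference: dict, rng) -> tuple[dict, dict]:
    """(vcf record fields, truth row) for one planted feature."""
    req = feat.meta["req"]
    op = req["op"]
    seq = reference[feat.chrom]
    s = feat.start0  # anchor/guard position
    pad = rng.random() < 0.3

    def rec(pos0: int, alt_insert: str, deleted_len: int):
        """VCF record deleting ``deleted_len`` bases after pos0 and/or
        inserting ``alt_insert`` there, anchored at pos0."""
        ref = seq[pos0 : pos0 + 1 + deleted_len]
        alt = seq[pos0] + alt_insert
        if pad:
            nxt = seq[pos0 + 1 + deleted_len]
            ref, alt = ref + nxt, alt + nxt
        return {"chrom": feat.chrom, "pos": pos0 + 1, "ref": ref, "alt": alt,
                "sample_id": req.get("sample", "S1")}

    if op in ("del1", "ins1"):
        b = feat.meta["b"]
        run = int(req["run"])
        if op == "del1":
            j = int(rng.integers(0, run))  # delete any base of the run
            record = rec(s + j, "", 1)
            motif, kind = b, "deletion"
        else:
            j = int(rng.integers(0, run + 1))
            record = rec(s + j, b, 0)
            motif, kind = b, "insertion"
        truth = _truth_1bp("del" if op == "del1" else "ins", b, run,
                           feat.meta["g5"], feat.meta["g3"])
    elif op in ("del_rep", "ins_rep"):
        unit, k = feat.meta["unit"], feat.meta["k"]
        c = feat.meta["ref_copies"]
        u = len(unit)
        if op == "del_rep":
            j = int(rng.integers(0, c - k + 1))
            record = rec(s + j * u, "", k * u)
            motif, kind = unit * k, "deletion"
        else:
            j = int(rng.integers(0, c + 1))
            record = rec(s + j * u, unit * k, 0)
            motif, kind = unit * k, "insertion"
        truth = _truth_repeat("del" if op == "del_rep" else "ins",
                              unit, feat.meta["total"], k)
    elif op == "del_nr":
        m = feat.meta["m"]
        record = rec(s, "", len(m))
        motif, kind = m, "deletion"
        truth = _truth_nonrep("del", len(m))
    elif op == "ins_nr":
        m = feat.meta["m"]
        record = rec(s, m, 0)
        motif, kind = m, "insertion"
        truth = _truth_nonrep("ins", len(m))
    elif op == "del_mh":
        m = feat.meta["m"]
        record = rec(s, "", len(m))
        motif, kind = m, "deletion"
        truth = _truth_mh(len(m), feat.meta["M"])
    elif op == "complex":
        D, ins = feat.meta["D"], feat.meta["I"]
        record = rec(s, ins, len(D))
        motif, kind = D, "complex"
        truth = _truth_complex(D, ins)
    else:  # pragma: no cover
        raise UnachievableChannelError(op)

    row = dict(record)
    row.update(
        op_class=kind, pos0=s, motif=motif,
        channel_full476=truth["full476"],
        channel_ind89=truth["ind89"],
        channel_cosmic83=truth["cosmic83"],
    )
    return record, row


def plant_indels(reference: dict, features: list[PlantedFeature], seed: int,
                 vcf_path=None) -> tuple[list[RawVariant], pd.DataFrame]:
    """Emit one (possibly denormalized) VCF record per planted feature.

    Returns the raw variants and the truth table; when ``vcf_path`` is
    given a valid single-or-multi-sample VCF 4.2 is also written.
    """
    rng = np.random.default_rng(seed)
    records, rows = [], []
    for feat in features:
        record, row = _emit_event(feat, reference, rng)
        records.append(record)
        rows.append(row)
    truth = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "sample_id", "op_class", "pos0",
                 "motif", "channel_full476", "channel_ind89", "channel_cosmic83"],
    )
    variants = [RawVariant(r["chrom"], r["pos"], r["ref"], r["alt"], r["sample_id"])
                for r in records]
    if vcf_path is not None:
        write_vcf(records, reference, vcf_path)
    return variants, truth


def write_vcf(records: list[dict], reference: dict, path) -> None:
    samples = sorted({r["sample_id"] for r in records})
    lines = ["##fileformat=VCFv4.2"]
    for name, seq in reference.items():
        lines.append(f"##contig=<ID={name},length={len(seq)}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    lines.append(header)
    order = {c: i for i, c in enumerate(reference)}
    for r in sorted(records, key=lambda r: (order[r["chrom"]], r["pos"])):
        gts = ["0/1" if s == r["sample_id"] else "0/0" for s in samples]
        lines.append(
            f"{r['chrom']}\t{r['pos']}\t.\t{r['ref']}\t{r['alt']}\t.\tPASS\t.\tGT\t"
            + "\t".join(gts)
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# fuzzed InDels for property testing
# ---------------------------------------------------------------------------


def _random_structured_sequence(rng, length: int) -> str:
    """Random sequence interleaving homopolymers, short tandem repeats
    and uniform stretches, so fuzzed InDels hit every division."""
    parts: list[str] = []
    n = 0
    while n < length:
        kind = rng.random()
        if kind < 0.35:
            b = str(rng.choice(list(_BASES)))
            run = int(rng.integers(1, 13))
            parts.append(b * run)
            n += run
        elif kind < 0.6:
            u = "".join(rng.choice(list(_BASES), size=int(rng.integers(2, 6))))
            copies = int(rng.integers(2, 8))
            parts.append(u * copies)
            n += len(u) * copies
        else:
            k = int(rng.integers(5, 20))
            parts.append("".join(rng.choice(list(_BASES), size=k)))
            n += k
    return "".join(parts)[:length]


def random_normalized_indels(n: int, seed: int, max_len: int = 12) -> list[NormalizedIndel]:
    """Fuzzed normalized InDels over a repeat-rich random reference."""
    rng = np.random.default_rng(seed)
    out: list[NormalizedIndel] = []
    contig = _random_structured_sequence(rng, 20000)
    ref = {"chrF": contig}
    margin = 200
    while len(out) < n:
        pos0 = int(rng.integers(margin, len(contig) - margin))
        r = rng.random()
        try:
            if r < 0.4:  # deletion
                L = int(rng.integers(1, max_len + 1))
                v = RawVariant("chrF", pos0 + 1, contig[pos0 : pos0 + 1 + L],
                               contig[pos0], "F")
            elif r < 0.8:  # insertion; sometimes copy local context
                L = int(rng.integers(1, max_len + 1))
                if rng.random() < 0.5:
                    ins = contig[pos0 + 1 : pos0 + 1 + L]
                else:
                    ins = "".join(rng.choice(list(_BASES), size=L))
                v = RawVariant("chrF", pos0 + 1, contig[pos0], contig[pos0] + ins, "F")
            else:  # complex
                d = int(rng.integers(1, 6))
                i = int(rng.integers(1, 6))
                ins = "".join(rng.choice(list(_BASES), size=i))
                v = RawVariant("chrF", pos0 + 1, contig[pos0 : pos0 + 1 + d],
                               contig[pos0] + ins, "F")
            norm = normalize(v, ref)
        except ValueError:
            continue
        if norm.pos0 < 0 or not norm.flank5:
            continue
        out.append(norm)
    return out


# ---------------------------------------------------------------------------
# signature-mixture catalogs and classifier cohorts
# ---------------------------------------------------------------------------


def simulate_catalogs(signatures: pd.DataFrame, exposures: pd.DataFrame,
                      seed: int) -> Catalog:
    """Multinomial catalog draws from per-sample signature mixtures.

    ``signatures`` is channels x signatures (columns sum to 1);
    ``exposures`` is samples x signatures (mutation counts attributed).
    """
    rng = np.random.default_rng(seed)
    S = signatures.to_numpy(dtype=float)
    S = S / S.sum(axis=0, keepdims=True)
    counts = np.zeros((exposures.shape[0], signatures.shape[0]), dtype=np.int64)
    for i, (_, expo) in enumerate(exposures.iterrows()):
        e = expo.reindex(signatures.columns).fillna(0.0).to_numpy(dtype=float)
        burden = int(round(e.sum()))
        if burden < 1:
            raise ValueError("per-sample exposure burden must be >= 1")
        density = S @ e
        density = density / density.sum()
        counts[i] = rng.multinomial(burden, density)
    return Catalog(list(exposures.index), list(signatures.index), counts)


#: signature names grouped by post-replicative-repair phenotype
SBS_GROUPS = {
    "MMRd": ["SBS6", "SBS15", "SBS26", "SBS44", "SBS97"],
    "Pol-dys": ["SBS10a", "SBS10d"],
    "MMRd/Pol-dys": ["SBS14", "SBS20"],
    "background": ["SBS1", "SBS5"],
}
IND_GROUPS = {
    "MMRd": ["InD7", "InD19"],
    "Pol-dys": ["InD14", "InD15"],
    "MMRd/Pol-dys": ["InD16a", "InD16b", "InD20", "InD21"],
    "background": ["InD1", "InD2a"],
}

#: class-conditional generator settings: fraction of SBS / InD exposure
#: mass on the class's own signature group, mean SNV burden, and mean
#: InDel/SNV ratio.  Defaults emulate strong, well-separated phenotypes:
#: MMRd is InDel-driven (high ratio), polymerase proofreading
#: dysfunction is substitution-driven (low ratio).
_CLASS_SETTINGS = {
    "MMRd": dict(sbs_frac=0.55, ind_frac=0.65, snv_mean=5e4, ratio_mean=0.5),
    "Pol-dys": dict(sbs_frac=0.60, ind_frac=0.50, snv_mean=2e5, ratio_mean=0.02),
    "MMRd/Pol-dys": dict(sbs_frac=0.50, ind_frac=0.55, snv_mean=1e5, ratio_mean=0.25),
    "Neg": dict(sbs_frac=0.0, ind_frac=0.0, snv_mean=5e3, ratio_mean=0.08),
}


@dataclass
class CohortSpec:
    """Labeled cohort emulating a PRRd training set: class mix defaults
    to 214 MMRd / 36 Pol-dys / 41 mixed / 280 negative out of 571."""

    seed: int
    n_samples: int = 571
    proportions: dict = field(default_factory=lambda: {
        "MMRd": 214 / 571, "Pol-dys": 36 / 571,
        "MMRd/Pol-dys": 41 / 571, "Neg": 280 / 571,
    })
    concentration: float = 150.0   # Dirichlet concentration; higher = tighter classes
    burden_sigma: float = 0.35     # lognormal dispersion of SNV burdens
    ratio_sigma: float = 0.25


def simulate_prr_cohort(spec: CohortSpec):
    """Exposure tables, mutation counts and labels for classifier work.

    Returns ``(sbs_exposures, ind_exposures, counts, labels)`` where
    exposures are samples x signatures mutation counts, ``counts`` has
    columns indel_count / snv_count and ``labels`` is a Series of the
    four phenotype classes.
    """
    rng = np.random.default_rng(spec.seed)
    classes = list(spec.proportions)
    n_per = {c: int(round(spec.proportions[c] * spec.n_samples)) for c in classes}
    while sum(n_per.values()) < spec.n_samples:
        n_per[classes[0]] += 1
    while sum(n_per.values()) > spec.n_samples:
        n_per[max(n_per, key=n_per.get)] -= 1

    sbs_cols = [s for g in SBS_GROUPS.values() for s in g]
    ind_cols = [s for g in IND_GROUPS.values() for s in g]
    rows_sbs, rows_ind, rows_cnt, labels, sample_ids = [], [], [], [], []
    i = 0
    for cls in classes:
        cfg = _CLASS_SETTINGS[cls]
        for _ in range(n_per[cls]):
            sid = f"G{i:04d}"
            i += 1
            snv = float(np.exp(rng.normal(np.log(cfg["snv_mean"]), spec.burden_sigma)))
            ratio = float(np.exp(rng.normal(np.log(cfg["ratio_mean"]), spec.ratio_sigma)))
            indel = max(1.0, snv * ratio)

            def mixture(groups, own_frac):
                base = {}
                for g, names in groups.items():
                    if g == "background":
                        share = 1.0 - own_frac
                    elif g == cls:
                        share = own_frac
                    else:
                        share = 0.0
                    for nm in names:
                        base[nm] = max(share / len(names), 1e-4)
                cols = list(base)
                alpha = np.array([base[c] for c in cols]) * spec.concentration
                frac = rng.dirichlet(alpha)
                return dict(zip(cols, frac))

            sbs_frac = mixture(SBS_GROUPS, cfg["sbs_frac"])
            ind_frac = mixture(IND_GROUPS, cfg["ind_frac"])
            rows_sbs.append({c: sbs_frac[c] * snv for c in sbs_cols})
            rows_ind.append({c: ind_frac[c] * indel for c in ind_cols})
            rows_cnt.append({"indel_count": int(round(indel)), "snv_count": int(round(snv))})
            labels.append(cls)
            sample_ids.append(sid)

    sbs = pd.DataFrame(rows_sbs, index=sample_ids)[sbs_cols]
    ind = pd.DataFrame(rows_ind, index=sample_ids)[ind_cols]
    cnt = pd.DataFrame(rows_cnt, index=sample_ids)
    return sbs, ind, cnt, pd.Series(labels, index=sample_ids, name="label")


def default_truth_requests(per_channel: int = 1) -> list[dict]:
    """Event requests covering every channel of the 89-channel scheme
    (and thereby every division of all three schemes), with a mix of
    pyrimidine- and purine-strand encodings for 1 bp events."""
    reqs: list[dict] = []

    def add(req: dict) -> None:
        req = dict(req)
        req["count"] = per_channel
        reqs.append(req)

    for m in "CT":
        for f3 in _others(m):
            add({"op": "ins1", "base": m, "run": 0, "g3": f3})
        for f5 in _others(m):
            add({"op": "ins1", "base": m, "run": 1, "g5": f5})
            add({"op": "del1", "base": m, "run": 1, "g5": f5})
        for run in range(2, 11):
            add({"op": "ins1", "base": m, "run": run})
            add({"op": "del1", "base": m, "run": run})
    # purine-strand encodings exercising the pyrimidine collapse
    for b in "AG":
        add({"op": "ins1", "base": b, "run": 0})
        add({"op": "ins1", "base": b, "run": 1})
        add({"op": "del1", "base": b, "run": 6})
    for unit in ("T", "CA", "GAT"):
        for total in (2, 3, 4, 5):
            k = max(1, 2 // len(unit))  # event motif >= 2 bp
            if k <= total:
                add({"op": "del_rep", "unit": unit, "total_copies": total, "event_copies": k})
            if total - k >= 0:
                add({"op": "ins_rep", "unit": unit, "total_copies": total, "event_copies": k})
    for unit in ("CTAG", "CATTG"):  # unit lengths 4 and 5 fold into the 3+ bins
        add({"op": "del_rep", "unit": unit, "total_copies": 3, "event_copies": 1})
        add({"op": "ins_rep", "unit": unit, "total_copies": 3, "event_copies": 1})
    for L in range(2, 8):
        add({"op": "del_nr", "length": L})
        add({"op": "ins_nr", "length": L})
    for L in range(2, 8):
        for M in range(1, min(L, 6)):
            add({"op": "del_mh", "L": L, "M": M})
    for d, i in ((1, 2), (2, 1), (2, 3), (3, 2), (4, 2), (2, 5), (1, 4)):
        add({"op": "complex", "del_len": d, "ins_len": i})
    return reqs


def simulate_strand_annotation(reference: dict, block_size: int, seed: int) -> StrandAnnotation:
    """Alternating leading/lagging blocks tiling each contig."""
    rng = np.random.default_rng(seed)
    intervals = []
    labels = ("leading", "lagging")
    for chrom, seq in reference.items():
        flip = int(rng.integers(0, 2))
        for j, start in enumerate(range(0, len(seq), block_size)):
            end = min(start + block_size, len(seq))
            intervals.append((chrom, start, end, labels[(j + flip) % 2]))
    return StrandAnnotation(tuple(intervals))
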