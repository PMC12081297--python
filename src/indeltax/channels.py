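"""InDel channel schemes: full 476, consolidated 89, legacy COSMIC-83.

The taxonomy first splits InDels into six divisions — 1 bp insertions,
1 bp deletions, >=2 bp insertions, >=2 bp deletions, >=2 bp deletions
with junction microhomology, and complex InDels — then bins within each
division on pyrimidine-collapsed motif content, homopolymer run length,
flanking bases (short runs only), repeat-unit length and tandem copy
counts from segmentation, and deletion-length x microhomology-length.

The full scheme enumerates 476 non-overlapping channels; the shipped
canonical merge map coarsens it to the 89-channel production scheme.
Because the exact published channel tables are supplementary assets, the
definitions here are a versioned reconstruction from the documented
design of the taxonomy; the asset TSVs under ``indeltax/data`` are
generated from this module and are the single source of truth for
channel ordering.

Routing precedence is complex > microhomology > repeat: a deletion in a
repeat context (total tandem copies > 1) is a slippage deletion even if
its junction shows homology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import Catalog, NormalizedIndel, RawVariant, normalize
from .segmentation import homopolymer_run, microhomology, segment

__all__ = [
    "ChannelDef",
    "ChannelScheme",
    "ClassificationError",
    "build_full_scheme",
    "build_ind89_scheme",
    "build_cosmic83_scheme",
    "get_scheme",
    "canonical_merge_map",
    "apply_merge_map",
    "consolidate",
    "classify",
    "classify_cosmic83",
    "build_catalog",
]

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_PYR = {"A": "T", "G": "C", "C": "C", "T": "T"}

DIVISIONS = ("ins1bp", "del1bp", "ins_ge2bp", "del_ge2bp", "del_mh", "complex")

#: dinucleotide repeat units collapsed by reverse complement
_DINUC_CLASSES = ("AC", "AG", "AT", "CA", "CG", "GA", "GC", "TA")


class ClassificationError(ValueError):
    """An InDel lacks the flanking context a channel lookup requires."""


@dataclass(frozen=True)
class ChannelDef:
    channel_id: str
    division: str
    motif_class: str = ""
    run_bin: str = ""      # homopolymer run, repeat-copy or total-length bin
    flank5: str = ""       # 5' base constraint (short-run 1 bp channels)
    flank3: str = ""       # 3'-adjacent / after-run base constraint
    L_bin: str = ""        # deletion length bin (del_mh, non-repeat)
    M_bin: str = ""        # microhomology length bin (del_mh)
    order_index: int = 0


@dataclass
class ChannelScheme:
    """Ordered channel definitions with a total classification function."""

    name: str
    channels: list[ChannelDef]
    classify_fn: object = field(repr=False)

    def __post_init__(self) -> None:
        ids = [c.channel_id for c in self.channels]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate channel ids in scheme {self.name}")
        self._index = {cid: i for i, cid in enumerate(ids)}

    @property
    def channel_ids(self) -> list[str]:
        return [c.channel_id for c in self.channels]

    @property
    def divisions(self) -> list[str]:
        seen: list[str] = []
        for c in self.channels:
            if c.division not in seen:
                seen.append(c.division)
        return seen

    def __len__(self) -> int:
        return len(self.channels)

    def index_of(self, channel_id: str) -> int:
        return self._index[channel_id]

    def classify(self, indel: NormalizedIndel) -> str:
        cid = self.classify_fn(indel)
        if cid not in self._index:
            raise AssertionError(
                f"scheme {self.name} produced unknown channel {cid!r}; "
                "this indicates a scheme bug"
            )
        return cid


def _cap(n: int, cap: int) -> str:
    return str(n) if n < cap else f"{cap}+"


def _collapse_1bp(base: str, f5: str, f3: str) -> tuple[str, str, str]:
    """Report a 1 bp InDel on the strand where the motif is a pyrimidine.

    Purine motifs are reverse-complemented, which swaps and complements
    the two flanking features.
    """
    if base in "CT":
        return base, f5, f3
    return _COMP[base], _COMP[f3] if f3 else "", _COMP[f5] if f5 else ""


def _features_1bp(indel: NormalizedIndel, need_flanks: bool):
    """(pyrimidine base, run, collapsed 5' base, collapsed 3'/after base)."""
    base = indel.motif
    run = homopolymer_run(indel)
    if not need_flanks:
        return _PYR[base], run, "", ""
    if not indel.flank5:
        raise ClassificationError(f"no 5' flank at {indel.chrom}:{indel.pos0}")
    # index of the base just 3' of the existing run of `base`
    after_idx = run if indel.op_class == "insertion" else run - 1
    if after_idx >= len(indel.flank3):
        raise ClassificationError(f"3' flank too short at {indel.chrom}:{indel.pos0}")
    b, f5, f3 = _collapse_1bp(base, indel.flank5[-1], indel.flank3[after_idx])
    if f5 not in "ACGT" or f3 not in "ACGT":
        raise ClassificationError(f"non-ACGT flank at {indel.chrom}:{indel.pos0}")
    return b, run, f5, f3


def _unit_class(unit: str) -> str:
    """Content class of a repeat unit: C/T for 1 bp (pyrimidine strand),
    reverse-complement-collapsed dinucleotide for 2 bp, none beyond."""
    if len(unit) == 1:
        return _PYR[unit]
    if len(unit) == 2:
        rc = _COMP[unit[1]] + _COMP[unit[0]]
        return min(unit, rc)
    return ""


# ---------------------------------------------------------------------------
# full 476-channel scheme
# ---------------------------------------------------------------------------

_FULL_FLANK_RUN_CAP = 4   # flank-pair sub-channels at runs <= 4
_FULL_RUN_CAP = 9         # per-length run bins, 9 meaning >=9
_FULL_COPY_CAP = 9        # repeat-copy bins 2..8, 9+
_FULL_NR_L_CAP = 10       # non-repeat length bins 2..9, 10+
_FULL_MH_L_CAP = 12       # microhomology length bins 2..11, 12+
_FULL_MH_M_CAP = 9
_FULL_CPX_CAP = 6         # complex total-length bins 2..5, 6+


def _others(base: str) -> list[str]:
    return [b for b in "ACGT" if b != base]


def _classify_full(indel: NormalizedIndel) -> str:
    if indel.op_class == "complex":
        t = len(indel.ins_motif) + len(indel.del_motif)
        return f"complex:T{_cap(t, _FULL_CPX_CAP)}"
    op = "ins" if indel.op_class == "insertion" else "del"
    if len(indel.motif) == 1:
        need = homopolymer_run(indel) <= _FULL_FLANK_RUN_CAP
        m, run, f5, f3 = _features_1bp(indel, need_flanks=need)
        rb = _cap(run, _FULL_RUN_CAP)
        if need:
            return f"{op}1:{m}:r{rb}:{f5}{f3}"
        return f"{op}1:{m}:r{rb}"
    seg = segment(indel)
    if seg.total_copies >= 2:
        ub = _cap(seg.unit_len, 5)
        cls = _unit_class(seg.unit)
        cb = _cap(seg.total_copies, _FULL_COPY_CAP)
        if cls:
            return f"{op}:u{ub}:{cls}:c{cb}"
        return f"{op}:u{ub}:c{cb}"
    if indel.op_class == "deletion":
        L, M = microhomology(indel)
        if M >= 1:
            return f"mh:L{_cap(L, _FULL_MH_L_CAP)}:M{_cap(M, _FULL_MH_M_CAP)}"
    return f"{op}:nr:L{_cap(len(indel.motif), _FULL_NR_L_CAP)}"


def _enumerate_full() -> list[ChannelDef]:
    defs: list[ChannelDef] = []

    def add(**kw) -> None:
        defs.append(ChannelDef(order_index=len(defs), **kw))

    for op, div in (("ins", "ins1bp"), ("del", "del1bp")):
        for m in "CT":
            runs = range(0, 10) if op == "ins" else range(1, 10)
            for run in runs:
                rb = _cap(run, _FULL_RUN_CAP)
                if run <= _FULL_FLANK_RUN_CAP:
                    for f5 in _others(m):
                        for f3 in _others(m):
                            add(
                                channel_id=f"{op}1:{m}:r{rb}:{f5}{f3}",
                                division=div, motif_class=m, run_bin=rb,
                                flank5=f5, flank3=f3,
                            )
                else:
                    add(channel_id=f"{op}1:{m}:r{rb}", division=div,
                        motif_class=m, run_bin=rb)
    for op, div in (("ins", "ins_ge2bp"), ("del", "del_ge2bp")):
        unit_groups = (
            [("1", c) for c in "CT"]
            + [("2", c) for c in _DINUC_CLASSES]
            + [("3", ""), ("4", ""), ("5+", "")]
        )
        for ub, cls in unit_groups:
            for cp in range(2, _FULL_COPY_CAP + 1):
                cb = _cap(cp, _FULL_COPY_CAP)
                mid = f"u{ub}:{cls}" if cls else f"u{ub}"
                add(channel_id=f"{op}:{mid}:c{cb}", division=div,
                    motif_class=f"u{ub}" + (f":{cls}" if cls else ""), run_bin=cb)
        for L in range(2, _FULL_NR_L_CAP + 1):
            lb = _cap(L, _FULL_NR_L_CAP)
            add(channel_id=f"{op}:nr:L{lb}", division=div,
                motif_class="nr", L_bin=lb)
    for L in range(2, _FULL_MH_L_CAP + 1):
        lb = _cap(L, _FULL_MH_L_CAP)
        for M in range(1, min(L - 1, _FULL_MH_M_CAP) + 1):
            mb = _cap(M, _FULL_MH_M_CAP)
            add(channel_id=f"mh:L{lb}:M{mb}", division="del_mh",
                L_bin=lb, M_bin=mb)
    for t in range(2, _FULL_CPX_CAP + 1):
        tb = _cap(t, _FULL_CPX_CAP)
        add(channel_id=f"complex:T{tb}", division="complex", run_bin=tb)
    return defs


def build_full_scheme() -> ChannelScheme:
    scheme = ChannelScheme("full476", _enumerate_full(), _classify_full)
    if len(scheme) != 476:
        raise AssertionError(f"full scheme enumerates {len(scheme)} channels, expected 476")
    return scheme


# ---------------------------------------------------------------------------
# consolidated 89-channel scheme
# ---------------------------------------------------------------------------

_IND89_RUN_CAP = 9
_IND89_UNIT_CAP = 3
_IND89_COPY_CAP = 4
_IND89_NR_L_CAP = 6
_IND89_MH_L_CAP = 5
_IND89_MH_M_CAP = 4


def _classify_ind89(indel: NormalizedIndel) -> str:
    if indel.op_class == "complex":
        return "complex"
    op = "ins" if indel.op_class == "insertion" else "del"
    if len(indel.motif) == 1:
        run = homopolymer_run(indel)
        need = (op == "ins" and run <= 1) or (op == "del" and run == 1)
        m, run, f5, f3 = _features_1bp(indel, need_flanks=need)
        rb = _cap(run, _IND89_RUN_CAP)
        if op == "ins" and run == 0:
            return f"ins1:{m}:r0:3{f3}"
        if run == 1:
            return f"{op}1:{m}:r1:5{f5}"
        return f"{op}1:{m}:r{rb}"
    seg = segment(indel)
    if seg.total_copies >= 2:
        ub = _cap(seg.unit_len, _IND89_UNIT_CAP)
        cb = _cap(seg.total_copies, _IND89_COPY_CAP)
        return f"{op}:u{ub}:c{cb}"
    if indel.op_class == "deletion":
        L, M = microhomology(indel)
        if M >= 1:
            return f"mh:L{_cap(L, _IND89_MH_L_CAP)}:M{_cap(M, _IND89_MH_M_CAP)}"
    return f"{op}:nr:L{_cap(len(indel.motif), _IND89_NR_L_CAP)}"


def _enumerate_ind89() -> list[ChannelDef]:
    defs: list[ChannelDef] = []

    def add(**kw) -> None:
        defs.append(ChannelDef(order_index=len(defs), **kw))

    for op, div in (("ins", "ins1bp"), ("del", "del1bp")):
        for m in "CT":
            if op == "ins":
                for f3 in _others(m):
                    add(channel_id=f"ins1:{m}:r0:3{f3}", division=div,
                        motif_class=m, run_bin="0", flank3=f3)
            for f5 in _others(m):
                add(channel_id=f"{op}1:{m}:r1:5{f5}", division=div,
                    motif_class=m, run_bin="1", flank5=f5)
            for run in range(2, _IND89_RUN_CAP + 1):
                rb = _cap(run, _IND89_RUN_CAP)
                add(channel_id=f"{op}1:{m}:r{rb}", division=div,
                    motif_class=m, run_bin=rb)
    for op, div in (("ins", "ins_ge2bp"), ("del", "del_ge2bp")):
        for u in range(1, _IND89_UNIT_CAP + 1):
            ub = _cap(u, _IND89_UNIT_CAP)
            for cp in range(2, _IND89_COPY_CAP + 1):
                cb = _cap(cp, _IND89_COPY_CAP)
                add(channel_id=f"{op}:u{ub}:c{cb}", division=div,
                    motif_class=f"u{ub}", run_bin=cb)
        for L in range(2, _IND89_NR_L_CAP + 1):
            lb = _cap(L, _IND89_NR_L_CAP)
            add(channel_id=f"{op}:nr:L{lb}", division=div,
                motif_class="nr", L_bin=lb)
    for L in range(2, _IND89_MH_L_CAP + 1):
        lb = _cap(L, _IND89_MH_L_CAP)
        for M in range(1, min(L - 1, _IND89_MH_M_CAP) + 1):
            mb = _cap(M, _IND89_MH_M_CAP)
            add(channel_id=f"mh:L{lb}:M{mb}", division="del_mh",
                L_bin=lb, M_bin=mb)
    add(channel_id="complex", division="complex")
    return defs


def build_ind89_scheme() -> ChannelScheme:
    scheme = ChannelScheme("ind89", _enumerate_ind89(), _classify_ind89)
    if len(scheme) != 89:
        raise AssertionError(f"ind89 enumerates {len(scheme)} channels, expected 89")
    if len(scheme.divisions) != 6:
        raise AssertionError("ind89 must span exactly 6 divisions")
    return scheme


# ---------------------------------------------------------------------------
# canonical merge map and data-driven consolidation
# ---------------------------------------------------------------------------


def _ind89_parent(cdef: ChannelDef) -> str:
    """The ind89 channel a full476 channel aggregates into."""
    div = cdef.division
    if div == "complex":
        return "complex"
    if div in ("ins1bp", "del1bp"):
        op = "ins" if div == "ins1bp" else "del"
        m, rb = cdef.motif_class, cdef.run_bin
        if op == "ins" and rb == "0":
            return f"ins1:{m}:r0:3{cdef.flank3}"
        if rb == "1":
            return f"{op}1:{m}:r1:5{cdef.flank5}"
        return f"{op}1:{m}:r{rb}"
    if div == "del_mh":
        L = _FULL_MH_L_CAP if cdef.L_bin.endswith("+") else int(cdef.L_bin)
        M = _FULL_MH_M_CAP if cdef.M_bin.endswith("+") else int(cdef.M_bin)
        return f"mh:L{_cap(min(L, _IND89_MH_L_CAP), _IND89_MH_L_CAP)}:" \
               f"M{_cap(min(M, _IND89_MH_M_CAP), _IND89_MH_M_CAP)}"
    op = "ins" if div == "ins_ge2bp" else "del"
    if cdef.motif_class == "nr":
        L = _FULL_NR_L_CAP if cdef.L_bin.endswith("+") else int(cdef.L_bin)
        return f"{op}:nr:L{_cap(min(L, _IND89_NR_L_CAP), _IND89_NR_L_CAP)}"
    u = cdef.motif_class.split(":")[0].removeprefix("u")
    u = 5 if u.endswith("+") else int(u)
    cp = _FULL_COPY_CAP if cdef.run_bin.endswith("+") else int(cdef.run_bin)
    return f"{op}:u{_cap(min(u, _IND89_UNIT_CAP), _IND89_UNIT_CAP)}:" \
           f"c{_cap(min(cp, _IND89_COPY_CAP), _IND89_COPY_CAP)}"


def canonical_merge_map(full_scheme: ChannelScheme | None = None) -> dict[str, str]:
    """Mapping full476 channel id -> ind89 channel id."""
    full_scheme = full_scheme or build_full_scheme()
    return {c.channel_id: _ind89_parent(c) for c in full_scheme.channels}


def apply_merge_map(
    full_scheme: ChannelScheme, mapping: dict[str, str], name: str = "merged"
) -> ChannelScheme:
    """Derive a coarse scheme by pushing full channels through ``mapping``."""
    order: list[str] = []
    parents: dict[str, ChannelDef] = {}
    for c in full_scheme.channels:
        tgt = mapping[c.channel_id]
        if tgt not in parents:
            parents[tgt] = c
            order.append(tgt)
    channels = [
        ChannelDef(channel_id=t, division=parents[t].division, order_index=i)
        for i, t in enumerate(order)
    ]

    def classify_fn(indel, _full=full_scheme, _map=mapping):
        return _map[_full.classify_fn(indel)]

    return ChannelScheme(name, channels, classify_fn)


def merge_catalog(catalog: Catalog, mapping: dict[str, str], target: ChannelScheme) -> Catalog:
    """Aggregate a full-scheme catalog through a merge map."""
    counts = np.zeros((len(catalog.sample_ids), len(target)), dtype=np.int64)
    for j, cid in enumerate(catalog.channel_ids):
        counts[:, target.index_of(mapping[cid])] += catalog.counts[:, j]
    return Catalog(list(catalog.sample_ids), target.channel_ids, counts)


def consolidate(
    full: ChannelScheme,
    cohort_catalog: Catalog,
    zero_drop: bool = True,
    low_signal_fraction: float = 0.0,
) -> tuple[ChannelScheme, dict[str, str]]:
    """Data-driven consolidation of a full scheme against a cohort.

    Channels with no cohort signal are dropped and channels below
    ``low_signal_fraction`` of the total signal are merged into their
    nearest parent aggregate (the canonical coarser bin in the same
    division).  Returns the consolidated scheme and the full -> merged
    channel mapping.  Applying :func:`canonical_merge_map` instead of a
    data-driven one reproduces the 89-channel scheme exactly.
    """
    if list(cohort_catalog.channel_ids) != full.channel_ids:
        raise ValueError("cohort catalog is not expressed in the full scheme")
    totals = cohort_catalog.counts.sum(axis=0).astype(float)
    grand = totals.sum()
    frac = totals / grand if grand > 0 else totals
    mapping: dict[str, str] = {}
    for c, f in zip(full.channels, frac):
        low = f < low_signal_fraction or (zero_drop and f == 0.0)
        mapping[c.channel_id] = _ind89_parent(c) if low else c.channel_id
    merged = apply_merge_map(full, mapping, name="consolidated")
    per_div = {d: sum(1 for c in merged.channels if c.division == d) for d in merged.divisions}
    if any(n < 2 for d, n in per_div.items() if d != "complex"):
        raise ValueError(f"consolidation threshold leaves a division with <2 channels: {per_div}")
    return merged, mapping


# ---------------------------------------------------------------------------
# legacy COSMIC-83 scheme
# ---------------------------------------------------------------------------


def _leading_copies(s: str, unit: str) -> int:
    k, n, i = len(unit), 0, 0
    while s[i : i + k] == unit:
        n += 1
        i += k
    return n


def _cosmic_1bp(op: str, base: str, run: int) -> str:
    m = _PYR[base]
    if op == "del":
        return f"1:Del:{m}:{min(run, 6) - 1}"
    return f"1:Ins:{m}:{min(run, 5)}"


def _cosmic_ge2(op: str, motif: str, flank5: str, flank3: str) -> str:
    l = min(len(motif), 5)
    if op == "ins":
        return f"{l}:Ins:R:{min(_leading_copies(flank3, motif), 5)}"
    total = 1 + _leading_copies(flank3, motif)
    if total >= 2:
        return f"{l}:Del:R:{min(total, 6) - 1}"
    M = 0
    for k in range(len(motif) - 1, 0, -1):
        if flank3[:k] == motif[:k] or (len(flank5) >= k and flank5[-k:] == motif[-k:]):
            M = k
            break
    if M >= 1:
        return f"{l}:Del:M:{min(M, 5)}"
    return f"{l}:Del:R:0"


def _classify_cosmic83(indel: NormalizedIndel) -> str:
    """PCAWG/COSMIC ID-83 assignment (SigProfiler-style channel ids).

    The legacy scheme has no complex division; complex InDels are routed
    by their larger component (the deletion on ties) so that the
    function stays total.
    """
    if indel.op_class == "complex":
        if len(indel.del_motif) >= len(indel.ins_motif):
            op, motif = "del", indel.del_motif
        else:
            op, motif = "ins", indel.ins_motif
    else:
        op = "ins" if indel.op_class == "insertion" else "del"
        motif = indel.motif
    if len(motif) == 1:
        run = _leading_copies(indel.flank3, motif) + (1 if op == "del" else 0)
        return _cosmic_1bp(op, motif, run)
    return _cosmic_ge2(op, motif, indel.flank5, indel.flank3)


def _enumerate_cosmic83() -> list[ChannelDef]:
    defs: list[ChannelDef] = []

    def add(cid: str, div: str, **kw) -> None:
        defs.append(ChannelDef(channel_id=cid, division=div, order_index=len(defs), **kw))

    for op, div in (("Del", "del1bp"), ("Ins", "ins1bp")):
        for m in "CT":
            for s in range(6):
                add(f"1:{op}:{m}:{s}", div, motif_class=m, run_bin=str(s))
    for op, div in (("Del", "del_ge2bp"), ("Ins", "ins_ge2bp")):
        for l in range(2, 6):
            for s in range(6):
                add(f"{l}:{op}:R:{s}", div, L_bin=str(l), run_bin=str(s))
    for l, m_max in ((2, 1), (3, 2), (4, 3), (5, 5)):
        for M in range(1, m_max + 1):
            add(f"{l}:Del:M:{M}", "del_mh", L_bin=str(l), M_bin=str(M))
    return defs


def build_cosmic83_scheme() -> ChannelScheme:
    scheme = ChannelScheme("cosmic83", _enumerate_cosmic83(), _classify_cosmic83)
    if len(scheme) != 83:
        raise AssertionError(f"cosmic83 enumerates {len(scheme)} channels, expected 83")
    return scheme


# ---------------------------------------------------------------------------
# public helpers
# ---------------------------------------------------------------------------

_BUILDERS = {
    "full476": build_full_scheme,
    "ind89": build_ind89_scheme,
    "cosmic83": build_cosmic83_scheme,
}

#: version tag of the reconstructed channel definition assets
ASSET_VERSION = "reconstructed-1.0"


def scheme_table(scheme: ChannelScheme) -> "pd.DataFrame":
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "channel_id": c.channel_id, "division": c.division,
                "motif_class": c.motif_class, "run_bin": c.run_bin,
                "flank5": c.flank5, "flank3": c.flank3,
                "L_bin": c.L_bin, "M_bin": c.M_bin,
                "order_index": c.order_index,
            }
            for c in scheme.channels
        ]
    )


def write_channel_assets(directory) -> None:
    """Write the versioned channel-definition TSVs (one per scheme plus
    the canonical full476 -> ind89 merge map)."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    full = build_full_scheme()
    for name in _BUILDERS:
        scheme = get_scheme(name)
        path = directory / f"channels_{name}.tsv"
        with open(path, "w") as fh:
            fh.write(f"# indeltax channel asset {name} version {ASSET_VERSION}\n")
            scheme_table(scheme).to_csv(fh, sep="\t", index=False)
    mm = canonical_merge_map(full)
    with open(directory / "merge_full476_to_ind89.tsv", "w") as fh:
        fh.write(f"# indeltax canonical merge map version {ASSET_VERSION}\n")
        fh.write("full476_channel\tind89_channel\n")
        for src, dst in mm.items():
            fh.write(f"{src}\t{dst}\n")


def get_scheme(name: str) -> ChannelScheme:
    try:
        return _BUILDERS[name]()
    except KeyError:
        raise ValueError(f"unknown scheme {name!r}; choose from {sorted(_BUILDERS)}") from None


def classify(indel: NormalizedIndel, scheme: ChannelScheme) -> str:
    """Assign an InDel to exactly one channel of ``scheme``."""
    return scheme.classify(indel)


def classify_cosmic83(indel: NormalizedIndel) -> str:
    return _classify_cosmic83(indel)


def build_catalog(
    variants,
    reference=None,
    scheme: ChannelScheme | None = None,
    sample_ids: list[str] | None = None,
) -> Catalog:
    """Count classified InDels per sample per channel.

    ``variants`` may be raw (normalized here against ``reference``) or
    already-normalized InDels.  Duplicates are counted as given — no
    deduplication happens at this layer.
    """
    if scheme is None:
        scheme = build_ind89_scheme()
    normed: list[NormalizedIndel] = []
    for v in variants:
        if isinstance(v, RawVariant):
            if reference is None:
                raise ValueError("raw variants require a reference")
            v = normalize(v, reference)
        normed.append(v)
    if sample_ids is None:
        sample_ids = sorted({v.sample_id for v in normed})
    row = {s: i for i, s in enumerate(sample_ids)}
    counts = np.zeros((len(sample_ids), len(scheme)), dtype=np.int64)
    for v in normed:
        counts[row[v.sample_id], scheme.index_of(scheme.classify(v))] += 1
    return Catalog(list(sample_ids), scheme.channel_ids, counts)
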