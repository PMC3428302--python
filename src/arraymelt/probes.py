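"""Probe-set constructors, naming, linkers, and duplex derivation.

Probes are written 5'->3' and are reverse complements of their target site,
whose coordinates are 1-based and inclusive on the sense strand of the
target gene.  Names follow the convention
``<target><start>-<end>[_<annotation>...]`` where a substitution annotation
is ``<probe position><original base><new base>`` (e.g. ``E1013-1034_10AC``),
a deletion is ``gap<position>`` and an insertion is ``I<position><base>``
(inserted after that probe position).  The parser also accepts the
typographic en-dash between coordinates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import edlib

from .parameters import (
    BASES,
    InvalidInputError,
    InvalidSequenceError,
    check_sequence,
    complement,
    is_watson_crick,
    revcomp,
)
from .thermo import (
    MISMATCH,
    PROBE_BULGE,
    TARGET_BULGE,
    WC,
    DuplexConformation,
    PairEvent,
    minimize_conformation,
)

POLY_T_LINKER = "T" * 20

MISMATCH_SET_NAMES = ("OneM", "PosM", "Gap", "Insertion", "TwoM", "Tandem")


class Annotation(NamedTuple):
    """A single probe modification relative to the perfect-match tile."""

    kind: str  # "sub" | "gap" | "ins"
    pos: int  # 1-based position from the probe 5' end
    orig: str | None = None  # original probe base (sub, gap)
    new: str | None = None  # new/inserted probe base (sub, ins)

    def segment(self) -> str:
        if self.kind == "sub":
            return f"{self.pos}{self.orig}{self.new}"
        if self.kind == "gap":
            return f"gap{self.pos}"
        if self.kind == "ins":
            return f"I{self.pos}{self.new}"
        raise InvalidInputError(f"unknown annotation kind {self.kind!r}")


@dataclass(frozen=True)
class ProbeRecord:
    name: str
    target_id: str
    start: int
    end: int
    sequence: str
    linker: str = POLY_T_LINKER
    annotations: tuple[Annotation, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "sequence", check_sequence(self.sequence))

    @property
    def site_length(self) -> int:
        """Length of the targeted site (= unmodified probe length)."""
        return self.end - self.start + 1


# ---------------------------------------------------------------------------
# naming codec
# ---------------------------------------------------------------------------

_NAME_RE = re.compile(r"^([A-Za-z]+?)(\d+)[-–](\d+)((?:_[A-Za-z0-9]+)*)$")
_SEG_GAP = re.compile(r"^gap(\d+)$")
_SEG_INS = re.compile(r"^I(\d+)([ACGT])$")
_SEG_SUB = re.compile(r"^(\d+)([ACGT])([ACGT])$")


def encode_name(
    target_id: str, start: int, end: int, annotations: Sequence[Annotation] = ()
) -> str:
    parts = [f"{target_id}{start}-{end}"]
    parts.extend(a.segment() for a in annotations)
    return "_".join(parts)


def decode_name(name: str) -> tuple[str, int, int, tuple[Annotation, ...]]:
    m = _NAME_RE.match(name)
    if not m:
        raise InvalidInputError(f"cannot parse probe name {name!r}")
    target_id, start, end, tail = m.group(1), int(m.group(2)), int(m.group(3)), m.group(4)
    annotations: list[Annotation] = []
    offset = m.end(3)
    for seg in filter(None, tail.split("_")):
        if g := _SEG_GAP.match(seg):
            annotations.append(Annotation("gap", int(g.group(1))))
        elif g := _SEG_INS.match(seg):
            annotations.append(Annotation("ins", int(g.group(1)), new=g.group(2)))
        elif g := _SEG_SUB.match(seg):
            annotations.append(
                Annotation("sub", int(g.group(1)), orig=g.group(2), new=g.group(3))
            )
        else:
            raise InvalidInputError(
                f"cannot parse probe name {name!r}: bad annotation {seg!r} "
                f"near position {offset}"
            )
        offset += len(seg) + 1
    return target_id, start, end, tuple(annotations)


# ---------------------------------------------------------------------------
# constructors
# ---------------------------------------------------------------------------

def tile_probes(
    target_seq: str,
    length: int = 22,
    min_pos: int = 50,
    max_pos: int = 1450,
    target_id: str = "E",
) -> list[ProbeRecord]:
    """Perfect-match probes tiling every admissible start position.

    One probe per start position s with ``min_pos <= s`` and
    ``s + length - 1 <= max_pos``; the bounds exclude unamplified gene
    terminals.
    """
    target_seq = check_sequence(target_seq)
    if len(target_seq) < max_pos:
        raise InvalidInputError(
            f"target length {len(target_seq)} is shorter than max_pos {max_pos}"
        )
    records = []
    for s in range(min_pos, max_pos - length + 2):
        site = target_seq[s - 1 : s - 1 + length]
        records.append(
            ProbeRecord(
                name=encode_name(target_id, s, s + length - 1),
                target_id=target_id,
                start=s,
                end=s + length - 1,
                sequence=revcomp(site),
            )
        )
    return records


def _substitutions(base: str) -> list[str]:
    return [b for b in BASES if b != base]


def _derive(tile: ProbeRecord, sequence: str, annotations: Sequence[Annotation]) -> ProbeRecord:
    return ProbeRecord(
        name=encode_name(tile.target_id, tile.start, tile.end, annotations),
        target_id=tile.target_id,
        start=tile.start,
        end=tile.end,
        sequence=sequence,
        linker=tile.linker,
        annotations=tuple(annotations),
    )


def _require_22mers(tiles: Iterable[ProbeRecord], set_name: str) -> None:
    for t in tiles:
        if len(t.sequence) != 22:
            raise InvalidInputError(
                f"{set_name} set is defined on 22-mer probes; "
                f"{t.name} has length {len(t.sequence)}"
            )


def even_subset(records: Sequence[ProbeRecord], n: int = 62) -> list[ProbeRecord]:
    """Evenly spaced sample of ``n`` probes, deterministic."""
    if n >= len(records):
        return list(records)
    idx = [round(i * (len(records) - 1) / (n - 1)) for i in range(n)]
    return [records[i] for i in sorted(set(idx))]


def _with_sub(seq: str, pos: int) -> list[tuple[str, Annotation]]:
    orig = seq[pos - 1]
    out = []
    for new in _substitutions(orig):
        out.append((seq[: pos - 1] + new + seq[pos:], Annotation("sub", pos, orig, new)))
    return out


def make_mismatch_sets(
    tiles: Sequence[ProbeRecord],
    set_name: str,
    subset: Sequence[ProbeRecord] | None = None,
) -> list[ProbeRecord]:
    """Derive a mismatch probe set from perfect-match tiles.

    OneM applies to every tile; the other sets apply to a probe subset
    (62 by convention; an evenly spaced sample when none is given).
    Per-tile variant counts: OneM 3, PosM 3*L, Gap 4, Insertion 4, TwoM 27,
    Tandem 9.
    """
    if set_name not in MISMATCH_SET_NAMES:
        raise InvalidInputError(
            f"unknown set {set_name!r}; expected one of {MISMATCH_SET_NAMES}"
        )
    if set_name == "OneM":
        base = list(tiles)
    else:
        base = list(subset) if subset is not None else even_subset(tiles)
    _require_22mers(base, set_name)

    out: list[ProbeRecord] = []
    for tile in base:
        seq = tile.sequence
        if set_name == "OneM":
            for new_seq, ann in _with_sub(seq, 11):
                out.append(_derive(tile, new_seq, [ann]))
        elif set_name == "PosM":
            for pos in range(1, len(seq) + 1):
                for new_seq, ann in _with_sub(seq, pos):
                    out.append(_derive(tile, new_seq, [ann]))
        elif set_name == "Gap":
            for pos in (5, 11, 12, 18):
                ann = Annotation("gap", pos)
                out.append(_derive(tile, seq[: pos - 1] + seq[pos:], [ann]))
        elif set_name == "Insertion":
            for new in BASES:
                ann = Annotation("ins", 11, new=new)
                out.append(_derive(tile, seq[:11] + new + seq[11:], [ann]))
        elif set_name == "TwoM":
            for p1, p2 in ((5, 11), (11, 18), (5, 18)):
                for s1, a1 in _with_sub(seq, p1):
                    for s2, a2 in _with_sub(s1, p2):
                        out.append(_derive(tile, s2, [a1, a2]))
        elif set_name == "Tandem":
            for s1, a1 in _with_sub(seq, 11):
                for s2, a2 in _with_sub(s1, 12):
                    out.append(_derive(tile, s2, [a1, a2]))
    return out


# ---------------------------------------------------------------------------
# poly-T linker adjustment
# ---------------------------------------------------------------------------

def adjust_linker_bases(facing: str, linker: str = POLY_T_LINKER) -> str:
    """Apply the linker rule to the three bases facing the linker stem.

    ``facing`` holds the target bases opposite linker positions 1-3 (nearest
    the probe first).  A T in those positions becomes an A whenever the
    facing target base is A or G, removing spurious dT-dA / dT-dG binding;
    positions 4 onward stay poly-T.
    """
    head = list(linker[:3])
    for i, t in enumerate(facing[:3].upper()):
        if head[i] == "T" and t in "AG":
            head[i] = "A"
    return "".join(head) + linker[3:]


def adjust_linker(probe: ProbeRecord, target_seq: str) -> str:
    """Adjusted linker for a probe given its full target gene sequence.

    The linker extends the probe 3' end, which pairs with the 5'-most site
    position (``start``); linker position i faces target position
    ``start - i``.  Positions before the gene start count as non-pairing.
    """
    target_seq = check_sequence(target_seq)
    facing = []
    for i in (1, 2, 3):
        pos = probe.start - i
        facing.append(target_seq[pos - 1] if pos >= 1 else "N")
    return adjust_linker_bases("".join(facing), probe.linker)


# ---------------------------------------------------------------------------
# duplex derivation against candidate (non-)targets
# ---------------------------------------------------------------------------

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def conformation_from_pair(
    probe_seq: str,
    candidate_seq: str,
    params,
    max_edits: int | None = None,
) -> DuplexConformation | None:
    """Best-site duplex conformation of a probe against a candidate gene.

    Locates the best-matching site by semi-global alignment (substitutions
    and single-base indels), converts the edit script into pairing events,
    and returns the relaxed-end-minimized conformation.  Returns ``None``
    when no site aligns within ``max_edits`` differences (default: a third
    of the probe length) -- to be treated as zero hybridization efficiency.
    """
    probe_seq = check_sequence(probe_seq)
    candidate_seq = check_sequence(candidate_seq)
    if max_edits is None:
        max_edits = len(probe_seq) // 3
    query = revcomp(probe_seq)
    aln = edlib.align(query, candidate_seq, mode="HW", task="path", k=max_edits)
    if aln["editDistance"] < 0 or not aln.get("cigar"):
        return None
    start, _end = aln["locations"][0]

    # walk the cigar in target order, collecting aligned columns
    qpos, tpos = 0, start
    columns: list[tuple[str | None, str | None]] = []
    for count, op in _CIGAR_RE.findall(aln["cigar"]):
        for _ in range(int(count)):
            if op in "=XM":
                columns.append((query[qpos], candidate_seq[tpos]))
                qpos += 1
                tpos += 1
            elif op == "I":  # extra query base: probe-side bulge
                columns.append((query[qpos], None))
                qpos += 1
            elif op == "D":  # extra target base: target-side bulge
                columns.append((None, candidate_seq[tpos]))
                tpos += 1

    # probe order is the reverse of query order; probe base = complement(query)
    events: list[PairEvent] = []
    for q, t in reversed(columns):
        if q is None:
            events.append(PairEvent(TARGET_BULGE, None, t))
        elif t is None:
            events.append(PairEvent(PROBE_BULGE, complement(q), None))
        elif q == t:
            events.append(PairEvent(WC, complement(q), t))
        else:
            events.append(PairEvent(MISMATCH, complement(q), t))
    conf = DuplexConformation(probe_seq, tuple(events))
    return minimize_conformation(conf, params)
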