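"""Standard free energy of probe/target duplex formation.

The duplex free energy is assembled additively: an initiation penalty, one
nearest-neighbor stack per pair of adjacent Watson-Crick-paired probe bases,
and one internal-loop term per mismatch feature.  Loop terms follow the
decomposition

    ddG = dG_loop - dG_NN(lost stacks)

relative to the perfect-match duplex of the same probe: a single mismatch
replaces two stacks with a triplet loop, a tandem (adjacent double) mismatch
replaces three stacks with a quadruplet loop scored by the eight
closing-pair/mismatch-class rules, a bulged base replaces two stacks
(deletion-type, target-side bulge relative to the unmodified probe) or one
stack (insertion-type, probe-side bulge) with a bulge loop mapped from the
solution scale by a single slope.  Two well-separated mismatches are additive.

Mismatches near a terminus may relax: all bases from the mismatch to the
nearer end are left unpaired, removing both the loop penalty and the clamped
terminal stacks.  The conformation used for prediction is the one of minimum
free energy among the imposed duplex and all such relaxations
(:func:`minimize_conformation`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, NamedTuple, Sequence

from .parameters import (
    InvalidInputError,
    InvalidSequenceError,
    ThermoParameterSet,
    bulge_key,
    check_sequence,
    closing_class,
    complement,
    is_watson_crick,
    mismatch_class,
    revcomp,
)

WC = "wc"
MISMATCH = "mm"
PROBE_BULGE = "probe_bulge"
TARGET_BULGE = "target_bulge"

#: event kinds that consume a probe base
_PROBE_KINDS = (WC, MISMATCH, PROBE_BULGE)


class PairEvent(NamedTuple):
    """One column of the duplex alignment, in probe 5'->3' order.

    ``probe_base`` is None for a target bulge; ``target_base`` is None for a
    probe bulge and for relaxed (unpaired) probe bases it is simply absent
    from the effective event list.
    """

    kind: str
    probe_base: str | None = None
    target_base: str | None = None


def wc_event(base: str) -> PairEvent:
    return PairEvent(WC, base, complement(base))


@dataclass
class DuplexConformation:
    """A probe/target alignment with mismatch and bulge features.

    ``events`` run along the duplex in probe 5'->3' order.  ``relaxed_left``
    and ``relaxed_right`` count probe-terminal bases left unpaired at the 5'
    and 3' ends respectively; relaxed bases contribute no stacks and no loop
    penalties.
    """

    probe_seq: str
    events: tuple[PairEvent, ...]
    relaxed_left: int = 0
    relaxed_right: int = 0

    def __post_init__(self) -> None:
        self.probe_seq = check_sequence(self.probe_seq)
        self.events = tuple(self.events)
        consumed = "".join(
            e.probe_base for e in self.events if e.kind in _PROBE_KINDS
        )
        if consumed != self.probe_seq:
            raise InvalidInputError(
                "events are inconsistent with the probe sequence"
            )
        if self.relaxed_left < 0 or self.relaxed_right < 0:
            raise InvalidInputError("relaxed counts must be non-negative")
        if self.relaxed_left + self.relaxed_right > len(self.probe_seq):
            raise InvalidInputError("relaxed spans overlap")

    @property
    def n_events(self) -> int:
        """Number of non-Watson-Crick features in the imposed duplex."""
        return sum(1 for e in self.events if e.kind != WC)

    def effective_events(self) -> tuple[PairEvent, ...]:
        """Events that remain paired after terminal relaxation.

        Target bulges adjacent to a relaxed span (or at a duplex terminus)
        are dropped as well: an unpaired target base at the end of the
        paired region is a dangling end, not an internal loop.
        """
        events = list(self.events)
        for side in ("left", "right"):
            n = self.relaxed_left if side == "left" else self.relaxed_right
            if side == "right":
                events.reverse()
            consumed = 0
            out = []
            for e in events:
                if consumed < n and e.kind in _PROBE_KINDS:
                    consumed += 1
                    continue
                if consumed < n and e.kind == TARGET_BULGE:
                    continue
                out.append(e)
            while out and out[0].kind == TARGET_BULGE:
                out.pop(0)
            if side == "right":
                out.reverse()
            events = out
        return tuple(events)


def perfect_conformation(probe_seq: str) -> DuplexConformation:
    probe_seq = check_sequence(probe_seq)
    return DuplexConformation(probe_seq, tuple(wc_event(b) for b in probe_seq))


def conformation_from_site(probe_seq: str, target_site: str) -> DuplexConformation:
    """Imposed full duplex of a probe and an equal-length target site.

    ``target_site`` is the targeted gene region 5'->3'; the probe pairs with
    it antiparallel, so probe position i faces site position L-1-i.  Any
    non-complementary column becomes a mismatch event.
    """
    probe_seq = check_sequence(probe_seq)
    target_site = check_sequence(target_site)
    if len(probe_seq) != len(target_site):
        raise InvalidInputError("probe and target site lengths differ")
    facing = target_site[::-1]  # aligned under the probe, 3'->5'
    events = []
    for p, t in zip(probe_seq, facing):
        if is_watson_crick(p, t):
            events.append(PairEvent(WC, p, t))
        else:
            events.append(PairEvent(MISMATCH, p, t))
    return DuplexConformation(probe_seq, tuple(events))


# ---------------------------------------------------------------------------
# elementary free-energy operations
# ---------------------------------------------------------------------------

def dg_perfect(probe_seq: str, params: ThermoParameterSet) -> float:
    """Free energy of the probe's perfect-match duplex, kcal/mol.

    Sum of the (L-1) nearest-neighbor stack energies plus the initiation
    penalty.  Invariant under reading the duplex from the other strand.
    """
    probe_seq = check_sequence(probe_seq)
    if len(probe_seq) < 2:
        raise InvalidInputError("probe must be at least 2 nt")
    total = params.dg_init
    for i in range(len(probe_seq) - 1):
        total += params.nn_stack(probe_seq[i : i + 2])
    return total


SingleMismatchMode = Literal["M5_table", "M4_linear"]
TandemMode = Literal["M9_rules", "M8_linear"]


def _mm_loop_value(
    top: str, bottom: str, params: ThermoParameterSet, mode: SingleMismatchMode
) -> float:
    if mode == "M5_table":
        return params.mismatch_loop(top, bottom)
    if mode == "M4_linear":
        alpha, beta = params.sm_linear
        return alpha * params.mismatch_loop_sln(top, bottom) + beta
    raise InvalidInputError(f"unknown single-mismatch mode {mode!r}")


def ddg_single_mismatch(
    top: str,
    bottom: str,
    params: ThermoParameterSet,
    mode: SingleMismatchMode = "M5_table",
) -> float:
    """Destabilization of one internal mismatch, kcal/mol.

    ``top`` is the probe triplet 5'->3' (closing base, mismatched base,
    closing base); ``bottom`` the facing target triplet aligned 3'->5'.
    The loop term replaces the two nearest-neighbor stacks of the
    perfect-match duplex.
    """
    top, bottom = check_sequence(top), check_sequence(bottom)
    loop = _mm_loop_value(top, bottom, params, mode)  # validates the triplet
    lost = params.nn_stack(top[0:2]) + params.nn_stack(top[1:3])
    return loop - lost


def ddg_bulge(
    flank5: str,
    bulged: str,
    flank3: str,
    params: ThermoParameterSet,
    kind: Literal["deletion", "insertion"],
) -> float:
    """Destabilization of a single-base bulge, kcal/mol.

    For a *deletion* (the probe lost a base; the orphaned target base
    bulges) the context bases are the deleted probe base and its two
    unmodified-probe neighbors, and two stacks of the unmodified duplex are
    lost.  For an *insertion* (an extra probe base bulges) the context is
    the inserted base between its probe neighbors, and one stack is lost.
    """
    for b in (flank5, bulged, flank3):
        if b not in "ACGT":
            raise InvalidSequenceError(f"non-ACGT base {b!r}")
    if kind == "deletion":
        # bulged base sits on the target strand; key follows that strand 5'->3'
        key_args = (complement(flank3), complement(bulged), complement(flank5))
        lost = params.nn_stack(flank5 + bulged) + params.nn_stack(bulged + flank3)
    elif kind == "insertion":
        key_args = (flank5, bulged, flank3)
        lost = params.nn_stack(flank5 + flank3)
    else:
        raise InvalidInputError(f"unknown bulge kind {kind!r}")
    loop = params.bulge_alpha * params.bulge_loop_sln(*key_args)
    return loop - lost


def _tandem_loop_value(
    top: str,
    bottom: str,
    params: ThermoParameterSet,
    mode: TandemMode,
    dg_tm_sln: float | None,
) -> float:
    if mode == "M9_rules":
        left = params.tandem_score(
            closing_class(top[0], bottom[0]), mismatch_class(top[1], bottom[1])
        )
        right = params.tandem_score(
            closing_class(top[3], bottom[3]), mismatch_class(top[2], bottom[2])
        )
        return left + right
    if mode == "M8_linear":
        if dg_tm_sln is None:
            raise InvalidInputError(
                "M8_linear requires a supplied solution quadruplet free energy"
            )
        alpha, beta = params.tandem_linear
        return alpha * dg_tm_sln + beta
    raise InvalidInputError(f"unknown tandem mode {mode!r}")


def ddg_tandem(
    top: str,
    bottom: str,
    params: ThermoParameterSet,
    mode: TandemMode = "M9_rules",
    dg_tm_sln: float | None = None,
) -> float:
    """Destabilization of two adjacent mismatches, kcal/mol.

    ``top`` is the probe quadruplet (closing, mismatch, mismatch, closing);
    ``bottom`` the facing target quadruplet aligned 3'->5'.  The rule-based
    loop scores each half (closing pair + mismatch) by closing-pair class
    (AT/GC) and mismatch class (GG/GA/GT/other) and sums the two halves.
    Three nearest-neighbor stacks are replaced.
    """
    top, bottom = check_sequence(top), check_sequence(bottom)
    if len(top) != 4 or len(bottom) != 4:
        raise InvalidInputError("a tandem context has four aligned pairs")
    if not (is_watson_crick(top[0], bottom[0]) and is_watson_crick(top[3], bottom[3])):
        raise InvalidInputError("tandem flanks must be Watson-Crick closing pairs")
    if is_watson_crick(top[1], bottom[1]) or is_watson_crick(top[2], bottom[2]):
        raise InvalidInputError(
            "tandem context requires two adjacent non-Watson-Crick pairs; "
            "separated mismatches are additive single mismatches"
        )
    loop = _tandem_loop_value(top, bottom, params, mode, dg_tm_sln)
    lost = sum(params.nn_stack(top[i : i + 2]) for i in range(3))
    return loop - lost


# ---------------------------------------------------------------------------
# whole-conformation free energy
# ---------------------------------------------------------------------------

class DgResult(NamedTuple):
    dg: float
    extended: bool  # True when an uncovered conformation used fallback rules


def _fallback_loop(
    run: Sequence[PairEvent],
    left: PairEvent | None,
    right: PairEvent | None,
    params: ThermoParameterSet,
) -> float:
    """Conservative loop penalty for conformations outside the tables.

    Uses an explicit extended-rule entry when the parameter set carries one
    for this closing-pair context; otherwise takes the least destabilizing
    single-mismatch loop among covered analogs sharing the available closing
    pairs.  Applied per non-Watson-Crick event in the run, so larger
    disruptions accrue proportionally larger penalties.
    """
    candidates = []
    for key, value in params.single_mm_loops.items():
        top, bottom = key.split("/")
        readings = [(top, bottom), (bottom[::-1], top[::-1])]
        for t, b in readings:
            if left is not None and (t[0], b[0]) != (left.probe_base, left.target_base):
                continue
            if right is not None and (t[2], b[2]) != (right.probe_base, right.target_base):
                continue
            candidates.append(value)
            break
    per_event = min(candidates) if candidates else min(params.single_mm_loops.values())
    if left is None or right is None:
        # terminal run: dangling-end stabilization is outside this model,
        # so an unpaired terminal feature never contributes negatively
        per_event = max(per_event, 0.0)
    if params.extended_rules:
        ctx = "{}|{}".format(
            left.probe_base if left else "-", right.probe_base if right else "-"
        )
        per_event = params.extended_rules.get(ctx, per_event)
    return per_event * max(1, len(run))


def dg_of_conformation(
    conf: DuplexConformation,
    params: ThermoParameterSet,
    sm_mode: SingleMismatchMode = "M5_table",
    tandem_mode: TandemMode = "M9_rules",
    with_flags: bool = False,
) -> float | DgResult:
    """Total duplex free energy of a conformation, kcal/mol.

    Stacks are summed over adjacent Watson-Crick-paired probe bases; each
    run of consecutive non-Watson-Crick events contributes an internal-loop
    term.  Runs covered by the derived tables (one mismatch, two adjacent
    mismatches, one bulged base) use those tables; anything else falls back
    to conservative extended rules and flags the result.
    """
    events = conf.effective_events()
    if not events:
        raise InvalidInputError("conformation has no paired bases")
    total = params.dg_init
    extended = False

    # split into alternating runs of WC and non-WC events
    runs: list[tuple[bool, list[PairEvent]]] = []
    for e in events:
        is_wc = e.kind == WC
        if runs and runs[-1][0] == is_wc:
            runs[-1][1].append(e)
        else:
            runs.append((is_wc, [e]))

    for idx, (is_wc, run) in enumerate(runs):
        if is_wc:
            for a, b in zip(run, run[1:]):
                total += params.nn_stack(a.probe_base + b.probe_base)
            continue
        left = runs[idx - 1][1][-1] if idx > 0 else None
        right = runs[idx + 1][1][0] if idx + 1 < len(runs) else None
        if left is None or right is None:
            # terminal mismatch/bulge: no closed loop; conservative fallback
            total += _fallback_loop(run, left, right, params)
            extended = True
            continue
        kinds = [e.kind for e in run]
        if kinds == [MISMATCH]:
            e = run[0]
            top = left.probe_base + e.probe_base + right.probe_base
            bottom = left.target_base + e.target_base + right.target_base
            total += _mm_loop_value(top, bottom, params, sm_mode)
        elif kinds == [MISMATCH, MISMATCH]:
            top = (
                left.probe_base
                + run[0].probe_base
                + run[1].probe_base
                + right.probe_base
            )
            bottom = (
                left.target_base
                + run[0].target_base
                + run[1].target_base
                + right.target_base
            )
            total += _tandem_loop_value(top, bottom, params, tandem_mode, None)
        elif kinds == [TARGET_BULGE]:
            # target strand 5'->3' around the bulge: comp(right), base, comp(left)
            total += params.bulge_alpha * params.bulge_loop_sln(
                complement(right.probe_base),
                run[0].target_base,
                complement(left.probe_base),
            )
        elif kinds == [PROBE_BULGE]:
            total += params.bulge_alpha * params.bulge_loop_sln(
                left.probe_base, run[0].probe_base, right.probe_base
            )
        else:
            total += _fallback_loop(run, left, right, params)
            extended = True

    if with_flags:
        return DgResult(total, extended)
    return total


# ---------------------------------------------------------------------------
# relaxed-end minimization
# ---------------------------------------------------------------------------

def _relaxation_candidates(events: Sequence[PairEvent]) -> tuple[list[int], list[int]]:
    """Candidate relaxed_left / relaxed_right probe-base counts.

    For every non-Watson-Crick feature, relaxing from that feature to either
    terminus is a candidate; both termini are enumerated for every feature so
    near-central mismatches are also covered.
    """
    probe_len = sum(1 for e in events if e.kind in _PROBE_KINDS)
    lefts, rights = {0}, {0}
    consumed = 0
    for e in events:
        if e.kind in _PROBE_KINDS:
            consumed += 1
        if e.kind != WC:
            # unpair everything from the 5' end through this feature, or up
            # to it (leaving it terminal)
            lefts.add(consumed)
            start = consumed - (1 if e.kind in _PROBE_KINDS else 0)
            lefts.add(start)
            # and symmetrically toward the 3' end
            rights.add(probe_len - start)
            rights.add(probe_len - consumed)
    return sorted(lefts), sorted(rights)


def minimize_conformation(
    conf: DuplexConformation,
    params: ThermoParameterSet,
    sm_mode: SingleMismatchMode = "M5_table",
    tandem_mode: TandemMode = "M9_rules",
) -> DuplexConformation:
    """Minimum-free-energy conformation over terminal relaxations.

    Evaluates the imposed duplex and every relaxation that unpairs all
    probe bases from a mismatch/bulge feature to a terminus, including
    simultaneous relaxation at both ends when two features flank the
    duplex.  Ties prefer the less relaxed conformation.
    """
    lefts, rights = _relaxation_candidates(conf.events)
    probe_len = len(conf.probe_seq)
    best: tuple[float, int, DuplexConformation] | None = None
    for rl in lefts:
        for rr in rights:
            if rl + rr > probe_len - 2:  # keep at least one stack paired
                continue
            cand = replace(conf, relaxed_left=rl, relaxed_right=rr)
            if not cand.effective_events():
                continue
            dg = dg_of_conformation(cand, params, sm_mode, tandem_mode)
            rank = (dg, rl + rr)
            if best is None or rank < (best[0], best[1]):
                best = (dg, rl + rr, cand)
    assert best is not None
    return best[2]


def minimize_from_site(
    probe_seq: str,
    target_site: str,
    params: ThermoParameterSet,
    **kwargs,
) -> DuplexConformation:
    """Convenience: imposed duplex from an aligned site, then minimized."""
    return minimize_conformation(
        conformation_from_site(probe_seq, target_site), params, **kwargs
    )
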