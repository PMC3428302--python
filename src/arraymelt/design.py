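"""Melting-point-guided probe design and specificity scoring.

The design workflow keeps an array at a single stringency: per target site
the probe length is adjusted so that every probe's predicted melting point
falls in a narrow formamide window (default 18-22%), hybridization is done
a few points below the window (default 15%), and each candidate's
specificity is scored by its predicted hybridization efficiency against
every potential non-target gene at the working formamide concentration.
Candidates with all non-target efficiencies below a threshold (default
0.05) are flagged specific.  Presence of an OTU is called from a panel of
probes by a pass-fraction rule (default 9 of 10).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .lfem import efficiency, melting_point
from .parameters import InvalidInputError, ThermoParameterSet
from .probes import ProbeRecord, conformation_from_pair, encode_name, revcomp
from .thermo import dg_of_conformation, dg_perfect

DEFAULT_MELTING_WINDOW = (18.0, 22.0)
DEFAULT_LENGTH_RANGE = (18, 26)
DEFAULT_WORKING_FA = 15.0
DEFAULT_EFFICIENCY_THRESHOLD = 0.05
#: Simulated-readout brightness threshold (fluorescence units) for "bright".
DEFAULT_BRIGHT_THRESHOLD = 1750.0
DEFAULT_OTU_PASS_FRACTION = 0.9


@dataclass
class CandidateReport:
    """Design outcome for one target site."""

    probe: ProbeRecord | None
    site_start: int
    length: int | None
    fa_half_pred: float | None
    target_efficiency: float | None
    window_met: bool
    nontarget_efficiencies: dict[str, float] = field(default_factory=dict)
    nontarget_extended: dict[str, bool] = field(default_factory=dict)
    specific: bool | None = None


@dataclass
class DesignReport:
    candidates: list[CandidateReport]
    window: tuple[float, float]
    working_fa: float
    threshold: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.candidates:
            row = {
                "site_start": c.site_start,
                "probe": c.probe.name if c.probe else "",
                "length": c.length if c.length else 0,
                "fa_half_pred": c.fa_half_pred,
                "target_efficiency": c.target_efficiency,
                "window_met": c.window_met,
                "specific": c.specific,
            }
            for nt, eff in c.nontarget_efficiencies.items():
                row[f"eff_vs_{nt}"] = eff
            rows.append(row)
        return pd.DataFrame(rows)


def select_by_melting_window(
    target_seq: str,
    params: ThermoParameterSet,
    window: tuple[float, float] = DEFAULT_MELTING_WINDOW,
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE,
    starts: Sequence[int] | None = None,
    target_id: str = "T",
) -> list[CandidateReport]:
    """Choose per site the probe length whose melting point fits the window.

    For each start position the admissible lengths are scanned and the one
    whose predicted melting point lands closest to the window center is
    selected; sites where no length reaches the window are reported with
    ``window_met=False`` and the closest length anyway.
    """
    low, high = window
    if not low < high:
        raise InvalidInputError("melting window must satisfy low < high")
    lmin, lmax = length_range
    center = 0.5 * (low + high)
    if starts is None:
        starts = range(1, len(target_seq) - lmax + 2)

    out: list[CandidateReport] = []
    for s in starts:
        best = None  # (distance to center, in-window, length, mp)
        for length in range(lmin, lmax + 1):
            if s - 1 + length > len(target_seq):
                continue
            site = target_seq[s - 1 : s - 1 + length]
            mp = melting_point(dg_perfect(revcomp(site), params), params)
            in_window = low <= mp <= high
            rank = (not in_window, abs(mp - center))
            if best is None or rank < best[0]:
                best = (rank, length, mp, site)
        if best is None:
            continue
        (not_in_window, _), length, mp, site = best
        probe = ProbeRecord(
            name=encode_name(target_id, s, s + length - 1),
            target_id=target_id,
            start=s,
            end=s + length - 1,
            sequence=revcomp(site),
        )
        out.append(
            CandidateReport(
                probe=probe,
                site_start=s,
                length=length,
                fa_half_pred=float(mp),
                target_efficiency=None,
                window_met=not not_in_window,
            )
        )
    return out


def specificity_score(
    probe_seq: str,
    nontargets: Mapping[str, str],
    working_fa: float,
    params: ThermoParameterSet,
    threshold: float = DEFAULT_EFFICIENCY_THRESHOLD,
    max_edits: int | None = None,
) -> tuple[dict[str, float], dict[str, bool], bool]:
    """Predicted efficiency against each non-target's best site.

    Returns (per-non-target efficiency, per-non-target extended-rule flag,
    specific flag).  A non-target with no alignable site contributes zero
    efficiency.  The probe is specific when every non-target efficiency is
    below the threshold.
    """
    if working_fa < 0:
        raise InvalidInputError("working formamide concentration must be >= 0")
    effs: dict[str, float] = {}
    ext: dict[str, bool] = {}
    for name, seq in nontargets.items():
        conf = conformation_from_pair(probe_seq, seq, params, max_edits=max_edits)
        if conf is None:
            effs[name], ext[name] = 0.0, False
            continue
        dg, flagged = dg_of_conformation(conf, params, with_flags=True)
        effs[name] = float(efficiency(dg, working_fa, params))
        ext[name] = flagged
    specific = all(e < threshold for e in effs.values())
    return effs, ext, specific


def design_probes(
    target_seq: str,
    nontargets: Mapping[str, str],
    params: ThermoParameterSet,
    window: tuple[float, float] = DEFAULT_MELTING_WINDOW,
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE,
    working_fa: float = DEFAULT_WORKING_FA,
    threshold: float = DEFAULT_EFFICIENCY_THRESHOLD,
    starts: Sequence[int] | None = None,
    target_id: str = "T",
) -> DesignReport:
    """Full design pass: window selection then specificity scoring."""
    candidates = select_by_melting_window(
        target_seq, params, window, length_range, starts, target_id
    )
    for cand in candidates:
        cand.target_efficiency = float(
            efficiency(dg_perfect(cand.probe.sequence, params), working_fa, params)
        )
        effs, ext, specific = specificity_score(
            cand.probe.sequence, nontargets, working_fa, params, threshold
        )
        cand.nontarget_efficiencies = effs
        cand.nontarget_extended = ext
        cand.specific = specific
    return DesignReport(candidates, window, working_fa, threshold)


def otu_call(
    bright_flags: Sequence[bool],
    pass_fraction: float = DEFAULT_OTU_PASS_FRACTION,
) -> bool:
    """Present/absent call for an OTU from its probe panel.

    The OTU is called present when the fraction of bright probes reaches
    the pass rule (default 0.9, i.e. 9 of 10).
    """
    flags = list(bright_flags)
    if not flags:
        raise InvalidInputError("an OTU panel needs at least one probe")
    return sum(flags) / len(flags) >= pass_fraction
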