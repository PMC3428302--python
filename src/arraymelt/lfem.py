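"""Linear free energy model of formamide denaturation.

Hybridization at the probe's microenvironment is treated as a two-state
local equilibrium P + T = PT with the target as the limiting species.  The
free energy of duplex formation grows linearly with denaturant:

    dG(FA) = dG0 + m * FA

with FA the formamide concentration (% v/v) and m the denaturant m-value
(kcal/mol per %).  The hybridization efficiency -- the fraction of locally
available target bound by the probe, [PT]/[T]0 -- is the logistic

    E(FA) = {P}o * K / (1 + {P}o * K),     K = exp(-dG(FA) / RT)

where {P}o is the effective probe concentration (activity coefficients
absorbed).  E decreases sigmoidally in FA and its maximum is always attained
at 0% formamide.  The melting point [FA]1/2 is where E falls to half of
E(0); it has the closed form RT*ln(2 + C)/m with C = {P}o*exp(-dG0/RT).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .parameters import ThermoParameterSet
from .thermo import (
    SingleMismatchMode,
    TandemMode,
    dg_of_conformation,
    minimize_from_site,
)

#: The 8-point experimental formamide series, % v/v.
DEFAULT_FA_SERIES = (0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 32.5, 45.0)


def efficiency(dg, fa, params: ThermoParameterSet):
    """Hybridization efficiency at formamide concentration ``fa`` (% v/v).

    ``dg`` is the duplex free energy at 0% formamide in kcal/mol (the
    nearest-neighbor sum including the initiation penalty).  Accepts scalars
    or arrays and broadcasts.
    """
    dg = np.asarray(dg, dtype=float)
    fa = np.asarray(fa, dtype=float)
    log_c = np.log(params.effective_probe_conc) - (dg + params.m_value * fa) / params.rt
    out = expit(log_c)  # E = 1 / (1 + exp(-log_c)), overflow-safe
    if out.ndim == 0:
        return float(out)
    return out


def melting_point(dg, params: ThermoParameterSet):
    """Formamide concentration where efficiency halves, [FA]1/2,pred (% v/v).

    Closed-form solution of E(FA) = E(0)/2; always non-negative.  More
    stable duplexes (more negative ``dg``) melt at higher formamide.
    """
    dg = np.asarray(dg, dtype=float)
    log_c = np.log(params.effective_probe_conc) - dg / params.rt
    # FA = RT * ln(2 + C) / m, computed via logaddexp for large C
    fa = params.rt * np.logaddexp(np.log(2.0), log_c) / params.m_value
    fa = np.maximum(fa, 0.0)
    if fa.ndim == 0:
        return float(fa)
    return fa


@dataclass(frozen=True)
class MeltingCurve:
    """Predicted efficiency over a formamide series for one duplex."""

    formamide_points: tuple[float, ...]
    efficiencies: tuple[float, ...]
    dg_used: float
    fa_half_pred: float
    params_id: str
    extended: bool = False


def curve_from_dg(
    dg: float,
    params: ThermoParameterSet,
    fa_series=DEFAULT_FA_SERIES,
    extended: bool = False,
) -> MeltingCurve:
    fa = tuple(float(x) for x in fa_series)
    eff = efficiency(dg, np.array(fa), params)
    return MeltingCurve(fa, tuple(float(e) for e in np.atleast_1d(eff)),
                        float(dg), melting_point(dg, params),
                        params.table_hash(), extended)


def predicted_curve(
    probe_seq: str,
    target_site: str,
    params: ThermoParameterSet,
    fa_series=DEFAULT_FA_SERIES,
    sm_mode: SingleMismatchMode = "M5_table",
    tandem_mode: TandemMode = "M9_rules",
) -> MeltingCurve:
    """Melting curve of a probe against an aligned target site.

    The duplex conformation is the relaxed-end minimum over the imposed
    alignment; its free energy drives the efficiency at every point of the
    series.
    """
    conf = minimize_from_site(
        probe_seq, target_site, params, sm_mode=sm_mode, tandem_mode=tandem_mode
    )
    dg, ext = dg_of_conformation(
        conf, params, sm_mode, tandem_mode, with_flags=True
    )
    return curve_from_dg(dg, params, fa_series, extended=ext)
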