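"""Intensity preprocessing and bi-level calibration of the melting model.

Raw replicate intensities (pixel units, 0..65536) are reduced per probe and
formamide point: a replicate more than three standard deviations (of the
remaining two) away from the mean of the remaining two is discarded; the
mean of the Nonsense control probes is subtracted as background, with
standard deviations combined in quadrature.

For fitting, each profile is normalized by its maximum background-corrected
mean (I_max) and matched to the theoretical efficiency curve through a
probe-specific proportionality factor gamma:

    I / I_max = gamma * E(dG, FA)

The fit is bi-level: an outer nonlinear least squares adjusts global model
parameters (the m-value and log10 of the effective probe concentration by
default) while, at every outer iterate, each gamma is solved in closed form
(gamma_i = sum(E*y)/sum(E^2) over the probe's fitted points).  Gamma factors
rescale the curve vertically only; they do not change the melting point.

Goodness of fit is summarized by the coefficient of determination R^2 and
by the error-squares statistic s^2 = sum(r^2)/nu with nu = n - (number of
fitted probes + number of global parameters), which charges the per-probe
gammas to the degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .lfem import efficiency, melting_point
from .parameters import InvalidInputError, ThermoParameterSet

#: Minimum I_max (a.u.) for a perfect-match probe to enter fitting.
IMAX_MIN_PERFECT = 1000.0
#: Minimum I_max (a.u.) for a mismatched probe to enter fitting.
IMAX_MIN_MISMATCHED = 500.0
#: Mismatched probes losing more than this fraction of signal over the first
#: formamide increment are dropped (early melters dominated by noise).
FIRST_INCREMENT_MAX_DROP = 0.5
#: Points left of the profile maximum below this fraction of I_max are
#: excluded from fitting (kinetic rise at low formamide).
PLATEAU_FRACTION = 0.8


@dataclass
class IntensityProfile:
    """Replicate-reduced signal of one probe over the formamide series."""

    probe_name: str
    fa: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n_replicates: np.ndarray
    background_corrected: bool = False

    @property
    def i_max(self) -> float:
        finite = self.mean[np.isfinite(self.mean)]
        return float(finite.max()) if finite.size else math.nan

    def normalized(self) -> np.ndarray:
        return self.mean / self.i_max


def remove_replicate_outlier(values: Sequence[float]) -> list[float]:
    """Drop at most one replicate by the leave-one-out three-sigma rule."""
    vals = [float(v) for v in values if np.isfinite(v)]
    if len(vals) < 3:
        return vals
    worst_idx, worst_score = None, 3.0
    for i, v in enumerate(vals):
        rest = vals[:i] + vals[i + 1 :]
        mu = float(np.mean(rest))
        sd = float(np.std(rest, ddof=1))
        if sd == 0.0:
            continue
        score = abs(v - mu) / sd
        if score > worst_score:
            worst_idx, worst_score = i, score
    if worst_idx is None:
        return vals
    return vals[:worst_idx] + vals[worst_idx + 1 :]


def preprocess(
    raw: pd.DataFrame,
    nonsense: Sequence[str],
) -> dict[str, IntensityProfile]:
    """Reduce a raw replicate table to background-corrected profiles.

    ``raw`` has columns ``probe``, ``fa`` and one ``rep*`` column per
    replicate feature.  ``nonsense`` names the background control probes;
    their average is subtracted from every mean and their scatter is folded
    into every standard deviation (error propagation in quadrature).  A
    (probe, fa) cell whose replicates are all removed yields NaN, not an
    error.
    """
    rep_cols = [c for c in raw.columns if c.startswith("rep")]
    if not rep_cols:
        raise InvalidInputError("raw table has no rep* columns")
    nonsense = set(nonsense)

    reduced: dict[str, dict[float, tuple[float, float, int]]] = {}
    for (probe, fa), grp in raw.groupby(["probe", "fa"], sort=True):
        vals: list[float] = []
        for _, row in grp.iterrows():
            vals.extend(float(row[c]) for c in rep_cols if np.isfinite(row[c]))
        kept = remove_replicate_outlier(vals)
        if kept:
            mean = float(np.mean(kept))
            sd = float(np.std(kept, ddof=1)) if len(kept) > 1 else 0.0
        else:
            mean, sd = math.nan, math.nan
        reduced.setdefault(probe, {})[float(fa)] = (mean, sd, len(kept))

    # background per formamide point from the Nonsense controls
    fa_values = sorted({fa for per in reduced.values() for fa in per})
    bg_mean, bg_sd = {}, {}
    for fa in fa_values:
        cells = [reduced[p][fa] for p in nonsense if p in reduced and fa in reduced[p]]
        means = [c[0] for c in cells if np.isfinite(c[0])]
        if means:
            bg_mean[fa] = float(np.mean(means))
            if len(means) > 1:
                bg_sd[fa] = float(np.std(means, ddof=1) / math.sqrt(len(means)))
            else:
                sd, n = cells[0][1], cells[0][2]
                bg_sd[fa] = sd / math.sqrt(n) if n else 0.0
        else:
            bg_mean[fa], bg_sd[fa] = 0.0, 0.0

    profiles: dict[str, IntensityProfile] = {}
    for probe, per_fa in reduced.items():
        if probe in nonsense:
            continue
        fas = np.array(sorted(per_fa))
        mean = np.array([per_fa[f][0] - bg_mean[f] for f in fas])
        sd = np.array(
            [math.hypot(per_fa[f][1], bg_sd[f]) if np.isfinite(per_fa[f][1]) else math.nan
             for f in fas]
        )
        nrep = np.array([per_fa[f][2] for f in fas])
        profiles[probe] = IntensityProfile(
            probe, fas, mean, sd, nrep, background_corrected=True
        )
    return profiles


ProbeClass = Literal["perfect", "mismatched"]


def filter_probes(
    profiles: Mapping[str, IntensityProfile],
    classes: Mapping[str, ProbeClass],
) -> dict[str, IntensityProfile]:
    """Drop probes too close to background to constrain the fit.

    Perfect-match probes need I_max >= 1000 a.u., mismatched probes
    I_max >= 500 a.u.; mismatched probes whose signal falls by more than 50%
    over the first formamide increment are dropped as well.
    """
    kept: dict[str, IntensityProfile] = {}
    for name, prof in profiles.items():
        cls = classes.get(name, "mismatched")
        imax = prof.i_max
        if not np.isfinite(imax):
            continue
        if cls == "perfect":
            if imax < IMAX_MIN_PERFECT:
                continue
        else:
            if imax < IMAX_MIN_MISMATCHED:
                continue
            if len(prof.fa) >= 2:
                i0, i1 = prof.mean[0], prof.mean[1]
                if np.isfinite(i0) and np.isfinite(i1) and i0 > 0:
                    if (i0 - i1) / i0 > FIRST_INCREMENT_MAX_DROP:
                        continue
        kept[name] = prof
    return kept


def trim_left_of_plateau(profile: IntensityProfile) -> np.ndarray:
    """Fitted-point mask excluding the sub-plateau rise left of I_max."""
    mean = profile.mean
    mask = np.isfinite(mean)
    if not mask.any():
        return mask
    k = int(np.nanargmax(mean))
    for i in range(k):
        if mask[i] and mean[i] < PLATEAU_FRACTION * mean[k]:
            mask[i] = False
    return mask


def fa_half_exp(profile: IntensityProfile) -> float:
    """Experimental half-denaturation point, % formamide.

    Linear interpolation between the two subsequent points bracketing
    I_max/2, scanning right of the maximum.  NaN when the profile never
    crosses the half level.
    """
    mean, fa = profile.mean, profile.fa
    finite = np.isfinite(mean)
    if not finite.any():
        return math.nan
    half = profile.i_max / 2.0
    k = int(np.nanargmax(mean))
    for j in range(k, len(fa) - 1):
        a, b = mean[j], mean[j + 1]
        if np.isfinite(a) and np.isfinite(b) and a > half >= b:
            return float(fa[j] + (fa[j + 1] - fa[j]) * (a - half) / (a - b))
    return math.nan


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def error_squares_stats(
    sum_sq_resid: float, n: int, n_probes: int, n_globals: int
) -> tuple[int, float]:
    """Degrees of freedom and the error-squares statistic s^2.

    nu = n - (n_probes + n_globals); every fitted gamma counts against the
    degrees of freedom alongside the global parameters.
    """
    nu = n - (n_probes + n_globals)
    if nu <= 0:
        raise InvalidInputError("no residual degrees of freedom")
    return nu, sum_sq_resid / nu


def coefficient_of_determination(residuals: np.ndarray, y: np.ndarray) -> float:
    ss_res = float(np.sum(residuals**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - ss_res / ss_tot


# ---------------------------------------------------------------------------
# bi-level fit
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Converged bi-level fit with per-probe gammas and fit statistics."""

    m_value: float
    log10_po: float
    gammas: dict[str, float]
    n: int
    nu: int
    sum_sq_resid: float
    mean_sq_resid: float
    s2: float
    r2: float
    eps2_val: float
    eps2_ov: float
    err_fa_half: pd.DataFrame  # probe, fa_half_pred, fa_half_exp, err, abs_err
    fitted_probes: tuple[str, ...]
    validation_probes: tuple[str, ...]
    n_total_probes: int
    seed: int
    converged: bool
    params: ThermoParameterSet = field(repr=False, default=None)

    @property
    def frac_abs_err_below(self) -> float:
        """Fraction of probes with |err[FA]1/2| < 5% formamide."""
        e = self.err_fa_half["abs_err"].dropna()
        return float((e < 5.0).mean()) if len(e) else math.nan

    def to_text(self) -> str:
        lines = [
            "# arraymelt fit result",
            f"# params_hash: {self.params.table_hash() if self.params else 'na'}",
            f"# seed: {self.seed}",
            f"m_value\t{self.m_value:.6f}",
            f"log10_po\t{self.log10_po:.6f}",
            f"n\t{self.n}",
            f"nu\t{self.nu}",
            f"n_fitted_probes\t{len(self.fitted_probes)}",
            f"n_total_probes\t{self.n_total_probes}",
            f"sum_sq_resid_per_n\t{self.mean_sq_resid:.6f}",
            f"s2\t{self.s2:.6f}",
            f"r2\t{self.r2:.6f}",
            f"eps2_val\t{self.eps2_val:.6f}",
            f"eps2_ov\t{self.eps2_ov:.6f}",
            f"frac_abs_err_below_5\t{self.frac_abs_err_below:.4f}",
        ]
        return "\n".join(lines) + "\n"


class FitConvergenceError(RuntimeError):
    """Raised when the outer optimizer fails; carries the last iterate."""

    def __init__(self, message: str, last_iterate: dict):
        super().__init__(message)
        self.last_iterate = last_iterate


def _closed_form_gamma(eff: np.ndarray, y: np.ndarray) -> float:
    denom = float(np.sum(eff * eff))
    if denom == 0.0:
        return 1.0
    return float(np.sum(eff * y) / denom)


def gamma_modes(
    profiles: Mapping[str, IntensityProfile],
    dgs: Mapping[str, float],
    params: ThermoParameterSet,
    mode: Literal["fitted", "unity", "inverse_max_eff"] = "fitted",
) -> dict[str, float]:
    """Per-probe gamma under the three supported conventions."""
    out = {}
    for name, prof in profiles.items():
        if mode == "unity":
            out[name] = 1.0
        elif mode == "inverse_max_eff":
            out[name] = 1.0 / efficiency(dgs[name], 0.0, params)
        elif mode == "fitted":
            mask = trim_left_of_plateau(prof)
            eff = efficiency(dgs[name], prof.fa[mask], params)
            out[name] = _closed_form_gamma(np.atleast_1d(eff), prof.normalized()[mask])
        else:
            raise InvalidInputError(f"unknown gamma mode {mode!r}")
    return out


def bilevel_fit(
    profiles: Mapping[str, IntensityProfile],
    dgs: Mapping[str, float],
    params: ThermoParameterSet,
    x0: tuple[float, float] = (0.2, -2.0),
    validation_fraction: float = 0.0,
    seed: int = 0,
    apply_trim: bool = True,
    max_iterations: int = 500,
) -> FitResult:
    """Fit (m, log10 {P}_o) to normalized profiles with per-probe gammas.

    The outer optimizer is trust-region least squares with a relative-cost
    tolerance of 1e-8 and at most ``max_iterations`` outer evaluations; the
    inner gammas are exact per iterate.  With ``validation_fraction`` > 0 a
    seeded uniform random probe subset is held out of the residuals and only
    scored at the optimum (eps2_val).  Deterministic for a fixed seed.
    """
    names = sorted(n for n in profiles if n in dgs)
    if not names:
        raise InvalidInputError("no profiles with free-energy assignments to fit")

    rng = np.random.default_rng(seed)
    n_val = int(round(validation_fraction * len(names)))
    val_idx = set(rng.choice(len(names), size=n_val, replace=False)) if n_val else set()
    fit_names = [n for i, n in enumerate(names) if i not in val_idx]
    val_names = [n for i, n in enumerate(names) if i in val_idx]

    def collect(subset):
        fa_list, y_list, dg_list, slices = [], [], [], []
        pos = 0
        for name in subset:
            prof = profiles[name]
            mask = trim_left_of_plateau(prof) if apply_trim else np.isfinite(prof.mean)
            fa_list.append(prof.fa[mask])
            y_list.append(prof.normalized()[mask])
            dg_list.append(np.full(mask.sum(), dgs[name]))
            slices.append(slice(pos, pos + int(mask.sum())))
            pos += int(mask.sum())
        return (
            np.concatenate(fa_list),
            np.concatenate(y_list),
            np.concatenate(dg_list),
            slices,
        )

    fa_f, y_f, dg_f, slices_f = collect(fit_names)

    def residuals(x):
        trial = params.with_globals(m_value=float(x[0]), log10_po=float(x[1]))
        eff = efficiency(dg_f, fa_f, trial)
        r = np.empty_like(y_f)
        for sl in slices_f:
            g = _closed_form_gamma(eff[sl], y_f[sl])
            r[sl] = y_f[sl] - g * eff[sl]
        return r

    sol = least_squares(
        residuals,
        x0=np.asarray(x0, dtype=float),
        bounds=([1e-4, -12.0], [2.0, 3.0]),
        ftol=1e-8,
        xtol=1e-10,
        max_nfev=max_iterations,
    )
    if not sol.success:
        raise FitConvergenceError(
            f"outer least squares did not converge: {sol.message}",
            {"m_value": float(sol.x[0]), "log10_po": float(sol.x[1])},
        )
    m_fit, logpo_fit = float(sol.x[0]), float(sol.x[1])
    fitted = params.with_globals(m_value=m_fit, log10_po=logpo_fit)

    r = residuals(sol.x)
    n = r.size
    nu, s2 = error_squares_stats(float(np.sum(r**2)), n, len(fit_names), 2)
    r2 = coefficient_of_determination(r, y_f)

    gammas: dict[str, float] = {}
    eff_f = efficiency(dg_f, fa_f, fitted)
    for name, sl in zip(fit_names, slices_f):
        gammas[name] = _closed_form_gamma(eff_f[sl], y_f[sl])

    # prediction error on held-out probes (gamma still solved per probe)
    def prediction_mse(subset):
        if not subset:
            return math.nan
        fa_v, y_v, dg_v, slices_v = collect(subset)
        eff_v = efficiency(dg_v, fa_v, fitted)
        rr = np.empty_like(y_v)
        for name, sl in zip(subset, slices_v):
            g = _closed_form_gamma(eff_v[sl], y_v[sl])
            gammas.setdefault(name, g)
            rr[sl] = y_v[sl] - g * eff_v[sl]
        return float(np.mean(rr**2))

    eps2_val = prediction_mse(val_names)
    eps2_ov = prediction_mse(names)

    rows = []
    for name in names:
        pred = melting_point(dgs[name], fitted)
        exp = fa_half_exp(profiles[name])
        err = pred - exp if np.isfinite(exp) else math.nan
        rows.append(
            {"probe": name, "fa_half_pred": pred, "fa_half_exp": exp,
             "err": err, "abs_err": abs(err)}
        )
    err_df = pd.DataFrame(rows)

    return FitResult(
        m_value=m_fit,
        log10_po=logpo_fit,
        gammas=gammas,
        n=n,
        nu=nu,
        sum_sq_resid=float(np.sum(r**2)),
        mean_sq_resid=float(np.mean(r**2)),
        s2=s2,
        r2=r2,
        eps2_val=eps2_val,
        eps2_ov=eps2_ov,
        err_fa_half=err_df,
        fitted_probes=tuple(fit_names),
        validation_probes=tuple(val_names),
        n_total_probes=len(names),
        seed=seed,
        converged=bool(sol.success),
        params=fitted,
    )
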