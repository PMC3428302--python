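"""Synthetic targets, probe sets, and noisy formamide-series intensities.

The generator emulates the statistical structure the calibration machinery
assumes: sigmoidal efficiency profiles from the linear free energy model,
strong probe-to-probe brightness variation (positional amplification and
labeling bias), homoscedastic Gaussian noise on the normalized scale,
triplicate features with occasional gross outliers, additive background
measured by a Nonsense control probe, and soft scanner saturation at the
top of the pixel scale.  Every output is a deterministic function of the
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .lfem import DEFAULT_FA_SERIES, efficiency, melting_point
from .parameters import ThermoParameterSet, default_params
from .probes import ProbeRecord, encode_name, revcomp, tile_probes
from .thermo import dg_perfect

#: Sequence of the background control feature (not complementary to targets).
NONSENSE_SEQUENCE = "AGAGAGAGAGAGAGAGAGAGAG"
NONSENSE_NAME = "Nonsense"


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic experiment.

    Defaults mirror the experimental design the model targets: a 16S-sized
    gene, the 8-point formamide series, normalized-scale noise SD 0.078
    (pooled experimental variance 0.0061), probe brightness spanning
    500-40,000 a.u., three replicate features, sparse outliers, and a
    65,536-unit scanner ceiling with saturation setting in around 40,000.
    Target fragmentation (fragment lengths 25-150, mean 65) motivates the
    smooth positional brightness field; fragments are not simulated
    explicitly.
    """

    seed: int = 0
    gene_length: int = 1542
    gc_content: float = 0.54
    fa_series: tuple[float, ...] = DEFAULT_FA_SERIES
    noise_sd: float = 0.078
    brightness_min: float = 500.0
    brightness_max: float = 40000.0
    replicates: int = 3
    outlier_rate: float = 0.01
    outlier_scale: float = 5.0
    background_level: float = 100.0
    background_sd: float = 10.0
    saturation_onset: float = 40000.0
    saturation_ceiling: float = 65536.0
    concentration_factor: float = 1.0  # 10.0 emulates the 10x target run
    n_probes: int = 250
    lengths: tuple[int, ...] = (18, 20, 22, 24, 26)
    gamma_mode: str = "unity"  # "unity" keeps truth gammas at 1


@dataclass
class SynthOutput:
    gene: str
    probes: list[ProbeRecord]
    intensities: pd.DataFrame  # probe, fa, rep1..repK
    truth: pd.DataFrame  # probe, dg, gamma, brightness, fa_half_pred
    config: SynthConfig


def _soft_saturate(values: np.ndarray, onset: float, ceiling: float) -> np.ndarray:
    """Compressive response above the saturation onset, hard-capped at the
    ceiling (pixel values cannot exceed the scanner scale)."""
    out = np.asarray(values, dtype=float).copy()
    over = out > onset
    span = ceiling - onset
    out[over] = onset + span * (1.0 - np.exp(-(out[over] - onset) / span))
    return np.minimum(out, ceiling)


def random_gene(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


def variable_length_probes(
    gene: str, config: SynthConfig, rng: np.random.Generator
) -> list[ProbeRecord]:
    """Perfect-match probes of varied length at evenly spaced sites.

    Varying the length spreads duplex stability, giving the wide melting
    point range the calibration needs.
    """
    min_pos, max_pos = 50, min(1450, len(gene))
    starts = np.linspace(min_pos, max_pos - max(config.lengths), config.n_probes)
    records = []
    for s in starts:
        s = int(round(s))
        length = int(rng.choice(config.lengths))
        site = gene[s - 1 : s - 1 + length]
        records.append(
            ProbeRecord(
                name=encode_name("S", s, s + length - 1),
                target_id="S",
                start=s,
                end=s + length - 1,
                sequence=revcomp(site),
            )
        )
    return records


def generate(
    config: SynthConfig,
    params: ThermoParameterSet | None = None,
    probes: list[ProbeRecord] | None = None,
    outdir: str | Path | None = None,
) -> SynthOutput:
    """Simulate a formamide-series hybridization experiment.

    Per probe i and formamide point j, each replicate feature reads

        I = background + b_i * (gamma_i * E(dG_i, FA_j) + noise)

    with b_i the probe brightness, E the model efficiency and noise drawn
    i.i.d. Gaussian with the configured SD on the normalized scale; the
    result passes through the saturation response.  Injected outliers
    multiply a single replicate.  The truth table records dG, gamma,
    brightness and the model melting point of every probe.

    With ``outdir`` set, writes ``target.fasta``, ``probes.tsv``,
    ``intensities.tsv`` and ``truth.tsv``.
    """
    if params is None:
        params = default_params()
    rng = np.random.default_rng(config.seed)
    gene = random_gene(rng, config.gene_length, config.gc_content)
    if probes is None:
        probes = variable_length_probes(gene, config, rng)

    fa = np.asarray(config.fa_series, dtype=float)
    rows = []
    truth_rows = []
    for rec in probes:
        dg = dg_perfect(rec.sequence, params)
        eff = np.atleast_1d(efficiency(dg, fa, params))
        log_b = rng.uniform(
            np.log(config.brightness_min), np.log(config.brightness_max)
        )
        brightness = float(np.exp(log_b)) * config.concentration_factor
        gamma = 1.0 if config.gamma_mode == "unity" else float(
            1.0 / max(eff[0], 1e-9)
        )
        signal = brightness * gamma * eff
        # noise_sd is the SD of a replicate-averaged data point on the
        # normalized scale; single features scatter sqrt(replicates) wider
        rep_sd = config.noise_sd * np.sqrt(config.replicates)
        reps = (
            signal[None, :]
            + brightness * rng.normal(0.0, rep_sd, (config.replicates, fa.size))
        )
        if config.background_sd > 0:
            reps = reps + rng.normal(
                config.background_level, config.background_sd, reps.shape
            )
        else:
            reps = reps + config.background_level
        # sparse gross outliers: one replicate blown up by a large factor
        outliers = rng.random(fa.size) < config.outlier_rate
        which = rng.integers(0, config.replicates, fa.size)
        for j in np.flatnonzero(outliers):
            reps[which[j], j] *= config.outlier_scale
        reps = _soft_saturate(
            np.maximum(reps, 0.0), config.saturation_onset, config.saturation_ceiling
        )
        for j, f in enumerate(fa):
            rows.append(
                {"probe": rec.name, "fa": f}
                | {f"rep{k+1}": reps[k, j] for k in range(config.replicates)}
            )
        truth_rows.append(
            {
                "probe": rec.name,
                "dg": dg,
                "gamma": gamma,
                "brightness": brightness,
                "fa_half_pred": melting_point(dg, params),
            }
        )

    # Nonsense background control: pure background, no target capture
    for f in fa:
        reps = rng.normal(
            config.background_level,
            max(config.background_sd, 1e-9),
            config.replicates,
        )
        rows.append(
            {"probe": NONSENSE_NAME, "fa": float(f)}
            | {f"rep{k+1}": max(reps[k], 0.0) for k in range(config.replicates)}
        )

    intensities = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)
    out = SynthOutput(gene, probes, intensities, truth, config)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "target.fasta", "w") as fh:
            fh.write(">synthetic_target\n")
            for i in range(0, len(gene), 70):
                fh.write(gene[i : i + 70] + "\n")
        probe_rows = [
            {
                "name": p.name,
                "target_id": p.target_id,
                "start": p.start,
                "end": p.end,
                "sequence": p.sequence,
                "annotations": ";".join(a.segment() for a in p.annotations),
            }
            for p in probes
        ]
        pd.DataFrame(probe_rows).to_csv(outdir / "probes.tsv", sep="\t", index=False)
        intensities.to_csv(
            outdir / "intensities.tsv", sep="\t", index=False, float_format="%.4f"
        )
        truth.to_csv(outdir / "truth.tsv", sep="\t", index=False, float_format="%.6f")
    return out
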