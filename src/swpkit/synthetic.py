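"""Synthetic slow-wave-potential generator.

The measured recordings this package was designed around are not publicly
archived, so the generator emulates the statistical structure the pipeline
assumes: a flat pre-wound baseline, a rapid (sigmoidal) depolarization of a
condition-dependent depth, a slow exponential repolarization parameterized by
its half-recovery time, white measurement noise, and a slow random-walk
baseline drift — all sampled at 100 Hz.

Depolarization is a *negative-going* deflection (surface-potential
convention), so the wound response is a drop below baseline followed by a
partial recovery toward it.

The default condition profiles encode a decodable darkness effect: traces
from plants kept longer in darkness (SED, LED) are deeper and longer-lasting
than Normal ones, with amplitudes and half-times separated by at least 25%
between neighbouring conditions. The magnitudes are illustrative defaults,
chosen so the three classes are separable by trace kinetics, not calibrated
to any measured distribution (none is published).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from swpkit.errors import DataError
from swpkit.io import (
    CONDITIONS,
    DatasetManifest,
    ManifestRecord,
    RawRecording,
    write_manifest,
    write_trace,
)


@dataclass(frozen=True)
class ConditionParams:
    """Waveform parameters of one (leaf, condition) group.

    Parameters
    ----------
    amplitude_mV : float
        Depth of the depolarization below baseline, mV.
    depol_duration_s : float
        Duration of the sigmoidal drop from baseline to the minimum, s.
    repol_half_time_s : float
        Time from the minimum to half recovery of the depolarization, s.
    baseline_mV : float
        Pre-wound resting surface potential, mV.
    noise_sd_mV : float
        SD of additive white measurement noise, mV.
    drift_sd_mV_per_s : float
        SD of the integrated (random-walk) baseline drift per second, mV/s.
    """

    amplitude_mV: float
    depol_duration_s: float
    repol_half_time_s: float
    baseline_mV: float = 0.0
    noise_sd_mV: float = 0.3
    drift_sd_mV_per_s: float = 0.01

    def __post_init__(self) -> None:
        if self.amplitude_mV <= 0 or self.depol_duration_s <= 0 or self.repol_half_time_s <= 0:
            raise DataError("amplitude, depolarization duration and half time must be positive")
        if self.noise_sd_mV < 0 or self.drift_sd_mV_per_s < 0:
            raise DataError("noise and drift SDs must be non-negative")


def _default_profiles() -> dict[tuple[int, str], ConditionParams]:
    # Deeper and slower with longer darkness; >= 25% separation between
    # neighbouring conditions in both amplitude and half time.
    return {
        (8, "Normal"): ConditionParams(20.0, 8.0, 60.0),
        (8, "SED"): ConditionParams(28.0, 11.0, 90.0),
        (8, "LED"): ConditionParams(40.0, 15.0, 140.0),
        (13, "Normal"): ConditionParams(10.0, 10.0, 50.0),
        (13, "SED"): ConditionParams(14.0, 14.0, 75.0),
        (13, "LED"): ConditionParams(20.0, 19.0, 120.0),
    }


@dataclass(frozen=True)
class SyntheticConfig:
    """Full description of a synthetic dataset.

    Defaults mirror the measured-study design: 20 Normal, 20 SED and 15 LED
    plants, each contributing a wounded (leaf 8) and a systemic (leaf 13)
    recording at 100 Hz.
    """

    profiles: dict = field(default_factory=_default_profiles)
    n_per_condition: tuple[int, int, int] = (20, 20, 15)  # Normal, SED, LED
    pre_wound_s: float = 20.0
    sampling_rate_hz: float = 100.0
    seed: int = 10

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.n_per_condition):
            raise DataError("n_per_condition entries must be >= 1")
        if self.pre_wound_s <= 0 or self.sampling_rate_hz <= 0:
            raise DataError("pre_wound_s and sampling_rate_hz must be positive")


def synthesize_recording(
    params: ConditionParams,
    sample_id: str,
    leaf: int,
    condition: str,
    seed: int,
    pre_wound_s: float = 20.0,
    sampling_rate_hz: float = 100.0,
) -> RawRecording:
    """Generate one SWP-like recording.

    The noiseless waveform is ``baseline`` until the wound, then a smooth
    half-cosine drop of depth ``amplitude_mV`` over ``depol_duration_s``,
    then exponential relaxation toward baseline,
    ``v(t) = baseline - A * 2**(-t / repol_half_time_s)`` for time ``t`` past
    the minimum — so the noiseless half-recovery level is crossed exactly one
    half time after the minimum. The recording extends 1.5 half times past
    the minimum, guaranteeing the crossing exists.
    """
    rate = sampling_rate_hz
    rng = np.random.default_rng(seed)
    n_pre = int(round(pre_wound_s * rate))
    n_depol = int(round(params.depol_duration_s * rate))
    n_repol = int(round(1.5 * params.repol_half_time_s * rate))
    if n_depol < 2:
        raise DataError("depol_duration_s too short for the sampling rate")

    A, b = params.amplitude_mV, params.baseline_mV
    t_dep = np.arange(1, n_depol + 1) / n_depol
    depol = b - A * 0.5 * (1.0 - np.cos(math.pi * t_dep))  # smooth drop to b - A
    t_rep = np.arange(1, n_repol + 1) / rate
    repol = b - A * np.exp2(-t_rep / params.repol_half_time_s)
    clean = np.concatenate([np.full(n_pre + 1, b), depol, repol])

    noise = rng.normal(0.0, params.noise_sd_mV, clean.size)
    drift_steps = rng.normal(0.0, params.drift_sd_mV_per_s / math.sqrt(rate), clean.size)
    drift = np.cumsum(drift_steps)
    return RawRecording(
        sample_id=sample_id,
        leaf=leaf,
        condition=condition,
        values=clean + noise + drift,
        wound_index=n_pre,
        sampling_rate_hz=rate,
    )


def synthesize_group(
    cfg: SyntheticConfig, leaf: int, condition: str, n: int
) -> list[RawRecording]:
    """Generate the ``n`` recordings of one (leaf, condition) group in memory."""
    params = cfg.profiles[(leaf, condition)]
    ss = np.random.SeedSequence(
        entropy=cfg.seed, spawn_key=(leaf, CONDITIONS.index(condition))
    )
    seeds = ss.generate_state(n)
    return [
        synthesize_recording(
            params,
            sample_id=f"leaf{leaf}_{condition}_{i:03d}",
            leaf=leaf,
            condition=condition,
            seed=int(seeds[i]),
            pre_wound_s=cfg.pre_wound_s,
            sampling_rate_hz=cfg.sampling_rate_hz,
        )
        for i in range(n)
    ]


def synthesize_leaf(cfg: SyntheticConfig, leaf: int) -> list[RawRecording]:
    """All recordings of one leaf, conditions in canonical order."""
    recs: list[RawRecording] = []
    for condition, n in zip(CONDITIONS, cfg.n_per_condition):
        recs.extend(synthesize_group(cfg, leaf, condition, n))
    return recs


def synthesize_dataset(cfg: SyntheticConfig, out_dir: str | Path) -> dict[int, DatasetManifest]:
    """Write the full synthetic dataset to disk: trace CSVs plus one manifest per leaf.

    Per-recording seeds are derived deterministically from ``cfg.seed`` and the
    sample's (leaf, condition, index) position, so regeneration is
    bit-reproducible and independent of generation order.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifests: dict[int, DatasetManifest] = {}
    for leaf in (8, 13):
        records = []
        for rec in synthesize_leaf(cfg, leaf):
            fname = f"{rec.sample_id}.csv"
            write_trace(rec, out_dir / fname)
            records.append(ManifestRecord(rec.sample_id, leaf, rec.condition, fname))
        manifest = DatasetManifest(records=tuple(records), provenance="synthetic")
        write_manifest(manifest, out_dir / f"manifest_leaf{leaf}.csv")
        manifests[leaf] = manifest
    return manifests
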