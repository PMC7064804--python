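"""Synthetic two-group fNIRS cohorts with known connectivity ground truth.

The generator emulates the acquisition conditions the pipeline is built
for — 80-channel whole-head montages sampled at 17 Hz, 8-minute usable
segments, and two groups of 30 subjects — and plants a known group
difference: a chosen edge set whose correlations are attenuated by delta
in the patient group.  Neural signal is Gaussian noise colored to the
0.01-0.08 Hz hemodynamic band and mixed through the Cholesky factor of a
per-subject target correlation matrix, which gives exact control of the
target functional connectivity.  On top of the neural signal the
generator layers the structured nuisance terms the preprocessing stage is
meant to remove: linear drift, a Mayer-wave band oscillation near 0.1 Hz,
a cardiac sinusoid near 1.2 Hz, a shared superficial (global) component,
and exponentially decaying motion spikes at Poisson times.

Symptom scores are a linear function of each subject's realized
planted-edge strength plus covariate terms and Gaussian noise, with the
true weights recorded so downstream correlation recovery can be tested.
The whole cohort is a pure function of (config, seed).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .layout_io import (
    ChannelMap,
    HemoglobinRecording,
    make_default_layout,
    validate_cohort,
)

__all__ = [
    "CovarianceSpec",
    "EffectSpec",
    "NoiseSpec",
    "SymptomSpec",
    "SimulationConfig",
    "SyntheticCohort",
    "build_target_covariance",
    "nearest_correlation",
    "simulate_recording",
    "simulate_scores",
    "simulate_cohort",
    "simulate_group_z_matrices",
    "simulate_labeled_components",
]

NEURAL_BAND = (0.01, 0.08)  # Hz; the hemodynamic band the neural signal lives in


@dataclasses.dataclass
class CovarianceSpec:
    """Block-structured target correlations keyed by functional network.

    ``r_within``/``r_between`` set same-network and cross-network channel
    correlations; ``r_homo`` is an additive boost for declared homolog
    pairs, emulating the strong homotopic coupling of resting-state
    networks.
    """

    r_within: float = 0.35
    r_between: float = 0.10
    r_homo: float = 0.30


@dataclasses.dataclass
class EffectSpec:
    """Planted patient-group attenuation on a fixed edge set.

    ``edges`` are 1-based channel-id pairs; patient correlations on those
    edges are reduced by ``delta`` on average.  Each subject additionally
    carries a single severity deviation of SD ``subject_sd`` shared
    across the planted edge set (in both groups), giving the symptom
    model realistic between-subject variance to couple to.
    """

    edges: tuple[tuple[int, int], ...] = ()
    delta: float = 0.25
    subject_sd: float = 0.10


@dataclasses.dataclass
class NoiseSpec:
    """Amplitudes (micromolar, relative to unit-SD neural signal) of the
    structured nuisance terms."""

    drift_amp: float = 0.5  # peak linear drift over the recording
    mayer_amp: float = 0.2
    mayer_freq: float = 0.1  # Hz
    cardiac_amp: float = 0.3
    cardiac_freq: float = 1.2  # Hz
    global_amp: float = 0.3
    spike_rate: float = 1.0 / 60.0  # motion events per second (whole head)
    spike_amp: float = 1.0
    spike_tau: float = 2.0  # s, exponential decay constant

    def zeroed(self) -> "NoiseSpec":
        return NoiseSpec(
            drift_amp=0.0,
            mayer_amp=0.0,
            mayer_freq=self.mayer_freq,
            cardiac_amp=0.0,
            cardiac_freq=self.cardiac_freq,
            global_amp=0.0,
            spike_rate=0.0,
            spike_amp=0.0,
            spike_tau=self.spike_tau,
        )


@dataclasses.dataclass
class SymptomSpec:
    """Linear model tying symptom scores to planted-edge strength.

    Scores are intercept + weight * (subject's mean planted-edge r minus
    the control-group target) + covariate terms + Gaussian noise, clipped
    at zero; negative weights encode "weaker connectivity, worse
    symptoms".  The total score is the sum of the two subscales.
    """

    inattentive_weight: float = -6.0
    hyperactive_weight: float = -10.0
    noise_sd: float = 1.0
    intercepts: dict = dataclasses.field(
        default_factory=lambda: {
            "patient": {"inattentive": 14.6, "hyperactive_impulsive": 8.4},
            "control": {"inattentive": 8.6, "hyperactive_impulsive": 7.0},
        }
    )
    age_weight: float = 0.02  # per month, centered at the cohort mean
    education_weight: float = -0.1  # per year
    sex_weight: float = 0.5  # male indicator


@dataclasses.dataclass
class SimulationConfig:
    n_channels: int = 80
    fs: float = 17.0
    duration_s: float = 480.0
    n_per_group: int = 30
    covariance: CovarianceSpec = dataclasses.field(default_factory=CovarianceSpec)
    effect: EffectSpec = dataclasses.field(default_factory=EffectSpec)
    noise: NoiseSpec = dataclasses.field(default_factory=NoiseSpec)
    symptoms: SymptomSpec = dataclasses.field(default_factory=SymptomSpec)
    subject_jitter_sd: float = 0.03  # per-subject SD on all target correlations
    male_fraction: float = 1.0  # study cohorts are boys; lower to mix sexes
    include_hbr: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.effect.edges:
            self.effect.edges = default_planted_clique(self.n_channels)

    def layout(self) -> ChannelMap:
        return make_default_layout(self.n_channels)

    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


@dataclasses.dataclass
class SyntheticCohort:
    recordings: list[HemoglobinRecording]
    cohort: pd.DataFrame
    truth: dict
    layout: ChannelMap


def default_planted_clique(n_channels: int) -> tuple[tuple[int, int], ...]:
    """Six-edge clique on four same-network channels in the left hemisphere."""
    half = n_channels // 2
    if half < 4:
        return ()
    start = max(1, half // 4)
    nodes = list(range(start, start + 4))
    return tuple(
        (a, b) for ai, a in enumerate(nodes) for b in nodes[ai + 1 :]
    )


def nearest_correlation(matrix: np.ndarray, floor: float = 1e-4) -> np.ndarray:
    """Repair a symmetric matrix to a positive-definite correlation matrix.

    Eigenvalues are clipped at ``floor`` and the result renormalized to a
    unit diagonal — the standard fix when edge-level edits break positive
    definiteness.
    """
    sym = (matrix + matrix.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    if vals.min() >= floor:
        out = sym
    else:
        out = (vecs * np.clip(vals, floor, None)) @ vecs.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out


def _edge_indices(
    edges: Sequence[tuple[int, int]], layout: ChannelMap
) -> np.ndarray:
    return np.array(
        [[layout.index_of(a), layout.index_of(b)] for a, b in edges], dtype=int
    )


def build_target_covariance(
    config: SimulationConfig, group: str, layout: ChannelMap | None = None
) -> np.ndarray:
    """Group-level target correlation matrix.

    Same-network pairs get ``r_within``, cross-network pairs
    ``r_between``, homolog pairs an extra ``r_homo``; the patient matrix
    additionally subtracts ``delta`` on the planted edges.  The result is
    repaired to the nearest positive-definite correlation matrix; a
    config whose targets cannot be made a valid correlation matrix is
    rejected.
    """
    if group not in ("patient", "control"):
        raise ValueError(f"unknown group {group!r}")
    layout = layout or config.layout()
    cov = config.covariance
    labels = layout.network_label
    same_net = labels[:, None] == labels[None, :]
    r = np.where(same_net, cov.r_within, cov.r_between).astype(float)
    for i, h in enumerate(layout.homolog_id):
        if h:
            j = layout.index_of(int(h))
            r[i, j] += cov.r_homo
            # symmetric partner handled when the loop reaches j
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    if group == "patient" and config.effect.edges:
        for i, j in _edge_indices(config.effect.edges, layout):
            r[i, j] -= config.effect.delta
            r[j, i] = r[i, j]
    off = r[~np.eye(len(layout), dtype=bool)]
    if np.abs(off).max() >= 1.0:
        raise ValueError("target correlations must satisfy |r| < 1")
    repaired = nearest_correlation(r)
    if np.linalg.eigvalsh(repaired).min() <= 0:
        raise ValueError("target correlation not positive definite after repair")
    return repaired


def _subject_target(
    config: SimulationConfig,
    group: str,
    layout: ChannelMap,
    group_target: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    n = group_target.shape[0]
    jit = rng.normal(0.0, config.subject_jitter_sd, size=(n, n))
    jit = np.triu(jit, 1)
    r = group_target + jit + jit.T
    if config.effect.edges and config.effect.subject_sd > 0:
        # One deviation per subject, shared across the planted edge set: a
        # subject's connectivity deficit on the planted circuit is a single
        # severity factor, which is what the symptom model couples to.
        dev = rng.normal(0.0, config.effect.subject_sd)
        for i, j in _edge_indices(config.effect.edges, layout):
            r[i, j] += dev
            r[j, i] = r[i, j]
    r = np.clip(r, -0.99, 0.99)
    np.fill_diagonal(r, 1.0)
    return nearest_correlation(r)


def _band_limited_noise(
    rng: np.random.Generator,
    n_channels: int,
    n_samples: int,
    fs: float,
    band: tuple[float, float],
) -> np.ndarray:
    """Independent unit-variance Gaussian signals confined to ``band``."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    spec[:, ~mask] = 0.0
    sig = np.fft.irfft(spec, n=n_samples, axis=1)
    sd = sig.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return sig / sd


def simulate_recording(
    config: SimulationConfig,
    group: str,
    subject_seed: int,
    subject_id: str = "",
    layout: ChannelMap | None = None,
    group_target: np.ndarray | None = None,
    return_truth: bool = False,
):
    """One subject's HbO recording, deterministic given (config, seeds).

    Neural signal: band-limited Gaussian noise mixed via the Cholesky
    factor of the subject's (jittered) target correlation.  Structured
    noise terms are added per ``config.noise``.  With ``return_truth``
    also returns the subject target matrix and the clean neural signal.
    """
    layout = layout or config.layout()
    if group_target is None:
        group_target = build_target_covariance(config, group, layout)
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, int(subject_seed)])
    )
    n = config.n_channels
    t_len = config.n_samples()
    target = _subject_target(config, group, layout, group_target, rng)
    base = _band_limited_noise(rng, n, t_len, config.fs, NEURAL_BAND)
    chol = np.linalg.cholesky(target + 1e-10 * np.eye(n))
    neural = chol @ base

    noise = config.noise
    t = np.arange(t_len) / config.fs
    data = neural.copy()
    if noise.drift_amp:
        slopes = rng.uniform(-1.0, 1.0, size=n) * noise.drift_amp
        data += slopes[:, None] * (t / t[-1])[None, :]
    if noise.mayer_amp:
        phases = rng.uniform(0, 2 * np.pi, size=n)
        amps = noise.mayer_amp * rng.uniform(0.5, 1.5, size=n)
        data += amps[:, None] * np.sin(
            2 * np.pi * noise.mayer_freq * t[None, :] + phases[:, None]
        )
    if noise.cardiac_amp:
        phases = rng.uniform(0, 2 * np.pi, size=n)
        amps = noise.cardiac_amp * rng.uniform(0.5, 1.5, size=n)
        data += amps[:, None] * np.sin(
            2 * np.pi * noise.cardiac_freq * t[None, :] + phases[:, None]
        )
    if noise.global_amp:
        shared = _band_limited_noise(rng, 1, t_len, config.fs, (0.01, 0.3))[0]
        weights = noise.global_amp * rng.uniform(0.5, 1.0, size=n)
        data += weights[:, None] * shared[None, :]
    if noise.spike_rate > 0 and noise.spike_amp > 0:
        # Head-motion events hit every optode at the same instant with
        # channel-specific amplitude and sign, so each event is a spatially
        # coherent, exponentially decaying jump.
        tau_samples = noise.spike_tau * config.fs
        kernel_len = int(min(t_len, np.ceil(6 * tau_samples)))
        kernel = np.exp(-np.arange(kernel_len) / tau_samples)
        n_events = rng.poisson(noise.spike_rate * config.duration_s)
        for _ in range(n_events):
            onset = int(rng.integers(0, t_len))
            heights = noise.spike_amp * rng.exponential(1.0, size=n)
            heights *= rng.choice([-1.0, 1.0], size=n)
            stop = min(t_len, onset + kernel_len)
            data[:, onset:stop] += heights[:, None] * kernel[: stop - onset]

    rec = HemoglobinRecording(
        subject_id=subject_id or f"s{subject_seed:03d}",
        species="HbO",
        data=data,
        fs=config.fs,
        channel_ids=layout.channel_id.copy(),
    )
    if return_truth:
        return rec, target, neural
    return rec


def simulate_scores(
    config: SimulationConfig,
    planted_strength: float,
    covariates: dict,
    group: str,
    rng: np.random.Generator,
    control_baseline: float,
) -> dict:
    """Symptom scores from the linear truth model.

    ``planted_strength`` is the subject's realized mean correlation on the
    planted edges; ``control_baseline`` is the control-group target on
    those edges, so the coupling term vanishes for an average control.
    """
    spec = config.symptoms
    dev = planted_strength - control_baseline
    common = (
        spec.age_weight * (float(covariates["age_months"]) - 114.0)
        + spec.education_weight * (float(covariates["education_years"]) - 3.5)
        + spec.sex_weight * (1.0 if covariates["sex"] == "male" else 0.0)
    )
    inatt = (
        spec.intercepts[group]["inattentive"]
        + spec.inattentive_weight * dev
        + common
        + rng.normal(0.0, spec.noise_sd)
    )
    hyper = (
        spec.intercepts[group]["hyperactive_impulsive"]
        + spec.hyperactive_weight * dev
        + common
        + rng.normal(0.0, spec.noise_sd)
    )
    inatt = max(0.0, inatt)
    hyper = max(0.0, hyper)
    return {
        "inattentive": inatt,
        "hyperactive_impulsive": hyper,
        "total": inatt + hyper,
    }


def _simulate_covariates(rng: np.random.Generator, config: SimulationConfig) -> dict:
    return {
        "age_months": float(np.clip(rng.normal(114.0, 15.0), 84.0, 150.0)),
        "sex": "male" if rng.random() < config.male_fraction else "female",
        "education_years": float(np.clip(rng.normal(3.5, 1.2), 1.0, 6.0)),
    }


def _planted_strength(
    target: np.ndarray, edge_idx: np.ndarray
) -> float:
    if edge_idx.size == 0:
        return 0.0
    return float(np.mean([target[i, j] for i, j in edge_idx]))


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Full two-group cohort: recordings, cohort table, and ground truth."""
    layout = config.layout()
    targets = {
        g: build_target_covariance(config, g, layout)
        for g in ("patient", "control")
    }
    edge_idx = _edge_indices(config.effect.edges, layout)
    control_baseline = _planted_strength(targets["control"], edge_idx)

    recordings: list[HemoglobinRecording] = []
    rows = []
    subject_truth = {}
    subject_seed = 0
    for group, prefix in (("patient", "adhd"), ("control", "hc")):
        for k in range(config.n_per_group):
            subject_seed += 1
            sid = f"{prefix}{k + 1:02d}"
            rec, target, _ = simulate_recording(
                config,
                group,
                subject_seed,
                subject_id=sid,
                layout=layout,
                group_target=targets[group],
                return_truth=True,
            )
            recordings.append(rec)
            if config.include_hbr:
                hbr_rng = np.random.default_rng(
                    np.random.SeedSequence([config.seed, subject_seed, 9])
                )
                hbr = rec.copy_with(
                    -0.5 * rec.data
                    + 0.05 * hbr_rng.standard_normal(rec.data.shape)
                )
                hbr.species = "HbR"
                hbr.subject_id = sid
                recordings.append(hbr)
            score_rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, subject_seed, 7])
            )
            covariates = _simulate_covariates(score_rng, config)
            strength = _planted_strength(target, edge_idx)
            scores = simulate_scores(
                config, strength, covariates, group, score_rng, control_baseline
            )
            rows.append({"subject_id": sid, "group": group, **covariates, **scores})
            subject_truth[sid] = {"planted_strength": strength}
    cohort = validate_cohort(pd.DataFrame(rows))
    truth = {
        "target_correlation": {g: targets[g] for g in targets},
        "planted_edges": [list(e) for e in config.effect.edges],
        "delta": config.effect.delta,
        "control_baseline": control_baseline,
        "score_weights": {
            "inattentive": config.symptoms.inattentive_weight,
            "hyperactive_impulsive": config.symptoms.hyperactive_weight,
        },
        "subjects": subject_truth,
    }
    return SyntheticCohort(
        recordings=recordings, cohort=cohort, truth=truth, layout=layout
    )


def simulate_labeled_components(
    n_channels: int = 80,
    n_samples: int = 8160,
    fs: float = 17.0,
    seed: int = 0,
    n_clean: int = 4,
    noise: NoiseSpec | None = None,
):
    """A component set with known clean/noise labels, for classifier
    calibration.

    Clean components are band-limited hemodynamic signals with focal
    spatial maps; noise components are one each of the artifact families
    the screening criteria target: a slow drift, a cardiac-band
    sinusoid, a spike-burst profile, and a globally dispersive
    superficial component.  Returns ``(ComponentSet, labels)`` where
    ``labels[k]`` is True for injected noise.
    """
    from .preprocessing import ComponentSet, _diagnose

    noise = noise or NoiseSpec()
    rng = np.random.default_rng(seed)
    t = np.arange(n_samples) / fs
    sources, maps, labels = [], [], []

    def focal_map(k_loaded: int = 3) -> np.ndarray:
        w = np.zeros(n_channels)
        idx = rng.choice(n_channels, size=k_loaded, replace=False)
        w[idx] = rng.uniform(0.5, 1.0, size=k_loaded)
        return w

    for _ in range(n_clean):
        sources.append(_band_limited_noise(rng, 1, n_samples, fs, NEURAL_BAND)[0])
        maps.append(focal_map())
        labels.append(False)
    # Drift: dominant frequency below the band.
    drift = t - t.mean()
    sources.append(drift / drift.std())
    maps.append(focal_map(5))
    labels.append(True)
    # Cardiac oscillation: dominant frequency above the band.
    sources.append(
        np.sin(2 * np.pi * noise.cardiac_freq * t + rng.uniform(0, 2 * np.pi))
    )
    maps.append(focal_map(5))
    labels.append(True)
    # Motion spikes: sudden decaying jumps on a smooth carrier.
    s = _band_limited_noise(rng, 1, n_samples, fs, NEURAL_BAND)[0]
    kernel = np.exp(-np.arange(int(4 * noise.spike_tau * fs)) / (noise.spike_tau * fs))
    for onset in rng.integers(0, max(1, n_samples - kernel.size), size=4):
        s[onset : onset + kernel.size] += 8.0 * kernel
    sources.append(s)
    maps.append(focal_map(5))
    labels.append(True)
    # Superficial physiology: globally dispersive spatial map.
    sources.append(_band_limited_noise(rng, 1, n_samples, fs, NEURAL_BAND)[0])
    maps.append(rng.uniform(0.7, 1.0, size=n_channels))
    labels.append(True)

    sources_arr = np.asarray(sources)
    mixing = np.asarray(maps).T
    comps = ComponentSet(
        mixing=mixing,
        sources=sources_arr,
        mean=np.zeros(n_channels),
        residual=np.zeros((n_channels, n_samples)),
        fs=fs,
        diagnostics=_diagnose(mixing, sources_arr, fs),
    )
    return comps, np.asarray(labels, dtype=bool)


def simulate_group_z_matrices(
    config: SimulationConfig, group: str, seed_offset: int = 0
) -> np.ndarray:
    """Stack of per-subject empirical Fisher-z matrices for one group.

    Convenience path for statistical calibration: simulates each
    subject's recording (at the configured noise levels) and computes its
    Pearson/Fisher-z matrix without writing any files.
    """
    from .connectivity import pearson_matrix

    layout = config.layout()
    group_target = build_target_covariance(config, group, layout)
    out = np.empty(
        (config.n_per_group, config.n_channels, config.n_channels)
    )
    for k in range(config.n_per_group):
        rec = simulate_recording(
            config,
            group,
            seed_offset + k,
            layout=layout,
            group_target=group_target,
        )
        z = pearson_matrix(rec).z
        np.fill_diagonal(z, 0.0)
        out[k] = z
    return out
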