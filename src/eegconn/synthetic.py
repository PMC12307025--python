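"""Synthetic EEG cohorts with known coupling and regression structure.

Every downstream stage of the pipeline is validated against data whose
ground truth is known.  The generator emulates 61-channel eyes-closed
resting recordings:

* per channel, a sum of band-limited stochastic oscillators (narrowband
  filtered white noise), with the alpha oscillator centred on the
  subject's true alpha peak so the IAPF stage has a recoverable target;
* 1/f background noise with configurable spectral slope;
* cross-channel coupling implemented by mixing a time-lagged copy of the
  source channel's band oscillator into the target at a given strength —
  this gives direct control of the imaginary cross-spectrum that the
  dwPLI estimator measures (default lag pi/2, which maximises it);
* optional zero-lag common-source mixing shared instantaneously by all
  channels, which inflates real-part coherence but leaves wPLI-family
  estimators untouched — the volume-conduction confound;
* behavioural fluency scores drawn from a linear model on a chosen graph
  metric with treatment-coded age/sex terms and a metric-by-age
  interaction, rounded to nonnegative integer word counts.

Older subjects draw their true alpha peak from N(9.4, 0.9) Hz and younger
from N(10.1, 0.9) Hz, matching the age-related slowing the band
individualisation exists to absorb.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .spectral import ContinuousEEG, derive_bands

__all__ = [
    "CouplingSpec",
    "SyntheticSubject",
    "CohortSpec",
    "TEN_TEN_61",
    "default_module_assignment",
    "generate_subject_signals",
    "generate_cohort",
    "plant_fluency_scores",
]

# 61-channel 10-10 montage (the standard extended international layout).
TEN_TEN_61 = [
    "Fp1", "Fp2", "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8", "O1", "Oz", "O2", "Iz",
]

# relative oscillator amplitudes per band; alpha dominant as at rest
_BAND_AMPLITUDE = {"delta": 1.0, "theta": 0.8, "alpha": 1.6, "beta": 0.7}
_NOISE_AMPLITUDE = 0.7

# default planted regression: intercept at the younger-adult semantic mean,
# age/sex/metric effects on the scale of word counts
DEFAULT_PLANTED_BETAS = {
    "intercept": 25.0,
    "metric": 1.45,
    "age": -2.46,
    "sex": -0.06,
    "interaction": -3.85,
}


@dataclass(frozen=True)
class CouplingSpec:
    """Directed phase-lagged sharing of a band oscillator between channels."""

    source_channel: str
    target_channel: str
    band: str
    phase_lag: float = math.pi / 2
    strength: float = 0.5

    def __post_init__(self) -> None:
        if not -math.pi < self.phase_lag <= math.pi:
            raise ValueError("phase_lag must lie in (-pi, pi]")
        if not 0 <= self.strength <= 1:
            raise ValueError("strength must lie in [0, 1]")
        if self.source_channel == self.target_channel:
            raise ValueError("source and target must differ")


@dataclass
class SyntheticSubject:
    """One simulated participant."""

    subject_id: str
    age_group: str  # "younger" | "older"
    sex: str  # "female" | "male"
    iapf_true: float
    couplings: list[CouplingSpec] = field(default_factory=list)
    module_assignment: dict[str, int] = field(default_factory=dict)
    noise_exponent: float = 1.0
    zero_lag_mix: float = 0.0
    sampling_rate: float = 250.0
    duration: float = 60.0
    channel_labels: list[str] = field(default_factory=lambda: list(TEN_TEN_61))

    def __post_init__(self) -> None:
        if not 7.0 <= self.iapf_true <= 13.0:
            raise ValueError("iapf_true must lie in [7, 13] Hz")
        if self.sampling_rate < 250:
            raise ValueError("sampling_rate must be >= 250 Hz")
        if self.duration < 60:
            raise ValueError("duration must be >= 60 s")
        if not 0 <= self.zero_lag_mix < 1:
            raise ValueError("zero_lag_mix must lie in [0, 1)")
        if self.age_group not in ("younger", "older"):
            raise ValueError("age_group must be 'younger' or 'older'")
        if self.sex not in ("female", "male"):
            raise ValueError("sex must be 'female' or 'male'")


@dataclass
class CohortSpec:
    """Cohort-level generation parameters.

    ``planted_betas`` holds the coefficients of the score model (keys:
    intercept, metric, age, sex, interaction); the metric is z-scaled
    before the betas apply, so they are in word-count units.
    """

    n_per_group: int
    n_channels: int = 61
    planted_betas: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PLANTED_BETAS))
    residual_sd: float = 5.0
    seed: int = 0
    iapf_mean_younger: float = 10.1
    iapf_mean_older: float = 9.4
    iapf_sd: float = 0.9
    coupling_strength: float = 0.55
    n_modules: int = 4
    sampling_rate: float = 250.0
    duration: float = 480.0
    noise_exponent: float = 1.0
    zero_lag_mix: float = 0.0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")


def default_module_assignment(labels: list[str], n_modules: int
                              ) -> dict[str, int]:
    """Contiguous blocks of channels as planted communities."""
    n = len(labels)
    size = math.ceil(n / n_modules)
    return {lab: min(i // size, n_modules - 1) for i, lab in enumerate(labels)}


def _band_envelope(band_name: str, iapf: float, freqs: np.ndarray
                   ) -> np.ndarray:
    """Spectral amplitude envelope of one band oscillator.

    Each oscillator occupies its full IAPF-relative band (lower edge
    clamped to 0.5 Hz); the alpha envelope carries an additional Gaussian
    bump (SD 0.75 Hz) centred on the true alpha peak so the power
    spectrum peaks exactly at the subject's IAPF.
    """
    bands = {b.name: b for b in derive_bands(iapf)}
    b = bands[band_name]
    lo = max(b.f_lo, 0.5)
    hi = b.f_hi
    env = ((freqs >= lo) & (freqs < hi)).astype(float)
    if band_name == "alpha":
        env = env * (1.0 + 4.0 * np.exp(-((freqs - iapf) ** 2)
                                        / (2 * 0.75 ** 2)))
    return env


def _band_oscillator(white: np.ndarray, env: np.ndarray,
                     phase: float = 0.0) -> np.ndarray:
    """Shape white noise by a spectral envelope, optionally rotating every
    positive-frequency component by ``phase`` radians (a uniform phase lag
    across the band)."""
    spec = np.fft.rfft(white) * env
    if phase:
        spec = spec * np.exp(-1j * phase)
    out = np.fft.irfft(spec, n=len(white))
    return _unit_var(out)


def _pink_noise(n: int, exponent: float, rng: np.random.Generator
                ) -> np.ndarray:
    """1/f^exponent noise by spectral shaping, unit variance."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    shape = np.ones_like(freqs)
    nz = freqs > 0
    shape[nz] = freqs[nz] ** (-exponent / 2.0)
    shape[0] = 0.0
    out = np.fft.irfft(spec * shape, n=n)
    sd = out.std()
    return out / sd if sd > 0 else out


def _unit_var(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_subject_signals(subject: SyntheticSubject, seed: int
                             ) -> ContinuousEEG:
    """Simulate one subject's multichannel recording.

    Each channel is an amplitude-weighted sum of four band-limited
    oscillators (spectrally shaped white noise) plus 1/f noise.  A
    coupling replaces part of the target's band oscillator with a
    phase-rotated copy of the source's: every positive-frequency
    component of the shared oscillator is rotated by ``phase_lag``
    radians, so the planted lag is uniform across the band and shows up
    directly in the imaginary cross-spectrum.  Deterministic for a fixed
    seed.
    """
    fs = subject.sampling_rate
    n = int(round(subject.duration * fs))
    if subject.duration < 12.0:
        raise ValueError(
            "duration too short: at least one 12 s epoch (12.0 s) is needed"
        )
    labels = list(subject.channel_labels)
    n_ch = len(labels)
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    envelopes = {band: _band_envelope(band, subject.iapf_true, freqs)
                 for band in ("delta", "theta", "alpha", "beta")}

    # per channel x band: the underlying white noise (couplings reuse the
    # source's noise) and the shaped unit-variance oscillator
    white: dict[tuple[str, str], np.ndarray] = {}
    osc: dict[tuple[str, str], np.ndarray] = {}
    for lab in labels:
        for band in ("delta", "theta", "alpha", "beta"):
            w = rng.standard_normal(n)
            white[(lab, band)] = w
            osc[(lab, band)] = _band_oscillator(w, envelopes[band])

    # apply couplings: target band component mixes a phase-lagged copy
    incoming: dict[tuple[str, str], list[CouplingSpec]] = {}
    for c in subject.couplings:
        incoming.setdefault((c.target_channel, c.band), []).append(c)
    mixed: dict[tuple[str, str], np.ndarray] = dict(osc)
    for (target, band), specs in incoming.items():
        s2 = sum(c.strength ** 2 for c in specs)
        if s2 > 1:
            raise ValueError(
                f"combined coupling strength into {target}/{band} exceeds 1")
        comp = math.sqrt(1.0 - s2) * osc[(target, band)]
        for c in specs:
            lagged = _band_oscillator(white[(c.source_channel, band)],
                                      envelopes[band], phase=c.phase_lag)
            comp = comp + c.strength * lagged
        mixed[(target, band)] = comp

    shared = _pink_noise(n, subject.noise_exponent, rng) \
        if subject.zero_lag_mix > 0 else 0.0

    data = np.empty((n_ch, n))
    for i, lab in enumerate(labels):
        x = _NOISE_AMPLITUDE * _pink_noise(n, subject.noise_exponent, rng)
        for band, amp in _BAND_AMPLITUDE.items():
            x = x + amp * mixed[(lab, band)]
        if subject.zero_lag_mix > 0:
            x = math.sqrt(1 - subject.zero_lag_mix ** 2) * x \
                + subject.zero_lag_mix * x.std() * shared
        data[i] = x
    return ContinuousEEG(labels, fs, data)


def _default_couplings(labels: list[str], modules: dict[str, int],
                       strength: float) -> list[CouplingSpec]:
    """Distance-decaying lattice coupling within each module (alpha band).

    Every member receives a lagged copy of its module hub's oscillator
    (strength ``strength``) and of its two nearest predecessors (0.75x
    and 0.6x), so planted communities are triangle-rich lattices rather
    than pure stars and support clustering/small-world structure
    downstream.
    """
    def wrap(phi: float) -> float:
        phi = (phi + math.pi) % (2 * math.pi) - math.pi
        return phi if phi > -math.pi else math.pi

    out = []
    # two travelling-wave fields: every channel receives the first and the
    # last channel's band oscillators at channel-specific phases, so every
    # pair shares consistent relative lags sin(phi_i - phi_j).  Two
    # incommensurate phase gradients keep almost every pair away from the
    # invisible zero-lag configuration, giving the broad, smoothly varying
    # coherence structure resting sensor-space EEG shows.
    drivers = ((labels[0], 2.0, 0.3), (labels[-1], 1.3, 0.7))
    for band in ("delta", "theta", "alpha", "beta"):
        for driver, grad, offset in drivers:
            for k, lab in enumerate(labels):
                if lab == driver:
                    continue
                out.append(CouplingSpec(driver, lab, band,
                                        wrap(offset + grad * k), strength))
    # module structure on top, in the alpha band: members additionally
    # share their module hub's oscillator with an intra-module phase
    # gradient, raising within-module coherence above between-module
    members: dict[int, list[str]] = {}
    for lab in labels:
        members.setdefault(modules[lab], []).append(lab)
    for mod_members in members.values():
        hub = mod_members[0]
        for j, lab in enumerate(mod_members[1:], start=1):
            if hub == driver and lab == driver:
                continue
            out.append(CouplingSpec(hub, lab, "alpha",
                                    wrap(0.25 + 0.4 * j), strength))
    return out


def generate_cohort(spec: CohortSpec, make_signals: bool = True
                    ) -> tuple[list[SyntheticSubject],
                               dict[str, ContinuousEEG]]:
    """Draw a balanced two-group cohort and (optionally) its recordings.

    Older subjects' true alpha peaks are drawn with a lower mean than
    younger subjects' (9.4 vs 10.1 Hz by default, SD 0.9, truncated to
    [7, 13]).  Reproducible for a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    labels = list(TEN_TEN_61[: spec.n_channels]) \
        if spec.n_channels <= 61 else \
        [f"ch{i:03d}" for i in range(spec.n_channels)]
    modules = default_module_assignment(labels, spec.n_modules)
    subjects: list[SyntheticSubject] = []
    for group, mean in (("younger", spec.iapf_mean_younger),
                        ("older", spec.iapf_mean_older)):
        for k in range(spec.n_per_group):
            iapf = float(np.clip(rng.normal(mean, spec.iapf_sd), 7.0, 13.0))
            subjects.append(SyntheticSubject(
                subject_id=f"sub-{group[0]}{k + 1:03d}",
                age_group=group,
                sex="female" if k % 2 == 0 else "male",
                iapf_true=iapf,
                couplings=_default_couplings(labels, modules,
                                             spec.coupling_strength),
                module_assignment=dict(modules),
                noise_exponent=spec.noise_exponent,
                zero_lag_mix=spec.zero_lag_mix,
                sampling_rate=spec.sampling_rate,
                duration=spec.duration,
                channel_labels=labels,
            ))
    signals: dict[str, ContinuousEEG] = {}
    if make_signals:
        seeds = rng.integers(2 ** 31 - 1, size=len(subjects))
        for subj, s in zip(subjects, seeds):
            signals[subj.subject_id] = generate_subject_signals(subj, int(s))
    return subjects, signals


def plant_fluency_scores(metrics: pd.DataFrame, spec: CohortSpec,
                         subjects: list[SyntheticSubject],
                         metric_column: str = "dwpli_mean",
                         band: str = "delta",
                         round_scores: bool = True) -> pd.DataFrame:
    """Generate fluency scores from a linear model on one graph metric.

    ``metrics`` is a long table (subject_id, band, plus metric columns).
    The chosen metric is z-scaled across subjects, then

        score = b0 + b_m * z + b_a * older + b_s * male
                + b_i * z * older + N(0, residual_sd)

    with treatment coding (younger/female reference).  The planted model
    drives ``semantic_fluency``; ``letter_fluency`` is generated from an
    intercept-plus-age model at the letter-task scale so both outcome
    columns exist.  Scores are rounded and clipped at zero (word counts)
    unless ``round_scores=False``.  Subjects whose metric is missing get
    missing scores — never imputed.
    """
    rows = metrics[metrics["band"] == band] if "band" in metrics.columns \
        else metrics
    rows = rows.set_index("subject_id")
    info = {s.subject_id: s for s in subjects}
    betas = spec.planted_betas
    rng = np.random.default_rng(spec.seed + 1)

    vals = rows[metric_column].astype(float)
    mu, sd = vals.mean(), vals.std(ddof=1)
    z = (vals - mu) / sd if sd > 0 else vals * 0.0

    out = []
    for sid in rows.index:
        subj = info[sid]
        older = 1.0 if subj.age_group == "older" else 0.0
        male = 1.0 if subj.sex == "male" else 0.0
        zi = z.loc[sid]
        noise = rng.normal(0.0, spec.residual_sd, size=2)
        if np.isnan(zi):
            semantic = letter = float("nan")
        else:
            semantic = (betas.get("intercept", 0.0)
                        + betas.get("metric", 0.0) * zi
                        + betas.get("age", 0.0) * older
                        + betas.get("sex", 0.0) * male
                        + betas.get("interaction", 0.0) * zi * older
                        + noise[0])
            letter = 15.0 - 2.0 * older + noise[1]
            if round_scores:
                semantic = float(max(round(semantic), 0))
                letter = float(max(round(letter), 0))
        out.append({
            "subject_id": sid,
            "age_group": subj.age_group,
            "sex": subj.sex,
            "semantic_fluency": semantic,
            "letter_fluency": letter,
        })
    return pd.DataFrame(out)
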