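"""Synthetic MEG cohorts with controllable phase coupling and cognition.

Each subject is a network of Kuramoto-style phase oscillators sampled at
the recording rate::

    theta_i(t+1) = theta_i(t) + 2 pi f_i / fs
                   + sum_j K_ij sin((theta_j(t) + c_j) - (theta_i(t) + c_i))
                   + phase noise

with natural frequencies ``f_i`` drawn inside the target band, coupling
``K_ij = kappa`` between ROIs of the designated resting-state network and
``background_coupling`` elsewhere, and per-ROI intrinsic phase offsets
``c_i`` drawn uniformly from ``[0, coupling_lag_rad)`` (heterogeneous
Sakaguchi-style frustration).  Coupling aligns the offset-corrected phases
``theta_i + c_i``, so synchronized ROIs hold persistent pairwise lags
``c_j - c_i``: the phase lag index rises monotonically with coupling
strength and saturates at 1, while uncoupled pairs drift and average to
PLI ~ 0.  (A single common lag inside the sine would cancel out of the
symmetric pair dynamics and make strong coupling lock pairs at *zero* lag,
which PLI discards by construction.)  The observed signal is
``sin(theta_i)`` plus white measurement noise.

Cohort construction draws each subject's within-RSN coupling strength
``kappa_s`` uniformly from ``[kappa_lo, kappa_hi]`` and ties the
working-memory score to it through a Gaussian copula: with
``rho = sin(pi * effect / 2)`` the population Kendall tau between
``kappa_s`` (hence, up to estimation noise, measured RSN PLI) and the
working-memory z-score equals ``effect``.  The other five domains are
generated without any linkage, and patients receive an additional
mean shift on working memory (SD units) to emulate the group deficit.
Only the configured effect band carries the subject-varying coupling;
other bands use a constant mid-range coupling for every subject.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import norm

from . import _kernels
from .cognition import DEFAULT_BATTERY, DOMAINS, HIGHER_BETTER, TestSpec
from .errors import ConfigurationError
from .io import AtlasDefinition, CognitiveTable, RoiTimeSeries, default_atlas
from .spectral import DEFAULT_BANDS, BandDefinition

import pandas as pd

#: control norms used for every synthetic test (raw-score scale)
NORM_MEAN = 50.0
NORM_SD = 10.0

_BURN_IN = 1024  # transient samples discarded before the recorded epochs


@dataclass(frozen=True)
class CohortConfig:
    """Generation parameters for a synthetic patient/control cohort."""

    n_patients: int = 20
    n_controls: int = 20
    n_rois: int = 78
    sample_rate_hz: float = 625.0
    epoch_samples: int = 4096
    n_epochs: int = 5
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
    effect_band: str = "theta"
    effect_rsn: str = "DMN"
    within_rsn_coupling: float = 0.04  # kappa_hi
    kappa_lo: float | None = None  # defaults to within_rsn_coupling / 4
    background_coupling: float = 0.0002
    coupling_lag_rad: float = math.pi / 4
    coupling_cognition_effect: float = 0.5
    wm_patient_shift: float = -0.55  # SD units added to patients' working memory
    noise_sd: float = 0.2
    phase_noise_sd: float = 0.3
    meg_controls: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_epochs < 1:
            raise ConfigurationError("n_epochs must be >= 1")
        if self.epoch_samples < 64:
            raise ConfigurationError("epoch_samples must be >= 64")
        if self.n_rois < 2:
            raise ConfigurationError("n_rois must be >= 2")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        if not 0.0 < self.coupling_lag_rad < math.pi:
            raise ConfigurationError("coupling_lag_rad must lie in (0, pi)")
        if not 0.0 <= self.background_coupling <= self.within_rsn_coupling:
            raise ConfigurationError(
                "need 0 <= background_coupling <= within_rsn_coupling"
            )
        if abs(self.coupling_cognition_effect) >= 1.0:
            raise ConfigurationError("|coupling_cognition_effect| must be < 1")
        if self.kappa_lo is None:
            object.__setattr__(self, "kappa_lo", self.within_rsn_coupling / 4.0)
        if not 0.0 <= self.kappa_lo <= self.within_rsn_coupling:
            raise ConfigurationError("need 0 <= kappa_lo <= within_rsn_coupling")

    @property
    def kappa_hi(self) -> float:
        return self.within_rsn_coupling

    def band(self, name: str) -> BandDefinition:
        for b in self.bands:
            if b.name == name:
                return b
        raise ConfigurationError(f"no band named {name!r} in config")

    def check_stability(self, n_rsn: int) -> None:
        """Per-step coupling drift must stay well below one radian."""
        row = (
            self.kappa_hi * max(n_rsn - 1, 0)
            + self.background_coupling * (self.n_rois - max(n_rsn, 1))
        )
        if row >= 1.0:
            raise ConfigurationError(
                f"total per-step coupling {row:.3f} >= 1; integration unstable"
            )


@dataclass(frozen=True)
class SubjectData:
    subject_id: str
    group: str  # "patient" | "control"
    kappa: float
    raw_scores: dict[str, float]
    timeseries: dict[str, RoiTimeSeries] = field(default_factory=dict)


@dataclass(frozen=True)
class SyntheticCohort:
    subjects: tuple[SubjectData, ...]
    config: CohortConfig
    atlas: AtlasDefinition
    battery: tuple[TestSpec, ...] = DEFAULT_BATTERY

    @property
    def patients(self) -> tuple[SubjectData, ...]:
        return tuple(s for s in self.subjects if s.group == "patient")

    @property
    def controls(self) -> tuple[SubjectData, ...]:
        return tuple(s for s in self.subjects if s.group == "control")

    def cognitive_table(self) -> CognitiveTable:
        rows = [
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "test": test,
                "raw_score": score,
            }
            for s in self.subjects
            for test, score in s.raw_scores.items()
        ]
        norms = pd.DataFrame(
            {
                "test": [t.name for t in self.battery],
                "control_mean": NORM_MEAN,
                "control_sd": NORM_SD,
            }
        )
        return CognitiveTable(scores=pd.DataFrame(rows), norms=norms)


def _toy_atlas(n_rois: int) -> AtlasDefinition:
    """Fallback atlas for small non-78-ROI configurations (tests, demos)."""
    labels = tuple(f"roi{i:02d}" for i in range(n_rois))
    k = max(2, n_rois // 4)
    step = max(1, (n_rois - k) // 2)
    return AtlasDefinition(
        roi_labels=labels,
        rsn_memberships={
            "DMN": labels[:k],
            "FPN_left": labels[k : k + max(2, step)],
            "FPN_right": labels[k + max(2, step) : k + 2 * max(2, step)],
        },
        name=f"toy{n_rois}",
    )


def resolve_atlas(config: CohortConfig, atlas: AtlasDefinition | None) -> AtlasDefinition:
    if atlas is not None:
        if atlas.n_rois != config.n_rois:
            raise ConfigurationError(
                f"atlas has {atlas.n_rois} ROIs but config.n_rois={config.n_rois}"
            )
        return atlas
    if config.n_rois == 78:
        return default_atlas()
    return _toy_atlas(config.n_rois)


def generate_subject(
    config: CohortConfig,
    kappa: float,
    rng: np.random.Generator,
    band: BandDefinition | None = None,
    atlas: AtlasDefinition | None = None,
    subject_id: str = "synthetic",
) -> RoiTimeSeries:
    """Simulate one subject's ROI time series for one frequency band."""
    if kappa < 0:
        raise ConfigurationError("kappa must be >= 0")
    atlas = resolve_atlas(config, atlas)
    band = band or config.band(config.effect_band)
    band.validate_for(config.sample_rate_hz)
    rsn_idx = atlas.rsn_indices(config.effect_rsn)
    cfg = config if kappa <= config.kappa_hi else replace(config, within_rsn_coupling=kappa, kappa_lo=None)
    cfg.check_stability(rsn_idx.size)

    n = config.n_rois
    t_total = config.n_epochs * config.epoch_samples
    steps = t_total + _BURN_IN
    width = band.hi_hz - band.lo_hz
    freqs = rng.uniform(band.lo_hz + 0.05 * width, band.hi_hz - 0.05 * width, size=n)
    omega = 2.0 * np.pi * freqs / config.sample_rate_hz
    in_rsn = np.zeros(n)
    in_rsn[rsn_idx] = 1.0
    offsets = rng.uniform(0.0, config.coupling_lag_rad, size=n)
    psi0 = rng.uniform(-np.pi, np.pi, size=n)
    phase_noise = rng.normal(0.0, config.phase_noise_sd, size=(steps, n))
    # integrate the offset-corrected phases psi = theta + c (no lag in psi)
    psi = _kernels.kuramoto(
        omega, in_rsn, float(kappa), float(config.background_coupling),
        0.0, psi0, phase_noise,
    )
    theta = psi[_BURN_IN:] - offsets[None, :]
    signal = np.sin(theta).T  # N x T
    signal = signal + rng.normal(0.0, config.noise_sd, size=signal.shape)
    return RoiTimeSeries(
        subject_id=subject_id,
        roi_labels=atlas.roi_labels,
        data=signal,
        sample_rate_hz=config.sample_rate_hz,
    )


def _raw_score(latent_z: float, orientation: str) -> float:
    direction = 1.0 if orientation == HIGHER_BETTER else -1.0
    return NORM_MEAN + direction * NORM_SD * latent_z


def generate_cohort(
    config: CohortConfig,
    atlas: AtlasDefinition | None = None,
    generate_meg: bool = True,
) -> SyntheticCohort:
    """Generate the full patient/control cohort.

    MEG time series are produced for patients (and for controls only when
    ``config.meg_controls`` is set); the emulated study correlates brain
    measures with cognition within the patient group and has no control
    MEG.  ``generate_meg=False`` skips all simulation for cognition-only
    uses.
    """
    atlas = resolve_atlas(config, atlas)
    rsn_idx = atlas.rsn_indices(config.effect_rsn)
    config.check_stability(rsn_idx.size)
    root = np.random.SeedSequence(config.seed)
    kappa_const = 0.5 * (config.kappa_lo + config.kappa_hi)
    rho = math.sin(math.pi * config.coupling_cognition_effect / 2.0)

    groups = ["patient"] * config.n_patients + ["control"] * config.n_controls
    seeds = root.spawn(len(groups))
    subjects: list[SubjectData] = []
    counters = {"patient": 0, "control": 0}
    for group, seq in zip(groups, seeds):
        counters[group] += 1
        sid = f"{group[:3]}{counters[group]:03d}"
        rng = np.random.default_rng(seq)
        kappa = rng.uniform(config.kappa_lo, config.kappa_hi)
        # Gaussian copula: z_kappa is the normal score of kappa's quantile
        q = (kappa - config.kappa_lo) / max(config.kappa_hi - config.kappa_lo, 1e-12)
        z_kappa = norm.ppf(np.clip(q, 1e-9, 1.0 - 1e-9))
        raw_scores: dict[str, float] = {}
        for spec in DEFAULT_BATTERY:
            eps = rng.normal()
            if spec.domain == "working_memory":
                latent = rho * z_kappa + math.sqrt(1.0 - rho * rho) * eps
                if group == "patient":
                    latent += config.wm_patient_shift
            else:
                latent = eps
            raw_scores[spec.name] = _raw_score(latent, spec.orientation)
        timeseries: dict[str, RoiTimeSeries] = {}
        if generate_meg and (group == "patient" or config.meg_controls):
            for band in config.bands:
                band_kappa = kappa if band.name == config.effect_band else kappa_const
                timeseries[band.name] = generate_subject(
                    config, band_kappa, rng, band=band, atlas=atlas, subject_id=sid
                )
        subjects.append(
            SubjectData(
                subject_id=sid,
                group=group,
                kappa=float(kappa),
                raw_scores=raw_scores,
                timeseries=timeseries,
            )
        )
    return SyntheticCohort(
        subjects=tuple(subjects), config=config, atlas=atlas, battery=DEFAULT_BATTERY
    )
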