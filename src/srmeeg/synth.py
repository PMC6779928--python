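"""Synthetic EEG + behaviour cohorts with planted, known effects.

No public recordings exist for the self-referential-memory (SRM)
paradigm this package analyses, so this module generates cohorts whose
statistical structure matches what the downstream analysis assumes:

* event-locked epochs (default 59 channels, 500 Hz, -300..+800 ms,
  70 trials per condition) of 1/f ("pink") background noise;
* an evoked alpha burst (Gaussian-windowed sinusoid, default 10 Hz,
  centred in the 100-300 ms window) whose phase is fixed across trials
  — so it survives trial averaging — and whose amplitude depends on
  group and task condition (the planted evoked-power effect);
* event-locked narrow-band coupling on a configurable edge set: a
  shared alpha source is injected into both channels of each coupled
  edge, delayed on the second channel by ``lag_ms`` in a
  ``coupling_consistency`` fraction of trials and advanced in the rest,
  so the across-trial phase-lag sign consistency — hence the PLI — is
  planted exactly (the planted connectivity effect);
* per-subject recognition-memory counts: hits ~ Binomial(n_old, p_hit)
  and false alarms ~ Binomial(n_new, p_fa) per condition, with subject
  random effects, reproducing the self-referential memory bias of the
  modelled control group;
* optionally, a planted correlation between a subject's evoked alpha
  power and their SRM bias score, implemented through a shared latent
  variable (see ``power_bias_corr``).

Everything is driven by a single integer seed; regeneration with the
same configuration is bit-identical. Per-subject random streams are
derived deterministically from ``(config.seed, subject)`` so subjects
can be generated independently and in any order.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
from scipy.stats import binom

from .epochs import CONDITIONS, GROUPS, EpochSet, default_labels
from .stats import BehavioralRecord

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "gen_epoch_set",
    "gen_behavior",
    "gen_cohort",
    "iter_cohort",
    "expected_pli",
    "default_coupled_edges",
]


def _cell_table(control: dict, patient: dict) -> dict:
    return {"control": dict(control), "patient": dict(patient)}


def _default_burst_amp() -> dict:
    # Controls: equal evoked alpha in all conditions. Patients: 30 %
    # amplitude reduction in the self condition only (the planted
    # group x condition evoked-power effect).
    return _cell_table(
        {"self": 2.0, "other": 2.0, "physical": 2.0},
        {"self": 1.4, "other": 2.0, "physical": 2.0},
    )


def _default_coupling() -> dict:
    # Patients: reduced phase-lag consistency on the coupled (posterior)
    # edges in all conditions, most strongly during self-referential
    # encoding (the planted connectivity deficit).
    return _cell_table(
        {"self": 0.85, "other": 0.85, "physical": 0.85},
        {"self": 0.60, "other": 0.70, "physical": 0.75},
    )


def _default_behavior() -> dict:
    # Hit probabilities chosen so that expected recognition scores match
    # the modelled regime: controls show a self-referential advantage
    # (recognition ~0.49 self vs ~0.35 other), patients do not
    # (~0.36 vs ~0.33), with a common false-alarm rate.
    return {
        "p_hit": _cell_table(
            {"self": 0.64, "other": 0.50, "physical": 0.50},
            {"self": 0.51, "other": 0.48, "physical": 0.50},
        ),
        "p_fa": _cell_table(
            {"self": 0.15, "other": 0.15, "physical": 0.15},
            {"self": 0.15, "other": 0.15, "physical": 0.15},
        ),
        "n_old": 70,
        "n_new": 100,
    }


def _default_rt() -> dict:
    # Condition-level reaction-time means/SDs (ms): referential
    # judgements are slow, the perceptual (physical) judgement fast.
    return {
        "mean": {"self": 999.4, "other": 1032.9, "physical": 630.5},
        "sd": {"self": 159.0, "other": 195.9, "physical": 101.4},
    }


def default_coupled_edges(n_channels: int) -> list[tuple[int, int]]:
    """All pairs among the posterior tail of the montage.

    The channel list is ordered anterior-to-posterior, so the last
    ``k = max(2, min(8, n_channels // 3))`` channels form the posterior
    cluster that carries the planted coupling.
    """
    k = max(2, min(8, n_channels // 3))
    nodes = list(range(n_channels - k, n_channels))
    return [(i, j) for ai, i in enumerate(nodes) for j in nodes[ai + 1:]]


@dataclass
class SimulationConfig:
    """Full description of a synthetic SRM-EEG cohort.

    Amplitudes are in microvolts, times in ms, rates in Hz. Group x
    condition tables are nested dicts ``{group: {condition: value}}``.

    Notable fields
    --------------
    burst_amp
        Evoked alpha burst amplitude per cell; the planted evoked-power
        effect.
    phase_jitter
        Per-trial burst-phase jitter, uniform on ``[-J, +J]`` radians.
        0 = perfectly phase-locked; pi = uniform phase, which cancels
        the evoked response in the trial average.
    coupling_consistency
        Fraction of trials (per cell) in which the coupled-edge lag is
        positive; must be >= 0.5. Determines the planted PLI via
        ``E |2 Binomial(N, p) / N - 1|``.
    alpha_amp_cv
        Between-subject coefficient of variation of evoked alpha
        *power* (a subject trait shared across conditions).
    power_bias_corr
        Target correlation, per group, between measured evoked alpha
        power (self condition) and the measured SRM bias score. The
        latent correlation is disattenuated analytically for binomial
        recognition noise and residual EEG noise so the planted value
        refers to the observables.
    common_source_edges / common_source_amp
        Optional zero-lag common-source mixture (volume-conduction
        fixture): both channels of each listed edge receive the same
        waveform with positive gains, which the PLI must ignore.
    """

    n_per_group: int = 18
    n_channels: int = 59
    fs: float = 500.0
    epoch_window: tuple[float, float] = (-300.0, 800.0)
    n_trials_per_condition: int = 70
    alpha_freq: float = 10.0
    burst_window: tuple[float, float] = (100.0, 300.0)
    burst_amp: dict = field(default_factory=_default_burst_amp)
    phase_jitter: float = 0.0
    coupling_consistency: dict = field(default_factory=_default_coupling)
    coupling_amp: float = 10.0
    coupled_edge_set: list | None = None
    lag_ms: float = 25.0
    noise_exponent: float = 1.0
    noise_rms: float = 10.0
    alpha_amp_cv: float = 0.35
    consistency_sd: float = 0.05
    mem_sd: float = 0.10
    bias_sd: float = 0.28
    common_source_edges: list = field(default_factory=list)
    common_source_amp: float = 0.0
    power_bias_corr: dict = field(
        default_factory=lambda: {"control": 0.0, "patient": 0.6})
    behavior_params: dict = field(default_factory=_default_behavior)
    rt_params: dict = field(default_factory=_default_rt)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.n_channels < 1 or self.n_per_group < 1:
            raise ValueError("counts must be positive")
        w0, w1 = self.epoch_window
        b0, b1 = self.burst_window
        if not (w0 <= b0 < b1 <= w1):
            raise ValueError("epoch_window must span burst_window")
        n_samp = (w1 - w0) * self.fs / 1000.0
        if abs(n_samp - round(n_samp)) > 1e-9:
            raise ValueError("fs x window length must be an integer "
                             "sample count")
        for grp in GROUPS:
            for cond in CONDITIONS:
                c = self.coupling_consistency[grp][cond]
                if not 0.5 <= c <= 1.0:
                    raise ValueError("coupling_consistency must lie in "
                                     "[0.5, 1]")
                for tab in (self.behavior_params["p_hit"],
                            self.behavior_params["p_fa"]):
                    p = tab[grp][cond]
                    if not 0.0 <= p <= 1.0:
                        raise ValueError("probabilities must lie in [0, 1]")
        if self.behavior_params["n_old"] <= 0 \
                or self.behavior_params["n_new"] <= 0:
            raise ValueError("n_old and n_new must be positive")
        if self.coupled_edge_set is None:
            self.coupled_edge_set = default_coupled_edges(self.n_channels)

    @property
    def n_samples(self) -> int:
        w0, w1 = self.epoch_window
        return int(round((w1 - w0) * self.fs / 1000.0))

    @property
    def times(self) -> np.ndarray:
        return self.epoch_window[0] + np.arange(self.n_samples) \
            * 1000.0 / self.fs

    def replace(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


# ----------------------------------------------------------------------
# deterministic per-subject randomness
# ----------------------------------------------------------------------

def _subject_key(subject_id: str) -> int:
    return zlib.crc32(subject_id.encode("utf8"))


def subject_latents(config: SimulationConfig, subject_id: str) -> dict:
    """Stable per-subject latent traits, derived from (seed, subject).

    ``u`` drives evoked alpha power, ``w`` the independent part of the
    memory-bias latent, ``mem`` overall recognition ability, ``cons``
    coupling-consistency jitter. The same latents are used by epoch and
    behaviour generation, which is what couples alpha power to the SRM
    bias when ``power_bias_corr`` is nonzero.
    """
    ss = np.random.SeedSequence(entropy=config.seed,
                                spawn_key=(1001, _subject_key(subject_id)))
    u, w, mem, cons = np.random.default_rng(ss).standard_normal(4)
    return {"u": u, "w": w, "mem": mem, "cons": cons}


# ----------------------------------------------------------------------
# noise and signal components
# ----------------------------------------------------------------------

def _spectral_weights(config: SimulationConfig) -> np.ndarray:
    freqs = np.fft.rfftfreq(config.n_samples, 1.0 / config.fs)
    w = np.zeros_like(freqs)
    w[1:] = freqs[1:] ** (-config.noise_exponent / 2.0)
    return w


def _noise_scale(config: SimulationConfig, w: np.ndarray) -> float:
    """Scale such that pink noise has expected RMS ``noise_rms``."""
    S = config.n_samples
    # Parseval: E[sum x^2] = (1/S) * (2 * sum_{0<f<nyq} E|X|^2 + E|X_nyq|^2)
    var = (4.0 * np.sum(w[1:-1] ** 2) + w[-1] ** 2) / S ** 2
    if var == 0:
        return 0.0
    return config.noise_rms / np.sqrt(var)


def _pink_noise(config: SimulationConfig, rng: np.random.Generator,
                n_trials: int) -> np.ndarray:
    """(n_channels, n_samples, n_trials) pink noise, RMS-calibrated."""
    if config.noise_rms == 0:
        return np.zeros((config.n_channels, config.n_samples, n_trials))
    w = _spectral_weights(config)
    shape = (config.n_channels, n_trials, w.size)
    spec = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    spec *= w
    spec[..., 0] = 0.0
    spec[..., -1] = spec[..., -1].real  # Nyquist bin must be real
    x = np.fft.irfft(spec, n=config.n_samples, axis=-1)
    x *= _noise_scale(config, w)
    return np.transpose(x, (0, 2, 1))


def _antithetic_phases(rng: np.random.Generator, n_trials: int) -> np.ndarray:
    """Per-trial phases, uniform marginally, cancelling in the average.

    Phases are drawn in antithetic pairs (psi, psi + pi), so the
    across-trial mean of ``cos(arg + psi)`` vanishes (up to one
    unpaired trial when the count is odd). Adding pi to both channels
    of an edge leaves the phase difference — hence the planted PLI —
    untouched.
    """
    half = rng.uniform(0.0, 2.0 * np.pi, (n_trials + 1) // 2)
    return np.concatenate([half, half + np.pi])[:n_trials]


def _classwise_antithetic_phases(rng: np.random.Generator,
                                 pos: np.ndarray) -> np.ndarray:
    """Antithetic phases drawn separately within each lag-sign class.

    The coupling source must be exactly non-phase-locked on *both*
    channels of an edge: the undelayed channel sees ``cos(arg + psi)``,
    the delayed one ``cos(arg + psi -/+ lag)`` depending on the trial's
    lag sign. Pairing phases antithetically within the positive-lag
    trials and, separately, within the negative-lag trials cancels the
    trial average of both channels (up to one unpaired trial per odd
    class) while leaving the lag signs i.i.d. Bernoulli across trials —
    the binomial model the planted PLI is derived from.
    """
    psi = np.empty(pos.size)
    for cls in (pos, ~pos):
        idx = np.flatnonzero(cls)
        psi[idx] = _antithetic_phases(rng, idx.size)
    return psi


def _burst_envelope(config: SimulationConfig) -> np.ndarray:
    b0, b1 = config.burst_window
    centre = 0.5 * (b0 + b1)
    sigma = (b1 - b0) / 4.0
    return np.exp(-((config.times - centre) ** 2) / (2.0 * sigma ** 2))


def _coupling_envelope(config: SimulationConfig,
                       ramp_ms: float = 20.0) -> np.ndarray:
    """Flat envelope across the burst window with short cosine ramps.

    Flat (rather than Gaussian) so that the planted lag consistency is
    uniform across the whole active window.
    """
    t = config.times
    b0, b1 = config.burst_window
    env = np.zeros_like(t)
    env[(t >= b0) & (t < b1)] = 1.0
    up = (t >= b0 - ramp_ms) & (t < b0)
    env[up] = 0.5 * (1 + np.cos(np.pi * (b0 - t[up]) / ramp_ms))
    dn = (t >= b1) & (t < b1 + ramp_ms)
    env[dn] = 0.5 * (1 + np.cos(np.pi * (t[dn] - b1) / ramp_ms))
    return env


def _latent_rho(config: SimulationConfig, group: str) -> float:
    """Latent correlation that yields ``power_bias_corr`` observably.

    The planted correlation refers to the observables (measured evoked
    alpha power vs measured SRM bias). The binomial sampling noise of
    the recognition counts attenuates any latent correlation by the
    exactly computable factor ``bias_sd / sqrt(bias_sd^2 + v_binom)``,
    so the latent value is disattenuated by it (capped at 0.97). The
    EEG side is not corrected here: the measurement attenuation of
    evoked power depends on the analysis, and configurations that plant
    a correlation should provide enough evoked-response SNR that it is
    small (see the methods note).
    """
    rho = float(config.power_bias_corr.get(group, 0.0))
    if rho == 0.0:
        return 0.0
    bp = config.behavior_params
    p_hs = bp["p_hit"][group]["self"]
    p_ho = bp["p_hit"][group]["other"]
    f_s = bp["p_fa"][group]["self"]
    f_o = bp["p_fa"][group]["other"]
    v_b = (p_hs * (1 - p_hs) + p_ho * (1 - p_ho)) / bp["n_old"] \
        + (f_s * (1 - f_s) + f_o * (1 - f_o)) / bp["n_new"]
    a_b = config.bias_sd / np.sqrt(config.bias_sd ** 2 + v_b)
    return float(np.clip(rho / a_b, -0.97, 0.97))


# ----------------------------------------------------------------------
# generators
# ----------------------------------------------------------------------

def gen_epoch_set(config: SimulationConfig, subject_id: str, group: str,
                  condition: str, seed=None) -> EpochSet:
    """Generate one subject x condition block of event-locked epochs.

    ``seed`` drives trial-level randomness (noise, per-trial phases,
    lag-sign draws); subject traits (amplitude, consistency jitter)
    come from latents derived from ``config.seed`` and ``subject_id``,
    so they are stable across conditions. Two calls with identical
    arguments return bit-identical arrays.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if config.fs <= 0:
        raise ValueError("fs must be positive")
    rng = np.random.default_rng(seed)
    lat = subject_latents(config, subject_id)
    T = config.n_trials_per_condition
    t_s = config.times / 1000.0  # seconds
    f = config.alpha_freq

    data = _pink_noise(config, rng, T)

    # evoked alpha burst: trial-consistent phase per channel
    amp_factor = np.sqrt(max(0.05, 1.0 + config.alpha_amp_cv * lat["u"]))
    amp = config.burst_amp[group][condition] * amp_factor
    if amp > 0:
        env = _burst_envelope(config)
        phi_ch = rng.uniform(0.0, 2.0 * np.pi, config.n_channels)
        if config.phase_jitter > 0:
            jit = rng.uniform(-config.phase_jitter, config.phase_jitter, T)
        else:
            jit = np.zeros(T)
        arg = (2.0 * np.pi * f * t_s)[None, :, None] \
            + phi_ch[:, None, None] + jit[None, None, :]
        data += amp * env[None, :, None] * np.cos(arg)

    # planted lagged coupling on the coupled edge set
    if config.coupling_amp > 0 and config.coupled_edge_set:
        cons = config.coupling_consistency[group][condition]
        cons = float(np.clip(cons + config.consistency_sd * lat["cons"],
                             0.5, 1.0))
        env_c = _coupling_envelope(config)
        lag_phase = 2.0 * np.pi * f * config.lag_ms / 1000.0
        base = 2.0 * np.pi * f * t_s
        for (i, j) in config.coupled_edge_set:
            pos = rng.random(T) < cons
            psi = _classwise_antithetic_phases(rng, pos)
            sgn = np.where(pos, 1.0, -1.0)
            src_i = np.cos(base[:, None] + psi[None, :])
            src_j = np.cos(base[:, None] + psi[None, :]
                           - lag_phase * sgn[None, :])
            data[i] += config.coupling_amp * env_c[:, None] * src_i
            data[j] += config.coupling_amp * env_c[:, None] * src_j

    # optional zero-lag common source (volume-conduction fixture);
    # power-of-two channel gains keep the two channels bit-exactly
    # proportional through any linear processing chain, so the PLI's
    # sign(0) = 0 convention yields exactly zero on noise-free fixtures
    if config.common_source_amp > 0 and config.common_source_edges:
        env_c = _coupling_envelope(config)
        base = 2.0 * np.pi * f * t_s
        for (i, j) in config.common_source_edges:
            psi = rng.uniform(0.0, 2.0 * np.pi, T)
            src = env_c[:, None] * np.cos(base[:, None] + psi[None, :])
            g_i, g_j = rng.choice([0.5, 1.0, 2.0], size=2)
            data[i] += config.common_source_amp * g_i * src
            data[j] += config.common_source_amp * g_j * src

    return EpochSet(data, config.fs, config.epoch_window[0],
                    default_labels(config.n_channels), condition=condition,
                    subject_id=subject_id, group=group)


def gen_behavior(config: SimulationConfig, subject_id: str, group: str,
                 seed=None) -> BehavioralRecord:
    """Generate one subject's recognition counts and reaction times.

    Hits ~ Binomial(n_old, p_hit) and false alarms ~ Binomial(n_new,
    p_fa) per condition. Subject random effects: a memory trait shared
    across conditions (``mem_sd``) and a bias latent applied to the
    self condition only (``bias_sd``), the latter correlated with the
    subject's alpha-amplitude latent when ``power_bias_corr`` is set.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    bp = config.behavior_params
    rng = np.random.default_rng(seed)
    lat = subject_latents(config, subject_id)
    rho_l = _latent_rho(config, group)
    v = rho_l * lat["u"] + np.sqrt(1.0 - rho_l ** 2) * lat["w"]
    counts = {}
    for cond in CONDITIONS:
        p_hit = bp["p_hit"][group][cond] + config.mem_sd * lat["mem"]
        if cond == "self":
            p_hit += config.bias_sd * v
        p_hit = float(np.clip(p_hit, 0.0, 1.0))
        p_fa = float(np.clip(bp["p_fa"][group][cond], 0.0, 1.0))
        hits = int(rng.binomial(bp["n_old"], p_hit))
        fa = int(rng.binomial(bp["n_new"], p_fa))
        rt = float(rng.normal(config.rt_params["mean"][cond],
                              config.rt_params["sd"][cond]))
        counts[cond] = (hits, bp["n_old"], fa, bp["n_new"], rt)
    return BehavioralRecord.from_counts(subject_id, group, counts)


def expected_pli(p: float, n_trials: int) -> float:
    """Exact E |2 B / N - 1| for B ~ Binomial(N, p).

    The expected single-sample PLI when the lag sign is positive with
    probability ``p`` independently across ``n_trials`` trials.
    """
    k = np.arange(n_trials + 1)
    return float(np.sum(binom.pmf(k, n_trials, p)
                        * np.abs(2.0 * k / n_trials - 1.0)))


@dataclass
class SyntheticCohort:
    """A generated cohort plus the ground truth planted into it."""

    config: SimulationConfig
    subjects: list            # [(subject_id, group), ...]
    epoch_sets: dict          # (subject_id, condition) -> EpochSet
    behavior: dict            # subject_id -> BehavioralRecord
    ground_truth: dict


def _subject_seeds(config: SimulationConfig, group_idx: int,
                   subj_idx: int) -> list:
    ss = np.random.SeedSequence(entropy=config.seed,
                                spawn_key=(7, group_idx, subj_idx))
    return ss.spawn(len(CONDITIONS) + 1)


def _ground_truth(config: SimulationConfig) -> dict:
    n = config.n_trials_per_condition
    exp_pli = {g: {c: expected_pli(config.coupling_consistency[g][c], n)
                   for c in CONDITIONS} for g in GROUPS}
    gt = {
        "burst_amp": config.burst_amp,
        "coupling_consistency": config.coupling_consistency,
        "expected_coupled_pli": exp_pli,
        "coupled_edges": list(map(tuple, config.coupled_edge_set)),
        "power_bias_corr": dict(config.power_bias_corr),
        "contrast_signs": {},
    }
    for cond in CONDITIONS:
        d_amp = (config.burst_amp["patient"][cond]
                 - config.burst_amp["control"][cond])
        gt["contrast_signs"][f"alpha_power_patient_minus_control_{cond}"] = \
            int(np.sign(d_amp))
        d_pli = (exp_pli["patient"][cond] - exp_pli["control"][cond])
        gt["contrast_signs"][f"pli_patient_minus_control_{cond}"] = \
            int(np.sign(d_pli))
        # Weaker planted coupling scatters the patient network toward a
        # uniform random graph, raising its global efficiency; this is
        # the planted network contrast. The characteristic-path-length
        # direction is NOT determined by construction: under the
        # connected-pairs convention the sparse control graphs (strong
        # posterior clique plus isolated nodes) measure artificially
        # short paths, so its sign is recorded as indeterminate.
        gt["contrast_signs"][f"e_global_patient_minus_control_{cond}"] = \
            int(-np.sign(d_pli))
        gt["contrast_signs"][f"cpl_patient_minus_control_{cond}"] = 0
    return gt


def iter_cohort(config: SimulationConfig
                ) -> Iterator[tuple[str, str, str, EpochSet]]:
    """Yield ``(subject_id, group, condition, EpochSet)`` lazily.

    Memory-friendly alternative to :func:`gen_cohort` for full-scale
    cohorts; ordering and seeds are identical.
    """
    for gi, group in enumerate(GROUPS):
        for k in range(config.n_per_group):
            sid = f"{group}-{k:02d}"
            seeds = _subject_seeds(config, gi, k)
            for ci, cond in enumerate(CONDITIONS):
                yield sid, group, cond, gen_epoch_set(
                    config, sid, group, cond, seed=seeds[ci])


def cohort_behavior(config: SimulationConfig) -> dict:
    """Behavioural records for every subject of the cohort."""
    out = {}
    for gi, group in enumerate(GROUPS):
        for k in range(config.n_per_group):
            sid = f"{group}-{k:02d}"
            seeds = _subject_seeds(config, gi, k)
            out[sid] = gen_behavior(config, sid, group, seed=seeds[-1])
    return out


def gen_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate the full two-group, three-condition cohort eagerly.

    ``n_per_group`` subjects per group, each with one
    :class:`~srmeeg.epochs.EpochSet` per condition and one behavioural
    record. Holds every epoch tensor in memory; for large
    configurations prefer :func:`iter_cohort`.
    """
    subjects, epoch_sets = [], {}
    for sid, group, cond, es in iter_cohort(config):
        if (sid, group) not in subjects:
            subjects.append((sid, group))
        epoch_sets[(sid, cond)] = es
    return SyntheticCohort(config, subjects, epoch_sets,
                           cohort_behavior(config), _ground_truth(config))
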