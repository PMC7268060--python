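"""Synthetic EEG/EMG cohort generator with known ground truth.

The generator builds physically plausible signals: motor-region channels carry
an alpha oscillation over a 1/f (pink) + white background; movement-phase
alpha amplitude is scaled by ``sqrt(1 + ERD/100)`` so that the oscillatory
band-power ratio between movement and rest equals ``1 + ERD/100`` by
construction.  Session-level trajectory noise enters through that same
amplitude mapping (never as post-hoc noise on an ERD number), keeping every
generated signal physical.

Trajectories are linear in the 0-based session index: subject ``i`` at session
``j`` has target ERD ``I_i + S_i * j`` per hemisphere, with ``(I_i, S_i)``
drawn from a bivariate normal around the population fixed effects.  The
clinical change is produced by a stage-2 interaction model on the
ipsilesional coefficients.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from erdpipe.io.recording import EEG_MONTAGE, ContinuousRecording, TrialEvent

EOG_LABELS = ("EOGv", "EOGh")
EMG_MUSCLES = ("ECU", "ED", "BIC", "TRI")
EMG_PARETIC = tuple(f"EMGp_{m}" for m in EMG_MUSCLES)
EMG_HEALTHY = tuple(f"EMGh_{m}" for m in EMG_MUSCLES)

ALL_LABELS = EEG_MONTAGE + EOG_LABELS + EMG_PARETIC + EMG_HEALTHY
ALL_KINDS = (
    ["EEG"] * len(EEG_MONTAGE)
    + ["EOG"] * len(EOG_LABELS)
    + ["EMG"] * (len(EMG_PARETIC) + len(EMG_HEALTHY))
)
EMG_SIDES = {**{lb: "paretic" for lb in EMG_PARETIC},
             **{lb: "healthy" for lb in EMG_HEALTHY}}

LEFT_MOTOR = ("C3", "Cp3", "P3")
RIGHT_MOTOR = ("C4", "Cp4", "P4")

ARTIFACT_TYPES = (
    "eog_blink", "hf_burst", "offset", "emg_paretic_rest", "emg_healthy_move",
)


@dataclass
class CohortSpec:
    """Full parameterization of the synthetic cohort."""

    n_subjects: int = 22
    sessions_per_subject: int = 17
    session_jitter_sd: float = 0.0
    trials_per_session: int = 165
    fs: float = 500.0
    iti_range_s: tuple[float, float] = (4.0, 7.0)
    prep_s: float = 2.0
    move_s: float = 5.0

    # stage-1 trajectory model (ipsilesional hemisphere)
    beta0: float = -30.0     # population initial ERD, %
    beta1: float = -0.5      # population ERD slope, %/session
    sd_b0: float = 10.0
    sd_b1: float = 0.4
    rho_b: float = 0.0
    sigma_eps: float = 8.0   # session-level residual ERD SD, %

    # contralesional hemisphere; None -> same population parameters
    beta0_contra: float | None = None
    beta1_contra: float | None = None

    # stage-2 outcome model: delta = g0 + g1*I + g2*S + g3*I*S + noise
    gamma: tuple[float, float, float, float] = (2.0, 0.05, -4.0, -0.15)
    sigma_out: float = 3.0
    baseline_cfma_mean: float = 12.0
    baseline_cfma_sd: float = 6.0

    artifact_rates: dict = field(default_factory=dict)
    lesion_side_assignment: str | list = "alternate"
    seed: int = 0

    # signal parameters
    alpha_freq_hz: float = 10.0
    alpha_amp_uv: float = 10.0
    pink_amp_uv: float = 2.0
    white_amp_uv: float = 1.0
    emg_noise_uv: float = 2.0

    # artifact magnitudes (microvolts)
    blink_amp_uv: float = 150.0
    hf_burst_amp_uv: float = 30.0
    offset_amp_uv: float = 500.0
    emg_burst_scale: float = 8.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.sessions_per_subject < 1:
            raise ValueError("cohort dimensions must be positive")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        for name in ("sd_b0", "sd_b1", "sigma_eps", "sigma_out"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not -1.0 <= self.rho_b <= 1.0:
            raise ValueError("rho_b must lie in [-1, 1]")
        lo, hi = self.iti_range_s
        if not (4.0 <= lo <= hi <= 7.0):
            raise ValueError("ITI range must lie within [4, 7] s")
        for name, rate in self.artifact_rates.items():
            if name not in ARTIFACT_TYPES:
                raise ValueError(
                    f"unknown artifact type {name!r}; known: {ARTIFACT_TYPES}"
                )
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"artifact rate for {name!r} outside [0, 1]")

    def re_cov(self) -> np.ndarray:
        """Random-effects covariance matrix; must be positive semi-definite."""
        cov = np.array([
            [self.sd_b0 ** 2, self.rho_b * self.sd_b0 * self.sd_b1],
            [self.rho_b * self.sd_b0 * self.sd_b1, self.sd_b1 ** 2],
        ])
        if np.min(np.linalg.eigvalsh(cov)) < -1e-12:
            raise ValueError("random-effects covariance is not positive semi-definite")
        return cov

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["iti_range_s"] = list(d["iti_range_s"])
        d["gamma"] = list(d["gamma"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        d = yaml.safe_load(Path(path).read_text())
        if "iti_range_s" in d:
            d["iti_range_s"] = tuple(d["iti_range_s"])
        if "gamma" in d:
            d["gamma"] = tuple(d["gamma"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Everything the generator knows that an analyzer must recover."""

    trajectories: pd.DataFrame  # subject, hemisphere, intercept, slope
    artifacts: pd.DataFrame     # subject, session, trial, type, channel, onset_sample
    true_delta: pd.DataFrame    # subject, delta_true (before outcome noise)


@dataclass
class Cohort:
    """A simulated cohort: session-level ERD targets, outcomes, ground truth."""

    spec: CohortSpec
    erd: pd.DataFrame        # subject, session, hemisphere, band, erd_percent
    outcomes: pd.DataFrame   # subject, baseline1, baseline2, post, delta
    ground_truth: GroundTruth
    lesion_sides: dict[str, str]
    n_sessions: dict[str, int]

    def session_targets(self, subject: str, session: int) -> dict[str, float]:
        """Target ERD by scalp side (left/right) for one subject-session."""
        sub = self.erd[(self.erd.subject == subject) & (self.erd.session == session)]
        ipsi = float(sub[sub.hemisphere == "ipsilesional"].erd_percent.iloc[0])
        contra = float(sub[sub.hemisphere == "contralesional"].erd_percent.iloc[0])
        if self.lesion_sides[subject] == "left":
            return {"left": ipsi, "right": contra}
        return {"left": contra, "right": ipsi}

    def materialize_session(self, subject: str, session: int,
                            n_trials: int | None = None) -> ContinuousRecording:
        """Generate the raw multichannel recording for one session.

        Deterministic given the cohort spec seed, subject and session.
        """
        subj_idx = int(subject.split("S")[-1])
        rng = np.random.default_rng([self.spec.seed, 7919, subj_idx, session])
        rec = simulate_session(
            self.spec,
            subject_id=subject,
            session_index=session,
            targets=self.session_targets(subject, session),
            lesion_side=self.lesion_sides[subject],
            rng=rng,
            n_trials=n_trials if n_trials is not None else self.spec.trials_per_session,
        )
        if self.spec.artifact_rates:
            rec, log = inject_artifacts(rec, self.spec.artifact_rates, rng,
                                        spec=self.spec)
            if len(log):
                log.insert(0, "session", session)
                log.insert(0, "subject", subject)
                self.ground_truth.artifacts = pd.concat(
                    [self.ground_truth.artifacts, log], ignore_index=True
                )
        return rec


def pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f noise via spectral shaping."""
    if n < 2:
        return rng.standard_normal(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    freqs[0] = freqs[1]  # avoid the DC singularity
    spec /= np.sqrt(freqs)
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _amplitude_scale(target_erd: float) -> float:
    if target_erd < -100:
        raise ValueError(
            f"target ERD {target_erd:g}% < -100%: band power cannot be negative"
        )
    return float(np.sqrt(1.0 + target_erd / 100.0))


def simulate_trial(spec: CohortSpec, target_erd, rng: np.random.Generator,
                   iti_s: float | None = None):
    """Simulate one trial (ITI + preparation + movement) on all 26 channels.

    Parameters
    ----------
    target_erd
        ERD percentage (>= -100), either a scalar applied to both scalp sides
        or a ``{"left": ..., "right": ...}`` mapping.
    iti_s
        Inter-trial interval; drawn uniformly from the spec range if omitted.

    Returns
    -------
    samples : (n_channels, n_samples) array, microvolts
    iti_s : float
    analytic : dict with the generator's expected alpha band powers
        (``rest`` and ``move``, per scalp side) for oracle tests.
    """
    if np.isscalar(target_erd):
        targets = {"left": float(target_erd), "right": float(target_erd)}
    else:
        targets = {k: float(v) for k, v in target_erd.items()}
    scales = {side: _amplitude_scale(v) for side, v in targets.items()}

    fs = spec.fs
    if iti_s is None:
        iti_s = float(rng.uniform(*spec.iti_range_s))
    n_iti = int(round(iti_s * fs))
    n_prep = int(round(spec.prep_s * fs))
    n_move = int(round(spec.move_s * fs))
    n = n_iti + n_prep + n_move
    t = np.arange(n) / fs

    samples = np.zeros((len(ALL_LABELS), n))
    move_start = n_iti + n_prep

    A = spec.alpha_amp_uv
    for side, chans in (("left", LEFT_MOTOR), ("right", RIGHT_MOTOR)):
        env = np.ones(n)
        env[move_start:] = scales[side]
        for ch in chans:
            i = ALL_LABELS.index(ch)
            phase = rng.uniform(0, 2 * np.pi)
            samples[i] += A * env * np.sin(2 * np.pi * spec.alpha_freq_hz * t + phase)

    for i, kind in enumerate(ALL_KINDS):
        if kind == "EEG":
            if spec.pink_amp_uv > 0:
                samples[i] += spec.pink_amp_uv * pink_noise(n, rng)
            if spec.white_amp_uv > 0:
                samples[i] += spec.white_amp_uv * rng.standard_normal(n)
        elif kind == "EOG":
            if spec.white_amp_uv > 0:
                samples[i] += spec.white_amp_uv * rng.standard_normal(n)
        else:  # EMG
            if spec.emg_noise_uv > 0:
                samples[i] += spec.emg_noise_uv * rng.standard_normal(n)

    analytic = {
        side: {
            "alpha_power_rest": A ** 2 / 2.0,
            "alpha_power_move": A ** 2 / 2.0 * (1.0 + targets[side] / 100.0),
        }
        for side in ("left", "right")
    }
    return samples, iti_s, analytic


def simulate_session(spec: CohortSpec, subject_id: str, session_index: int,
                     targets, lesion_side: str, rng: np.random.Generator,
                     n_trials: int) -> ContinuousRecording:
    """Concatenate trials into a continuous recording with event markers."""
    chunks, events = [], []
    cursor = 0
    for _ in range(n_trials):
        samples, iti_s, _ = simulate_trial(spec, targets, rng)
        n_iti = int(round(iti_s * spec.fs))
        events.append(
            TrialEvent(onset=cursor + n_iti, iti_s=iti_s,
                       prep_s=spec.prep_s, move_s=spec.move_s)
        )
        chunks.append(samples)
        cursor += samples.shape[1]
    return ContinuousRecording(
        samples=np.concatenate(chunks, axis=1),
        fs=spec.fs,
        channel_labels=list(ALL_LABELS),
        channel_kinds=list(ALL_KINDS),
        events=events,
        subject_id=subject_id,
        session_index=session_index,
        lesion_side=lesion_side,
        emg_sides=dict(EMG_SIDES),
    )


def _raised_cosine(n: int) -> np.ndarray:
    return 0.5 * (1 - np.cos(2 * np.pi * np.arange(n) / max(n - 1, 1)))


def inject_artifacts(rec: ContinuousRecording, artifact_rates: dict,
                     rng: np.random.Generator, spec: CohortSpec | None = None):
    """Inject artifacts per trial at the stated per-trial probabilities.

    Returns a new recording plus a log of every injection
    (trial, type, channel, onset_sample).  All-zero rates return an identical
    copy of the input.
    """
    for name in artifact_rates:
        if name not in ARTIFACT_TYPES:
            raise ValueError(
                f"unknown artifact type {name!r}; known: {ARTIFACT_TYPES}"
            )
    out = ContinuousRecording(
        samples=rec.samples.copy(), fs=rec.fs,
        channel_labels=list(rec.channel_labels),
        channel_kinds=list(rec.channel_kinds),
        events=list(rec.events), subject_id=rec.subject_id,
        session_index=rec.session_index, lesion_side=rec.lesion_side,
        emg_sides=dict(rec.emg_sides),
    )
    fs = rec.fs
    log_rows: list[dict] = []
    eeg_idx = out.pick("EEG")
    paretic = [lb for lb, s in rec.emg_sides.items() if s == "paretic"]
    healthy = [lb for lb, s in rec.emg_sides.items() if s == "healthy"]

    mag = spec if spec is not None else CohortSpec()
    blink_amp = mag.blink_amp_uv
    hf_amp = mag.hf_burst_amp_uv
    offset_amp = mag.offset_amp_uv
    emg_scale = mag.emg_burst_scale
    emg_noise = mag.emg_noise_uv

    for trial, ev in enumerate(out.events):
        n_rest = int(round(4.0 * fs))
        n_prep = int(round(ev.prep_s * fs))
        n_move = int(round(ev.move_s * fs))
        trial_start = ev.onset - n_rest
        move_start = ev.onset + n_prep
        trial_end = move_start + n_move

        for name, rate in artifact_rates.items():
            if rng.uniform() >= rate:
                continue
            if name == "eog_blink":
                dur = int(round(0.4 * fs))
                onset = int(rng.integers(trial_start, trial_end - dur))
                tmpl = blink_amp * _raised_cosine(dur)
                mix = {"EOGv": 1.0, "EOGh": 0.3, "Fp1": 0.5, "Fp2": 0.5,
                       "F3": 0.2, "F4": 0.2}
                for lb, w in mix.items():
                    if lb in out.channel_labels:
                        out.samples[out.channel_index(lb), onset:onset + dur] += w * tmpl
                log_rows.append(dict(trial=trial, type=name, channel="EOGv",
                                     onset_sample=onset))
            elif name == "hf_burst":
                dur = int(round(0.2 * fs))
                onset = int(rng.integers(trial_start, trial_end - dur))
                tt = np.arange(dur) / fs
                burst = hf_amp * np.sin(2 * np.pi * 125.0 * tt) * _raised_cosine(dur)
                chans = rng.choice(eeg_idx, size=min(8, len(eeg_idx)), replace=False)
                for ci in chans:
                    out.samples[ci, onset:onset + dur] += burst
                log_rows.append(dict(
                    trial=trial, type=name,
                    channel=out.channel_labels[int(chans[0])], onset_sample=onset))
            elif name == "offset":
                # short pulses: long/frequent offsets inflate the session SD
                # enough to mask themselves at a 20 SD threshold
                dur = int(round(0.06 * fs))
                onset = int(rng.integers(trial_start, trial_end - dur))
                jump = offset_amp * np.sign(rng.uniform(-1, 1) or 1.0)
                out.samples[eeg_idx, onset:onset + dur] += jump
                log_rows.append(dict(trial=trial, type=name, channel="*EEG",
                                     onset_sample=onset))
            elif name == "emg_paretic_rest":
                dur = int(round(0.5 * fs))
                lo, hi = trial_start, ev.onset - dur
                onset = int(rng.integers(lo, max(hi, lo + 1)))
                lb = str(rng.choice(paretic))
                burst = emg_scale * emg_noise * rng.standard_normal(dur)
                out.samples[out.channel_index(lb), onset:onset + dur] += burst
                log_rows.append(dict(trial=trial, type=name, channel=lb,
                                     onset_sample=onset))
            elif name == "emg_healthy_move":
                dur = int(round(0.5 * fs))
                lo, hi = move_start, trial_end - dur
                onset = int(rng.integers(lo, max(hi, lo + 1)))
                lb = str(rng.choice(healthy))
                burst = emg_scale * emg_noise * rng.standard_normal(dur)
                out.samples[out.channel_index(lb), onset:onset + dur] += burst
                log_rows.append(dict(trial=trial, type=name, channel=lb,
                                     onset_sample=onset))

    log = pd.DataFrame(log_rows, columns=["trial", "type", "channel", "onset_sample"])
    return out, log


def _lesion_sides(spec: CohortSpec) -> list[str]:
    if isinstance(spec.lesion_side_assignment, str):
        if spec.lesion_side_assignment != "alternate":
            raise ValueError("lesion_side_assignment must be 'alternate' or a list")
        return ["left" if i % 2 == 0 else "right" for i in range(spec.n_subjects)]
    sides = list(spec.lesion_side_assignment)
    if len(sides) != spec.n_subjects or any(s not in ("left", "right") for s in sides):
        raise ValueError("lesion side list must give left/right per subject")
    return sides


def simulate_cohort(spec: CohortSpec) -> Cohort:
    """Draw per-subject trajectories, session ERD targets, and outcomes.

    The ERD table contains the session-mean target ERD per hemisphere (the
    value an ideal analyzer would measure in expectation); signals for any
    subject-session can be materialized on demand.
    """
    rng = np.random.default_rng(spec.seed)
    cov = spec.re_cov()
    sides = _lesion_sides(spec)
    mean_ipsi = np.array([spec.beta0, spec.beta1])
    mean_contra = np.array([
        spec.beta0 if spec.beta0_contra is None else spec.beta0_contra,
        spec.beta1 if spec.beta1_contra is None else spec.beta1_contra,
    ])

    traj_rows, erd_rows, out_rows, delta_rows = [], [], [], []
    lesion_sides, n_sessions = {}, {}
    g0, g1, g2, g3 = spec.gamma

    for i in range(spec.n_subjects):
        subject = f"S{i:02d}"
        lesion_sides[subject] = sides[i]
        n_sess = spec.sessions_per_subject
        if spec.session_jitter_sd > 0:
            n_sess = max(2, int(round(rng.normal(n_sess, spec.session_jitter_sd))))
        n_sessions[subject] = n_sess

        coeffs = {}
        for hemi, mean in (("ipsilesional", mean_ipsi),
                           ("contralesional", mean_contra)):
            b = rng.multivariate_normal(mean, cov)
            coeffs[hemi] = b
            traj_rows.append(dict(subject=subject, hemisphere=hemi,
                                  intercept=b[0], slope=b[1]))
            for j in range(n_sess):
                eps = rng.normal(0.0, spec.sigma_eps) if spec.sigma_eps > 0 else 0.0
                target = max(b[0] + b[1] * j + eps, -100.0)
                erd_rows.append(dict(subject=subject, session=j, hemisphere=hemi,
                                     band="alpha", erd_percent=target))

        I_i, S_i = coeffs["ipsilesional"]
        delta_true = g0 + g1 * I_i + g2 * S_i + g3 * I_i * S_i
        delta = delta_true + (rng.normal(0.0, spec.sigma_out)
                              if spec.sigma_out > 0 else 0.0)
        b1v = float(np.clip(rng.normal(spec.baseline_cfma_mean,
                                       spec.baseline_cfma_sd), 0, 54))
        b2v = float(np.clip(rng.normal(spec.baseline_cfma_mean,
                                       spec.baseline_cfma_sd), 0, 54))
        post = (b1v + b2v) / 2.0 + delta
        # keep the score range without breaking post - mean(baselines) == delta
        if post < 0 or post > 54:
            shift = -post if post < 0 else 54 - post
            b1v = float(np.clip(b1v + shift, 0, 54))
            b2v = float(np.clip(b2v + shift, 0, 54))
            post = (b1v + b2v) / 2.0 + delta
        delta_rows.append(dict(subject=subject, delta_true=delta_true))
        out_rows.append(dict(subject=subject, baseline1=b1v, baseline2=b2v,
                             post=post, delta=delta))

    gt = GroundTruth(
        trajectories=pd.DataFrame(traj_rows),
        artifacts=pd.DataFrame(
            columns=["subject", "session", "trial", "type", "channel",
                     "onset_sample"]),
        true_delta=pd.DataFrame(delta_rows),
    )
    return Cohort(
        spec=spec,
        erd=pd.DataFrame(erd_rows),
        outcomes=pd.DataFrame(out_rows),
        ground_truth=gt,
        lesion_sides=lesion_sides,
        n_sessions=n_sessions,
    )
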