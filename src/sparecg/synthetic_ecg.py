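"""Synthetic multi-lead ECG records and labelled registries.

Each beat is a sum of five Gaussian bumps (P, Q, R, S, T) placed relative
to the R peak; RR intervals are drawn from a truncated normal distribution
(floor 0.3 s), and sinusoidal baseline wander plus white noise are added.
The 12 leads are fixed linear mixtures of two latent sources — a QRS
complex source and a P/T source — with lead-specific gains, which is
enough to exercise per-lead code paths without a torso model.

A controllable two-class morphology difference (``class_effect``, a
multiplicative perturbation of designated wave parameters — by default the
P wave, the physiologically plausible correlate of paroxysmal AF) makes
case records separable from controls to a known, tunable degree, so
classifier behaviour can be tested against planted ground truth.

Everything is deterministic given the seed; the generator returns the true
R-peak positions alongside each record.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .signal_io import ECGRecord

#: (amplitude mV, centre offset s relative to R, width s) per wave; the
#: Gaussian standard deviation is width/4 so +-2 sd spans the stated width.
#: Values approximate lead-II morphology.
DEFAULT_WAVES = {
    "P": (0.15, -0.20, 0.08),
    "Q": (-0.10, -0.04, 0.02),
    "R": (1.00, 0.00, 0.04),
    "S": (-0.15, 0.04, 0.02),
    "T": (0.30, 0.30, 0.16),
}

_QRS_WAVES = ("Q", "R", "S")

#: 12-lead mixing: lead = qrs_gain * QRS source + pt_gain * P/T source.
LEAD_MIXING = {
    "I": (0.6, 0.7), "II": (1.0, 1.0), "III": (0.5, 0.4),
    "aVR": (-0.8, -0.8), "aVL": (0.3, 0.4), "aVF": (0.7, 0.6),
    "V1": (-0.4, 0.3), "V2": (0.9, 0.5), "V3": (1.1, 0.6),
    "V4": (1.2, 0.8), "V5": (1.1, 0.9), "V6": (0.9, 0.9),
}

RR_FLOOR = 0.3  # s; truncation floor of the RR distribution


@dataclass
class SyntheticECGParams:
    """Generator settings; defaults emulate a 10 s, 500 Hz resting ECG."""

    fs: float = 500.0
    duration: float = 10.0
    mean_rr: float = 0.8
    rr_sd: float = 0.05
    wave_params: dict = field(default_factory=lambda: dict(DEFAULT_WAVES))
    baseline_amp: float = 0.05
    baseline_freq: float = 0.33
    noise_sd: float = 0.02
    class_effect: float = 1.0
    effect_waves: tuple = ("P",)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs < 125:
            raise ValueError("fs must be at least 125 Hz")
        if self.duration < 5:
            raise ValueError("duration must be at least 5 s")
        if self.rr_sd < 0:
            raise ValueError("rr_sd must be nonnegative")
        if self.mean_rr <= 0:
            raise ValueError("mean_rr must be positive")
        for wave, (_, _, width) in self.wave_params.items():
            if width <= 0:
                raise ValueError(f"wave {wave} width must be positive")


@dataclass
class GeneratedECG:
    """A synthetic record plus its generation ground truth."""

    record: ECGRecord
    r_peak_times: np.ndarray    # seconds
    r_peak_indices: np.ndarray  # samples
    label: str                  # "case" or "control"


def _beat_train(t: np.ndarray, beat_times: np.ndarray, waves: dict,
                wave_names) -> np.ndarray:
    out = np.zeros_like(t)
    for name in wave_names:
        amp, centre, width = waves[name]
        sd = width / 4.0
        for bt in beat_times:
            mu = bt + centre
            # Gaussians are negligible beyond 8 sd (tail < 1e-14 of amp);
            # restrict the evaluation window
            lo = np.searchsorted(t, mu - 8 * sd)
            hi = np.searchsorted(t, mu + 8 * sd)
            out[lo:hi] += amp * np.exp(-0.5 * ((t[lo:hi] - mu) / sd) ** 2)
    return out


def _case_waves(params: SyntheticECGParams) -> dict:
    waves = dict(params.wave_params)
    for name in params.effect_waves:
        amp, centre, width = waves[name]
        waves[name] = (amp * params.class_effect, centre,
                       width * params.class_effect)
    return waves


def generate_ecg(params: SyntheticECGParams, is_case: bool = False,
                 record_id: str = "synthetic", patient_id: str | None = None,
                 ) -> GeneratedECG:
    """Generate one 12-lead synthetic ECG with ground-truth R peaks.

    ``is_case=True`` applies the ``class_effect`` perturbation to the
    designated waves.  With rr_sd=0, noise_sd=0 and baseline_amp=0 the
    output is exactly periodic.
    """
    rng = np.random.default_rng(params.seed)
    n = int(round(params.fs * params.duration))
    t = np.arange(n) / params.fs

    beat_times = []
    current = params.mean_rr / 2  # first R half a cycle in
    while current < params.duration:
        beat_times.append(current)
        rr = params.mean_rr if params.rr_sd == 0 else max(
            RR_FLOOR, rng.normal(params.mean_rr, params.rr_sd))
        current += rr
    beat_times = np.asarray(beat_times)

    waves = _case_waves(params) if is_case else dict(params.wave_params)
    qrs_source = _beat_train(t, beat_times, waves, _QRS_WAVES)
    pt_source = _beat_train(t, beat_times, waves, ("P", "T"))

    baseline_phase = rng.uniform(0, 2 * np.pi)
    baseline = params.baseline_amp * np.sin(
        2 * np.pi * params.baseline_freq * t + baseline_phase)

    lead_names = list(LEAD_MIXING)
    samples = np.empty((len(lead_names), n))
    for i, lead in enumerate(lead_names):
        qrs_gain, pt_gain = LEAD_MIXING[lead]
        samples[i] = qrs_gain * qrs_source + pt_gain * pt_source + baseline
        if params.noise_sd > 0:
            samples[i] += rng.normal(0, params.noise_sd, n)

    record = ECGRecord(
        record_id=record_id,
        patient_id=patient_id or record_id,
        fs=params.fs,
        lead_names=lead_names,
        samples=samples,
        rhythm_labels={"SR"},
    )
    indices = np.round(beat_times * params.fs).astype(int)
    return GeneratedECG(record=record, r_peak_times=beat_times,
                        r_peak_indices=indices,
                        label="case" if is_case else "control")


def generate_registry(n_case_patients: int, n_control_patients: int,
                      records_per_patient: int = 1,
                      params: SyntheticECGParams | None = None,
                      n_comorbid_patients: int = 0,
                      ) -> tuple[list[GeneratedECG], pd.DataFrame]:
    """Generate a labelled record registry emulating a clinical ECG archive.

    Case patients receive ``records_per_patient`` sinus-rhythm records with
    case morphology plus one AFIB-labelled record (so the cohort pipeline
    can identify them); control patients receive SR records only; optional
    comorbid patients receive SR records tagged with a superclass label.
    Ages are uniform over 40–89, sexes balanced.  Deterministic given
    ``params.seed``.
    """
    if min(n_case_patients, n_control_patients) < 1 or records_per_patient < 1:
        raise ValueError("patient and record counts must be >= 1")
    params = params or SyntheticECGParams()
    rng = np.random.default_rng(params.seed)

    generated: list[GeneratedECG] = []
    meta_rows: list[dict] = []

    def add_patient(prefix: str, idx: int, is_case: bool, superclass: str,
                    age: float, sex: str) -> None:
        patient_id = f"{prefix}{idx:04d}"
        n_records = records_per_patient + (1 if is_case else 0)
        for r in range(n_records):
            record_id = f"{patient_id}_r{r}"
            rhythm = "AFIB" if (is_case and r == n_records - 1) else "SR"
            rec_params = replace(params, seed=int(rng.integers(2**31)))
            gen = generate_ecg(rec_params, is_case=is_case,
                               record_id=record_id, patient_id=patient_id)
            gen.record.age = age
            gen.record.sex = sex
            gen.record.rhythm_labels = {rhythm}
            if superclass:
                gen.record.superclass_labels = {superclass}
            generated.append(gen)
            meta_rows.append({
                "record_id": record_id, "patient_id": patient_id,
                "age": age, "sex": sex, "rhythm_labels": rhythm,
                "superclass_labels": superclass,
            })

    # Case demographics are mirrored onto the first controls so that every
    # case stratum (sex x decade) has a matching control available and the
    # cohort comes out balanced whenever n_control >= n_case.
    case_demo = [(float(rng.integers(40, 90)), "male" if i % 2 == 0 else "female")
                 for i in range(n_case_patients)]
    for i, (age, sex) in enumerate(case_demo):
        add_patient("case", i, True, "", age, sex)
    for i in range(n_control_patients):
        if i < n_case_patients:
            age, sex = case_demo[i]
        else:
            age, sex = float(rng.integers(40, 90)), "male" if i % 2 == 0 else "female"
        add_patient("ctrl", i, False, "", age, sex)
    for i in range(n_comorbid_patients):
        add_patient("como", i, False, "MI",
                    float(rng.integers(40, 90)), "male" if i % 2 == 0 else "female")

    return generated, pd.DataFrame(meta_rows)
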