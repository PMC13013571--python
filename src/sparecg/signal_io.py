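"""Reading, writing and resampling of multi-lead ECG records.

Records arrive either as WFDB header/signal pairs (the format PhysioNet
distributes; only the 16-bit sample format is supported, which is what
PTB-XL uses) or as plain delimited text with one column per lead.  Metadata
(patient id, age, sex, rhythm and diagnostic-superclass labels) is joined
from a CSV table keyed by record id.

Resampling from 500 Hz to 125 Hz is pure decimation — every fourth sample,
no interpolation, no anti-alias filter — so that sample values downstream
are bit-identical to stored values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: The standard 12-lead vocabulary; lead names outside this set are rejected.
LEAD_VOCABULARY = ("I", "II", "III", "AVR", "AVL", "AVF",
                   "V1", "V2", "V3", "V4", "V5", "V6")

_LEAD_CANON = {name.upper(): name for name in
               ("I", "II", "III", "aVR", "aVL", "aVF",
                "V1", "V2", "V3", "V4", "V5", "V6")}


class SignalIOError(IOError):
    """Raised when a record file is missing or malformed."""


def canonical_lead(name: str) -> str:
    """Map a lead name to canonical case (``avl`` -> ``aVL``).

    Raises ``ValueError`` for names outside the 12-lead vocabulary.
    """
    key = name.strip().upper()
    if key not in _LEAD_CANON:
        raise ValueError(
            f"unknown lead name {name!r}; expected one of {sorted(_LEAD_CANON.values())}"
        )
    return _LEAD_CANON[key]


@dataclass
class ECGRecord:
    """One multi-lead recording plus patient/label metadata.

    ``samples`` is a (leads x time) array in millivolts.  ``age`` and ``sex``
    are ``None`` when unknown — never sentinel numbers.
    """

    record_id: str
    patient_id: str
    fs: float
    lead_names: list[str]
    samples: np.ndarray
    age: float | None = None
    sex: str | None = None  # "male" / "female" / None
    rhythm_labels: set[str] = field(default_factory=set)
    superclass_labels: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2D (leads x time) array")
        if self.samples.shape[0] != len(self.lead_names):
            raise ValueError(
                f"samples has {self.samples.shape[0]} rows for "
                f"{len(self.lead_names)} lead names"
            )
        if self.samples.shape[1] < 2:
            raise ValueError("each lead needs at least 2 samples")
        if self.fs <= 0:
            raise ValueError("sampling frequency must be positive")
        self.lead_names = [canonical_lead(n) for n in self.lead_names]
        if len(set(self.lead_names)) != len(self.lead_names):
            raise ValueError("duplicate lead names")
        if self.sex is not None and self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male', 'female' or None, got {self.sex!r}")
        if self.age is not None and self.age < 0:
            raise ValueError("age must be nonnegative")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


# ---------------------------------------------------------------------------
# metadata

def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a record-metadata CSV indexed by record_id.

    Expected columns: record_id, patient_id, age, sex, rhythm_labels,
    superclass_labels; the two label columns are semicolon-joined strings.
    """
    meta = pd.read_csv(path, dtype={"record_id": str, "patient_id": str})
    required = {"record_id", "patient_id"}
    missing = required - set(meta.columns)
    if missing:
        raise SignalIOError(f"metadata at {path} lacks columns {sorted(missing)}")
    return meta.set_index("record_id", drop=False)


def _split_labels(value) -> set[str]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return set()
    text = str(value).strip()
    if not text:
        return set()
    return {tok.strip() for tok in text.split(";") if tok.strip()}


def _apply_metadata(record: ECGRecord, metadata: pd.DataFrame | None) -> ECGRecord:
    if metadata is None or record.record_id not in metadata.index:
        return record
    row = metadata.loc[record.record_id]
    age = row.get("age")
    sex = row.get("sex")
    record.patient_id = str(row["patient_id"])
    record.age = float(age) if age is not None and not pd.isna(age) else None
    record.sex = str(sex).lower() if isinstance(sex, str) and sex.strip() else None
    record.rhythm_labels = _split_labels(row.get("rhythm_labels"))
    record.superclass_labels = _split_labels(row.get("superclass_labels"))
    return record


# ---------------------------------------------------------------------------
# WFDB (format 16)

def read_wfdb_record(path: str | Path, metadata: pd.DataFrame | None = None) -> ECGRecord:
    """Read a WFDB header/signal pair (sample format 16 only).

    ``path`` may point at the ``.hea`` file or be the extensionless record
    path.  Labels are populated from ``metadata`` when a row for the record
    id exists, else left empty.
    """
    path = Path(path)
    hea_path = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea_path.exists():
        raise SignalIOError(f"missing WFDB header: {hea_path}")
    lines = [ln for ln in hea_path.read_text().splitlines()
             if ln.strip() and not ln.lstrip().startswith("#")]
    head = lines[0].split()
    record_name = head[0].split("/")[0]
    n_sig = int(head[1])
    fs = float(head[2]) if len(head) > 2 else 250.0
    n_samp = int(head[3]) if len(head) > 3 else 0
    if len(lines) - 1 < n_sig:
        raise SignalIOError(f"header {hea_path} declares {n_sig} signals, "
                            f"found {len(lines) - 1} signal lines")

    dat_files: list[str] = []
    gains, baselines, names = [], [], []
    for spec_line in lines[1:1 + n_sig]:
        toks = spec_line.split()
        dat_files.append(toks[0])
        fmt = toks[1].split("x")[0].split(":")[0].split("+")[0]
        if fmt != "16":
            raise SignalIOError(f"unsupported WFDB sample format {fmt!r} in {hea_path}")
        gain_tok = toks[2] if len(toks) > 2 else "200"
        gain_part = gain_tok.split("/")[0]
        if "(" in gain_part:
            gain_str, base_str = gain_part[:-1].split("(")
            baseline = int(base_str)
        else:
            gain_str = gain_part
            baseline = int(toks[4]) if len(toks) > 4 else 0
        gain = float(gain_str) or 200.0
        gains.append(gain)
        baselines.append(baseline)
        names.append(toks[-1])

    if len(set(dat_files)) != 1:
        raise SignalIOError("multi-file WFDB records are not supported")
    dat_path = hea_path.parent / dat_files[0]
    if not dat_path.exists():
        raise SignalIOError(f"missing WFDB signal file: {dat_path}")
    raw = np.fromfile(dat_path, dtype="<i2")
    if n_samp and raw.size < n_samp * n_sig:
        raise SignalIOError(f"signal file {dat_path} truncated: "
                            f"{raw.size} samples < {n_samp * n_sig}")
    if n_samp:
        raw = raw[: n_samp * n_sig]
    adc = raw.reshape(-1, n_sig).T.astype(float)
    samples = (adc - np.array(baselines)[:, None]) / np.array(gains)[:, None]

    record = ECGRecord(
        record_id=record_name,
        patient_id=record_name,
        fs=fs,
        lead_names=names,
        samples=samples,
    )
    return _apply_metadata(record, metadata)


def write_wfdb_record(record: ECGRecord, directory: str | Path,
                      gain: float = 1000.0) -> Path:
    """Write a record as a WFDB format-16 header/signal pair; returns the
    header path.  Quantisation step is ``1/gain`` mV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    hea_path = directory / f"{record.record_id}.hea"
    dat_name = f"{record.record_id}.dat"
    n_sig, n_samp = record.samples.shape
    adc = np.clip(np.round(record.samples * gain), -32768, 32767).astype("<i2")
    adc.T.reshape(-1).tofile(directory / dat_name)
    fs_str = f"{record.fs:g}"
    lines = [f"{record.record_id} {n_sig} {fs_str} {n_samp}"]
    for i, lead in enumerate(record.lead_names):
        first = int(adc[i, 0])
        lines.append(f"{dat_name} 16 {gain:g}(0)/mV 16 0 {first} 0 0 {lead}")
    hea_path.write_text("\n".join(lines) + "\n")
    return hea_path


# ---------------------------------------------------------------------------
# CSV records

def read_csv_record(path: str | Path, fs: float,
                    record_id: str | None = None,
                    metadata: pd.DataFrame | None = None) -> ECGRecord:
    """Read a record from delimited text: one column per lead, header row of
    lead names, sampling frequency supplied by the caller."""
    path = Path(path)
    if not path.exists():
        raise SignalIOError(f"missing record file: {path}")
    frame = pd.read_csv(path)
    record = ECGRecord(
        record_id=record_id or path.stem,
        patient_id=record_id or path.stem,
        fs=fs,
        lead_names=list(frame.columns),
        samples=frame.to_numpy().T,
    )
    return _apply_metadata(record, metadata)


def write_csv_record(record: ECGRecord, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(record.samples.T, columns=record.lead_names).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# resampling / lead selection

def downsample(record: ECGRecord, factor: int) -> ECGRecord:
    """Decimate by pure sample selection: keep every ``factor``-th sample
    starting at index 0 and divide ``fs`` by ``factor``.

    No filtering or interpolation is applied, so retained samples are
    bit-identical to the input.  The canonical use is 500 Hz -> 125 Hz with
    ``factor=4``.
    """
    if int(factor) != factor or factor < 1:
        raise ValueError(f"downsampling factor must be a positive integer, got {factor}")
    factor = int(factor)
    if factor == 1:
        return replace(record, samples=record.samples.copy())
    return replace(record, samples=record.samples[:, ::factor].copy(),
                   fs=record.fs / factor)


def select_lead(record: ECGRecord, lead: str) -> tuple[np.ndarray, float]:
    """Return one lead's samples (mV) and the record's sampling frequency."""
    lead = canonical_lead(lead)
    if lead not in record.lead_names:
        raise ValueError(
            f"lead {lead!r} not present in record {record.record_id}; "
            f"available: {record.lead_names}"
        )
    return record.samples[record.lead_names.index(lead)], record.fs
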