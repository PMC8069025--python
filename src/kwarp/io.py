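"""Record and lab-table I/O.

ECGs are stored as WFDB records (text ``.hea`` header plus 16-bit
little-endian interleaved ``.dat``, format 16); the writer/reader here
covers that single-segment subset, with per-lead gain in ADC counts per
microvolt, so amplitudes round-trip losslessly up to the ADC resolution
(default 3.75 uV, the Holter device's quantisation).  Lab potassium
tables are plain CSV with a header row and '.' decimals.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .preprocess import INDEPENDENT_LEADS, EcgRecording

DEFAULT_ADC_UV = 3.75  # microvolt per ADC count


def write_wfdb(rec: EcgRecording, prefix: str, adc_uv: float = DEFAULT_ADC_UV) -> None:
    """Write a WFDB format-16 record to ``prefix``.hea / ``prefix``.dat."""
    name = os.path.basename(prefix)
    counts = np.round(rec.samples / adc_uv).astype(np.int16)
    gain = 1.0 / adc_uv  # ADC counts per uV
    with open(prefix + ".hea", "w") as fh:
        fh.write(f"{name} {len(rec.leads)} {rec.fs:.10g} {rec.n_samples}\n")
        for i, lead in enumerate(rec.leads):
            first = int(counts[i, 0]) if rec.n_samples else 0
            fh.write(f"{name}.dat 16 {gain:.10g}/uV 16 0 {first} 0 0 {lead}\n")
    counts.T.reshape(-1).tofile(prefix + ".dat")


def read_wfdb(prefix: str) -> EcgRecording:
    """Read a WFDB format-16 record written by :func:`write_wfdb`."""
    hea = prefix + ".hea"
    try:
        with open(hea) as fh:
            lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    except OSError as exc:
        raise FileNotFoundError(f"cannot read WFDB header {hea}: {exc}") from exc
    head = lines[0].split()
    if len(head) < 4:
        raise ValueError(f"malformed WFDB header line: {lines[0]!r}")
    n_sig, fs, n_samp = int(head[1]), float(head[2]), int(head[3])
    leads, gains = [], []
    for ln in lines[1:1 + n_sig]:
        parts = ln.split()
        if len(parts) < 3 or parts[1] != "16":
            raise ValueError(f"unsupported WFDB signal line (need format 16): {ln!r}")
        gains.append(float(parts[2].split("/")[0]))
        leads.append(parts[-1])
    if len(leads) != n_sig:
        raise ValueError("WFDB header signal count mismatch")
    raw = np.fromfile(prefix + ".dat", dtype="<i2")
    if raw.size != n_sig * n_samp:
        raise ValueError(f".dat size {raw.size} != {n_sig}x{n_samp}")
    counts = raw.reshape(n_samp, n_sig).T.astype(float)
    uv = counts / np.asarray(gains)[:, None]
    return EcgRecording(tuple(leads), uv, fs)


def select_independent_leads(rec: EcgRecording) -> EcgRecording:
    """Keep the 8 linearly independent leads (I, II, V1-V6); drop derived ones.

    III, aVR, aVL and aVF are linear combinations of I and II, so a
    12-lead record reduces to these 8 with no information loss.
    """
    missing = [l for l in INDEPENDENT_LEADS if l not in rec.leads]
    if missing:
        raise ValueError(f"recording lacks independent leads {missing}")
    return rec.select_leads(INDEPENDENT_LEADS)


def read_ecg(path: str, format: str = "wfdb") -> EcgRecording:
    """Read an ECG record; only the WFDB subset is supported."""
    if format == "wfdb":
        prefix = path[:-4] if path.endswith((".hea", ".dat")) else path
        return read_wfdb(prefix)
    if format == "edf":
        raise NotImplementedError(
            "EDF input is not supported by this build; convert to WFDB format 16"
        )
    raise ValueError(f"unknown ECG format {format!r}")


def read_lab_csv(path: str) -> pd.DataFrame:
    """Read a lab [K+] table (patient_id, hour_label, time_h, k_mmol)."""
    try:
        df = pd.read_csv(path, dtype={"patient_id": str, "hour_label": str})
    except Exception as exc:
        raise ValueError(f"malformed lab CSV {path}: {exc}") from exc
    required = {"patient_id", "hour_label", "time_h", "k_mmol"}
    if not required.issubset(df.columns):
        raise ValueError(f"lab CSV {path} must have columns {sorted(required)}")
    return df
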