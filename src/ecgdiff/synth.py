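"""Class-conditional synthetic multi-lead ECG-like records.

Each record is a quasi-periodic train of P/Q/R/S/T-shaped Gaussian bumps whose
beat rate and bump amplitudes depend on a binary multilabel vector: label
effects add on the log beat rate and multiply the R/T amplitudes, so
multilabel combinations compose predictably. Leads are linear mixes of one
source train (12-lead outputs are built so the limb-lead identities hold
exactly in the noise-free case). Purely a test/training fixture — physiological
fidelity is explicitly not a goal.

Also provides a minimal reader/writer for single-segment format-16 WFDB
records (text header + 16-bit little-endian signal file) plus patient-grouped
splitting, so real PhysioNet-style data can be used when available; nothing in
the package requires it.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ClassEffect", "SynthConfig", "default_class_effects",
    "default_lead_names", "beat_template", "generate_dataset",
    "two_class_config", "dominant_frequency", "classify_by_rate",
    "write_wfdb_record", "read_wfdb_record", "load_wfdb_records",
    "split_by_person",
]

# default P, Q, R, S, T bump parameters on the unit beat interval
DEFAULT_AMPS = (0.12, -0.15, 1.0, -0.2, 0.3)
DEFAULT_CENTERS = (0.15, 0.28, 0.33, 0.38, 0.60)
# widths are generous relative to real ECG so that the beat fundamental
# dominates the spectrum at desk-scale sampling rates (fs ~ 64 Hz)
DEFAULT_WIDTHS = (0.05, 0.02, 0.045, 0.02, 0.12)

# per-lead scale of the common source train (index order = lead_names)
_LEAD_SCALES = {
    "I": 1.0, "aVF": 0.8, "V1": -0.5, "V2": -0.2, "V3": 0.35,
    "V4": 0.9, "V5": 1.1, "V6": 1.0,
}


@dataclass(frozen=True)
class ClassEffect:
    """Per-label modifiers: additive on log beat rate, multiplicative on
    the R and T bump amplitudes."""

    log_rate: float = 0.0
    r_amp: float = 1.0
    t_amp: float = 1.0


def default_class_effects(label_dim: int) -> tuple[ClassEffect, ...]:
    """One effect per label: beat rates spread log-evenly from 1x to 2.4x the
    base rate, with mild alternating amplitude modifiers."""
    if label_dim == 1:
        return (ClassEffect(),)
    top = float(np.log(3.0 / 1.25))
    return tuple(
        ClassEffect(log_rate=i * top / (label_dim - 1),
                    r_amp=1.0 + 0.1 * (i % 2),
                    t_amp=1.0 - 0.1 * (i % 3 == 2))
        for i in range(label_dim))


@dataclass
class SynthConfig:
    n_records: int = 256
    fs: float = 64.0
    duration_s: float = 2.0
    n_leads: int = 2
    label_dim: int = 2
    base_rate_hz: float = 1.25
    class_effects: tuple[ClassEffect, ...] | None = None
    prevalence: tuple[float, ...] | None = None
    noise_sd: float = 0.05
    exclusive: bool = False   # one-hot labels instead of independent Bernoulli
    seed: int = 0

    def __post_init__(self):
        if self.n_leads not in (1, 2, 8, 12):
            raise ValueError(f"n_leads must be 1, 2, 8 or 12, got {self.n_leads}")
        if self.class_effects is None:
            self.class_effects = default_class_effects(self.label_dim)
        if self.prevalence is None:
            self.prevalence = tuple(
                [1.0 / self.label_dim if self.exclusive else 0.5]
                * self.label_dim)
        if len(self.class_effects) != self.label_dim:
            raise ValueError("one ClassEffect per label required")
        if len(self.prevalence) != self.label_dim:
            raise ValueError("one prevalence per label required")
        if any(not 0 <= p <= 1 for p in self.prevalence):
            raise ValueError("prevalences must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        L = self.fs * self.duration_s
        if abs(L - round(L)) > 1e-9 or round(L) < 1:
            raise ValueError(
                f"fs*duration_s must be a positive integer, got {L}")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration_s))

    def label_rates(self) -> np.ndarray:
        """Beat rate (Hz) when exactly one label is active, per label."""
        return self.base_rate_hz * np.exp(
            [e.log_rate for e in self.class_effects])


def two_class_config(n_records: int, seed: int = 0, fs: float = 64.0,
                     duration_s: float = 2.0, n_leads: int = 2,
                     noise_sd: float = 0.05) -> SynthConfig:
    """The desk-scale two-class setup: exclusive one-hot labels with beat
    rates 1.25 Hz and 3.0 Hz."""
    return SynthConfig(n_records=n_records, fs=fs, duration_s=duration_s,
                       n_leads=n_leads, label_dim=2, exclusive=True,
                       noise_sd=noise_sd, seed=seed)


def beat_template(amps, centers, widths, length: int) -> np.ndarray:
    """One beat as a sum of Gaussian bumps on the unit interval."""
    amps = np.asarray(amps, dtype=float)
    centers = np.asarray(centers, dtype=float)
    widths = np.asarray(widths, dtype=float)
    if np.any(widths <= 0):
        raise ValueError("bump widths must be positive")
    if length < 1:
        raise ValueError("beat length must be >= 1")
    tau = (np.arange(length) + 0.5) / length
    return np.sum(
        amps[:, None] * np.exp(-(tau[None, :] - centers[:, None]) ** 2
                               / (2 * widths[:, None] ** 2)), axis=0)


def _sample_labels(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.exclusive:
        p = np.asarray(cfg.prevalence, dtype=float)
        p = p / p.sum()
        idx = rng.choice(cfg.label_dim, size=cfg.n_records, p=p)
        labels = np.zeros((cfg.n_records, cfg.label_dim))
        labels[np.arange(cfg.n_records), idx] = 1.0
        return labels
    return (rng.random((cfg.n_records, cfg.label_dim))
            < np.asarray(cfg.prevalence)).astype(float)


def default_lead_names(n_leads: int) -> tuple[str, ...]:
    from .leads import EIGHT_LEADS, TWELVE_LEADS
    if n_leads == 12:
        return TWELVE_LEADS
    if n_leads == 8:
        return EIGHT_LEADS
    return EIGHT_LEADS[:n_leads]


def _source_train(cfg: SynthConfig, labels: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """Beat train for one record given its label vector."""
    log_rate = np.log(cfg.base_rate_hz) + sum(
        e.log_rate * l for e, l in zip(cfg.class_effects, labels))
    rate = float(np.exp(log_rate))
    r_amp = float(np.prod([e.r_amp ** l for e, l in
                           zip(cfg.class_effects, labels)]))
    t_amp = float(np.prod([e.t_amp ** l for e, l in
                           zip(cfg.class_effects, labels)]))
    amps = np.asarray(DEFAULT_AMPS, dtype=float)
    amps[2] *= r_amp
    amps[4] *= t_amp
    beat_len = max(2, int(round(cfg.fs / rate)))
    beat = beat_template(amps, DEFAULT_CENTERS, DEFAULT_WIDTHS, beat_len)
    L = cfg.n_samples
    reps = L // beat_len + 2
    train = np.tile(beat, reps)
    phase = rng.integers(0, beat_len)
    return train[phase:phase + L]


def generate_dataset(cfg: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    """Return (records, labels): records (n, n_leads, L), labels (n, C)."""
    rng = np.random.default_rng(cfg.seed)
    labels = _sample_labels(cfg, rng)
    names = default_lead_names(cfg.n_leads)
    L = cfg.n_samples
    records = np.empty((cfg.n_records, cfg.n_leads, L))
    for r in range(cfg.n_records):
        src = _source_train(cfg, labels[r], rng)
        if cfg.n_leads == 12:
            from .leads import derive_four_leads
            lead_i = _LEAD_SCALES["I"] * src
            lead_avf = _LEAD_SCALES["aVF"] * src
            ii, iii, avl, avr = derive_four_leads(lead_i, lead_avf)
            rec = np.vstack([lead_i, ii, iii, avr, avl, lead_avf]
                            + [_LEAD_SCALES[n] * src for n in names[6:]])
        else:
            rec = np.vstack([_LEAD_SCALES[n] * src for n in names])
        if cfg.noise_sd > 0:
            rec = rec + cfg.noise_sd * rng.standard_normal(rec.shape)
        records[r] = rec
    return records, labels


# --------------------------------------------------------------------------
# Dominant-frequency detector (separability probe for the two-class fixture)


def dominant_frequency(x: np.ndarray, fs: float,
                       f_lo: float = 0.5, f_hi: float | None = None) -> float:
    """Frequency (Hz) of the largest spectral magnitude in [f_lo, f_hi]."""
    x = np.asarray(x, dtype=float)
    if f_hi is None:
        f_hi = fs / 4
    freqs = np.fft.rfftfreq(x.shape[-1], d=1.0 / fs)
    mag = np.abs(np.fft.rfft(x - x.mean()))
    band = (freqs >= f_lo) & (freqs <= f_hi)
    return float(freqs[band][np.argmax(mag[band])])


def classify_by_rate(records: np.ndarray, fs: float,
                     rates: np.ndarray) -> np.ndarray:
    """Assign each record to the label whose beat rate is nearest (in log
    space) to the record's dominant frequency, searched up to 1.5x the
    fastest candidate rate. records: (n, leads, L)."""
    rates = np.asarray(rates, dtype=float)
    f_hi = min(1.5 * rates.max(), fs / 4)
    out = np.empty(records.shape[0], dtype=int)
    for i, rec in enumerate(records):
        f = dominant_frequency(rec[0], fs, f_hi=f_hi)
        out[i] = int(np.argmin(np.abs(np.log(rates) - np.log(max(f, 1e-9)))))
    return out


# --------------------------------------------------------------------------
# Minimal WFDB (single-segment, format 16) I/O

_GAIN = 200.0  # ADC units per mV


def write_wfdb_record(directory: str, name: str, signal: np.ndarray,
                      fs: float, lead_names) -> None:
    """Write `name.hea` + `name.dat` (format 16, one .dat for all channels)."""
    signal = np.asarray(signal, dtype=float)
    nsig, nsamp = signal.shape
    digital = np.clip(np.rint(signal * _GAIN), -32768, 32767).astype("<i2")
    frames = digital.T.reshape(-1)  # sample-major interleave
    lines = [f"{name} {nsig} {fs:g} {nsamp}"]
    for ch in range(nsig):
        checksum = int(np.int16(digital[ch].astype(np.int64).sum() & 0xFFFF))
        lines.append(f"{name}.dat 16 {_GAIN:g}(0)/mV 16 0 "
                     f"{int(digital[ch, 0])} {checksum} 0 {lead_names[ch]}")
    with open(os.path.join(directory, name + ".hea"), "w") as fh:
        fh.write("\n".join(lines) + "\n")
    frames.tofile(os.path.join(directory, name + ".dat"))


def read_wfdb_record(directory: str, name: str
                     ) -> tuple[np.ndarray, float, list[str]]:
    """Read a record written in the subset of WFDB this package emits."""
    hea = os.path.join(directory, name + ".hea")
    if not os.path.exists(hea):
        raise FileNotFoundError(f"missing WFDB header for record {name!r}")
    with open(hea) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()
                 and not ln.startswith("#")]
    rec, nsig, fs, nsamp = lines[0].split()[:4]
    nsig, nsamp = int(nsig), int(nsamp)
    gains, baselines, leads = [], [], []
    for ln in lines[1:1 + nsig]:
        fields = ln.split()
        fmt = fields[1]
        if fmt != "16":
            raise ValueError(f"unsupported WFDB format {fmt} in record {name!r}")
        gspec = fields[2].split("/")[0]
        if "(" in gspec:
            g, b = gspec.split("(")
            baselines.append(int(b.rstrip(")")))
        else:
            g = gspec
            baselines.append(0)
        gains.append(float(g))
        leads.append(fields[-1])
    dat = os.path.join(directory, name + ".dat")
    if not os.path.exists(dat):
        raise FileNotFoundError(f"missing WFDB signal file for record {name!r}")
    raw = np.fromfile(dat, dtype="<i2")
    digital = raw.reshape(nsamp, nsig).T.astype(float)
    analog = (digital - np.asarray(baselines)[:, None]) \
        / np.asarray(gains)[:, None]
    return analog, float(fs), leads


def load_wfdb_records(path: str, ids, manifest: pd.DataFrame | None = None
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Load records by id; labels come from a manifest with a `record` column
    and `label_*` columns (read from `labels.csv` in `path` if not given)."""
    ids = list(ids)
    if not ids:
        return np.empty((0, 0, 0)), np.empty((0, 0))
    if manifest is None:
        csv = os.path.join(path, "labels.csv")
        manifest = pd.read_csv(csv) if os.path.exists(csv) else None
    records = []
    for rid in ids:
        analog, _, _ = read_wfdb_record(path, rid)
        records.append(analog)
    records = np.stack(records)
    if manifest is not None:
        cols = [c for c in manifest.columns if c.startswith("label_")]
        lookup = manifest.set_index("record")
        labels = np.stack([lookup.loc[rid, cols].to_numpy(dtype=float)
                           for rid in ids])
    else:
        labels = np.zeros((len(ids), 0))
    return records, labels


def split_by_person(manifest: pd.DataFrame, fractions=(0.8, 0.1, 0.1),
                    seed: int = 0) -> dict[str, list]:
    """Partition record ids into train/val/test without splitting any
    person_id across subsets."""
    persons = manifest["person_id"].unique()
    rng = np.random.default_rng(seed)
    rng.shuffle(persons)
    n = len(persons)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    groups = {
        "train": persons[:n_train],
        "val": persons[n_train:n_train + n_val],
        "test": persons[n_train + n_val:],
    }
    return {split: manifest.loc[manifest["person_id"].isin(ps), "record"]
            .tolist() for split, ps in groups.items()}
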