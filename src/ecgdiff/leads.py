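"""Reconstruction of a full 12-lead ECG from the 8 generated leads
(I, aVF, V1–V6) via Einthoven's law and Goldberger's equations:

    III = II − I,  aVL = (I − III)/2,  aVF = (II + III)/2,  −aVR = (I + II)/2

The generator emits I and aVF, so the system is first inverted to
II = aVF + I/2; the remaining identities then hold by construction.
aVR is stored with its conventional (negative) sign.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MultiLeadSignal", "derive_four_leads", "assemble_12_lead",
           "reduce_to_8_lead", "EIGHT_LEADS", "TWELVE_LEADS",
           "check_consistency"]

EIGHT_LEADS = ("I", "aVF", "V1", "V2", "V3", "V4", "V5", "V6")
TWELVE_LEADS = ("I", "II", "III", "aVR", "aVL", "aVF",
                "V1", "V2", "V3", "V4", "V5", "V6")


@dataclass
class MultiLeadSignal:
    """A channels × timesteps record with sampling-rate and lead metadata."""

    values: np.ndarray
    fs: float
    lead_names: tuple[str, ...]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.lead_names = tuple(self.lead_names)
        if self.values.ndim != 2:
            raise ValueError(f"values must be 2-D, got shape {self.values.shape}")
        if len(self.lead_names) != self.values.shape[0]:
            raise ValueError(
                f"{len(self.lead_names)} lead names for "
                f"{self.values.shape[0]} channels")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite signal values")

    def lead(self, name: str) -> np.ndarray:
        return self.values[self.lead_names.index(name)]


def derive_four_leads(lead_i: np.ndarray, lead_avf: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Return (II, III, aVL, aVR) from leads I and aVF."""
    lead_i = np.asarray(lead_i, dtype=float)
    lead_avf = np.asarray(lead_avf, dtype=float)
    if lead_i.shape != lead_avf.shape:
        raise ValueError(
            f"lead length mismatch: I {lead_i.shape}, aVF {lead_avf.shape}")
    if not (np.isfinite(lead_i).all() and np.isfinite(lead_avf).all()):
        raise ValueError("non-finite lead values")
    lead_ii = lead_avf + lead_i / 2
    lead_iii = lead_ii - lead_i
    lead_avl = (lead_i - lead_iii) / 2
    lead_avr = -(lead_i + lead_ii) / 2
    return lead_ii, lead_iii, lead_avl, lead_avr


def assemble_12_lead(eight: MultiLeadSignal) -> MultiLeadSignal:
    """Expand an 8-lead record [I, aVF, V1–V6] into the canonical 12-lead
    order [I, II, III, aVR, aVL, aVF, V1–V6]; precordials pass through."""
    if eight.lead_names != EIGHT_LEADS:
        raise ValueError(
            f"expected leads {EIGHT_LEADS}, got {eight.lead_names}")
    lead_i, lead_avf = eight.values[0], eight.values[1]
    lead_ii, lead_iii, lead_avl, lead_avr = derive_four_leads(lead_i, lead_avf)
    values = np.vstack([lead_i, lead_ii, lead_iii, lead_avr, lead_avl,
                        lead_avf, eight.values[2:]])
    return MultiLeadSignal(values=values, fs=eight.fs, lead_names=TWELVE_LEADS)


def reduce_to_8_lead(twelve: MultiLeadSignal) -> MultiLeadSignal:
    """Keep the generated subset [I, aVF, V1–V6] of a 12-lead record."""
    if twelve.lead_names != TWELVE_LEADS:
        raise ValueError(
            f"expected leads {TWELVE_LEADS}, got {twelve.lead_names}")
    idx = [twelve.lead_names.index(n) for n in EIGHT_LEADS]
    return MultiLeadSignal(values=twelve.values[idx], fs=twelve.fs,
                           lead_names=EIGHT_LEADS)


def check_consistency(twelve: MultiLeadSignal, atol: float = 1e-10) -> float:
    """Max-abs residual of the four limb/augmented-lead identities."""
    g = twelve.lead
    res = [
        g("III") - (g("II") - g("I")),
        g("aVL") - (g("I") - g("III")) / 2,
        g("aVF") - (g("II") + g("III")) / 2,
        -g("aVR") - (g("I") + g("II")) / 2,
    ]
    return float(max(np.abs(r).max() for r in res))
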