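"""Closed-form spin-echo signal equations.

These equations serve double duty: they simulate magnitude acquisitions
(inversion-recovery and multi-echo spin-echo series) and they resynthesize
arbitrarily weighted contrasts from quantitative PD/T1/T2 maps — the core
idea of synthetic MRI, where a single quantitative scan replaces several
weighted acquisitions.

Model assumptions
-----------------
* Perfect inversion: the inversion-recovery bracket uses a factor of
  exactly 2; inversion efficiency is not a free parameter.
* Effective timings only: echo-train and partition effects of fast
  spin-echo readouts are ignored; each contrast is characterized by its
  effective TR/TE/TI.
* Magnitude convention: public signal functions return absolute values,
  matching scanner magnitude images.  The signed recovery curve is
  available via ``ir_se_signal_signed`` for curve fitting.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "SequenceParams",
    "TissueParams",
    "ir_se_signal",
    "ir_se_signal_signed",
    "t2_decay",
    "synthesize_weighted",
    "null_t1_for_sequence",
]

BACKGROUND_LABEL = 0


@dataclass(frozen=True)
class SequenceParams:
    """Effective timing parameters of one spin-echo acquisition, in ms.

    ``ti`` is ``None`` for sequences without an inversion pulse (e.g. a
    plain T2-weighted fast spin echo).
    """

    tr: float
    te: float
    ti: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.tr) or self.tr <= 0:
            raise ValueError(f"TR must be a positive finite time in ms, got {self.tr}")
        if not math.isfinite(self.te) or self.te < 0:
            raise ValueError(f"TE must be a non-negative time in ms, got {self.te}")
        if self.te >= self.tr:
            raise ValueError(f"TE ({self.te} ms) must be shorter than TR ({self.tr} ms)")
        if self.ti is not None:
            if not math.isfinite(self.ti) or self.ti < 0:
                raise ValueError(f"TI must be a non-negative time in ms, got {self.ti}")
            if self.ti >= self.tr:
                raise ValueError(f"TI ({self.ti} ms) must be shorter than TR ({self.tr} ms)")

    @property
    def has_inversion(self) -> bool:
        return self.ti is not None


# Effective contrast timings of the three weighted protocols simulated by
# default (axial T1w IR-FSE, coronal T2w FSE, T2-FLAIR).
T1W = SequenceParams(tr=1800.0, te=23.0, ti=750.0, label="T1w")
T2W = SequenceParams(tr=4545.0, te=110.0, label="T2w")
FLAIR = SequenceParams(tr=9000.0, te=92.0, ti=2472.0, label="T2-FLAIR")


@dataclass(frozen=True)
class TissueParams:
    """Quantitative parameters of one tissue class.

    pd is proton density in arbitrary units; t1 and t2 are relaxation
    times in ms.  Physically plausible tissue has t2 <= t1; violations
    are warned about but accepted (useful for degenerate test inputs).
    """

    pd: float
    t1: float
    t2: float
    name: str = ""

    def __post_init__(self) -> None:
        if self.pd < 0 or not math.isfinite(self.pd):
            raise ValueError(f"PD must be >= 0 and finite, got {self.pd}")
        for attr in ("t1", "t2"):
            v = getattr(self, attr)
            if v <= 0 or not math.isfinite(v):
                raise ValueError(f"{attr.upper()} must be a positive finite time, got {v}")
        if self.t2 > self.t1:
            warnings.warn(
                f"T2 ({self.t2} ms) exceeds T1 ({self.t1} ms) for tissue "
                f"{self.name or '<unnamed>'}; physically implausible",
                stacklevel=2,
            )


def _check_positive_times(**kwargs: float) -> None:
    for name, value in kwargs.items():
        arr = np.asarray(value, dtype=float)
        if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
            raise ValueError(f"{name} must be positive and finite, got {value!r}")


def ir_se_signal_signed(ti, tr, t1, pd=1.0):
    """Signed inversion-recovery spin-echo signal.

    S(TI) = pd * (1 - 2 exp(-TI/T1) + exp(-TR/T1))

    This is the real-valued longitudinal recovery after a perfect 180deg
    inversion with repetition time TR; it is negative for TI well below
    the null point TI ~= T1 ln 2 (for TR >> T1).
    """
    _check_positive_times(tr=tr, t1=t1)
    ti = np.asarray(ti, dtype=float)
    if np.any(ti < 0) or not np.all(np.isfinite(ti)):
        raise ValueError(f"TI must be >= 0 and finite, got {ti!r}")
    signal = pd * (1.0 - 2.0 * np.exp(-ti / np.asarray(t1, float)) + np.exp(-np.asarray(tr, float) / np.asarray(t1, float)))
    return signal if signal.ndim else float(signal)


def ir_se_signal(ti, tr, t1, pd=1.0):
    """Magnitude inversion-recovery spin-echo signal |S(TI)|, in a.u.

    Parameters are times in ms (``ti`` may be 0) and a non-negative
    proton density.  Scalars and arrays broadcast.
    """
    out = np.abs(ir_se_signal_signed(ti, tr, t1, pd))
    return out if np.ndim(out) else float(out)


def t2_decay(te, t2, s0=1.0):
    """Mono-exponential transverse decay S(TE) = s0 * exp(-TE/T2)."""
    _check_positive_times(t2=t2)
    te = np.asarray(te, dtype=float)
    if np.any(te < 0) or not np.all(np.isfinite(te)):
        raise ValueError(f"TE must be >= 0 and finite, got {te!r}")
    signal = np.asarray(s0, float) * np.exp(-te / np.asarray(t2, float))
    return signal if signal.ndim else float(signal)


def spin_echo_signal(tissue_pd, t1, t2, seq: SequenceParams):
    """Magnitude signal of ``seq`` for tissue (pd, t1, t2); broadcasts.

    With an inversion pulse the signal is the IR recovery bracket times
    the TE decay; without one it is the saturation-recovery form
    pd * (1 - exp(-TR/T1)) * exp(-TE/T2).
    """
    if seq.has_inversion:
        return ir_se_signal(seq.ti, seq.tr, t1, tissue_pd) * t2_decay(seq.te, t2, 1.0)
    recovery = 1.0 - np.exp(-seq.tr / np.asarray(t1, float))
    out = np.asarray(tissue_pd, float) * recovery * t2_decay(seq.te, t2, 1.0)
    return out if np.ndim(out) else float(out)


def synthesize_weighted(maps, seq: SequenceParams) -> np.ndarray:
    """Resynthesize a weighted image volume from quantitative maps.

    ``maps`` must carry co-registered ``pd``, ``t1``, ``t2`` and
    ``labels`` volumes on one grid (see
    :class:`synthmri.synthetic_data.QuantitativeMaps`).  Voxels labelled
    background produce exactly 0 signal.
    """
    pd_map = np.asarray(maps.pd, dtype=float)
    t1_map = np.asarray(maps.t1, dtype=float)
    t2_map = np.asarray(maps.t2, dtype=float)
    labels = np.asarray(maps.labels)
    shapes = {pd_map.shape, t1_map.shape, t2_map.shape, labels.shape}
    if len(shapes) != 1:
        raise ValueError(f"quantitative maps must share one grid, got shapes {sorted(shapes)}")

    mask = labels != BACKGROUND_LABEL
    out = np.zeros(pd_map.shape, dtype=float)
    if not mask.any():
        return out
    t1_v = t1_map[mask]
    t2_v = t2_map[mask]
    if np.any(t1_v <= 0) or np.any(t2_v <= 0):
        raise ValueError("non-background voxels must have positive T1 and T2")
    out[mask] = spin_echo_signal(pd_map[mask], t1_v, t2_v, seq)
    return out


def null_t1_for_sequence(seq: SequenceParams) -> float:
    """T1 (ms) whose IR signal is nulled by this sequence's TI/TR.

    Solves 1 - 2 exp(-TI/T1) + exp(-TR/T1) = 0 for T1 by bracketed root
    search on [1, 10*TR].  This is the tissue a FLAIR-style sequence
    suppresses (TI chosen to null CSF).
    """
    if not seq.has_inversion:
        raise ValueError("sequence has no inversion pulse; no null T1 exists")
    ti, tr = float(seq.ti), float(seq.tr)

    def bracket(t1: float) -> float:
        return 1.0 - 2.0 * math.exp(-ti / t1) + math.exp(-tr / t1)

    lo, hi = 1.0, 10.0 * tr
    if bracket(lo) * bracket(hi) > 0:
        raise ValueError(
            f"no sign change of the IR bracket on [{lo}, {hi}] ms for TI={ti}, TR={tr}"
        )
    root = brentq(bracket, lo, hi, xtol=1e-12, rtol=8.9e-16)
    return float(root)
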