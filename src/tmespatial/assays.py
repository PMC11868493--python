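"""Cytotoxicity- and staining-assay arithmetic.

Small, exactly specified formulas used to summarize killing assays and
quantitative immunostaining:

* ``per_capita_killing`` — targets killed per CTL, kctl = n_killed / n_ctl.
* ``specific_lysis`` — background-corrected target-cell death,
  ``100 × (death − basal) / (100 − basal)``. The denominator is
  (100 − basal), the standard cytotoxicity convention.
* ``realtime_norm`` — plate-reader death signal normalized against a
  positive (full-kill) control: ``(control − sample) / control``; lower
  values mean more death in the sample.
* ``jc1_ratio`` — mitochondrial membrane-potential readout, red
  J-aggregate / green J-monomer fluorescence, optionally as fold change
  versus a control ratio (rendered as an n-fold decrease when < 1).
* ``ir_score`` — immunoreactivity: positive-cell fraction among tumor cells
  (DAPI-counted) multiplied by staining intensity, in arbitrary units, plus
  mean-intensity stratification of ROIs into high/low groups.

All functions accept scalars or numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError


# ---------------------------------------------------------------------------
# killing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KillingObservation:
    """One killing-assay well: effector count, target count, killed count."""

    effector_count: int
    target_count: int
    killed_count: int

    def __post_init__(self):
        if self.effector_count <= 0:
            raise InputError("effector_count must be > 0")
        if self.target_count <= 0:
            raise InputError("target_count must be > 0")
        if not 0 <= self.killed_count <= self.target_count:
            raise InputError("killed_count must be in [0, target_count]")

    @property
    def et_ratio(self) -> float:
        return self.effector_count / self.target_count

    @property
    def kctl(self) -> float:
        return per_capita_killing(self.killed_count, self.effector_count)


def per_capita_killing(n_killed, n_ctl):
    """Targets killed per CTL: kctl = n_killed / n_ctl."""
    n_ctl = np.asarray(n_ctl, dtype=float)
    if (n_ctl <= 0).any():
        raise InputError("per_capita_killing requires effector count > 0")
    out = np.asarray(n_killed, dtype=float) / n_ctl
    return float(out) if out.ndim == 0 else out


def kctl_table(killing: "np.typing.ArrayLike") -> "object":
    """Append a kctl column to a killing table (killed_count / effector_count)."""
    import pandas as pd

    table = pd.DataFrame(killing).copy()
    table["kctl"] = per_capita_killing(
        table["killed_count"].to_numpy(), table["effector_count"].to_numpy()
    )
    return table


# ---------------------------------------------------------------------------
# lysis and plate-reader normalization
# ---------------------------------------------------------------------------

def specific_lysis(pct_death, pct_basal):
    """Background-corrected lysis: 100 × (death − basal) / (100 − basal)."""
    death = np.asarray(pct_death, dtype=float)
    basal = np.asarray(pct_basal, dtype=float)
    if ((basal >= 100) | (basal < 0)).any():
        raise InputError("pct_basal must be in [0, 100)")
    if ((death > 100) | (death < 0)).any():
        raise InputError("pct_death must be in [0, 100]")
    out = 100.0 * (death - basal) / (100.0 - basal)
    return float(out) if out.ndim == 0 else out


def realtime_norm(sample_signal, positive_control_signal):
    """Death normalized to a positive control: (control − sample) / control.

    Equals 1 only when the sample signal is 0; lower values indicate less
    death relative to the full-kill control.
    """
    control = np.asarray(positive_control_signal, dtype=float)
    if (control <= 0).any():
        raise InputError("positive control signal must be > 0")
    out = (control - np.asarray(sample_signal, dtype=float)) / control
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class JC1Result:
    ratio: float
    fold_change: float | None = None

    @property
    def fold_decrease(self) -> float | None:
        """n-fold decrease rendering: 1/fold_change when the ratio dropped."""
        if self.fold_change is None:
            return None
        return 1.0 / self.fold_change if self.fold_change < 1 else None


def jc1_ratio(red_aggregate, green_monomer, control_ratio: float | None = None) -> JC1Result:
    """Red/green JC-1 fluorescence ratio, optionally vs a control ratio."""
    green = float(green_monomer)
    if green <= 0:
        raise InputError("green (monomer) signal must be > 0")
    ratio = float(red_aggregate) / green
    if control_ratio is None:
        return JC1Result(ratio)
    if control_ratio <= 0:
        raise InputError("control ratio must be > 0")
    return JC1Result(ratio, fold_change=ratio / control_ratio)


def live_dead_ratio(n_live, n_dead):
    """Live-to-dead cell count ratio."""
    n_dead = np.asarray(n_dead, dtype=float)
    if (n_dead <= 0).any():
        raise InputError("live/dead ratio requires dead count > 0")
    out = np.asarray(n_live, dtype=float) / n_dead
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# immunoreactivity
# ---------------------------------------------------------------------------

def ir_score(n_positive, n_total_tumor_cells, staining_intensity):
    """Immunoreactivity = (positive cells / total tumor cells) × intensity.

    ``staining_intensity`` is by default the mean per-cell marker intensity
    over tumor-region cells of the ROI (an all-tumor-cell mean; a
    positive-cell mean is an equally valid caller-side choice).
    """
    n_total = np.asarray(n_total_tumor_cells, dtype=float)
    if (n_total <= 0).any():
        raise InputError("n_total_tumor_cells must be > 0")
    n_pos = np.asarray(n_positive, dtype=float)
    if ((n_pos < 0) | (n_pos > n_total)).any():
        raise InputError("n_positive must be in [0, n_total]")
    intensity = np.asarray(staining_intensity, dtype=float)
    if (intensity < 0).any():
        raise InputError("staining_intensity must be >= 0")
    out = n_pos / n_total * intensity
    return float(out) if out.ndim == 0 else out


def ir_stratify(intensity_values, cutoff: float | None = None) -> np.ndarray:
    """Split ROIs/samples into high/low at a mean-intensity cutoff.

    When ``cutoff`` is None the mean of ``intensity_values`` is used; values
    strictly above the cutoff are "high".
    """
    v = np.asarray(intensity_values, dtype=float)
    if len(v) == 0:
        raise InputError("ir_stratify requires at least one value")
    if cutoff is None:
        cutoff = float(v.mean())
    return np.where(v > cutoff, "high", "low")
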