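"""Spectral preprocessing: contralateral unit-length normalization and
chemical-shift referencing to the total-creatine peak.

UL2CA normalization divides every datapoint of a spectrum by the
Euclidean norm of the same animal's contralateral (non-infarcted)
spectrum over the full 0-4.5 ppm window and multiplies by 100, so a
spectrum normalized against itself has Euclidean norm exactly 100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import Cohort, SpectrumRecord, ValidationError, ppm_to_index

__all__ = [
    "NormalizationReport",
    "DegenerateReferenceError",
    "ReferencingWarning",
    "ul2ca_normalize",
    "reference_to_tcr",
    "normalize_cohort",
    "TCR_PPM",
]

TCR_PPM = 3.03  # total creatine N-methyl resonance used for referencing


class DegenerateReferenceError(ValueError):
    """Contralateral reference has zero intensity norm."""


class ReferencingWarning(UserWarning):
    """Chemical-shift referencing could not find a usable peak maximum."""


@dataclass(frozen=True)
class NormalizationReport:
    spectrum_id: str
    reference_id: str
    norm_constant: float  # Euclidean norm of the contralateral spectrum


def ul2ca_normalize(
    spectrum: SpectrumRecord, contralateral: SpectrumRecord
) -> tuple[SpectrumRecord, NormalizationReport]:
    """Unit-length normalization to the contralateral area.

    Every datapoint h is replaced by 100 * h / ||h_CA||_2, with the norm
    taken over the contralateral spectrum's full 0-4.5 ppm vector.
    """
    if spectrum.normalized or contralateral.normalized:
        raise ValidationError("inputs to ul2ca_normalize must be unnormalized")
    if spectrum.ppm_axis.shape != contralateral.ppm_axis.shape or not np.allclose(
        spectrum.ppm_axis, contralateral.ppm_axis
    ):
        raise ValidationError("spectrum and contralateral reference share no common axis")
    norm = float(np.linalg.norm(contralateral.intensities))
    if norm <= 0.0 or not np.isfinite(norm):
        raise DegenerateReferenceError(
            f"contralateral spectrum {contralateral.spectrum_id} has zero norm"
        )
    out = spectrum.copy_with(
        intensities=100.0 * spectrum.intensities / norm, normalized=True
    )
    return out, NormalizationReport(spectrum.spectrum_id, contralateral.spectrum_id, norm)


def reference_to_tcr(
    spectrum: SpectrumRecord, target_ppm: float = TCR_PPM, window: float = 0.15
) -> SpectrumRecord:
    """Shift a spectrum by whole datapoints so the creatine maximum sits at 3.03 ppm.

    The maximum is searched within +/- `window` ppm of `target_ppm`; the
    intensity vector is rolled by an integer number of datapoints (edge
    values are repeated, never interpolated).  If no interior local
    maximum exists in the window (e.g. a flat spectrum) the input is
    returned unshifted with a ReferencingWarning.
    """
    if spectrum.normalized:
        raise ValidationError("reference_to_tcr expects an unnormalized spectrum")
    axis = spectrum.ppm_axis
    mask = np.abs(axis - target_ppm) <= window
    idx = np.flatnonzero(mask)
    vals = spectrum.intensities[idx]
    if vals.size < 3 or np.ptp(vals) == 0:
        warnings.warn(
            f"{spectrum.spectrum_id}: no peak found near {target_ppm} ppm; unshifted",
            ReferencingWarning,
        )
        return spectrum
    k = int(np.argmax(vals))
    if k == 0 or k == vals.size - 1:
        warnings.warn(
            f"{spectrum.spectrum_id}: maximum at window edge near {target_ppm} ppm; unshifted",
            ReferencingWarning,
        )
        return spectrum
    peak_index = int(idx[k])
    target_index = ppm_to_index(axis, target_ppm)
    shift = target_index - peak_index
    if shift == 0:
        return spectrum
    shifted = np.empty_like(spectrum.intensities)
    if shift > 0:
        shifted[shift:] = spectrum.intensities[:-shift]
        shifted[:shift] = spectrum.intensities[0]
    else:
        shifted[:shift] = spectrum.intensities[-shift:]
        shifted[shift:] = spectrum.intensities[-1]
    return spectrum.copy_with(intensities=shifted)


def normalize_cohort(
    cohort: Cohort, reference: bool = True
) -> tuple[Cohort, list[NormalizationReport]]:
    """Reference every spectrum to TCr, then apply UL2CA normalization pairwise.

    Each spectrum is normalized against its `contralateral_map` entry
    (after that reference has itself been TCr-referenced).  Records
    lacking a reference raise ValidationError.
    """
    refd = {}
    for r in cohort.records:
        refd[r.spectrum_id] = reference_to_tcr(r) if reference else r
    out, reports = [], []
    for r in cohort.records:
        ref_id = cohort.contralateral_map.get(r.spectrum_id)
        if ref_id is None:
            raise ValidationError(f"{r.spectrum_id}: no contralateral reference assigned")
        norm_rec, rep = ul2ca_normalize(refd[r.spectrum_id], refd[ref_id])
        out.append(norm_rec)
        reports.append(rep)
    return Cohort(out, list(cohort.class_labels), dict(cohort.contralateral_map)), reports
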