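"""Patient-specific piecewise-constant phantoms from organ segmentations.

A finished organ label map of a patient is turned into a phantom CT by
assigning each label its tissue CT number — the construction used for
hold-out dosimetric and external validation. Segmentation itself is out of
scope; the module consumes label maps produced elsewhere.
"""

from __future__ import annotations

from .metrics.paired import CannyParams, PairedReport, evaluate_paired_volumes
from .phantoms import render_ct
from .volumes import LabelVolume, TissueTable, Volume

__all__ = ["labels_to_phantom", "validate_against_patient"]


def labels_to_phantom(labels: LabelVolume, tissues: TissueTable) -> Volume:
    """Piecewise-constant CT-number volume in patient geometry.

    Label 0 renders as air (-1000 HU); any unmapped label raises a lookup
    error naming the offending labels. Deterministic and idempotent.
    """
    return render_ct(labels, tissues)


def validate_against_patient(phantom_realistic: Volume, patient_ct: Volume,
                             canny_params: CannyParams | None = None,
                             lpips_backend=None) -> PairedReport:
    """Slice-by-slice paired evaluation of a realistic phantom against the
    co-registered patient CT (mean ± SD summaries per metric)."""
    if phantom_realistic.shape != patient_ct.shape:
        raise ValueError(
            f"geometry mismatch: {phantom_realistic.shape} vs {patient_ct.shape}"
        )
    return evaluate_paired_volumes(phantom_realistic, patient_ct,
                                   canny_params=canny_params,
                                   lpips_backend=lpips_backend)
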