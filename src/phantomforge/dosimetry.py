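"""Dose-volume histograms and their clinical summary statistics.

The DVH of a structure is the empirical cumulative curve V(d): the fraction
of structure voxels receiving at least dose d. D_p% is the largest dose such
that V(d) >= p/100 — e.g. D95% is the minimum dose covering 95% of a target,
D2% the dose to the most exposed 2% of an organ at risk. Plan comparisons
report the difference Δ = recalculated − reference per metric, with the
relative error taken against the prescribed dose for targets and against the
reference-plan metric for organs at risk.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .volumes import Volume

__all__ = ["DVHCurve", "DoseSummary", "dvh", "d_percent", "compare_plans"]


@dataclasses.dataclass
class DVHCurve:
    dose_gy: np.ndarray          # ascending unique dose values
    volume_fraction: np.ndarray  # V(d) = fraction of voxels with dose >= d
    structure: str
    n_voxels: int
    _sorted_doses: np.ndarray = dataclasses.field(repr=False, default=None)

    def to_csv(self, path) -> None:
        np.savetxt(path, np.column_stack([self.dose_gy, self.volume_fraction]),
                   delimiter=",", header="dose_gy,volume_fraction", comments="")


def dvh(dose, mask, structure: str = "") -> DVHCurve:
    """Empirical cumulative DVH over the masked voxels (equal voxel weight)."""
    data = dose.data if isinstance(dose, Volume) else np.asarray(dose, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != data.shape:
        raise ValueError(f"mask shape {mask.shape} != dose shape {data.shape}")
    if not mask.any():
        raise ValueError(f"empty structure mask {structure!r}")
    vals = np.sort(data[mask].astype(np.float64))
    n = vals.size
    unique, first_idx = np.unique(vals, return_index=True)
    vfrac = 1.0 - first_idx / n  # fraction of voxels with dose >= unique[i]
    return DVHCurve(unique, vfrac, structure, n, _sorted_doses=vals)


def d_percent(curve: DVHCurve, p: float) -> float:
    """D_p%: the largest dose d with V(d) >= p/100 (ties take the higher dose).

    Equivalently the empirical (100-p)th percentile of the masked dose with
    the higher-value convention.
    """
    if not 0 < p < 100:
        raise ValueError("p must be in (0, 100)")
    ok = curve.volume_fraction >= p / 100.0
    if not ok.any():  # p larger than any achievable coverage: min dose
        return float(curve.dose_gy[0])
    return float(curve.dose_gy[ok][-1])


@dataclasses.dataclass
class DoseSummary:
    """Per-structure metric values for both plans, with Δ and relative error.

    ``metrics[structure]`` holds ``{metric, ref, recalc, delta, error_pct,
    denominator}``; targets use the prescribed dose as error denominator,
    organs at risk the reference-plan metric. ``error_pct`` is None when the
    denominator is zero.
    """

    prescribed_gy: float
    metrics: dict


def compare_plans(ref_dose, recalc_dose, target_masks: dict, oar_masks: dict,
                  prescribed_gy: float, target_p: float = 95.0,
                  oar_p: float = 2.0) -> DoseSummary:
    """DVH-metric comparison of a reference and a recalculated dose grid.

    Targets are scored with D_{target_p}% (default D95%), organs at risk with
    D_{oar_p}% (default D2%).
    """
    out: dict[str, dict] = {}
    for group, masks, p, use_prescribed in (
        ("target", target_masks, target_p, True),
        ("oar", oar_masks, oar_p, False),
    ):
        for name, mask in masks.items():
            ref_val = d_percent(dvh(ref_dose, mask, name), p)
            new_val = d_percent(dvh(recalc_dose, mask, name), p)
            delta = new_val - ref_val
            denom = prescribed_gy if use_prescribed else ref_val
            out[name] = {
                "group": group,
                "metric": f"D{p:g}%",
                "ref": ref_val,
                "recalc": new_val,
                "delta": delta,
                "denominator": denom,
                "error_pct": (100.0 * delta / denom) if denom != 0 else None,
            }
    return DoseSummary(prescribed_gy, out)
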