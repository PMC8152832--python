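"""Tissue- and relaxation-corrected MRS metabolite quantification.

Converts water-referenced metabolite signal amplitudes from a single-voxel
spectroscopy acquisition into concentration estimates (institutional
mM-equivalent units), correcting for the voxel's partial-volume composition
and for compartment-specific water relaxation, in the water-scaling framework
of Gasparovic-style quantification.  The voxel is modelled as a mixture of
gray matter (GM), white matter (WM) and cerebrospinal fluid (CSF); each
compartment contributes water signal in proportion to its volume fraction,
relative water density and T1/T2 relaxation attenuation at the sequence's
TR/TE, while the metabolite itself is assumed to reside only in tissue
(hence the 1 - f_csf divisor).

Quality control follows the conventional single-voxel gates: a spectrum is
usable when its linewidth is below 10 Hz and its time-domain SNR exceeds 5.

The shipped relaxation constants are literature compartment *water* values
(T1: GM 1331 ms, WM 832 ms, CSF 3817 ms; T2: GM 110 ms, WM 79 ms, CSF
503 ms) at the acquisition's TR = 2000 ms, TE = 68 ms.  Metabolite-specific
relaxation attenuation is deliberately a separate multiplicative factor
defaulting to 1 (no metabolite relaxation correction); see docs/methods.md.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "REGIONS",
    "METABOLITES",
    "TissueFractions",
    "RelaxationConstants",
    "QCResult",
    "qc_filter",
    "apply_qc",
    "compartment_attenuation",
    "correct_concentration",
    "signal_from_concentration",
    "correct_panel",
    "compute_ratio",
    "ratio_table",
]

#: Voxel locations quantified by the pipeline.
REGIONS = ("LSM1", "RSM1", "preSMA", "RIFG", "LSTR", "RSTR", "OCC")

#: Metabolites quantified from the edit-OFF spectra.
METABOLITES = ("NAA", "Glx", "Cr", "Cho", "mIns")

#: QC gates: spectra need linewidth < 10 Hz and SNR > 5 (strict inequalities).
QC_MAX_LINEWIDTH_HZ = 10.0
QC_MIN_SNR = 5.0


@dataclass(frozen=True)
class TissueFractions:
    """GM/WM/CSF volume fractions of an MRS voxel.

    Fractions are renormalized to sum to one on construction; a mis-sum
    larger than 1e-3 (typical of rounded segmentation output) triggers a
    warning rather than a rejection.
    """

    f_gm: float
    f_wm: float
    f_csf: float

    def __post_init__(self) -> None:
        vals = (self.f_gm, self.f_wm, self.f_csf)
        if any(not math.isfinite(v) or v < 0.0 or v > 1.0 for v in vals):
            raise ValueError(f"tissue fractions must lie in [0, 1], got {vals}")
        total = sum(vals)
        if total <= 0.0:
            raise ValueError("tissue fractions sum to zero")
        if abs(total - 1.0) > 1e-6:
            if abs(total - 1.0) > 1e-3:
                warnings.warn(
                    f"tissue fractions sum to {total:.4f}; renormalizing",
                    stacklevel=2,
                )
            object.__setattr__(self, "f_gm", self.f_gm / total)
            object.__setattr__(self, "f_wm", self.f_wm / total)
            object.__setattr__(self, "f_csf", self.f_csf / total)


@dataclass(frozen=True)
class RelaxationConstants:
    """Compartment water relaxation times, water densities and sequence timing.

    All times in ms.  Water contents are relative molar water densities;
    ``pure_water_concentration`` is the molar concentration of pure water
    (55 510 mM), the scale factor of water-referenced quantification.
    """

    t1_gm: float = 1331.0
    t1_wm: float = 832.0
    t1_csf: float = 3817.0
    t2_gm: float = 110.0
    t2_wm: float = 79.0
    t2_csf: float = 503.0
    tr: float = 2000.0
    te: float = 68.0
    water_content_gm: float = 0.78
    water_content_wm: float = 0.65
    water_content_csf: float = 0.97
    pure_water_concentration: float = 55510.0

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if not math.isfinite(value) or value <= 0.0:
                raise ValueError(f"{name} must be positive and finite, got {value}")
        if self.te >= self.tr:
            raise ValueError(f"TE ({self.te}) must be shorter than TR ({self.tr})")

    def water_attenuations(self) -> tuple[float, float, float]:
        """Relaxation attenuation of the water signal in (GM, WM, CSF)."""
        return (
            compartment_attenuation(self.t1_gm, self.t2_gm, self.tr, self.te),
            compartment_attenuation(self.t1_wm, self.t2_wm, self.tr, self.te),
            compartment_attenuation(self.t1_csf, self.t2_csf, self.tr, self.te),
        )


@dataclass(frozen=True)
class QCResult:
    passed: bool
    reason: str | None = None


def qc_filter(
    snr: float | None,
    linewidth_hz: float | None,
    *,
    min_snr: float = QC_MIN_SNR,
    max_linewidth_hz: float = QC_MAX_LINEWIDTH_HZ,
) -> QCResult:
    """Apply the spectral quality gates.

    Passes iff ``linewidth_hz < max_linewidth_hz`` and ``snr > min_snr``
    (both strict).  Missing QC fields fail with reason ``"missing-qc"``.
    The returned reason names the rule that fired (``"linewidth"`` is
    reported first when both fail).
    """
    if (
        snr is None
        or linewidth_hz is None
        or not math.isfinite(snr)
        or not math.isfinite(linewidth_hz)
    ):
        return QCResult(False, "missing-qc")
    if linewidth_hz >= max_linewidth_hz:
        return QCResult(False, "linewidth")
    if snr <= min_snr:
        return QCResult(False, "snr")
    return QCResult(True, None)


def apply_qc(
    panel: pd.DataFrame,
    *,
    min_snr: float = QC_MIN_SNR,
    max_linewidth_hz: float = QC_MAX_LINEWIDTH_HZ,
) -> pd.DataFrame:
    """Append ``qc_pass`` / ``qc_reason`` columns to a metabolite panel."""
    results = [
        qc_filter(
            row.snr if pd.notna(row.snr) else None,
            row.linewidth_hz if pd.notna(row.linewidth_hz) else None,
            min_snr=min_snr,
            max_linewidth_hz=max_linewidth_hz,
        )
        for row in panel.itertuples()
    ]
    out = panel.copy()
    out["qc_pass"] = [r.passed for r in results]
    out["qc_reason"] = [r.reason if r.reason is not None else "" for r in results]
    return out


def compartment_attenuation(t1: float, t2: float, tr: float, te: float) -> float:
    """Steady-state relaxation attenuation (1 - exp(-TR/T1)) * exp(-TE/T2).

    The saturation term accounts for incomplete longitudinal recovery over
    TR; the exponential term for transverse decay over TE.  Returns a factor
    in (0, 1).
    """
    for name, v in (("t1", t1), ("t2", t2), ("tr", tr), ("te", te)):
        if not math.isfinite(v) or v <= 0.0:
            raise ValueError(f"{name} must be positive and finite, got {v}")
    return (1.0 - math.exp(-tr / t1)) * math.exp(-te / t2)


def _water_weighted_fractions(
    fractions: TissueFractions, constants: RelaxationConstants
) -> tuple[float, float, float]:
    raw = (
        fractions.f_gm * constants.water_content_gm,
        fractions.f_wm * constants.water_content_wm,
        fractions.f_csf * constants.water_content_csf,
    )
    total = sum(raw)
    return tuple(v / total for v in raw)  # type: ignore[return-value]


def correct_concentration(
    signal_ratio: float,
    fractions: TissueFractions,
    constants: RelaxationConstants | None = None,
    metabolite_attenuation: float = 1.0,
) -> float:
    """Tissue- and relaxation-corrected concentration from a water-referenced signal.

    With water-content-weighted fractions ``f'_k = f_k w_k / sum_j f_j w_j``
    and water attenuations ``R_k``::

        C = signal_ratio * C_water * (sum_k f'_k R_k) / ((1 - f'_csf) * A_met)

    where ``C_water`` is the pure-water concentration and ``A_met`` the
    metabolite relaxation attenuation (default 1).  The correction is linear
    in ``signal_ratio`` and strictly increasing in CSF fraction at fixed
    signal and GM/WM ratio.
    """
    if constants is None:
        constants = RelaxationConstants()
    if not math.isfinite(signal_ratio):
        raise ValueError("signal_ratio must be finite")
    if not (0.0 < metabolite_attenuation <= 1.0 + 1e-12):
        raise ValueError("metabolite_attenuation must lie in (0, 1]")
    fw = _water_weighted_fractions(fractions, constants)
    if fw[2] >= 1.0 - 1e-12:
        raise ValueError("voxel is pure CSF: corrected concentration undefined")
    r = constants.water_attenuations()
    water_term = sum(f * ri for f, ri in zip(fw, r))
    return (
        signal_ratio
        * constants.pure_water_concentration
        * water_term
        / ((1.0 - fw[2]) * metabolite_attenuation)
    )


def signal_from_concentration(
    concentration: float,
    fractions: TissueFractions,
    constants: RelaxationConstants | None = None,
    metabolite_attenuation: float = 1.0,
) -> float:
    """Inverse of :func:`correct_concentration` (used by the synthetic generator)."""
    unit = correct_concentration(1.0, fractions, constants, metabolite_attenuation)
    return concentration / unit


def correct_panel(
    panel: pd.DataFrame,
    constants: RelaxationConstants | None = None,
    metabolite_attenuation: float = 1.0,
    *,
    min_snr: float = QC_MIN_SNR,
    max_linewidth_hz: float = QC_MAX_LINEWIDTH_HZ,
) -> pd.DataFrame:
    """QC-gate and correct a long-format metabolite panel.

    Expects columns ``subject_id, group, region, metabolite, level, snr,
    linewidth_hz, f_gm, f_wm, f_csf`` (``level`` = water-referenced signal
    ratio).  Returns the panel with ``qc_pass``, ``qc_reason`` and
    ``corrected_concentration`` columns appended; the concentration is NaN
    wherever QC failed.
    """
    if constants is None:
        constants = RelaxationConstants()
    out = apply_qc(panel, min_snr=min_snr, max_linewidth_hz=max_linewidth_hz)
    conc = np.full(len(out), np.nan)
    for i, row in enumerate(out.itertuples()):
        if not row.qc_pass:
            continue
        fr = TissueFractions(row.f_gm, row.f_wm, row.f_csf)
        conc[i] = correct_concentration(
            row.level, fr, constants, metabolite_attenuation
        )
    out["corrected_concentration"] = conc
    return out


def compute_ratio(
    corrected_panel: pd.DataFrame,
    region: str,
    numerator: str = "NAA",
    denominator: str = "mIns",
) -> pd.Series:
    """Per-subject ratio of corrected concentrations within one region.

    The ratio is missing (NaN, with a warning) for a subject whenever either
    input failed QC or the denominator is non-positive.
    """
    sub = corrected_panel[corrected_panel["region"] == region]
    num = sub[sub["metabolite"] == numerator].set_index("subject_id")[
        "corrected_concentration"
    ]
    den = sub[sub["metabolite"] == denominator].set_index("subject_id")[
        "corrected_concentration"
    ]
    num, den = num.align(den, join="outer")
    bad_den = den.notna() & (den <= 0.0)
    if bad_den.any():
        warnings.warn(
            f"{int(bad_den.sum())} non-positive {denominator} concentrations in "
            f"{region}; ratio set to missing",
            stacklevel=2,
        )
        den = den.mask(bad_den)
    ratio = num / den
    ratio.name = f"{numerator}/{denominator}"
    return ratio


def ratio_table(
    corrected_panel: pd.DataFrame,
    numerator: str = "NAA",
    denominator: str = "mIns",
) -> pd.DataFrame:
    """Long table of per-subject per-region concentration ratios.

    Mirrors the corrected-panel layout with ``metabolite`` set to
    ``"<numerator>/<denominator>"`` so ratios can be screened alongside
    single metabolites.
    """
    frames = []
    groups = corrected_panel.drop_duplicates("subject_id").set_index("subject_id")[
        "group"
    ]
    for region in corrected_panel["region"].unique():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ratio = compute_ratio(corrected_panel, region, numerator, denominator)
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": ratio.index,
                    "group": groups.reindex(ratio.index).to_numpy(),
                    "region": region,
                    "metabolite": f"{numerator}/{denominator}",
                    "corrected_concentration": ratio.to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
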