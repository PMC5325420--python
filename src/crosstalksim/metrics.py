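"""Scalar indices of drug effect: relative drug efficacy and Bliss synergy.

Relative drug efficacy (RDE) compares the drug-induced fractional
reduction of integrated output in a module against the same quantity in
the crosstalk-free baseline module 0:

    RDE = (1 - IO_drug / IO_no_drug)  -  (1 - IO_drug(0) / IO_no_drug(0))

RDE > 0 means the module responds more strongly to the drug than the
baseline; RDE < 0 marks crosstalk-mediated resistance.

Synergy of a drug pair is scored by the Bliss combination index.  With
R_k the positive fractional reduction of integrated output under drug k
alone and R_12 under the combination,

    CI = R_12 - (R_1 + R_2 - R_1 * R_2)

so CI = 0 exactly when the remaining output under the combination is the
product of the single-drug remaining fractions (Bliss independence),
CI > 0 indicates synergy and CI < 0 antagonism.  A tolerance band
(default 0.05) absorbs small perturbations before labeling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

__all__ = [
    "EfficacyRecord",
    "SynergyRecord",
    "relative_drug_efficacy",
    "bliss_combination_index",
    "classify_synergy",
    "compare_combo_to_single",
    "SYNERGY_TOL",
    "TIE_TOL",
]

SYNERGY_TOL = 0.05   # +-5% band: additivity unless |CI| clears it
TIE_TOL = 1e-9       # |difference| below this counts as a tie


@dataclass(frozen=True)
class EfficacyRecord:
    """RDE of one (module, regimen) cell with its four IO inputs."""

    module_id: Union[int, str]
    regimen: str
    io_no_drug: float
    io_drug: float
    io_base_no_drug: float
    io_base_drug: float
    rde: float


@dataclass(frozen=True)
class SynergyRecord:
    """Bliss scoring of one drug pair in one module."""

    module_id: Union[int, str]
    drug1: str
    drug2: str
    r1: float
    r2: float
    r12: float
    ci: float
    label: str


def relative_drug_efficacy(
    io_module: tuple[float, float],
    io_base: tuple[float, float],
) -> float:
    """Relative drug efficacy of a module versus the baseline module.

    Parameters
    ----------
    io_module : (float, float)
        (untreated IO, treated IO) of the module under study.
    io_base : (float, float)
        (untreated IO, treated IO) of the baseline module 0 under the
        same regimen and stimulus.

    Returns
    -------
    float
        Positive when the module's relative reduction exceeds the
        baseline's, negative when the module resists the drug.
    """
    no_drug_m, drug_m = io_module
    no_drug_0, drug_0 = io_base
    if no_drug_m <= 0 or no_drug_0 <= 0:
        raise ValueError(
            "untreated integrated output must be positive; the index is "
            "undefined for a silent module"
        )
    return (1.0 - drug_m / no_drug_m) - (1.0 - drug_0 / no_drug_0)


def bliss_combination_index(
    io_no_drug: float,
    io_d1: float,
    io_d2: float,
    io_d12: float,
    signed_r: bool = False,
) -> tuple[float, float, float, float]:
    """Fractional reductions and Bliss combination index of a drug pair.

    Parameters
    ----------
    io_no_drug, io_d1, io_d2, io_d12 : float
        Integrated output untreated, under each single drug, and under
        the combination, all in the same module.
    signed_r : bool
        If True use the signed ratio (IO_treated - IO_untreated)/IO_untreated
        instead of the positive fractional reduction.  The signed form
        mislabels Bliss-independent pairs (two independent half-effective
        drugs score CI = +0.5) and is provided for comparison only.

    Returns
    -------
    (r1, r2, r12, ci)
    """
    if io_no_drug <= 0:
        raise ValueError("untreated integrated output must be positive")
    sign = -1.0 if signed_r else 1.0
    r1 = sign * (io_no_drug - io_d1) / io_no_drug
    r2 = sign * (io_no_drug - io_d2) / io_no_drug
    r12 = sign * (io_no_drug - io_d12) / io_no_drug
    ci = r12 - (r1 + r2 - r1 * r2)
    return r1, r2, r12, ci


def classify_synergy(ci: float, tol: float = SYNERGY_TOL) -> str:
    """Label a combination index: synergy / additivity / antagonism.

    CI > tol is synergy, CI < -tol antagonism, anything inside the band
    additivity.  With tol = 0 this reduces to the pure sign rule.
    """
    if tol < 0:
        raise ValueError("tol must be nonnegative")
    if ci > tol:
        return "synergy"
    if ci < -tol:
        return "antagonism"
    return "additivity"


def compare_combo_to_single(
    rde_combo: float, rde_single: float, tie_tol: float = TIE_TOL
) -> str:
    """Direction of the combination's RDE relative to the single drug.

    Returns "increase" when the combination improves on the single-drug
    relative efficacy, "decrease" when it falls short, "tie" within
    machine tolerance.
    """
    delta = rde_combo - rde_single
    if abs(delta) < tie_tol:
        return "tie"
    return "increase" if delta > 0 else "decrease"
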