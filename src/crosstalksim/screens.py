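"""The in-silico screens: single-drug efficacy, drug combinations,
crosstalk-strength scans and stimulus-shape scans.

Every screen simulates the required treatment arms with the RK4
integrator, reduces each arm to its integrated output, and tabulates
relative drug efficacy (RDE) and, for combinations, the Bliss
combination index (CI) in a long-form table — one record per
(module, regimen, crosstalk scale, stimulus) cell.  Module 0 is always
simulated because it is the baseline of the RDE definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dynamics import integrated_output, simulate
from .metrics import (
    bliss_combination_index,
    classify_synergy,
    compare_combo_to_single,
    relative_drug_efficacy,
)
from .model_core import (
    DrugRegimen,
    KineticParameters,
    MODULE_IDS,
    Species,
    build_module,
    stimulus_library,
)

__all__ = [
    "ScreenConfig",
    "ScreenResult",
    "RESULT_COLUMNS",
    "single_drug_screen",
    "combination_screen",
    "strength_scan",
    "stimulus_scan",
    "switching_summary",
    "resistance_summary",
]

RESULT_COLUMNS = (
    "module_id", "regimen", "partner", "crosstalk_scale", "stimulus",
    "rde", "ci", "label", "direction",
)

DEFAULT_SCALE_GRID = tuple(np.geomspace(1.0, 10.0, 8))


@dataclass(frozen=True)
class ScreenConfig:
    """Shared configuration of all screens.

    Defaults follow the standard protocol: B-targeting anchor drug at
    dose 1.0 applied from t = 0, basic S0 pulse stimulus, horizon T = 100
    with RK4 step h = 0.01, and a geometric 1 -> 10 crosstalk-scale grid.
    """

    modules: tuple[int, ...] = MODULE_IDS
    anchor_target: Species = Species.B
    partner_targets: tuple[Species, ...] = (
        Species.A, Species.B, Species.C, Species.D,
    )
    dose: float = 1.0
    partner_dose: float | None = None  # None -> same as dose; 0 = inert partner
    stimulus: str = "S0"
    T: float = 100.0
    h: float = 0.01
    scale_grid: tuple[float, ...] = DEFAULT_SCALE_GRID
    tol: float = 0.05
    inhibition: str = "deactivation"
    params: KineticParameters = field(default_factory=KineticParameters)

    def __post_init__(self) -> None:
        mods = tuple(sorted({int(m) for m in self.modules}))
        for m in mods:
            if m not in MODULE_IDS:
                raise ValueError(f"unknown module id {m}; expected 0-8")
        object.__setattr__(self, "modules", mods)
        object.__setattr__(self, "anchor_target",
                           Species.parse(self.anchor_target))
        object.__setattr__(
            self, "partner_targets",
            tuple(Species.parse(t) for t in self.partner_targets),
        )
        if self.dose <= 0:
            raise ValueError("dose must be positive")
        if self.partner_dose is not None and self.partner_dose < 0:
            raise ValueError("partner_dose must be nonnegative")
        if self.T <= 0 or self.h <= 0:
            raise ValueError("T and h must be positive")
        grid = tuple(float(s) for s in self.scale_grid)
        if not grid or any(s <= 0 for s in grid):
            raise ValueError("scale_grid must be nonempty and strictly positive")
        object.__setattr__(self, "scale_grid", grid)
        if self.tol < 0:
            raise ValueError("tol must be nonnegative")
        if self.stimulus not in stimulus_library():
            raise ValueError(
                f"unknown stimulus {self.stimulus!r}; "
                f"known: {sorted(stimulus_library())}"
            )

    @property
    def modules_with_baseline(self) -> tuple[int, ...]:
        return tuple(sorted(set(self.modules) | {0}))

    def to_dict(self) -> dict:
        return {
            "modules": list(self.modules),
            "anchor_target": self.anchor_target.name,
            "partner_targets": [t.name for t in self.partner_targets],
            "dose": self.dose,
            "partner_dose": self.partner_dose,
            "stimulus": self.stimulus,
            "T": self.T,
            "h": self.h,
            "scale_grid": list(self.scale_grid),
            "tol": self.tol,
            "inhibition": self.inhibition,
            "params": self.params.to_dict(),
        }


@dataclass(frozen=True)
class ScreenResult:
    """Long-form screen output plus provenance metadata."""

    kind: str
    records: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(RESULT_COLUMNS) - set(self.records.columns)
        if missing:
            raise ValueError(f"records missing columns {sorted(missing)}")
        keys = self.records[
            ["module_id", "regimen", "crosstalk_scale", "stimulus"]
        ]
        if keys.duplicated().any():
            raise ValueError("duplicate (module, regimen, scale, stimulus) cells")


class _ArmCache:
    """Memoizes integrated outputs of simulation arms within one screen."""

    def __init__(self, cfg: ScreenConfig):
        self.cfg = cfg
        self._io: dict[tuple, float] = {}

    def io(self, module_id: int, scale: float, regimen: DrugRegimen,
           stim_pair, stim_label: str) -> float:
        key = (module_id, scale, regimen.label, stim_label)
        if key not in self._io:
            topology = build_module(module_id, scale, self.cfg.params)
            try:
                traj = simulate(
                    topology, self.cfg.params, stim_pair, regimen,
                    T=self.cfg.T, h=self.cfg.h,
                    inhibition=self.cfg.inhibition,
                )
            except Exception as exc:
                raise RuntimeError(
                    f"simulation failed for module {module_id} at scale "
                    f"{scale:g}, regimen {regimen.label}, stimulus "
                    f"{stim_label}: {exc}"
                ) from exc
            self._io[key] = integrated_output(traj, self.cfg.T)
        return self._io[key]


def _finalize(kind: str, rows: list[dict], cfg: ScreenConfig,
              extra_meta: dict | None = None) -> ScreenResult:
    records = pd.DataFrame(rows, columns=list(RESULT_COLUMNS))
    metadata = {"kind": kind, "config": cfg.to_dict()}
    if extra_meta:
        metadata.update(extra_meta)
    return ScreenResult(kind=kind, records=records, metadata=metadata)


def _single_rows(cfg: ScreenConfig, cache: _ArmCache, scale: float,
                 stim_pair, stim_label: str) -> list[dict]:
    anchor = DrugRegimen.single(cfg.anchor_target, cfg.dose)
    io0 = cache.io(0, scale, DrugRegimen.untreated(), stim_pair, stim_label)
    io0_drug = cache.io(0, scale, anchor, stim_pair, stim_label)
    rows = []
    for m in cfg.modules_with_baseline:
        io_m = cache.io(m, scale, DrugRegimen.untreated(), stim_pair, stim_label)
        io_m_drug = cache.io(m, scale, anchor, stim_pair, stim_label)
        rde = relative_drug_efficacy((io_m, io_m_drug), (io0, io0_drug))
        rows.append({
            "module_id": m, "regimen": anchor.label, "partner": "",
            "crosstalk_scale": scale, "stimulus": stim_label,
            "rde": rde, "ci": np.nan, "label": "", "direction": "",
        })
    return rows


def single_drug_screen(cfg: ScreenConfig | None = None) -> ScreenResult:
    """RDE of the anchor drug (default: B-targeting, dose 1) per module.

    Simulates each requested module untreated and treated, computes the
    integrated output over [0, T], and scores RDE against module 0.
    """
    cfg = cfg or ScreenConfig()
    cache = _ArmCache(cfg)
    stim_pair = stimulus_library()[cfg.stimulus]
    rows = _single_rows(cfg, cache, 1.0, stim_pair, cfg.stimulus)
    return _finalize("single_drug", rows, cfg)


def combination_screen(cfg: ScreenConfig | None = None) -> ScreenResult:
    """Pairwise screen of the anchor drug combined with each partner.

    For every module and partner target, four arms are simulated
    (untreated, anchor alone, partner alone, anchor+partner).  Each cell
    reports the combination RDE (scored against module 0 under the same
    combination), the Bliss CI with its synergy label, and whether the
    combination increased or decreased the RDE relative to the anchor
    drug alone.
    """
    cfg = cfg or ScreenConfig()
    cache = _ArmCache(cfg)
    stim_pair = stimulus_library()[cfg.stimulus]
    stim = cfg.stimulus
    untreated = DrugRegimen.untreated()
    anchor = DrugRegimen.single(cfg.anchor_target, cfg.dose)

    # single-anchor RDE per module, the reference for increase/decrease
    io0 = cache.io(0, 1.0, untreated, stim_pair, stim)
    io0_anchor = cache.io(0, 1.0, anchor, stim_pair, stim)
    rde_single = {
        m: relative_drug_efficacy(
            (cache.io(m, 1.0, untreated, stim_pair, stim),
             cache.io(m, 1.0, anchor, stim_pair, stim)),
            (io0, io0_anchor),
        )
        for m in cfg.modules_with_baseline
    }

    partner_dose = cfg.dose if cfg.partner_dose is None else cfg.partner_dose
    rows = []
    for partner in cfg.partner_targets:
        partner_reg = DrugRegimen.single(partner, partner_dose)
        combo = DrugRegimen(
            (*DrugRegimen.single(cfg.anchor_target, cfg.dose).entries,
             *partner_reg.entries)
        )
        io0_combo = cache.io(0, 1.0, combo, stim_pair, stim)
        for m in cfg.modules_with_baseline:
            io_m = cache.io(m, 1.0, untreated, stim_pair, stim)
            io_m_anchor = cache.io(m, 1.0, anchor, stim_pair, stim)
            io_m_partner = cache.io(m, 1.0, partner_reg, stim_pair, stim)
            io_m_combo = cache.io(m, 1.0, combo, stim_pair, stim)
            rde = relative_drug_efficacy((io_m, io_m_combo), (io0, io0_combo))
            _, _, _, ci = bliss_combination_index(
                io_m, io_m_anchor, io_m_partner, io_m_combo
            )
            rows.append({
                "module_id": m, "regimen": combo.label,
                "partner": partner.name, "crosstalk_scale": 1.0,
                "stimulus": stim, "rde": rde, "ci": ci,
                "label": classify_synergy(ci, cfg.tol),
                "direction": compare_combo_to_single(rde, rde_single[m]),
            })
    return _finalize(
        "combination", rows, cfg,
        {"rde_single_anchor": {str(k): v for k, v in rde_single.items()}},
    )


def strength_scan(cfg: ScreenConfig | None = None) -> ScreenResult:
    """Single-drug screen repeated over the crosstalk-scale grid.

    Detects switching between drug-sensitive (RDE > 0) and drug-resistant
    (RDE < 0) behavior as crosstalk strengthens; the per-module summary
    is stored in the result metadata (see ``switching_summary``).
    """
    cfg = cfg or ScreenConfig()
    cache = _ArmCache(cfg)
    stim_pair = stimulus_library()[cfg.stimulus]
    rows = []
    for scale in cfg.scale_grid:
        rows.extend(_single_rows(cfg, cache, scale, stim_pair, cfg.stimulus))
    result = _finalize("strength_scan", rows, cfg)
    summary = switching_summary(result)
    result.metadata["switching"] = summary.to_dict(orient="records")
    return result


def switching_summary(result: ScreenResult) -> pd.DataFrame:
    """Per-module endpoints and sign behavior of RDE along the scale grid.

    Behaviors: "resistant_to_sensitive" (sign - -> +),
    "sensitive_to_resistant" (+ -> -), otherwise "monotone_negative" /
    "monotone_positive" by the direction of change, or "flat".
    """
    out = []
    for m, grp in result.records.groupby("module_id"):
        grp = grp.sort_values("crosstalk_scale")
        first, last = grp["rde"].iloc[0], grp["rde"].iloc[-1]
        if first < 0 and last > 0:
            behavior = "resistant_to_sensitive"
        elif first > 0 and last < 0:
            behavior = "sensitive_to_resistant"
        elif abs(last - first) < 1e-12:
            behavior = "flat"
        elif last < first:
            behavior = "monotone_negative"
        else:
            behavior = "monotone_positive"
        out.append({
            "module_id": m,
            "rde_at_min_scale": first,
            "rde_at_max_scale": last,
            "behavior": behavior,
        })
    return pd.DataFrame(out)


def _stimulus_conditions(names: Sequence[str]) -> list[tuple[str, str]]:
    """Expand stimulus names into (label, variant, channel) conditions."""
    library = stimulus_library()
    conditions = []
    for name in names:
        if name not in library:
            raise ValueError(
                f"unknown stimulus {name!r}; known: {sorted(library)}"
            )
        if name == "S0":
            conditions.append((name, "both"))
        else:
            conditions.extend(
                [(name, "G1"), (name, "G2"), (name, "both")]
            )
    return conditions


def stimulus_scan(
    cfg: ScreenConfig | None = None,
    stimulus_names: Sequence[str] | None = None,
) -> ScreenResult:
    """Single-drug screen repeated across stimulus shapes.

    Each variant is applied to G1 alone (G2 keeps the basic S0 pulse),
    to G2 alone, and to both channels.  The metadata flags the modules
    whose RDE is negative under a majority of the conditions as prone to
    resisting the anchor drug (see ``resistance_summary``).
    """
    cfg = cfg or ScreenConfig()
    if stimulus_names is None:
        stimulus_names = list(stimulus_library())
    if not stimulus_names:
        raise ValueError("stimulus_names must be a nonempty list")
    library = stimulus_library()
    base_g1, base_g2 = library["S0"]
    cache = _ArmCache(cfg)
    rows = []
    for name, channel in _stimulus_conditions(stimulus_names):
        var_g1, var_g2 = library[name]
        if channel == "G1":
            pair, label = (var_g1, base_g2), f"{name}@G1"
        elif channel == "G2":
            pair, label = (base_g1, var_g2), f"{name}@G2"
        else:
            pair = (var_g1, var_g2)
            label = name if name == "S0" else f"{name}@both"
        rows.extend(_single_rows(cfg, cache, 1.0, pair, label))
    result = _finalize("stimulus_scan", rows, cfg)
    result.metadata["majority_resistant"] = resistance_summary(result)
    return result


def resistance_summary(result: ScreenResult) -> list[int]:
    """Modules with RDE < 0 in more than half of the stimulus conditions."""
    flagged = []
    for m, grp in result.records.groupby("module_id"):
        if (grp["rde"] < 0).sum() > len(grp) / 2:
            flagged.append(int(m))
    return sorted(flagged)
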