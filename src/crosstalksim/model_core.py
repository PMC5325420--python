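"""Domain types for the two-pathway crosstalk signaling model.

The model describes two parallel three-node signaling cascades driven by
growth factors G1 and G2::

    G1 -> A -> B \
                  O        (backbone: A->B, B->O, C->D, D->O)
    G2 -> C -> D /

A and C stand for upstream receptors/proteins, B and D for downstream
effectors or transcription factors, and O is the unique signaling output.
Nine registered module topologies (0-8) differ only in which crosstalk
edges link the two cascades; module 0 has none and serves as the
crosstalk-free baseline in every efficacy comparison.

All concentrations are dimensionless activation fractions in [0, 1] and
time is dimensionless.
"""

from __future__ import annotations

import enum
import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence, Union

import numpy as np

__all__ = [
    "Species",
    "BACKBONE_EDGES",
    "MODULE_IDS",
    "KineticParameters",
    "ModuleTopology",
    "StimulusProfile",
    "DrugDose",
    "DrugRegimen",
    "build_module",
    "default_parameters",
    "stimulus_library",
    "validate_topology",
]

N_SPECIES = 5


class Species(enum.IntEnum):
    """The five model species; O is the unique signaling output."""

    A = 1
    B = 2
    C = 3
    D = 4
    O = 5

    @property
    def idx(self) -> int:
        """Zero-based array index."""
        return int(self) - 1

    @classmethod
    def parse(cls, value: Union["Species", int, str]) -> "Species":
        """Coerce a species given as enum member, 1-based index or letter."""
        if isinstance(value, cls):
            return value
        if isinstance(value, str):
            try:
                return cls[value.strip().upper()]
            except KeyError:
                raise ValueError(
                    f"unknown species {value!r}; expected one of A, B, C, D, O"
                ) from None
        if isinstance(value, (int, np.integer)):
            try:
                return cls(int(value))
            except ValueError:
                raise ValueError(
                    f"species index {value} out of range 1-5 (A, B, C, D, O)"
                ) from None
        raise TypeError(f"cannot interpret {value!r} as a species")


#: Within-pathway activations shared by every module.
BACKBONE_EDGES: tuple[tuple[Species, Species], ...] = (
    (Species.A, Species.B),
    (Species.B, Species.O),
    (Species.C, Species.D),
    (Species.D, Species.O),
)

# Crosstalk edges per registered module as (source, target, weight) where a
# positive weight w means activation at w * V_act and a negative weight w
# means inhibition at |w| * V_inh.  Module 6's mutual inhibition is
# asymmetric: D -| A at full strength, B -| C at half strength.
_MODULE_CROSSTALK: dict[int, tuple[tuple[Species, Species, float], ...]] = {
    0: (),
    1: ((Species.A, Species.D, +1.0),),
    2: ((Species.A, Species.D, -1.0),),
    3: ((Species.B, Species.C, +1.0),),
    4: ((Species.B, Species.C, -1.0),),
    5: ((Species.B, Species.C, +1.0), (Species.D, Species.A, +1.0)),
    6: ((Species.B, Species.C, -0.5), (Species.D, Species.A, -1.0)),
    7: ((Species.B, Species.C, -1.0), (Species.D, Species.A, +1.0)),
    8: ((Species.B, Species.C, +1.0), (Species.D, Species.A, -1.0)),
}

MODULE_IDS: tuple[int, ...] = tuple(sorted(_MODULE_CROSSTALK))


@dataclass(frozen=True)
class KineticParameters:
    """Standard kinetic constants of the model.

    Attributes
    ----------
    d : float
        First-order degradation/deactivation rate of every species.
    V_A, K_A : float
        Maximal rate and Michaelis constant of the G1 -> A input.
    V_C, K_C : float
        Maximal rate and Michaelis constant of the G2 -> C input.
    K_D : float
        Drug Michaelis constant; a dose D on species i inflates that
        species' Michaelis constants by the factor 1 + D / K_D.
    V_act, V_inh : float
        Default maximal rates of activating (+0.4) and inhibiting (-1)
        edges.
    K_default : float
        Michaelis constant of every edge (0.8).
    """

    d: float = 0.2
    V_A: float = 0.2
    K_A: float = 0.5
    V_C: float = 0.2
    K_C: float = 0.5
    K_D: float = 0.1
    V_act: float = 0.4
    V_inh: float = -1.0
    K_default: float = 0.8

    def __post_init__(self) -> None:
        for name in ("d", "V_A", "K_A", "V_C", "K_C", "K_D", "K_default"):
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name} must be strictly positive")
        if self.V_act <= 0 or self.V_inh >= 0:
            raise ValueError("V_act must be positive and V_inh negative")

    @property
    def d_vector(self) -> np.ndarray:
        return np.full(N_SPECIES, self.d)

    def to_dict(self) -> dict:
        return {
            "d": self.d, "V_A": self.V_A, "K_A": self.K_A,
            "V_C": self.V_C, "K_C": self.K_C, "K_D": self.K_D,
            "V_act": self.V_act, "V_inh": self.V_inh,
            "K_default": self.K_default,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "KineticParameters":
        return cls(**dict(data))

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def default_parameters() -> KineticParameters:
    """Return the standard parameter set (d=0.2, V=±0.4/−1, K=0.8, ...)."""
    return KineticParameters()


@dataclass(frozen=True)
class ModuleTopology:
    """Interaction matrices of one module.

    ``V[j, i]`` is the maximal rate of the edge from species j to species i
    (zero-based indices; positive = activation, negative = inhibition) and
    ``K[j, i]`` the matching Michaelis constant.  ``crosstalk_edges`` marks
    which nonzero entries are crosstalk links rather than backbone links;
    ``crosstalk_scale`` is the magnitude multiplier that was applied to
    them when the topology was built.
    """

    module_id: Union[int, str]
    V: np.ndarray
    K: np.ndarray
    crosstalk_edges: frozenset[tuple[Species, Species]] = frozenset()
    crosstalk_scale: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "V", np.asarray(self.V, dtype=float))
        object.__setattr__(self, "K", np.asarray(self.K, dtype=float))
        if self.V.shape != (N_SPECIES, N_SPECIES):
            raise ValueError(f"V must be 5x5, got {self.V.shape}")
        if self.K.shape != (N_SPECIES, N_SPECIES):
            raise ValueError(f"K must be 5x5, got {self.K.shape}")
        if self.crosstalk_scale <= 0:
            raise ValueError("crosstalk_scale must be strictly positive")
        object.__setattr__(
            self,
            "crosstalk_edges",
            frozenset((Species.parse(j), Species.parse(i))
                      for j, i in self.crosstalk_edges),
        )

    def edge(self, source, target) -> float:
        """Rate V of the edge source -> target (0 if absent)."""
        return float(self.V[Species.parse(source).idx,
                            Species.parse(target).idx])

    def to_dict(self) -> dict:
        return {
            "module_id": self.module_id,
            "V": self.V.tolist(),
            "K": self.K.tolist(),
            "crosstalk_edges": sorted(
                [s.name, t.name] for s, t in self.crosstalk_edges
            ),
            "crosstalk_scale": self.crosstalk_scale,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "ModuleTopology":
        return cls(
            module_id=data["module_id"],
            V=np.asarray(data["V"], dtype=float),
            K=np.asarray(data["K"], dtype=float),
            crosstalk_edges=frozenset(
                (Species.parse(j), Species.parse(i))
                for j, i in data.get("crosstalk_edges", ())
            ),
            crosstalk_scale=float(data.get("crosstalk_scale", 1.0)),
        )


def build_module(
    module_id: int,
    crosstalk_scale: float = 1.0,
    params: KineticParameters | None = None,
) -> ModuleTopology:
    """Assemble the topology of one registered module.

    Every module carries the four backbone activations (V = +0.4,
    K = 0.8).  Crosstalk edges get V = crosstalk_scale * (+0.4) when
    activating and crosstalk_scale * (-1) when inhibiting; the scale
    multiplies crosstalk magnitudes only, so the backbone is unchanged
    and scale -> 0 degenerates every module to module 0.

    Parameters
    ----------
    module_id : int
        Registered module, 0-8.
    crosstalk_scale : float
        Positive multiplier on crosstalk-edge magnitudes (1 = the normal
        strength; 10 probes the strong-crosstalk regime).
    params : KineticParameters, optional
        Source of V_act, V_inh and K_default; standard values if omitted.
    """
    if module_id not in _MODULE_CROSSTALK:
        raise ValueError(
            f"unknown module_id {module_id!r}; expected an integer in 0-8"
        )
    if crosstalk_scale <= 0:
        raise ValueError("crosstalk_scale must be strictly positive")
    p = params or default_parameters()

    V = np.zeros((N_SPECIES, N_SPECIES))
    K = np.zeros((N_SPECIES, N_SPECIES))
    for src, dst in BACKBONE_EDGES:
        V[src.idx, dst.idx] = p.V_act
        K[src.idx, dst.idx] = p.K_default

    edges = set()
    for src, dst, weight in _MODULE_CROSSTALK[module_id]:
        base = p.V_act if weight > 0 else p.V_inh
        V[src.idx, dst.idx] = crosstalk_scale * abs(weight) * base
        K[src.idx, dst.idx] = p.K_default
        edges.add((src, dst))

    return ModuleTopology(
        module_id=module_id, V=V, K=K,
        crosstalk_edges=frozenset(edges), crosstalk_scale=crosstalk_scale,
    )


def validate_topology(topology: ModuleTopology) -> list[str]:
    """Check topology invariants; returns a list of violation messages.

    An empty list means the topology is valid.  Checked: the four backbone
    activations are present at V = +0.4; every nonzero V entry has a
    strictly positive Michaelis constant; module 0 carries no crosstalk
    edges; crosstalk annotations point at nonzero, non-backbone entries;
    for registered module ids the crosstalk-edge signs match the registry.
    """
    violations: list[str] = []
    p = default_parameters()
    for src, dst in BACKBONE_EDGES:
        v = topology.V[src.idx, dst.idx]
        if not np.isclose(v, p.V_act):
            violations.append(
                f"backbone edge {src.name}->{dst.name} must have "
                f"V={p.V_act}, found {v}"
            )
    nz = np.argwhere(topology.V != 0)
    for j, i in nz:
        if topology.K[j, i] <= 0:
            violations.append(
                f"K[{Species(j + 1).name},{Species(i + 1).name}] must be "
                f"> 0 where V is nonzero, found {topology.K[j, i]}"
            )
    backbone = {(s.idx, t.idx) for s, t in BACKBONE_EDGES}
    for src, dst in topology.crosstalk_edges:
        if (src.idx, dst.idx) in backbone:
            violations.append(
                f"crosstalk annotation {src.name}->{dst.name} marks a "
                "backbone edge"
            )
        elif topology.V[src.idx, dst.idx] == 0:
            violations.append(
                f"crosstalk edge {src.name}->{dst.name} has V=0"
            )
    if topology.module_id == 0 and topology.crosstalk_edges:
        violations.append("module 0 must have no crosstalk edges")
    if isinstance(topology.module_id, int) and topology.module_id in MODULE_IDS:
        expected = {
            (s, t): (1.0 if w > 0 else -1.0)
            for s, t, w in _MODULE_CROSSTALK[topology.module_id]
        }
        if topology.crosstalk_edges != set(expected):
            violations.append(
                f"module {topology.module_id} crosstalk edges "
                f"{sorted((s.name, t.name) for s, t in topology.crosstalk_edges)} "
                f"differ from the registry"
            )
        else:
            for (src, dst), sign in expected.items():
                v = topology.V[src.idx, dst.idx]
                if np.sign(v) != sign:
                    violations.append(
                        f"crosstalk edge {src.name}->{dst.name} has sign "
                        f"{np.sign(v):+.0f}, registry requires {sign:+.0f}"
                    )
    return violations


@dataclass(frozen=True)
class StimulusProfile:
    """Piecewise-constant time course of one growth factor.

    ``segments`` is an ordered list of (t_start, t_end, amplitude);
    evaluation returns the amplitude of the covering segment and 0
    outside every segment.
    """

    name: str
    channel: str  # "G1" or "G2"
    segments: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        if self.channel not in ("G1", "G2"):
            raise ValueError(f"channel must be 'G1' or 'G2', got {self.channel!r}")
        segs = tuple(
            (float(a), float(b), float(amp)) for a, b, amp in self.segments
        )
        prev_end = -np.inf
        for t0, t1, amp in sorted(segs):
            if t0 >= t1:
                raise ValueError(f"segment ({t0}, {t1}) has nonpositive length")
            if t0 < 0:
                raise ValueError("segments must start at t >= 0")
            if amp < 0:
                raise ValueError("amplitude must be nonnegative")
            if t0 < prev_end:
                raise ValueError(f"segments overlap at t={t0}")
            prev_end = t1
        object.__setattr__(self, "segments", segs)

    def __call__(self, t: float) -> float:
        for t0, t1, amp in self.segments:
            if t0 <= t < t1:
                return amp
        return 0.0

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "channel": self.channel,
            "segments": [list(s) for s in self.segments],
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "StimulusProfile":
        return cls(
            name=data["name"], channel=data["channel"],
            segments=tuple(tuple(s) for s in data["segments"]),
        )

    @classmethod
    def pulse(cls, name: str, channel: str, t_on: float = 0.0,
              t_off: float = 30.0, amplitude: float = 1.0) -> "StimulusProfile":
        return cls(name, channel, ((t_on, t_off, amplitude),))


def _variant_segments(kind: str) -> tuple[tuple[float, float, float], ...]:
    if kind == "S0":          # basic pulse
        return ((0.0, 30.0, 1.0),)
    if kind == "S1":          # sustained step over the whole horizon
        return ((0.0, 100.0, 1.0),)
    if kind == "S2":          # short pulse
        return ((0.0, 10.0, 1.0),)
    if kind == "S3":          # double pulse
        return ((0.0, 15.0, 1.0), (40.0, 55.0, 1.0))
    if kind == "S4":          # rising staircase ramp
        return tuple((5.0 * k, 5.0 * (k + 1), (k + 1) / 6.0) for k in range(6))
    if kind == "S5":          # half-amplitude pulse
        return ((0.0, 30.0, 0.5),)
    if kind == "S6":          # delayed pulse
        return ((20.0, 50.0, 1.0),)
    raise KeyError(kind)


STIMULUS_NAMES: tuple[str, ...] = ("S0", "S1", "S2", "S3", "S4", "S5", "S6")


def stimulus_library() -> dict[str, tuple[StimulusProfile, StimulusProfile]]:
    """Named stimulus pairs (G1 profile, G2 profile).

    S0 is the basic unit pulse on t in [0, 30) applied to both channels;
    S1-S6 are shape variants (sustained step, short pulse, double pulse,
    staircase ramp, half amplitude, delayed pulse) used to probe the
    robustness of the resistance classification to the input shape.
    """
    return {
        name: (
            StimulusProfile(name, "G1", _variant_segments(name)),
            StimulusProfile(name, "G2", _variant_segments(name)),
        )
        for name in STIMULUS_NAMES
    }


@dataclass(frozen=True)
class DrugDose:
    """One drug: a competitive inhibitor of its target's activation."""

    target: Species
    dose: float = 1.0
    t_on: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "target", Species.parse(self.target))
        if self.dose < 0:
            raise ValueError(f"dose must be nonnegative, got {self.dose}")
        if self.t_on < 0:
            raise ValueError(f"t_on must be nonnegative, got {self.t_on}")


@dataclass(frozen=True)
class DrugRegimen:
    """A set of drug doses; the empty regimen is the untreated control.

    Two entries may share a target (doses add inside the drug factor),
    which is how "B combined with B" double-dosing is expressed.
    """

    entries: tuple[DrugDose, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))

    @classmethod
    def untreated(cls) -> "DrugRegimen":
        return cls(())

    @classmethod
    def single(cls, target, dose: float = 1.0, t_on: float = 0.0) -> "DrugRegimen":
        return cls((DrugDose(Species.parse(target), dose, t_on),))

    @classmethod
    def combo(cls, targets: Iterable, dose: float = 1.0,
              t_on: float = 0.0) -> "DrugRegimen":
        return cls(tuple(DrugDose(Species.parse(t), dose, t_on)
                         for t in targets))

    @property
    def label(self) -> str:
        if not self.entries:
            return "untreated"
        return "+".join(f"{e.target.name}({e.dose:g})" for e in self.entries)

    def to_dict(self) -> dict:
        return {
            "entries": [
                {"target": e.target.name, "dose": e.dose, "t_on": e.t_on}
                for e in self.entries
            ]
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "DrugRegimen":
        return cls(tuple(
            DrugDose(Species.parse(e["target"]), float(e.get("dose", 1.0)),
                     float(e.get("t_on", 0.0)))
            for e in data.get("entries", ())
        ))
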