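"""Parameter sets for the McdAB Brownian-ratchet model.

All tunables of the simulator live here, grouped the way the model is
built: domain geometry, McdA/McdB kinetics, the two elastic springs
(McdA-McdB bond and carboxysome self-association), run control, and the
classification thresholds used to call a trajectory clustered and/or
positioned.

Units follow the conventions stated on each field: lengths are µm for the
domain and nm for everything at particle scale, times in seconds, rates in
1/s, stiffnesses in pN/nm, energies in pN·nm.  The simulation core works
internally in nm / s / pN.
"""

from __future__ import annotations

import dataclasses
import math
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any


class ParamError(ValueError):
    """A parameter file or parameter set violates a model invariant."""


@dataclass
class Geometry:
    """Rectangular nucleoid domain and cargo size.

    nucleoid_length / nucleoid_width : µm — the 2D nucleoid surface on which
        McdA binds and carboxysomes move.  Long axis is x.
    lattice_spacing : nm — spacing of the square McdA binding-site lattice.
    carboxysome_diameter : nm — hard-core diameter of the cargo disks.
    """

    nucleoid_length: float = 2.0
    nucleoid_width: float = 0.5
    lattice_spacing: float = 25.0
    carboxysome_diameter: float = 150.0


@dataclass
class Kinetics:
    """Stochastic rates, diffusivities and copy numbers.

    k_off_intrinsic : 1/s — intrinsic (unstimulated) McdA release from the
        nucleoid; acts only on unbonded McdA.
    k_rebind : 1/s — cytoplasm→nucleoid rebinding per McdA; slow rebinding
        is what lets the moving cargo leave a depletion wake.
    k_bond_on : 1/s — McdA-McdB bond formation attempt rate once a free
        McdB site has a free McdA within capture_radius.
    k_bond_off : 1/s — spontaneous bond break rate; a break ejects the McdA
        to the cytoplasm immediately (stimulated release).
    D_mcdA_nucleoid : µm²/s — McdA surface diffusion (lattice hopping).
    D_carb : µm²/s — free carboxysome diffusivity; sets the drag
        γ = kBT / D_carb.
    n_mcdA : total McdA copies; n_mcdB_per_carb : McdB sites per cargo.
    capture_radius : nm — bond formation range.
    kBT : pN·nm — thermal energy.
    """

    k_off_intrinsic: float = 0.03
    k_rebind: float = 0.25
    k_bond_on: float = 50.0
    k_bond_off: float = 2.0
    D_mcdA_nucleoid: float = 0.008
    D_carb: float = 2.0e-3
    n_mcdA: int = 800
    n_mcdB_per_carb: int = 100
    capture_radius: float = 25.0
    kBT: float = 4.1


@dataclass
class Springs:
    """The two Hookean interactions of the model (pN/nm, nm).

    k_AB — McdA-McdB bond stiffness (zero rest length: pure tether).
    k_self — carboxysome self-association stiffness, engaged only while the
        center-center distance is at most self_range; rest length is
        contact (one diameter).
    max_extension_AB — hard guard: a bond stretched past this breaks
        unconditionally within the step.
    """

    k_AB: float = 0.8
    k_self: float = 0.6
    rest_length_AB: float = 0.0
    rest_length_self: float = 150.0
    self_range: float = 200.0
    max_extension_AB: float = 30.0


@dataclass
class RunSpec:
    """Run control: duration and dt in s, counts, base seed."""

    duration: float = 300.0
    dt: float = 5.0e-4
    n_carboxysomes: int = 2
    n_trajectories: int = 64
    seed: int = 0
    record_interval: float = 0.1


@dataclass
class ClassifyThresholds:
    """Regime-calling thresholds.

    clustered_time_fraction — a pair is "clustered" if its centers are
        within self_range for strictly more than this fraction of recorded
        samples (0.90 = the >90%-of-time rule).
    positioned_range_fraction — a trajectory is "positioned" if the
        movement range is strictly less than this fraction of the nucleoid
        length (0.25 rule).
    """

    clustered_time_fraction: float = 0.90
    positioned_range_fraction: float = 0.25


@dataclass
class SimParams:
    geometry: Geometry = field(default_factory=Geometry)
    kinetics: Kinetics = field(default_factory=Kinetics)
    springs: Springs = field(default_factory=Springs)
    run: RunSpec = field(default_factory=RunSpec)
    classify: ClassifyThresholds = field(default_factory=ClassifyThresholds)

    def copy(self) -> "SimParams":
        return SimParams(
            geometry=dataclasses.replace(self.geometry),
            kinetics=dataclasses.replace(self.kinetics),
            springs=dataclasses.replace(self.springs),
            run=dataclasses.replace(self.run),
            classify=dataclasses.replace(self.classify),
        )


_SECTIONS = ("geometry", "kinetics", "springs", "run", "classify")

_INT_KEYS = {
    ("kinetics", "n_mcdA"),
    ("kinetics", "n_mcdB_per_carb"),
    ("run", "n_carboxysomes"),
    ("run", "n_trajectories"),
    ("run", "seed"),
}


def default_params() -> SimParams:
    """The calibrated reference parameter set.

    Carries every printed model constant (150 nm disks, k_self = 0.6 pN/nm,
    300 s, 64 trajectories, 2 carboxysomes, 90% / 0.25·L thresholds) plus
    the calibrated microscopic constants documented in docs/methods.md.
    """
    p = SimParams()
    validate(p)
    return p


def _is_multiple(a: float, b: float, tol: float = 1e-9) -> bool:
    if b <= 0:
        return False
    r = a / b
    return abs(r - round(r)) < tol


def validate(p: SimParams) -> None:
    """Raise ParamError naming the offending dotted key on any violation."""
    g, k, s, r, c = p.geometry, p.kinetics, p.springs, p.run, p.classify

    def bad(key: str, msg: str) -> None:
        raise ParamError(f"{key}: {msg}")

    length_nm = g.nucleoid_length * 1e3
    width_nm = g.nucleoid_width * 1e3
    if not length_nm > width_nm:
        bad("geometry.nucleoid_length", "must exceed nucleoid_width")
    if not width_nm > g.carboxysome_diameter:
        bad("geometry.nucleoid_width", "must exceed carboxysome_diameter")
    if g.lattice_spacing <= 0:
        bad("geometry.lattice_spacing", "must be positive")
    if not _is_multiple(length_nm, g.lattice_spacing):
        bad("geometry.nucleoid_length", "must be an integer multiple of lattice_spacing")
    if not _is_multiple(width_nm, g.lattice_spacing):
        bad("geometry.nucleoid_width", "must be an integer multiple of lattice_spacing")
    if g.carboxysome_diameter <= 0:
        bad("geometry.carboxysome_diameter", "must be positive")

    for key, val in (
        ("kinetics.k_off_intrinsic", k.k_off_intrinsic),
        ("kinetics.k_rebind", k.k_rebind),
        ("kinetics.k_bond_on", k.k_bond_on),
        ("kinetics.k_bond_off", k.k_bond_off),
        ("kinetics.D_mcdA_nucleoid", k.D_mcdA_nucleoid),
        ("kinetics.D_carb", k.D_carb),
    ):
        if val < 0 or not math.isfinite(val):
            bad(key, "rates and diffusivities must be finite and >= 0")
    if k.n_mcdA < 1:
        bad("kinetics.n_mcdA", "count must be >= 1")
    if k.n_mcdB_per_carb < 1:
        bad("kinetics.n_mcdB_per_carb", "count must be >= 1")
    if k.capture_radius <= 0:
        bad("kinetics.capture_radius", "must be positive")
    if k.kBT <= 0:
        bad("kinetics.kBT", "must be positive")

    if s.k_AB < 0:
        bad("springs.k_AB", "stiffness must be >= 0")
    if s.k_self < 0:
        bad("springs.k_self", "stiffness must be >= 0")
    if s.rest_length_AB < 0:
        bad("springs.rest_length_AB", "must be >= 0")
    if not s.rest_length_self >= g.carboxysome_diameter:
        bad("springs.rest_length_self", "must be >= carboxysome_diameter (contact)")
    if not s.self_range >= s.rest_length_self:
        bad("springs.self_range", "must be >= rest_length_self")
    if not s.max_extension_AB > k.capture_radius:
        bad("springs.max_extension_AB", "must exceed kinetics.capture_radius")

    if r.duration <= 0:
        bad("run.duration", "must be positive")
    if r.dt <= 0:
        bad("run.dt", "must be positive")
    if r.record_interval < r.dt:
        bad("run.record_interval", "must be >= dt")
    if not _is_multiple(r.duration, r.dt, tol=1e-6):
        bad("run.duration", "must be an integer number of dt steps")
    if not _is_multiple(r.record_interval, r.dt, tol=1e-6):
        bad("run.record_interval", "must be an integer number of dt steps")
    if r.n_carboxysomes < 1:
        bad("run.n_carboxysomes", "count must be >= 1")
    if r.n_trajectories < 1:
        bad("run.n_trajectories", "count must be >= 1")

    for key, val in (
        ("classify.clustered_time_fraction", c.clustered_time_fraction),
        ("classify.positioned_range_fraction", c.positioned_range_fraction),
    ):
        if not (0.0 < val < 1.0):
            bad(key, "must be strictly between 0 and 1")


def to_dict(p: SimParams) -> dict[str, dict[str, Any]]:
    return {sec: dataclasses.asdict(getattr(p, sec)) for sec in _SECTIONS}


def from_dict(d: dict[str, Any], *, strict: bool = True) -> SimParams:
    """Build SimParams from a nested dict, defaults filling unset keys.

    With strict=True (the default) unknown sections or keys raise
    ParamError, so typos in config files cannot silently fall back to a
    default value.
    """
    p = SimParams()
    for sec, entries in d.items():
        if sec not in _SECTIONS:
            if strict:
                raise ParamError(f"{sec}: unknown config section")
            continue
        target = getattr(p, sec)
        if not isinstance(entries, dict):
            raise ParamError(f"{sec}: expected a table of key = value entries")
        for key, val in entries.items():
            if not hasattr(target, key):
                if strict:
                    raise ParamError(f"{sec}.{key}: unknown config key")
                continue
            if (sec, key) in _INT_KEYS:
                if isinstance(val, bool) or not isinstance(val, int):
                    raise ParamError(f"{sec}.{key}: must be an integer")
                setattr(target, key, int(val))
            else:
                if isinstance(val, bool) or not isinstance(val, (int, float)):
                    raise ParamError(f"{sec}.{key}: must be a number")
                setattr(target, key, float(val))
    validate(p)
    return p


def load_params(path: str | Path) -> SimParams:
    """Load and validate a TOML parameter file.

    Keys not present take the documented defaults; unknown keys are an
    error.  An empty file yields ``default_params()``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    try:
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    except tomllib.TOMLDecodeError as exc:
        raise ParamError(f"{path}: config parse failure: {exc}") from exc
    return from_dict(raw)


_UNITS = {
    "geometry": {
        "nucleoid_length": "um",
        "nucleoid_width": "um",
        "lattice_spacing": "nm",
        "carboxysome_diameter": "nm",
    },
    "kinetics": {
        "k_off_intrinsic": "1/s",
        "k_rebind": "1/s",
        "k_bond_on": "1/s",
        "k_bond_off": "1/s",
        "D_mcdA_nucleoid": "um^2/s",
        "D_carb": "um^2/s",
        "n_mcdA": "count",
        "n_mcdB_per_carb": "count",
        "capture_radius": "nm",
        "kBT": "pN nm",
    },
    "springs": {
        "k_AB": "pN/nm",
        "k_self": "pN/nm",
        "rest_length_AB": "nm",
        "rest_length_self": "nm",
        "self_range": "nm",
        "max_extension_AB": "nm",
    },
    "run": {
        "duration": "s",
        "dt": "s",
        "n_carboxysomes": "count",
        "n_trajectories": "count",
        "seed": "integer",
        "record_interval": "s",
    },
    "classify": {
        "clustered_time_fraction": "fraction",
        "positioned_range_fraction": "fraction of nucleoid length",
    },
}


def dumps_params(p: SimParams) -> str:
    validate(p)
    lines = ["# mcdratchet parameter file (TOML), schema v1"]
    for sec in _SECTIONS:
        lines.append("")
        lines.append(f"[{sec}]")
        for key, val in dataclasses.asdict(getattr(p, sec)).items():
            unit = _UNITS[sec].get(key, "")
            comment = f"  # {unit}" if unit else ""
            if isinstance(val, int):
                lines.append(f"{key} = {val}{comment}")
            else:
                lines.append(f"{key} = {val!r}{comment}")
    return "\n".join(lines) + "\n"


def save_params(p: SimParams, path: str | Path) -> None:
    """Write a TOML file that round-trips: load_params(path) == p."""
    Path(path).write_text(dumps_params(p))
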