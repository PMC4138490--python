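"""The assembled UBC model: morphology + mechanisms + calcium + cascade.

The canonical parameterization ships as ``config/canonical.yaml``; Table
base densities appear there verbatim, and per-compartment dimensionless
multipliers carry the compartment-specific tuning (e.g. CaLVA denser in
the brush than the soma, Na concentrated in the AIS).
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field, replace
from importlib import resources

import yaml

from .calcium import ca_out_for_reversal
from .cascade import CascadeParams
from .channels import MarkovNaSpec
from .morphology import Morphology, build_canonical_ubc

__all__ = ["MechanismConfig", "CalciumConfig", "UBCModel", "load_canonical", "canonical_densities"]

MECH_NAMES = ("leak", "trp", "h", "kv", "ka", "kslow", "kca", "cahva", "calva", "na")

_GROUPS = {
    "all": ["brush", "shaft", "soma"] + [f"ais{i}" for i in range(1, 6)] + [f"axon{i}" for i in range(1, 6)],
    "ais": [f"ais{i}" for i in range(1, 6)],
    "axon": [f"axon{i}" for i in range(1, 6)],
    "dend": ["brush", "shaft"],
}

_MECH_KEYS = {"gmax", "reversal", "q10", "q10_inact", "texp", "texp_inact", "density", "tau_mode", "markov"}


@dataclass
class MechanismConfig:
    """Density, reversal and temperature metadata of one mechanism."""

    name: str
    gmax: float  # S/cm^2 (cm/s for the GHK mechanism)
    reversal: float | None
    q10: float = 3.0
    texp: float = 30.0
    density: dict[str, float] = field(default_factory=dict)
    q10_inact: float | None = None  # CaLVA: separate Q10 for inactivation
    texp_inact: float | None = None  # CaLVA: separate reference T for inactivation
    tau_mode: str | None = None  # H: "calibrated" | "raw"
    markov: dict[str, float] | None = None  # Na scheme constants

    def rate_multiplier(
        self, t_sim: float, q10: float | None = None, texp: float | None = None
    ) -> float:
        q = self.q10 if q10 is None else q10
        te = self.texp if texp is None else texp
        return q ** ((t_sim - te) / 10.0)

    def expanded_density(self) -> dict[str, float]:
        """Resolve group aliases to per-compartment multipliers."""
        out: dict[str, float] = {}
        for key, mult in self.density.items():
            for name in _GROUPS.get(key, [key]):
                out[name] = mult
        return out


@dataclass
class CalciumConfig:
    shell_depth_um: float = 0.2
    beta_ca: float = 1.5  # 1/ms
    ca_rest: float = 1.0e-4  # mM
    reversal_init: float = 129.33  # mV; fixes the bath concentration
    compartments: tuple[str, ...] = ("brush", "shaft", "soma")

    @property
    def ca_out(self) -> float:
        return ca_out_for_reversal(self.reversal_init, self.ca_rest)


@dataclass
class UBCModel:
    morphology: Morphology
    mechanisms: dict[str, MechanismConfig]
    calcium: CalciumConfig
    cascade: CascadeParams
    temperature: float = 30.0
    name: str = "ubc"

    def config_hash(self) -> str:
        """Stable hash of the full parameterization."""
        payload = {
            "name": self.name,
            "temperature": self.temperature,
            "morphology": self.morphology.to_dict(),
            "mechanisms": {
                k: {
                    "gmax": m.gmax,
                    "reversal": m.reversal,
                    "q10": m.q10,
                    "q10_inact": m.q10_inact,
                    "texp": m.texp,
                    "texp_inact": m.texp_inact,
                    "density": m.density,
                    "tau_mode": m.tau_mode,
                    "markov": m.markov,
                }
                for k, m in sorted(self.mechanisms.items())
            },
            "calcium": {
                "shell_depth_um": self.calcium.shell_depth_um,
                "beta_ca": self.calcium.beta_ca,
                "ca_rest": self.calcium.ca_rest,
                "reversal_init": self.calcium.reversal_init,
                "compartments": list(self.calcium.compartments),
            },
            "cascade": self.cascade.__dict__,
        }
        blob = json.dumps(payload, sort_keys=True, default=float).encode()
        return hashlib.sha256(blob).hexdigest()

    def na_spec(self) -> MarkovNaSpec:
        m = self.mechanisms["na"]
        spec = MarkovNaSpec(gmax_density=m.gmax, reversal=m.reversal or 63.0, q10=m.q10)
        if m.markov:
            spec.params.update(m.markov)
        return spec

    # -- model surgery ------------------------------------------------------

    def copy(self) -> "UBCModel":
        return copy.deepcopy(self)

    def with_block(self, mechanisms: set[str] | list[str]) -> "UBCModel":
        """Copy with the listed maximum conductances / permeabilities zeroed."""
        unknown = set(mechanisms) - set(MECH_NAMES)
        if unknown:
            raise KeyError(f"unknown mechanism(s): {sorted(unknown)}")
        out = self.copy()
        for name in mechanisms:
            out.mechanisms[name].gmax = 0.0
            for comp in out.morphology.compartments:
                if name in comp.channel_densities:
                    comp.channel_densities[name] = 0.0
        return out

    def with_scaled(self, mechanism: str, factor: float) -> "UBCModel":
        """Copy with one mechanism's maximum density scaled by ``factor``."""
        if mechanism not in MECH_NAMES:
            raise KeyError(f"unknown mechanism: {mechanism}")
        if factor < 0:
            raise ValueError("scale factor must be >= 0")
        out = self.copy()
        out.mechanisms[mechanism].gmax *= factor
        for comp in out.morphology.compartments:
            if mechanism in comp.channel_densities:
                comp.channel_densities[mechanism] *= factor
        return out

    def with_cascade(self, **kwargs) -> "UBCModel":
        out = self.copy()
        out.cascade = replace(out.cascade, **kwargs)
        return out

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "temperature": self.temperature,
            "passive": {
                "axial_resistivity": self.morphology.compartments[0].axial_resistivity,
                "specific_capacitance": self.morphology.compartments[0].specific_capacitance,
            },
            "morphology": self.morphology.to_dict(),
            "mechanisms": {
                k: {
                    key: val
                    for key, val in (
                        ("gmax", m.gmax),
                        ("reversal", m.reversal),
                        ("q10", m.q10),
                        ("q10_inact", m.q10_inact),
                        ("texp", m.texp),
                        ("texp_inact", m.texp_inact),
                        ("tau_mode", m.tau_mode),
                        ("markov", m.markov),
                        ("density", m.density),
                    )
                    if val is not None
                }
                for k, m in self.mechanisms.items()
            },
            "calcium": {
                "shell_depth_um": self.calcium.shell_depth_um,
                "beta_ca": self.calcium.beta_ca,
                "ca_rest": self.calcium.ca_rest,
                "reversal_init": self.calcium.reversal_init,
                "compartments": list(self.calcium.compartments),
            },
            "cascade": dict(self.cascade.__dict__),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "UBCModel":
        known = {"name", "temperature", "passive", "morphology", "mechanisms", "calcium", "cascade"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        passive = data.get("passive", {})
        ra = passive.get("axial_resistivity", 100.0)
        cm = passive.get("specific_capacitance", 1.0)
        mechs: dict[str, MechanismConfig] = {}
        for name, m in data["mechanisms"].items():
            if name not in MECH_NAMES:
                raise ValueError(f"unknown mechanism {name!r}")
            bad = set(m) - _MECH_KEYS
            if bad:
                raise ValueError(f"unknown key(s) in mechanism {name!r}: {sorted(bad)}")
            mechs[name] = MechanismConfig(
                name=name,
                gmax=float(m["gmax"]),
                reversal=m.get("reversal"),
                q10=float(m.get("q10", 3.0)),
                texp=float(m.get("texp", 30.0)),
                density={k: float(v) for k, v in m.get("density", {}).items()},
                q10_inact=m.get("q10_inact"),
                texp_inact=m.get("texp_inact"),
                tau_mode=m.get("tau_mode"),
                markov=m.get("markov"),
            )
        cal = data.get("calcium", {})
        calcium = CalciumConfig(
            shell_depth_um=float(cal.get("shell_depth_um", 0.2)),
            beta_ca=float(cal.get("beta_ca", 1.5)),
            ca_rest=float(cal.get("ca_rest", 1.0e-4)),
            reversal_init=float(cal.get("reversal_init", 129.33)),
            compartments=tuple(cal.get("compartments", ("brush", "shaft", "soma"))),
        )
        cascade = CascadeParams(**data.get("cascade", {}))
        # densities resolved onto compartments
        tmp = cls(
            morphology=Morphology.from_dict(data["morphology"], ra, cm)
            if "morphology" in data
            else build_canonical_ubc({}, ra, cm),
            mechanisms=mechs,
            calcium=calcium,
            cascade=cascade,
            temperature=float(data.get("temperature", 30.0)),
            name=data.get("name", "ubc"),
        )
        for comp in tmp.morphology.compartments:
            comp.channel_densities = {
                name: mech.gmax * mult
                for name, mech in mechs.items()
                for cname, mult in mech.expanded_density().items()
                if cname == comp.name
            }
        return tmp

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "UBCModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _canonical_config() -> dict:
    text = resources.files("ubcsim").joinpath("config/canonical.yaml").read_text()
    return yaml.safe_load(text)


def load_canonical() -> UBCModel:
    """Load the packaged canonical UBC model."""
    cfg = _canonical_config()
    if "morphology" not in cfg:
        cfg = dict(cfg)
        passive = cfg.get("passive", {})
        morph = build_canonical_ubc(
            {},
            axial_resistivity=passive.get("axial_resistivity", 100.0),
            specific_capacitance=passive.get("specific_capacitance", 1.0),
            pipette_access_resistance=cfg.get("pipette", {}).get("access_resistance", 20.0),
        )
        md = morph.to_dict()
        cfg.pop("pipette", None)
        cfg["morphology"] = md
    return UBCModel.from_dict(cfg)


def canonical_densities() -> dict[str, dict[str, float]]:
    """Per-compartment mechanism densities of the canonical model."""
    model = load_canonical()
    return {c.name: dict(c.channel_densities) for c in model.morphology.compartments}
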