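"""Physical parameters and run configuration.

Defaults are the porcine study conditions: mean arterial pressure at the
catheterized root, central venous pressure at the sink, blood as the carrier
fluid, and a 2 M dichloroacetyl chloride (DCACl) solution in Lipiodol as the
injected bolus.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class FlowParams:
    """Boundary conditions and fluid properties for the network flow solve.

    Attributes
    ----------
    p_map : float
        Mean arterial pressure at the root node, mmHg.
    p_cvp : float
        Central venous (sink) pressure behind every terminal node, mmHg.
    mu : float
        Dynamic viscosity of blood, Pa s.
    gamma_a : float
        Lumped conductance parameter of the unsegmented vasculature between
        each terminal node and the venous sink, m^3; ``gamma_a / mu`` is a
        hydraulic conductance in m^3/(Pa s). Calibrated, not measured.
    """

    p_map: float = 100.0
    p_cvp: float = 5.0
    mu: float = 8.9e-4
    gamma_a: float = 1e-12

    def __post_init__(self) -> None:
        if self.p_map <= self.p_cvp:
            raise ValueError("root pressure must exceed sink pressure")
        if self.mu <= 0:
            raise ValueError("viscosity must be positive")
        if self.gamma_a < 0:
            raise ValueError("gamma_a must be non-negative")


@dataclass
class BolusParams:
    """Properties of the DCACl/Lipiodol bolus and its hydrolysis reaction.

    ``epsilon`` is the volume saturation of DCACl in the bolus; with a 2 M
    solution, epsilon = M * W / rho_dcacl = 2 * 0.147 / 1.532 = 0.1919.
    ``gamma_t`` (1/s) is the first-order hydrolysis time constant, the key
    calibrated parameter. ``h`` is the exothermic energy release per mole of
    DCACl hydrolyzed. The bolus viscosity ``mu_o`` is recorded for
    completeness but does not feed back into the flow field: the bolus is
    advected passively on the blood-flow solution.
    """

    epsilon: float = 0.1919
    rho_dcacl: float = 1532.0
    rho_o: float = 1280.0
    cp_o: float = 1970.0
    mu_o: float = 7e-4
    h: float = 138e3
    molar_mass: float = 0.147
    molarity: float = 2.0
    gamma_t: float = 13.0
    v_dcacl_ul: float = 200.0
    rho_b: float = 1045.0
    cp_b: float = 3600.0

    def __post_init__(self) -> None:
        if not 0.0 < self.epsilon < 1.0:
            raise ValueError("epsilon must lie in (0, 1)")
        for name in ("rho_dcacl", "rho_o", "cp_o", "h", "molar_mass", "v_dcacl_ul", "rho_b", "cp_b"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.gamma_t < 0:
            raise ValueError("gamma_t must be non-negative")

    @property
    def decay_rate(self) -> float:
        """First-order saturation decay rate lambda = gamma_t * epsilon * rho_dcacl / rho_o, 1/s."""
        return self.gamma_t * self.epsilon * self.rho_dcacl / self.rho_o

    @staticmethod
    def epsilon_from_chemistry(molarity: float = 2.0, molar_mass: float = 0.147,
                               rho_dcacl: float = 1532.0) -> float:
        """DCACl volume saturation implied by molarity M (mol/L), molar mass W
        (kg/mol) and DCACl density (kg/m^3): epsilon = 1000*M*W / rho_dcacl."""
        return 1000.0 * molarity * molar_mass / rho_dcacl


@dataclass
class RunConfig:
    """Full configuration of a pipeline run, serializable to YAML."""

    flow: FlowParams = field(default_factory=FlowParams)
    bolus: BolusParams = field(default_factory=BolusParams)
    delta: float = 0.01
    seed: int = 0
    root_ijk: tuple[int, int, int] | None = None
    liver_fraction_mean: float = 0.0204
    liver_fraction_sd: float = 0.0033
    flow_per_100g: float = 22.28
    courant: float = 0.5
    out_dir: str = "emboflow_out"

    def __post_init__(self) -> None:
        if not 0.0 < self.delta < 1.0:
            raise ValueError("delta must lie in (0, 1)")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        if d["root_ijk"] is not None:
            d["root_ijk"] = list(d["root_ijk"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        flow = FlowParams(**d.pop("flow", {}))
        bolus = BolusParams(**d.pop("bolus", {}))
        root = d.pop("root_ijk", None)
        if root is not None:
            root = tuple(int(v) for v in root)
        return cls(flow=flow, bolus=bolus, root_ijk=root, **d)
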