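"""Sub-membrane calcium shell dynamics.

A thin shell (depth d) under the membrane of each Ca-bearing compartment
integrates

    d[Ca]/dt = -I_Ca / (2 F A d) - beta_ca * ([Ca] - [Ca]_rest)

where only currents named in ``contributing`` feed the pool (the L-type
CaHVA does; the T-type CaLVA is excluded by construction).  The shell
concentration gates the BK current and sets the calcium reversal
potential through the divalent Nernst relation, updated at run time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .constants import FARADAY, rt_over_f

__all__ = ["CalciumShell", "step_calcium", "calcium_reversal", "ca_out_for_reversal"]


@dataclass
class CalciumShell:
    """State and parameters of one compartment's calcium shell.

    depth in um (canonical 0.2 um = 200 nm), beta_ca in 1/ms, areas in
    um^2, concentrations in mM.
    """

    area_um2: float
    depth_um: float = 0.2
    beta_ca: float = 1.5
    ca_rest: float = 1.0e-4
    ca_in: float = 1.0e-4
    ca_out: float = 2.0
    contributing: frozenset[str] = field(default_factory=lambda: frozenset({"cahva"}))

    @property
    def influx_factor(self) -> float:
        """mM per (nA * ms): 1/(2 F * A * d) with volume in cm^3.

        charge nA*ms = 1e-12 C; /(2F) mol; /volume(cm^3) mol/cm^3; *1e6 mM.
        """
        vol_cm3 = (self.area_um2 * 1e-8) * (self.depth_um * 1e-4)
        return 1e-12 / (2.0 * FARADAY) / vol_cm3 * 1e6


def step_calcium(shell: CalciumShell, i_ca: float, dt: float) -> CalciumShell:
    """Advance the shell by dt (ms) under calcium current i_ca (nA, inward
    negative), holding the current fixed over the step (exponential
    update, exact for constant current)."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    b = shell.beta_ca
    influx = -i_ca * shell.influx_factor  # mM/ms
    ca_inf = shell.ca_rest + influx / b
    shell.ca_in = ca_inf + (shell.ca_in - ca_inf) * math.exp(-b * dt)
    if shell.ca_in < 1e-12:
        shell.ca_in = 1e-12
    return shell


def calcium_reversal(ca_in: float, ca_out: float, temperature: float = 30.0) -> float:
    """Divalent Nernst equilibrium potential in mV."""
    if ca_in <= 0 or ca_out <= 0:
        raise ValueError("concentrations must be > 0")
    return rt_over_f(temperature) / 2.0 * math.log(ca_out / ca_in)


def ca_out_for_reversal(
    e_rev: float, ca_in: float = 1.0e-4, temperature: float = 30.0
) -> float:
    """Back-solve the fixed extracellular [Ca2+] (mM) that reproduces the
    configured initial reversal potential at resting shell calcium."""
    return ca_in * math.exp(2.0 * e_rev / rt_over_f(temperature))
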