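"""Physiological constants of the reduced rule-maintenance network.

The rule module is a mean-field reduction of a spiking working-memory
network: two selective excitatory populations (the two task rules)
embedded in shared nonselective excitatory cells and inhibitory
interneurons.  All constants below describe that underlying circuit;
the reduction maps them onto four effective couplings (NMDA- and
AMPA-mediated, self and cross) and a baseline input current.

Conventions
-----------
* time constants in ms, rates in Hz, conductances in uS, voltages in mV;
  products g * V are currents in nA.
* ``w_minus`` is derived from the coding level and the potentiated
  weight so that total recurrent excitation is balanced:
  ``w- = 1 - f*(w+ - 1)/(1 - f)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields


@dataclass(frozen=True)
class PhysioConstants:
    """Fixed biophysical constants of the rule-module circuit."""

    C_E: float = 0.8          # relative number of excitatory neurons
    C_I: float = 0.2          # relative number of inhibitory neurons
    C_ext: float = 800.0      # external connections per neuron
    f: float = 0.15           # coding level (relative selective-pool size)

    c_E: float = 310.0        # excitatory f-I gain, Hz/nA
    g_E: float = 0.16         # excitatory f-I curvature constant, s
    I_E: float = 125.0        # excitatory f-I rate constant, Hz
    c_I: float = 615.0        # inhibitory f-I gain, Hz/nA
    I_I: float = 177.0        # inhibitory f-I rate constant, Hz
    g_I2: float = 1.7876      # inhibitory f-I slope divisor (linearized)

    V_E: float = -53.4        # mean excitatory membrane voltage, mV
    V_I: float = -51.1        # mean inhibitory membrane voltage, mV
    V_I_rev: float = -70.0    # inhibitory (GABA) reversal voltage, mV

    r_ext: float = 3.0        # external input rate per connection, Hz
    r_ns: float = 2.0         # nonselective-pool rate, Hz
    r0: float = 11.3721       # interneuron reference rate, Hz

    tau_GABA: float = 10.0    # ms
    tau_AMPA: float = 2.0     # ms
    tau_NMDA: float = 100.0   # ms

    g_AMPAext_E: float = 0.0021   # uS
    g_AMPA_E: float = 0.1         # uS
    g_NMDA_E: float = 0.3         # uS (scaled by s_NMDA)
    g_GABA_E: float = 1.3         # uS (scaled by s_GABA)
    g_AMPAext_I: float = 0.00162  # uS
    g_AMPA_I: float = 0.086       # uS
    g_NMDA_I: float = 0.258       # uS
    g_GABA_I: float = 1.0         # uS

    w_plus: float = 1.68      # potentiated intra-pool weight
    gamma: float = 0.641      # NMDA gating rise constant

    def __post_init__(self) -> None:
        for fld in fields(self):
            v = getattr(self, fld.name)
            if not isinstance(v, (int, float)) or v != v:
                raise ValueError(f"constant {fld.name} must be a finite number")
            if fld.name.startswith("V_"):
                if v >= 0:
                    raise ValueError(f"{fld.name} must be negative (mV)")
            elif v <= 0:
                raise ValueError(f"constant {fld.name} must be strictly positive")
        if abs(self.C_E + self.C_I - 1.0) > 1e-12:
            raise ValueError("C_E + C_I must equal 1")

    @property
    def w_minus(self) -> float:
        """Depressed inter-pool weight balancing the potentiated one."""
        return 1.0 - self.f * (self.w_plus - 1.0) / (1.0 - self.f)

    def replace(self, **kwargs) -> "PhysioConstants":
        from dataclasses import replace as _replace

        return _replace(self, **kwargs)


DEFAULT_CONSTANTS = PhysioConstants()
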