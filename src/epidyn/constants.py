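"""Fixed biophysical constants of the neural-mass and hemodynamic models.

These values are never fitted. The neural constants are the canonical
reduced Wong-Wang single-population settings; the hemodynamic constants are
the canonical Balloon-Windkessel settings for 3T BOLD.
"""

# --- reduced Wong-Wang neural-mass constants ---
A_NC = 270.0        # transfer-function gain, 1/nC
B_HZ = 108.0        # transfer-function threshold, Hz
D_S = 0.154         # transfer-function curvature, s
GAMMA_KINETIC = 0.641   # kinetic rate of synaptic gating (dimensionless)
TAU_S = 0.1         # synaptic gating time constant, s
J_NA = 0.2609       # synaptic coupling, nA

# --- Balloon-Windkessel hemodynamic constants ---
KAPPA = 0.65        # vasodilatory signal decay, 1/s
GAMMA_H = 0.41      # flow-dependent elimination, 1/s
TAU_H = 0.98        # hemodynamic transit time, s
ALPHA_GRUBB = 0.32  # Grubb's vessel stiffness exponent
RHO_O2 = 0.34       # resting oxygen extraction fraction
V0 = 0.02           # resting venous blood volume fraction
K1 = 7.0 * RHO_O2
K2 = 2.0
K3 = 2.0 * RHO_O2 - 0.2

# --- estimation plausibility box for regional parameters ---
RC_BOUNDS = (0.0, 10.0)      # recurrent connection strength w_i
I_BOUNDS = (0.0, 0.5)        # external input, nA
SIGMA_BOUNDS = (0.0, 0.01)   # noise sd (exclusive at 0)
G_BOUNDS = (0.5, 10.0)       # global coupling
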