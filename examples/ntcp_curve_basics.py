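"""Evaluate the logistic NTCP model and convert between slope conventions.

Builds the predefined model used throughout the framework (D50 = 1 on the
mean-normalized dose scale, gamma = 1), evaluates it at a few doses, and
converts a published LKB slope parameter to the normalized slope.
"""

import ntcpsim as ns

params = ns.NTCPParams(d50=1.0, gamma=1.0)
print(f"model: D50={params.d50}, gamma={params.gamma}, s=4*gamma/D50={params.s}")
for d in (0.5, 1.0, 1.25, 2.0):
    print(f"  NTCP({d:4.2f}) = {ns.ntcp(d, params):.4f}")

# An LKB probit model with slope m = 1.21 has the same midpoint steepness as
# a logistic model with normalized slope gamma = 1/(m*sqrt(2*pi)):
m = 1.21
print(f"LKB m = {m} -> gamma = {ns.gamma_from_lkb_m(m):.2f}")

# NTCP(D50) is 0.5 by construction; gamma sets how fast the curve rises
# around it (the derivative at D50 is gamma/D50), so steeper dose-response
# relationships concentrate outcome information near the midpoint.
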