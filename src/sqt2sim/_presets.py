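"""Frozen default rate coefficients and calibrated tissue constants.

Rate coefficients were produced by
:func:`sqt2sim.clamp_and_fit.fit_default_presets` against the default
synthetic clamp targets (:mod:`sqt2sim.fixtures`): Boltzmann activation
with WT V_half +20 mV / slope 12 mV, mutant shift -36 mV, two-fold
slower mutant deactivation and two-fold faster mutant activation, with
sign-constrained voltage sensitivities (monotone equilibrium
activation) and a 20/ms rate cap.  Regenerate with::

    sqt2sim refit-presets

Tissue constants come from the anchor calibrations in
:mod:`sqt2sim.calibrate`.
"""

WT_RATE_COEFFICIENTS = {
    "alpha": (0.01427823983740696, 1.1553599899906536e-05),
    "beta": (0.003626861812125629, -1.4462679928782739e-05),
    "gamma": (0.00563974600639866, 0.01747830545815786),
    "delta": (0.0049206593626827605, -0.031055496113169122),
    "theta": (0.02964107330251567, -1.2787231481970305e-10),
    "eta": (0.03251026354576478, -1.6351224146467994e-15),
    "psi": (0.013194643081450491, 0.0),
    "omega": (0.012263431602619508, 0.0),
}

V307L_RATE_COEFFICIENTS = {
    "alpha": (0.01727287440532311, -9.08335737607106e-09),
    "beta": (0.0030129125386718016, -1.0830387879929414e-07),
    "gamma": (0.010677577902737084, 0.029048258936661506),
    "delta": (0.0012393599324500592, -0.029767350874324132),
    "theta": (0.02284646428465955, 9.953744563175323e-13),
    "eta": (0.03610677793105308, -3.9503463162009825e-14),
    "psi": (0.013365827961240216, 0.0),
    "omega": (0.009520951279319817, 0.0),
}

# anchor-calibrated tissue constants (see sqt2sim.calibrate)
G_KS_WT = 0.12019531250000001     # nS/pF, WT EPI/ENDO; MIDDLE keeps the 1:4 host ratio
MUTANT_SCALE = 1.0   # mutant relative-amplitude multiplier
DIFFUSION = 0.144921875   # mm^2/ms, planar CV = 70 cm/s in the WT strand
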