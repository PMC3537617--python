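"""Physical constants and package-wide defaults (SI units)."""

#: Gas constant, J mol^-1 K^-1.
R_GAS = 8.3145

#: Avogadro's number, mol^-1.
N_AVOGADRO = 6.02214076e23

#: Default unquenched fluorescence lifetime of serum albumin, seconds.
TAU0_DEFAULT_S = 5e-9

#: Maximum diffusion-collisional quenching rate constant, M^-1 s^-1.
COLLISIONAL_LIMIT_PER_M_PER_S = 1e10

#: Default analysis temperature, K.
T_DEFAULT_K = 298.0

#: Default denaturation baseline windows, mol/L urea: (native, intermediate,
#: unfolded).  The native plateau ends where unfolding starts (~2.2-2.4 M),
#: the intermediate accumulates around 4.8-5.2 M (the window is widened to
#: the nearest 0.25 M grid points so it holds >= 2 samples on a standard
#: 0.25 M titration grid), the unfolded plateau lies at >= 8 M.
DEFAULT_REGIONS = ((0.0, 2.2), (4.75, 5.25), (8.0, float("inf")))
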