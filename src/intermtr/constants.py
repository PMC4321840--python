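"""Physical constants used throughout the package."""

#: Proton gyromagnetic ratio, rad s^-1 T^-1.
GAMMA = 2.675e8

#: Conventional on-resonance value of the super-Lorentzian absorption
#: lineshape, in seconds.  The integral form of the lineshape diverges at
#: zero offset; quantitative MT work assigns this finite value instead.
G_ZERO_DEFAULT = 1.4e-5

#: Offsets below this magnitude (Hz) are treated as "on resonance" for
#: lineshape evaluation and clamped to the tissue's G(0).
NEAR_RESONANCE_CUTOFF_HZ = 1000.0
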