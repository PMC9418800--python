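# Default six-box mercury-cycle coefficients (annual fractions, yr^-1).
#
# Calibrated once against present-day (2012) source-attribution anchors for
# a single growing source run 1970-2012 from empty compartments against an
# all-sources steady-state baseline:
#   net-deposition share rD = 0.122, plankton-MeHg share rP ~ 0.10,
#   soil-Hg share rS ~ 0.0063.
# dep_total = 1.0 encodes an atmospheric lifetime (~0.5-1 yr) shorter than
# the annual step: the year's airborne load deposits within the year, and
# legacy re-emission returns to the air with a one-year delay.  Strong
# prompt recycling (fast-soil re-emission, surface-ocean evasion) is what
# damps the growth of the net deposition flux below the emission growth.
dep_total: 1.0
dep_land_fraction: 0.22
fast_reemit: 0.76
fast_to_slow: 0.03
fast_to_armored: 0.002
fast_export: 0.022          # riverine export to coastal sediment (loss)
slow_reemit: 0.01
slow_to_armored: 0.016
armored_reemit: 0.0005
armored_burial: 0.00042
ocean_evasion: 0.59
ocean_to_subsurface: 0.41
upwelling: 0.0036
subsurface_burial: 0.074
# constant all-sources primary emission whose steady state initialises the
# baseline scenario (metric tons yr^-1)
baseline_total_emission_t: 6070.1
# diagnostic yields: baseline plankton MeHg 5.67 fmol/L, baseline soil
# index 1.0 at the steady state above
plankton_yield_fmol_per_t: 0.000375157
soil_yield_per_t: 7.97943e-06
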