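# Default dose-response coefficients for the two MeHg endpoints.
# beta: blood Hg per unit daily intake (ug/L per ug/day), one-compartment
#   toxicokinetic model.
# lambda_: hair-to-blood ratio (ug/g per ug/L), the conventional 250:1.
# gamma: IQ points lost per ug/g hair Hg (linear, no threshold).
# phi: fatal-heart-attack dose-effect per ug/g hair Hg (log-linear).
# omega: subjective weight on the FHA endpoint, reflecting the thinner
#   epidemiological evidence base.
beta: 0.8
lambda_: 0.25
gamma: 0.18
phi: 0.066
omega: 0.5
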