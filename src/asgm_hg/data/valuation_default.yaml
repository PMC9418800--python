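# Default valuation parameters.
# EL_ref: lifelong earning loss per IQ point (USD, el_currency_year value)
#   for the reference economy; VSL_ref: value of statistical life (USD,
#   vsl_currency_year value).  ref_income is the reference economy's
#   PPP-adjusted GDP per capita; country values are transferred with the
#   stated income elasticity.  cpi_factors are US CPI-U annual averages
#   (1982-84 = 100) used for currency-year conversion.
EL_ref: 18832.0
el_currency_year: 2008
VSL_ref: 6300000.0
vsl_currency_year: 2005
ref_income: 48000.0
elasticity: 1.0
discount_rate: 0.03
discount_base_year: 2020
cpi_factors:
  2005: 195.3
  2008: 215.3
  2012: 229.6
  2020: 258.8
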