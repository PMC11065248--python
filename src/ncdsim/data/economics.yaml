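# Economic constants (2023 international dollars).
# gdp_per_capita is set so that three times GDP per capita equals the
# published willingness-to-pay ceiling of $10,992 per DALY averted.
gdp_per_capita: 3664.0
discount_rate: 0.03
currency: "2023 international dollars"
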