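# Literature reference values for low-LET (1 MeV electron) water radiolysis at
# 1 us, from published track-structure IRT simulations validated against pulse
# radiolysis experiments: G(e_aq) across the 25-150 C temperature range at pH 7
# and across pH 5-9 at 25 C, plus the reported material-balance discrepancies
# |Gred - Gox| (percent) at the same conditions.
# kind: temperature (condition = degC) | ph (condition = pH)
# quantity: g_e_aq (molecules / 100 eV) | balance_pct (percent)
kind,condition,quantity,value
temperature,25,g_e_aq,2.59
temperature,50,g_e_aq,2.69
temperature,75,g_e_aq,2.75
temperature,100,g_e_aq,2.80
temperature,125,g_e_aq,2.89
temperature,150,g_e_aq,3.03
ph,5,g_e_aq,2.10
ph,6,g_e_aq,2.54
ph,7,g_e_aq,2.59
ph,8,g_e_aq,2.59
ph,9,g_e_aq,2.60
temperature,25,balance_pct,0.11
temperature,50,balance_pct,0.21
temperature,75,balance_pct,0.31
temperature,100,balance_pct,0.31
temperature,125,balance_pct,0.24
temperature,150,balance_pct,0.44
ph,5,balance_pct,0.19
ph,6,balance_pct,0.11
ph,7,balance_pct,0.11
ph,8,balance_pct,0.07
ph,9,balance_pct,0.07
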