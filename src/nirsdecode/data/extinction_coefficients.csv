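# Molar extinction coefficients of hemoglobin in 1/(M*cm), decadic.
# Compiled from the W.B. Gratzer / S. Prahl tabulation (Oregon Medical Laser Center).
# version: 1
wavelength_nm,eps_hbo,eps_hbr
690,276.0,2051.96
730,390.0,1102.2
760,586.0,1548.52
780,710.0,1075.44
808,844.0,755.2
830,974.0,693.04
850,1058.0,691.32
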