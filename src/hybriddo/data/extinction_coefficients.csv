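# Molar extinction coefficients of oxy- and deoxy-hemoglobin.
# Provenance: compiled tabulation of Gratzer (Med. Res. Council Labs) and
# Kollias (Wellman Labs), as distributed by the Oregon Medical Laser Center
# hemoglobin spectrum compilation; original units cm^-1/M, converted here to
# 1/(mM*mm) (divide by 1e4). Absorption uses the ln(10) convention:
# mua = ln(10) * (eps_hbo2*[HbO2] + eps_hhb*[Hhb]) with concentrations in mM.
wavelength_nm,eps_hbo2_per_mM_mm,eps_hhb_per_mM_mm
690,0.027600,0.205196
830,0.097400,0.069304
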