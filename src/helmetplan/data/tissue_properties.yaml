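# Dielectric and thermal tissue properties at the applicator's operating
# frequencies, 250 / 375 / 500 MHz.
#
# Dielectric values (relative permittivity eps_r and conductivity sigma, S/m)
# follow the IT'IS / Gabriel parametric database at the three discrete
# frequencies; tumor dielectrics are an average of reported malignant-tissue
# values. Thermal values: density rho (kg/m^3), specific heat cp (J/kg/K),
# thermal conductivity k_th (W/m/K), blood perfusion (ml/min/kg). Tumor
# thermal properties: rho=1090, cp=3421, k_th=0.49.
#
# This file is a versioned constant of the package; it is loaded at import
# time and can be overridden by the user via TissueModel(property_table=...).
version: 1
frequencies_hz: [250.0e+6, 375.0e+6, 500.0e+6]
tissues:
  water:
    eps_r:  [78.0, 78.0, 78.0]
    sigma:  [0.02, 0.03, 0.05]
    rho: 1000.0
    cp: 4181.0
    k_th: 0.60
    perfusion: 0.0
  skin:
    eps_r:  [46.6, 45.1, 44.2]
    sigma:  [0.60, 0.66, 0.70]
    rho: 1109.0
    cp: 3391.0
    k_th: 0.37
    perfusion: 106.0
  muscle:
    eps_r:  [57.4, 56.9, 56.5]
    sigma:  [0.74, 0.78, 0.82]
    rho: 1090.0
    cp: 3421.0
    k_th: 0.49
    perfusion: 37.0
  bone_cortical:
    eps_r:  [13.7, 13.2, 12.9]
    sigma:  [0.073, 0.086, 0.096]
    rho: 1908.0
    cp: 1313.0
    k_th: 0.32
    perfusion: 10.0
  csf:
    eps_r:  [72.5, 71.3, 70.5]
    sigma:  [2.22, 2.26, 2.30]
    rho: 1007.0
    cp: 4096.0
    k_th: 0.57
    perfusion: 0.0
  brain_gray:
    eps_r:  [56.0, 54.2, 53.1]
    sigma:  [0.66, 0.72, 0.79]
    rho: 1045.0
    cp: 3696.0
    k_th: 0.55
    perfusion: 763.0
  brain_white:
    eps_r:  [41.1, 39.9, 39.0]
    sigma:  [0.42, 0.46, 0.51]
    rho: 1041.0
    cp: 3583.0
    k_th: 0.51
    perfusion: 212.0
  eye_vitreous:
    eps_r:  [69.1, 68.9, 68.7]
    sigma:  [1.53, 1.55, 1.60]
    rho: 1005.0
    cp: 4047.0
    k_th: 0.59
    perfusion: 0.0
  cartilage:
    eps_r:  [44.5, 43.4, 42.7]
    sigma:  [0.54, 0.59, 0.62]
    rho: 1100.0
    cp: 3568.0
    k_th: 0.49
    perfusion: 35.0
  pharynx_air:
    eps_r:  [1.0, 1.0, 1.0]
    sigma:  [0.0, 0.0, 0.0]
    rho: 1.2
    cp: 1004.0
    k_th: 0.026
    perfusion: 0.0
  tumor:
    eps_r:  [59.0, 57.9, 57.1]
    sigma:  [0.86, 0.92, 0.97]
    rho: 1090.0
    cp: 3421.0
    k_th: 0.49
    perfusion: 70.0
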