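# Bundled yeast iron-trafficking model: three trained cellular states
# (W healthy iron-replete, Y frataxin-deficient, D iron-deficient), the two
# selected autoregulatory mechanisms, and the published derived rates and
# rate constants used as a validation reference.
#
# Concentrations are local (uM).  States Y and D carry derive_o2: true —
# their mitochondrial [O2] is back-solved from the shared respiration
# constant (derived from the reference W state) and the state's assigned
# respiration rate, which is how the published constants were generated;
# the printed [O2] values below are the rounded versions.
name: yeast-iron-trafficking
compartments: {f_cyt: 0.8, f_mit: 0.1, f_vac: 0.1}
o2_setpoint: 1.0
km: {cyt: 10.0, mit: 20.0, vac: 20.0, cia: 20.0, "23": 200.0, isu: 100.0, res: 1.0}
reference_state: W
states:
  W:
    concentrations: {FC: 20.0, CIA: 80.0, F2: 200.0, F3: 3400.0, FM: 100.0, FS: 500.0, MP: 50.0, O2: 1.0}
    alpha: 0.003333
    iron: 40.0
    oxygen: 100.0
    r_res: 9090.909091
  Y:
    concentrations: {FC: 10.0, CIA: 70.0, F2: 30.0, F3: 420.0, FM: 200.0, FS: 150.0, MP: 8500.0, O2: 0.48}
    alpha: 0.002
    iron: 40.0
    oxygen: 100.0
    r_res: 1772.36
    derive_o2: true
  D:
    concentrations: {FC: 5.0, CIA: 68.0, F2: 20.0, F3: 60.0, FM: 50.0, FS: 300.0, MP: 20.0, O2: 1.2}
    alpha: 0.003333
    iron: 1.0
    oxygen: 100.0
    r_res: 6000.0
    derive_o2: true
# hypoxic prediction scenarios: external OXYGEN reduced from the given start state
predictions:
  H_W:
    from: W
    oxygen: 25.0
    crm: case1
    reported: {CIA: 174.0, F2: 1736.0, F3: 1194.0, FC: 16.8, FM: 44.7, FS: 545.0, MP: 1.93, O2: 0.13}
  H_Y:
    from: Y
    oxygen: 1.0
    crm: case1
    reported: {CIA: 100.0, F2: 5500.0, F3: 100.0, FC: 18.5, FM: 467.0, FS: 273.0, MP: 1129.0, O2: 0.0051}
# the two autoregulatory mechanisms surviving all six selection filters
crms:
  case1:
    "23": {sensor: FC, n: 0.249, setpoint: 15.1, k_reg: 0.294, k_unreg: 0.0, mode: feedforward}
    cia: {sensor: FM, n: -0.0388, setpoint: 0.992, k_reg: 5.51, k_unreg: 0.418, mode: feedback}
    vac: {sensor: FC, n: 0.680, setpoint: 14.0, k_reg: 2.89, k_unreg: 0.160, mode: feedforward}
    mit: {sensor: FS, n: -0.022, setpoint: 0.992, k_reg: 169.0, k_unreg: 0.539, mode: feedback}
    cyt: {sensor: FC, n: -1.00, setpoint: 8.74, k_reg: 2.16, k_unreg: 2.63, mode: feedback}
    O2: {sensor: FS, n: 0.0135, setpoint: 258.0, k_reg: 95.4, k_unreg: 0.0, mode: feedforward}
    mp: {sensor: FM, n: 0.0587, setpoint: 225.0, k_reg: 0.931, k_unreg: 0.00106, mode: feedforward}
  case2:
    "23": {sensor: FC, n: 0.249, setpoint: 15.1, k_reg: 0.294, k_unreg: 0.0, mode: feedforward}
    cia: {sensor: FM, n: -0.0388, setpoint: 0.992, k_reg: 5.51, k_unreg: 0.418, mode: feedback}
    vac: {sensor: FC, n: 0.680, setpoint: 14.0, k_reg: 2.89, k_unreg: 0.160, mode: feedforward}
    mit: {sensor: FS, n: -0.022, setpoint: 0.992, k_reg: 169.0, k_unreg: 0.539, mode: feedback}
    cyt: {sensor: F2, n: -0.159, setpoint: 7.91, k_reg: 16.6, k_unreg: 2.63, mode: feedback}
    O2: {sensor: FS, n: 0.0135, setpoint: 258.0, k_reg: 95.4, k_unreg: 0.0, mode: feedforward}
    mp: {sensor: FM, n: 0.0587, setpoint: 225.0, k_reg: 0.931, k_unreg: 0.00106, mode: feedforward}
# published steady-state rates and rate constants (validation reference)
reference_table:
  W:
    R_cia: 0.266640
    R_23: 11.332200
    R_isu: 1.666500
    R_mp: 0.166650
    R_vac: 1.499850
    R_mit: 0.270806
    R_cyt: 2.103960
    R_res: 9090.909091
    R_O2: 9091.080000
    D_FC: 0.066660
    D_CIA: 0.266640
    D_F2: 0.666600
    D_F3: 11.332200
    D_FM: 0.333300
    D_FS: 1.666500
    D_MP: 0.166650
    D_O2: 0.003333
    k_cia: 0.533280
    k_23: 0.226643
    k_isu: 6.666000
    k_mp: 0.001667
    k_vac: 2.999702
    k_mit: 0.541613
    k_cyt: 2.629947
    k_res: 36.363636
    k_O2: 91.829091
  Y:
    R_cia: 0.140000
    R_23: 0.840000
    R_isu: 0.300000
    R_mp: 17.000000
    R_vac: 0.112500
    R_mit: 2.212500
    R_cyt: 2.485000
    R_res: 1772.360000
    R_O2: 1789.360000
    D_FC: 0.020000
    D_CIA: 0.140000
    D_F2: 0.060000
    D_F3: 0.840000
    D_FM: 0.400000
    D_FS: 0.300000
    D_MP: 17.000000
    D_O2: 0.000963
    k_cia: 0.420000
    k_23: 0.064400
    k_isu: 0.666600
    k_mp: 0.176597
    k_vac: 0.337501
    k_mit: 6.637541
    k_cyt: 3.106247
    k_res: 36.363636
    k_O2: 17.980069
  D:
    R_cia: 0.226644
    R_23: 0.199980
    R_isu: 0.999900
    R_mp: 0.066660
    R_vac: 0.033330
    R_mit: 0.154151
    R_cyt: 0.430790
    R_res: 6000.000000
    R_O2: 6000.070000
    D_FC: 0.016665
    D_CIA: 0.226644
    D_F2: 0.066660
    D_F3: 0.199980
    D_FM: 0.166650
    D_FS: 0.999900
    D_MP: 0.066660
    D_O2: 0.004074
    k_cia: 1.133219
    k_23: 0.021998
    k_isu: 6.666000
    k_mp: 0.001091
    k_vac: 0.166650
    k_mit: 0.770759
    k_cyt: 4.738685
    k_res: 36.363636
    k_O2: 60.743001
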