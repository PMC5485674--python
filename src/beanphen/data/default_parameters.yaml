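# Published nonlinear-least-squares estimates for the three trait modules
# of the common bean (Calima x Jamapa RI family, five sites).
# Coefficients act on covariates centered at the across-site means listed
# under env_means; marker values are +1 (Calima) / -1 (Jamapa).
traits:
  RF:
    mean: 0.029
    env:
      TMEAN: 7.5e-4
      SRAD: -7.3e-6
      DL: -2.2e-3
    qtl:
      TF1: 9.8e-4
      TF2: 1.7e-3
      TF3: -3.9e-4
      TF4: 2.0e-4
      TF5: -1.5e-4
      TF6: 8.9e-4
      TF7: -5.3e-4
      TF8: -3.1e-4
      TF9: -3.4e-4
      TF10: -9.7e-5
      TF11: 2.6e-4
      TF12: -6.6e-5
    qtl_env:
      - {marker: TF2, covariate: TMEAN, value: -3.6e-5}
      - {marker: TF3, covariate: TMEAN, value: 6.7e-5}
      - {marker: TF3, covariate: DL, value: -1.1e-3}
      - {marker: TF5, covariate: TMEAN, value: 5.5e-5}
      - {marker: TF7, covariate: DL, value: -2.6e-4}
      - {marker: TF12, covariate: SRAD, value: -6.4e-6}
      - {marker: TF12, covariate: DL, value: -3.9e-4}
    env_env:
      - {covariates: [TMEAN, DL], value: -3.3e-4}
    env_means:
      TMEAN: 21.35
      SRAD: 18.31
      DL: 12.7
    se:
      mu: 1.5e-4
      "env:TMEAN": 3.6e-5
      "env:SRAD": 1.4e-5
      "env:DL": 8.9e-5
      "qtl:TF1": 1.1e-4
      "qtl:TF2": 1.3e-4
      "qtl:TF3": 1.5e-4
      "qtl:TF4": 1.3e-4
      "qtl:TF5": 1.2e-4
      "qtl:TF6": 1.2e-4
      "qtl:TF7": 9.9e-5
      "qtl:TF8": 8.9e-5
      "qtl:TF9": 9.0e-5
      "qtl:TF10": 9.0e-5
      "qtl:TF11": 1.5e-4
      "qtl:TF12": 1.5e-4
      "qtl_env:TF2:TMEAN": 3.4e-5
      "qtl_env:TF3:TMEAN": 3.7e-5
      "qtl_env:TF3:DL": 7.1e-5
      "qtl_env:TF5:TMEAN": 2.6e-5
      "qtl_env:TF7:DL": 5.9e-5
      "qtl_env:TF12:SRAD": 1.3e-5
      "qtl_env:TF12:DL": 5.8e-5
      "env_env:TMEAN:DL": 2.3e-5
  MSNODMAX:
    mean: 12.37
    env:
      TMEAN: 0.43
      SRAD: 0.10
      DL: 1.2
    qtl:
      MSN1: -0.43
      MSN2: -3.56
      MSN3: -0.63
      MSN4: -0.20
      MSN5: -0.60
      MSN6: 0.32
    qtl_env:
      - {marker: MSN2, covariate: TMEAN, value: -0.08}
      - {marker: MSN2, covariate: SRAD, value: -0.05}
      - {marker: MSN2, covariate: DL, value: -0.62}
      - {marker: MSN6, covariate: TMEAN, value: -0.02}
      - {marker: MSN6, covariate: SRAD, value: 0.01}
    env_means:
      TMEAN: 21.85
      SRAD: 18.74
      DL: 12.81
    se:
      mu: 0.13
      "env:TMEAN": 0.05
      "env:SRAD": 0.03
      "env:DL": 0.08
      "qtl:MSN1": 0.12
      "qtl:MSN2": 0.15
      "qtl:MSN3": 0.10
      "qtl:MSN4": 0.10
      "qtl:MSN5": 0.10
      "qtl:MSN6": 0.12
      "qtl_env:MSN2:TMEAN": 0.05
      "qtl_env:MSN2:SRAD": 0.04
      "qtl_env:MSN2:DL": 0.09
      "qtl_env:MSN6:TMEAN": 0.05
      "qtl_env:MSN6:SRAD": 0.03
  NAR:
    mean: 0.252
    env:
      TMEAN: 2.0e-2
      SRAD: -7.9e-4
      DL: 4.4e-3
    qtl:
      NAR1: -6.0e-3
      NAR2: 7.0e-3
      NAR3: 8.2e-3
      NAR4: -4.5e-3
    qtl_env:
      - {marker: NAR1, covariate: DL, value: -1.9e-4}
      - {marker: NAR2, covariate: TMEAN, value: 2.1e-3}
    env_means:
      TMEAN: 21.51
      SRAD: 17.38
      DL: 12.74
    se:
      mu: 4.0e-3
      "env:TMEAN": 5.7e-4
      "env:SRAD": 3.2e-4
      "env:DL": 8.0e-4
      "qtl:NAR1": 1.0e-3
      "qtl:NAR2": 1.0e-3
      "qtl:NAR3": 9.2e-4
      "qtl:NAR4": 9.0e-4
      "qtl_env:NAR1:DL": 6.6e-4
      "qtl_env:NAR2:TMEAN": 5.2e-4
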