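{
  "coefficients": {
    "d_e_fold": 0.30661664032539665,
    "d_nhbond_p1p2": -0.25654594459576446,
    "dd_evdw_site_all": 0.12808093743667645,
    "ddg_solv": 0.04134310404595291,
    "elec_mut_p1p2": -0.00590032331750593,
    "l_mut": -0.0022581200185435224,
    "location_mut": 0.6316409782990284,
    "nhbond_wt_site_all": 0.30695132531742975,
    "sa_ratio_com_p2": 0.0721603708729737
  },
  "intercept": 0.7207398129516219,
  "n_training": 219,
  "p_values": {
    "d_e_fold": 5.236281744399062e-08,
    "d_nhbond_p1p2": 4.5856646430115375e-12,
    "dd_evdw_site_all": 5.697152603822676e-07,
    "ddg_solv": 0.0064619115869600655,
    "elec_mut_p1p2": 0.04099566465950599,
    "l_mut": 0.006775082296592006,
    "location_mut": 2.804992033995348e-07,
    "nhbond_wt_site_all": 2.9680550225412198e-08,
    "sa_ratio_com_p2": 0.22717340761399013
  },
  "std_coefficients": {
    "d_e_fold": 0.2818554113605561,
    "d_nhbond_p1p2": -0.36244791603665,
    "dd_evdw_site_all": 0.25807542969793235,
    "ddg_solv": 0.13557084963439361,
    "elec_mut_p1p2": -0.10107191092186171,
    "l_mut": -0.1349864273933964,
    "location_mut": 0.26036155630741203,
    "nhbond_wt_site_all": 0.2882553205010964,
    "sa_ratio_com_p2": 0.0605982314052217
  },
  "training_r": 0.7109143929639864,
  "training_rmse": 0.8498654601523372,
  "training_slope": 0.5053992741233538
}
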