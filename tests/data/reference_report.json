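{
 "reports": [
  {
   "state": "baseline",
   "SV": 75.02905564560866,
   "EDV": 123.80022391764692,
   "ESV": 48.77116827203825,
   "EF": 60.60494340908358,
   "CO": 93.78631955701083,
   "MAP": 86.10916452704012,
   "max_flow": 727.4868967739816,
   "aSBP": 111.6848952987083,
   "aDBP": 53.324395754759905,
   "aPP": 58.36049954394839,
   "t_peak": 0.18846016036203625,
   "t_inflection": 0.21046016036203624,
   "P_inflection": 111.61117868722317,
   "AP": -0.07371661148512487,
   "AIx": -0.12631250942191224,
   "phenotype": "TypeC",
   "Zc": 0.037822559776917765,
   "amp_f": 34.40179116505149,
   "amp_b": 29.350405634238378,
   "peak_f": 61.07602764150154,
   "peak_b": 53.970439351235434,
   "t_peak_f": 0.10646016036203623,
   "max_slope_f": 888.1032749824044,
   "reflection_coefficient": 0.8531650428729776,
   "forward_fraction": 0.5894704711899392,
   "heart_Ees": 3.2,
   "heart_Vd": 15.0,
   "heart_P0": 2.3,
   "heart_beta": 0.013,
   "heart_Pfill": 11.5,
   "heart_period": 0.8,
   "heart_t_systole": 0.3,
   "CT": 0.96,
   "TPR": 0.9200000000002672
  },
  {
   "state": "banding",
   "SV": 74.90409533695177,
   "EDV": 131.50523722680947,
   "ESV": 56.60114188985769,
   "EF": 56.9590207329639,
   "CO": 93.6301191711897,
   "MAP": 111.79707378650092,
   "max_flow": 464.0265014017632,
   "aSBP": 154.9633279709869,
   "aDBP": 59.88597426798688,
   "aPP": 95.07735370300003,
   "t_peak": 0.23665009235531753,
   "t_inflection": 0.08365009235531749,
   "P_inflection": 143.0841451304378,
   "AP": 11.879182840549106,
   "AIx": 12.494229569805828,
   "phenotype": "TypeA",
   "Zc": 0.13846067593157146,
   "amp_f": 74.60177029128702,
   "amp_b": 45.88380304920709,
   "peak_f": 104.54475742528047,
   "peak_b": 70.22554065627048,
   "t_peak_f": 0.0976500923553175,
   "max_slope_f": 1355.0721881103564,
   "reflection_coefficient": 0.6150497886317049,
   "forward_fraction": 0.7846428974488072,
   "heart_Ees": 3.2,
   "heart_Vd": 10.0,
   "heart_P0": 2.3,
   "heart_beta": 0.013,
   "heart_Pfill": 12.711283333868028,
   "heart_period": 0.8,
   "heart_t_systole": 0.3,
   "CT": 0.58,
   "TPR": 1.1960000000003475
  },
  {
   "state": "remodeling",
   "SV": 75.04056137686212,
   "EDV": 118.209344335717,
   "ESV": 43.1687829588549,
   "EF": 63.48107402046437,
   "CO": 93.80070172107764,
   "MAP": 112.00369806429885,
   "max_flow": 502.111514664516,
   "aSBP": 153.70635117626261,
   "aDBP": 59.44058660200157,
   "aPP": 94.26576457426106,
   "t_peak": 0.11147362291221154,
   "t_inflection": 0.19047362291221154,
   "P_inflection": 152.688171625264,
   "AP": -1.0181795509986102,
   "AIx": -1.0801159419828443,
   "phenotype": "TypeC",
   "Zc": 0.13720194148011342,
   "amp_f": 79.15821134620138,
   "amp_b": 47.026631089071486,
   "peak_f": 108.87850464720216,
   "peak_b": 70.57029252090042,
   "t_peak_f": 0.08647362291221154,
   "max_slope_f": 1539.5134430070248,
   "reflection_coefficient": 0.5940840538121657,
   "forward_fraction": 0.8397344646140521,
   "heart_Ees": 4.364091252066525,
   "heart_Vd": 10.0,
   "heart_P0": 2.3,
   "heart_beta": 0.017729120711520257,
   "heart_Pfill": 18.702494795871218,
   "heart_period": 0.8,
   "heart_t_systole": 0.3,
   "CT": 0.58,
   "TPR": 1.1960000000003475
  }
 ],
 "remodeling": {
  "Ees_remodel": 4.364091252066525,
  "beta_remodel": 0.017729120711520257,
  "Pfill_remodel": 18.702494795871218,
  "sigma_target": 180.3647151659642,
  "sigma_final": 181.59643177499697,
  "iterations": 3,
  "trace": [
   [
    3.2,
    250.43963427412032
   ],
   [
    4.070280080324106,
    194.97544048235716
   ],
   [
    4.301083654691608,
    184.13929460626824
   ],
   [
    4.364091252066525,
    181.59643177499697
   ]
  ]
 }
}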