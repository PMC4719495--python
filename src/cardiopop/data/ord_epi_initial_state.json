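{
 "v": -87.93666176478882,
 "nai": 7.8766950266173,
 "nass": 7.876777382837007,
 "ki": 143.97727482886387,
 "kss": 143.97724218069752,
 "cai": 7.647548369393568e-05,
 "cass": 7.54425255963866e-05,
 "cansr": 2.0041573825812207,
 "cajsr": 1.9488313034962628,
 "m": 0.007392464043039941,
 "hf": 0.6958431403419448,
 "hs": 0.6958330015989769,
 "j": 0.6957743272887393,
 "hsp": 0.4523192061401362,
 "jp": 0.695733188362314,
 "mL": 0.00019060918789632304,
 "hL": 0.5020232007915472,
 "hLp": 0.27604874541854596,
 "a": 0.0010055080965328058,
 "iF": 0.9995491116077347,
 "iS": 0.999542054320585,
 "ap": 0.0005123346254099037,
 "iFp": 0.9995491119252056,
 "iSp": 0.9995476069565712,
 "d": 2.3771626614726184e-09,
 "ff": 0.999999990713013,
 "fs": 0.9228710201469139,
 "fcaf": 0.9999999907130517,
 "fcas": 0.9998906405349589,
 "jca": 0.9999846122784317,
 "nca": 0.0017447220152961098,
 "ffp": 0.9999999907112284,
 "fcafp": 0.9999999907113369,
 "xrf": 8.116407094457452e-06,
 "xrs": 0.42309077874784284,
 "xs1": 0.2413467317492955,
 "xs2": 0.00019423787643989138,
 "xk1": 0.9967767026548313,
 "Jrelnp": 4.612019644515489e-07,
 "Jrelp": 5.764051252938649e-07,
 "CaMKt": 0.015966235012607834
}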