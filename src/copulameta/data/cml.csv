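study,n_A,r1_A,r2_A,n_B,r1_B,r2_B,n2_A,n2_B
Cortes 2010,252,171,222,250,175,230,252,250
Kantarjian 2010,260,189,239,259,216,243,260,259
Radich 2012,61,42,117,70,59,118,123,123
Kantarjian 2011,243,184,267,236,219,276,283,281
Baccarani 2009,108,63,74,108,69,77,108,108
Preudhomme 2010,158,92,149,160,104,149,159,160
Hehlmann 2017,306,151,308,328,206,317,324,338
Cortes 2016,157,103,149,319,223,311,157,319
Deininger 2014,49,33,68,41,35,60,73,72
Wang 2015,133,107,125,134,104,124,133,134
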