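name,L_cm,d_open_s,d_closed_s,p,r_per_s,D_cm2_s,g_decimals,source_note
Saturniid silkworm,1.0,0.5,5.0,,,0.176,1,"open bouts < 1 s (taken 0.5 s) separated by 2-10 s (taken 5 s)"
Cataglyphis bicolor (abdominal),0.28,,,0.2,24,0.176,1,"r = 24 flutters/s measured; p = 0.2 assumed (not measured)"
Cataglyphis bicolor (thoracic),0.38,,,0.2,24,0.176,1,"r = 24 flutters/s measured; p = 0.2 assumed; longer path to head"
Gromphadorhina portentosa,1.6,,,0.28,2.33,0.176,1,"printed truncations of open 0.6 s / closed 1.5 s bouts"
Pine weevil (Hylobius abietis),0.3,,,0.2,0.1,0.176,2,"spiracles open/close about every 10 s; p = 0.2 assumed"
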