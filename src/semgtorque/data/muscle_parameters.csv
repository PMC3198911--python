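muscle,role,fmax_mean_N,fmax_sd_N,ma_mean_m,ma_sd_m,pcsa_cm2,represents,represents_pcsa_cm2
ECRL,extensor,84.0,16.8,-0.013,0.0026,2.4,,
EDC,extensor,119.0,23.8,-0.010,0.0020,3.4,EDM;EIP;EPL,0.9;0.6;1.0
ECU,extensor,119.0,23.8,-0.012,0.0024,3.4,,
ECRB,extensor,101.5,20.3,-0.016,0.0032,2.9,,
FCR,flexor,70.0,14.0,0.015,0.0030,2.0,,
PL,flexor,42.0,8.4,0.012,0.0024,1.2,FPL,2.1
FDS,flexor,217.0,43.4,0.012,0.0024,6.2,FDP,7.9
FCU,flexor,119.0,23.8,0.019,0.0038,3.4,,
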