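sample,sample_flow_ul_min,sheath_flow_ul_min,he_flow_mg_min,intra_train_mhz,pulses_per_train,trains_per_s,displacement_um,beam_x_um,beam_y_um,photon_energy_kev
HEWL,30.0,NA,27.0,0.564,202,10,79.3,3.5,3.5,11.0
HEWL+water,20.0,10.0,31.0,1.128,100,10,41.6,0.6,0.6,11.0
HEWL+PEO,20.0,10.0,28.5,1.128,352,10,38.5,0.6,0.6,11.0
PSI,30.0,NA,33.0,1.128,352,10,40.1,0.6,0.6,9.3
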