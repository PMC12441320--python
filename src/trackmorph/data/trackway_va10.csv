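trackway_id,track_id,foot,x_cm,y_cm,axis_bearing_deg,L_cm
VA10,VA10-1,left,0.0,0.0,354.44,35.75
VA10,VA10-2,right,10.259,104.4976,5.52,33.95
VA10,VA10-3,left,0.0,210.0,n/a,32.79
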