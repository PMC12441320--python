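trackway_id,track_id,foot,x_cm,y_cm,axis_bearing_deg,L_cm
SM.1976.2004.002a,2004.002a-1,right,0.0,0.0,342.93,9.82
SM.1976.2004.002a,2004.002a-2,left,7.9743,25.9211,16.83,10.77
SM.1976.2004.002a,2004.002a-3,right,0.0,52.25,n/a,10.25
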