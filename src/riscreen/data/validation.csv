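pesticide,slope,intercept,r_squared,lod_ugL,loq_ugL,rsd_interday_pct,rsd_intraday_pct
Chlorpyrifos,402,3550,0.9991,0.0225,0.0964,1.97,2.98
Fipronil,291,-1380,0.9996,0.0155,0.0565,1.44,3.17
Procymidone,594,2910,0.9993,0.0088,0.0354,1.63,3.82
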