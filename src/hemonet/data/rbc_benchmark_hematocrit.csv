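kind,bifurcation,channel,mean_hct_pct,se_pct
EDT,1,0,20.06,0.03
EDT,1,1,19.23,0.14
EDT,1,2,20.80,0.10
DT,1,0,20.08,0.06
DT,1,1,19.96,0.19
DT,1,2,20.26,0.05
X,1,0,20.06,0.02
X,1,1,19.67,0.09
X,1,2,20.35,0.20
EDT,2,1,19.23,0.14
EDT,2,3,19.05,0.22
EDT,2,4,19.40,0.23
DT,2,1,19.96,0.19
DT,2,3,16.83,0.24
DT,2,4,23.04,0.46
X,2,1,19.67,0.09
X,2,3,22.12,0.26
X,2,4,17.09,0.13
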