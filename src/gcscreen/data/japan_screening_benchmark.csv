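# Published lifetime cost-effectiveness estimates for 15 endoscopic gastric
# cancer screening strategies in Japan (per 1000 individuals; costs in
# $1000s, 2015 US$, discounted 3%/yr; deaths and endoscopies undiscounted).
# icer_printed is the published frontier ICER in $/QALY; empty = dominated
# or anchor.
strategy,gc_deaths_per_1000,gc_mortality_reduction_pct,endoscopies_per_1000,qalys_gained_per_1000,cost_per_1000_thousands,icer_printed
none,9.1,0.0,810,0.0,693,
50-none-3,2.3,74.8,14516,30.1,2247,
50-none-2,1.8,80.5,21379,28.1,3091,
50-75-2,3.0,67.3,14873,25.9,2662,
50-80-2,2.5,72.3,16666,27.4,2798,
45-75-2,2.7,70.3,17237,26.4,3263,
45-80-2,2.0,77.9,19928,28.6,3465,
40-75-2,2.5,72.7,20559,25.5,4064,
40-80-2,2.0,77.6,22358,26.7,4199,
50-75-3,3.4,63.0,9694,27.2,1934,45665
50-80-3,2.8,69.1,11507,29.4,2066,60731
45-75-3,3.0,67.6,11907,30.9,2380,
45-80-3,2.4,73.7,13660,32.7,2504,130149
40-75-3,2.8,69.6,14101,31.1,2909,
40-80-3,2.4,73.4,15024,31.5,2975,
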