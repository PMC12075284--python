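# SYNTHETIC ex vivo master curve (placeholder, not measured data):
# generated from a two-term Prony material and scaled by 0.5;
# substitute a measured curve (columns below) for real use.
frequency_hz,gprime_pa,gdoubleprime_pa
0.05,750.217,14.5657
0.107107,750.993,31.1759
0.229439,754.539,66.5284
0.491491,770.45,140.065
1.05284,836.632,278.233
2.25534,1044.03,449.887
4.83126,1367.34,481.024
10.3493,1581.46,410.3
22.1696,1737.41,434.385
47.4904,2010.34,493.217
101.731,2312.06,386.093
217.923,2450.86,213.872
466.822,2488.8,104.137
1000,2497.54,49.0751
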