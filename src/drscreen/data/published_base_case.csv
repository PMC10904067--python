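# Externally published base-case summary (one-off screening, 2020 USD):
# incremental cost and QALYs per person and the reported ICUR for each
# pairwise comparison.  Used only to cross-check the ICUR arithmetic.
setting,comparison,incremental_cost,incremental_qaly,icur
rural,community_vs_none,14.29,0.00342,4178.51
rural,telemedicine_vs_none,21.23,0.00914,2323.04
rural,telemedicine_vs_community,6.93,0.00572,1211.93
urban,community_vs_none,17.81,0.00467,3812.91
urban,telemedicine_vs_none,23.47,0.00963,2437.28
urban,telemedicine_vs_community,5.66,0.00496,1141.13
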