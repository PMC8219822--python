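year,participants_total,participants_women_only,participants_men_only,participants_both_women,participants_both_men
2010,1442,71,945,174,252
2011,2080,173,1189,275,443
2012,3109,211,2439,142,317
2013,2009,97,1010,469,433
2014,2859,112,2012,238,497
2015,3240,179,1716,489,856
2016,2667,104,1213,623,727
2017,2959,69,1304,584,1002
2018,4102,304,2594,419,785
2019,3563,488,1463,676,936
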