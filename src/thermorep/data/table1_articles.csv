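year,articles_total,articles_women_only,articles_men_only,articles_both
2010,95,5,69,21
2011,120,6,88,26
2012,108,7,81,20
2013,117,6,79,32
2014,162,8,126,28
2015,167,6,120,41
2016,134,4,96,34
2017,162,6,103,53
2018,166,11,111,44
2019,176,15,106,55
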