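species,clade,p50_mpa,p50_ci_lo,p50_ci_hi,n_p50,pmaxrate_mpa,pmax_ci_lo,pmax_ci_hi,n_pmax
Amelanchier ovalis,angiosperm,-5.45,-6.18,-4.72,5,-8.21,-8.60,-7.82,6
Berberis vulgaris,angiosperm,-5.74,-6.31,-5.17,4,-7.03,-7.55,-6.52,5
Dysoxylum papuanum,angiosperm,-2.63,-2.97,-2.34,21,-2.18,-2.81,-1.55,3
Elaeocarpus grandis,angiosperm,-3.05,-3.41,-2.63,21,-2.94,-3.48,-2.41,3
Hedera helix,angiosperm,-1.81,-2.19,-1.51,18,-2.09,-2.50,-1.69,3
Lonicera xylosteum,angiosperm,-3.89,-4.34,-3.44,5,-5.90,-6.26,-5.53,5
Malus domestica var. Braeburn,angiosperm,-3.46,-3.75,-3.17,49,-4.44,-4.77,-4.11,4
Malus domestica var. Golden Delicious,angiosperm,-3.81,-4.05,-3.57,46,-4.69,-4.97,-4.40,5
Malus domestica var. Red Delicious,angiosperm,-2.73,-2.93,-2.53,40,-4.45,-4.92,-3.98,4
Populus alba,angiosperm,-1.50,-1.60,-1.39,92,-2.27,-2.71,-1.84,5
Populus tremula,angiosperm,-2.19,-2.33,-2.04,56,-3.29,-3.75,-2.82,8
Quercus petraea,angiosperm,-2.38,-2.64,-2.10,35,-1.69,-1.92,-1.47,3
Sorbus aucuparia,angiosperm,-3.19,-3.36,-3.01,33,-3.32,-3.67,-2.97,3
Syzygium sayeri,angiosperm,-2.10,-2.47,-1.87,19,-2.53,,,2
Viburnum lantana,angiosperm,-6.41,-6.55,-6.27,4,-7.79,-9.03,-6.54,4
Juniperus communis,gymnosperm,-5.96,-6.51,-5.41,5,-5.61,-5.90,-5.32,13
Picea abies,gymnosperm,-3.71,-3.81,-3.59,127,-3.21,-3.32,-3.11,3
Pinus mugo,gymnosperm,-3.82,-3.94,-3.70,3,-2.58,-2.85,-2.31,5
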