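# Reference two-factor loading pattern for the ten personality items,
# per study cohort (varimax-rotated ML solutions; h2 = communality).
item,study,factor1,factor2,h2
sociable,2,0.826,0.013,0.682
kind,2,0.822,-0.105,0.686
friendly,2,0.780,-0.040,0.610
easygoing,2,0.779,-0.029,0.608
aggressive,2,-0.605,0.161,0.393
trustworthy,2,0.018,0.798,0.637
confident,2,0.022,0.684,0.469
independent,2,-0.275,0.662,0.514
intelligent,2,0.030,0.620,0.386
mature,2,-0.321,0.506,0.359
sociable,3,0.843,-0.054,0.713
kind,3,0.868,-0.119,0.767
friendly,3,0.816,-0.033,0.667
easygoing,3,0.843,-0.188,0.745
aggressive,3,-0.703,0.251,0.557
trustworthy,3,-0.024,0.743,0.552
confident,3,-0.064,0.713,0.513
independent,3,-0.316,0.687,0.572
intelligent,3,0.012,0.752,0.565
mature,3,-0.298,0.573,0.417
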